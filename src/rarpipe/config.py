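"""Configuration objects for cohort simulation and pipeline runs.

All tunables of the synthetic cohort generator live in
:class:`SimulationConfig`.  Defaults emulate a five-wave post-treatment
cohort of colorectal-cancer survivors wearing a thigh accelerometer for
seven consecutive 24-h days per wave: minute-level activity counts follow
a 24-h cosinor with person-level heterogeneity, waking time is partitioned
into sedentary / standing / activity bouts, in-bed counts are attenuated,
and configurable exposure->rhythm effects are embedded in the truth panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "RhythmDefaults",
    "BehaviorDefaults",
    "SimulationConfig",
    "DEFAULT_TRUTH_EFFECTS",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a simulation or run configuration violates an invariant."""


#: Raw-scale slopes (outcome units per additional hour/day of the exposure)
#: embedded in the truth panel.  Magnitudes correspond to standardized
#: coefficients of roughly -0.59 SD per 2 h/day sedentary time on the mesor
#: (population SDs: mesor 0.17, amplitude 0.18, dichotomy index 0.11).
DEFAULT_TRUTH_EFFECTS: dict[str, dict[str, float]] = {
    "sedentary": {"mesor": -0.0502, "amplitude": -0.0675, "dichotomy_index": -0.0468},
    "standing": {"mesor": 0.0697, "amplitude": 0.0720, "dichotomy_index": 0.0649},
    "total_activity": {"mesor": 0.2023, "amplitude": 0.2232, "dichotomy_index": 0.1221},
    "mvpa": {"mesor": 0.0306, "amplitude": 0.0378, "dichotomy_index": 0.0143},
    "lpa": {},
}

#: Outcomes the generator can parameterise directly.
EMBEDDABLE_OUTCOMES = ("mesor", "amplitude", "acrophase", "dichotomy_index")


@dataclass(frozen=True)
class RhythmDefaults:
    """Population distribution of the diurnal rhythm parameters.

    ``mesor``/``amplitude`` are on the (arbitrary) activity-count scale;
    ``acrophase`` is a clock hour in [0, 24).  ``inbed_attenuation`` is the
    multiplicative suppression of expected counts while in bed (it is
    re-solved per participant-visit so that the model-implied dichotomy
    index hits its linear truth target).  ``noise_sigma`` is the SD of the
    mean-one lognormal minute-count noise.
    """

    mesor_mean: float = 3.7
    mesor_sd: float = 0.10
    amplitude_mean: float = 0.6
    amplitude_sd: float = 0.10
    acrophase_mean: float = 14.2
    acrophase_sd: float = 1.05
    acrophase_visit_sd: float = 0.25
    dichotomy_mean: float = 0.85
    inbed_attenuation: float = 0.6
    noise_sigma: float = 0.30


@dataclass(frozen=True)
class BehaviorDefaults:
    """Mean hours/day of waking behaviors and their bout micro-structure.

    Waking time is an alternating-renewal (semi-Markov) process over
    {sedentary, standing, activity} with geometric bout lengths (minutes).
    ``*_mult`` are relative count multipliers per behavior state; they are
    renormalised per participant-visit to have mean one under that visit's
    behavior composition, so the cosinor curve stays the expected count.
    """

    sedentary_h: float = 10.8
    sedentary_sd: float = 1.3
    standing_h: float = 3.0
    standing_sd: float = 0.8
    activity_h: float = 1.5
    activity_sd: float = 0.5
    within_person_sd: float = 0.45  # visit-to-visit SD of each behavior, h/day
    sedentary_bout_mean_min: float = 22.0
    standing_bout_mean_min: float = 6.0
    activity_bout_mean_min: float = 5.0
    sedentary_mult: float = 0.8
    standing_mult: float = 1.3
    activity_mult: float = 3.5
    # self-reported exposures (lognormal on h/day)
    lpa_log_mean: float = 0.10
    lpa_log_sd: float = 1.0
    mvpa_log_mean: float = 0.0
    mvpa_log_sd: float = 0.8
    # bed schedule (clock hours)
    bed_start_mean: float = 23.25
    bed_start_sd: float = 0.5
    wake_mean: float = 7.5
    wake_sd: float = 0.5
    day_jitter_sd: float = 0.3  # night-to-night jitter of bed/wake times


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_participants: int = 268
    visit_labels: tuple[str, ...] = ("6w", "6m", "12m", "24m", "60m")
    #: fraction of the enrolled cohort still measured at each visit
    retention_per_visit: tuple[float, ...] = (
        1.0,
        254 / 268,
        214 / 268,
        138 / 268,
        77 / 268,
    )
    visit_days_since_treatment: tuple[float, ...] = (42, 183, 365, 730, 1826)
    days_per_visit: int = 7
    epoch_length: int = 60  # seconds
    sample_rate: float = 25.0  # Hz
    nonwear_rate: float = 0.37  # expected non-wear episodes per week
    nonwear_duration_mean_h: float = 2.0
    truth_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUTH_EFFECTS.items()}
    )
    rhythm: RhythmDefaults = field(default_factory=RhythmDefaults)
    behavior: BehaviorDefaults = field(default_factory=BehaviorDefaults)
    seed: int = 0

    # -- validation ------------------------------------------------------
    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if len(self.visit_labels) != len(self.retention_per_visit):
            raise ConfigurationError("visit_labels and retention_per_visit differ in length")
        if len(self.visit_labels) != len(self.visit_days_since_treatment):
            raise ConfigurationError("visit_labels and visit_days_since_treatment differ in length")
        prev = 1.0 + 1e-12
        for r in self.retention_per_visit:
            if not 0.0 < r <= 1.0:
                raise ConfigurationError(f"retention fraction {r} outside (0, 1]")
            if r > prev + 1e-12:
                raise ConfigurationError("retention_per_visit must be non-increasing")
            prev = r
        if self.days_per_visit < 1:
            raise ConfigurationError("days_per_visit must be >= 1")
        spe = self.sample_rate * self.epoch_length
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigurationError("sample_rate * epoch_length must be an integer")
        if self.nonwear_rate < 0:
            raise ConfigurationError("nonwear_rate must be >= 0")
        for exposure, effects in self.truth_effects.items():
            for outcome, slope in effects.items():
                if outcome not in EMBEDDABLE_OUTCOMES:
                    raise ConfigurationError(
                        f"truth effect {exposure}->{outcome}: outcome not embeddable "
                        f"(choose from {EMBEDDABLE_OUTCOMES})"
                    )
                float(slope)
        if self.rhythm.amplitude_mean >= self.rhythm.mesor_mean:
            raise ConfigurationError("amplitude must be < mesor (counts are non-negative)")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sample_rate * self.epoch_length))

    @property
    def n_visits(self) -> int:
        return len(self.visit_labels)

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth_effects"] = {k: dict(v) for k, v in self.truth_effects.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "rhythm" in d and isinstance(d["rhythm"], Mapping):
            d["rhythm"] = RhythmDefaults(**d["rhythm"])
        if "behavior" in d and isinstance(d["behavior"], Mapping):
            d["behavior"] = BehaviorDefaults(**d["behavior"])
        for key in ("visit_labels", "retention_per_visit", "visit_days_since_treatment"):
            if key in d and isinstance(d[key], Sequence) and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config(seed: int = 0) -> SimulationConfig:
    """A small three-wave cohort that runs end to end in a few minutes."""
    return SimulationConfig(
        n_participants=40,
        visit_labels=("6w", "6m", "12m"),
        retention_per_visit=(1.0, 0.9, 0.8),
        visit_days_since_treatment=(42, 183, 365),
        seed=seed,
    )
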