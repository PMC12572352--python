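"""Synthetic cohort generator: raw tri-axial signal, bed logs, covariates.

The generator emulates a five-wave prospective accelerometer cohort with a
known ground truth.  For every participant-visit it draws

* behavior composition (hours/day sedentary / standing / activity during
  waking time, realised as an alternating-renewal bout process),
* diurnal rhythm parameters (mesor M*, amplitude A*, acrophase phi* of a
  24-h cosinor on the activity-count scale),
* an in-bed attenuation factor solved numerically so that the
  model-implied dichotomy index equals a truth target that is *exactly
  linear* in the exposures (the embedded exposure->rhythm effects),

and can then synthesise a 25 Hz tri-axial acceleration week whose 1-min
signal-magnitude-area counts follow the cosinor curve modulated by the
behavior bouts, multiplicative lognormal noise, and in-bed attenuation.

Randomness is fanned out from a single seed through named
``numpy.random.SeedSequence`` substreams keyed by (participant, visit,
day, purpose), so regenerating a participant is independent of cohort
size and bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr  # fast standard-normal CDF

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "BedTimeLog",
    "DaySignal",
    "RawAccelRecording",
    "Cohort",
    "generate_cohort",
    "simulate_day_counts",
    "counts_to_signal",
    "synthesize_day_signal",
    "inject_nonwear",
    "cosinor_curve",
]

MINUTES_PER_DAY = 1440
#: frequency of the synthetic body-movement oscillation (Hz); one epoch at
#: the default 25 Hz / 60 s holds an integer number of cycles, so the
#: dynamic component has exactly zero mean per epoch.
WAVE_FREQ = 2.0
#: calendar anchor for synthetic recordings (a Monday)
EPOCH_DATE = dt.date(2015, 1, 5)

STATE_SED, STATE_STAND, STATE_ACT, STATE_INBED = 0, 1, 2, 3
STATE_NAMES = np.array(["sedentary", "standing", "activity", "in_bed"])


# ---------------------------------------------------------------------------
# small numerical helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: independent of cohort size, stable across runs."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def cosinor_curve(hours: np.ndarray, mesor: float, amplitude: float, acrophase: float) -> np.ndarray:
    """Expected count at clock time ``hours``: M + A cos(2 pi (t - phi)/24)."""
    return mesor + amplitude * np.cos(2 * np.pi * (np.asarray(hours, float) - acrophase) / 24.0)


def _minute_hours() -> np.ndarray:
    return (np.arange(MINUTES_PER_DAY) + 0.5) / 60.0


def _implied_dichotomy(kappa: float, inbed_means: np.ndarray, out_median: float, sigma: float) -> float:
    """Model-implied P(in-bed count < out-of-bed median) for attenuation ``kappa``."""
    m = kappa * np.asarray(inbed_means, float)
    if sigma <= 0:
        return float(np.mean(m < out_median))
    z = (np.log(out_median) - (np.log(m) - sigma**2 / 2.0)) / sigma
    return float(ndtr(z).mean())


def _solve_attenuation(target: float, inbed_means: np.ndarray, out_median: float, sigma: float) -> float:
    """Invert the dichotomy-index map: find kappa with implied I<O = target."""
    lo, hi = 1e-4, 2.0  # I<O decreasing in kappa
    if _implied_dichotomy(lo, inbed_means, out_median, sigma) < target:
        return lo
    if _implied_dichotomy(hi, inbed_means, out_median, sigma) > target:
        return hi
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if _implied_dichotomy(mid, inbed_means, out_median, sigma) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _project_cosinor(values: np.ndarray) -> tuple[float, float, float]:
    """Least-squares harmonic projection of a 1440-minute profile."""
    t = _minute_hours()
    w = 2 * np.pi / 24.0
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, np.asarray(values, float), rcond=None)
    m, bc, bs = beta
    amp = float(np.hypot(bc, bs))
    phi = float(np.arctan2(bs, bc) / w % 24.0)
    return float(m), amp, phi


# ---------------------------------------------------------------------------
# bed-time log
# ---------------------------------------------------------------------------

@dataclass
class BedTimeLog:
    """Self-reported bed and wake times, one row per calendar day.

    ``frame`` columns: ``date`` (datetime.date), ``wake_h`` and ``bed_h``
    (decimal clock hours).  Within each 24-h calendar day the in-bed
    minutes are [00:00, wake) plus [bed, 24:00); the two never overlap
    because wake < bed.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if not {"date", "wake_h", "bed_h"}.issubset(f.columns):
            raise ValueError("bed log requires columns date, wake_h, bed_h")
        if bool((f["wake_h"] >= f["bed_h"]).any()):
            raise ValueError("wake time must precede bed time within each calendar day")

    def in_bed_mask(self, date: dt.date) -> np.ndarray | None:
        """Boolean per-minute mask for one calendar day; None if unlogged."""
        rows = self.frame[self.frame["date"] == date]
        if rows.empty:
            return None
        wake_m = int(round(rows.iloc[0]["wake_h"] * 60))
        bed_m = int(round(rows.iloc[0]["bed_h"] * 60))
        mask = np.zeros(MINUTES_PER_DAY, bool)
        mask[:wake_m] = True
        mask[bed_m:] = True
        return mask

    @property
    def dates(self) -> list[dt.date]:
        return list(self.frame["date"])


# ---------------------------------------------------------------------------
# raw-signal containers
# ---------------------------------------------------------------------------

@dataclass
class DaySignal:
    """One calendar day of raw tri-axial signal (g units) with wear flags."""

    date: dt.date
    sample_rate: float
    acc: np.ndarray  # (n_samples, 3) float32
    wear: np.ndarray  # (n_samples,) bool

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]


@dataclass
class RawAccelRecording:
    """A participant-visit week of raw signal, stored day-chunked."""

    participant_id: str
    visit: str
    sample_rate: float
    days: list[DaySignal] = field(default_factory=list)

    @property
    def start_date(self) -> dt.date:
        return self.days[0].date

    def to_frame(self) -> pd.DataFrame:
        """Materialise as a timestamped long table (large: ~2.2M rows/day)."""
        parts = []
        for day in self.days:
            t0 = pd.Timestamp(day.date)
            ts = t0 + pd.to_timedelta(np.arange(day.n_samples) / day.sample_rate, unit="s")
            parts.append(
                pd.DataFrame(
                    {
                        "timestamp": ts,
                        "ax": day.acc[:, 0],
                        "ay": day.acc[:, 1],
                        "az": day.acc[:, 2],
                        "wear_flag": day.wear.astype(int),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# minute-level day simulation
# ---------------------------------------------------------------------------

def _sample_bout_states(
    n_minutes: int,
    shares: np.ndarray,
    bout_means: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating-renewal sampler over {sedentary, standing, activity}.

    Bout lengths are geometric (minutes) with the configured means; the
    embedded jump chain visits states proportionally to share/mean-length,
    which makes long-run time shares track ``shares`` approximately.
    """
    shares = np.maximum(np.asarray(shares, float), 1e-9)
    shares = shares / shares.sum()
    rates = shares / bout_means  # visit rates of the jump chain
    out = np.empty(n_minutes, dtype=np.int8)
    pos = 0
    state = int(rng.choice(3, p=shares))
    while pos < n_minutes:
        length = int(rng.geometric(min(1.0, 1.0 / bout_means[state])))
        end = min(pos + length, n_minutes)
        out[pos:end] = state
        pos = end
        w = rates.copy()
        w[state] = 0.0
        w = w / w.sum()
        state = int(rng.choice(3, p=w))
    return out


def simulate_day_counts(
    mesor: float,
    amplitude: float,
    acrophase: float,
    in_bed: np.ndarray,
    *,
    shares: np.ndarray | None = None,
    bout_means: np.ndarray | None = None,
    multipliers: np.ndarray | None = None,
    attenuation: float = 1.0,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one day of 1-min activity counts.

    Returns ``(counts, states)`` where ``states`` codes sedentary=0,
    standing=1, activity=2, in-bed=3.  Expected waking count at minute t
    is the cosinor curve (behavior multipliers are renormalised to mean
    one under ``shares``); expected in-bed count is ``attenuation`` times
    the curve; noise is mean-one lognormal with SD parameter ``sigma``.
    """
    if amplitude >= mesor:
        raise ConfigurationError("amplitude >= mesor would force negative expected counts")
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    rng = rng or np.random.default_rng(0)
    in_bed = np.asarray(in_bed, bool)
    curve = cosinor_curve(_minute_hours(), mesor, amplitude, acrophase)

    states = np.full(MINUTES_PER_DAY, STATE_INBED, dtype=np.int8)
    mult = np.ones(MINUTES_PER_DAY)
    waking = ~in_bed
    if shares is not None and waking.any():
        shares = np.asarray(shares, float)
        bout_means = np.asarray(bout_means if bout_means is not None else [22.0, 6.0, 5.0], float)
        multipliers = np.asarray(multipliers if multipliers is not None else [0.8, 1.3, 3.5], float)
        seq = _sample_bout_states(int(waking.sum()), shares, bout_means, rng)
        states[waking] = seq
        # normalise by the realised day's mean multiplier so the waking
        # modulation has exactly unit mean every day (the sampler's
        # stationary shares only approximate the targets)
        norm = float(multipliers[seq].mean())
        mult[waking] = multipliers[seq] / norm
    else:
        states[waking] = STATE_SED

    mean_counts = curve * mult
    mean_counts[in_bed] = attenuation * curve[in_bed]
    if sigma > 0:
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, MINUTES_PER_DAY))
        counts = mean_counts * noise
    else:
        counts = mean_counts.copy()
    return counts, states


# ---------------------------------------------------------------------------
# counts -> raw 25 Hz tri-axial signal
# ---------------------------------------------------------------------------

def _wave_abs_mean(samples_per_epoch: int, sample_rate: float) -> float:
    """Discrete mean of |sin| of the movement waveform over one epoch."""
    n = np.arange(samples_per_epoch)
    return float(np.abs(np.sin(2 * np.pi * WAVE_FREQ * n / sample_rate)).mean())


def counts_to_signal(
    counts: np.ndarray,
    states: np.ndarray,
    *,
    sample_rate: float = 25.0,
    epoch_length: int = 60,
    calibration: float = 1.0,
    dtype=np.float32,
) -> np.ndarray:
    """Render minute counts as a raw tri-axial day signal (g units).

    The dynamic (movement) component is a ``WAVE_FREQ`` Hz sinusoid on the
    anterior axis whose per-minute amplitude is chosen so that the
    signal-magnitude-area count of the epoch reproduces ``counts``
    exactly (to float precision) under epoch-mean gravity removal.  The
    static component encodes posture: thigh vertical (gravity on the
    longitudinal x axis) while upright, thigh horizontal (gravity on z)
    while sitting/lying or in bed.
    """
    counts = np.asarray(counts, float)
    states = np.asarray(states)
    spe = int(round(sample_rate * epoch_length))
    n_min = counts.size
    n = n_min * spe
    abs_mean = _wave_abs_mean(spe, sample_rate)
    amp_per_min = counts / (calibration * abs_mean)

    # WAVE_FREQ * epoch_length is an integer, so the waveform repeats
    # identically every epoch: build one epoch and broadcast per minute.
    wave = np.sin(2 * np.pi * WAVE_FREQ * np.arange(spe) / sample_rate).astype(dtype)

    upright = (states == STATE_STAND) | (states == STATE_ACT)
    gx = np.where(upright, -1.0, 0.0).astype(dtype)
    gz = np.where(upright, 0.0, 1.0).astype(dtype)

    az = amp_per_min[:, None].astype(dtype) * wave[None, :]
    az += gz[:, None]
    acc = np.empty((n, 3), dtype=dtype)
    acc[:, 0] = np.repeat(gx, spe)
    acc[:, 1] = 0.0
    acc[:, 2] = az.ravel()
    return acc


def synthesize_day_signal(
    mesor: float,
    amplitude: float,
    acrophase: float,
    in_bed: np.ndarray,
    date: dt.date = EPOCH_DATE,
    *,
    sample_rate: float = 25.0,
    epoch_length: int = 60,
    calibration: float = 1.0,
    dtype=np.float32,
    rng: np.random.Generator | None = None,
    **day_kwargs,
) -> tuple[DaySignal, np.ndarray, np.ndarray]:
    """One synthetic day: raw signal plus the minute counts/states used."""
    counts, states = simulate_day_counts(
        mesor, amplitude, acrophase, in_bed, rng=rng, **day_kwargs
    )
    acc = counts_to_signal(
        counts,
        states,
        sample_rate=sample_rate,
        epoch_length=epoch_length,
        calibration=calibration,
        dtype=dtype,
    )
    day = DaySignal(date=date, sample_rate=sample_rate, acc=acc, wear=np.ones(acc.shape[0], bool))
    return day, counts, states


# ---------------------------------------------------------------------------
# non-wear injection
# ---------------------------------------------------------------------------

def inject_nonwear(
    recording: RawAccelRecording,
    rate_per_week: float,
    duration_mean_h: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> RawAccelRecording:
    """Flag Poisson-process non-wear episodes; all samples stay unchanged.

    Episode count over the recording is Poisson with mean
    ``rate_per_week * n_days / 7``; episode starts are uniform over the
    recording and durations exponential with mean ``duration_mean_h``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_days = len(recording.days)
    out = RawAccelRecording(
        participant_id=recording.participant_id,
        visit=recording.visit,
        sample_rate=recording.sample_rate,
        days=[
            DaySignal(d.date, d.sample_rate, d.acc, d.wear.copy()) for d in recording.days
        ],
    )
    if rate_per_week <= 0 or n_days == 0:
        return out
    n_episodes = rng.poisson(rate_per_week * n_days / 7.0)
    fs = recording.sample_rate
    total = sum(d.n_samples for d in out.days)
    for _ in range(n_episodes):
        start = rng.uniform(0, total)
        dur = rng.exponential(duration_mean_h) * 3600.0 * fs
        lo, hi = int(start), int(min(start + dur, total))
        offset = 0
        for day in out.days:
            a = max(lo - offset, 0)
            b = min(hi - offset, day.n_samples)
            if a < b:
                day.wear[a:b] = False
            offset += day.n_samples
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_VISIT_BEHAVIOR_TREND = {"sedentary": -0.55, "standing": 0.45, "activity": 0.25}


def _draw_participants(cfg: SimulationConfig) -> pd.DataFrame:
    """Fixed covariates plus person-level latent bases, one row per person."""
    n = cfg.n_participants
    rng = _rng(cfg.seed, 0)
    beh, rhy = cfg.behavior, cfg.rhythm
    edu = rng.choice(["low", "medium", "high"], size=n, p=[0.27, 0.38, 0.35])
    smoking = rng.choice(["current", "former", "never"], size=n, p=[0.09, 0.60, 0.31])
    comorb = rng.choice(["0", "1", "2+"], size=n, p=[0.20, 0.26, 0.54])
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": np.clip(rng.normal(66.8, 8.9, n), 30, 92).round(1),
            "sex": np.where(rng.random(n) < 0.668, "male", "female"),
            "education": edu,
            "neoadjuvant": rng.random(n) < 0.26,
            "adjuvant_chemo": rng.random(n) < 0.38,
            "smoking_base": smoking,
            "comorbidity_base": comorb,
            "employment_base": rng.random(n) < 0.30,
            "stoma_base": rng.random(n) < 0.28,
            "bmi_base": np.clip(rng.normal(27.5, 4.4, n), 17, 45),
            "dropout_u": rng.random(n),  # monotone MCAR dropout latent
            # latent behavior and rhythm bases
            "sed_base": np.clip(rng.normal(beh.sedentary_h, beh.sedentary_sd, n), 5, 16),
            "stand_base": np.clip(rng.normal(beh.standing_h, beh.standing_sd, n), 0.5, 7),
            "act_base": np.clip(rng.normal(beh.activity_h, beh.activity_sd, n), 0.2, 5),
            "lpa_base": np.exp(rng.normal(beh.lpa_log_mean, beh.lpa_log_sd, n)),
            "mvpa_base": np.exp(rng.normal(beh.mvpa_log_mean, beh.mvpa_log_sd, n)),
            "mesor_base": rng.normal(rhy.mesor_mean, rhy.mesor_sd, n),
            "amp_base": np.clip(rng.normal(rhy.amplitude_mean, rhy.amplitude_sd, n), 0.15, None),
            "phi_base": (rng.normal(rhy.acrophase_mean, rhy.acrophase_sd, n)) % 24.0,
            "io_base": np.clip(rng.normal(rhy.dichotomy_mean, 0.08, n), 0.35, 0.985),
            "bed_start_base": np.clip(
                rng.normal(beh.bed_start_mean, beh.bed_start_sd, n), 21.5, 23.95
            ),
            "wake_base": np.clip(rng.normal(beh.wake_mean, beh.wake_sd, n), 5.5, 10.0),
        }
    )
    return df


def _truth_panel(cfg: SimulationConfig, participants: pd.DataFrame) -> pd.DataFrame:
    """One row per attended participant-visit with all truth quantities."""
    beh, rhy = cfg.behavior, cfg.rhythm
    mults = np.array([beh.sedentary_mult, beh.standing_mult, beh.activity_mult])
    exposure_means = {
        "sedentary": beh.sedentary_h,
        "standing": beh.standing_h,
        "total_activity": beh.activity_h,
        "lpa": np.exp(beh.lpa_log_mean),
        "mvpa": np.exp(beh.mvpa_log_mean),
    }
    hours = _minute_hours()
    rows = []
    for i, p in participants.iterrows():
        for j, label in enumerate(cfg.visit_labels):
            if p["dropout_u"] >= cfg.retention_per_visit[j]:
                continue
            vr = _rng(cfg.seed, 1, i, j)
            days_since = float(cfg.visit_days_since_treatment[j] + vr.integers(-10, 11))
            bed_start = float(np.clip(p["bed_start_base"] + vr.normal(0, 0.15), 21.5, 23.95))
            wake = float(np.clip(p["wake_base"] + vr.normal(0, 0.15), 5.0, 10.5))
            waking_h = bed_start - wake

            trend = 0.0 if j == 0 else 1.0
            sed = p["sed_base"] + trend * _VISIT_BEHAVIOR_TREND["sedentary"] + vr.normal(0, beh.within_person_sd)
            stand = p["stand_base"] + trend * _VISIT_BEHAVIOR_TREND["standing"] + vr.normal(0, beh.within_person_sd / 2)
            act = p["act_base"] + trend * _VISIT_BEHAVIOR_TREND["activity"] + vr.normal(0, beh.within_person_sd / 3)
            raw = np.maximum([sed, stand, act], 0.05)
            scale = waking_h / raw.sum()
            sed, stand, act = raw * scale
            shares = np.array([sed, stand, act]) / waking_h

            lpa = float(p["lpa_base"] * np.exp(vr.normal(0, 0.25)))
            mvpa = float(p["mvpa_base"] * np.exp(vr.normal(0, 0.25)))
            x = {
                "sedentary": sed,
                "standing": stand,
                "total_activity": act,
                "lpa": lpa,
                "mvpa": mvpa,
            }

            def _effect(outcome: str) -> float:
                tot = 0.0
                for exp_name, eff in cfg.truth_effects.items():
                    if outcome in eff:
                        tot += eff[outcome] * (x[exp_name] - exposure_means[exp_name])
                return tot

            mesor = float(p["mesor_base"] + _effect("mesor"))
            amp = float(np.clip(p["amp_base"] + _effect("amplitude"), 0.05, 0.9 * mesor))
            phi = float((p["phi_base"] + _effect("acrophase") + vr.normal(0, rhy.acrophase_visit_sd)) % 24.0)
            io_target = float(p["io_base"] + _effect("dichotomy_index"))
            io_clipped = not (0.05 <= io_target <= 0.995)
            io_target = float(np.clip(io_target, 0.05, 0.995))

            # model-implied quantities for this visit's mean bed window
            in_bed = np.zeros(MINUTES_PER_DAY, bool)
            in_bed[: int(round(wake * 60))] = True
            in_bed[int(round(bed_start * 60)):] = True
            curve = cosinor_curve(hours, mesor, amp, phi)
            sigma = rhy.noise_sigma
            mnorm = mults / float((shares * mults).sum())
            wak_means = np.concatenate([curve[~in_bed] * m for m in mnorm])
            wak_w = np.concatenate([np.full((~in_bed).sum(), s) for s in shares])
            # weighted mixture median via resampling weights into the grid
            order = np.argsort(wak_means)
            cum = np.cumsum(wak_w[order]) / wak_w.sum()
            med0 = float(wak_means[order][np.searchsorted(cum, 0.5)])
            med = _weighted_mixture_median(wak_means, wak_w, sigma, med0)
            kappa = _solve_attenuation(io_target, curve[in_bed], med, sigma)

            mean_profile = curve.copy()
            mean_profile[in_bed] *= kappa
            m_exp, a_exp, phi_exp = _project_cosinor(mean_profile)
            # model-implied lag-24 h autocorrelation (shared profile variance
            # over total minute variance)
            e2_mult = float((shares * mnorm**2).sum())
            var_min = np.empty(MINUTES_PER_DAY)
            var_min[~in_bed] = curve[~in_bed] ** 2 * (e2_mult * np.exp(sigma**2) - 1.0)
            var_min[in_bed] = (kappa * curve[in_bed]) ** 2 * (np.exp(sigma**2) - 1.0)
            r24 = float(np.var(mean_profile) / (np.var(mean_profile) + var_min.mean()))

            rows.append(
                {
                    "participant_id": p["participant_id"],
                    "visit": label,
                    "visit_index": j,
                    "days_since_treatment": days_since,
                    "sedentary_h": sed,
                    "standing_h": stand,
                    "total_activity_h": act,
                    "lpa_h": lpa,
                    "mvpa_h": mvpa,
                    "bed_start_h": bed_start,
                    "wake_h": wake,
                    "mesor_true": mesor,
                    "amplitude_true": amp,
                    "acrophase_true": phi,
                    "cq_true": amp / mesor,
                    "dichotomy_true": io_target,
                    "dichotomy_clipped": io_clipped,
                    "attenuation": kappa,
                    "noise_sigma": sigma,
                    "r24_true": r24,
                    "mesor_expected": m_exp,
                    "amplitude_expected": a_exp,
                    "acrophase_expected": phi_exp,
                    # time-varying covariates
                    "bmi": float(np.clip(p["bmi_base"] + 0.15 * j + vr.normal(0, 0.4), 16, 48)),
                    "comorbidities": (
                        p["comorbidity_base"]
                        if vr.random() < 0.8
                        else str(vr.choice(["0", "1", "2+"]))
                    ),
                    "stoma": bool(p["stoma_base"]) and (j == 0 or vr.random() < 0.6),
                    "smoking": p["smoking_base"],
                    "employment": bool(p["employment_base"]) and vr.random() < 0.9**j,
                    "alcohol_g_day": 0.0 if vr.random() < 0.25 else float(np.exp(vr.normal(np.log(9.0), 1.0))),
                }
            )
    return pd.DataFrame(rows)


def _weighted_mixture_median(means: np.ndarray, weights: np.ndarray, sigma: float, x0: float) -> float:
    """Median of a weighted mixture of mean-one lognormals scaled by ``means``."""
    if sigma <= 0:
        order = np.argsort(means)
        cum = np.cumsum(weights[order]) / weights.sum()
        return float(means[order][np.searchsorted(cum, 0.5)])
    w = weights / weights.sum()
    mu_ln = np.log(means) - sigma**2 / 2.0
    lo, hi = np.log(x0) - 4 * sigma, np.log(x0) + 4 * sigma
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float((w * ndtr((mid - mu_ln) / sigma)).sum()) < 0.5:
            lo = mid
        else:
            hi = mid
    return float(np.exp(0.5 * (lo + hi)))


@dataclass
class Cohort:
    """Bundle of everything the generator knows about a synthetic cohort.

    ``participants`` holds fixed covariates (plus latent bases, prefixed
    columns); ``truth`` is the participant-visit truth panel; raw signal
    and bed logs are synthesised lazily per participant-visit so a large
    cohort never holds a week of 25 Hz data per person in memory.
    """

    config: SimulationConfig
    participants: pd.DataFrame
    truth: pd.DataFrame

    def _truth_row(self, participant_id: str, visit: str) -> pd.Series:
        rows = self.truth[
            (self.truth["participant_id"] == participant_id) & (self.truth["visit"] == visit)
        ]
        if rows.empty:
            raise KeyError(f"no attended visit {visit!r} for {participant_id!r}")
        return rows.iloc[0]

    def start_date(self, participant_id: str, visit: str) -> dt.date:
        row = self._truth_row(participant_id, visit)
        pid_idx = int(participant_id[1:])
        return EPOCH_DATE + dt.timedelta(days=int(row["days_since_treatment"]) + pid_idx % 7)

    def bedlog(self, participant_id: str, visit: str) -> BedTimeLog:
        row = self._truth_row(participant_id, visit)
        pid_idx = int(participant_id[1:])
        j = int(row["visit_index"])
        start = self.start_date(participant_id, visit)
        jit = self.config.behavior.day_jitter_sd
        rows = []
        for d in range(self.config.days_per_visit):
            r = _rng(self.config.seed, 2, pid_idx, j, d)
            rows.append(
                {
                    "date": start + dt.timedelta(days=d),
                    "wake_h": float(np.clip(row["wake_h"] + r.normal(0, jit), 4.5, 11.0)),
                    "bed_h": float(np.clip(row["bed_start_h"] + r.normal(0, jit), 20.5, 23.95)),
                }
            )
        return BedTimeLog(pd.DataFrame(rows))

    def minute_counts(
        self, participant_id: str, visit: str, bedlog: BedTimeLog | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Minute-level counts/states/in-bed masks for the whole week.

        Returns arrays of shape (days, 1440).
        """
        cfg = self.config
        row = self._truth_row(participant_id, visit)
        pid_idx = int(participant_id[1:])
        j = int(row["visit_index"])
        bedlog = bedlog or self.bedlog(participant_id, visit)
        beh = cfg.behavior
        shares = np.array([row["sedentary_h"], row["standing_h"], row["total_activity_h"]])
        shares = shares / shares.sum()
        counts = np.empty((cfg.days_per_visit, MINUTES_PER_DAY))
        states = np.empty((cfg.days_per_visit, MINUTES_PER_DAY), dtype=np.int8)
        inbeds = np.empty((cfg.days_per_visit, MINUTES_PER_DAY), dtype=bool)
        for d, date in enumerate(bedlog.dates):
            rng = _rng(cfg.seed, 3, pid_idx, j, d)
            in_bed = bedlog.in_bed_mask(date)
            c, s = simulate_day_counts(
                row["mesor_true"],
                row["amplitude_true"],
                row["acrophase_true"],
                in_bed,
                shares=shares,
                bout_means=np.array(
                    [beh.sedentary_bout_mean_min, beh.standing_bout_mean_min, beh.activity_bout_mean_min]
                ),
                multipliers=np.array([beh.sedentary_mult, beh.standing_mult, beh.activity_mult]),
                attenuation=float(row["attenuation"]),
                sigma=float(row["noise_sigma"]),
                rng=rng,
            )
            counts[d], states[d], inbeds[d] = c, s, in_bed
        return counts, states, inbeds

    def recording(
        self,
        participant_id: str,
        visit: str,
        *,
        nonwear: bool = True,
        calibration: float = 1.0,
    ) -> tuple[RawAccelRecording, BedTimeLog]:
        """Synthesise the raw 25 Hz week for one participant-visit."""
        cfg = self.config
        bedlog = self.bedlog(participant_id, visit)
        counts, states, _ = self.minute_counts(participant_id, visit, bedlog)
        rec = RawAccelRecording(
            participant_id=participant_id, visit=visit, sample_rate=cfg.sample_rate
        )
        for d, date in enumerate(bedlog.dates):
            acc = counts_to_signal(
                counts[d],
                states[d],
                sample_rate=cfg.sample_rate,
                epoch_length=cfg.epoch_length,
                calibration=calibration,
            )
            rec.days.append(
                DaySignal(date=date, sample_rate=cfg.sample_rate, acc=acc, wear=np.ones(acc.shape[0], bool))
            )
        if nonwear and cfg.nonwear_rate > 0:
            pid_idx = int(participant_id[1:])
            j = int(self._truth_row(participant_id, visit)["visit_index"])
            rec = inject_nonwear(
                rec,
                cfg.nonwear_rate,
                cfg.nonwear_duration_mean_h,
                seed=_rng(cfg.seed, 4, pid_idx, j),
            )
        return rec, bedlog

    def iter_measurements(self):
        """Yield (participant_id, visit) for every attended visit."""
        for _, row in self.truth.iterrows():
            yield row["participant_id"], row["visit"]

    @property
    def covariate_panel(self) -> pd.DataFrame:
        """Participant-visit covariate table (no truth columns)."""
        fixed = self.participants[
            ["participant_id", "age", "sex", "education", "neoadjuvant", "adjuvant_chemo"]
        ]
        tv = self.truth[
            [
                "participant_id",
                "visit",
                "visit_index",
                "days_since_treatment",
                "bmi",
                "comorbidities",
                "stoma",
                "smoking",
                "employment",
                "alcohol_g_day",
                "lpa_h",
                "mvpa_h",
            ]
        ]
        return tv.merge(fixed, on="participant_id", how="left")


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort, deterministic given ``config.seed``."""
    participants = _draw_participants(config)
    truth = _truth_panel(config, participants)
    return Cohort(config=config, participants=participants, truth=truth)
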