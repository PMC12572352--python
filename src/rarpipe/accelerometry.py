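"""Raw tri-axial signal -> labeled 1-minute epochs -> behavior exposures.

Implements a transparent two-stage scheme in place of the proprietary
device classifier: activity counts are the signal magnitude area (SMA) of
the gravity-removed signal per epoch, posture comes from the thigh
inclination of the low-frequency (gravity) component, and intensity from
a configurable count threshold standing in for the 1.5 MET cut.  Wear-
and valid-day rules: a day is wear-complete only with zero non-wear over
the full 24 h, and a measurement is valid only with at least four valid
days including one weekend day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import BedTimeLog, RawAccelRecording, MINUTES_PER_DAY

__all__ = [
    "Thresholds",
    "compute_epoch_counts",
    "classify_epochs",
    "detect_prolonged_bouts",
    "summarize_day",
    "aggregate_visit",
]

BEHAVIORS = ("sedentary", "standing", "activity")


@dataclass(frozen=True)
class Thresholds:
    """Classifier calibration shared with the signal generator.

    ``met_count_cut`` is the count level standing in for 1.5 MET on the
    arbitrary count scale; ``incline_cut_deg`` separates an upright thigh
    (inclination below the cut) from sitting/lying.
    """

    met_count_cut: float = 8.0
    incline_cut_deg: float = 45.0
    min_bout_min: int = 30


# ---------------------------------------------------------------------------
# epoch counts
# ---------------------------------------------------------------------------

def _day_epochs(
    day_acc: np.ndarray,
    day_wear: np.ndarray,
    spe: int,
    calibration: float,
    gravity_mode: str,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-epoch (count, inclination_deg, nonwear_fraction) for one day."""
    n_full = day_acc.shape[0] // spe
    acc = day_acc[: n_full * spe].reshape(n_full, spe, 3)
    grav = acc.mean(axis=1, dtype=np.float64)  # low-pass gravity estimate per epoch
    counts = np.zeros(n_full)
    if gravity_mode == "epoch_mean":
        # axis-by-axis in the input dtype, accumulating in float64, to
        # avoid materialising a float64 copy of the whole day
        for k in range(3):
            dyn = acc[:, :, k] - grav[:, k, None].astype(acc.dtype)
            np.abs(dyn, out=dyn)
            counts += dyn.mean(axis=1, dtype=np.float64)
    elif gravity_mode == "butterworth":
        sos = sps.butter(4, 0.25, btype="highpass", fs=sample_rate, output="sos")
        dyn = sps.sosfiltfilt(sos, day_acc[: n_full * spe].astype(np.float64), axis=0)
        counts = np.abs(dyn).sum(axis=1).reshape(n_full, spe).mean(axis=1)
    else:
        raise ValueError(f"unknown gravity_mode {gravity_mode!r}")
    counts = calibration * counts
    norm = np.linalg.norm(grav, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        incline = np.degrees(np.arccos(np.clip(np.abs(grav[:, 0]) / norm, 0, 1)))
    nonwear_frac = 1.0 - day_wear[: n_full * spe].reshape(n_full, spe).mean(axis=1)
    return counts, incline, nonwear_frac


def compute_epoch_counts(
    recording: RawAccelRecording,
    epoch_length: int = 60,
    *,
    calibration: float = 1.0,
    gravity_mode: str = "epoch_mean",
) -> pd.DataFrame:
    """SMA activity counts per 1-min epoch over a participant-visit week.

    Returns a tidy frame with one row per epoch: ``timestamp``, ``date``,
    ``minute`` (of the day), ``count``, ``incline_deg`` (thigh
    inclination of the gravity estimate), and ``nonwear`` (over half the
    epoch's samples flagged non-wear).  Trailing partial epochs are
    dropped.  Non-wear epochs keep their count; exclusion happens
    downstream.
    """
    spe = recording.sample_rate * epoch_length
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(
            f"sample rate {recording.sample_rate} Hz incompatible with "
            f"{epoch_length}-s epochs (non-integer samples per epoch)"
        )
    spe = int(round(spe))
    frames = []
    for day in recording.days:
        if abs(day.sample_rate - recording.sample_rate) > 1e-9:
            raise ValueError("sample-rate mismatch between recording and day segment")
        counts, incline, nw = _day_epochs(
            day.acc, day.wear, spe, calibration, gravity_mode, recording.sample_rate
        )
        n = counts.size
        t0 = pd.Timestamp(day.date)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": t0 + pd.to_timedelta(np.arange(n) * epoch_length, unit="s"),
                    "date": day.date,
                    "minute": (np.arange(n) * epoch_length) // 60,
                    "count": counts,
                    "incline_deg": incline,
                    "nonwear": nw > 0.5,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_epochs(
    epochs: pd.DataFrame,
    bedlog: BedTimeLog,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Assign posture, behavior and context labels to every epoch.

    Waking epochs get exactly one behavior: ``activity`` if the count
    exceeds the MET cut regardless of posture, otherwise ``standing``
    when the thigh is upright and ``sedentary`` (sitting/lying) when
    recumbent.  In-bed epochs are labeled by the bed log irrespective of
    posture; non-wear propagates; days absent from the bed log are left
    unlabeled (context NA) and cannot be valid.
    """
    out = epochs.copy()
    out["posture"] = np.where(
        out["incline_deg"] < thresholds.incline_cut_deg, "upright", "recumbent"
    )
    context = np.full(len(out), None, dtype=object)
    for date, idx in out.groupby("date", sort=False).groups.items():
        mask = bedlog.in_bed_mask(date)
        if mask is None:
            continue
        minutes = out.loc[idx, "minute"].to_numpy()
        context[out.index.get_indexer(idx)] = np.where(mask[minutes], "in_bed", "waking")
    out["context"] = context
    out.loc[out["nonwear"], "context"] = "nonwear"

    behavior = np.full(len(out), None, dtype=object)
    waking = (out["context"] == "waking").to_numpy()
    high = (out["count"].to_numpy() > thresholds.met_count_cut)
    upright = (out["posture"] == "upright").to_numpy()
    behavior[waking & high] = "activity"
    behavior[waking & ~high & upright] = "standing"
    behavior[waking & ~high & ~upright] = "sedentary"
    out["behavior"] = behavior
    return out


# ---------------------------------------------------------------------------
# prolonged sedentary bouts
# ---------------------------------------------------------------------------

def detect_prolonged_bouts(labeled: pd.DataFrame, min_duration: int = 30) -> pd.DataFrame:
    """Maximal uninterrupted waking-sedentary runs of >= ``min_duration`` min.

    Any epoch that is not waking-sedentary (including non-wear and in-bed
    epochs) breaks a run; so does a gap in the timestamps.  Returns one
    row per bout with ``start``, ``end`` (inclusive) and ``n_min``.
    """
    df = labeled.sort_values("timestamp")
    sed = ((df["behavior"] == "sedentary") & (df["context"] == "waking")).to_numpy()
    ts = df["timestamp"].to_numpy()
    step = np.ones(len(df), bool)
    if len(df) > 1:
        step[1:] = (ts[1:] - ts[:-1]) == np.timedelta64(60, "s")
    bouts = []
    run_start = None
    n = len(df)
    for i in range(n + 1):
        cont = i < n and sed[i] and (run_start is None or step[i])
        if cont and run_start is None:
            run_start = i
        elif not cont and run_start is not None:
            length = i - run_start
            if length >= min_duration:
                bouts.append(
                    {"start": ts[run_start], "end": ts[i - 1], "n_min": length}
                )
            run_start = i if (i < n and sed[i]) else None
    return pd.DataFrame(bouts, columns=["start", "end", "n_min"])


# ---------------------------------------------------------------------------
# daily summaries and visit aggregation
# ---------------------------------------------------------------------------

def summarize_day(labeled: pd.DataFrame, date) -> pd.Series:
    """Daily behavior durations (hours) plus wear-complete / weekend flags.

    Durations accumulate only in the waking context; ``wear_complete``
    requires a full 1440-epoch day with zero non-wear and a bed log.
    """
    day = labeled[labeled["date"] == date]
    n_nonwear = int(day["nonwear"].sum())
    has_labels = day["context"].notna().all() and len(day) > 0
    wear_complete = len(day) == MINUTES_PER_DAY and n_nonwear == 0 and has_labels
    hours = {}
    for b in BEHAVIORS:
        hours[b] = float((day["behavior"] == b).sum()) / 60.0
    bouts = detect_prolonged_bouts(day)
    prolonged = float(bouts["n_min"].sum()) / 60.0 if len(bouts) else 0.0
    weekday = pd.Timestamp(date).dayofweek
    return pd.Series(
        {
            "date": date,
            "sedentary_h": hours["sedentary"],
            "prolonged_sedentary_h": prolonged,
            "standing_h": hours["standing"],
            "activity_h": hours["activity"],
            "in_bed_h": float((day["context"] == "in_bed").sum()) / 60.0,
            "wear_complete": bool(wear_complete),
            "weekend": weekday >= 5,
        }
    )


def aggregate_visit(
    summaries: pd.DataFrame,
    self_report_lpa: float = np.nan,
    self_report_mvpa: float = np.nan,
    *,
    min_valid_days: int = 4,
) -> pd.Series:
    """Visit-level exposures: behavior means over valid days.

    A measurement is valid only with >= ``min_valid_days`` wear-complete
    days of which at least one falls on a weekend.  Behavior means use
    valid days only; self-reported LPA/MVPA (h/day) pass through.
    """
    if len(summaries) == 0:
        raise ValueError("aggregate_visit needs at least one daily summary")
    valid = summaries[summaries["wear_complete"]]
    n_valid = len(valid)
    measurement_valid = n_valid >= min_valid_days and bool(valid["weekend"].any())
    cols = ["sedentary_h", "prolonged_sedentary_h", "standing_h", "activity_h"]
    means = {c: (float(valid[c].mean()) if n_valid else np.nan) for c in cols}
    return pd.Series(
        {
            **means,
            "lpa_h": self_report_lpa,
            "mvpa_h": self_report_mvpa,
            "n_valid_days": n_valid,
            "n_days": len(summaries),
            "measurement_valid": measurement_valid,
        }
    )
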