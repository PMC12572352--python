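"""Diurnal rest-activity rhythm (RAR) parameters from 1-min epoch counts.

Six parameters per the standard actigraphy operationalisation:

* mesor M, amplitude A and acrophase phi from a single-harmonic cosinor
  y(t) = M + A cos(2 pi (t - phi)/24) fitted by least squares to one
  calendar day (midnight to midnight, all 1440 epochs);
* circadian quotient CQ = A / M;
* dichotomy index I<O = proportion of in-bed counts strictly below the
  median out-of-bed count, per 24-h calendar day;
* R24 = lag-1440 Pearson autocorrelation of the pooled 7-day minute
  series, defined only when all seven days are wear-complete.

Daily parameters are averaged per visit (circular mean for the
acrophase); outcomes are standardized by dividing raw values by the mean
of the per-visit SDs (no centering), and acrophase is categorized into
tertiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CosinorFit",
    "fit_cosinor_day",
    "circadian_quotient",
    "dichotomy_index_day",
    "autocorr_24h",
    "circular_mean_hours",
    "aggregate_rar",
    "standardize_outcomes",
    "acrophase_tertiles",
    "DEFAULT_TERTILE_BOUNDS",
]

OMEGA = 2 * np.pi / 24.0
RAR_PARAMS = ("mesor", "amplitude", "cq", "dichotomy_index", "r24")


def _hms(h: int, m: int, s: int) -> float:
    return h + m / 60.0 + s / 3600.0


#: Default early / mid-day / late acrophase group boundaries (decimal
#: hours, hh:mm:ss 01:23:35-13:51:20 / 13:51:28-14:42:40 / 14:42:55-20:10:02).
#: Intervals are closed on the left, open on the right, the last closed;
#: a value falling in a gap between printed bounds maps to the lower group.
DEFAULT_TERTILE_BOUNDS: tuple[tuple[float, float], ...] = (
    (_hms(1, 23, 35), _hms(13, 51, 20)),
    (_hms(13, 51, 28), _hms(14, 42, 40)),
    (_hms(14, 42, 55), _hms(20, 10, 2)),
)


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosinorFit:
    """Least-squares single-harmonic cosinor fit for one day.

    ``acrophase`` is NaN (and ``acrophase_defined`` False) for a flat
    series, where the peak time is unidentifiable.
    """

    mesor: float
    amplitude: float
    acrophase: float
    n_epochs: int

    @property
    def acrophase_defined(self) -> bool:
        return np.isfinite(self.acrophase)

    @property
    def cq(self) -> float:
        return circadian_quotient(self.amplitude, self.mesor)

    def predict(self, hours: np.ndarray) -> np.ndarray:
        phi = self.acrophase if self.acrophase_defined else 0.0
        return self.mesor + self.amplitude * np.cos(OMEGA * (np.asarray(hours, float) - phi))

    def summary(self) -> str:
        return (
            f"Cosinor fit (n={self.n_epochs} epochs)\n"
            f"  mesor     {self.mesor:10.4f} counts\n"
            f"  amplitude {self.amplitude:10.4f} counts\n"
            f"  acrophase {self.acrophase:10.4f} h\n"
            f"  CQ        {self.cq:10.4f}\n"
        )


def fit_cosinor_day(counts: np.ndarray, hours: np.ndarray | None = None) -> CosinorFit:
    """Fit y(t) = M + beta_c cos(wt) + beta_s sin(wt) by least squares.

    ``hours`` are decimal clock hours of each epoch; by default epochs
    are assumed to be the 1440 minute centers of one day.  Amplitude is
    sqrt(beta_c^2 + beta_s^2) and acrophase atan2(beta_s, beta_c)/w
    wrapped into [0, 24).
    """
    y = np.asarray(counts, float)
    if hours is None:
        if y.size != 1440:
            raise ValueError("without explicit hours, expected 1440 one-minute epochs")
        hours = (np.arange(1440) + 0.5) / 60.0
    hours = np.asarray(hours, float)
    if np.unique(hours).size < 2:
        raise ValueError("cosinor fit needs at least two distinct clock times")
    X = np.column_stack([np.ones_like(hours), np.cos(OMEGA * hours), np.sin(OMEGA * hours)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = map(float, beta)
    amplitude = float(np.hypot(bc, bs))
    tol = 1e-12 * max(1.0, abs(mesor))
    if amplitude <= tol:
        return CosinorFit(mesor=mesor, amplitude=0.0, acrophase=np.nan, n_epochs=y.size)
    acrophase = float(np.arctan2(bs, bc) / OMEGA % 24.0)
    return CosinorFit(mesor=mesor, amplitude=amplitude, acrophase=acrophase, n_epochs=y.size)


def circadian_quotient(amplitude: float, mesor: float) -> float:
    """CQ = amplitude / mesor; NaN (flagged undefined) when mesor <= 0."""
    if not np.isfinite(mesor) or mesor <= 0:
        return np.nan
    return float(amplitude) / float(mesor)


# ---------------------------------------------------------------------------
# dichotomy index and 24-h autocorrelation
# ---------------------------------------------------------------------------

def dichotomy_index_day(counts: np.ndarray, in_bed: np.ndarray) -> float:
    """I<O: share of in-bed counts strictly below the median out-of-bed count.

    Ties (a count exactly equal to the median) do not qualify.  NaN when
    either the in-bed or the out-of-bed set is empty.
    """
    counts = np.asarray(counts, float)
    in_bed = np.asarray(in_bed, bool)
    if counts.shape != in_bed.shape:
        raise ValueError("counts and in_bed mask differ in shape")
    i, o = counts[in_bed], counts[~in_bed]
    if i.size == 0 or o.size == 0:
        return np.nan
    return float((i < np.median(o)).mean())


def autocorr_24h(
    counts: np.ndarray,
    valid_days: np.ndarray | None = None,
    *,
    mode: str = "pooled",
    epochs_per_day: int = 1440,
) -> float:
    """Lag-24-h Pearson autocorrelation of a 7-day 1-min count series.

    ``counts`` is either flat (7*1440,) or shaped (7, 1440).  The value
    is only defined for seven wear-complete days (``valid_days`` all
    True); otherwise NaN is returned and the measurement keeps its other
    parameters.  ``mode='pooled'`` correlates the leading with the
    trailing 6-day segment in one pass (each segment keeps its own
    mean); ``mode='pairwise'`` averages the 6 per-day-pair correlations.
    """
    x = np.asarray(counts, float).reshape(-1)
    if x.size % epochs_per_day:
        raise ValueError("series length must be a whole number of days")
    n_days = x.size // epochs_per_day
    if valid_days is not None and not np.all(np.asarray(valid_days, bool)):
        return np.nan
    if n_days != 7:
        return np.nan
    lag = epochs_per_day
    a, b = x[:-lag], x[lag:]
    if mode == "pooled":
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])
    if mode == "pairwise":
        rs = []
        for d in range(n_days - 1):
            u = x[d * lag : (d + 1) * lag]
            v = x[(d + 1) * lag : (d + 2) * lag]
            if u.std() == 0 or v.std() == 0:
                continue
            rs.append(np.corrcoef(u, v)[0, 1])
        return float(np.mean(rs)) if rs else np.nan
    raise ValueError(f"unknown mode {mode!r}")


def circular_mean_hours(hours) -> float:
    """Circular mean of clock hours on the 24-h circle, in [0, 24)."""
    h = np.asarray(hours, float)
    h = h[np.isfinite(h)]
    if h.size == 0:
        return np.nan
    ang = h * OMEGA
    return float(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / OMEGA % 24.0)


# ---------------------------------------------------------------------------
# visit-level aggregation
# ---------------------------------------------------------------------------

def aggregate_rar(daily: pd.DataFrame, r24: float = np.nan) -> pd.Series:
    """Average daily RAR parameters into one measurement-level record.

    Arithmetic means for mesor, amplitude, CQ and I<O; circular mean for
    the acrophase; R24 is attached as supplied (NaN when fewer than
    seven wear-complete days made it undefined).
    """
    if len(daily) == 0:
        raise ValueError("no valid daily RAR records to aggregate")
    return pd.Series(
        {
            "mesor": float(daily["mesor"].mean()),
            "amplitude": float(daily["amplitude"].mean()),
            "acrophase": circular_mean_hours(daily["acrophase"]),
            "cq": float(daily["cq"].mean()),
            "dichotomy_index": float(daily["dichotomy_index"].mean()),
            "r24": float(r24),
            "n_valid_days": int(len(daily)),
        }
    )


def standardize_outcomes(
    panel: pd.DataFrame,
    columns=RAR_PARAMS,
    visit_col: str = "visit",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Divide each outcome by the mean of its per-visit SDs (no centering).

    The divisor for a parameter is the mean, over visits, of that
    visit's cross-sectional SD.  Visits with fewer than two non-missing
    observations are excluded from the divisor with a warning.  Returns
    the panel with added ``<col>_std`` columns and the divisor map.
    """
    out = panel.copy()
    divisors: dict[str, float] = {}
    for col in columns:
        sds = []
        for visit, grp in panel.groupby(visit_col, sort=False):
            vals = grp[col].dropna()
            if len(vals) < 2:
                warnings.warn(
                    f"visit {visit!r} has <2 observations for {col!r}; "
                    "excluded from the standardization divisor"
                )
                continue
            sds.append(vals.std(ddof=1))
        if not sds:
            raise ValueError(f"no visit provides an SD for {col!r}")
        divisor = float(np.mean(sds))
        scale = float(np.nanmax(np.abs(panel[col]))) or 1.0
        if divisor <= 1e-12 * max(1.0, scale):
            raise ValueError(f"degenerate outcome {col!r}: all values equal (divisor 0)")
        divisors[col] = divisor
        out[f"{col}_std"] = out[col] / divisor
    return out, divisors


def acrophase_tertiles(
    phi: np.ndarray,
    bounds: tuple[tuple[float, float], ...] | None = None,
) -> tuple[np.ndarray, tuple[tuple[float, float], ...]]:
    """Map acrophases (decimal hours) to tertile labels {1, 2, 3}.

    With ``bounds=None`` the boundaries are the empirical tertiles of the
    supplied sample; otherwise the three (lower, upper) intervals are
    used, closed on the left, open on the right, with the final interval
    closed and values in the printed gaps assigned to the lower group.
    Missing acrophases yield label 0 (undefined).  Returns labels and
    the boundaries used.
    """
    phi = np.asarray(phi, float)
    finite = np.isfinite(phi)
    labels = np.zeros(phi.shape, dtype=int)
    if bounds is None:
        if finite.sum() < 3:
            raise ValueError("need at least 3 observed acrophases for empirical tertiles")
        q1, q2 = np.quantile(phi[finite], [1 / 3, 2 / 3])
        labels[finite] = 1 + (phi[finite] > q1).astype(int) + (phi[finite] > q2).astype(int)
        used = ((float(phi[finite].min()), float(q1)), (float(q1), float(q2)), (float(q2), float(phi[finite].max())))
        return labels, used
    (lo1, hi1), (lo2, hi2), (lo3, hi3) = bounds
    cut2, cut3 = lo2, lo3  # gap values fall to the lower tertile
    lab = np.ones(phi.shape, dtype=int)
    lab[phi >= cut2] = 2
    lab[phi >= cut3] = 3
    labels[finite] = lab[finite]
    return labels, bounds
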