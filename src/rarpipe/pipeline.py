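"""End-to-end orchestration: simulate -> process -> rar -> model -> report.

Every stage's tabular outputs are persisted as CSV; a JSON manifest
records row counts, seeds and SHA-256 checksums.  Raw 25 Hz signal is
streamed per participant-visit into epoch counts rather than persisted
(a cohort of raw CSV weeks would be hundreds of gigabytes and feeds no
analysis stage); ``rarpipe simulate --write-raw`` materialises it on
request for small cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rar as rarmod
from .accelerometry import (
    Thresholds,
    aggregate_visit,
    classify_epochs,
    compute_epoch_counts,
    summarize_day,
)
from .config import SimulationConfig, demo_config
from .io import sha256_of, write_csv
from .longitudinal import (
    DEFAULT_COVARIATES,
    MixedEffectsAssociation,
    benjamini_hochberg,
    correlations_baseline,
    fit_multinomial_acrophase,
    fit_time_lag,
)
from .panel import EXPOSURE_COLUMNS, build_panel
from .simulate import Cohort, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "process_cohort", "render_report"]

OUTCOME_COLUMNS = ("mesor_std", "amplitude_std", "cq_std", "dichotomy_index_std", "r24_std")


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    outdir: Path
    simulation: SimulationConfig = field(default_factory=demo_config)
    thresholds: Thresholds = field(default_factory=Thresholds)
    calibration: float = 1.0
    r24_mode: str = "pooled"
    tertile_bounds: str = "empirical"  # or "reference"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    exposures: tuple[str, ...] = tuple(EXPOSURE_COLUMNS.values())
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS
    time_lag: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)


def process_measurement(
    cohort: Cohort,
    participant_id: str,
    visit: str,
    thresholds: Thresholds,
    calibration: float = 1.0,
    r24_mode: str = "pooled",
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame, pd.Series | None]:
    """One participant-visit: raw week -> exposures + daily/visit RAR.

    Returns (visit_exposures, daily_summaries, daily_rar, measurement_rar);
    the last is None when the measurement fails the >=4-valid-days-with-
    a-weekend rule.
    """
    cfg = cohort.config
    recording, bedlog = cohort.recording(participant_id, visit, calibration=calibration)
    epochs = compute_epoch_counts(
        recording, cfg.epoch_length, calibration=calibration
    )
    labeled = classify_epochs(epochs, bedlog, thresholds)
    summaries = pd.DataFrame(
        [summarize_day(labeled, d.date) for d in recording.days]
    )
    truth_row = cohort._truth_row(participant_id, visit)
    exposures = aggregate_visit(
        summaries,
        self_report_lpa=float(truth_row["lpa_h"]),
        self_report_mvpa=float(truth_row["mvpa_h"]),
    )
    exposures["participant_id"], exposures["visit"] = participant_id, visit

    daily_rar_rows = []
    week_counts, week_valid = [], []
    for d in recording.days:
        day = labeled[labeled["date"] == d.date]
        counts = day["count"].to_numpy()
        wear_complete = bool(
            summaries.loc[summaries["date"] == d.date, "wear_complete"].iloc[0]
        )
        week_counts.append(counts)
        week_valid.append(wear_complete)
        if not wear_complete:
            continue
        fit = rarmod.fit_cosinor_day(counts)
        in_bed = (day["context"] == "in_bed").to_numpy()
        io_val = rarmod.dichotomy_index_day(counts, in_bed)
        daily_rar_rows.append(
            {
                "participant_id": participant_id,
                "visit": visit,
                "date": d.date,
                "mesor": fit.mesor,
                "amplitude": fit.amplitude,
                "acrophase": fit.acrophase,
                "cq": fit.cq,
                "dichotomy_index": io_val,
            }
        )
    daily_rar = pd.DataFrame(daily_rar_rows)

    measurement = None
    if exposures["measurement_valid"]:
        lengths = {c.size for c in week_counts}
        r24 = np.nan
        if len(week_counts) == 7 and all(week_valid) and lengths == {1440}:
            r24 = rarmod.autocorr_24h(
                np.concatenate(week_counts), week_valid, mode=r24_mode
            )
        measurement = rarmod.aggregate_rar(daily_rar, r24)
        measurement["participant_id"], measurement["visit"] = participant_id, visit
    return exposures, summaries, daily_rar, measurement


def process_cohort(
    cohort: Cohort,
    thresholds: Thresholds = Thresholds(),
    *,
    calibration: float = 1.0,
    r24_mode: str = "pooled",
    tertile_bounds: str = "empirical",
) -> dict[str, pd.DataFrame | dict]:
    """Process every attended measurement of a synthetic cohort."""
    exp_rows, day_rows, rar_rows, meas_rows = [], [], [], []
    for pid, visit in cohort.iter_measurements():
        exposures, summaries, daily_rar, measurement = process_measurement(
            cohort, pid, visit, thresholds, calibration, r24_mode
        )
        summaries["participant_id"], summaries["visit"] = pid, visit
        exp_rows.append(exposures)
        day_rows.append(summaries)
        if len(daily_rar):
            rar_rows.append(daily_rar)
        if measurement is not None:
            meas_rows.append(measurement)
    exposures = pd.DataFrame(exp_rows).reset_index(drop=True)
    daily = pd.concat(day_rows, ignore_index=True)
    daily_rar = (
        pd.concat(rar_rows, ignore_index=True) if rar_rows else pd.DataFrame()
    )
    measurements = pd.DataFrame(meas_rows).reset_index(drop=True)
    if measurements.empty:
        raise RuntimeError("no valid measurements produced by the cohort")

    measurements, divisors = rarmod.standardize_outcomes(measurements)
    bounds = None if tertile_bounds == "empirical" else rarmod.DEFAULT_TERTILE_BOUNDS
    labels, used_bounds = rarmod.acrophase_tertiles(
        measurements["acrophase"].to_numpy(), bounds
    )
    measurements["acrophase_tertile"] = labels
    meta = {
        "standardization_divisors": divisors,
        "tertile_bounds": [list(b) for b in used_bounds],
        "r24_mode": r24_mode,
    }
    return {
        "visit_exposures": exposures,
        "daily_summaries": daily,
        "daily_rar": daily_rar,
        "measurement_rar": measurements,
        "metadata": meta,
    }


def fit_models(
    panel: pd.DataFrame,
    exposures,
    outcomes,
    covariates=DEFAULT_COVARIATES,
    *,
    time_lag: bool = False,
    p_adjust: bool = False,
) -> pd.DataFrame:
    """Overall + inter/intra LMMs per exposure x outcome, plus acrophase models.

    ``p_adjust=True`` appends Benjamini-Hochberg adjusted p-values (no
    multiplicity correction is applied by default).
    """
    import logging

    log = logging.getLogger(__name__)
    rows = []
    for exp in exposures:
        for out in outcomes:
            sub = panel.dropna(subset=[exp, out])
            if sub.empty or sub[exp].nunique() <= 1:
                continue
            overall_beta = np.nan
            for decompose in (False, True):
                try:
                    res = MixedEffectsAssociation(
                        panel, exp, out, covariates, decompose=decompose
                    ).fit()
                    if not decompose:
                        overall_beta = res.beta
                    elif np.isfinite(overall_beta):
                        lo = min(res.beta_inter, res.beta_intra) - 1e-9
                        hi = max(res.beta_inter, res.beta_intra) + 1e-9
                        if not lo <= overall_beta <= hi:
                            # empirical regularity, not a theorem: log only
                            log.info(
                                "overall beta %.4f outside [inter, intra] "
                                "(%.4f, %.4f) for %s -> %s",
                                overall_beta, res.beta_inter, res.beta_intra, exp, out,
                            )
                    rows.append(res.to_row())
                except (ValueError, np.linalg.LinAlgError) as err:
                    rows.append(
                        {"exposure": exp, "outcome": out, "estimand": "inter/intra" if decompose else "overall", "converged": False, "error": str(err)}
                    )
        if time_lag:
            for out in outcomes:
                try:
                    res = fit_time_lag(panel, exp, out, covariates)
                    rows.append(res.to_row())
                except (ValueError, np.linalg.LinAlgError) as err:
                    rows.append({"exposure": exp, "outcome": out, "estimand": "time_lag", "converged": False, "error": str(err)})
        # acrophase tertile models
        try:
            fits = fit_multinomial_acrophase(panel, exp, covariates)
            r1, r2 = fits["ref1"], fits["ref2"]
            for tert in (2, 3):
                rows.append(
                    {
                        "exposure": exp,
                        "outcome": "acrophase_tertile",
                        "estimand": f"OR_t{tert}_vs_t1",
                        "beta": r1.odds_ratios[tert],
                        "ci_low": r1.ci[tert][0],
                        "ci_high": r1.ci[tert][1],
                        "pvalue": r1.pvalues[tert],
                        "n_obs": r1.n_obs,
                        "n_participants": r1.n_participants,
                        "converged": not r1.separation_flag,
                    }
                )
            rows.append(
                {
                    "exposure": exp,
                    "outcome": "acrophase_tertile",
                    "estimand": "OR_t3_vs_t2",
                    "beta": r2.odds_ratios[3],
                    "ci_low": r2.ci[3][0],
                    "ci_high": r2.ci[3][1],
                    "pvalue": r2.pvalues[3],
                    "n_obs": r2.n_obs,
                    "n_participants": r2.n_participants,
                    "converged": not r2.separation_flag,
                }
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append({"exposure": exp, "outcome": "acrophase_tertile", "estimand": "OR", "converged": False, "error": str(err)})
    results = pd.DataFrame(rows)
    if p_adjust and "pvalue" in results.columns:
        results["pvalue_bh"] = benjamini_hochberg(results["pvalue"])
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages, persisting artifacts under ``config.outdir``.

    Deterministic for a fixed configuration: rerunning writes
    byte-identical results tables.  Raises with the failing stage named;
    artifacts of completed stages are retained.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    manifest: dict[str, object] = {"seed": config.simulation.seed, "stages": {}, "files": {}}

    def _persist(name: str, df: pd.DataFrame) -> None:
        path = write_csv(df, out / f"{name}.csv")
        manifest["files"][f"{name}.csv"] = {"sha256": sha256_of(path), "rows": int(len(df))}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    # 1. simulate -------------------------------------------------------
    cohort = _stage("simulate", lambda: generate_cohort(config.simulation))
    artifacts["cohort"] = cohort
    _persist("participants", cohort.participants.drop(columns=["dropout_u"]))
    _persist("truth_panel", cohort.truth)
    _persist("covariates", cohort.covariate_panel)
    manifest["stages"]["simulate"] = {"participants": int(len(cohort.participants)), "measurements": int(len(cohort.truth))}

    # 2-3. process + rar ------------------------------------------------
    processed = _stage(
        "process",
        lambda: process_cohort(
            cohort,
            config.thresholds,
            calibration=config.calibration,
            r24_mode=config.r24_mode,
            tertile_bounds=config.tertile_bounds,
        ),
    )
    artifacts.update(processed)
    for name in ("visit_exposures", "daily_summaries", "daily_rar", "measurement_rar"):
        _persist(name, processed[name])
    (out / "rar_metadata.json").write_text(json.dumps(processed["metadata"], indent=2))

    # 4. model ----------------------------------------------------------
    def _build_and_fit():
        panel = build_panel(
            processed["visit_exposures"],
            processed["measurement_rar"],
            cohort.covariate_panel,
        )
        results = fit_models(
            panel,
            config.exposures,
            config.outcomes,
            config.covariates,
            time_lag=config.time_lag,
        )
        return panel, results

    panel, results = _stage("model", _build_and_fit)
    artifacts["panel"] = panel
    artifacts["results"] = results
    _persist("panel", panel)
    _persist("model_results", results)
    manifest["stages"]["model"] = {"models": int(len(results))}

    corr = correlations_baseline(panel, list(config.exposures), list(config.outcomes))
    corr_tidy = corr.rename_axis("exposure").reset_index()
    artifacts["baseline_correlations"] = corr
    _persist("baseline_correlations", corr_tidy)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest

    report = render_report(artifacts)
    (out / "report.md").write_text(report)
    artifacts["report"] = report
    return artifacts


def _desc(series: pd.Series) -> str:
    s = series.dropna()
    if s.empty:
        return "NA"
    return f"{s.mean():.2f} +/- {s.std(ddof=1):.2f}"


def render_report(artifacts: dict) -> str:
    """Human-readable run summary: descriptives, associations, recovery."""
    lines = ["# Rest-activity rhythm pipeline report", ""]
    meas = artifacts.get("measurement_rar")
    expo = artifacts.get("visit_exposures")
    results = artifacts.get("results")
    cohort: Cohort | None = artifacts.get("cohort")

    if meas is not None and expo is not None and len(meas):
        lines.append("## Descriptives per visit (mean +/- SD)")
        lines.append("")
        lines.append("| visit | n | sedentary h/d | standing h/d | activity h/d | mesor | amplitude | CQ | I<O | R24 |")
        lines.append("|---|---|---|---|---|---|---|---|---|---|")
        merged = expo.merge(meas, on=["participant_id", "visit"], how="inner")
        for visit, grp in merged.groupby("visit", sort=False):
            lines.append(
                f"| {visit} | {len(grp)} | {_desc(grp['sedentary_h'])} | "
                f"{_desc(grp['standing_h'])} | {_desc(grp['activity_h'])} | "
                f"{_desc(grp['mesor'])} | {_desc(grp['amplitude'])} | "
                f"{_desc(grp['cq'])} | {_desc(grp['dichotomy_index'])} | {_desc(grp['r24'])} |"
            )
        lines.append("")

    if results is not None and len(results):
        conv = results[results.get("converged", pd.Series(dtype=bool)) == True]  # noqa: E712
        lines.append("## Longitudinal associations")
        lines.append("")
        if conv.empty:
            lines.append("No models converged.")
        else:
            lines.append("| exposure | outcome | estimand | beta/OR | 95% CI |")
            lines.append("|---|---|---|---|---|")
            for _, r in conv.iterrows():
                beta = r.get("beta")
                if pd.isna(beta) and not pd.isna(r.get("beta_intra")):
                    lines.append(
                        f"| {r['exposure']} | {r['outcome']} | intra | {r['beta_intra']:.3f} | "
                        f"({r['intra_ci_low']:.3f}, {r['intra_ci_high']:.3f}) |"
                    )
                    lines.append(
                        f"| {r['exposure']} | {r['outcome']} | inter | {r['beta_inter']:.3f} | "
                        f"({r['inter_ci_low']:.3f}, {r['inter_ci_high']:.3f}) |"
                    )
                else:
                    lines.append(
                        f"| {r['exposure']} | {r['outcome']} | {r['estimand']} | {beta:.3f} | "
                        f"({r.get('ci_low', float('nan')):.3f}, {r.get('ci_high', float('nan')):.3f}) |"
                    )
        lines.append("")

    if cohort is not None and meas is not None and len(meas):
        lines.append("## Recovery vs simulation truth")
        lines.append("")
        truth = cohort.truth
        merged = meas.merge(truth, on=["participant_id", "visit"], how="inner")
        if len(merged):
            lines.append("| parameter | mean estimate | mean model-implied truth | mean error |")
            lines.append("|---|---|---|---|")
            pairs = [
                ("mesor", "mesor_expected"),
                ("amplitude", "amplitude_expected"),
                ("acrophase", "acrophase_expected"),
                ("dichotomy_index", "dichotomy_true"),
                ("r24", "r24_true"),
            ]
            for est, tru in pairs:
                sub = merged[[est, tru]].dropna()
                if sub.empty:
                    continue
                err = (sub[est] - sub[tru]).mean()
                lines.append(
                    f"| {est} | {sub[est].mean():.3f} | {sub[tru].mean():.3f} | {err:+.3f} |"
                )
        lines.append("")
    elif cohort is None:
        lines.append("_No truth panel available: recovery section omitted._")
        lines.append("")
    return "\n".join(lines)
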