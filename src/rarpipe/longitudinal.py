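"""Longitudinal association models for standardized RAR outcomes.

Statsmodels-backed model objects in the Model/Results style:

* :class:`MixedEffectsAssociation` — confounder-adjusted linear mixed
  model of a standardized rhythm outcome on one exposure, REML with a
  random intercept and, when a likelihood-ratio test on ML refits
  supports it (p < 0.05, 50:50 chi2(1)/chi2(2) mixture), a random
  exposure slope.  Optionally includes the within/between (person-mean
  centered) decomposition in a single model.
* :class:`MultinomialTertileModel` — pooled multinomial logit of the
  acrophase tertile with participant-clustered robust standard errors.

Plus helpers: the inter/intra decomposition, interaction (effect
modification) tests, time-lag re-pairing, and baseline Pearson
correlations.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "DEFAULT_COVARIATES",
    "AssociationResults",
    "MixedEffectsAssociation",
    "decompose_inter_intra",
    "TertileModelResult",
    "MultinomialTertileModel",
    "fit_multinomial_acrophase",
    "interaction_test",
    "make_lagged_panel",
    "benjamini_hochberg",
    "fit_time_lag",
    "correlations_baseline",
]

#: A-priori confounders: sex, age at enrollment, time since treatment,
#: neoadjuvant therapy, adjuvant chemotherapy, comorbidities, BMI, stoma,
#: smoking, employment, alcohol intake.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "C(sex)",
    "age",
    "days_since_treatment",
    "C(neoadjuvant)",
    "C(adjuvant_chemo)",
    "C(comorbidities)",
    "bmi",
    "C(stoma)",
    "C(smoking)",
    "C(employment)",
    "alcohol_g_day",
)

_TERM_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def _columns_in_terms(terms) -> list[str]:
    cols = []
    for t in terms:
        for name in _TERM_RE.findall(t):
            if name not in {"C", "Treatment", "np", "log"} and name not in cols:
                cols.append(name)
    return cols


def _mixture_lrt_pvalue(stat: float) -> float:
    """p-value for adding a random slope (variance + covariance term):
    50:50 mixture of chi-square with 1 and 2 df."""
    stat = max(stat, 0.0)
    return 0.5 * (stats.chi2.sf(stat, 1) + stats.chi2.sf(stat, 2))


@dataclass
class AssociationResults:
    """Fitted longitudinal association of one exposure with one outcome.

    ``beta`` is in outcome SD units per exposure unit (2 h/day for
    sedentary exposures, 1 h/day otherwise, as encoded in the panel).
    When the model contained the within/between decomposition,
    ``beta_intra``/``beta_inter`` carry the two components.
    """

    exposure: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_obs: int
    n_participants: int
    random_slope_included: bool
    lrt_pvalue: float
    converged: bool
    estimand: str = "overall"
    beta_intra: float = np.nan
    intra_ci: tuple[float, float] = (np.nan, np.nan)
    intra_pvalue: float = np.nan
    beta_inter: float = np.nan
    inter_ci: tuple[float, float] = (np.nan, np.nan)
    inter_pvalue: float = np.nan
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Linear mixed model: {self.outcome} ~ {self.exposure} (+ confounders)",
            f"  observations {self.n_obs}, participants {self.n_participants}, "
            f"converged={self.converged}",
            f"  random slope: {'yes' if self.random_slope_included else 'no'} "
            f"(LRT p={self.lrt_pvalue:.4f})",
            f"  overall beta {self.beta:8.3f}  95% CI ({self.ci_low:.3f}, {self.ci_high:.3f})"
            f"  p={self.pvalue:.2e}",
        ]
        if np.isfinite(self.beta_intra):
            lines.append(
                f"  intra   beta {self.beta_intra:8.3f}  95% CI "
                f"({self.intra_ci[0]:.3f}, {self.intra_ci[1]:.3f})  p={self.intra_pvalue:.2e}"
            )
        if np.isfinite(self.beta_inter):
            lines.append(
                f"  inter   beta {self.beta_inter:8.3f}  95% CI "
                f"({self.inter_ci[0]:.3f}, {self.inter_ci[1]:.3f})  p={self.inter_pvalue:.2e}"
            )
        return "\n".join(lines) + "\n"

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "estimand": self.estimand,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "beta_intra": self.beta_intra,
            "intra_ci_low": self.intra_ci[0],
            "intra_ci_high": self.intra_ci[1],
            "beta_inter": self.beta_inter,
            "inter_ci_low": self.inter_ci[0],
            "inter_ci_high": self.inter_ci[1],
            "random_slope": self.random_slope_included,
            "lrt_pvalue": self.lrt_pvalue,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "converged": self.converged,
        }


class MixedEffectsAssociation:
    """Confounder-adjusted linear mixed model for one exposure/outcome pair.

    Parameters
    ----------
    panel : DataFrame with one row per participant-visit.  Must contain
        ``participant_id``, the exposure, the (standardized) outcome and
        the covariate columns.
    exposure, outcome : column names.  The exposure must already be on
        its analysis unit (e.g. 2-h units for sedentary time).
    covariates : formula terms added as fixed effects.
    random_slope : "lrt" (default; include iff the likelihood-ratio test
        on ML refits gives p < 0.05), "never", or "always".
    decompose : if True, replace the raw exposure by its person-mean
        centered between/within split and report both coefficients.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        exposure: str,
        outcome: str,
        covariates=DEFAULT_COVARIATES,
        *,
        random_slope: str = "lrt",
        decompose: bool = False,
        group_col: str = "participant_id",
    ) -> None:
        if random_slope not in {"lrt", "never", "always"}:
            raise ValueError("random_slope must be 'lrt', 'never' or 'always'")
        self.exposure, self.outcome = exposure, outcome
        self.covariates = tuple(covariates)
        self.random_slope = random_slope
        self.decompose = decompose
        self.group_col = group_col

        cols = [group_col, exposure, outcome] + _columns_in_terms(self.covariates)
        cols = [c for c in dict.fromkeys(cols) if c in panel.columns]
        missing = [c for c in [exposure, outcome] if c not in panel.columns]
        if missing:
            raise KeyError(f"panel lacks columns {missing}")
        data = panel[cols].dropna().copy()  # complete-case per model
        if data[exposure].nunique() <= 1:
            raise ValueError(f"exposure {exposure!r} is constant: design is rank deficient")
        if decompose:
            data = decompose_inter_intra(data, exposure, group_col=group_col)
        # centered copy for the random-slope design: [1, x - mean(x)] spans
        # the same space as [1, x] but is far better conditioned
        slope_src = f"{exposure}_within" if decompose else exposure
        data["_slope_c"] = data[slope_src] - data[slope_src].mean()
        self.data = data

    # -- internals -------------------------------------------------------
    def _formula(self) -> str:
        if self.decompose:
            fixed = [f"{self.exposure}_between", f"{self.exposure}_within"]
        else:
            fixed = [self.exposure]
        rhs = " + ".join(list(fixed) + list(self.covariates)) or "1"
        return f"{self.outcome} ~ {rhs}"

    def _slope_term(self) -> str:
        return "_slope_c"

    def _fit_one(self, re_formula: str, reml: bool, method=("lbfgs", "cg")):
        model = smf.mixedlm(
            self._formula(), self.data, groups=self.data[self.group_col], re_formula=re_formula
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=list(method), maxiter=200)

    def fit(self) -> AssociationResults:
        lrt_p = np.nan
        include_slope = self.random_slope == "always"
        if self.random_slope == "lrt":
            try:
                red = self._fit_one("1", reml=False)
                full = self._fit_one(f"1 + {self._slope_term()}", reml=False)
                if full.llf < red.llf - 1e-8:
                    # gradient method stuck below the nested optimum:
                    # retry the slope model with a derivative-free search
                    full = self._fit_one(
                        f"1 + {self._slope_term()}", reml=False, method=("powell",)
                    )
                stat = 2.0 * (full.llf - red.llf)
                lrt_p = _mixture_lrt_pvalue(stat)
                include_slope = bool(lrt_p < 0.05) and np.isfinite(full.llf)
            except (np.linalg.LinAlgError, ValueError):
                include_slope = False
        re_formula = f"1 + {self._slope_term()}" if include_slope else "1"
        try:
            res = self._fit_one(re_formula, reml=True)
        except (np.linalg.LinAlgError, ValueError):
            if include_slope:
                warnings.warn(
                    "random-slope covariance singular under REML; slope dropped"
                )
                include_slope = False
                res = self._fit_one("1", reml=True)
            else:
                raise
        if include_slope and not res.converged:
            warnings.warn("random-slope model did not converge; slope dropped")
            include_slope = False
            res = self._fit_one("1", reml=True)

        ci = res.conf_int()
        n_groups = self.data[self.group_col].nunique()

        def _triplet(name):
            return (
                float(res.params[name]),
                float(res.bse[name]),
                (float(ci.loc[name, 0]), float(ci.loc[name, 1])),
                float(res.pvalues[name]),
            )

        meta = {"formula": self._formula(), "re_formula": re_formula, "reml": True}
        if self.decompose:
            bw, sew, ciw, pw = _triplet(f"{self.exposure}_within")
            bb, seb, cib, pb = _triplet(f"{self.exposure}_between")
            return AssociationResults(
                exposure=self.exposure,
                outcome=self.outcome,
                beta=np.nan,
                se=np.nan,
                ci_low=np.nan,
                ci_high=np.nan,
                pvalue=np.nan,
                estimand="inter/intra",
                beta_intra=bw,
                intra_ci=ciw,
                intra_pvalue=pw,
                beta_inter=bb,
                inter_ci=cib,
                inter_pvalue=pb,
                n_obs=len(self.data),
                n_participants=n_groups,
                random_slope_included=include_slope,
                lrt_pvalue=lrt_p,
                converged=bool(res.converged),
                metadata=meta,
            )
        b, se, cib, p = _triplet(self.exposure)
        return AssociationResults(
            exposure=self.exposure,
            outcome=self.outcome,
            beta=b,
            se=se,
            ci_low=cib[0],
            ci_high=cib[1],
            pvalue=p,
            n_obs=len(self.data),
            n_participants=n_groups,
            random_slope_included=include_slope,
            lrt_pvalue=lrt_p,
            converged=bool(res.converged),
            metadata=meta,
        )


def decompose_inter_intra(
    panel: pd.DataFrame, exposure: str, group_col: str = "participant_id"
) -> pd.DataFrame:
    """Split an exposure into between- and within-person regressors.

    ``<exposure>_between`` = person mean minus grand mean;
    ``<exposure>_within`` = visit value minus person mean.  Their sum
    plus the grand mean reconstructs the exposure exactly.
    """
    out = panel.copy()
    person_mean = out.groupby(group_col)[exposure].transform("mean")
    grand = out[exposure].mean()
    out[f"{exposure}_between"] = person_mean - grand
    out[f"{exposure}_within"] = out[exposure] - person_mean
    return out


# ---------------------------------------------------------------------------
# multinomial acrophase model
# ---------------------------------------------------------------------------

@dataclass
class TertileModelResult:
    """Odds ratios for acrophase tertile membership per exposure unit."""

    exposure: str
    reference: int
    odds_ratios: dict[int, float]
    ci: dict[int, tuple[float, float]]
    pvalues: dict[int, float]
    n_obs: int
    n_participants: int
    separation_flag: bool
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Multinomial acrophase model, reference tertile {self.reference} "
            f"(n={self.n_obs}, participants={self.n_participants}, "
            f"cluster-robust SEs)"
        ]
        for k in sorted(self.odds_ratios):
            lo, hi = self.ci[k]
            lines.append(
                f"  tertile {k} vs {self.reference}: OR {self.odds_ratios[k]:6.3f} "
                f"95% CI ({lo:.3f}, {hi:.3f})  p={self.pvalues[k]:.3g}"
            )
        return "\n".join(lines) + "\n"


class MultinomialTertileModel:
    """Pooled multinomial logit of acrophase tertile with clustered SEs.

    The under-specified "longitudinal multinomial logistic regression"
    is implemented as a pooled participant-visit multinomial logit with
    participant-clustered sandwich standard errors.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        exposure: str,
        covariates=DEFAULT_COVARIATES,
        *,
        reference: int = 1,
        tertile_col: str = "acrophase_tertile",
        group_col: str = "participant_id",
        cluster: bool = True,
    ) -> None:
        if reference not in (1, 2, 3):
            raise ValueError("reference tertile must be 1, 2 or 3")
        self.exposure = exposure
        self.reference = reference
        self.covariates = tuple(covariates)
        self.cluster = cluster
        cols = [group_col, exposure, tertile_col] + _columns_in_terms(self.covariates)
        cols = [c for c in dict.fromkeys(cols) if c in panel.columns]
        data = panel[cols].dropna().copy()
        data = data[data[tertile_col].isin([1, 2, 3])]
        counts = data[tertile_col].value_counts()
        empty = [k for k in (1, 2, 3) if counts.get(k, 0) == 0]
        if empty:
            raise ValueError(f"empty acrophase tertile(s): {empty}")
        # relabel so the reference sorts first (statsmodels uses the
        # lowest category as the multinomial base)
        order = [reference] + [k for k in (1, 2, 3) if k != reference]
        self._code_to_tertile = {i: k for i, k in enumerate(order)}
        data["_y"] = data[tertile_col].map({k: i for i, k in enumerate(order)})
        self.data = data
        self.group_col = group_col
        self.tertile_col = tertile_col

    def fit(self) -> TertileModelResult:
        rhs = " + ".join([self.exposure] + list(self.covariates)) or "1"
        model = smf.mnlogit(f"_y ~ {rhs}", self.data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.cluster:
                res = model.fit(
                    method="newton",
                    maxiter=200,
                    disp=False,
                    cov_type="cluster",
                    cov_kwds={"groups": self.data[self.group_col]},
                )
            else:
                res = model.fit(method="newton", maxiter=200, disp=False)
        params = res.params  # columns: one per non-reference category code
        bse = res.bse
        conf = res.conf_int()
        ors, cis, pvals = {}, {}, {}
        z = stats.norm.ppf(0.975)
        for col in params.columns:
            tert = self._code_to_tertile[int(col) + 1]
            b = float(params.loc[self.exposure, col])
            se = float(bse.loc[self.exposure, col])
            ors[tert] = float(np.exp(b))
            cis[tert] = (float(np.exp(b - z * se)), float(np.exp(b + z * se)))
            pvals[tert] = float(res.pvalues.loc[self.exposure, col])
        separation = bool(np.any(np.abs(params.to_numpy()) > 15))
        if separation:
            warnings.warn("possible separation: extreme multinomial coefficients")
        return TertileModelResult(
            exposure=self.exposure,
            reference=self.reference,
            odds_ratios=ors,
            ci=cis,
            pvalues=pvals,
            n_obs=len(self.data),
            n_participants=self.data[self.group_col].nunique(),
            separation_flag=separation,
            metadata={
                "loglike": float(res.llf),
                "cov_type": "cluster" if self.cluster else "nonrobust",
                "params": params,
                "conf_int_raw": conf,
            },
        )


def fit_multinomial_acrophase(
    panel: pd.DataFrame,
    exposure: str,
    covariates=DEFAULT_COVARIATES,
    **kwargs,
) -> dict[str, TertileModelResult]:
    """Both parameterisations: tertile 1 reference (2v1, 3v1) and 2 reference (3v2)."""
    ref1 = MultinomialTertileModel(panel, exposure, covariates, reference=1, **kwargs).fit()
    ref2 = MultinomialTertileModel(panel, exposure, covariates, reference=2, **kwargs).fit()
    return {"ref1": ref1, "ref2": ref2}


# ---------------------------------------------------------------------------
# interaction / effect modification
# ---------------------------------------------------------------------------

def interaction_test(
    panel: pd.DataFrame,
    exposure: str,
    outcome: str,
    modifier: str,
    covariates=DEFAULT_COVARIATES,
    *,
    categorical: bool | None = None,
    group_col: str = "participant_id",
    alpha: float = 0.05,
) -> dict:
    """Joint Wald test for exposure x modifier interaction in the LMM.

    ``modifier`` is typically sex, BMI (continuous) or the visit label
    (indicator coding).  Returns the joint p-value and, when it falls
    below ``alpha`` and the modifier is categorical, per-level exposure
    effects (linear combinations of the main effect and interactions).
    """
    cols = [group_col, exposure, outcome, modifier] + _columns_in_terms(covariates)
    data = panel[[c for c in dict.fromkeys(cols) if c in panel.columns]].dropna().copy()
    if data[modifier].nunique() <= 1:
        raise ValueError(f"modifier {modifier!r} is constant")
    if categorical is None:
        categorical = not pd.api.types.is_numeric_dtype(data[modifier])
    mod_term = f"C({modifier})" if categorical else modifier
    covs = [t for t in covariates if modifier not in t]
    rhs = " + ".join([exposure, mod_term, f"{exposure}:{mod_term}"] + covs)
    model = smf.mixedlm(f"{outcome} ~ {rhs}", data, groups=data[group_col], re_formula="1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method=["lbfgs", "cg"], maxiter=200)
    inter_names = [p for p in res.fe_params.index if ":" in p]
    if not inter_names:
        raise RuntimeError("no interaction terms in the design")
    k_fe = len(res.fe_params)
    contrasts = np.zeros((len(inter_names), len(res.params)))
    for i, name in enumerate(inter_names):
        contrasts[i, list(res.params.index).index(name)] = 1.0
    wald = res.wald_test(contrasts, scalar=True)
    pval = float(np.squeeze(wald.pvalue))
    out = {
        "exposure": exposure,
        "outcome": outcome,
        "modifier": modifier,
        "p_interaction": pval,
        "significant": pval < alpha,
        "per_level": {},
    }
    if categorical:
        cov = res.cov_params().iloc[:k_fe, :k_fe].to_numpy()
        fe = res.fe_params
        names = list(fe.index)
        base_idx = names.index(exposure)
        levels = sorted(data[modifier].astype(str).unique())
        for lev in levels:
            vec = np.zeros(k_fe)
            vec[base_idx] = 1.0
            for i, name in enumerate(names):
                if ":" in name and f"[T.{lev}]" in name:
                    vec[i] = 1.0
            est = float(vec @ fe.to_numpy())
            se = float(np.sqrt(vec @ cov @ vec))
            out["per_level"][lev] = {"beta": est, "se": se}
    return out


# ---------------------------------------------------------------------------
# time-lag sensitivity models
# ---------------------------------------------------------------------------

def make_lagged_panel(
    panel: pd.DataFrame,
    outcome_cols,
    *,
    visit_index_col: str = "visit_index",
    group_col: str = "participant_id",
) -> pd.DataFrame:
    """Pair each visit's exposures/covariates with the next visit's outcome.

    Row (i, k) keeps everything measured at visit k but replaces the
    outcome columns by their value at visit k+1; participants without a
    consecutive next visit contribute no row.
    """
    outcome_cols = [outcome_cols] if isinstance(outcome_cols, str) else list(outcome_cols)
    df = panel.sort_values([group_col, visit_index_col])
    nxt = df.groupby(group_col)[outcome_cols + [visit_index_col]].shift(-1)
    keep = nxt[visit_index_col] == df[visit_index_col] + 1
    lagged = df[keep].copy()
    for c in outcome_cols:
        lagged[c] = nxt.loc[keep, c]
    if lagged.empty:
        raise ValueError("no consecutive visit pairs available for the time-lag model")
    return lagged


def fit_time_lag(
    panel: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates=DEFAULT_COVARIATES,
    **kwargs,
) -> AssociationResults:
    """Exposure at visit k vs outcome at visit k+1 (covariates at k)."""
    lagged = make_lagged_panel(panel, outcome)
    res = MixedEffectsAssociation(lagged, exposure, outcome, covariates, **kwargs).fit()
    res.estimand = "time_lag"
    res.metadata["lagged_rows"] = len(lagged)
    return res


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; see fit_models)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# baseline correlations
# ---------------------------------------------------------------------------

def correlations_baseline(
    panel: pd.DataFrame,
    exposures,
    outcomes,
    *,
    visit_index_col: str = "visit_index",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Pearson r at the first visit (exposures x outcomes)."""
    first = panel[panel[visit_index_col] == panel[visit_index_col].min()]
    mat = pd.DataFrame(index=list(exposures), columns=list(outcomes), dtype=float)
    for e in exposures:
        for o in outcomes:
            x, y = first[e], first[o]
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                mat.loc[e, o] = np.nan
            else:
                mat.loc[e, o] = float(x[ok].corr(y[ok]))
    return mat
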