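"""Covariate-adjusted associations between shape modes and OA outcomes.

Each hip shape mode, expressed in cohort SD units, is modelled as a
continuous exposure against each outcome: binary outcomes (radiographic
hip OA, binary radiographic features, binary pain measures) by
maximum-likelihood logistic regression, the 0-20 WOMAC composite by
proportional-odds (ordinal logistic) regression.  Results are odds
ratios per SD increase in the mode, with Wald 95% confidence intervals
exp(beta +/- 1.96 SE) and two-sided Wald p-values.  Adjusted models
include age, height, weight and race (indicator-coded against a "white"
reference) as a priori confounders.  With the ten highest-variance
modes treated as independent exposures, the Bonferroni-corrected
significance threshold is 0.05 / 10 = 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "SeparationError",
    "encode_covariates",
    "fit_logistic",
    "fit_ordinal",
    "bonferroni_threshold",
    "collapse_sparse_levels",
    "default_battery",
    "run_association_battery",
]

_Z95 = 1.96  # Wald 95% CI multiplier


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect separation)."""


@dataclass(frozen=True)
class AssociationResult:
    """OR per SD for one exposure-outcome pair."""

    exposure: str
    outcome: str
    model: str  # "logistic" or "ordinal"
    or_per_sd: float
    ci95: tuple[float, float]
    p: float
    n_used: int
    adjusted: bool

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.or_per_sd <= hi):
            raise ValueError("point estimate outside its confidence interval")


def encode_covariates(covariates: pd.DataFrame, reference: str = "white") -> pd.DataFrame:
    """Design columns for age/height/weight/race adjustment.

    Race is expanded to indicator contrasts against ``reference``
    (the largest category).  Continuous covariates pass through.
    """
    cov = covariates.copy()
    if "race" in cov.columns:
        dummies = pd.get_dummies(cov["race"], prefix="race", dtype=float)
        ref_col = f"race_{reference}"
        if ref_col in dummies.columns:
            dummies = dummies.drop(columns=ref_col)
        cov = pd.concat([cov.drop(columns="race"), dummies], axis=1)
    return cov.astype(float)


def _design(exposure, covariates, exposure_name: str) -> pd.DataFrame:
    X = pd.DataFrame({exposure_name: np.asarray(exposure, dtype=float)})
    if covariates is not None:
        cov = encode_covariates(pd.DataFrame(covariates)).reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    return X


def _result_from_fit(params, bses, pvalues, exposure_name, outcome_name, model,
                     n_used, adjusted) -> AssociationResult:
    b = float(params[exposure_name])
    se = float(bses[exposure_name])
    return AssociationResult(
        exposure=exposure_name,
        outcome=outcome_name,
        model=model,
        or_per_sd=float(np.exp(b)),
        ci95=(float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se))),
        p=float(pvalues[exposure_name]),
        n_used=int(n_used),
        adjusted=adjusted,
    )


def fit_logistic(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Logistic regression of a binary outcome on a continuous exposure.

    Complete-case: rows with any missing value are dropped and the
    remaining count reported as ``n_used``.  Raises SeparationError if
    the likelihood has no finite maximizer.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    X = _design(exposure, covariates, exposure_name)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"outcome must be binary 0/1, saw values {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    Xc = sm.add_constant(X, prepend=True)
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence checked explicitly below
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", True):
                fit = None
        except (PerfectSeparationError, np.linalg.LinAlgError):
            fit = None
        if fit is None:
            # Newton stumbles on near-separated tables (singular Hessian);
            # BFGS still finds the finite MLE when one exists
            try:
                fit = sm.Logit(y, Xc).fit(
                    method="bfgs", maxiter=2000, gtol=1e-8, disp=0
                )
            except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
                raise SeparationError(
                    f"separation fitting {exposure_name!r}: {exc}"
                ) from exc
    grad = np.max(np.abs(np.asarray(fit.mle_retvals.get("gopt", [0.0]))))
    if not fit.mle_retvals.get("converged", True) and not grad < 1e-4:
        raise SeparationError(
            f"non-convergence (possible separation) fitting {exposure_name!r}"
        )
    if np.abs(fit.params[exposure_name]) > 20:
        raise SeparationError(f"diverging coefficient for {exposure_name!r}")
    return _result_from_fit(
        fit.params, fit.bse, fit.pvalues, exposure_name, outcome_name,
        "logistic", len(y), covariates is not None,
    )


def collapse_sparse_levels(y: pd.Series, min_count: int = 5) -> pd.Series:
    """Merge sparse ordinal levels downward until every level has >= min_count.

    The 0-20 WOMAC composite has a long sparse upper tail; proportional
    odds fitting needs every modelled category populated.  Levels are
    merged from the top into the next lower level, preserving order.
    Returns dense 0..K-1 integer codes.
    """
    y = pd.Series(y).astype(float)
    levels = sorted(y.dropna().unique())
    counts = y.value_counts()
    merged = {lv: lv for lv in levels}
    work = list(levels)
    cnt = {lv: int(counts.get(lv, 0)) for lv in levels}
    i = len(work) - 1
    while i > 0 and len(work) > 2:
        if cnt[work[i]] < min_count:
            cnt[work[i - 1]] += cnt[work[i]]
            absorbed = work.pop(i)
            for lv in levels:
                if merged[lv] == absorbed:
                    merged[lv] = work[i - 1]
        i -= 1
    rank = {lv: r for r, lv in enumerate(work)}
    return y.map(lambda v: rank[merged[v]] if pd.notna(v) else np.nan)


def fit_ordinal(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    min_level_count: int = 5,
) -> AssociationResult:
    """Proportional-odds regression of an ordinal outcome on an exposure.

    The common odds ratio per SD applies across all outcome thresholds.
    Sparse top levels are collapsed so every modelled category has at
    least ``min_level_count`` observations.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    X = _design(exposure, covariates, exposure_name)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep].reset_index(drop=True), X[keep].reset_index(drop=True)
    y = collapse_sparse_levels(y, min_count=min_level_count)
    if y.nunique() < 2:
        raise ValueError("ordinal outcome has fewer than 2 levels after collapsing")
    model = OrderedModel(y.astype(int), X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence judged on the gradient below
        fit = model.fit(method="bfgs", maxiter=500, gtol=1e-8, disp=False)
    grad = np.max(np.abs(fit.mle_retvals.get("gopt", [np.inf])))
    if not fit.mle_retvals.get("converged", True) and not grad < 1e-4:
        raise RuntimeError(
            f"proportional-odds fit did not converge for {exposure_name!r} "
            f"(max |gradient| {grad:.2e})"
        )
    return _result_from_fit(
        fit.params, fit.bse, fit.pvalues, exposure_name, outcome_name,
        "ordinal", len(y), covariates is not None,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for m independent exposures."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def default_battery(
    croft_thresholds=(2, 3),
    osteophyte_grades=(1, 2),
    jsn_grade: int = 1,
    sclerosis_grade: int = 1,
) -> list[dict]:
    """The standard outcome battery: RHOA, component features, pain, WOMAC.

    Each item is a declarative dict: ``column`` names an outcomes-table
    column; a non-None ``threshold`` dichotomizes it at >= threshold;
    ``model`` picks logistic or proportional-odds.
    """
    items: list[dict] = []
    for t in croft_thresholds:
        items.append(
            {"name": f"rhoa_croft{t}", "column": "croft_grade", "threshold": t,
             "model": "logistic"}
        )
    sites = ["lateral_acetabular", "lateral_femoral", "inferior_acetabular",
             "inferior_femoral"]
    for g in osteophyte_grades:
        for s in sites:
            items.append(
                {"name": f"osteophyte_{s}_ge{g}", "column": f"osteophyte_{s}",
                 "threshold": g, "model": "logistic"}
            )
    for r in ["medial", "lateral", "concentric"]:
        items.append(
            {"name": f"jsn_{r}_ge{jsn_grade}", "column": f"jsn_{r}",
             "threshold": jsn_grade, "model": "logistic"}
        )
    items.append(
        {"name": f"sclerosis_ge{sclerosis_grade}", "column": "sclerosis",
         "threshold": sclerosis_grade, "model": "logistic"}
    )
    items.append(
        {"name": "pain_internal_rotation", "column": "pain_internal_rotation",
         "threshold": 1, "model": "logistic"}
    )
    items.append(
        {"name": "walking_pain", "column": "walking_pain_raw", "threshold": 1,
         "model": "logistic"}
    )
    items.append({"name": "womac", "column": "womac", "threshold": None,
                  "model": "ordinal"})
    return items


def run_association_battery(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    battery: list[dict] | None = None,
    n_modes: int = 10,
    alpha: float = 0.05,
    adjusted_settings=(False, True),
    max_join_loss: float = 0.2,
) -> pd.DataFrame:
    """Fit every (mode, outcome, adjustment) cell of the battery.

    ``scores`` has columns ``image_id, mode_1..mode_k`` (SD units);
    ``outcomes`` has ``image_id`` plus the battery's outcome columns;
    ``covariates`` has ``image_id, age, height, weight, race``.  Tables
    are inner-joined on ``image_id``.  Per-cell model failures are
    recorded in the ``error`` column rather than aborting the battery.
    Rows are flagged significant when p < alpha / n_modes.
    """
    if battery is None:
        battery = default_battery()
    df = scores.merge(outcomes, on="image_id", how="inner")
    if covariates is not None:
        df = df.merge(covariates, on="image_id", how="inner")
    lost = 1.0 - len(df) / max(len(scores), 1)
    if lost > max_join_loss:
        warnings.warn(
            f"join lost {lost:.1%} of scored participants "
            f"({len(scores)} -> {len(df)})", stacklevel=2,
        )
    thresh = bonferroni_threshold(alpha, n_modes)
    cov_cols = ["age", "height", "weight", "race"]
    rows = []
    for item in battery:
        col = item["column"]
        y_raw = df[col]
        y = (y_raw >= item["threshold"]).astype(float) if item["threshold"] is not None else y_raw
        y = y.where(y_raw.notna())
        for mode in range(1, n_modes + 1):
            expo = df[f"mode_{mode}"]
            for adjusted in adjusted_settings:
                cov = df[cov_cols] if (adjusted and covariates is not None) else None
                base = {
                    "exposure": f"mode_{mode}", "outcome": item["name"],
                    "model": item["model"], "adjusted": bool(adjusted),
                }
                try:
                    fitter = fit_logistic if item["model"] == "logistic" else fit_ordinal
                    res = fitter(
                        y, expo, cov, exposure_name=f"mode_{mode}",
                        outcome_name=item["name"],
                    )
                    rows.append({
                        **base, "or": res.or_per_sd, "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1], "p": res.p, "n_used": res.n_used,
                        "significant": res.p < thresh, "error": "",
                    })
                except Exception as exc:  # per-cell failures are data, not fatal
                    rows.append({
                        **base, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan, "n_used": 0, "significant": False,
                        "error": f"{type(exc).__name__}: {exc}",
                    })
    return pd.DataFrame(rows)
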