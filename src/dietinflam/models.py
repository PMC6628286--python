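"""Unconditional logistic regression layer for case-control analyses.

Exposure–outcome associations are estimated by maximum likelihood on the
binomial logit model (IRLS, relative tolerance 1e-10, at most 100
iterations), with Wald 95% confidence intervals ``exp(beta +- 1.96 * se)``.
On top of the single fit the module provides the standard epidemiologic
machinery:

* crude 2x2 odds ratio with Woolf interval (also the independent oracle for
  the regression on a saturated binary design);
* dose-response trend tests (exposure entered as the ordinal quartile index
  1..4);
* likelihood-ratio tests for effect-measure modification (models with and
  without exposure x modifier terms);
* stratified analyses (stratifier dropped from the covariate set per
  stratum);
* the three conventional sensitivity analyses: excluding cases interviewed
  more than six months after diagnosis, additionally adjusting for
  non-alcohol energy and alcohol intake, and restricting to non-drinkers.

Categorical covariates are dummy-coded against a declared (or first sorted)
reference level; an explicit "unknown" level is retained as its own dummy,
never dropped.  No multiple-testing correction is applied; reports annotate
the number of tests run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("dietinflam.models")

__all__ = [
    "ModelSpec",
    "ModelResult",
    "LrtResult",
    "FitError",
    "fit_logistic",
    "crude_or_2x2",
    "trend_test",
    "lrt_interaction",
    "stratified_analysis",
    "sensitivity_suite",
    "or_report",
]

EXPOSURE_TYPES = ("continuous", "ordinal", "quartile", "categorical")


class FitError(RuntimeError):
    """Model could not be estimated (rank deficiency, separation, no data)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one logistic model.

    ``exposure_type``:
      * ``continuous`` — per-unit effect of a numeric score;
      * ``ordinal`` — numeric 1..4 quartile index (trend coding);
      * ``quartile`` — indicator set over quartiles 1..4, Q1 reference;
      * ``categorical`` — indicator set over string levels, reference either
        declared via ``exposure_ref`` or the first sorted level.
    """

    exposure: str
    exposure_type: str = "continuous"
    covariates: tuple[str, ...] = ()
    outcome: str = "case_status"
    categorical_refs: dict = field(default_factory=dict)
    exposure_ref: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.exposure_type not in EXPOSURE_TYPES:
            raise ValueError(f"exposure_type must be one of {EXPOSURE_TYPES}")


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float


@dataclass
class ModelResult:
    """Estimates from one fitted logistic model.

    ``terms`` is indexed by term name with columns estimate (log-odds), se,
    or, ci_low, ci_high, p; ``exposure_terms`` names the rows belonging to
    the exposure.
    """

    terms: pd.DataFrame
    loglik: float
    n_cases: int
    n_controls: int
    n_excluded: int
    exposure_terms: list[str]
    label: str = ""
    trend_p: float | None = None
    lrt: LrtResult | None = None

    def exposure_or(self) -> pd.DataFrame:
        return self.terms.loc[self.exposure_terms, ["or", "ci_low", "ci_high", "p"]]


def _dummy_columns(series: pd.Series, name: str, ref: str | None) -> pd.DataFrame:
    levels = sorted(series.astype(str).unique())
    if ref is None:
        ref = levels[0]
    elif ref not in levels:
        raise FitError(f"declared reference level {ref!r} absent from column {name!r}")
    cols = {}
    for level in levels:
        if level == ref:
            continue
        cols[f"{name}[{level}]"] = (series.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=series.index)


def _build_design(study: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame, int, list[str]]:
    """Return (y, X with intercept, n rows dropped, exposure term names)."""
    used = [spec.outcome, spec.exposure, *spec.covariates]
    missing = [c for c in used if c not in study.columns]
    if missing:
        raise FitError(f"column(s) {missing} absent from the study table")
    data = study.loc[:, used].dropna()
    n_excluded = len(study) - len(data)

    y = data[spec.outcome].astype(int)
    if set(y.unique()) != {0, 1}:
        raise FitError(f"outcome {spec.outcome!r} must carry both levels 0 and 1")

    parts: list[pd.DataFrame] = []
    exposure_terms: list[str]
    exp = data[spec.exposure]
    if spec.exposure_type in ("continuous", "ordinal"):
        parts.append(exp.astype(float).to_frame(spec.exposure))
        exposure_terms = [spec.exposure]
    elif spec.exposure_type == "quartile":
        quart = exp.astype(int)
        if not quart.isin([1, 2, 3, 4]).all():
            raise FitError(f"quartile exposure {spec.exposure!r} must lie in 1..4")
        dummies = _dummy_columns(quart.map(lambda q: f"Q{q}"), spec.exposure, "Q1")
        parts.append(dummies)
        exposure_terms = list(dummies.columns)
    else:
        dummies = _dummy_columns(exp, spec.exposure, spec.exposure_ref)
        parts.append(dummies)
        exposure_terms = list(dummies.columns)

    for cov in spec.covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col) and cov not in spec.categorical_refs:
            parts.append(col.astype(float).to_frame(cov))
        else:
            parts.append(_dummy_columns(col, cov, spec.categorical_refs.get(cov)))

    X = pd.concat(parts, axis=1)
    X.insert(0, "const", 1.0)
    return y, X, n_excluded, exposure_terms


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        constant = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
        detail = f"constant column(s) {constant}" if constant else "collinear columns"
        raise FitError(f"design matrix is rank deficient ({detail})")


def _fit_glm(y: pd.Series, X: pd.DataFrame):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        fit = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparation subclasses
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.converged:
        raise FitError(f"IRLS did not converge in 100 iterations (deviance {fit.deviance:.6g})")
    if np.abs(fit.params.to_numpy()).max() > 30:
        raise FitError(
            "estimates diverged (|log-odds| > 30); the data likely exhibit "
            f"separation on term(s) {list(fit.params.abs().nlargest(3).index)}"
        )
    return fit


def fit_logistic(study: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Maximum-likelihood fit of the logistic model described by ``spec``.

    Rows with missing values in any used column are excluded and counted in
    ``n_excluded`` (an explicit "unknown" category is a level, not a missing
    value, and is retained).
    """
    y, X, n_excluded, exposure_terms = _build_design(study, spec)
    _check_rank(X)
    fit = _fit_glm(y, X)
    est = fit.params
    se = fit.bse
    z = est / se
    terms = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "or": np.exp(est),
            "ci_low": np.exp(est - 1.96 * se),
            "ci_high": np.exp(est + 1.96 * se),
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        }
    )
    return ModelResult(
        terms=terms,
        loglik=float(fit.llf),
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        n_excluded=n_excluded,
        exposure_terms=exposure_terms,
        label=spec.label,
    )


def crude_or_2x2(a: float, b: float, c: float, d: float) -> dict:
    """Crude odds ratio from a 2x2 table with Woolf 95% CI.

    ``a``/``b`` = exposed cases/controls, ``c``/``d`` = unexposed
    cases/controls.  OR = a*d / (b*c); CI = exp(ln OR +- 1.96 *
    sqrt(1/a + 1/b + 1/c + 1/d)).  Zero cells are an error (no continuity
    correction is applied by default).
    """
    cells = {"a": a, "b": b, "c": c, "d": d}
    if any(v < 0 for v in cells.values()):
        raise ValueError(f"negative cell count: {cells}")
    zero = [k for k, v in cells.items() if v == 0]
    if zero:
        raise ValueError(f"zero cell(s) {zero}: crude OR undefined without correction")
    or_ = (a * d) / (b * c)
    half = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {"or": or_, "ci95": (or_ * math.exp(-half), or_ * math.exp(half))}


def trend_test(study: pd.DataFrame, spec: ModelSpec) -> float:
    """Dose-response trend p-value.

    The exposure (a quartile index 1..4, or any ordinal code) is entered as a
    single continuous ordinal term in the covariate-adjusted model; the Wald
    p-value of that coefficient is returned.
    """
    ordinal = replace(spec, exposure_type="ordinal")
    result = fit_logistic(study, ordinal)
    return float(result.terms.loc[spec.exposure, "p"])


def lrt_interaction(study: pd.DataFrame, spec: ModelSpec, modifier: str) -> LrtResult:
    """Likelihood-ratio test for effect modification by ``modifier``.

    Compares the covariate-adjusted model (with the modifier as a main
    effect) against the same model plus exposure x modifier product terms.
    The statistic ``2 * (ll_with - ll_without)`` is nonnegative by nesting;
    degrees of freedom equal the number of product terms added.
    """
    if modifier in study.columns and study[modifier].dropna().nunique() <= 1:
        # a constant modifier admits no interaction contrast
        return LrtResult(0.0, 0, 1.0)
    base_spec = spec if modifier in spec.covariates else replace(
        spec, covariates=(*spec.covariates, modifier)
    )
    y, X0, _, exposure_terms = _build_design(study, base_spec)
    _check_rank(X0)

    mod_cols = [c for c in X0.columns if c.startswith(f"{modifier}[")]
    if not mod_cols and modifier in X0.columns:
        mod_cols = [modifier]
    products = {}
    for et in exposure_terms:
        for mc in mod_cols:
            col = X0[et] * X0[mc]
            if col.nunique() > 1:  # drop degenerate (e.g. constant-zero) products
                products[f"{et}:{mc}"] = col
    products = {
        name: col for name, col in products.items()
        if not any((col == X0[c]).all() for c in X0.columns)
    }
    if not products:
        return LrtResult(0.0, 0, 1.0)
    X1 = pd.concat([X0, pd.DataFrame(products, index=X0.index)], axis=1)
    _check_rank(X1)
    fit0 = _fit_glm(y, X0)
    fit1 = _fit_glm(y, X1)
    statistic = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    df = len(products)
    return LrtResult(statistic, df, float(stats.chi2.sf(statistic, df)))


def stratified_analysis(
    study: pd.DataFrame, spec: ModelSpec, stratifier: str
) -> dict[str, ModelResult]:
    """Refit the model within each level of ``stratifier``.

    The stratifier is removed from the covariate set (it is constant within a
    stratum).  Strata that are empty or lack one outcome level are skipped
    with a warning.
    """
    if stratifier not in study.columns:
        raise FitError(f"stratifier {stratifier!r} absent from the study table")
    stratum_spec = replace(
        spec, covariates=tuple(c for c in spec.covariates if c != stratifier)
    )
    out: dict[str, ModelResult] = {}
    for level, subset in study.groupby(study[stratifier].astype(str), sort=True):
        outcomes = set(subset[spec.outcome].dropna().astype(int).unique())
        if outcomes != {0, 1}:
            logger.warning("stratum %s=%r skipped: one outcome level only", stratifier, level)
            continue
        result = fit_logistic(subset, replace(stratum_spec, label=f"{stratifier}={level}"))
        out[level] = result
    return out


def sensitivity_suite(
    study: pd.DataFrame,
    spec: ModelSpec,
    months_col: str = "months_diagnosis_to_interview",
    energy_col: str = "energy_nonalcohol",
    alcohol_col: str = "alcohol_g",
) -> dict[str, ModelResult]:
    """The three conventional sensitivity re-fits of a final model.

    1. ``exclude_delayed`` — drop cases interviewed more than 6 months after
       diagnosis (controls are kept);
    2. ``energy_alcohol_adjusted`` — further adjust for energy from
       non-alcohol sources and alcohol grams/day;
    3. ``nondrinkers`` — restrict to subjects reporting zero alcohol.

    A sensitivity whose required column is missing is skipped with a warning.
    """
    out: dict[str, ModelResult] = {}

    if months_col in study.columns:
        is_case = study[spec.outcome].astype(int) == 1
        delayed = is_case & (study[months_col] > 6)
        kept = study.loc[~delayed]
        result = fit_logistic(kept, replace(spec, label="exclude_delayed"))
        result.n_excluded += int(delayed.sum())
        out["exclude_delayed"] = result
    else:
        logger.warning("sensitivity 'exclude_delayed' skipped: %r missing", months_col)

    if energy_col in study.columns and alcohol_col in study.columns:
        extra = tuple(
            c for c in (energy_col, alcohol_col)
            if c not in spec.covariates and study[c].dropna().nunique() > 1
        )
        out["energy_alcohol_adjusted"] = fit_logistic(
            study, replace(spec, covariates=(*spec.covariates, *extra),
                           label="energy_alcohol_adjusted")
        )
    else:
        logger.warning("sensitivity 'energy_alcohol_adjusted' skipped: columns missing")

    if alcohol_col in study.columns:
        nondrinkers = study.loc[study[alcohol_col] == 0]
        if set(nondrinkers[spec.outcome].dropna().astype(int).unique()) == {0, 1}:
            out["nondrinkers"] = fit_logistic(nondrinkers, replace(spec, label="nondrinkers"))
        else:
            logger.warning("sensitivity 'nondrinkers' skipped: outcome degenerate")
    else:
        logger.warning("sensitivity 'nondrinkers' skipped: %r missing", alcohol_col)
    return out


def or_report(results: dict[str, ModelResult], digits: int = 6) -> pd.DataFrame:
    """Flatten exposure estimates of several models into one tidy table.

    One row per (model, exposure term): OR, CI bounds, Wald p, trend p where
    available, LRT p where available, and the analysis sample sizes — the
    layout of a standard case-control results table.
    """
    rows = []
    for name, res in results.items():
        for term in res.exposure_terms:
            t = res.terms.loc[term]
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "or": round(t["or"], digits),
                    "ci_low": round(t["ci_low"], digits),
                    "ci_high": round(t["ci_high"], digits),
                    "p": round(t["p"], digits),
                    "trend_p": round(res.trend_p, digits) if res.trend_p is not None else "",
                    "lrt_p": round(res.lrt.p, digits) if res.lrt is not None else "",
                    "n_cases": res.n_cases,
                    "n_controls": res.n_controls,
                }
            )
    return pd.DataFrame(rows)
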