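"""One-sample MR: logistic regression of case status on the scaled GRS.

The causal log odds ratio per year of exposure is read off a
maximum-likelihood logistic fit of disease on the year-scaled score,
adjusted for age, study and principal components of genetic ancestry (and
optionally further scores, e.g. a BMI risk score).  Consortium-level
estimates are pooled by inverse-variance fixed-effects meta-analysis.
Stratified analyses refit the model per stratum and test effect
heterogeneity with a likelihood-ratio test on the score-by-stratum
interaction; colon-vs-rectum heterogeneity uses the case-only design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._estimate import MrEstimate
from .grs import GrsVector

__all__ = [
    "ConvergenceError",
    "StratifiedResult",
    "fit_grs_logistic",
    "meta_fixed",
    "stratified_analysis",
    "site_heterogeneity_case_only",
]

MISSING_LEVELS = {"missing", "none", "nan", ""}


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge or the outcome is separable."""


def _as_binary(case_status: pd.Series) -> np.ndarray:
    if case_status.dtype == object or isinstance(case_status.dtype, pd.CategoricalDtype):
        return (case_status.astype(str) == "case").to_numpy(dtype=float)
    return case_status.to_numpy(dtype=float)


def _design(
    cohort: pd.DataFrame,
    score: np.ndarray,
    covariates: list[str],
    extra_scores: list[np.ndarray] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the regression design; complete-case on used columns."""
    frame = pd.DataFrame({"grs": score}, index=cohort.index)
    for i, extra in enumerate(extra_scores or []):
        frame[f"extra_score_{i + 1}"] = np.asarray(extra, float)
    for col in covariates:
        if col not in cohort.columns:
            raise KeyError(f"covariate column {col!r} not in cohort")
        if cohort[col].dtype == object:
            dummies = pd.get_dummies(cohort[col].astype(str), prefix=col,
                                     drop_first=True, dtype=float)
            frame = pd.concat([frame, dummies], axis=1)
        else:
            frame[col] = cohort[col].to_numpy(dtype=float)
    y = _as_binary(cohort["case_status"])
    keep = np.isfinite(frame.to_numpy(dtype=float)).all(axis=1) & np.isfinite(y)
    frame = sm.add_constant(frame.loc[keep], has_constant="add")
    return frame, y[keep]


def _fit_logit(X: pd.DataFrame, y: np.ndarray) -> sm.Logit:
    if y.sum() == 0 or y.sum() == len(y):
        raise ConvergenceError("need at least one case and one control")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence issues raised below
            result = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    if not np.isfinite(result.bse).all():
        raise ConvergenceError("non-finite standard errors (separation?)")
    return result


def default_covariates(cohort: pd.DataFrame, n_pcs: int = 3) -> list[str]:
    """Age, study and the first ``n_pcs`` principal-component columns."""
    cols = [c for c in ("age", "study") if c in cohort.columns]
    cols += [f"pc{i + 1}" for i in range(n_pcs) if f"pc{i + 1}" in cohort.columns]
    return cols


def fit_grs_logistic(
    cohort: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    covariates: list[str] | None = None,
    extra_scores: list | None = None,
    method_label: str = "grs_logistic",
) -> MrEstimate:
    """Covariate-adjusted logistic fit; beta is the GRS coefficient.

    ``extra_scores`` supports sensitivity adjustment by further risk scores
    (each entered as one additional linear term).  Non-convergence or
    complete separation raises :class:`ConvergenceError` — never a silent
    fallback.
    """
    score = grs.values if isinstance(grs, GrsVector) else np.asarray(grs, float)
    if np.var(score) == 0:
        raise ValueError("GRS has zero variance")
    covariates = default_covariates(cohort) if covariates is None else list(covariates)
    extras = [e.values if isinstance(e, GrsVector) else np.asarray(e, float)
              for e in (extra_scores or [])]
    X, y = _design(cohort, score, covariates, extras)
    result = _fit_logit(X, y)
    return MrEstimate(
        method=method_label,
        beta=float(result.params["grs"]),
        se=float(result.bse["grs"]),
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )


def meta_fixed(estimates: list[MrEstimate], method_label: str | None = None) -> MrEstimate:
    """Inverse-variance fixed-effects pooling of log-OR estimates."""
    if not estimates:
        raise ValueError("nothing to pool")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    n_cases = sum(e.n_cases for e in estimates) if all(
        e.n_cases is not None for e in estimates) else None
    n_controls = sum(e.n_controls for e in estimates) if all(
        e.n_controls is not None for e in estimates) else None
    return MrEstimate(
        method=method_label or f"meta_fixed({estimates[0].method})",
        beta=beta, se=se, n_cases=n_cases, n_controls=n_controls,
    )


@dataclass
class StratifiedResult:
    """Per-stratum estimates plus an interaction likelihood-ratio test."""

    stratum: str
    estimates: dict[str, MrEstimate]
    heterogeneity_p: float | None
    undefined: bool = False


def stratified_analysis(
    cohort: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    stratum: str,
    covariates: list[str] | None = None,
) -> StratifiedResult:
    """Refit per stratum level; LRT on the GRS-by-stratum interaction.

    Individuals with a missing stratum value are excluded.  The
    heterogeneity p-value compares the pooled model with and without
    interaction terms (chi-square, levels − 1 df).  A single-level stratum
    leaves heterogeneity undefined and is flagged, not raised.
    """
    score = grs.values if isinstance(grs, GrsVector) else np.asarray(grs, float)
    covariates = default_covariates(cohort) if covariates is None else list(covariates)
    values = cohort[stratum].astype(str)
    usable = ~values.str.lower().isin(MISSING_LEVELS) & values.notna()
    sub = cohort.loc[usable].reset_index(drop=True)
    sub_score = score[np.asarray(usable)]
    levels = sorted(sub[stratum].astype(str).unique())

    estimates: dict[str, MrEstimate] = {}
    for level in levels:
        mask = (sub[stratum].astype(str) == level).to_numpy()
        estimates[level] = fit_grs_logistic(
            sub.loc[mask].reset_index(drop=True), sub_score[mask],
            covariates=[c for c in covariates if c != stratum],
            method_label=f"{stratum}={level}",
        )

    if len(levels) < 2:
        return StratifiedResult(stratum, estimates, None, undefined=True)

    base_cov = [c for c in covariates if c != stratum] + [stratum]
    X0, y0 = _design(sub, sub_score, base_cov)
    strat_dummies = pd.get_dummies(sub[stratum].astype(str), prefix="ix",
                                   drop_first=True, dtype=float).loc[X0.index]
    X1 = X0.copy()
    for col in strat_dummies.columns:
        X1[f"grs_x_{col}"] = X0["grs"] * strat_dummies[col]
    ll0 = _fit_logit(X0, y0).llf
    ll1 = _fit_logit(X1, y0).llf
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p_het = float(stats.chi2.sf(lrt, df=len(levels) - 1))
    return StratifiedResult(stratum, estimates, p_het)


def site_heterogeneity_case_only(
    cases: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    covariates: list[str] | None = None,
) -> float:
    """Case-only test of colon-vs-rectum effect heterogeneity.

    Logistic regression of tumour site on the score among cases (adjusted
    as the main model); the Wald p-value of the score term tests whether the
    exposure effect differs between the two sites.
    """
    score = grs.values if isinstance(grs, GrsVector) else np.asarray(grs, float)
    sites = cases["site"].astype(str)
    n_colon = int((sites == "colon").sum())
    n_rectum = int((sites == "rectum").sum())
    if n_colon == 0 or n_rectum == 0:
        raise ValueError("case-only test needs both colon and rectal cases")
    if np.var(score) == 0:
        raise ValueError("GRS has zero variance among cases")
    covariates = default_covariates(cases) if covariates is None else list(covariates)
    sub = cases.loc[sites.isin(["colon", "rectum"])].reset_index(drop=True)
    sub_score = score[np.asarray(sites.isin(["colon", "rectum"]))]
    pseudo = sub.copy()
    pseudo["case_status"] = np.where(sub["site"].astype(str) == "colon", "case", "control")
    X, y = _design(pseudo, sub_score, covariates)
    result = _fit_logit(X, y)
    return float(result.pvalues["grs"])
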