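"""Instrument diagnostics and study power.

Covers the three instrumental-variable assumptions and the design question
of what effect size the study could detect:

* instrument strength via the F-statistic ``R²(n−K−1)/((1−R²)K)``, with the
  conventional F > 10 rule of thumb — here the GRS is one instrument
  (K = 1) and *n* the analysis sample size;
* a confounder screen regressing known risk factors on the score among
  controls (linear for continuous, logistic for binary, multinomial for
  multi-level factors), which should come up null for a valid instrument;
* power of the score's Wald test on a binary outcome, analytically via the
  normal approximation and by Monte-Carlo simulation of score-outcome
  cohorts at the study's exact case/control counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PowerSpec",
    "ConfounderScreenRow",
    "f_statistic",
    "instrument_is_strong",
    "confounder_screen",
    "mr_power",
]

F_STRONG_THRESHOLD = 10.0


def f_statistic(r2: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic ``R²(n−K−1)/((1−R²)K)``.

    ``r2`` is the exposure variance explained by the instrument, ``n`` the
    sample size, ``k`` the number of instruments (1 for a single combined
    risk score).
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    return r2 * (n - k - 1) / ((1.0 - r2) * k)


def instrument_is_strong(f: float) -> bool:
    """Conventional strength rule: F above 10."""
    return f > F_STRONG_THRESHOLD


# confounder screen ---------------------------------------------------------

@dataclass
class ConfounderScreenRow:
    risk_factor: str
    model: str  # linear | logistic | multinomial | constant
    coefficient: float | None
    pvalue: float | None
    flagged: bool = False


DEFAULT_SCREEN_FACTORS = (
    "smoking", "family_history", "education", "aspirin_use",
    "bmi", "mht_combined", "mht_estrogen_only",
)

_MISSING = {"missing", "nan", ""}


def confounder_screen(
    grs,
    cohort: pd.DataFrame,
    factors: tuple[str, ...] | list[str] | None = None,
    controls_only: bool = True,
) -> list[ConfounderScreenRow]:
    """Association screen of risk factors on the score, among controls.

    Continuous factors use linear regression of the factor on the score;
    two-level factors logistic regression; multi-level factors multinomial
    logistic with a likelihood-ratio p-value.  Constant factors are flagged
    with no p-value.  Raw p-values are reported without multiplicity
    correction.
    """
    score = np.asarray(grs.values if hasattr(grs, "values") else grs, float)
    if controls_only:
        mask = (cohort["case_status"].astype(str) == "control").to_numpy()
    else:
        mask = np.ones(len(cohort), dtype=bool)
    sub = cohort.loc[mask]
    sub_score = score[mask]
    rows: list[ConfounderScreenRow] = []
    for factor in (factors or DEFAULT_SCREEN_FACTORS):
        if factor not in cohort.columns:
            raise KeyError(f"factor column {factor!r} not in cohort")
        col = sub[factor]
        if col.dtype != object:
            ok = np.isfinite(col.to_numpy(float)) & np.isfinite(sub_score)
            yv = col.to_numpy(float)[ok]
            xv = sub_score[ok]
            if np.var(yv) == 0:
                rows.append(ConfounderScreenRow(factor, "constant", None, None, True))
                continue
            fit = sm.OLS(yv, sm.add_constant(xv)).fit()
            rows.append(ConfounderScreenRow(
                factor, "linear", float(fit.params[1]), float(fit.pvalues[1])))
            continue
        values = col.astype(str)
        ok = ~values.str.lower().isin(_MISSING)
        values = values[ok]
        xv = sub_score[ok.to_numpy()]
        levels = sorted(values.unique())
        if len(levels) < 2:
            rows.append(ConfounderScreenRow(factor, "constant", None, None, True))
        elif len(levels) == 2:
            yv = (values == levels[1]).to_numpy(float)
            fit = sm.Logit(yv, sm.add_constant(xv)).fit(disp=0)
            rows.append(ConfounderScreenRow(
                factor, "logistic", float(fit.params[1]), float(fit.pvalues[1])))
        else:
            codes = pd.Categorical(values, categories=levels).codes.astype(float)
            full = sm.MNLogit(codes, sm.add_constant(xv)).fit(disp=0)
            null = sm.MNLogit(codes, np.ones((len(codes), 1))).fit(disp=0)
            lrt = max(2.0 * (full.llf - null.llf), 0.0)
            p = float(stats.chi2.sf(lrt, df=len(levels) - 1))
            rows.append(ConfounderScreenRow(
                factor, "multinomial", float(full.params[1, 0]), p))
    return rows


def screen_to_frame(rows: list[ConfounderScreenRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


# power ---------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the GRS Wald-test power calculation.

    ``r2`` is the exposure variance explained by the instrument;
    ``or_per_sd`` the detectable odds ratio per SD of exposure;
    ``sd_years`` records the SD in natural units (1.5 y menarche, 4.8 y
    menopause) for reporting only — the test is scale-invariant.
    """

    n_cases: int = 12_944
    n_controls: int = 10_741
    r2: float = 0.069
    or_per_sd: float = 0.85
    sd_years: float = 1.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must be in (0,1)")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0,0.5)")
        if self.or_per_sd <= 0 or self.sd_years <= 0:
            raise ValueError("or_per_sd and sd_years must be positive")


def _analytic_power(spec: PowerSpec) -> float:
    n = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n
    lam = abs(math.log(spec.or_per_sd)) * math.sqrt(n * spec.r2 * phi * (1.0 - phi))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def _simulated_power(spec: PowerSpec, n_reps: int, seed: int | None) -> float:
    """Monte-Carlo rejection rate of the score Wald test.

    Each replicate draws a standardised exposure with a genetic score
    explaining ``r2`` of its variance, assigns disease by a logistic model
    at ``log(or_per_sd)`` per SD, and samples cases/controls retrospectively
    to the exact study counts before fitting the score-only logistic model.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n
    beta = math.log(spec.or_per_sd)
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    m = int(math.ceil(1.45 * n))
    rejections = 0
    for _ in range(n_reps):
        while True:
            g = rng.normal(0.0, math.sqrt(spec.r2), m)
            x = g + rng.normal(0.0, math.sqrt(1.0 - spec.r2), m)
            lp = beta * x
            alpha0 = brentq(lambda a: expit(a + lp).mean() - phi, -20.0, 20.0)
            y = rng.uniform(size=m) < expit(alpha0 + lp)
            cases = np.flatnonzero(y)
            ctrls = np.flatnonzero(~y)
            if len(cases) >= spec.n_cases and len(ctrls) >= spec.n_controls:
                break
        sel = np.concatenate([
            rng.choice(cases, spec.n_cases, replace=False),
            rng.choice(ctrls, spec.n_controls, replace=False),
        ])
        b, se = _logit_slope_wald(g[sel], y[sel].astype(float))
        if abs(b / se) > z_crit:
            rejections += 1
    return rejections / n_reps


def _logit_slope_wald(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Newton-Raphson MLE of an intercept+slope logistic model.

    A dedicated two-parameter solver keeps the simulation loop fast; it
    returns the identical MLE and observed-information Wald SE a generic
    GLM routine would.
    """
    b0, b1 = 0.0, 0.0
    for _ in range(50):
        eta = b0 + b1 * x
        mu = expit(eta)
        wgt = mu * (1.0 - mu)
        s0 = (y - mu).sum()
        s1 = ((y - mu) * x).sum()
        h00 = wgt.sum()
        h01 = (wgt * x).sum()
        h11 = (wgt * x * x).sum()
        det = h00 * h11 - h01 * h01
        d0 = (h11 * s0 - h01 * s1) / det
        d1 = (h00 * s1 - h01 * s0) / det
        b0 += d0
        b1 += d1
        if abs(d0) < 1e-10 and abs(d1) < 1e-10:
            break
    else:
        warnings.warn("power-simulation logistic fit hit iteration cap")
    eta = b0 + b1 * x
    wgt = expit(eta) * (1.0 - expit(eta))
    h00 = wgt.sum()
    h01 = (wgt * x).sum()
    h11 = (wgt * x * x).sum()
    se1 = math.sqrt(h00 / (h00 * h11 - h01 * h01))
    return b1, se1


def mr_power(
    spec: PowerSpec,
    method: str = "analytic",
    n_reps: int = 2000,
    seed: int | None = None,
) -> float:
    """Power of the two-sided GRS Wald test, as a fraction in [0, 1].

    ``method='analytic'`` uses the normal approximation
    ``Φ(λ − z) + Φ(−λ − z)`` with ``λ = |log OR|·√(N·R²·φ(1−φ))`` and φ the
    case fraction; at OR = 1 this reduces exactly to α.
    ``method='simulation'`` draws ``n_reps`` replicate score-outcome cohorts
    at the spec's exact counts and reports the rejection fraction.
    """
    if method == "analytic":
        return _analytic_power(spec)
    if method == "simulation":
        if n_reps < 500:
            raise ValueError("simulation mode needs n_reps >= 500")
        return _simulated_power(spec, n_reps, seed)
    raise ValueError(f"unknown method {method!r}")
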