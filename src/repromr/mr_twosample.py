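"""Two-sample MR on GWAS summary statistics.

Given per-SNP exposure betas (years per allele, from the published GWAS)
and outcome betas (log-OR per allele, from the case-control sample), each
SNP yields a Wald ratio ``beta_outcome / beta_exposure`` with first-order
delta-method SE ``se_outcome / |beta_exposure|``.  Three combiners are
provided:

* **IVW** — weighted least squares of outcome on exposure betas through the
  origin (weights ``1/se_outcome²``); algebraically the precision-weighted
  mean of the ratios.  Consistent only when every instrument is valid.
* **MR-Egger** — the same regression with a free intercept.  Under the
  InSIDE assumption the slope is a pleiotropy-adjusted causal estimate and
  the intercept estimates the average direct (pleiotropic) effect; its
  deviation from zero is the directional-pleiotropy test.  Exposure betas
  are oriented non-negative before fitting (Egger is not
  orientation-invariant).
* **Weighted median** — the ratio at cumulative inverse-variance weight
  one-half; consistent while valid instruments carry at least half the
  weight.  Its SE comes from a parametric bootstrap (normal resampling of
  both beta columns at their stated SEs).

SEs for IVW/Egger take the stated outcome variances at face value (no
multiplicative over-dispersion adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._estimate import MrEstimate

__all__ = [
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "funnel_data",
    "FunnelData",
]

_REQUIRED = ["beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]


def _validated(stats_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in stats_table.columns]
    if missing:
        raise ValueError(f"summary-statistics table missing columns: {missing}")
    if stats_table.empty:
        raise ValueError("empty summary-statistics table")
    if (stats_table["se_exposure"] <= 0).any() or (stats_table["se_outcome"] <= 0).any():
        raise ValueError("standard errors must be positive")
    return stats_table


def _drop_null_exposure(table: pd.DataFrame) -> pd.DataFrame:
    null = table["beta_exposure"] == 0
    if null.any():
        warnings.warn(f"dropping {int(null.sum())} SNP(s) with zero exposure beta")
        table = table.loc[~null]
    if table.empty:
        raise ValueError("no SNPs with nonzero exposure beta")
    return table


def ratio_estimates(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP Wald ratios with delta-method SEs and precisions."""
    table = _drop_null_exposure(_validated(stats_table))
    ratio = table["beta_outcome"] / table["beta_exposure"]
    se_ratio = table["se_outcome"] / table["beta_exposure"].abs()
    out = pd.DataFrame({
        "ratio": ratio.to_numpy(),
        "se_ratio": se_ratio.to_numpy(),
        "precision": 1.0 / se_ratio.to_numpy(),
    })
    if "rsid" in table.columns:
        out.insert(0, "rsid", table["rsid"].to_numpy())
    return out


def ivw(stats_table: pd.DataFrame) -> MrEstimate:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression)."""
    table = _drop_null_exposure(_validated(stats_table))
    bx = table["beta_exposure"].to_numpy(float)
    by = table["beta_outcome"].to_numpy(float)
    w = 1.0 / table["se_outcome"].to_numpy(float) ** 2
    denom = (w * bx**2).sum()
    beta = float((w * bx * by).sum() / denom)
    se = float(1.0 / np.sqrt(denom))
    return MrEstimate(method="ivw", beta=beta, se=se, n_snps=len(table))


def egger(stats_table: pd.DataFrame) -> MrEstimate:
    """MR-Egger weighted regression with a free intercept.

    Returns the slope (pleiotropy-adjusted causal estimate) with the
    intercept and its SE attached; the intercept p-value is the
    directional-pleiotropy test.
    """
    table = _drop_null_exposure(_validated(stats_table))
    if len(table) < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx = table["beta_exposure"].to_numpy(float).copy()
    by = table["beta_outcome"].to_numpy(float).copy()
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    if np.ptp(bx) == 0:
        raise ValueError("zero variance in exposure betas")
    w = 1.0 / table["se_outcome"].to_numpy(float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)  # scale fixed at 1: stated variances are taken as known
    if not (np.isfinite(cov).all() and cov[0, 0] > 0 and cov[1, 1] > 0):
        raise ValueError("degenerate exposure betas: Egger design is singular")
    params = cov @ (X.T @ (w * by))
    return MrEstimate(
        method="egger",
        beta=float(params[1]),
        se=float(np.sqrt(cov[1, 1])),
        n_snps=len(table),
        intercept=float(params[0]),
        intercept_se=float(np.sqrt(cov[0, 0])),
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median: SNP j sits at cumulative S_j − w_j/2.

    Tied ratios are merged (weights summed) first, so the estimate depends
    only on the weighted empirical distribution — duplicating every SNP is
    an exact no-op.
    """
    r, inverse = np.unique(ratio, return_inverse=True)
    w = np.zeros_like(r)
    np.add.at(w, inverse, weight)
    w = w / w.sum()
    pos = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, pos, r))


def weighted_median(
    stats_table: pd.DataFrame, n_boot: int = 10_000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Ratios are ordered, weighted by their inverse variance, and the estimate
    interpolated at cumulative weight one-half.  The bootstrap resamples
    both beta columns from normal distributions at their stated SEs and
    recomputes the estimate; the SD over replicates is the SE.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable bootstrap SE")
    table = _drop_null_exposure(_validated(stats_table))
    if len(table) < 2:
        raise ValueError("weighted median needs at least 2 SNPs")
    bx = table["beta_exposure"].to_numpy(float)
    by = table["beta_outcome"].to_numpy(float)
    sx = table["se_exposure"].to_numpy(float)
    sy = table["se_outcome"].to_numpy(float)

    point = _weighted_median(by / bx, (bx / sy) ** 2)

    rng = np.random.default_rng(seed)
    k = len(bx)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    bxs[bxs == 0] = np.finfo(float).tiny
    ratios = bys / bxs
    weights = (bxs / sy) ** 2
    order = np.argsort(ratios, axis=1)
    r_sorted = np.take_along_axis(ratios, order, axis=1)
    w_sorted = np.take_along_axis(weights, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    pos = np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted
    below = pos < 0.5
    j = below.sum(axis=1)  # first position with pos >= 0.5
    rows = np.arange(n_boot)
    j_hi = np.clip(j, 0, k - 1)
    j_lo = np.clip(j - 1, 0, k - 1)
    p_lo = pos[rows, j_lo]
    p_hi = pos[rows, j_hi]
    r_lo = r_sorted[rows, j_lo]
    r_hi = r_sorted[rows, j_hi]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(p_hi > p_lo, (0.5 - p_lo) / (p_hi - p_lo), 0.0)
    boot = np.where(j == 0, r_sorted[:, 0],
                    np.where(j >= k, r_sorted[:, -1], r_lo + frac * (r_hi - r_lo)))
    se = float(boot.std(ddof=1))
    return MrEstimate(method="weighted_median", beta=point, se=se, n_snps=k)


@dataclass
class FunnelData:
    """Per-SNP (ratio, precision) pairs with estimator overlays."""

    table: pd.DataFrame
    ivw: MrEstimate
    egger: MrEstimate
    asymmetry_slope: float
    asymmetry_p: float


def funnel_data(stats_table: pd.DataFrame) -> FunnelData:
    """Funnel-plot data plus an Egger-type asymmetry test.

    The asymmetry statistic is the weighted regression of each ratio on its
    standard error (weights = precision²); a slope away from zero means
    small (imprecise) instruments drift systematically, the funnel-plot
    signature of directional pleiotropy.
    """
    ratios = ratio_estimates(stats_table)
    se_r = ratios["se_ratio"].to_numpy(float)
    r = ratios["ratio"].to_numpy(float)
    w = 1.0 / se_r**2
    X = np.column_stack([np.ones_like(se_r), se_r])
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    params = cov @ (X.T @ (w * r))
    slope = float(params[1])
    slope_se = float(np.sqrt(cov[1, 1]))
    p = 2.0 * float(stats.norm.sf(abs(slope / slope_se)))
    return FunnelData(
        table=ratios[[c for c in ("rsid", "ratio", "precision") if c in ratios.columns]],
        ivw=ivw(stats_table),
        egger=egger(stats_table),
        asymmetry_slope=slope,
        asymmetry_p=p,
    )
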