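"""Weighted genetic risk scores and their year-scaling.

The raw score for individual *k* is the plain weighted allele-dose sum
``GRS_k = sum_n beta_n * G_kn`` over the curated instrument set (betas in
years per effect allele, doses in [0, 2]); it is *not* divided by the SNP
count.  Because a raw score has no interpretable unit, it is divided by the
regression coefficient of a linear regression of the raw score on
self-reported exposure age fitted in calibration controls — after which a
logistic odds ratio on the scaled score reads as risk change per year of
exposure.  When no calibration data are supplied the published coefficients
are used: 0.57 for age at menarche and 0.98 for age at menopause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .instruments import FLAG_LIFETIME_FLIPPED, InstrumentRecord

__all__ = [
    "DEFAULT_SCALING_BETAS",
    "GrsVector",
    "ScalingFit",
    "compute_grs",
    "fit_scaling",
    "scale_grs",
    "lifetime_grs",
]

DEFAULT_SCALING_BETAS = {"menarche": 0.57, "menopause": 0.98}


@dataclass
class GrsVector:
    """Per-individual risk score, raw and (optionally) scaled to years."""

    raw: np.ndarray
    trait: str
    ids: pd.Index | None = None
    scaled: np.ndarray | None = None
    scaling_beta: float | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.scaled is not None:
            self.scaled = np.asarray(self.scaled, dtype=float)

    @property
    def values(self) -> np.ndarray:
        """Scaled scores when available, raw otherwise."""
        return self.scaled if self.scaled is not None else self.raw

    def __len__(self) -> int:
        return len(self.raw)


@dataclass
class ScalingFit:
    """Per-study and pooled slopes of raw GRS on self-reported age."""

    per_study: pd.DataFrame  # columns: study, beta, se, n
    beta: float
    se: float


class MissingInstrumentError(KeyError):
    pass


def compute_grs(
    dosages: pd.DataFrame,
    instruments: Sequence[InstrumentRecord],
    control_mask: np.ndarray | None = None,
    missing: str = "mean",
) -> GrsVector:
    """Beta-weighted allele-dose sum over ``instruments``.

    Missing dosage entries are mean-imputed per SNP (from controls when
    ``control_mask`` is given — the standard choice, unbiased under data
    missing at random); pass ``missing='error'`` to reject incomplete input
    instead.
    """
    if not instruments:
        raise ValueError("empty instrument set")
    rsids = [rec.rsid for rec in instruments]
    absent = [r for r in rsids if r not in dosages.columns]
    if absent:
        raise MissingInstrumentError(
            f"instruments absent from dosage matrix: {absent[:5]}"
            + ("..." if len(absent) > 5 else "")
        )
    mat = dosages[rsids]
    if mat.isna().to_numpy().any():
        if missing == "error":
            raise ValueError("dosage matrix contains missing values")
        source = mat.loc[np.asarray(control_mask, bool)] if control_mask is not None else mat
        mat = mat.fillna(source.mean())
    values = mat.to_numpy(dtype=float)
    if values.size and (values.min() < -1e-9 or values.max() > 2.0 + 1e-9):
        raise ValueError("dosages outside [0, 2]")
    # dosage columns count the trait-increasing allele of the harmonised
    # manifest; records re-oriented for the lifetime score count 2 - G
    flipped = np.array([FLAG_LIFETIME_FLIPPED in rec.flags for rec in instruments])
    if flipped.any():
        values = np.where(flipped[None, :], 2.0 - values, values)
    betas = np.array([rec.beta for rec in instruments])
    trait = instruments[0].trait if len({r.trait for r in instruments}) == 1 else "lifetime"
    return GrsVector(raw=values @ betas, trait=trait, ids=dosages.index)


def fit_scaling(
    raw: GrsVector | np.ndarray,
    self_reported_age: np.ndarray,
    study: np.ndarray,
    min_pairs: int = 30,
) -> ScalingFit:
    """Per-study OLS slope of raw score on age, pooled by fixed effects."""
    score = raw.raw if isinstance(raw, GrsVector) else np.asarray(raw, float)
    age = np.asarray(self_reported_age, dtype=float)
    study = np.asarray(study)
    rows = []
    for label in pd.unique(study):
        mask = (study == label) & np.isfinite(age) & np.isfinite(score)
        n = int(mask.sum())
        if n < min_pairs:
            warnings.warn(f"study {label}: only {n} usable pairs, excluded")
            continue
        if np.var(age[mask]) == 0:
            warnings.warn(f"study {label}: zero age variance, excluded")
            continue
        X = sm.add_constant(age[mask])
        fit = sm.OLS(score[mask], X).fit()
        rows.append({"study": label, "beta": float(fit.params[1]),
                     "se": float(fit.bse[1]), "n": n})
    if not rows:
        raise ValueError("no study provided a usable calibration fit")
    per_study = pd.DataFrame(rows)
    w = 1.0 / per_study["se"].to_numpy() ** 2
    beta = float((w * per_study["beta"].to_numpy()).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return ScalingFit(per_study=per_study, beta=beta, se=se)


def scale_grs(raw: GrsVector, scaling_beta: float | None = None) -> GrsVector:
    """Divide the raw score by the scaling slope, yielding year units.

    With ``scaling_beta=None`` the published default for the score's trait
    is applied (0.57 menarche, 0.98 menopause).
    """
    if scaling_beta is None:
        try:
            scaling_beta = DEFAULT_SCALING_BETAS[raw.trait]
        except KeyError:
            raise ValueError(
                f"no default scaling beta for trait {raw.trait!r}; pass one explicitly"
            ) from None
    if scaling_beta == 0:
        raise ValueError("scaling_beta must be nonzero")
    return replace(raw, scaled=raw.raw / scaling_beta, scaling_beta=float(scaling_beta))


def lifetime_grs(menarche_scaled: GrsVector, menopause_scaled: GrsVector) -> GrsVector:
    """Sum of the two scaled scores: the lifetime oestrogen-exposure score.

    The menarche component must be built from the instrument set
    re-harmonised to the trait-decreasing allele, so that a higher combined
    score always reflects a longer exposure window.
    """
    if len(menarche_scaled) != len(menopause_scaled):
        raise ValueError("component score lengths differ")
    for comp in (menarche_scaled, menopause_scaled):
        if comp.scaled is None:
            raise ValueError("components must be scaled to years first")
    total = menarche_scaled.scaled + menopause_scaled.scaled
    return GrsVector(raw=total, trait="lifetime", ids=menarche_scaled.ids,
                     scaled=total, scaling_beta=1.0)


def write_scores(grs: GrsVector, path) -> None:
    """Write per-individual scores as CSV (individual_id, raw, scaled, trait)."""
    ids = grs.ids if grs.ids is not None else pd.RangeIndex(len(grs))
    pd.DataFrame({
        "individual_id": np.asarray(ids),
        "raw": grs.raw,
        "scaled": grs.scaled if grs.scaled is not None else np.nan,
        "trait": grs.trait,
    }).to_csv(path, index=False)
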