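"""Synthetic cohorts with the statistical structure a GRS-based MR study assumes.

The generator emulates a retrospective case-control study of colorectal
cancer in women, instrumented by genetic risk scores (GRS) for age at
menarche and age at natural menopause:

* an instrument *manifest* mimicking a published GWAS hit list, including
  the curation hazards a real list carries (sex-chromosome variants,
  panel-missing variants with/without LD proxies, correlated pairs,
  BMI-associated subsets);
* per-individual imputed allele *dosages* in [0, 2], drawn as hard genotypes
  under Hardy-Weinberg proportions and shrunk toward the panel frequency to
  mimic imputation uncertainty (per-SNP quality in [0.9, 1], matching the
  0.97-0.98 mean quality typical of well-imputed GWAS variants);
* a continuous *exposure* (age in years) built from the true weighted
  genotype score, an optional BMI confounder path, and a residual whose
  variance is calibrated so the GRS explains exactly ``target_r2`` of the
  exposure variance;
* binary *disease* assigned by a logistic model on the exposure (a chosen
  log-odds ratio per year), the confounder, and optional direct (pleiotropic)
  SNP effects; cases and controls are then sampled retrospectively to exact
  counts, which leaves logistic odds ratios intact.

Every operation takes an explicit seed; with the seed fixed all outputs are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .instruments import (
    FLAG_BMI_ASSOCIATED,
    FLAG_CORRELATED,
    FLAG_PROXY_AVAILABLE,
    FLAG_PROXY_NEEDED,
    FLAG_SEX_CHROMOSOME,
    InstrumentRecord,
    LdMatrix,
    ProxyTable,
)

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "CalibrationError",
    "generate_manifest",
    "derive_proxy_table",
    "derive_ld_matrix",
    "generate_cohort",
    "generate_summary_stats",
    "generate_scaling_calibration",
    "write_dataset",
]

_BASES = np.array(["A", "C", "G", "T"])

# baseline ages (years) the simulated exposures are centred on
_BASELINE_AGE = {"menarche": 13.0, "menopause": 50.0}


class CalibrationError(ValueError):
    """Raised when the requested explained variance cannot be reached."""


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    ``target_r2`` is the variance in the exposure age explained by the true
    GRS; ``causal_logor_per_year`` the log odds ratio on disease per year of
    exposure; ``confounder_spec`` the (years-per-SD, log-OR-per-SD) effects
    of BMI on exposure and disease; ``pleiotropy_spec`` the (fraction, mean,
    SD) of direct per-allele SNP effects on the disease log-odds (mean 0 for
    balanced, nonzero for directional pleiotropy).  ``bmi_pleiotropy_r`` sets
    the correlation between the exposure GRS and BMI, emulating instruments
    that act on the exposure partly through adiposity.
    """

    n_cases: int = 12_944
    n_controls: int = 10_741
    n_snps: int = 358
    target_r2: float = 0.069
    causal_logor_per_year: float = 0.0
    exposure_sd_years: float = 1.5
    confounder_spec: tuple[float, float] = (0.0, 0.0)
    pleiotropy_spec: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_studies: int = 4
    seed: int = 0
    trait: str = "menarche"
    bmi_pleiotropy_r: float = 0.0
    study_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_studies) < 1:
            raise ValueError("counts must be >= 1")
        if not (0.0 < self.target_r2 < 1.0):
            raise ValueError("target_r2 must be in (0,1)")
        if self.exposure_sd_years <= 0:
            raise ValueError("exposure_sd_years must be positive")
        if not (0.0 <= self.pleiotropy_spec[0] <= 1.0):
            raise ValueError("pleiotropic fraction must be in [0,1]")
        if self.study_proportions is not None:
            if len(self.study_proportions) != self.n_studies:
                raise ValueError("study_proportions length must equal n_studies")
            if abs(sum(self.study_proportions) - 1.0) > 1e-8:
                raise ValueError("study_proportions must sum to 1")


@dataclass
class SyntheticDataset:
    manifest: list
    dosages: pd.DataFrame
    cohort: pd.DataFrame
    true_params: SimulationSpec
    second_manifest: list | None = None
    bmi_manifest: list | None = None
    truth: pd.DataFrame | None = None  # latent per-individual variables, for checks


# manifest ------------------------------------------------------------------

def generate_manifest(
    n_total: int,
    n_sex_chr: int = 0,
    n_missing: int = 0,
    n_no_proxy: int = 0,
    n_correlated: int = 0,
    seed: int = 0,
    trait: str = "menarche",
    target_r2: float = 0.069,
    exposure_sd_years: float = 1.5,
    n_bmi_associated: int = 0,
) -> list[InstrumentRecord]:
    """Draw an instrument manifest with controlled curation hazards.

    ``n_missing`` records are flagged as absent from the genotype panel, of
    which ``n_no_proxy`` will have no qualifying proxy; ``n_correlated``
    *pairs* of records are put in LD above the pruning threshold (pairs are
    placed among records untouched by the other hazards).  Per-allele betas
    are scaled so that the records surviving curation carry a GRS variance of
    ``target_r2 * exposure_sd_years**2`` — the variance a cohort generated at
    ``target_r2`` needs from its genetic component.
    """
    if n_sex_chr + n_missing > n_total:
        raise ValueError("n_sex_chr + n_missing exceeds n_total")
    if n_no_proxy > n_missing:
        raise ValueError("n_no_proxy exceeds n_missing")
    if n_total - n_sex_chr - n_missing < 2 * n_correlated:
        raise ValueError("not enough clean records to host correlated pairs")
    if n_sex_chr + n_correlated > n_total:
        raise ValueError("inconsistent counts")

    rng = np.random.default_rng(seed)
    records: list[InstrumentRecord] = []
    eaf = rng.uniform(0.05, 0.95, n_total).clip(0.01, 0.99)
    beta = np.abs(rng.normal(0.0, 1.0, n_total))
    pval = 10.0 ** (-rng.uniform(8.0, 30.0, n_total))
    se = beta / np.sqrt(-2.0 * np.log(pval))  # |beta|/se consistent with p
    se = np.maximum(se, 1e-6)

    for i in range(n_total):
        a, b = rng.choice(4, size=2, replace=False)
        flags: set = set()
        chrom = str(int(rng.integers(1, 23)))
        if i < n_sex_chr:
            chrom = "X"
            flags.add(FLAG_SEX_CHROMOSOME)
        elif i < n_sex_chr + n_missing:
            flags.add(FLAG_PROXY_NEEDED)
            if i < n_sex_chr + (n_missing - n_no_proxy):
                flags.add(FLAG_PROXY_AVAILABLE)
        records.append(InstrumentRecord(
            rsid=f"rs{trait}{i + 1:05d}",
            chrom=chrom,
            pos=int(rng.integers(10_000, 250_000_000)),
            effect_allele=str(_BASES[a]),
            other_allele=str(_BASES[b]),
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(pval[i]),
            trait=trait,
            flags=flags,
        ))

    # correlated pairs among clean records
    clean = list(range(n_sex_chr + n_missing, n_total))
    pair_members = rng.choice(clean, size=2 * n_correlated, replace=False)
    dropped_by_prune: set[int] = set()
    for p in range(n_correlated):
        i, j = int(pair_members[2 * p]), int(pair_members[2 * p + 1])
        r2 = float(rng.uniform(0.1, 1.0))
        for x, y in ((i, j), (j, i)):
            records[x].flags.add(FLAG_CORRELATED)
            records[x].partner_rsid = records[y].rsid
            records[x].pair_r2 = r2
        loser = i if records[i].pvalue > records[j].pvalue else j
        dropped_by_prune.add(loser)

    # scale betas so the post-curation GRS variance hits the calibration target
    survivors = [
        i for i, rec in enumerate(records)
        if FLAG_SEX_CHROMOSOME not in rec.flags
        and not (FLAG_PROXY_NEEDED in rec.flags and FLAG_PROXY_AVAILABLE not in rec.flags)
        and i not in dropped_by_prune
    ]
    var_terms = np.array([
        2.0 * records[i].eaf * (1.0 - records[i].eaf) * records[i].beta ** 2
        for i in survivors
    ])
    scale = math.sqrt(target_r2 * exposure_sd_years**2 / var_terms.sum())
    for rec in records:
        rec.beta *= scale
        rec.se *= scale

    if n_bmi_associated:
        eligible = [i for i in survivors]
        chosen = rng.choice(eligible, size=n_bmi_associated, replace=False)
        for i in chosen:
            records[int(i)].flags.add(FLAG_BMI_ASSOCIATED)

    order = rng.permutation(n_total)
    return [records[int(i)] for i in order]


def derive_proxy_table(manifest: Sequence[InstrumentRecord], seed: int = 0) -> ProxyTable:
    """Build the proxy lookup implied by the manifest's missing-SNP flags.

    Records flagged proxy-available get a strong candidate (r² in
    [0.83, 1.0], the range typical of published proxy substitutions) with a
    random allele orientation; half of the no-proxy records get a weak,
    sub-threshold candidate so that the r² filter is exercised, the rest
    none at all.
    """
    rng = np.random.default_rng(seed)
    rows = []
    weak_toggle = True
    for rec in manifest:
        if FLAG_PROXY_NEEDED not in rec.flags:
            continue
        if FLAG_PROXY_AVAILABLE in rec.flags:
            r2 = float(rng.uniform(0.83, 1.0))
        elif weak_toggle:
            weak_toggle = False
            r2 = float(rng.uniform(0.2, 0.8))
        else:
            weak_toggle = True
            continue
        aligned = bool(rng.integers(0, 2))
        a, b = rng.choice(4, size=2, replace=False)
        eaf = float(np.clip(rec.eaf + rng.normal(0, 0.02), 0.01, 0.99))
        rows.append({
            "missing_rsid": rec.rsid,
            "proxy_rsid": rec.rsid + "p",
            "r2": r2,
            "proxy_effect_allele": str(_BASES[a]),
            "proxy_other_allele": str(_BASES[b]),
            "proxy_eaf": eaf if aligned else 1.0 - eaf,
            "aligned": aligned,
        })
    if not rows:
        return ProxyTable.empty()
    return ProxyTable(pd.DataFrame(rows))


def derive_ld_matrix(manifest: Sequence[InstrumentRecord]) -> LdMatrix:
    """Collect the pairwise r² entries carried on correlated-pair flags."""
    ld = LdMatrix()
    seen = set()
    for rec in manifest:
        if rec.partner_rsid is None or rec.pair_r2 is None:
            continue
        key = frozenset((rec.rsid, rec.partner_rsid))
        if key in seen:
            continue
        seen.add(key)
        ld.set(rec.rsid, rec.partner_rsid, rec.pair_r2)
    return ld


# cohort --------------------------------------------------------------------

def _draw_dosages(
    rng: np.random.Generator, manifest: Sequence[InstrumentRecord], n: int
) -> np.ndarray:
    freqs = np.array([rec.eaf for rec in manifest])
    hard = rng.binomial(2, freqs, size=(n, len(manifest))).astype(float)
    quality = rng.uniform(0.9, 1.0, len(manifest))
    return quality * hard + (1.0 - quality) * 2.0 * freqs


def _solve_intercept(lp: np.ndarray, prevalence: float) -> float:
    return brentq(lambda a: expit(a + lp).mean() - prevalence, -30.0, 30.0)


def generate_cohort(
    spec: SimulationSpec,
    manifest: Sequence[InstrumentRecord],
    second_manifest: Sequence[InstrumentRecord] | None = None,
    bmi_manifest: Sequence[InstrumentRecord] | None = None,
) -> SyntheticDataset:
    """Simulate a retrospective case-control cohort around ``manifest``.

    The exposure age is ``baseline + genetic score + confounder + residual``
    with the residual variance set so the true GRS explains ``target_r2`` of
    the exposure variance (empirically, on the simulated dosages).  Disease
    is assigned prospectively in an oversampled population and cases/controls
    are then drawn without replacement to exact counts — odds ratios from
    logistic regression are invariant to this outcome-dependent sampling.

    ``second_manifest`` adds a second exposure (the complementary
    reproductive-timing trait) on the same individuals, for lifetime-exposure
    analyses; ``bmi_manifest`` adds SNPs contributing to BMI, supporting a
    BMI risk-score adjustment.
    """
    if not manifest:
        raise ValueError("manifest must be non-empty")
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n_total
    c_exp, c_dis = spec.confounder_spec
    frac_pleio, pleio_mean, pleio_sd = spec.pleiotropy_spec

    m = int(math.ceil(1.45 * n_total))
    for _attempt in range(6):
        doses = _draw_dosages(rng, manifest, m)
        betas = np.array([rec.beta for rec in manifest])
        raw = doses @ betas
        g_centred = raw - raw.mean()
        var_g = float(g_centred.var())

        resid_var = var_g * (1.0 - spec.target_r2) / spec.target_r2 - c_exp**2
        if resid_var <= 0:
            raise CalibrationError(
                f"target_r2={spec.target_r2} unreachable: GRS variance {var_g:.4g} "
                f"with confounder path {c_exp} leaves no residual variance"
            )

        # BMI: optionally correlated with the exposure score and/or driven by
        # its own SNP set
        bmi_noise = rng.normal(size=m)
        rho = spec.bmi_pleiotropy_r
        w_bmi_snps = 0.5 if bmi_manifest else 0.0
        if bmi_manifest:
            bmi_doses = _draw_dosages(rng, bmi_manifest, m)
            bmi_betas = np.array([rec.beta for rec in bmi_manifest])
            bmi_score = bmi_doses @ bmi_betas
            bmi_score = (bmi_score - bmi_score.mean()) / bmi_score.std()
        else:
            bmi_doses = None
            bmi_score = np.zeros(m)
        resid_w = math.sqrt(max(1.0 - rho**2 - w_bmi_snps**2, 0.05))
        g_std = g_centred / math.sqrt(var_g)
        bmi_z = rho * g_std + w_bmi_snps * bmi_score + resid_w * bmi_noise

        exposure = (
            _BASELINE_AGE.get(spec.trait, 13.0)
            + g_centred
            + c_exp * bmi_z
            + rng.normal(0.0, math.sqrt(resid_var), m)
        )

        if second_manifest:
            doses2 = _draw_dosages(rng, second_manifest, m)
            betas2 = np.array([rec.beta for rec in second_manifest])
            raw2 = doses2 @ betas2
            g2 = raw2 - raw2.mean()
            resid2 = g2.var() * (1.0 - spec.target_r2) / spec.target_r2
            exposure2 = 50.0 + g2 + rng.normal(0.0, math.sqrt(resid2), m)
        else:
            doses2 = None
            exposure2 = None

        lp = spec.causal_logor_per_year * (exposure - exposure.mean()) + c_dis * bmi_z
        if frac_pleio > 0:
            k = int(round(frac_pleio * len(manifest)))
            idx = rng.choice(len(manifest), size=k, replace=False)
            delta = rng.normal(pleio_mean, pleio_sd, k)
            freqs = np.array([manifest[int(i)].eaf for i in idx])
            lp = lp + (doses[:, idx] - 2.0 * freqs) @ delta

        alpha = _solve_intercept(lp, phi)
        y = rng.uniform(size=m) < expit(alpha + lp)
        case_idx = np.flatnonzero(y)
        ctrl_idx = np.flatnonzero(~y)
        if len(case_idx) >= spec.n_cases and len(ctrl_idx) >= spec.n_controls:
            break
        m = int(math.ceil(1.5 * m))  # rare: oversample harder and redraw
    else:
        raise CalibrationError("could not realise requested case/control counts")

    chosen_cases = rng.choice(case_idx, size=spec.n_cases, replace=False)
    chosen_ctrls = rng.choice(ctrl_idx, size=spec.n_controls, replace=False)
    sel = np.concatenate([chosen_cases, chosen_ctrls])
    sel = sel[rng.permutation(n_total)]
    is_case = y[sel]

    ids = [f"id{i + 1:06d}" for i in range(n_total)]
    props = spec.study_proportions or tuple([1.0 / spec.n_studies] * spec.n_studies)
    studies = np.array([f"S{i + 1}" for i in range(spec.n_studies)])
    study = rng.choice(studies, size=n_total, p=np.asarray(props))
    n_gecco = max(1, math.ceil(spec.n_studies / 2))
    consortium = np.where(
        np.isin(study, studies[:n_gecco]), "GECCO", "CORECT"
    )

    cohort = pd.DataFrame({"individual_id": ids})
    cohort["case_status"] = np.where(is_case, "case", "control")
    site = np.full(n_total, "none", dtype=object)
    site[is_case] = rng.choice(["colon", "rectum"], size=int(is_case.sum()), p=[0.77, 0.23])
    cohort["site"] = site
    cohort["age"] = np.round(rng.normal(62.0, 8.0, n_total).clip(30, 90), 1)
    cohort["study"] = study
    cohort["consortium"] = consortium
    for j in range(10):
        cohort[f"pc{j + 1}"] = rng.normal(size=n_total)
    bmi_sel = 27.0 + 4.5 * bmi_z[sel]
    cohort["bmi"] = np.round(bmi_sel.clip(15.0, 55.0), 1)
    cohort["bmi_category"] = pd.cut(
        cohort["bmi"], bins=[0, 18.5, 25.0, 30.0, np.inf],
        labels=["underweight", "normal", "overweight", "obese"], right=False,
    ).astype(str)
    cohort["mht_combined"] = rng.choice(
        ["ever", "never", "missing"], size=n_total, p=[0.30, 0.55, 0.15])
    cohort["mht_estrogen_only"] = rng.choice(
        ["ever", "never", "missing"], size=n_total, p=[0.20, 0.65, 0.15])
    cohort["menopausal_status"] = rng.choice(
        ["pre", "post", "missing"], size=n_total, p=[0.12, 0.83, 0.05])
    cohort["aspirin_use"] = rng.choice(["ever", "never"], size=n_total, p=[0.4, 0.6])
    cohort["smoking"] = rng.choice(["ever", "never"], size=n_total, p=[0.45, 0.55])
    cohort["family_history"] = rng.choice(["yes", "no"], size=n_total, p=[0.12, 0.88])
    cohort["education"] = rng.choice(
        ["basic", "secondary", "tertiary"], size=n_total, p=[0.35, 0.4, 0.25])

    report_noise = rng.normal(0.0, 0.6, n_total)
    exp_sel = exposure[sel] + report_noise
    missing_self = rng.uniform(size=n_total) < 0.10
    exp_sel[missing_self] = np.nan
    if spec.trait == "menarche":
        cohort["self_reported_menarche"] = np.round(exp_sel, 1)
        if exposure2 is not None:
            cohort["self_reported_menopause"] = np.round(exposure2[sel], 1)
        else:
            cohort["self_reported_menopause"] = np.round(
                rng.normal(50.0, 4.8, n_total), 1)
    else:
        cohort["self_reported_menopause"] = np.round(exp_sel, 1)
        cohort["self_reported_menarche"] = np.round(rng.normal(13.0, 1.5, n_total), 1)

    dose_blocks = [doses[sel]]
    columns = [rec.rsid for rec in manifest]
    if doses2 is not None:
        dose_blocks.append(doses2[sel])
        columns += [rec.rsid for rec in second_manifest]
    if bmi_doses is not None:
        dose_blocks.append(bmi_doses[sel])
        columns += [rec.rsid for rec in bmi_manifest]
    dosages = pd.DataFrame(np.hstack(dose_blocks), columns=columns, index=ids)
    dosages.index.name = "individual_id"

    truth = pd.DataFrame({
        "exposure": exposure[sel],
        "bmi_z": bmi_z[sel],
        "linear_predictor": alpha + lp[sel],
    }, index=ids)
    if exposure2 is not None:
        truth["exposure_second"] = exposure2[sel]

    return SyntheticDataset(
        manifest=list(manifest),
        dosages=dosages,
        cohort=cohort,
        true_params=spec,
        second_manifest=list(second_manifest) if second_manifest else None,
        bmi_manifest=list(bmi_manifest) if bmi_manifest else None,
        truth=truth,
    )


# two-sample summary statistics ---------------------------------------------

def generate_summary_stats(
    manifest: Sequence[InstrumentRecord],
    spec: SimulationSpec,
    seed: int | None = None,
    se_outcome: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP exposure/outcome association table for two-sample MR.

    Exposure betas and SEs come from the manifest; outcome betas are the
    ratio-implied values ``causal_effect * beta_exposure`` plus any direct
    (pleiotropic) effect, plus normal noise at the stated outcome SE.
    """
    if not manifest:
        raise ValueError("manifest must be non-empty")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = len(manifest)
    beta_x = np.array([rec.beta for rec in manifest])
    se_x = np.array([rec.se for rec in manifest])
    se_y = np.full(k, float(se_outcome))
    frac, mu, sd = spec.pleiotropy_spec
    direct = np.zeros(k)
    if frac > 0:
        idx = rng.choice(k, size=int(round(frac * k)), replace=False)
        direct[idx] = rng.normal(mu, sd, len(idx))
    beta_y = spec.causal_logor_per_year * beta_x + direct + rng.normal(0.0, se_y)
    return pd.DataFrame({
        "rsid": [rec.rsid for rec in manifest],
        "beta_exposure": beta_x,
        "se_exposure": se_x,
        "beta_outcome": beta_y,
        "se_outcome": se_y,
    })


# scaling-calibration set ----------------------------------------------------

def generate_scaling_calibration(
    true_slope: float,
    n_per_study: int,
    n_studies: int = 2,
    seed: int = 0,
    trait: str = "menarche",
) -> pd.DataFrame:
    """Control-only calibration set for year-scaling of a raw GRS.

    Draws self-reported exposure ages and a raw score whose regression on
    age has expected slope ``true_slope`` — the design under which published
    scaling coefficients (0.57 for menarche, 0.98 for menopause) were fitted.
    """
    rng = np.random.default_rng(seed)
    mean, sd = (13.0, 1.5) if trait == "menarche" else (50.0, 4.8)
    frames = []
    for s in range(n_studies):
        age = rng.normal(mean, sd, n_per_study)
        raw = true_slope * age + rng.normal(0.0, 0.4 * sd, n_per_study)
        frames.append(pd.DataFrame({
            "raw_grs": raw, "self_reported_age": age, "study": f"C{s + 1}",
        }))
    return pd.concat(frames, ignore_index=True)


# persistence ----------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write manifest (TSV), dosages (TSV matrix) and cohort (CSV) to a directory."""
    from pathlib import Path
    from .instruments import write_manifest

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(dataset.manifest, out / "manifest.tsv")
    if dataset.second_manifest:
        write_manifest(dataset.second_manifest, out / "manifest_second.tsv")
    if dataset.bmi_manifest:
        write_manifest(dataset.bmi_manifest, out / "manifest_bmi.tsv")
    dataset.dosages.round(4).to_csv(out / "dosages.tsv", sep="\t")
    dataset.cohort.to_csv(out / "cohort.csv", index=False)
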