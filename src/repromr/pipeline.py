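"""End-to-end orchestration: curate -> QC -> GRS -> MR -> diagnostics -> power.

A single YAML config names the inputs (instrument manifests, proxy/LD
tables, dosage matrix, cohort) and the analysis settings; ``run_pipeline``
executes the stages in method order and writes a report bundle:

* ``main_results.tsv`` — per trait (menarche, menopause, lifetime): the GRS
  estimate, the BMI-GRS-adjusted and restricted-score sensitivity variants,
  and the two-sample MR-Egger and weighted-median estimates;
* ``stratified_results.tsv`` — per-stratum estimates with heterogeneity
  likelihood-ratio p-values, plus site-specific estimates with the
  case-only heterogeneity test;
* ``diagnostics.json`` — instrument F-statistics, the confounder screen,
  Egger intercepts and funnel asymmetry; funnel data as TSV per trait;
* ``power.json`` — analytic (and optionally simulated) power;
* ``run_manifest.json`` — SHA-256 of every input plus the seed, so a rerun
  with identical inputs is verifiably identical.

Stage outputs are pure functions of (inputs, config, seed); any stage error
propagates with the stage name and offending input attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import instruments as ins
from . import mr_twosample as mr2
from ._estimate import MrEstimate
from .grs import DEFAULT_SCALING_BETAS, GrsVector, compute_grs, fit_scaling, lifetime_grs, scale_grs
from .mr_onesample import (
    fit_grs_logistic,
    meta_fixed,
    site_heterogeneity_case_only,
    stratified_analysis,
)
from .validation import PowerSpec, confounder_screen, f_statistic, mr_power, screen_to_frame

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "outcome_associations"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


class ConfigError(ValueError):
    pass


@dataclass
class TraitConfig:
    manifest: str
    proxy_table: str | None = None
    ld_table: str | None = None
    scaling_beta: float | None = None
    calibration: str | None = None  # CSV: raw_grs, self_reported_age, study
    r2: float | None = None  # explained variance, for the F-statistic
    bmi_excluded: str | None = None  # text file of rsids for the restricted score
    strata: list[str] = dc_field(default_factory=list)
    summary_stats: str | None = None  # two-sample table; estimated from dosages if absent


@dataclass
class RunConfig:
    dosages: str
    cohort: str
    seed: int
    traits: dict[str, TraitConfig]
    cross_ld_table: str | None = None
    bmi_grs_manifest: str | None = None
    pcs_per_consortium: dict[str, int] = dc_field(
        default_factory=lambda: {"GECCO": 3, "CORECT": 10})
    drop_palindromic: bool = False
    two_sample_methods: tuple[str, ...] = ("ivw", "egger", "weighted_median")
    n_boot: int = 10_000
    power: list[PowerSpec] = dc_field(default_factory=list)
    power_simulation_reps: int = 0  # 0: analytic only
    qc: dict[str, float] = dc_field(
        default_factory=lambda: {"callrate_min": 0.98, "hwe_alpha": 1e-4, "maf_min": 0.01})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        def _resolve(p):
            if p is None:
                return None
            p = str(p)
            return str((base / p)) if base and not Path(p).is_absolute() else p

        for key in ("dosages", "cohort", "seed", "traits"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
        traits = {}
        for name, tc in raw["traits"].items():
            if "manifest" not in tc:
                raise ConfigError(f"trait {name!r} missing manifest path")
            traits[name] = TraitConfig(
                manifest=_resolve(tc["manifest"]),
                proxy_table=_resolve(tc.get("proxy_table")),
                ld_table=_resolve(tc.get("ld_table")),
                scaling_beta=tc.get("scaling_beta"),
                calibration=_resolve(tc.get("calibration")),
                r2=tc.get("r2"),
                bmi_excluded=_resolve(tc.get("bmi_excluded")),
                strata=list(tc.get("strata", [])),
                summary_stats=_resolve(tc.get("summary_stats")),
            )
        power = [PowerSpec(**p) for p in raw.get("power", [])]
        cfg = cls(
            dosages=_resolve(raw["dosages"]),
            cohort=_resolve(raw["cohort"]),
            seed=int(raw["seed"]),
            traits=traits,
            cross_ld_table=_resolve(raw.get("cross_ld_table")),
            bmi_grs_manifest=_resolve(raw.get("bmi_grs_manifest")),
            pcs_per_consortium=dict(raw.get("pcs_per_consortium",
                                            {"GECCO": 3, "CORECT": 10})),
            drop_palindromic=bool(raw.get("drop_palindromic", False)),
            two_sample_methods=tuple(raw.get("two_sample_methods",
                                             ("ivw", "egger", "weighted_median"))),
            n_boot=int(raw.get("n_boot", 10_000)),
            power=power,
            power_simulation_reps=int(raw.get("power_simulation_reps", 0)),
            qc=dict(raw.get("qc", {"callrate_min": 0.98, "hwe_alpha": 1e-4,
                                   "maf_min": 0.01})),
        )
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        paths = {"dosages": self.dosages, "cohort": self.cohort,
                 "cross_ld_table": self.cross_ld_table,
                 "bmi_grs_manifest": self.bmi_grs_manifest}
        for name, tc in self.traits.items():
            for attr in ("manifest", "proxy_table", "ld_table", "calibration",
                         "bmi_excluded", "summary_stats"):
                paths[f"{name}.{attr}"] = getattr(tc, attr)
        for label, p in paths.items():
            if p is not None and not Path(p).exists():
                raise ConfigError(f"config path {label!r} does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def outcome_associations(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    manifest: Sequence[ins.InstrumentRecord],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP logistic association of case status with allele dose.

    Produces the SNP-outcome half of a two-sample summary table from the
    individual-level data, adjusted like the main model.
    """
    from .mr_onesample import _design, _fit_logit, default_covariates

    covariates = default_covariates(cohort) if covariates is None else covariates
    rows = []
    for rec in manifest:
        X, y = _design(cohort, dosages[rec.rsid].to_numpy(float), covariates)
        fit = _fit_logit(X, y)
        beta_out = float(fit.params["grs"])
        if ins.FLAG_LIFETIME_FLIPPED in rec.flags:
            beta_out = -beta_out  # record counts the complementary allele
        rows.append({
            "rsid": rec.rsid,
            "beta_exposure": rec.beta,
            "se_exposure": rec.se,
            "beta_outcome": beta_out,
            "se_outcome": float(fit.bse["grs"]),
        })
    return pd.DataFrame(rows)


def _per_consortium_meta(
    cohort: pd.DataFrame,
    grs: GrsVector,
    pcs_per_consortium: dict[str, int],
    extra_scores=None,
    label: str = "grs_logistic",
) -> MrEstimate:
    """Fit within each consortium with its own PC count, then pool."""
    if "consortium" not in cohort.columns:
        from .mr_onesample import default_covariates
        return fit_grs_logistic(cohort, grs, default_covariates(cohort, 3),
                                extra_scores=extra_scores, method_label=label)
    fits = []
    score = grs.values
    for cons, n_pcs in pcs_per_consortium.items():
        mask = (cohort["consortium"].astype(str) == cons).to_numpy()
        if not mask.any():
            continue
        sub = cohort.loc[mask].reset_index(drop=True)
        cov = ["age", "study"] + [f"pc{i + 1}" for i in range(n_pcs)
                                  if f"pc{i + 1}" in cohort.columns]
        sub_extras = None
        if extra_scores is not None:
            sub_extras = [np.asarray(e.values if isinstance(e, GrsVector) else e)[mask]
                          for e in extra_scores]
        fits.append(fit_grs_logistic(sub, score[mask], cov,
                                     extra_scores=sub_extras, method_label=label))
    if not fits:
        raise PipelineError("no consortium matched the pcs_per_consortium keys")
    return meta_fixed(fits, method_label=label)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed

    with _stage("load"):
        dosages = pd.read_csv(config.dosages, sep="\t", index_col=0)
        cohort = pd.read_csv(config.cohort)
        control_mask = (cohort["case_status"].astype(str) == "control").to_numpy()

    with _stage("qc"):
        dosages, qc_report = ins.qc_genotypes(
            dosages, control_mask, **config.qc)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)

    curated: dict[str, list] = {}
    logs: dict[str, ins.CurationLog] = {}
    with _stage("curate"):
        for name, tc in config.traits.items():
            manifest = ins.read_manifest(tc.manifest)
            proxies = (ins.ProxyTable(pd.read_csv(tc.proxy_table, sep="\t"))
                       if tc.proxy_table else None)
            ld = ins.read_ld_table(tc.ld_table) if tc.ld_table else None
            recs, log = ins.curate(manifest, proxies, ld,
                                   drop_palindromic=config.drop_palindromic)
            # drop instruments whose SNP failed genotype QC or is absent
            kept = [r for r in recs if r.rsid in dosages.columns]
            for r in recs:
                if r.rsid not in dosages.columns:
                    log.drop(r.rsid, "failed_qc_or_absent")
            curated[name] = kept
            logs[name] = log
            log.to_frame().to_csv(out / f"curation_{name}.tsv", sep="\t", index=False)

    scores: dict[str, GrsVector] = {}
    scaling_used: dict[str, float] = {}
    with _stage("grs"):
        for name, tc in config.traits.items():
            raw = compute_grs(dosages, curated[name], control_mask)
            if tc.calibration:
                cal = pd.read_csv(tc.calibration)
                fitted = fit_scaling(cal["raw_grs"].to_numpy(),
                                     cal["self_reported_age"].to_numpy(),
                                     cal["study"].to_numpy())
                beta_scale = fitted.beta
            else:
                beta_scale = (tc.scaling_beta if tc.scaling_beta is not None
                              else DEFAULT_SCALING_BETAS.get(name))
            if beta_scale is None:
                raise ConfigError(f"trait {name!r}: no scaling beta available")
            scores[name] = scale_grs(raw, beta_scale)
            scaling_used[name] = float(beta_scale)

    lifetime_set = None
    with _stage("lifetime"):
        if {"menarche", "menopause"} <= set(curated):
            cross = (ins.read_ld_table(config.cross_ld_table)
                     if config.cross_ld_table else ins.LdMatrix())
            lifetime_set = ins.combine_lifetime_instruments(
                curated["menarche"], curated["menopause"], cross)
            men_flip = [r for r in lifetime_set if r.trait == "menarche"]
            pau_part = [r for r in lifetime_set if r.trait == "menopause"]
            g_men = scale_grs(compute_grs(dosages, men_flip, control_mask),
                              scaling_used["menarche"])
            g_pau = scale_grs(compute_grs(dosages, pau_part, control_mask),
                              scaling_used["menopause"])
            scores["lifetime"] = lifetime_grs(g_men, g_pau)

    bmi_grs = None
    with _stage("bmi_grs"):
        if config.bmi_grs_manifest:
            bmi_manifest = ins.read_manifest(config.bmi_grs_manifest)
            bmi_present = [r for r in bmi_manifest if r.rsid in dosages.columns]
            if bmi_present:
                bmi_grs = compute_grs(dosages, bmi_present, control_mask)

    main_rows = []
    with _stage("one_sample_mr"):
        for name, grs_vec in scores.items():
            tc = config.traits.get(name)
            est = _per_consortium_meta(cohort, grs_vec, config.pcs_per_consortium,
                                       label="grs")
            row = {"trait": name, **{f"grs_{k}": v for k, v in est.to_dict().items()}}
            if bmi_grs is not None:
                adj = _per_consortium_meta(cohort, grs_vec, config.pcs_per_consortium,
                                           extra_scores=[bmi_grs], label="grs_bmi_adj")
                row.update({f"bmi_adj_{k}": v for k, v in adj.to_dict().items()})
            excluded = _bmi_excluded_rsids(tc, curated.get(name), lifetime_set, name)
            if excluded:
                members = curated[name] if name in curated else lifetime_set
                restricted = ins.restrict_bmi_associated(members, excluded)
                if restricted and len(restricted) < len(members):
                    if name == "lifetime":
                        g_m = scale_grs(compute_grs(
                            dosages, [r for r in restricted if r.trait == "menarche"],
                            control_mask), scaling_used["menarche"])
                        g_p = scale_grs(compute_grs(
                            dosages, [r for r in restricted if r.trait == "menopause"],
                            control_mask), scaling_used["menopause"])
                        r_scaled = lifetime_grs(g_m, g_p)
                    else:
                        r_raw = compute_grs(dosages, restricted, control_mask)
                        r_scaled = scale_grs(r_raw, scaling_used[name])
                    rest = _per_consortium_meta(cohort, r_scaled,
                                                config.pcs_per_consortium,
                                                label="grs_restricted")
                    row.update({f"restricted_{k}": v for k, v in rest.to_dict().items()})
            main_rows.append(row)

    strat_rows = []
    with _stage("stratified"):
        for name, tc in config.traits.items():
            for stratum in tc.strata:
                res = stratified_analysis(cohort, scores[name], stratum)
                for level, est in res.estimates.items():
                    strat_rows.append({
                        "trait": name, "stratum": stratum, "level": level,
                        **est.to_dict(),
                        "heterogeneity_p": res.heterogeneity_p,
                    })
            # site-specific: each site's cases against all controls
            cases_mask = (cohort["case_status"].astype(str) == "case").to_numpy()
            site = cohort["site"].astype(str)
            for site_label in ("colon", "rectum"):
                m = (site == site_label).to_numpy() | ~cases_mask
                if (site == site_label).sum() == 0:
                    continue
                est = fit_grs_logistic(
                    cohort.loc[m].reset_index(drop=True),
                    scores[name].values[m], method_label=f"site={site_label}")
                strat_rows.append({"trait": name, "stratum": "site",
                                   "level": site_label, **est.to_dict(),
                                   "heterogeneity_p": None})
            if (site.isin(["colon", "rectum"])).sum() and cases_mask.any():
                p_site = site_heterogeneity_case_only(
                    cohort.loc[cases_mask].reset_index(drop=True),
                    scores[name].values[cases_mask])
                strat_rows.append({"trait": name, "stratum": "site",
                                   "level": "case_only_heterogeneity",
                                   "method": "case_only", "heterogeneity_p": p_site})

    diagnostics: dict[str, Any] = {"f_statistics": {}, "two_sample": {},
                                   "scaling_betas": scaling_used}
    with _stage("two_sample_mr"):
        n_analysis = len(cohort)
        for name, tc in config.traits.items():
            if tc.r2 is not None:
                diagnostics["f_statistics"][name] = f_statistic(tc.r2, n_analysis, 1)
            if tc.summary_stats:
                stats_table = pd.read_csv(tc.summary_stats, sep="\t")
            else:
                stats_table = outcome_associations(dosages, cohort, curated[name])
            stats_table.to_csv(out / f"summary_stats_{name}.tsv", sep="\t", index=False)
            results = {}
            if "ivw" in config.two_sample_methods:
                results["ivw"] = mr2.ivw(stats_table).to_dict()
            if "egger" in config.two_sample_methods:
                results["egger"] = mr2.egger(stats_table).to_dict()
            if "weighted_median" in config.two_sample_methods:
                results["weighted_median"] = mr2.weighted_median(
                    stats_table, n_boot=config.n_boot, seed=rng_seed).to_dict()
            fd = mr2.funnel_data(stats_table)
            fd.table.to_csv(out / f"funnel_{name}.tsv", sep="\t", index=False)
            results["funnel_asymmetry_p"] = fd.asymmetry_p
            diagnostics["two_sample"][name] = results
            for r in main_rows:
                if r["trait"] == name:
                    for meth in ("egger", "weighted_median"):
                        if meth in results:
                            r.update({f"{meth}_{k}": v for k, v in results[meth].items()
                                      if k in ("beta", "se", "or", "ci_low", "ci_high", "p")})

    with _stage("confounder_screen"):
        first = next(iter(scores))
        rows = confounder_screen(scores[first], cohort)
        screen_frame = screen_to_frame(rows)
        screen_frame.to_csv(out / "confounder_screen.tsv", sep="\t", index=False)
        diagnostics["confounder_screen"] = screen_frame.to_dict(orient="records")

    power_out = []
    with _stage("power"):
        for pspec in config.power:
            entry = {"spec": pspec.__dict__,
                     "analytic": mr_power(pspec, "analytic")}
            if config.power_simulation_reps >= 500:
                entry["simulation"] = mr_power(
                    pspec, "simulation", n_reps=config.power_simulation_reps,
                    seed=rng_seed)
                entry["n_reps"] = config.power_simulation_reps
            power_out.append(entry)

    with _stage("report"):
        main = pd.DataFrame(main_rows)
        main.to_csv(out / "main_results.tsv", sep="\t", index=False)
        pd.DataFrame(strat_rows).to_csv(out / "stratified_results.tsv",
                                        sep="\t", index=False)
        (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2,
                                                         default=float))
        (out / "power.json").write_text(json.dumps(power_out, indent=2,
                                                   default=float))
        manifest_hashes = {"seed": config.seed, "inputs": {}}
        for label, p in _input_paths(config).items():
            manifest_hashes["inputs"][label] = _sha256(p)
        (out / "run_manifest.json").write_text(json.dumps(manifest_hashes, indent=2))

    return {"main": main_rows, "stratified": strat_rows,
            "diagnostics": diagnostics, "power": power_out}


def _bmi_excluded_rsids(tc, trait_set, lifetime_set, name) -> set[str]:
    """BMI-associated rsids to exclude: from file, or from manifest flags."""
    if tc is not None and tc.bmi_excluded:
        return {line.strip() for line in Path(tc.bmi_excluded).read_text().splitlines()
                if line.strip()}
    members = trait_set if trait_set is not None else (lifetime_set or [])
    return {r.rsid for r in members if ins.FLAG_BMI_ASSOCIATED in r.flags}


def _input_paths(config: RunConfig) -> dict[str, str]:
    paths = {"dosages": config.dosages, "cohort": config.cohort}
    if config.cross_ld_table:
        paths["cross_ld_table"] = config.cross_ld_table
    if config.bmi_grs_manifest:
        paths["bmi_grs_manifest"] = config.bmi_grs_manifest
    for name, tc in config.traits.items():
        for attr in ("manifest", "proxy_table", "ld_table", "calibration",
                     "bmi_excluded", "summary_stats"):
            p = getattr(tc, attr)
            if p:
                paths[f"{name}.{attr}"] = p
    return paths
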