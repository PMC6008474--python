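"""Instrument curation for reproductive-timing genetic risk scores.

An *instrument* is a SNP robustly associated with age at menarche or age at
natural menopause in a large GWAS, carried here as an
:class:`InstrumentRecord` with its per-allele effect in years.  Before a
weighted score can be built the published instrument list has to be curated
against the genotype data actually in hand:

1. variants on sex chromosomes are dropped (typically untyped in autosomal
   imputation panels);
2. variants missing from the panel are replaced by proxies in strong LD
   (r² above a threshold, conventionally 0.8), or dropped when no qualifying
   proxy exists;
3. correlated instruments (pairwise r² above a pruning threshold,
   conventionally 0.01) are thinned, keeping the member with the stronger
   exposure association;
4. genotype-level QC removes SNPs with poor call rate, Hardy–Weinberg
   disequilibrium in controls, or low minor allele frequency.

All effect sizes are harmonised so that the stored effect allele is the
trait-increasing allele (beta >= 0).  For the combined lifetime-exposure
score the menarche set is re-harmonised to the trait-*decreasing* allele so
that a higher allele count always means a longer oestrogen-exposure window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstrumentRecord",
    "ProxyTable",
    "LdMatrix",
    "CurationLog",
    "harmonise",
    "drop_sex_chromosomes",
    "substitute_proxies",
    "prune_correlated",
    "qc_genotypes",
    "combine_lifetime_instruments",
    "restrict_bmi_associated",
    "curate",
    "read_manifest",
    "write_manifest",
    "read_ld_table",
]

# flag vocabulary -----------------------------------------------------------

FLAG_SEX_CHROMOSOME = "sex_chromosome"
FLAG_PROXY_NEEDED = "proxy_needed"
FLAG_PROXY_AVAILABLE = "proxy_available"
FLAG_PROXY = "proxy"
FLAG_CORRELATED = "correlated"
FLAG_BMI_ASSOCIATED = "bmi_associated"
FLAG_PALINDROMIC = "palindromic"
FLAG_LIFETIME_FLIPPED = "lifetime_flipped"

SEX_CHROMOSOMES = {"X", "Y", "23", "24", "XY"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class CurationError(ValueError):
    """Raised when an instrument set cannot be curated as requested."""


@dataclass
class InstrumentRecord:
    """One exposure SNP with harmonised per-allele effect in years.

    ``beta`` is the effect of each copy of ``effect_allele`` on the exposure
    age, in years; after harmonisation it is non-negative for single-trait
    sets.  ``flags`` carries curation state; ``partner_rsid`` names the other
    member of a correlated pair when the record is flagged ``correlated``.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    trait: str = "menarche"
    flags: set = field(default_factory=set)
    partner_rsid: str | None = None
    pair_r2: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: se must be positive, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must be in (0,1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: identical alleles")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class ProxyTable:
    """Candidate proxies for instruments missing from the genotype panel.

    ``table`` columns: missing_rsid, proxy_rsid, r2, proxy_effect_allele,
    proxy_other_allele, proxy_eaf, aligned.  ``aligned`` is True when the
    proxy effect allele tags the original trait-increasing allele.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "missing_rsid", "proxy_rsid", "r2",
            "proxy_effect_allele", "proxy_other_allele", "proxy_eaf", "aligned",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"proxy table missing columns: {sorted(missing)}")
        r2 = self.table["r2"].to_numpy(float)
        if len(r2) and (r2.min() < 0 or r2.max() > 1):
            raise ValueError("proxy r2 outside [0,1]")

    def candidates(self, rsid: str) -> pd.DataFrame:
        return self.table[self.table["missing_rsid"] == rsid]

    @classmethod
    def empty(cls) -> "ProxyTable":
        cols = ["missing_rsid", "proxy_rsid", "r2", "proxy_effect_allele",
                "proxy_other_allele", "proxy_eaf", "aligned"]
        return cls(pd.DataFrame(columns=cols))


class LdMatrix:
    """Sparse symmetric pairwise r² lookup over rsids (diagonal == 1)."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._pairs: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise ValueError("diagonal entries are fixed at 1")
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self._pairs[frozenset((a, b))] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(frozenset((a, b)), 0.0)

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for key, r2 in self._pairs.items():
            a, b = sorted(key)
            yield a, b, r2

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "LdMatrix":
        ld = cls()
        for row in table.itertuples(index=False):
            ld.set(str(row.rsid_a), str(row.rsid_b), float(row.r2))
        return ld

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.pairs()), columns=["rsid_a", "rsid_b", "r2"])


@dataclass
class CurationLog:
    """Per-SNP record of exclusions with reasons, for audit output."""

    entries: list = field(default_factory=list)

    def drop(self, rsid: str, reason: str) -> None:
        self.entries.append({"rsid": rsid, "reason": reason})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rsid", "reason"])

    def reasons(self, reason: str) -> list[str]:
        return [e["rsid"] for e in self.entries if e["reason"] == reason]


# harmonisation -------------------------------------------------------------

def harmonise(record: InstrumentRecord) -> InstrumentRecord:
    """Orient ``record`` so the effect allele increases the trait (beta >= 0).

    Flipping swaps the alleles, complements the allele frequency, and negates
    the beta.  Idempotent: an already-harmonised record is returned unchanged.
    """
    if record.beta >= 0:
        return record
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=1.0 - record.eaf,
        beta=-record.beta,
    )


def _flip_orientation(record: InstrumentRecord) -> InstrumentRecord:
    """Re-orient to the trait-decreasing allele for the lifetime score.

    The beta keeps its magnitude and stays positive: each copy of the (now)
    effect allele shortens the trait age by ``beta`` years and therefore
    lengthens the oestrogen-exposure window by ``beta`` years.  The flag
    tells the scoring step that dosage columns — coded on the trait-increasing
    allele — must be complemented (2 − G) for this record.
    """
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=1.0 - record.eaf,
        flags=set(record.flags) | {FLAG_LIFETIME_FLIPPED},
    )


# curation steps ------------------------------------------------------------

def drop_sex_chromosomes(
    manifest: Sequence[InstrumentRecord], log: CurationLog | None = None
) -> list[InstrumentRecord]:
    """Remove sex-chromosome variants (untyped in autosomal panels)."""
    log = log if log is not None else CurationLog()
    kept = []
    for rec in manifest:
        if FLAG_SEX_CHROMOSOME in rec.flags or str(rec.chrom).upper() in SEX_CHROMOSOMES:
            log.drop(rec.rsid, "sex_chromosome")
        else:
            kept.append(rec)
    return kept


def substitute_proxies(
    manifest: Sequence[InstrumentRecord],
    proxies: ProxyTable,
    r2_min: float = 0.8,
    log: CurationLog | None = None,
) -> list[InstrumentRecord]:
    """Replace panel-missing instruments by their best qualifying proxy.

    A record flagged ``proxy_needed`` is replaced by the candidate proxy with
    the highest r² strictly above ``r2_min``; the proxy inherits the original
    beta/se/p (it tags the same signal) and is re-harmonised so the effect
    allele increases the trait.  Records with no qualifying proxy are dropped
    and logged, never raised.
    """
    if not (0 < r2_min < 1):
        raise ValueError("r2_min must be in (0,1)")
    log = log if log is not None else CurationLog()
    out: list[InstrumentRecord] = []
    for rec in manifest:
        if FLAG_PROXY_NEEDED not in rec.flags:
            out.append(rec)
            continue
        cand = proxies.candidates(rec.rsid)
        cand = cand[cand["r2"] > r2_min]
        if cand.empty:
            log.drop(rec.rsid, "no_proxy")
            continue
        best = cand.loc[cand["r2"].idxmax()]
        beta = rec.beta if bool(best["aligned"]) else -rec.beta
        new_flags = (set(rec.flags) - {FLAG_PROXY_NEEDED, FLAG_PROXY_AVAILABLE}) | {FLAG_PROXY}
        out.append(harmonise(replace(
            rec,
            rsid=str(best["proxy_rsid"]),
            effect_allele=str(best["proxy_effect_allele"]),
            other_allele=str(best["proxy_other_allele"]),
            eaf=float(best["proxy_eaf"]),
            beta=beta,
            flags=new_flags,
        )))
    return out


def prune_correlated(
    manifest: Sequence[InstrumentRecord],
    ld: LdMatrix,
    r2_max: float = 0.01,
    log: CurationLog | None = None,
) -> list[InstrumentRecord]:
    """Thin correlated instruments, keeping the stronger association.

    While any surviving pair has r² > ``r2_max``, the member with the higher
    exposure p-value is removed (ties broken toward the lexicographically
    larger rsid, so the result is independent of input order).  Input order
    of survivors is preserved.
    """
    log = log if log is not None else CurationLog()
    alive = {rec.rsid: rec for rec in manifest}
    if len(alive) != len(manifest):
        raise CurationError("duplicate rsids in manifest")

    def _loser(a: InstrumentRecord, b: InstrumentRecord) -> InstrumentRecord:
        if a.pvalue != b.pvalue:
            return a if a.pvalue > b.pvalue else b
        return a if a.rsid > b.rsid else b

    while True:
        offenders = [
            (alive[a], alive[b], r2)
            for a, b, r2 in ld.pairs()
            if r2 > r2_max and a in alive and b in alive
        ]
        if not offenders:
            break
        # drop the single worst loser, then re-scan: order-free and handles
        # overlapping pairs (A-B, B-C) correctly
        losers = [_loser(a, b) for a, b, _ in offenders]
        worst = max(losers, key=lambda r: (r.pvalue, r.rsid))
        del alive[worst.rsid]
        log.drop(worst.rsid, "correlated")
    return [rec for rec in manifest if rec.rsid in alive]


def qc_genotypes(
    dosages: pd.DataFrame,
    control_mask: np.ndarray,
    callrate_min: float = 0.98,
    hwe_alpha: float = 1e-4,
    maf_min: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype-level QC on a dosage matrix (individuals × rsids).

    A SNP column is removed when its call rate is below ``callrate_min``,
    its minor allele frequency is at or below ``maf_min``, or its
    Hardy–Weinberg goodness-of-fit p-value in controls (on dosages hard-called
    to the nearest genotype) is below ``hwe_alpha``.  Returns the filtered
    matrix and a report frame with one (rsid, reason) row per removal.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.shape[0] != dosages.shape[0]:
        raise ValueError("control_mask length must match dosage rows")
    removed: list[dict] = []
    keep: list[str] = []
    controls = dosages.loc[control_mask]
    for rsid in dosages.columns:
        col = dosages[rsid]
        callrate = 1.0 - col.isna().mean()
        if callrate < callrate_min:
            removed.append({"rsid": rsid, "reason": "callrate"})
            continue
        freq = col.mean(skipna=True) / 2.0
        maf = min(freq, 1.0 - freq)
        if maf <= maf_min:
            removed.append({"rsid": rsid, "reason": "maf"})
            continue
        hard = controls[rsid].dropna().round().astype(int).clip(0, 2)
        p_hwe = _hwe_pvalue(hard.to_numpy())
        if p_hwe < hwe_alpha:
            removed.append({"rsid": rsid, "reason": "hwe"})
            continue
        keep.append(rsid)
    report = pd.DataFrame(removed, columns=["rsid", "reason"])
    return dosages[keep], report


def _hwe_pvalue(genotypes: np.ndarray) -> float:
    """Chi-square (1 df) Hardy–Weinberg goodness of fit on hard calls."""
    n = genotypes.size
    if n == 0:
        return 1.0
    n2 = int((genotypes == 2).sum())
    n1 = int((genotypes == 1).sum())
    p = (2 * n2 + n1) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2])
    observed = np.array([n - n1 - n2, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def combine_lifetime_instruments(
    menarche: Sequence[InstrumentRecord],
    menopause: Sequence[InstrumentRecord],
    cross_ld: LdMatrix,
    r2_max: float = 0.01,
    log: CurationLog | None = None,
) -> list[InstrumentRecord]:
    """Build the instrument set for the lifetime oestrogen-exposure score.

    Menarche records are re-harmonised to the trait-decreasing allele
    (earlier menarche -> longer exposure window) and menopause records kept
    on the trait-increasing allele.  Both members of any cross-trait pair
    with r² > ``r2_max`` are removed: their signals are not independent and,
    with the two traits' p-values not comparable, neither member can claim
    precedence.
    """
    log = log if log is not None else CurationLog()
    men_rsids = {r.rsid for r in menarche}
    pau_rsids = {r.rsid for r in menopause}
    dup = men_rsids & pau_rsids
    if dup:
        cross = {frozenset((a, b)) for a, b, _ in cross_ld.pairs()}
        unexplained = {d for d in dup if not any(d in pair for pair in cross)}
        if unexplained:
            raise CurationError(
                f"rsids appear in both traits without a cross-LD entry: {sorted(unexplained)}"
            )
    drop: set[str] = set()
    for a, b, r2 in cross_ld.pairs():
        if r2 > r2_max and ((a in men_rsids and b in pau_rsids) or
                            (b in men_rsids and a in pau_rsids)):
            drop.update((a, b))
    out: list[InstrumentRecord] = []
    for rec in menarche:
        if rec.rsid in drop:
            log.drop(rec.rsid, "cross_trait_ld")
        else:
            out.append(_flip_orientation(rec))
    for rec in menopause:
        if rec.rsid in drop:
            log.drop(rec.rsid, "cross_trait_ld")
        else:
            out.append(rec)
    return out


def restrict_bmi_associated(
    manifest: Sequence[InstrumentRecord], bmi_assoc: set[str]
) -> list[InstrumentRecord]:
    """Drop instruments whose rsid is in the BMI-associated exclusion set."""
    return [rec for rec in manifest if rec.rsid not in bmi_assoc]


def curate(
    manifest: Sequence[InstrumentRecord],
    proxies: ProxyTable | None = None,
    ld: LdMatrix | None = None,
    proxy_r2_min: float = 0.8,
    prune_r2_max: float = 0.01,
    drop_palindromic: bool = False,
) -> tuple[list[InstrumentRecord], CurationLog]:
    """Full single-trait curation: sex-chr drop -> proxies -> LD pruning.

    Proxy substitution precedes pruning, matching the order in which the
    published instrument lists were processed.  Palindromic (A/T, C/G)
    records with intermediate frequency are flagged and kept unless
    ``drop_palindromic`` is set.
    """
    log = CurationLog()
    records = [harmonise(rec) for rec in manifest]
    for rec in records:
        if rec.is_palindromic and 0.4 <= rec.eaf <= 0.6:
            rec.flags.add(FLAG_PALINDROMIC)
    records = drop_sex_chromosomes(records, log)
    if drop_palindromic:
        kept = []
        for rec in records:
            if FLAG_PALINDROMIC in rec.flags:
                log.drop(rec.rsid, "palindromic")
            else:
                kept.append(rec)
        records = kept
    records = substitute_proxies(records, proxies or ProxyTable.empty(),
                                 r2_min=proxy_r2_min, log=log)
    records = prune_correlated(records, ld or LdMatrix(), r2_max=prune_r2_max, log=log)
    return records, log


# I/O -----------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "trait", "flags", "partner_rsid", "pair_r2",
]


def write_manifest(manifest: Sequence[InstrumentRecord], path) -> None:
    """Write instruments as a GWAS-summary-style TSV."""
    rows = []
    for rec in manifest:
        rows.append({
            "rsid": rec.rsid, "chrom": rec.chrom, "pos": rec.pos,
            "effect_allele": rec.effect_allele, "other_allele": rec.other_allele,
            "eaf": rec.eaf, "beta": rec.beta, "se": rec.se, "pvalue": rec.pvalue,
            "trait": rec.trait, "flags": ";".join(sorted(rec.flags)),
            "partner_rsid": rec.partner_rsid or "",
            "pair_r2": "" if rec.pair_r2 is None else rec.pair_r2,
        })
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> list[InstrumentRecord]:
    """Read instruments from a GWAS-summary-style TSV written by this package."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "partner_rsid": str})
    records = []
    for row in df.itertuples(index=False):
        flags = set(str(row.flags).split(";")) - {"", "nan"} if "flags" in df.columns else set()
        partner = getattr(row, "partner_rsid", None)
        partner = None if (partner is None or pd.isna(partner) or partner == "") else str(partner)
        pair_r2 = getattr(row, "pair_r2", None)
        pair_r2 = None if (pair_r2 is None or pd.isna(pair_r2)) else float(pair_r2)
        records.append(InstrumentRecord(
            rsid=str(row.rsid), chrom=str(row.chrom), pos=int(row.pos),
            effect_allele=str(row.effect_allele), other_allele=str(row.other_allele),
            eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
            pvalue=float(row.pvalue), trait=str(row.trait), flags=flags,
            partner_rsid=partner, pair_r2=pair_r2,
        ))
    return records


def read_ld_table(path) -> LdMatrix:
    """Read a 3-column (rsid_a, rsid_b, r2) TSV into an LdMatrix."""
    return LdMatrix.from_table(pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str}))
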