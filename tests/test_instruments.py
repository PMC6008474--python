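"""Instrument curation: proxies, pruning, QC, harmonisation, combined sets."""

import numpy as np
import pandas as pd
import pytest

from repromr import instruments as ins
from repromr import synthdata as sd
from repromr.instruments import InstrumentRecord, LdMatrix, ProxyTable


def _rec(rsid, beta=0.05, pvalue=1e-10, eaf=0.3, ea="A", oa="G", **kw):
    return InstrumentRecord(
        rsid=rsid, chrom=kw.pop("chrom", "1"), pos=kw.pop("pos", 1000),
        effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta,
        se=kw.pop("se", 0.005), pvalue=pvalue, **kw,
    )


class TestHarmonise:
    def test_negative_beta_flips_alleles_and_frequency(self):
        rec = _rec("rs1", beta=-0.04, eaf=0.2, ea="A", oa="G")
        out = ins.harmonise(rec)
        assert out.beta == pytest.approx(0.04)
        assert (out.effect_allele, out.other_allele) == ("G", "A")
        assert out.eaf == pytest.approx(0.8)

    def test_idempotent(self):
        rec = ins.harmonise(_rec("rs1", beta=-0.04))
        assert ins.harmonise(rec) == rec


class TestSubstituteProxies:
    def test_counts_match_published_curation(self, menarche_fixture):
        manifest, proxies, ld = menarche_fixture
        log = ins.CurationLog()
        autosomal = ins.drop_sex_chromosomes(manifest, log)
        out = ins.substitute_proxies(autosomal, proxies, log=log)
        assert len(log.reasons("no_proxy")) == 7
        assert len(out) == len(autosomal) - 7

    def test_identity_without_flags(self):
        records = [_rec("rs1"), _rec("rs2")]
        assert ins.substitute_proxies(records, ProxyTable.empty()) == records

    def test_unaligned_proxy_is_reharmonised(self):
        rec = _rec("rs1", beta=0.05, eaf=0.25)
        rec.flags.add(ins.FLAG_PROXY_NEEDED)
        proxies = ProxyTable(pd.DataFrame([{
            "missing_rsid": "rs1", "proxy_rsid": "rs1p", "r2": 0.95,
            "proxy_effect_allele": "C", "proxy_other_allele": "T",
            "proxy_eaf": 0.7, "aligned": False,
        }]))
        (out,) = ins.substitute_proxies([rec], proxies)
        assert out.rsid == "rs1p"
        assert out.beta == pytest.approx(0.05)  # sign restored by harmonisation
        assert out.effect_allele == "T"
        assert out.eaf == pytest.approx(0.3)

    def test_sub_threshold_candidate_drops_record(self):
        rec = _rec("rs1")
        rec.flags.add(ins.FLAG_PROXY_NEEDED)
        proxies = ProxyTable(pd.DataFrame([{
            "missing_rsid": "rs1", "proxy_rsid": "rs1p", "r2": 0.5,
            "proxy_effect_allele": "C", "proxy_other_allele": "T",
            "proxy_eaf": 0.3, "aligned": True,
        }]))
        log = ins.CurationLog()
        assert ins.substitute_proxies([rec], proxies, log=log) == []
        assert log.reasons("no_proxy") == ["rs1"]


class TestPruneCorrelated:
    def test_menarche_fixture_gives_358(self, curated_menarche):
        assert len(curated_menarche) == 358

    def test_menopause_fixture_gives_51(self, curated_menopause):
        assert len(curated_menopause) == 51

    def test_uncorrelated_set_is_identity(self):
        records = [_rec(f"rs{i}") for i in range(5)]
        assert ins.prune_correlated(records, LdMatrix()) == records

    def test_higher_pvalue_member_dropped(self):
        a = _rec("rsA", pvalue=1e-20)
        b = _rec("rsB", pvalue=1e-10)
        ld = LdMatrix({("rsA", "rsB"): 0.5})
        assert [r.rsid for r in ins.prune_correlated([a, b], ld)] == ["rsA"]

    def test_tied_pvalues_drop_lexicographically_larger(self):
        a = _rec("rsA", pvalue=1e-10)
        b = _rec("rsB", pvalue=1e-10)
        ld = LdMatrix({("rsA", "rsB"): 0.5})
        assert [r.rsid for r in ins.prune_correlated([a, b], ld)] == ["rsA"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        """Greedy pairwise enumeration oracle on sets of <= 20 SNPs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        records = [_rec(f"rs{i:02d}", pvalue=float(10 ** -rng.uniform(5, 20)))
                   for i in range(n)]
        ld = LdMatrix()
        for _ in range(int(rng.integers(1, 8))):
            i, j = rng.choice(n, 2, replace=False)
            ld.set(f"rs{i:02d}", f"rs{j:02d}", float(rng.uniform(0, 0.5)))

        # oracle: repeatedly enumerate all offending pairs and greedily drop
        # the weakest member overall
        alive = {r.rsid: r for r in records}
        while True:
            worst = None
            for a, b, r2 in ld.pairs():
                if r2 <= 0.01 or a not in alive or b not in alive:
                    continue
                ra, rb = alive[a], alive[b]
                loser = max((ra, rb), key=lambda r: (r.pvalue, r.rsid))
                if worst is None or (loser.pvalue, loser.rsid) > (worst.pvalue, worst.rsid):
                    worst = loser
            if worst is None:
                break
            del alive[worst.rsid]
        expected = [r.rsid for r in records if r.rsid in alive]

        got = [r.rsid for r in ins.prune_correlated(records, ld, r2_max=0.01)]
        assert got == expected

    def test_order_independent(self, menarche_fixture):
        manifest, proxies, ld = menarche_fixture
        fwd, _ = ins.curate(manifest, proxies, ld)
        rev, _ = ins.curate(list(reversed(manifest)), proxies, ld)
        assert {r.rsid for r in fwd} == {r.rsid for r in rev}


class TestQcGenotypes:
    @staticmethod
    def _matrix(col, n=400):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.3, n).astype(float)
        return pd.DataFrame({"good": good, "probe": col}), np.ones(n, dtype=bool)

    def test_low_maf_removed(self):
        col = np.zeros(400)
        col[:4] = 1.0  # MAF 0.005
        dosages, controls = self._matrix(col)
        kept, report = ins.qc_genotypes(dosages, controls)
        assert list(kept.columns) == ["good"]
        assert report.set_index("rsid").loc["probe", "reason"] == "maf"

    def test_hwe_failure_removed(self):
        # all heterozygous at freq 0.5: gross HWE violation
        col = np.ones(400)
        dosages, controls = self._matrix(col)
        kept, report = ins.qc_genotypes(dosages, controls)
        assert "probe" not in kept.columns
        assert report.set_index("rsid").loc["probe", "reason"] == "hwe"

    def test_low_callrate_removed(self):
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.3, 400).astype(float)
        col[:20] = np.nan  # call rate 0.95
        dosages, controls = self._matrix(col)
        kept, report = ins.qc_genotypes(dosages, controls)
        assert report.set_index("rsid").loc["probe", "reason"] == "callrate"

    def test_clean_snp_retained(self):
        rng = np.random.default_rng(2)
        col = rng.binomial(2, 0.3, 400).astype(float)
        dosages, controls = self._matrix(col)
        kept, report = ins.qc_genotypes(dosages, controls)
        assert set(kept.columns) == {"good", "probe"}
        assert report.empty

    def test_hwe_uses_controls_only(self):
        rng = np.random.default_rng(3)
        n = 800
        controls = np.zeros(n, dtype=bool)
        controls[:400] = True
        col = np.ones(n)  # would fail HWE everywhere...
        col[:400] = rng.binomial(2, 0.5, 400)  # ...but controls are clean
        dosages = pd.DataFrame({"probe": col})
        kept, _ = ins.qc_genotypes(dosages, controls)
        assert "probe" in kept.columns


class TestCombineLifetime:
    def test_cross_trait_pairs_removed(self, curated_menarche, curated_menopause):
        cross = LdMatrix()
        cross.set(curated_menarche[0].rsid, curated_menopause[0].rsid, 0.6)
        cross.set(curated_menarche[1].rsid, curated_menopause[1].rsid, 0.3)
        combined = ins.combine_lifetime_instruments(
            curated_menarche, curated_menopause, cross)
        assert len(combined) == 358 + 51 - 4

    def test_empty_menopause_gives_flipped_menarche(self, curated_menarche):
        combined = ins.combine_lifetime_instruments(
            curated_menarche, [], LdMatrix())
        assert len(combined) == len(curated_menarche)
        assert all(ins.FLAG_LIFETIME_FLIPPED in r.flags for r in combined)

    def test_flip_reorients_to_decreasing_allele(self):
        rec = _rec("rs1", beta=0.05, eaf=0.3, ea="A", oa="G")
        (out,) = ins.combine_lifetime_instruments([rec], [], LdMatrix())
        assert out.effect_allele == "G"
        assert out.eaf == pytest.approx(0.7)
        assert out.beta == pytest.approx(0.05)  # magnitude kept, duration units

    def test_duplicate_rsid_without_cross_ld_entry_raises(self):
        a = _rec("rs1", trait="menarche")
        b = _rec("rs1", trait="menopause")
        with pytest.raises(ins.CurationError):
            ins.combine_lifetime_instruments([a], [b], LdMatrix())


class TestRestrictBmiAssociated:
    def test_published_counts(self, curated_menarche):
        flagged = {r.rsid for r in curated_menarche
                   if ins.FLAG_BMI_ASSOCIATED in r.flags}
        assert len(flagged) == 42
        restricted = ins.restrict_bmi_associated(curated_menarche, flagged)
        assert len(restricted) == 316

    def test_empty_and_disjoint_sets_are_identity(self, curated_menarche):
        assert ins.restrict_bmi_associated(curated_menarche, set()) == curated_menarche
        assert ins.restrict_bmi_associated(
            curated_menarche, {"rs_not_there"}) == curated_menarche


class TestManifestIo:
    def test_roundtrip(self, tmp_path, curated_menarche):
        path = tmp_path / "manifest.tsv"
        ins.write_manifest(curated_menarche, path)
        back = ins.read_manifest(path)
        assert len(back) == len(curated_menarche)
        for a, b in zip(back, curated_menarche):
            assert a.rsid == b.rsid
            assert a.beta == pytest.approx(b.beta)
            assert a.flags == b.flags
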