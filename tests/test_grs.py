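"""Risk-score computation, year-scaling, and the lifetime score."""

import numpy as np
import pandas as pd
import pytest

from repromr import instruments as ins
from repromr import synthdata as sd
from repromr.grs import (
    GrsVector,
    compute_grs,
    fit_scaling,
    lifetime_grs,
    scale_grs,
)
from repromr.instruments import InstrumentRecord, LdMatrix
from repromr.mr_onesample import fit_grs_logistic


def _rec(rsid, beta, eaf=0.3):
    return InstrumentRecord(
        rsid=rsid, chrom="1", pos=1, effect_allele="A", other_allele="G",
        eaf=eaf, beta=beta, se=0.01, pvalue=1e-9,
    )


class TestComputeGrs:
    def test_weighted_sum_arithmetic(self):
        dosages = pd.DataFrame([[2.0, 1.0, 0.0]], columns=["rs1", "rs2", "rs3"])
        instruments = [_rec("rs1", 0.1), _rec("rs2", 0.2), _rec("rs3", 0.3)]
        score = compute_grs(dosages, instruments)
        assert score.raw[0] == pytest.approx(0.4)

    def test_zero_betas_give_zero_scores(self):
        dosages = pd.DataFrame(np.random.default_rng(0).uniform(0, 2, (5, 2)),
                               columns=["rs1", "rs2"])
        score = compute_grs(dosages, [_rec("rs1", 0.0), _rec("rs2", 0.0)])
        assert np.all(score.raw == 0.0)

    def test_all_zero_dosages_give_zero(self):
        dosages = pd.DataFrame(np.zeros((3, 2)), columns=["rs1", "rs2"])
        score = compute_grs(dosages, [_rec("rs1", 0.3), _rec("rs2", 0.1)])
        assert np.all(score.raw == 0.0)

    def test_linearity_in_betas(self):
        rng = np.random.default_rng(1)
        dosages = pd.DataFrame(rng.uniform(0, 2, (20, 3)),
                               columns=["rs1", "rs2", "rs3"])
        base = [_rec(f"rs{i+1}", b) for i, b in enumerate((0.1, 0.2, 0.3))]
        tripled = [_rec(f"rs{i+1}", 3 * b) for i, b in enumerate((0.1, 0.2, 0.3))]
        np.testing.assert_allclose(compute_grs(dosages, tripled).raw,
                                   3.0 * compute_grs(dosages, base).raw)

    def test_missing_instrument_column_names_rsid(self):
        dosages = pd.DataFrame([[1.0]], columns=["rs1"])
        with pytest.raises(KeyError, match="rs_absent"):
            compute_grs(dosages, [_rec("rs_absent", 0.1)])

    def test_missing_dosages_mean_imputed_from_controls(self):
        dosages = pd.DataFrame({"rs1": [0.0, 2.0, np.nan, 1.0]})
        controls = np.array([True, True, False, False])
        score = compute_grs(dosages, [_rec("rs1", 1.0)], control_mask=controls)
        assert score.raw[2] == pytest.approx(1.0)  # control mean dose
        with pytest.raises(ValueError):
            compute_grs(dosages, [_rec("rs1", 1.0)], missing="error")

    def test_allele_recoding_shifts_scores_but_not_association(self, null_dataset):
        """Recoding a SNP (G -> 2-G with flipped weight) is a constant shift."""
        dataset, manifest = null_dataset
        score = compute_grs(dataset.dosages, manifest)
        recoded_doses = dataset.dosages.copy()
        rsid0 = manifest[0].rsid
        recoded_doses[rsid0] = 2.0 - recoded_doses[rsid0]
        # the same association restated on the complementary allele coding
        flipped0 = InstrumentRecord(
            rsid=rsid0, chrom="1", pos=1, effect_allele=manifest[0].other_allele,
            other_allele=manifest[0].effect_allele, eaf=1 - manifest[0].eaf,
            beta=-manifest[0].beta, se=manifest[0].se, pvalue=manifest[0].pvalue,
        )
        score2 = compute_grs(recoded_doses, [flipped0] + list(manifest[1:]))
        shift = score2.raw - score.raw
        np.testing.assert_allclose(shift, shift[0], atol=1e-12)
        est1 = fit_grs_logistic(dataset.cohort, score)
        est2 = fit_grs_logistic(dataset.cohort, score2)
        assert est1.beta == pytest.approx(est2.beta, abs=1e-8)


class TestFitScaling:
    def test_recovers_published_menarche_slope(self):
        cal = sd.generate_scaling_calibration(0.57, n_per_study=850, n_studies=2,
                                              seed=40)
        fit = fit_scaling(cal["raw_grs"].to_numpy(),
                          cal["self_reported_age"].to_numpy(),
                          cal["study"].to_numpy())
        assert abs(fit.beta - 0.57) < 2 * fit.se
        assert fit.se <= fit.per_study["se"].min()

    def test_single_study_pooled_equals_per_study(self):
        cal = sd.generate_scaling_calibration(0.98, n_per_study=500, n_studies=1,
                                              seed=41, trait="menopause")
        fit = fit_scaling(cal["raw_grs"].to_numpy(),
                          cal["self_reported_age"].to_numpy(),
                          cal["study"].to_numpy())
        assert fit.beta == pytest.approx(fit.per_study.loc[0, "beta"])
        assert fit.se == pytest.approx(fit.per_study.loc[0, "se"])

    def test_zero_age_variance_study_excluded(self):
        rng = np.random.default_rng(42)
        n = 100
        age = np.concatenate([np.full(n, 13.0), rng.normal(13, 1.5, n)])
        raw = 0.5 * age + rng.normal(0, 0.5, 2 * n)
        study = np.array(["flat"] * n + ["ok"] * n)
        with pytest.warns(UserWarning, match="zero age variance"):
            fit = fit_scaling(raw, age, study)
        assert list(fit.per_study["study"]) == ["ok"]


class TestScaleGrs:
    def test_identity_at_unit_beta(self):
        score = GrsVector(raw=np.array([1.0, 2.0]), trait="menarche")
        scaled = scale_grs(score, 1.0)
        np.testing.assert_allclose(scaled.scaled, scaled.raw)

    def test_default_menopause_beta(self):
        score = GrsVector(raw=np.array([0.98]), trait="menopause")
        scaled = scale_grs(score)
        assert scaled.scaling_beta == pytest.approx(0.98)
        assert scaled.scaled[0] == pytest.approx(1.0)

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=50)
        a = scale_grs(GrsVector(raw=raw, trait="menarche"), 0.57)
        b = scale_grs(GrsVector(raw=3.0 * raw, trait="menarche"), 3.0 * 0.57)
        np.testing.assert_allclose(a.scaled, b.scaled)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            scale_grs(GrsVector(raw=np.array([1.0]), trait="menarche"), 0.0)

    def test_scaling_identity_in_logistic_model(self, null_dataset):
        """Coefficient on the scaled score times 1/scaling-beta recovers the
        raw-score coefficient: b_scaled == b_raw * scaling_beta exactly."""
        dataset, manifest = null_dataset
        raw = compute_grs(dataset.dosages, manifest)
        scaled = scale_grs(raw, 0.57)
        b_raw = fit_grs_logistic(dataset.cohort, raw.raw).beta
        b_scaled = fit_grs_logistic(dataset.cohort, scaled).beta
        assert b_scaled == pytest.approx(b_raw * 0.57, abs=1e-8)


class TestLifetimeGrs:
    def test_zero_menopause_component_is_identity(self):
        men = GrsVector(raw=np.array([1.0, 2.0]), trait="menarche",
                        scaled=np.array([1.0, 2.0]), scaling_beta=1.0)
        pau = GrsVector(raw=np.zeros(2), trait="menopause",
                        scaled=np.zeros(2), scaling_beta=1.0)
        total = lifetime_grs(men, pau)
        np.testing.assert_allclose(total.values, men.scaled)
        assert total.trait == "lifetime"

    def test_length_mismatch_raises(self):
        men = GrsVector(raw=np.zeros(3), trait="menarche", scaled=np.zeros(3),
                        scaling_beta=1.0)
        pau = GrsVector(raw=np.zeros(2), trait="menopause", scaled=np.zeros(2),
                        scaling_beta=1.0)
        with pytest.raises(ValueError):
            lifetime_grs(men, pau)

    def test_correlates_with_exposure_window(self, curated_menarche,
                                             curated_menopause):
        """Higher lifetime score must mean a longer menarche-to-menopause window."""
        spec = sd.SimulationSpec(n_cases=2000, n_controls=2000, seed=50)
        dataset = sd.generate_cohort(spec, curated_menarche,
                                     second_manifest=curated_menopause)
        combined = ins.combine_lifetime_instruments(
            curated_menarche, curated_menopause, LdMatrix())
        men_part = [r for r in combined if r.trait == "menarche"]
        pau_part = [r for r in combined if r.trait == "menopause"]
        g_men = scale_grs(compute_grs(dataset.dosages, men_part), 1.0)
        g_pau = scale_grs(compute_grs(dataset.dosages, pau_part), 1.0)
        total = lifetime_grs(g_men, g_pau)
        window = (dataset.truth["exposure_second"] - dataset.truth["exposure"])
        r = np.corrcoef(total.values, window)[0, 1]
        assert r > 0.2
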