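import math

import pytest

from repromr import instruments as ins
from repromr import synthdata as sd


@pytest.fixture(scope="session")
def menarche_fixture():
    """Published-list-sized menarche manifest with all curation hazards."""
    manifest = sd.generate_manifest(
        389, n_sex_chr=12, n_missing=42, n_no_proxy=7, n_correlated=12,
        seed=101, n_bmi_associated=42,
    )
    proxies = sd.derive_proxy_table(manifest, seed=102)
    ld = sd.derive_ld_matrix(manifest)
    return manifest, proxies, ld


@pytest.fixture(scope="session")
def curated_menarche(menarche_fixture):
    manifest, proxies, ld = menarche_fixture
    records, _ = ins.curate(manifest, proxies, ld)
    return records


@pytest.fixture(scope="session")
def menopause_fixture():
    manifest = sd.generate_manifest(
        54, n_correlated=3, seed=103, trait="menopause",
        target_r2=0.057, exposure_sd_years=4.8,
    )
    return manifest, sd.derive_proxy_table(manifest, seed=104), sd.derive_ld_matrix(manifest)


@pytest.fixture(scope="session")
def curated_menopause(menopause_fixture):
    manifest, proxies, ld = menopause_fixture
    records, _ = ins.curate(manifest, proxies, ld)
    return records


@pytest.fixture(scope="session")
def null_dataset():
    """Small cohort with no causal effect, no confounding, no pleiotropy."""
    manifest = sd.generate_manifest(50, seed=201)
    spec = sd.SimulationSpec(n_cases=1500, n_controls=1500, n_snps=50, seed=202)
    return sd.generate_cohort(spec, manifest), manifest


@pytest.fixture(scope="session")
def causal_dataset():
    """Cohort with a protective effect of OR 0.90 per year of exposure."""
    manifest = sd.generate_manifest(50, seed=203)
    spec = sd.SimulationSpec(
        n_cases=3000, n_controls=3000, n_snps=50,
        causal_logor_per_year=math.log(0.90), seed=204,
    )
    return sd.generate_cohort(spec, manifest), manifest
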