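import numpy as np
import pytest

import uniblup as ub


@pytest.fixture
def trio_pedigree():
    """Unrelated sire and dam with two full-sib offspring."""
    return ub.Pedigree.from_records(
        [("S", None, None), ("D", None, None), ("O1", "S", "D"), ("O2", "S", "D")]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small but structured dataset shared by read-only tests."""
    cfg = ub.SimConfig(
        n_sires=20,
        n_dams=35,
        family_size_mean=12.0,
        family_size_range=(6, 20),
        family_size_sigma=0.3,
        n_snps=400,
        genotyped_families=15,
        sigma2_av_exp=0.2,
        sigma2_cv_exp=0.1,
        r_g_mean_disp=0.5,
        seed=7,
    )
    return ub.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """Converged sire-dam DHGLM fit on the small dataset (pedigree kernel)."""
    data = small_dataset
    rels = ub.build_relationship_set(data.pedigree)
    spec = ub.ModelSpec(genetic_param="sire_dam", relationship="A")
    kin = ub.kinship_inverse_for(spec, rels, data.pedigree)
    y, _ = ub.standardize(data.phenotypes.weight)
    fit = ub.fit_dhglm(data.phenotypes, spec, kin, data.pedigree, response=y)
    return data, spec, kin, y, fit


def assert_symmetric(matrix, tol=1e-10):
    assert np.abs(matrix - matrix.T).max() <= tol
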