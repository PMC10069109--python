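import numpy as np
import pytest

import ftirpred as fp
from ftirpred.io import prepare_analysis_data


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated cohort shared across read-only tests."""
    cfg = fp.SimConfig(
        n_cows=200,
        n_snps=150,
        n_wavelengths=60,
        n_batches=6,
        herd_sizes=(160, 40),
        traits={"t1": fp.TraitTargets(0.4, 0.2), "t2": fp.TraitTargets(0.1, 0.3)},
        rng_seed=11,
    )
    return fp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_bundle):
    b = small_bundle
    data, kin, attrition = prepare_analysis_data(
        b.cow_table, b.spectra, b.genotypes, b.pedigree
    )
    return data, kin, attrition


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
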