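import numpy as np
import pytest

from cooltrio import methylome
from cooltrio.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Small two-patient cohort on a 3.7-Mb genome for structural tests."""
    return SyntheticConfig(
        seed=11,
        chrom_sizes={"chr1": 1_500_000, "chr2": 1_500_000, "chrX": 700_000},
        n_patients=2, n_normal_cells=5, n_cancer_cells=8,
        n_genes=60, n_promoter_hyper=8, n_promoter_hypo=4,
        n_shared_ndrs=15, n_cancer_ndrs=8, n_normal_ndrs=8,
        cnv_bin_size=100_000,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_wcg(tiny_ds):
    return {c: methylome.usable_sites(tiny_ds.wcg[c]) for c in tiny_ds.cells}


@pytest.fixture(scope="session")
def tiny_gch(tiny_ds):
    return {c: methylome.usable_sites(tiny_ds.gch[c]) for c in tiny_ds.cells}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
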