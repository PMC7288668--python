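import numpy as np
import pytest

from zipprofiler.simulate import ZipperDesign, make_bzip_protein, make_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """A 40-protein designed family shared by aggregate-level tests."""
    return make_family(n_proteins=40, seed=777)


@pytest.fixture
def four_heptad_protein():
    """A 4-heptad design with an Asn at a of L2 and one attractive pair."""
    design = ZipperDesign(
        n_heptads=4,
        a_slots={2: "N"},
        ge_design={0: "attractive_basic_acidic"},
    )
    return design, *make_bzip_protein(design, seed=11)
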