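import pytest

import amplitag as at
from amplitag.primers import S615F_CER, S947R_CER


@pytest.fixture(scope="session")
def constraints():
    return at.DesignConstraints()


@pytest.fixture(scope="session")
def fw_set(constraints):
    return at.design_barcodes(S615F_CER, constraints, target_size=18, seed=1)


@pytest.fixture(scope="session")
def rv_set(constraints):
    return at.design_barcodes(
        S947R_CER, constraints, target_size=18, seed=2, orientation="reverse"
    )


@pytest.fixture(scope="session")
def paper_scheme(fw_set, rv_set):
    """150 samples on the 18x18 grid, as in the study layout."""
    grid = at.build_grid(fw_set, rv_set)
    samples = [f"S{i + 1:03d}" for i in range(150)]
    return at.select_combinations(
        grid, samples, seed=5,
        fw_primer=str(S615F_CER), rv_primer=str(S947R_CER),
    )


@pytest.fixture(scope="session")
def small_scheme(fw_set, rv_set):
    """12 samples on the 18x18 grid; primers attached for matching."""
    grid = at.build_grid(fw_set, rv_set)
    samples = [f"AEG{i + 1:02d}" for i in range(12)]
    return at.select_combinations(
        grid, samples, seed=3,
        fw_primer=str(S615F_CER), rv_primer=str(S947R_CER),
    )


@pytest.fixture(scope="session")
def desk_table():
    """Desk-scale OTU table with planted sharing, guilds and 8% non-target OTUs."""
    table, traits, truth = at.make_otu_table(
        n_otus=200, n_samples=12, shared_frac=0.8, nontarget_frac=0.08, seed=4
    )
    return table, traits, truth
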