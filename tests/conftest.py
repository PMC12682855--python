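import numpy as np
import pytest

from pindicator import (
    HarvestRecord,
    TrialDesign,
    load_table3_fixture,
)


@pytest.fixture(scope="session")
def table_4pmi():
    return load_table3_fixture("4PMI")


@pytest.fixture(scope="session")
def table_alsia():
    return load_table3_fixture("ALSIA")


@pytest.fixture
def small_design():
    return TrialDesign(
        genotypes=("GA", "GB"),
        p_applied={"P+": 0.05, "P-": 0.005},
        replicates_per_cell=2,
        platform_label="TEST",
    )


@pytest.fixture
def small_records(small_design):
    """Hand-built 2-genotype x 2-level x 2-replicate harvest table."""
    rows = [
        # genotype, level, rep, shoot, root, conc, uptake
        ("GA", "P+", 1, 1.00, 0.30, 0.50, 0.020),
        ("GA", "P+", 2, 1.20, 0.40, 0.60, 0.030),
        ("GA", "P-", 1, 0.40, 0.20, 0.10, 0.004),
        ("GA", "P-", 2, 0.50, 0.25, 0.20, 0.003),
        ("GB", "P+", 1, 0.80, 0.20, 0.40, 0.016),
        ("GB", "P+", 2, 0.90, 0.25, 0.50, 0.024),
        ("GB", "P-", 1, 0.30, 0.15, 0.15, 0.002),
        ("GB", "P-", 2, 0.35, 0.10, 0.25, 0.001),
    ]
    return [
        HarvestRecord(genotype=g, p_level=lv, replicate=r, shoot_dw=s,
                      root_dw=rt, plant_p_concentration=c, p_uptake=u)
        for g, lv, r, s, rt, c, u in rows
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
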