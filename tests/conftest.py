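import numpy as np
import pytest

from haplomine import default_config, simulate_panel
from haplomine.genomic_io import GroupSummary


@pytest.fixture(scope="session")
def sd1_guangzhou():
    """Printed PH summaries for the 4-haplotype gene at the first location."""
    return [
        GroupSummary("Hap1", 25, 91.8, 10.1),
        GroupSummary("Hap2", 91, 120.7, 24.2),
        GroupSummary("Hap3", 28, 136.8, 18.2),
        GroupSummary("Hap4", 46, 137.2, 21.3),
    ]


@pytest.fixture(scope="session")
def sd1_yangjiang():
    return [
        GroupSummary("Hap1", 26, 90.1, 8.9),
        GroupSummary("Hap2", 92, 125.1, 19.1),
        GroupSummary("Hap3", 28, 142.9, 19.2),
        GroupSummary("Hap4", 56, 142.9, 18.0),
    ]


@pytest.fixture(scope="session")
def two_hap_guangzhou():
    """Printed PH summaries for the 2-haplotype gene at the first location."""
    return (
        GroupSummary("Hap1", 174, 122.6, 26.7),
        GroupSummary("Hap2", 88, 141.0, 17.8),
    )


@pytest.fixture(scope="session")
def combo_table():
    """Printed 6-combination summaries: column -> [(n, mean, sd, letter)] rows 1..6."""
    return {
        ("SL", "GST"): [
            (19, 27.7, 2.3, "a"), (74, 30.9, 3.7, "b"), (8, 36.5, 4.6, "b"),
            (15, 36.3, 3.9, "b"), (14, 40.2, 5.0, "c"), (29, 38.0, 4.9, "bc"),
        ],
        ("SL", "GSF"): [
            (20, 24.0, 2.5, "a"), (74, 27.6, 3.3, "b"), (8, 27.9, 3.7, "b"),
            (15, 27.4, 4.2, "b"), (14, 31.9, 3.4, "c"), (29, 31.5, 4.3, "c"),
        ],
        ("SL", "DST"): [
            (20, 18.6, 2.2, "a"), (74, 22.0, 2.7, "b"), (8, 22.9, 3.5, "b"),
            (15, 23.3, 3.2, "bc"), (14, 25.4, 3.3, "c"), (29, 25.4, 3.3, "c"),
        ],
        ("PH", "Guangzhou"): [
            (20, 91.6, 9.8, "a"), (74, 122.7, 23.6, "b"), (8, 130.6, 19.5, "bc"),
            (15, 140.6, 16.9, "c"), (14, 141.7, 19.3, "c"), (29, 134.9, 22.3, "bc"),
        ],
        ("PH", "Yangjiang"): [
            (16, 91.9, 10.0, "a"), (67, 121.9, 18.0, "b"), (8, 138.0, 20.9, "c"),
            (15, 146.0, 19.1, "c"), (13, 141.7, 18.7, "c"), (26, 138.8, 20.7, "c"),
        ],
    }


@pytest.fixture(scope="session")
def sim_panel():
    """One default simulated panel (343 accessions, 10 genes, planted causal)."""
    return simulate_panel(default_config(seed=20240325))


@pytest.fixture(scope="session")
def small_panel():
    """A fast small panel for I/O and plumbing tests."""
    cfg = default_config(seed=7, n_genes=3, causal_index=1, n_accessions=80)
    return simulate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
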