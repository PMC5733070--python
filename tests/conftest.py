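import numpy as np
import pandas as pd
import pytest

from haplopaint.data_model import GeneticMap, GenotypeMatrix, SampleMetadata
from haplopaint.synthetic_data import DonorSimConfig, simulate_donor_pops


@pytest.fixture(scope="session")
def small_donors():
    """Four differentiated subpops, modest size; shared across test modules."""
    cfg = DonorSimConfig(
        n_subpops=4,
        fst=0.2,
        n_snps=600,
        n_chromosomes=4,
        map_length_cm=120.0,
        n_samples=25,
        seed=11,
    )
    return simulate_donor_pops(cfg)


@pytest.fixture(scope="session")
def ld_donors():
    """High-LD panel (few founders, light mixing) for haplotype-driven tests."""
    cfg = DonorSimConfig(
        n_subpops=4,
        fst=0.2,
        n_snps=1200,
        n_chromosomes=4,
        map_length_cm=120.0,
        n_samples=50,
        n_founders=6,
        n_generations=3,
        seed=11,
    )
    return simulate_donor_pops(cfg)


@pytest.fixture
def toy_matrix():
    calls = np.array(
        [
            [0, 1, 0, 1],
            [0, 1, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["s1", "s2", "s3"], ["a", "b", "c", "d"], calls)


@pytest.fixture
def toy_map():
    return GeneticMap.from_records(
        [("a", "1A", 0.0), ("b", "1A", 5.0), ("c", "1A", 11.0), ("d", "2B", 3.0)]
    )


def make_metadata(donor_pops=None, recipients=()):
    rows = []
    if donor_pops:
        for sid, pop in donor_pops.items():
            rows.append((sid, "donor", pop, None, None, None))
    for sid, year, state in recipients:
        rows.append((sid, "recipient", None, "AU", year, state))
    df = pd.DataFrame(
        rows, columns=["sample_id", "role", "subpop_id", "country", "year", "state"]
    ).set_index("sample_id")
    return SampleMetadata(df)
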