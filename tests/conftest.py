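import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from introscan.io import GenotypeMatrix, GroupMap, slice_blocks
from introscan.sim import PlantedTract, SimulationConfig, simulate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_matrix(dosage, chrom="chr1", start_pos=1, ids=None, spacing=1):
    """Small GenotypeMatrix from a dosage array with evenly spaced sites."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_acc, n_sites = dosage.shape
    if ids is None:
        ids = [f"s{i:02d}" for i in range(n_acc)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": start_pos + spacing * np.arange(n_sites),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
        }
    )
    return GenotypeMatrix(list(ids), sites, dosage)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default-scale dataset with one indica -> tropical japonica tract of
    500 kb (block-aligned), 30% carriers; the workhorse detection fixture."""
    cfg = SimulationConfig(seed=1)
    tract = PlantedTract(
        "chr1", 2_000_000, 2_500_000, "indica", "tropical_japonica",
        replacement_fraction=0.3,
    )
    return simulate_dataset(cfg, [tract])


@pytest.fixture(scope="session")
def null_dataset():
    """No planted tracts; P1/P2 symmetric by construction (equal F)."""
    cfg = SimulationConfig(seed=2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tree_grid(planted_dataset):
    cfg = planted_dataset.config
    return slice_blocks(planted_dataset.genotypes.sites, 500_000, cfg.chrom_lengths())


@pytest.fixture
def toy_groups():
    return GroupMap(
        {f"A{i}": "A" for i in range(1, 4)} | {f"B{i}": "B" for i in range(1, 4)},
        ["A", "B"],
    )
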