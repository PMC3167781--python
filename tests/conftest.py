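import numpy as np
import pandas as pd
import pytest

from segnet import simulate
from segnet.types import GenotypeMatrix, MarkerMap, RegulatoryArchitecture, TraitMatrix


@pytest.fixture(scope="session")
def tiny_map() -> MarkerMap:
    """Two chromosomes, 5 + 4 markers, short coordinates."""
    return MarkerMap(
        np.array([f"1_{p}" for p in (10, 20, 30, 40, 50)] + [f"2_{p}" for p in (5, 15, 25, 35)],
                 dtype=object),
        np.array([1] * 5 + [2] * 4),
        np.array([10, 20, 30, 40, 50, 5, 15, 25, 35]),
        {1: 60, 2: 40},
    )


@pytest.fixture(scope="session")
def small_genotypes(tiny_map) -> GenotypeMatrix:
    return simulate.simulate_genotypes(24, tiny_map, recomb_prob=0.3, seed=5)


@pytest.fixture(scope="session")
def default_map() -> MarkerMap:
    return simulate.default_marker_map()


def make_traits(n_genes: int, n_seg: int, seed: int, prefix: str = "g") -> TraitMatrix:
    rng = np.random.default_rng(seed)
    return TraitMatrix(
        [f"{prefix}{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_seg)],
        rng.normal(size=(n_genes, n_seg)),
    )


def single_gene_architecture(
    gene_id: str = "G1",
    transmission: float = 0.0,
    chromosome: int = 1,
    position: int = 30,
    hotspots=None,
) -> RegulatoryArchitecture:
    genes = pd.DataFrame(
        {
            "gene_id": [gene_id],
            "community": ["none"],
            "chromosome": [chromosome],
            "position": [position],
            "transmission": [transmission],
            "cis_layer": [""],
            "cis_effect": [0.0],
        }
    )
    return RegulatoryArchitecture(genes=genes, hotspots=hotspots or [])
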