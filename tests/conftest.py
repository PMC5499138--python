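import numpy as np
import pandas as pd
import pytest

from rcgs import simulate_founders, simulate_map
from rcgs.breeding import Population, make_meta
from rcgs.genome import GeneticMap, GenotypeTable


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return simulate_map(3, 40, 150.0, 10_000_000, seed=11)


@pytest.fixture(scope="session")
def founder_panel(small_map):
    return simulate_founders(small_map, n_parents=18, missing_rate=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def two_marker_map(cm_gap: float) -> GeneticMap:
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2"],
                "chrom": ["chr1", "chr1"],
                "pos_bp": [100, 200],
                "pos_cM": [0.0, cm_gap],
            }
        )
    )


def inbred_pair(gmap: GeneticMap) -> Population:
    """Two fully inbred individuals carrying opposite alleles everywhere."""
    m = gmap.n_markers
    hap = np.zeros((2, 2, m), dtype=np.uint8)
    hap[1] = 1
    return Population(gmap, hap, make_meta(["A", "B"], family="founders"))


def table_from_dosage(gmap: GeneticMap, dosage, samples=None) -> GenotypeTable:
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    samples = samples or [f"s{i}" for i in range(dosage.shape[0])]
    return GenotypeTable(samples, gmap, dosage)


def uniform_map(n_markers: int, chrom: str = "chr1", spacing_cm: float = 1.0) -> GeneticMap:
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": [f"{chrom}_m{i}" for i in range(n_markers)],
                "chrom": chrom,
                "pos_bp": np.arange(1, n_markers + 1) * 1000,
                "pos_cM": np.arange(n_markers) * spacing_cm,
            }
        )
    )
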