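import numpy as np
import pandas as pd
import pytest

from outbredkit.genotypes import ColonyPanel, FounderPanel, GenotypeMatrix, MarkerMap
from outbredkit.simulate import SimConfig, breed_colony, simulate_founders


def make_map(positions, chrom="1", alleles=("A", "G")):
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(positions))],
                "chromosome": chrom,
                "position_bp": positions,
                "allele_a": alleles[0],
                "allele_b": alleles[1],
            }
        )
    )


def make_matrix(calls, positions=None, samples=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(calls.shape[1])]
    if samples is None:
        samples = [f"s{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(list(samples), make_map(positions, chrom=chrom), calls)


@pytest.fixture(scope="session")
def small_founders():
    return simulate_founders(4, 120, 0.3, seed=11, region_span_bp=12_000_000)


@pytest.fixture(scope="session")
def bred_colony(small_founders):
    cfg = SimConfig(
        n_founders=4,
        n_markers=120,
        region_span_bp=12_000_000,
        generations=10,
        census_size=60,
        seed=7,
    )
    return breed_colony(small_founders, cfg, colony_id="C0")


@pytest.fixture(scope="session")
def three_colonies(small_founders):
    colonies = []
    truths = []
    for s in range(3):
        cfg = SimConfig(
            n_founders=4,
            n_markers=120,
            region_span_bp=12_000_000,
            generations=10,
            census_size=60,
            seed=20 + s,
        )
        c, t = breed_colony(small_founders, cfg, colony_id=f"C{s}")
        colonies.append(c)
        truths.append(t)
    return colonies, truths
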