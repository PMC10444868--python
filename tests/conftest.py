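import numpy as np
import pytest

from msatyard import GenotypeMatrix, SimulationSpec, simulate_population


def matrix_from_pairs(pairs, locus="L1", label="pop"):
    """Build a one-locus GenotypeMatrix from [(a1, a2), ...]; None = missing."""
    calls = np.array(
        [[(0, 0) if p is None else p] for p in pairs], dtype=np.int32
    )
    ids = [f"i{k + 1}" for k in range(len(pairs))]
    return GenotypeMatrix(ids, [locus], calls, population_label=label)


def matrix_from_columns(columns, loci=None, label="pop"):
    """Multi-locus matrix from a list of per-locus pair lists (equal length)."""
    n = len(columns[0])
    calls = np.zeros((n, len(columns), 2), dtype=np.int32)
    for j, col in enumerate(columns):
        for i, p in enumerate(col):
            calls[i, j] = (0, 0) if p is None else p
    loci = loci or [f"L{j + 1}" for j in range(len(columns))]
    return GenotypeMatrix([f"i{k + 1}" for k in range(n)], loci, calls, label)


def biallelic_matrix(n_aa, n_ab, n_bb, a=100, b=102, locus="L1"):
    pairs = [(a, a)] * n_aa + [(a, b)] * n_ab + [(b, b)] * n_bb
    return matrix_from_pairs(pairs, locus=locus)


@pytest.fixture(scope="session")
def sim_population():
    """A moderate simulated population reused across read-only tests."""
    return simulate_population(
        SimulationSpec(n_individuals=60, n_loci=12, alleles_per_locus=6, seed=42,
                       label="simpop")
    )
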