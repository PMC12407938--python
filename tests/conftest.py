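import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from synteny3d.io_formats import GeneRecord, GenomeSpec, SparseContacts
from synteny3d.synthetic_data import SimulationConfig, simulate_all

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Scaled-down stated world for structural tests (seconds, not minutes)."""
    base = dict(
        seed=seed,
        n_outgroup_chroms=2,
        genes_per_chrom=40,
        genome_sizes={"squid": 8_000_000, "cuttlefish": 7_000_000,
                      "octopus": 4_000_000, "scallop": 4_000_000},
        rearrangement_plans={"octopus": [("fusion", "c1", "c2", True)]},
        n_conserved_loops=4,
        n_private_loops=2,
        loop_gene_separation=(10, 25),
        cne_count=200,
        n_coding_blocks=50,
        repeat_count=200,
        n_tissues=8,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_all(small_config(seed=0))


@pytest.fixture(scope="session")
def default_dataset():
    """One full-scale synthetic dataset at generator defaults."""
    return simulate_all(seed=0)


@pytest.fixture
def toy_genome():
    return GenomeSpec("toy", (("chr1", 2_000_000), ("chr2", 1_000_000)))


@pytest.fixture
def toy_genes():
    return [
        GeneRecord("gA", "chr1", 150_000, 250_000),
        GeneRecord("gB", "chr1", 420_000, 480_000),
        GeneRecord("gC", "chr1", 900_000, 950_000),
        GeneRecord("gD", "chr2", 100_000, 180_000),
    ]


def contacts_from_dense(matrix: np.ndarray, chrom: str = "chr1",
                        resolution: int = 100_000, sample_id: str = "toy") -> SparseContacts:
    """Upper-triangle sparse container from a dense symmetric matrix,
    omitting zero entries (sparse semantics)."""
    n = matrix.shape[0]
    rows = [
        (chrom, i, j, float(matrix[i, j]))
        for i in range(n)
        for j in range(i, n)
        if matrix[i, j] != 0
    ]
    return SparseContacts(
        sample_id, resolution,
        pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "value"]),
    )


def brute_force_insulation(dense: np.ndarray, w: int) -> np.ndarray:
    """Independent reference: explicit double loop over the sliding square,
    then log2 normalisation by the mean of the valid raw scores."""
    n = dense.shape[0]
    raw = np.full(n, np.nan)
    for i in range(n):
        if i - w < 0 or i + w > n - 1:
            continue
        vals = []
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                vals.append(dense[a, b])
        raw[i] = float(np.mean(vals))
    valid = np.isfinite(raw)
    out = np.full(n, np.nan)
    if valid.any():
        m = raw[valid].mean()
        if m > 0:
            with np.errstate(divide="ignore"):
                out[valid] = np.log2(raw[valid] / m)
    return out
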