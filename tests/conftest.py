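"""Shared fixtures: tiny matrices built in memory, never from stored data."""
from __future__ import annotations

import numpy as np
import pytest

from sweepscan import HaplotypeMatrix, MISSING


def make_matrix(
    calls,
    populations=None,
    positions=None,
    scaffold="scaf1",
    genetic_pos=None,
) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    sample_ids = [f"s{i+1}" for i in range(n)]
    if populations is None:
        pops = {s: "pop1" for s in sample_ids}
    elif isinstance(populations, dict):
        pops = populations
    else:
        pops = dict(zip(sample_ids, populations))
    if positions is None:
        positions = np.arange(1, L + 1) * 100
    return HaplotypeMatrix(
        sample_ids=sample_ids,
        populations=pops,
        scaffolds=np.full(L, scaffold, dtype=object),
        positions_bp=np.asarray(positions, dtype=np.int64),
        ref_allele=np.full(L, "A", dtype=object),
        alt_allele=np.full(L, "T", dtype=object),
        calls=calls,
        genetic_pos=genetic_pos,
    )


@pytest.fixture
def two_pop_matrix() -> HaplotypeMatrix:
    """10 + 10 samples, 3 sites; site 0 is a fixed difference."""
    rng = np.random.default_rng(7)
    calls = np.zeros((20, 3), dtype=np.int8)
    calls[:10, 0] = 1                      # fixed difference
    calls[:, 1] = rng.integers(0, 2, 20)   # shared polymorphism
    calls[:12, 2] = 1                      # skewed polymorphism
    return make_matrix(calls, populations=["A"] * 10 + ["B"] * 10)


@pytest.fixture
def random_complete_matrix() -> HaplotypeMatrix:
    rng = np.random.default_rng(11)
    calls = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
    pops = ["P"] * 6 + ["Q"] * 6
    return make_matrix(calls, populations=pops)
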