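"""Shared fixtures. The full-scale benchmark run is expensive (about a
minute), so one session-scoped run is shared by every test that scores
FFAVES/ESFW output against ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import entropysort as es


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark plus a converged FFAVES run."""
    truth = es.generate_benchmark(es.SyntheticConfig(seed=1))
    mask, corrected, history = es.run_ffaves(truth.corrupted_discrete)
    return truth, mask, corrected, history


@pytest.fixture(scope="session")
def benchmark_scores(benchmark):
    truth, mask, _, _ = benchmark
    return es.score_mask(mask, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_discrete(rng, n_cells: int, n_genes: int, p: float = 0.3) -> es.DiscreteStateMatrix:
    states = (rng.uniform(size=(n_cells, n_genes)) < p).astype(np.int8)
    return es.DiscreteStateMatrix(
        states,
        [f"c{i}" for i in range(n_cells)],
        [f"g{j}" for j in range(n_genes)],
    )
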