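"""Shared fixtures and random-instance helpers."""

from __future__ import annotations

import numpy as np
import pytest

from dtipair import InteractionNetwork, SimilarityMatrix


def random_network(rng: np.random.Generator, D: int, T: int, p: float = 0.4) -> InteractionNetwork:
    A = (rng.random((D, T)) < p).astype(np.int64)
    drugs = [f"d{i}" for i in range(D)]
    targets = [f"t{j}" for j in range(T)]
    return InteractionNetwork(drugs, targets, A)


def random_similarity(rng: np.random.Generator, ids: list[str]) -> SimilarityMatrix:
    n = len(ids)
    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids, S)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_network() -> InteractionNetwork:
    # d0 hits t0,t1; d1 hits t1,t2; d2 hits t3 only (t3 single with d2)
    A = np.array(
        [
            [1, 1, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 0, 1],
        ]
    )
    return InteractionNetwork(["d0", "d1", "d2"], ["t0", "t1", "t2", "t3"], A)
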