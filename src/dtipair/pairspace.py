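"""PCA pair space: confidence scoring and candidate ranking.

PCA is fitted on the feature vectors of all pairs (known and unapproved)
with mean-centering and no variance scaling: the four scores share the
[0, 1] scale, so covariance PCA is appropriate.  A pair's confidence
score is the Euclidean norm of its projection onto the retained
components, i.e. its distance to the origin of the principal-component
space (the centered mean of the cloud).  Unapproved pairs dominate the
cloud and gather near this origin; known interactions sit far from it,
so distance ranks candidate interactions.

With all four components retained the score reduces analytically to the
Euclidean distance between the raw feature vector and the training mean,
which serves as the primary correctness oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .features import FeatureTable
from .netio import InteractionNetwork

__all__ = [
    "PairSpace",
    "RankedPrediction",
    "fit_pair_space",
    "confidence_scores",
    "rank_candidates",
    "export_coordinates",
]


@dataclass
class PairSpace:
    """A fitted PCA model over 4-score feature vectors."""

    center: np.ndarray  # (4,)
    components: np.ndarray  # (k, 4), orthonormal rows
    explained_variance: np.ndarray  # (k,), nonincreasing
    k: int


@dataclass(frozen=True)
class RankedPrediction:
    drug_id: str
    target_id: str
    score: float
    rank: int


def _scores_matrix(features) -> np.ndarray:
    if isinstance(features, FeatureTable):
        return features.scores
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.asarray([f.scores for f in features], dtype=float)


def fit_pair_space(features, k: int = 4) -> PairSpace:
    """Covariance PCA on the feature vectors, retaining ``k`` components.

    Component signs are fixed deterministically: the first loading of
    nonnegligible magnitude in each component is made positive.
    """
    X = _scores_matrix(features)
    n = X.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 feature vectors to fit a pair space")
    if not 1 <= k <= X.shape[1]:
        raise ValidationError(f"k must be in 1..{X.shape[1]}, got {k}")
    center = X.mean(axis=0)
    Xc = X - center
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:k]
    variance = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T
    for row in components:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return PairSpace(center=center, components=components,
                     explained_variance=variance, k=k)


def confidence_scores(space: PairSpace, features) -> np.ndarray:
    """Distance of each pair to the pair-space origin (one per feature)."""
    X = _scores_matrix(features)
    proj = (X - space.center) @ space.components.T
    return np.linalg.norm(proj, axis=1)


def transform(space: PairSpace, features) -> np.ndarray:
    """Principal-component coordinates, (n, k)."""
    X = _scores_matrix(features)
    return (X - space.center) @ space.components.T


def rank_candidates(
    net: InteractionNetwork, scores: np.ndarray, top_k: int | None = None
) -> list[RankedPrediction]:
    """Rank unapproved pairs by descending confidence score.

    ``scores`` holds one score per pair in row-major (drug, target) order.
    Ties break lexicographically on (drug_id, target_id).
    """
    scores = np.asarray(scores, dtype=float)
    D, T = net.n_drugs, net.n_targets
    if scores.shape != (D * T,):
        raise ValidationError(f"expected {D * T} scores, got {scores.shape}")
    rows = [
        (-scores[y * T + x], net.drug_ids[y], net.target_ids[x])
        for y, x in np.argwhere(net.A == 0)
    ]
    rows.sort()
    if top_k is not None:
        rows = rows[:top_k]
    return [
        RankedPrediction(drug_id=d, target_id=t, score=-neg, rank=r)
        for r, (neg, d, t) in enumerate(rows, start=1)
    ]


def export_coordinates(space: PairSpace, features) -> pd.DataFrame:
    """PC coordinates plus confidence score per pair, for external plotting."""
    coords = transform(space, features)
    scores = np.linalg.norm(coords, axis=1)
    frame = pd.DataFrame(
        {
            "drug_id": [f.drug_id for f in features],
            "target_id": [f.target_id for f in features],
            "is_known": [int(f.is_known) for f in features],
            "motif": [f.motif.value if f.motif is not None else "" for f in features],
        }
    )
    for j in range(space.k):
        frame[f"PC{j + 1}"] = coords[:, j]
    frame["score"] = scores
    return frame
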