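"""Topological similarity and similarity combination rules.

The matching index (MI) between two drugs counts both the targets they
share and the targets interacting with neither, normalised by the total
number of targets::

    MI(d_i, d_j) = (T - |d_i| - |d_j| + 2 |d_i ∩ d_j|) / T

(symmetrically for targets with denominator D).  Unlike interaction-profile
kernels whose values stay strictly positive, MI covers the full range
[0, 1]: two drugs with complementary neighbourhoods spanning every target
score exactly 0.

Because topological similarity is most informative around low-degree nodes
while chemical/sequence similarity wins around hubs, the combined
similarity is chosen adaptively per anchoring node: given the degree ``g``
of the node whose neighbourhood is being scored and thresholds

    u = 0.5 * max(degrees),   l = mean(degrees)

the rule selects the primary (chemical/sequence) matrix when ``g >= u``,
the elementwise maximum of both when ``l < g < u``, and the topological
matrix when ``g <= l``; branches are tested in that order, first match
wins.  A linearly weighted combination is provided as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .netio import InteractionNetwork, SimilarityMatrix

__all__ = [
    "DegreeThresholds",
    "mi_similarity",
    "degree_thresholds",
    "adaptive_similarity",
    "linear_combination",
]


@dataclass(frozen=True)
class DegreeThresholds:
    """Degree gates of the adaptive combination rule.

    ``u`` is half the maximum degree and ``l`` the mean degree over all
    anchoring nodes (zero-degree nodes included).
    """

    u: float
    l: float
    degrees: tuple[int, ...]

    @classmethod
    def from_degrees(cls, degrees) -> "DegreeThresholds":
        degs = tuple(int(d) for d in degrees)
        if not degs:
            raise ValidationError("cannot derive thresholds from an empty node set")
        if any(d < 0 for d in degs):
            raise ValidationError("degrees must be nonnegative")
        return cls(u=0.5 * max(degs), l=float(np.mean(degs)), degrees=degs)


def mi_similarity(net: InteractionNetwork, side: str = "drugs") -> SimilarityMatrix:
    """Matching-index similarity between drugs or between targets."""
    A = net.A
    if side == "drugs":
        n_opp = net.n_targets
        co = A @ A.T
        deg = net.drug_degrees
        ids = net.drug_ids
    elif side == "targets":
        n_opp = net.n_drugs
        co = A.T @ A
        deg = net.target_degrees
        ids = net.target_ids
    else:
        raise ValidationError(f"unknown side {side!r}")
    S = (n_opp - deg[:, None] - deg[None, :] + 2 * co) / float(n_opp)
    # diagonal is (n_opp - 2k + 2k)/n_opp = 1 analytically; enforce exactly
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids, S)


def degree_thresholds(net: InteractionNetwork, anchor_side: str = "targets") -> DegreeThresholds:
    """Thresholds (u, l) over the degrees of the anchoring node set.

    ``anchor_side="targets"`` gates drug-drug similarity selection (the
    anchor is a target whose drug neighbourhood is being scored), and
    vice versa.
    """
    if anchor_side == "targets":
        return DegreeThresholds.from_degrees(net.target_degrees)
    if anchor_side == "drugs":
        return DegreeThresholds.from_degrees(net.drug_degrees)
    raise ValidationError(f"unknown anchor_side {anchor_side!r}")


def select_branch(anchor_degree: int, thr: DegreeThresholds) -> str:
    """Which branch of the adaptive rule applies for this anchor degree.

    Branches are evaluated in the fixed order primary / max / topo so that
    overlapping boundary cases (e.g. g = u = l) resolve deterministically.
    """
    if anchor_degree < 0:
        raise ValidationError("anchor degree must be nonnegative")
    if anchor_degree >= thr.u:
        return "primary"
    if thr.l < anchor_degree < thr.u:
        return "max"
    return "topo"


def _check_same_ids(primary: SimilarityMatrix, topo: SimilarityMatrix) -> None:
    if primary.ids != topo.ids:
        raise ValidationError("primary and topological similarity id orders differ")


def adaptive_similarity(
    primary: SimilarityMatrix,
    topo: SimilarityMatrix,
    anchor_degree: int,
    thr: DegreeThresholds,
) -> SimilarityMatrix:
    """Degree-gated combination of a primary and a topological similarity."""
    _check_same_ids(primary, topo)
    branch = select_branch(anchor_degree, thr)
    if branch == "primary":
        return primary
    if branch == "topo":
        return topo
    return SimilarityMatrix(primary.ids, np.maximum(primary.S, topo.S))


def linear_combination(
    primary: SimilarityMatrix, topo: SimilarityMatrix, alpha: float
) -> SimilarityMatrix:
    """alpha * primary + (1 - alpha) * topo, alpha in [0, 1]."""
    _check_same_ids(primary, topo)
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must lie in [0, 1], got {alpha}")
    return SimilarityMatrix(primary.ids, alpha * primary.S + (1.0 - alpha) * topo.S)
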