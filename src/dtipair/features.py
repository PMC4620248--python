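"""Per-pair feature vectors of within-scores and between-scores.

Every drug-target pair (d_y, t_x) is described by four similarity maxima:

* ``C_t^w`` — max similarity between t_x and the targets interacting with
  d_y (target-view within-score);
* ``C_t^b`` — max similarity between t_x and the targets NOT interacting
  with d_y (target-view between-score);
* ``C_d^w`` / ``C_d^b`` — the drug-view mirror images anchored on t_x.

For a known interaction the pair itself is removed from the interacting
sets before the maxima are taken (otherwise every known pair would score
C^w = 1 trivially), and the queried node is never compared with itself in
the between-score complement.  An empty set yields a null score, recorded
in the null mask and then filled with 1.0.

Known interactions fall into four local-topology motifs depending on the
pair's degrees (counted including the pair): ``multiple`` (both > 1),
``drug_centered`` (target degree 1), ``target_centered`` (drug degree 1)
and ``single`` (both 1).  The motif determines which within-scores are
null: drug-centered pairs lack C_d^w, target-centered pairs lack C_t^w,
single pairs lack both.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .netio import InteractionNetwork, SimilarityMatrix
from .similarity import (
    adaptive_similarity,
    degree_thresholds,
    linear_combination,
    mi_similarity,
    select_branch,
)

__all__ = [
    "Motif",
    "PairFeature",
    "FeatureTable",
    "classify_motif",
    "target_view_scores",
    "drug_view_scores",
    "pair_feature",
    "feature_matrix",
    "score_histograms",
    "SCORE_NAMES",
    "HISTOGRAM_EDGES",
]

SCORE_NAMES = ("ctw", "ctb", "cdw", "cdb")

#: histogram bin edges: 38 bins of width 0.02 starting at 0.35
HISTOGRAM_EDGES = np.round(0.35 + 0.02 * np.arange(39), 10)


class Motif(str, enum.Enum):
    MULTIPLE = "multiple"
    DRUG_CENTERED = "drug_centered"
    TARGET_CENTERED = "target_centered"
    SINGLE = "single"


@dataclass
class PairFeature:
    """One drug-target pair's motif and four-score feature vector."""

    drug_id: str
    target_id: str
    is_known: bool
    motif: Motif | None
    scores: np.ndarray  # (ctw, ctb, cdw, cdb), nulls already filled with 1.0
    null_mask: np.ndarray  # True where the score was null before filling


def classify_motif(net: InteractionNetwork, drug_index: int, target_index: int) -> Motif:
    """Motif of a known interaction; degrees include the pair itself."""
    if net.A[drug_index, target_index] != 1:
        raise ValidationError("motifs are defined for known interactions only")
    deg_d = int(net.A[drug_index].sum())
    deg_t = int(net.A[:, target_index].sum())
    if deg_d > 1 and deg_t > 1:
        return Motif.MULTIPLE
    if deg_d > 1:  # deg_t == 1
        return Motif.DRUG_CENTERED
    if deg_t > 1:  # deg_d == 1
        return Motif.TARGET_CENTERED
    return Motif.SINGLE


def _as_array(sim) -> np.ndarray:
    return sim.S if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)


def target_view_scores(
    net: InteractionNetwork,
    St,
    target_index: int,
    drug_index: int,
    exclude_pair: bool = False,
) -> tuple[float | None, float | None]:
    """(C_t^w, C_t^b) for target t_x against anchor drug d_i.

    With ``exclude_pair`` the queried target is removed from the
    interacting set; it is always absent from the complement set.  An empty
    set yields ``None``.
    """
    S = _as_array(St)
    row = net.A[drug_index]
    inter = np.flatnonzero(row == 1)
    if exclude_pair:
        inter = inter[inter != target_index]
    comp = np.flatnonzero(row == 0)
    comp = comp[comp != target_index]
    ctw = float(S[target_index, inter].max()) if inter.size else None
    ctb = float(S[target_index, comp].max()) if comp.size else None
    return ctw, ctb


def drug_view_scores(
    net: InteractionNetwork,
    Sd,
    drug_index: int,
    target_index: int,
    exclude_pair: bool = False,
) -> tuple[float | None, float | None]:
    """(C_d^w, C_d^b) for drug d_y against anchor target t_j; mirrors
    :func:`target_view_scores` with the two node sets swapped."""
    S = _as_array(Sd)
    col = net.A[:, target_index]
    inter = np.flatnonzero(col == 1)
    if exclude_pair:
        inter = inter[inter != drug_index]
    comp = np.flatnonzero(col == 0)
    comp = comp[comp != drug_index]
    cdw = float(S[drug_index, inter].max()) if inter.size else None
    cdb = float(S[drug_index, comp].max()) if comp.size else None
    return cdw, cdb


def _normalize_combiner(combiner: str, alpha: float | None) -> tuple[str, float | None]:
    if combiner == "linear":
        if alpha is None or not 0.0 <= alpha <= 1.0:
            raise ValidationError("combiner 'linear' needs alpha in [0, 1]")
        return combiner, float(alpha)
    if combiner in ("adaptive", "primary", "topo"):
        return combiner, None
    raise ValidationError(f"unknown combiner {combiner!r}")


def pair_feature(
    net: InteractionNetwork,
    Sd_primary: SimilarityMatrix,
    St_primary: SimilarityMatrix,
    drug_index: int,
    target_index: int,
    combiner: str = "adaptive",
    alpha: float | None = None,
    Sd_topo: SimilarityMatrix | None = None,
    St_topo: SimilarityMatrix | None = None,
) -> PairFeature:
    """Feature vector of a single pair.

    Under the adaptive combiner the drug-drug similarity is gated by the
    degree of anchor target t_x against target-degree thresholds, and the
    target-target similarity by the degree of anchor drug d_y against
    drug-degree thresholds; both view's within- and between-scores use the
    same selected matrix.
    """
    combiner, alpha = _normalize_combiner(combiner, alpha)
    y, x = drug_index, target_index
    known = bool(net.A[y, x] == 1)

    if combiner != "primary":
        if Sd_topo is None:
            Sd_topo = mi_similarity(net, "drugs")
        if St_topo is None:
            St_topo = mi_similarity(net, "targets")

    if combiner == "adaptive":
        thr_t = degree_thresholds(net, "targets")
        thr_d = degree_thresholds(net, "drugs")
        Sd_use = adaptive_similarity(Sd_primary, Sd_topo, int(net.A[:, x].sum()), thr_t)
        St_use = adaptive_similarity(St_primary, St_topo, int(net.A[y].sum()), thr_d)
    elif combiner == "linear":
        Sd_use = linear_combination(Sd_primary, Sd_topo, alpha)
        St_use = linear_combination(St_primary, St_topo, alpha)
    elif combiner == "topo":
        Sd_use, St_use = Sd_topo, St_topo
    else:
        Sd_use, St_use = Sd_primary, St_primary

    ctw, ctb = target_view_scores(net, St_use, x, y, exclude_pair=known)
    cdw, cdb = drug_view_scores(net, Sd_use, y, x, exclude_pair=known)
    raw = (ctw, ctb, cdw, cdb)
    null_mask = np.array([v is None for v in raw])
    scores = np.array([1.0 if v is None else v for v in raw])
    motif = classify_motif(net, y, x) if known else None
    return PairFeature(
        drug_id=net.drug_ids[y],
        target_id=net.target_ids[x],
        is_known=known,
        motif=motif,
        scores=scores,
        null_mask=null_mask,
    )


class FeatureTable(Sequence):
    """Feature vectors for all D x T pairs, row-major over drugs then targets.

    Behaves as a sequence of :class:`PairFeature` while storing the scores
    as dense arrays for downstream PCA.
    """

    def __init__(self, net: InteractionNetwork, scores, null_mask, motifs) -> None:
        self.drug_ids = net.drug_ids
        self.target_ids = net.target_ids
        self.is_known = (net.A.reshape(-1) == 1)
        self.scores = np.asarray(scores, dtype=float)
        self.null_mask = np.asarray(null_mask, dtype=bool)
        self.motifs = list(motifs)
        self._T = net.n_targets

    def __len__(self) -> int:
        return self.scores.shape[0]

    def __getitem__(self, index):
        if isinstance(index, slice):
            return [self[i] for i in range(*index.indices(len(self)))]
        y, x = divmod(index, self._T)
        return PairFeature(
            drug_id=self.drug_ids[y],
            target_id=self.target_ids[x],
            is_known=bool(self.is_known[index]),
            motif=self.motifs[index],
            scores=self.scores[index],
            null_mask=self.null_mask[index],
        )

    def pair_index(self, drug_index: int, target_index: int) -> int:
        return drug_index * self._T + target_index

    def to_frame(self) -> pd.DataFrame:
        """Flat table: ids, known flag, motif, the four scores, null mask."""
        y, x = np.divmod(np.arange(len(self)), self._T)
        frame = pd.DataFrame(
            {
                "drug_id": np.asarray(self.drug_ids, dtype=object)[y],
                "target_id": np.asarray(self.target_ids, dtype=object)[x],
                "is_known": self.is_known.astype(int),
                "motif": [m.value if m is not None else "" for m in self.motifs],
            }
        )
        for i, name in enumerate(SCORE_NAMES):
            frame[name] = self.scores[:, i]
        frame["null_mask"] = ["".join("1" if f else "0" for f in m) for m in self.null_mask]
        return frame


def _variant_matrices(primary: np.ndarray, topo: np.ndarray | None,
                      combiner: str, alpha: float | None) -> dict[str, np.ndarray]:
    """Branch-name -> similarity matrix with the diagonal set to -1.

    The poisoned diagonal implements self-exclusion inside vectorised
    column maxima: a max that comes out negative means the effective set
    was empty (a null score).
    """

    def poisoned(M: np.ndarray) -> np.ndarray:
        M = M.copy()
        np.fill_diagonal(M, -1.0)
        return M

    if combiner == "adaptive":
        return {
            "primary": poisoned(primary),
            "max": poisoned(np.maximum(primary, topo)),
            "topo": poisoned(topo),
        }
    if combiner == "linear":
        return {"only": poisoned(alpha * primary + (1.0 - alpha) * topo)}
    if combiner == "topo":
        return {"only": poisoned(topo)}
    return {"only": poisoned(primary)}


def feature_matrix(
    net: InteractionNetwork,
    Sd_primary: SimilarityMatrix,
    St_primary: SimilarityMatrix,
    combiner: str = "adaptive",
    alpha: float | None = None,
    Sd_topo: SimilarityMatrix | None = None,
    St_topo: SimilarityMatrix | None = None,
) -> FeatureTable:
    """Feature vectors for every pair, vectorised over rows and columns.

    Equivalent to calling :func:`pair_feature` on each of the D x T pairs
    (with exclude_pair set exactly for known interactions) but roughly two
    orders of magnitude faster, which matters inside leave-one-out folds.
    """
    combiner, alpha = _normalize_combiner(combiner, alpha)
    if Sd_primary.ids != net.drug_ids or St_primary.ids != net.target_ids:
        raise ValidationError("similarity matrices are not aligned to the network; "
                              "call netio.align_inputs first")
    D, T = net.n_drugs, net.n_targets
    A = net.A
    dd = net.drug_degrees
    td = net.target_degrees

    topo_d = topo_t = None
    if combiner != "primary":
        topo_d = (Sd_topo or mi_similarity(net, "drugs")).S
        topo_t = (St_topo or mi_similarity(net, "targets")).S
    drug_mats = _variant_matrices(Sd_primary.S, topo_d, combiner, alpha)
    targ_mats = _variant_matrices(St_primary.S, topo_t, combiner, alpha)
    if combiner == "adaptive":
        thr_t = degree_thresholds(net, "targets")  # gates drug-side matrices
        thr_d = degree_thresholds(net, "drugs")  # gates target-side matrices

    scores = np.empty((D * T, 4))
    null_mask = np.zeros((D * T, 4), dtype=bool)

    # target-view scores, one drug row at a time
    for y in range(D):
        St_use = (
            targ_mats[select_branch(int(dd[y]), thr_d)]
            if combiner == "adaptive"
            else targ_mats["only"]
        )
        inter = np.flatnonzero(A[y] == 1)
        comp = np.flatnonzero(A[y] == 0)
        rows = slice(y * T, (y + 1) * T)
        for cols, k in ((inter, 0), (comp, 1)):
            if cols.size:
                col = St_use[:, cols].max(axis=1)
                null = col < 0.0
            else:
                col = np.empty(T)
                null = np.ones(T, dtype=bool)
            col[null] = 1.0
            scores[rows, k] = col
            null_mask[rows, k] = null

    # drug-view scores, one target column at a time
    for x in range(T):
        Sd_use = (
            drug_mats[select_branch(int(td[x]), thr_t)]
            if combiner == "adaptive"
            else drug_mats["only"]
        )
        inter = np.flatnonzero(A[:, x] == 1)
        comp = np.flatnonzero(A[:, x] == 0)
        rows = x + T * np.arange(D)
        for cols, k in ((inter, 2), (comp, 3)):
            if cols.size:
                col = Sd_use[:, cols].max(axis=1)
                null = col < 0.0
            else:
                col = np.empty(D)
                null = np.ones(D, dtype=bool)
            col[null] = 1.0
            scores[rows, k] = col
            null_mask[rows, k] = null

    # motif labels for known pairs
    motifs: list[Motif | None] = [None] * (D * T)
    for y, x in np.argwhere(A == 1):
        if dd[y] > 1 and td[x] > 1:
            m = Motif.MULTIPLE
        elif dd[y] > 1:
            m = Motif.DRUG_CENTERED
        elif td[x] > 1:
            m = Motif.TARGET_CENTERED
        else:
            m = Motif.SINGLE
        motifs[y * T + x] = m

    return FeatureTable(net, scores, null_mask, motifs)


def score_histograms(features, score_index: int) -> pd.DataFrame:
    """Normalised per-group histograms of one of the four scores.

    Groups are the four motifs of known interactions plus the unapproved
    pairs.  Bins run from 0.35 to 1.1 in steps of 0.02 (38 bins); values
    below/above the range clamp into the first/last bin.  Scores that were
    null before filling are not counted.  Heights of a non-empty group sum
    to 1; ``group_total`` is 0 for an empty group.
    """
    if score_index not in (1, 2, 3, 4):
        raise ValidationError("score_index must be in 1..4")
    k = score_index - 1
    groups: dict[str, list[float]] = {m.value: [] for m in Motif}
    groups["unapproved"] = []
    for f in features:
        if f.null_mask[k]:
            continue
        key = f.motif.value if f.is_known else "unapproved"
        groups[key].append(float(f.scores[k]))
    records = []
    edges = HISTOGRAM_EDGES
    nbins = len(edges) - 1
    for name, values in groups.items():
        counts = np.zeros(nbins)
        for v in values:
            idx = int(np.clip((v - edges[0]) // 0.02, 0, nbins - 1))
            counts[idx] += 1
        total = counts.sum()
        heights = counts / total if total else counts
        for b in range(nbins):
            records.append(
                {
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "group": name,
                    "height": heights[b],
                    "group_total": int(total),
                }
            )
    return pd.DataFrame.from_records(records)
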