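"""Input/output for interaction networks, similarity matrices and predictions.

All tabular files are plain TSV (UTF-8, tab-separated, ``.`` decimal
separator, no quoting).  Matrix files carry identifiers in the header row
and the first column; the top-left header cell is ignored on read and
written as ``id``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: entries of a similarity matrix may stray this far outside [0, 1] / off
#: the unit diagonal before we refuse the file
VALUE_TOL = 1e-9
#: largest asymmetry repaired by averaging S and S.T; larger is an error
SYMMETRY_CEILING = 1e-6


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class InteractionNetwork:
    """A binary drug-target interaction network.

    ``A`` is the D x T adjacency matrix with ``A[i, j] = 1`` when drug
    ``drug_ids[i]`` is known to interact with target ``target_ids[j]``.
    """

    drug_ids: list[str]
    target_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(i) for i in self.drug_ids]
        self.target_ids = [str(i) for i in self.target_ids]
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.target_ids, "target")
        A = np.asarray(self.A)
        if A.ndim != 2:
            raise ValidationError("interaction matrix must be 2-dimensional")
        if A.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValidationError(
                f"matrix shape {A.shape} does not match identifier counts "
                f"({len(self.drug_ids)} drugs, {len(self.target_ids)} targets)"
            )
        if A.shape[0] < 1 or A.shape[1] < 1:
            raise ValidationError("network needs at least one drug and one target")
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("interaction matrix entries must be 0 or 1")
        self.A = A.astype(np.int64)
        self._drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self._target_index = {t: j for j, t in enumerate(self.target_ids)}

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def drug_degrees(self) -> np.ndarray:
        """Number of targets per drug (row sums of A)."""
        return self.A.sum(axis=1)

    @property
    def target_degrees(self) -> np.ndarray:
        """Number of drugs per target (column sums of A)."""
        return self.A.sum(axis=0)

    def drug_index(self, drug_id: str) -> int:
        return self._drug_index[drug_id]

    def target_index(self, target_id: str) -> int:
        return self._target_index[target_id]

    def known_pairs(self) -> np.ndarray:
        """(n, 2) array of (drug_index, target_index) for every interaction."""
        return np.argwhere(self.A == 1)

    def without_interaction(self, drug_index: int, target_index: int) -> "InteractionNetwork":
        """Copy of the network with one known interaction removed."""
        if self.A[drug_index, target_index] != 1:
            raise ValidationError(
                f"({self.drug_ids[drug_index]}, {self.target_ids[target_index]}) "
                "is not a known interaction"
            )
        A = self.A.copy()
        A[drug_index, target_index] = 0
        return InteractionNetwork(self.drug_ids, self.target_ids, A)


@dataclass
class SimilarityMatrix:
    """A square symmetric similarity matrix over one node set.

    Entries lie in [0, 1] and the diagonal equals 1 (within 1e-9).
    """

    ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        _check_unique(self.ids, "similarity")
        S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if S.shape != (n, n):
            raise ValidationError(f"similarity matrix shape {S.shape} != ({n}, {n})")
        asym = float(np.abs(S - S.T).max()) if n else 0.0
        if asym > VALUE_TOL:
            raise ValidationError(f"similarity matrix asymmetric (max |S - S.T| = {asym:g})")
        if S.min() < -VALUE_TOL or S.max() > 1 + VALUE_TOL:
            raise ValidationError(
                f"similarity entries outside [0, 1]: min {S.min():g}, max {S.max():g}"
            )
        diag_err = float(np.abs(np.diag(S) - 1.0).max())
        if diag_err > VALUE_TOL:
            raise ValidationError(f"similarity diagonal deviates from 1 by {diag_err:g}")
        self.S = np.clip(S, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/reorder to ``ids``; every requested id must be present."""
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise ValidationError(f"ids missing from similarity matrix: {missing}")
        idx = np.array([self._index[i] for i in ids], dtype=int)
        return SimilarityMatrix(list(ids), self.S[np.ix_(idx, idx)])


def _read_rows(path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8") as fh:
        rows = [line.rstrip("\r\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def read_interaction_matrix(path, orientation: str = "drugs_as_rows") -> InteractionNetwork:
    """Read a binary adjacency TSV.

    ``orientation`` says which axis the file's rows represent; the returned
    network always has drugs as rows.
    """
    if orientation not in ("drugs_as_rows", "targets_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    rows = _read_rows(path)
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError(f"{path}: need a header row plus at least one data row")
    col_ids = rows[0][1:]
    width = len(rows[0])
    row_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(col_ids)), dtype=np.int64)
    for r, row in enumerate(rows[1:]):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {r + 2} has {len(row)} fields, expected {width}"
            )
        row_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            try:
                value = float(cell)
            except ValueError:
                value = math.nan
            if value not in (0.0, 1.0):
                raise FormatError(
                    f"{path}: cell (row {row[0]!r}, column {col_ids[c]!r}) "
                    f"is {cell!r}, expected 0 or 1"
                )
            data[r, c] = int(value)
    if orientation == "targets_as_rows":
        return InteractionNetwork(col_ids, row_ids, data.T)
    return InteractionNetwork(row_ids, col_ids, data)


def read_pair_list(
    path,
    drug_universe: Sequence[str] | None = None,
    target_universe: Sequence[str] | None = None,
) -> InteractionNetwork:
    """Read a two-column (drug_id, target_id) interaction list.

    When universes are not supplied, the distinct ids in the file are used,
    sorted lexicographically so downstream results are deterministic.
    """
    rows = _read_rows(path)
    pairs: set[tuple[str, str]] = set()
    for r, row in enumerate(rows):
        if len(row) != 2:
            raise FormatError(f"{path}: line {r + 1} has {len(row)} fields, expected 2")
        pairs.add((row[0], row[1]))
    drugs = list(drug_universe) if drug_universe is not None else sorted({d for d, _ in pairs})
    targets = (
        list(target_universe) if target_universe is not None else sorted({t for _, t in pairs})
    )
    dset, tset = set(drugs), set(targets)
    bad = [(d, t) for d, t in sorted(pairs) if d not in dset or t not in tset]
    if bad:
        raise ValidationError(f"pairs reference ids outside the supplied universe: {bad}")
    net = InteractionNetwork(drugs, targets, np.zeros((len(drugs), len(targets)), dtype=np.int64))
    for d, t in pairs:
        net.A[net.drug_index(d), net.target_index(t)] = 1
    return net


def read_similarity(path) -> SimilarityMatrix:
    """Read a square similarity TSV with matching header/index identifiers.

    Asymmetries up to 1e-6 are repaired by averaging S with its transpose;
    anything larger is rejected.
    """
    rows = _read_rows(path)
    ids = rows[0][1:]
    n = len(ids)
    if len(rows) - 1 != n:
        raise FormatError(f"{path}: matrix is not square ({len(rows) - 1} rows, {n} columns)")
    data = np.empty((n, n), dtype=float)
    for r, row in enumerate(rows[1:]):
        if len(row) != n + 1:
            raise FormatError(f"{path}: row {r + 2} has {len(row)} fields, expected {n + 1}")
        if row[0] != ids[r]:
            raise FormatError(
                f"{path}: row identifier {row[0]!r} != header identifier {ids[r]!r}"
            )
        try:
            data[r] = [float(c) for c in row[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {row[0]!r}: {exc}") from exc
    if data.min() < -VALUE_TOL or data.max() > 1 + VALUE_TOL:
        bad = np.unravel_index(np.argmax(np.abs(data - 0.5)), data.shape)
        raise ValidationError(
            f"{path}: entry ({ids[bad[0]]}, {ids[bad[1]]}) = {data[bad]:g} outside [0, 1]"
        )
    asym = float(np.abs(data - data.T).max())
    if asym > SYMMETRY_CEILING:
        raise ValidationError(f"{path}: asymmetry {asym:g} exceeds {SYMMETRY_CEILING:g}")
    data = (data + data.T) / 2.0
    return SimilarityMatrix(ids, data)


def write_interaction_matrix(net: InteractionNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(net.target_ids) + "\n")
        for i, drug in enumerate(net.drug_ids):
            fh.write(drug + "\t" + "\t".join(str(int(v)) for v in net.A[i]) + "\n")


def write_similarity(sim: SimilarityMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, node in enumerate(sim.ids):
            fh.write(node + "\t" + "\t".join(f"{v:.10g}" for v in sim.S[i]) + "\n")


def align_inputs(
    net: InteractionNetwork, Sd: SimilarityMatrix, St: SimilarityMatrix
) -> tuple[InteractionNetwork, SimilarityMatrix, SimilarityMatrix]:
    """Reorder both similarity matrices to the network's identifier order.

    Network ids missing from a similarity matrix are an error; similarity
    ids absent from the network are dropped with a warning.
    """
    for ids, sim, what in ((net.drug_ids, Sd, "drug"), (net.target_ids, St, "target")):
        missing = [i for i in ids if i not in sim._index]
        if missing:
            raise ValidationError(f"network {what} ids missing from similarity matrix: {missing}")
        extra = sorted(set(sim.ids) - set(ids))
        if extra:
            logger.warning("dropping %d %s similarity ids absent from the network: %s",
                           len(extra), what, extra)
    return net, Sd.reorder(net.drug_ids), St.reorder(net.target_ids)


def write_predictions(ranked: Iterable, path) -> None:
    """Write ranked candidate pairs as TSV (rank, drug_id, target_id, score)."""
    rows = []
    for item in ranked:
        if hasattr(item, "drug_id"):
            rows.append((item.rank, item.drug_id, item.target_id, item.score))
        else:
            drug_id, target_id, score, rank = item
            rows.append((rank, drug_id, target_id, score))
    for rank, _, _, score in rows:
        if not math.isfinite(score):
            raise ValidationError(f"non-finite score at rank {rank}")
    rows.sort(key=lambda r: r[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdrug_id\ttarget_id\tscore\n")
        for rank, drug_id, target_id, score in rows:
            fh.write(f"{rank}\t{drug_id}\t{target_id}\t{score:.6f}\n")


def read_predictions(path) -> list[tuple[str, str, float, int]]:
    """Read back a predictions TSV as (drug_id, target_id, score, rank) tuples."""
    rows = _read_rows(path)
    if rows[0] != ["rank", "drug_id", "target_id", "score"]:
        raise FormatError(f"{path}: unexpected header {rows[0]}")
    out = []
    for row in rows[1:]:
        if len(row) != 4:
            raise FormatError(f"{path}: malformed prediction row {row}")
        out.append((row[1], row[2], float(row[3]), int(row[0])))
    return out
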