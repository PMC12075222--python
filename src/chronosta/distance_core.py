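"""Partial divergence-time matrices, the consensus supermatrix, pair
selection, the weighted cluster-distance update and backpropagation.

Each input timetree contributes one :class:`PartialTimeMatrix` of pairwise
MRCA ages.  The :class:`Supermatrix` averages matching cells across all
partial matrices over the union of their labels; cells for pairs never seen
together in any tree are missing.  Missing values are represented by NaN and
every reduction skips them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PartialTimeMatrix",
    "Supermatrix",
    "ClusterRecord",
    "DisconnectedCollectionError",
    "consensus_supermatrix",
    "find_min_pair",
    "weighted_cluster_distance",
    "backpropagate_cluster",
]

MISSING = np.nan  # reserved missing-value marker; no valid age is NaN


class DisconnectedCollectionError(ValueError):
    """The collection splits into groups with no shared divergence times."""

    def __init__(self, components: Sequence[FrozenSet[str]]):
        self.components = [frozenset(c) for c in components]
        listing = "; ".join(
            "{" + ", ".join(sorted(c)[:8]) + (", ..." if len(c) > 8 else "") + "}"
            for c in self.components
        )
        super().__init__(
            f"collection is disconnected into {len(self.components)} groups with "
            f"no linking divergence times: {listing}. Consider adding shared "
            f"outgroup taxa with known ages to every input tree."
        )


def _check_square(labels: Sequence[str], D: np.ndarray) -> None:
    n = len(labels)
    if len(set(labels)) != n:
        raise ValueError("duplicate labels in matrix")
    if D.shape != (n, n):
        raise ValueError(f"matrix shape {D.shape} does not match {n} labels")


@dataclass
class PartialTimeMatrix:
    """Symmetric divergence-time matrix from one source tree.

    ``labels`` are cluster ids (initially leaf names); ``D`` holds ages with
    NaN marking missing cells; ``origin`` identifies the source tree.
    """

    labels: List[str]
    D: np.ndarray
    origin: Optional[str] = None

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        _check_square(self.labels, self.D)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index_of(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    def copy(self) -> "PartialTimeMatrix":
        return PartialTimeMatrix(list(self.labels), self.D.copy(), self.origin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str) -> None:
        """Debug dump; missing cells are left empty."""
        self.to_frame().to_csv(path, sep="\t", na_rep="")


@dataclass
class Supermatrix:
    """Cumulative averaged matrix over all partial matrices.

    Each present cell is the arithmetic mean of the matching present cells
    across partial matrices; ``support`` counts how many matrices
    contributed to each cell.
    """

    labels: List[str]
    D: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        _check_square(self.labels, self.D)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index_of(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> float:
        return float(self.D[self._index[a], self._index[b]])

    @property
    def n_missing_offdiag(self) -> int:
        n = len(self.labels)
        miss = np.isnan(self.D)
        return int((miss.sum() - np.diag(miss).sum()) // 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    def connected_components(self) -> List[FrozenSet[str]]:
        """Components of the label graph with edges where a cell is present."""
        n = len(self.labels)
        present = ~np.isnan(self.D)
        np.fill_diagonal(present, False)
        seen = np.zeros(n, dtype=bool)
        comps: List[FrozenSet[str]] = []
        for s in range(n):
            if seen[s]:
                continue
            stack = [s]
            comp = []
            seen[s] = True
            while stack:
                v = stack.pop()
                comp.append(self.labels[v])
                for u in np.nonzero(present[v])[0]:
                    if not seen[u]:
                        seen[u] = True
                        stack.append(int(u))
            comps.append(frozenset(comp))
        return comps


@dataclass(frozen=True)
class ClusterRecord:
    """One merge event: cluster id, member leaves, merge age, iteration."""

    cluster_id: str
    members: FrozenSet[str]
    merge_age: float
    iteration: int

    @property
    def n(self) -> int:
        return len(self.members)


def consensus_supermatrix(partials: Sequence[PartialTimeMatrix]) -> Supermatrix:
    """Average matching cells across partial matrices over the label union.

    A cell is present iff it is present in at least one partial matrix; its
    value is the mean over the partials where it is present, and ``support``
    records that count.
    """
    if not partials:
        raise ValueError("consensus_supermatrix requires at least one partial matrix")
    labels = sorted(set().union(*(p.labels for p in partials)))
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    total = np.zeros((n, n), dtype=float)
    count = np.zeros((n, n), dtype=int)
    for p in partials:
        rows = np.array([idx[lab] for lab in p.labels])
        present = ~np.isnan(p.D)
        sub = np.where(present, p.D, 0.0)
        total[np.ix_(rows, rows)] += sub
        count[np.ix_(rows, rows)] += present
    with np.errstate(invalid="ignore"):
        D = np.where(count > 0, total / np.maximum(count, 1), MISSING)
    np.fill_diagonal(D, 0.0)
    return Supermatrix(labels=labels, D=D, support=count)


def find_min_pair(
    S: Supermatrix,
    members: Optional[Mapping[str, FrozenSet[str]]] = None,
) -> Tuple[str, str, float]:
    """The off-diagonal present cell with the smallest divergence time.

    Ties are broken deterministically by the lexicographically smallest
    sorted list of member leaves of the candidate pair (falling back to the
    labels themselves when no membership map is given).
    """
    if len(S.labels) < 2:
        raise ValueError("need at least two labels to select a pair")
    D = S.D.copy()
    np.fill_diagonal(D, MISSING)
    if np.all(np.isnan(D)):
        raise DisconnectedCollectionError(S.connected_components())
    best = np.nanmin(D)
    ii, jj = np.nonzero(D <= best)  # NaN compares False
    candidates = []
    for i, j in zip(ii, jj):
        if i < j:
            a, b = S.labels[i], S.labels[j]
            if members is not None:
                key = tuple(sorted(members.get(a, frozenset([a])) | members.get(b, frozenset([b]))))
            else:
                key = tuple(sorted((a, b)))
            candidates.append((key, a, b, float(D[i, j])))
    candidates.sort()
    _, a, b, age = candidates[0]
    return a, b, age


def weighted_cluster_distance(
    D_ik: float, D_jk: float, n_i: int, n_j: int
) -> float:
    """Member-weighted mean distance from a new cluster (ij) to cluster k.

    D_(ij),k = n_i/(n_i+n_j) * D_ik + n_j/(n_i+n_j) * D_jk.  If only one of
    the two distances is known, that value is the only information available
    and is returned as-is; if neither is known the result is missing.
    """
    if n_i < 1 or n_j < 1:
        raise ValueError("cluster member counts must be positive")
    i_missing = D_ik is None or np.isnan(D_ik)
    j_missing = D_jk is None or np.isnan(D_jk)
    if i_missing and j_missing:
        return MISSING
    if i_missing:
        return float(D_jk)
    if j_missing:
        return float(D_ik)
    w = n_i / (n_i + n_j)
    return w * float(D_ik) + (1.0 - w) * float(D_jk)


def backpropagate_cluster(
    partials: Sequence[PartialTimeMatrix],
    rec: ClusterRecord,
    i: str,
    j: str,
    n_i: int,
    n_j: int,
) -> Tuple[List[PartialTimeMatrix], Dict[Optional[str], float]]:
    """Substitute the newly formed cluster into every partial matrix.

    In matrices containing both ``i`` and ``j`` the two rows/columns are
    replaced by one for the cluster, with entries from
    :func:`weighted_cluster_distance` using the clusters' *global* member
    counts ``n_i``, ``n_j`` (leaf counts, not per-matrix counts); matrices
    with exactly one of the pair have that row/column relabelled (entries
    unchanged); matrices with neither are untouched.

    Returns the updated matrices and a log of the within-matrix pairwise
    distance of (i, j) in each matrix that contained both (keyed by matrix
    origin) — retained for inspection, not used for the merge age.
    """
    if i == j:
        raise ValueError("cannot merge a cluster with itself")
    if n_i + n_j != rec.n:
        raise ValueError("record members inconsistent with n_i + n_j")
    stored: Dict[Optional[str], float] = {}
    out: List[PartialTimeMatrix] = []
    for p in partials:
        if rec.cluster_id in p:
            raise RuntimeError(
                f"cluster id {rec.cluster_id!r} already present in matrix "
                f"{p.origin!r}"
            )
        has_i, has_j = i in p, j in p
        if not has_i and not has_j:
            out.append(p)
            continue
        if has_i and has_j:
            ii, jj = p.index_of(i), p.index_of(j)
            pair_val = p.D[ii, jj]
            if not np.isnan(pair_val):
                stored[p.origin] = float(pair_val)
            keep = [k for k in range(len(p.labels)) if k not in (ii, jj)]
            new_row = np.array(
                [
                    weighted_cluster_distance(p.D[ii, k], p.D[jj, k], n_i, n_j)
                    for k in keep
                ]
            )
            labels = [p.labels[k] for k in keep] + [rec.cluster_id]
            m = len(labels)
            D = np.full((m, m), MISSING)
            D[: m - 1, : m - 1] = p.D[np.ix_(keep, keep)]
            D[m - 1, : m - 1] = new_row
            D[: m - 1, m - 1] = new_row
            D[m - 1, m - 1] = 0.0
            out.append(PartialTimeMatrix(labels, D, p.origin))
        else:
            old = i if has_i else j
            labels = [rec.cluster_id if lab == old else lab for lab in p.labels]
            out.append(PartialTimeMatrix(labels, p.D.copy(), p.origin))
    return out, stored
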