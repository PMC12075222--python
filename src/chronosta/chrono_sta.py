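"""Chronological supertree assembly (Chrono-STA).

The algorithm merges a collection of partially overlapping, time-scaled
phylogenies into one ultrametric supertree.  Each input tree is decomposed
into a pairwise divergence-time matrix; the matrices are averaged into a
consensus supermatrix over the union of taxa; the closest pair in the
supermatrix is clustered; and — the key step — the new cluster is
*backpropagated* into every per-tree matrix, replacing its members and
inheriting their distances as member-weighted means.  Because a cluster can
stand in for a member that a given tree never sampled, each round fills in
divergence times for taxon pairs that never co-occur in any input tree.
Rounds repeat until all taxa are clustered; the recorded merge ages define a
complete divergence-time matrix, from which the supertree is built by
average linkage (UPGMA, cluster heights in age units) and projected onto
the nearest ultrametric tree by constrained least squares.

Two entry points are provided: the functional :func:`run_chrono_sta`, and a
model/results pair (:class:`ChronoSTA` / :class:`ChronoSTAResults`) for
interactive use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .distance_core import (
    MISSING,
    ClusterRecord,
    DisconnectedCollectionError,
    Supermatrix,
    backpropagate_cluster,
    consensus_supermatrix,
    find_min_pair,
)
from .timetree_io import Timetree, node_age_matrix, write_newick

__all__ = [
    "ChronoStaResult",
    "run_chrono_sta",
    "complete_matrix_from_records",
    "average_linkage_tree",
    "smooth_to_ultrametric",
    "graft_outgroup",
    "ChronoSTA",
    "ChronoSTAResults",
]

# absolute age tolerance, as a fraction of the collection's maximum root age
RELATIVE_AGE_TOL = 1e-9


# --------------------------------------------------------------------------
# ultrametric smoothing
# --------------------------------------------------------------------------

def smooth_to_ultrametric(
    tree: Timetree,
    observed_ages: Optional[Mapping[int, float]] = None,
) -> Timetree:
    """Project observed node ages onto the nearest ultrametric assignment.

    Minimizes ``sum_v (a_v - observed_v)**2`` over internal-node ages subject
    to ``a_parent >= a_child`` on every edge and every tip fixed at age 0, so
    that all implied branch durations are non-negative.  The problem is a
    small convex quadratic program with a unique solution; feasible inputs
    are returned unchanged.
    """
    obs = dict(observed_ages) if observed_ages is not None else dict(tree.age)
    internal = [v for v in tree.postorder() if not tree.is_leaf(v)]
    if not internal:
        return tree.copy()
    scale = max(1.0, max(abs(obs.get(v, 0.0)) for v in internal))
    tol = RELATIVE_AGE_TOL * scale

    def feasible() -> bool:
        for v in internal:
            if obs.get(v, 0.0) < -tol:
                return False
            p = tree.parent[v]
            if p is not None and obs.get(p, 0.0) < obs.get(v, 0.0) - tol:
                return False
        return True

    out = tree.copy()
    if feasible():
        for v in internal:
            out.age[v] = max(0.0, float(obs.get(v, 0.0)))
        for v in out.label:
            out.age[v] = 0.0
        return out

    idx = {v: k for k, v in enumerate(internal)}
    y = np.array([obs.get(v, 0.0) for v in internal])
    rows: List[Tuple[int, int, float]] = []
    r = 0
    lower: List[float] = []
    for v in internal:
        p = tree.parent[v]
        if p is not None:
            rows.append((r, idx[p], 1.0))
            rows.append((r, idx[v], -1.0))
            lower.append(0.0)
            r += 1
    # tips at 0 imply every internal node age >= 0
    for v in internal:
        rows.append((r, idx[v], 1.0))
        lower.append(0.0)
        r += 1
    A = scipy.sparse.coo_matrix(
        ([w for _, _, w in rows], ([i for i, _, _ in rows], [j for _, j, _ in rows])),
        shape=(r, len(internal)),
    ).tocsr()
    constraint = scipy.optimize.LinearConstraint(A, np.array(lower), np.inf)

    def fun(a: np.ndarray) -> float:
        d = a - y
        return float(d @ d)

    def jac(a: np.ndarray) -> np.ndarray:
        return 2.0 * (a - y)

    hess = scipy.sparse.identity(len(internal)) * 2.0
    x0 = np.maximum.accumulate(np.maximum(y, 0.0))  # feasible start (postorder)
    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda a: hess,
        method="trust-constr",
        constraints=[constraint],
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 2000},
    )
    a = _polish_blocks(tree, internal, idx, y, res.x, tol=1e-4 * scale)
    # clip tiny constraint violations left by the solver
    for v in tree.postorder():
        if tree.is_leaf(v):
            out.age[v] = 0.0
        else:
            out.age[v] = max(0.0, float(a[idx[v]]))
            for c in tree.children[v]:
                if out.age[c] > out.age[v]:
                    out.age[v] = out.age[c]
    return out


def _polish_blocks(
    tree: Timetree,
    internal: Sequence[int],
    idx: Mapping[int, int],
    y: np.ndarray,
    x: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Exact KKT refinement of a near-optimal smoothing solution.

    Nodes joined by active order constraints must share one age equal to the
    mean of their observations (clamped at 0 when the non-negativity bound
    is active).  Pools such blocks exactly; falls back to the solver output
    if the pooled assignment is infeasible or worse.
    """
    parent_block: Dict[int, int] = {idx[v]: idx[v] for v in internal}

    def find(i: int) -> int:
        while parent_block[i] != i:
            parent_block[i] = parent_block[parent_block[i]]
            i = parent_block[i]
        return i

    for v in internal:
        p = tree.parent[v]
        if p is not None and abs(x[idx[p]] - x[idx[v]]) <= tol:
            parent_block[find(idx[p])] = find(idx[v])
    sums: Dict[int, float] = {}
    counts: Dict[int, int] = {}
    for v in internal:
        r = find(idx[v])
        sums[r] = sums.get(r, 0.0) + y[idx[v]]
        counts[r] = counts.get(r, 0) + 1
    polished = np.array(
        [max(0.0, sums[find(idx[v])] / counts[find(idx[v])]) for v in internal]
    )
    # accept only if feasible and no worse
    for v in internal:
        p = tree.parent[v]
        if polished[idx[v]] < -1e-12:
            return x
        if p is not None and polished[idx[p]] < polished[idx[v]] - 1e-12:
            return x
    if float((polished - y) @ (polished - y)) <= float((x - y) @ (x - y)) + tol:
        return polished
    return x


# --------------------------------------------------------------------------
# completed matrix and average-linkage tree
# --------------------------------------------------------------------------

def complete_matrix_from_records(
    records: Sequence[ClusterRecord], leaves: Iterable[str]
) -> Supermatrix:
    """Divergence-time matrix implied by a full merge sequence.

    Entry (x, y) is the merge age of the earliest record whose members
    contain both x and y; a full merge sequence leaves no missing cells.
    """
    labels = sorted(set(leaves))
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.full((n, n), MISSING)
    np.fill_diagonal(D, 0.0)
    for rec in records:
        mem = [idx[m] for m in rec.members if m in idx]
        for a, b in itertools.combinations(mem, 2):
            if np.isnan(D[a, b]):
                D[a, b] = rec.merge_age
                D[b, a] = rec.merge_age
    if np.isnan(D).any():
        ii, jj = np.nonzero(np.isnan(D))
        pair = (labels[ii[0]], labels[jj[0]])
        raise ValueError(
            f"merge records do not cover the pair {pair}; the collection was "
            f"not fully connected upstream"
        )
    return Supermatrix(labels=labels, D=D, support=np.ones((n, n), dtype=int))


def average_linkage_tree(S: Supermatrix) -> Timetree:
    """UPGMA on a complete divergence-time matrix, heights in age units.

    Merges the closest pair repeatedly; the merged cluster's distance to any
    other cluster is the member-count-weighted mean, and the internal node
    created by each merge is placed at the pair's current distance (ages,
    not half-distances, since matrix entries are divergence times).  Tips
    sit at age 0.  Ties are broken by the lexicographically smallest sorted
    member list, matching the main clustering loop.
    """
    if np.isnan(S.D).any():
        raise ValueError("average_linkage_tree requires a complete matrix")
    labels = list(S.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two labels")
    D = S.D.astype(float).copy()

    children: Dict[int, List[int]] = {}
    parent: Dict[int, Optional[int]] = {}
    age: Dict[int, float] = {}
    leaf_label: Dict[int, str] = {}
    active: Dict[int, Tuple[int, Tuple[str, ...]]] = {}  # col -> (node, members)
    for k, lab in enumerate(labels):
        children[k] = []
        age[k] = 0.0
        leaf_label[k] = lab
    next_node = n
    col_node = {k: k for k in range(n)}
    col_members = {k: (labels[k],) for k in range(n)}
    col_size = {k: 1 for k in range(n)}
    alive = set(range(n))

    while len(alive) > 1:
        cols = np.array(sorted(alive))
        sub = D[np.ix_(cols, cols)].copy()
        np.fill_diagonal(sub, np.inf)
        h = float(sub.min())
        ti, tj = np.nonzero(sub == h)
        best = None
        for u, v in zip(cols[ti], cols[tj]):
            if u < v:
                key = (tuple(sorted(col_members[u] + col_members[v])), int(u), int(v))
                if best is None or key < best:
                    best = key
        assert best is not None
        _, a, b = best
        v = next_node
        next_node += 1
        children[v] = [col_node[a], col_node[b]]
        age[v] = float(h)
        # weighted average update
        na, nb = col_size[a], col_size[b]
        for k in alive:
            if k in (a, b):
                continue
            D[a, k] = D[k, a] = (na * D[a, k] + nb * D[b, k]) / (na + nb)
        col_node[a] = v
        col_members[a] = tuple(sorted(col_members[a] + col_members[b]))
        col_size[a] = na + nb
        alive.remove(b)

    root = col_node[alive.pop()]
    parent[root] = None
    stack = [root]
    while stack:
        v = stack.pop()
        for c in children[v]:
            parent[c] = v
            stack.append(c)
    return Timetree(children, parent, age, leaf_label, root)


# --------------------------------------------------------------------------
# the main loop
# --------------------------------------------------------------------------

@dataclass
class ChronoStaResult:
    """Raw output of :func:`run_chrono_sta`."""

    records: List[ClusterRecord]
    supertree: Timetree
    completed_matrix: Supermatrix
    diagnostics: List[Dict[str, object]]
    stored_pair_log: List[Dict[str, object]] = field(default_factory=list)
    pre_smoothing_tree: Optional[Timetree] = None


def _unique_cluster_id(iteration: int, taken: Iterable[str]) -> str:
    cid = f"C{iteration}"
    taken = set(taken)
    while cid in taken:
        cid += "_"
    return cid


def run_chrono_sta(
    trees: Sequence[Timetree],
    max_iter: Optional[int] = None,
) -> ChronoStaResult:
    """Assemble a supertree from a collection of timetrees.

    Iterates {consensus supermatrix -> minimum-divergence pair -> record
    cluster -> backpropagate} until a single cluster remains, then builds
    the completed divergence-time matrix from the merge records, the
    average-linkage supertree, and smooths it to ultrametric.

    Raises :class:`DisconnectedCollectionError` if the taxon co-occurrence
    graph has more than one component (no divergence time links the parts);
    the usual remedy is adding common outgroup taxa at known ages to every
    input tree (see :func:`graft_outgroup`).
    """
    if not trees:
        raise ValueError("need at least one input tree")
    all_leaves = sorted(set().union(*(t.leaf_labels for t in trees)))
    if len(all_leaves) < 2:
        raise ValueError("need at least two distinct leaves overall")

    partials = []
    for k, t in enumerate(trees):
        m = node_age_matrix(t)
        m.origin = f"tree_{k + 1:02d}"
        partials.append(m)

    S = consensus_supermatrix(partials)
    comps = S.connected_components()
    if len(comps) > 1:
        raise DisconnectedCollectionError(comps)

    members: Dict[str, FrozenSet[str]] = {lab: frozenset([lab]) for lab in all_leaves}
    records: List[ClusterRecord] = []
    diagnostics: List[Dict[str, object]] = []
    stored_log: List[Dict[str, object]] = []
    n_merges = len(all_leaves) - 1
    cap = n_merges if max_iter is None else min(max_iter, n_merges)
    prev_missing = None

    for it in range(1, cap + 1):
        if it > 1:
            S = consensus_supermatrix(partials)
        if prev_missing is not None and len(S.labels) >= prev_missing[0]:
            raise RuntimeError("no progress between iterations; aborting")
        prev_missing = (len(S.labels),)
        a, b, merge_age = find_min_pair(S, members)
        cid = _unique_cluster_id(it, members)
        rec = ClusterRecord(
            cluster_id=cid,
            members=members[a] | members[b],
            merge_age=merge_age,
            iteration=it,
        )
        n_a, n_b = len(members[a]), len(members[b])
        partials, stored = backpropagate_cluster(partials, rec, a, b, n_a, n_b)
        for origin, val in stored.items():
            stored_log.append(
                {"iteration": it, "cluster_id": cid, "origin": origin, "age": val}
            )
        ia, ib = S.index_of(a), S.index_of(b)
        diagnostics.append(
            {
                "iteration": it,
                "pair": (a, b),
                "cluster_id": cid,
                "merge_age": merge_age,
                "support": int(S.support[ia, ib]),
                "n_labels": len(S.labels),
                "n_missing_cells": S.n_missing_offdiag,
            }
        )
        members[cid] = rec.members
        del members[a], members[b]
        records.append(rec)

    completed = complete_matrix_from_records(records, all_leaves)
    raw = average_linkage_tree(completed)
    supertree = smooth_to_ultrametric(raw)
    return ChronoStaResult(
        records=records,
        supertree=supertree,
        completed_matrix=completed,
        diagnostics=diagnostics,
        stored_pair_log=stored_log,
        pre_smoothing_tree=raw,
    )


def graft_outgroup(tree: Timetree, label: str, age: float) -> Timetree:
    """Attach an outgroup taxon above the root at the stated divergence age.

    Mirrors the practice of adding distant, unambiguously placed root
    species to every input tree so that otherwise disjoint collections
    share anchors.  ``age`` must exceed the tree's root age.
    """
    if label in tree.leaf_labels:
        raise ValueError(f"outgroup label {label!r} already present in tree")
    if age <= tree.root_age:
        raise ValueError(
            f"outgroup age {age} must exceed the tree's root age {tree.root_age}"
        )
    out = tree.copy()
    new_root = max(out.children) + 1
    leaf = new_root + 1
    out.children[new_root] = [out.root, leaf]
    out.children[leaf] = []
    out.parent[out.root] = new_root
    out.parent[new_root] = None
    out.parent[leaf] = new_root
    out.age[new_root] = float(age)
    out.age[leaf] = 0.0
    out.label[leaf] = label
    out.root = new_root
    out._leaf_node[label] = leaf
    return out


# --------------------------------------------------------------------------
# model / results surface
# --------------------------------------------------------------------------

class ChronoSTA:
    """Chronological supertree model over a collection of timetrees.

    Parameters
    ----------
    trees
        Rooted ultrametric :class:`~chronosta.timetree_io.Timetree` objects
        (parse with :func:`~chronosta.timetree_io.parse_timetree`).
    outgroups
        Optional ``[(label, age), ...]`` grafted onto *every* input tree
        before fitting, to root/connect sparse collections.  Ages are in the
        trees' time units and must exceed each tree's root age.
    """

    def __init__(
        self,
        trees: Sequence[Timetree],
        outgroups: Optional[Sequence[Tuple[str, float]]] = None,
    ):
        if outgroups:
            fitted_trees = []
            for t in trees:
                for label, age in outgroups:
                    t = graft_outgroup(t, label, float(age))
                fitted_trees.append(t)
            trees = fitted_trees
        self.trees = list(trees)

    @classmethod
    def from_newick(
        cls,
        paths: Sequence[str],
        outgroups: Optional[Sequence[Tuple[str, float]]] = None,
        **parse_kwargs,
    ) -> "ChronoSTA":
        from .timetree_io import read_timetrees

        return cls(read_timetrees(paths, **parse_kwargs), outgroups=outgroups)

    def fit(self) -> "ChronoSTAResults":
        return ChronoSTAResults(self, run_chrono_sta(self.trees))


class ChronoSTAResults:
    """Fitted supertree: merge records, diagnostics and the tree itself."""

    def __init__(self, model: ChronoSTA, result: ChronoStaResult):
        self.model = model
        self._result = result

    # pass-throughs ------------------------------------------------------
    @property
    def supertree(self) -> Timetree:
        return self._result.supertree

    @property
    def records(self) -> List[ClusterRecord]:
        return self._result.records

    @property
    def completed_matrix(self) -> Supermatrix:
        return self._result.completed_matrix

    @property
    def diagnostics(self) -> List[Dict[str, object]]:
        return self._result.diagnostics

    # tables -------------------------------------------------------------
    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [r.cluster_id for r in self.records],
                "iteration": [r.iteration for r in self.records],
                "merge_age": [r.merge_age for r in self.records],
                "n_members": [r.n for r in self.records],
                "members": [",".join(sorted(r.members)) for r in self.records],
                "support": [d["support"] for d in self.diagnostics],
            }
        )

    def diagnostics_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.diagnostics)
        df["pair"] = df["pair"].map(lambda p: f"{p[0]}|{p[1]}")
        return df

    def summary(self) -> str:
        n_leaves = self.supertree.n_leaves
        lines = [
            "Chrono-STA supertree",
            "=" * 60,
            f"input trees:        {len(self.model.trees)}",
            f"taxa (union):       {n_leaves}",
            f"merges recorded:    {len(self.records)}",
            f"supertree root age: {self.supertree.root_age:.4f}",
            "",
            self.records_frame()
            .drop(columns="members")
            .to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    # output -------------------------------------------------------------
    def to_newick(self, decimals: int = 6) -> str:
        return write_newick(self.supertree, decimals=decimals)

    def save_newick(self, path: str, decimals: int = 6) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick(decimals) + "\n")

    def save_records(self, path: str) -> None:
        self.records_frame().to_csv(path, sep="\t", index=False)

    def evaluate(self, reference: Timetree):
        """Topological and chronological agreement with a reference tree."""
        from .evaluation import evaluate_against_reference

        return evaluate_against_reference(reference, self.supertree)
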