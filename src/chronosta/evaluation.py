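"""Topological and chronological accuracy metrics for supertrees.

Compares an inferred supertree with a reference timetree via the
Robinson–Foulds bipartition distance (plain and polytomy-aware) and via
node-age agreement: a regression through the origin of estimated MRCA ages
on reference node ages, and the percent time error

    dTE_v = 100 * (t_est - t_ref) / t_ref

for every reference internal node whose descendant set is present in the
inferred tree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .timetree_io import Timetree

__all__ = [
    "EvalReport",
    "bipartitions",
    "normalized_rf",
    "polytomy_aware_nrf",
    "time_agreement",
    "evaluate_against_reference",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Agreement between an inferred supertree and a reference timetree."""

    rf: int
    nrf: float
    m: int
    slope: float
    r_squared: float
    delta_te: List[float]
    delta_te_median: float
    n_nodes_compared: int = 0
    n_nodes_skipped: int = 0
    polytomy_aware: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        return {
            "rf": self.rf,
            "nrf": self.nrf,
            "m": self.m,
            "slope": self.slope,
            "r_squared": self.r_squared,
            "delta_te_median": self.delta_te_median,
            "delta_te": list(self.delta_te),
            "n_nodes_compared": self.n_nodes_compared,
            "n_nodes_skipped": self.n_nodes_skipped,
            "polytomy_aware_nrf": self.polytomy_aware,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


# --------------------------------------------------------------------------
# Robinson–Foulds
# --------------------------------------------------------------------------

def bipartitions(tree: Timetree) -> Set[FrozenSet[str]]:
    """Non-trivial unrooted bipartitions, one canonical side per split.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest leaf is the canonical representative.
    Trivial splits (singleton or full-complement) are excluded.
    """
    leaves = tree.leaf_labels
    m = len(leaves)
    ref = min(leaves)
    out: Set[FrozenSet[str]] = set()
    for v in tree.postorder():
        if v == tree.root or tree.is_leaf(v):
            continue
        clade = tree.leaves_under(v)
        side = leaves - clade if ref in clade else clade
        if 2 <= len(side) <= m - 2:
            out.add(frozenset(side))
    return out


def _require_same_leaves(a: Timetree, b: Timetree) -> None:
    if a.leaf_labels != b.leaf_labels:
        only_a = sorted(a.leaf_labels - b.leaf_labels)
        only_b = sorted(b.leaf_labels - a.leaf_labels)
        raise ValueError(
            f"trees have different leaf sets (only in first: {only_a[:10]}; "
            f"only in second: {only_b[:10]}); prune to the shared taxa first"
        )


def normalized_rf(tree_a: Timetree, tree_b: Timetree) -> Tuple[int, float]:
    """Robinson–Foulds distance and its normalized form RF / (2(m-3)).

    RF counts non-trivial bipartitions present in exactly one of the two
    trees; m is the (shared) number of species.  For m <= 3 there are no
    non-trivial splits and nRF is defined as 0.
    """
    _require_same_leaves(tree_a, tree_b)
    m = len(tree_a.leaf_labels)
    rf = len(bipartitions(tree_a) ^ bipartitions(tree_b))
    nrf = rf / (2.0 * (m - 3)) if m > 3 else 0.0
    return rf, nrf


def _splits_compatible(x: FrozenSet[str], y: FrozenSet[str], leaves: FrozenSet[str]) -> bool:
    """Two splits are compatible iff some quadrant of their crossing is empty."""
    if not x & y:
        return True
    if not x - y or not y - x:
        return True
    return not (leaves - (x | y))


def polytomy_aware_nrf(study_tree: Timetree, supertree_subset: Timetree) -> float:
    """Compatibility-based RF variant that does not penalize polytomies.

    A split counts as conflicting only when it is incompatible with at
    least one split of the other tree, so a binary resolution of a polytomy
    is not treated as an error.  Normalization is by the total number of
    non-trivial splits across both trees (equal to 2(m-3) when both are
    fully binary), giving a fraction in [0, 1].
    """
    _require_same_leaves(study_tree, supertree_subset)
    leaves = study_tree.leaf_labels
    sa = bipartitions(study_tree)
    sb = bipartitions(supertree_subset)
    denom = len(sa) + len(sb)
    if denom == 0:
        return 0.0
    conflicts = 0
    for x in sa:
        if any(not _splits_compatible(x, y, leaves) for y in sb):
            conflicts += 1
    for y in sb:
        if any(not _splits_compatible(y, x, leaves) for x in sa):
            conflicts += 1
    return conflicts / denom


# --------------------------------------------------------------------------
# chronological agreement
# --------------------------------------------------------------------------

def time_agreement(
    reference: Timetree, inferred: Timetree
) -> Tuple[float, float, List[float], float, int, int]:
    """Node-age agreement between a reference tree and an inferred tree.

    For every internal node of the reference, the estimate is the inferred
    age of the MRCA of that node's descendant taxa (the mapping is applied
    even where the topologies disagree).  Returns ``(slope, r_squared,
    delta_te, delta_te_median, n_compared, n_skipped)`` where slope and R^2
    come from the least-squares regression of estimated on reference ages
    through the origin (uncentered R^2 = 1 - SS_res / sum t_est^2).
    """
    inf_leaves = inferred.leaf_labels
    t_ref: List[float] = []
    t_est: List[float] = []
    skipped = 0
    for v in reference.postorder():
        if reference.is_leaf(v):
            continue
        desc = reference.leaves_under(v)
        if not desc <= inf_leaves:
            skipped += 1
            logger.info("skipping reference node with absent descendants: %s",
                        sorted(desc - inf_leaves)[:5])
            continue
        t_ref.append(reference.age[v])
        t_est.append(inferred.mrca_age(desc))
    tr = np.asarray(t_ref)
    te = np.asarray(t_est)
    if tr.size == 0:
        raise ValueError("no comparable internal nodes between the trees")
    slope = float(tr @ te / (tr @ tr))
    ss_res = float(((te - slope * tr) ** 2).sum())
    ss_tot = float((te ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dte = 100.0 * (te - tr) / tr
    dte = dte[np.isfinite(dte)]
    median = float(np.median(dte)) if dte.size else 0.0
    return slope, r2, [float(x) for x in dte], median, int(tr.size), skipped


def evaluate_against_reference(
    reference: Timetree,
    inferred: Timetree,
    polytomy_aware: bool = False,
) -> EvalReport:
    """Full evaluation report; trees are pruned to their shared taxa first."""
    shared = reference.leaf_labels & inferred.leaf_labels
    if len(shared) < 3:
        raise ValueError("fewer than three shared taxa; nothing to compare")
    ref_p = reference.restrict_to(shared) if reference.leaf_labels != shared else reference
    inf_p = inferred.restrict_to(shared) if inferred.leaf_labels != shared else inferred
    rf, nrf = normalized_rf(ref_p, inf_p)
    slope, r2, dte, med, n_cmp, n_skip = time_agreement(ref_p, inf_p)
    pa = polytomy_aware_nrf(ref_p, inf_p) if polytomy_aware else None
    return EvalReport(
        rf=rf,
        nrf=nrf,
        m=len(shared),
        slope=slope,
        r_squared=r2,
        delta_te=dte,
        delta_te_median=med,
        n_nodes_compared=n_cmp,
        n_nodes_skipped=n_skip,
        polytomy_aware=pa,
    )


def plot_time_agreement(reference: Timetree, inferred: Timetree, ax=None):
    """Scatter of reference vs. estimated node ages with the through-origin fit."""
    import matplotlib.pyplot as plt

    slope, r2, _, _, _, _ = time_agreement(reference, inferred)
    tr, te = [], []
    inf_leaves = inferred.leaf_labels
    for v in reference.postorder():
        if not reference.is_leaf(v):
            desc = reference.leaves_under(v)
            if desc <= inf_leaves:
                tr.append(reference.age[v])
                te.append(inferred.mrca_age(desc))
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(tr, te, s=12, alpha=0.7)
    hi = max(max(tr), max(te))
    ax.plot([0, hi], [0, hi], color="gray", lw=1, label="equality")
    ax.plot([0, hi], [0, slope * hi], "k--", lw=1,
            label=f"fit: slope={slope:.3f}, $R^2$={r2:.3f}")
    ax.set_xlabel("reference node age")
    ax.set_ylabel("estimated node age")
    ax.legend()
    return ax
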