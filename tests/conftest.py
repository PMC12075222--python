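"""Shared fixtures: small hand-built trees and random-collection helpers."""

import numpy as np
import pytest

from chronosta import Timetree, parse_timetree, simulate_model_tree


@pytest.fixture
def three_taxon_tree() -> Timetree:
    return parse_timetree("((A:1,B:1):2,C:3);")


@pytest.fixture
def balanced_four_taxon_model() -> Timetree:
    """Ultrametric model with cherries (A,B)@1 and (C,D)@2, root at 3."""
    return parse_timetree("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture
def seven_taxon_model() -> Timetree:
    """Seven-leaf ultrametric model with six distinct internal ages.

    Node ages: (A,B)=10, (C,D)=25, (ABCD)=40, (E,F)=15, (EFG)=55, root=70.
    """
    return parse_timetree(
        "(((A:10,B:10):30,(C:25,D:25):15):30,((E:15,F:15):40,G:55):15);"
    )


SPARSE_SEVEN_TAXON_SUBSETS = [
    {"A", "B", "C"},
    {"C", "D", "E"},
    {"E", "F", "G"},
    {"B", "D", "G"},
    {"A", "F"},
]


@pytest.fixture
def sparse_seven_taxon_collection(seven_taxon_model):
    """Five overlapping restrictions of the seven-leaf model.

    Pairwise co-occurrence is deliberately incomplete (8 of the 21 leaf
    pairs never appear together in any tree), but every model node's age is
    witnessed by at least one cross-clade pair in some tree.
    """
    return [seven_taxon_model.restrict_to(s) for s in SPARSE_SEVEN_TAXON_SUBSETS]


def random_model(n: int, seed: int, root_age: float = 100.0) -> Timetree:
    return simulate_model_tree(n, root_age=root_age, seed=seed)


def complete_cooccurrence_collection(model: Timetree, seed: int, n_trees: int = 4):
    """Leaf-restricted copies of ``model`` in which every leaf pair
    co-occurs in at least one tree (patched with one extra tree if the
    random subsets leave pairs uncovered)."""
    rng = np.random.default_rng(seed)
    leaves = sorted(model.leaf_labels)
    n = len(leaves)
    subsets = []
    for _ in range(n_trees):
        k = int(rng.integers(max(3, int(0.6 * n)), n + 1))
        subsets.append(set(rng.choice(leaves, size=k, replace=False)))
    uncovered = [
        (a, b)
        for i, a in enumerate(leaves)
        for b in leaves[i + 1 :]
        if not any(a in s and b in s for s in subsets)
    ]
    if uncovered:
        subsets.append({x for pair in uncovered for x in pair} | {leaves[0]})
    return [model.restrict_to(s) for s in subsets]


def trees_equal(a: Timetree, b: Timetree, age_tol: float = 1e-9) -> bool:
    """Topology and ages equal (up to child ordering)."""
    if a.leaf_labels != b.leaf_labels:
        return False

    def clade_ages(t: Timetree):
        return {
            frozenset(t.leaves_under(v)): t.age[v]
            for v in t.postorder()
            if not t.is_leaf(v)
        }

    ca, cb = clade_ages(a), clade_ages(b)
    if set(ca) != set(cb):
        return False
    scale = max(1.0, abs(a.root_age))
    return all(abs(ca[k] - cb[k]) <= age_tol * scale for k in ca)
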