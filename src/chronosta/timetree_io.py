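"""Reading, writing and age arithmetic for rooted time-scaled trees.

A *timetree* is a rooted phylogeny whose branch lengths are in units of
absolute time (e.g. millions of years), so that every node carries an age:
extant tips sit at age 0 and internal nodes at the age of the divergence
they represent.  :class:`Timetree` is the universal in-memory object of this
package; Newick I/O is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "Timetree",
    "TimetreeError",
    "NonUltrametricError",
    "normalize_label",
    "parse_timetree",
    "parse_timetrees",
    "read_timetrees",
    "node_age_matrix",
    "write_newick",
]

DEFAULT_ULTRAMETRIC_TOLERANCE = 1e-6


class TimetreeError(ValueError):
    """Malformed or unsupported tree input."""


class NonUltrametricError(TimetreeError):
    """Tip ages deviate from zero beyond the allowed tolerance."""


def normalize_label(label: str) -> str:
    """Canonical taxon name: stripped, internal whitespace -> underscores.

    Matching across trees is exact string equality after this normalization.
    """
    return "_".join(str(label).strip().split())


@dataclass
class Timetree:
    """Rooted tree with node ages.

    Nodes are integer ids; ``children[v]`` lists the children of ``v`` (empty
    for leaves), ``parent[v]`` is the parent (``None`` for the root),
    ``age[v]`` is the node age in time units and ``label[v]`` names the leaf
    nodes.  Polytomies are permitted.
    """

    children: Dict[int, List[int]]
    parent: Dict[int, Optional[int]]
    age: Dict[int, float]
    label: Dict[int, str]
    root: int
    _leaf_node: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._leaf_node:
            self._leaf_node = {lab: v for v, lab in self.label.items()}

    # -- basic accessors -------------------------------------------------
    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(self.label.values())

    @property
    def n_leaves(self) -> int:
        return len(self.label)

    @property
    def root_age(self) -> float:
        return self.age[self.root]

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    def postorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def leaves_under(self, v: int) -> FrozenSet[str]:
        out: List[str] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(self.label[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def _pair_mrca(self, u: int, v: int) -> int:
        anc = set()
        x: Optional[int] = u
        while x is not None:
            anc.add(x)
            x = self.parent[x]
        y: int = v
        while y not in anc:
            y = self.parent[y]  # type: ignore[assignment]
        return y

    def mrca(self, labels: Iterable[str]) -> int:
        """Node id of the most recent common ancestor of the given taxa."""
        nodes = []
        for lab in labels:
            try:
                nodes.append(self._leaf_node[lab])
            except KeyError:
                raise KeyError(f"taxon {lab!r} not in tree") from None
        if not nodes:
            raise ValueError("mrca of empty taxon set")
        cur = nodes[0]
        for u in nodes[1:]:
            cur = self._pair_mrca(cur, u)
        return cur

    def mrca_age(self, labels: Iterable[str]) -> float:
        return self.age[self.mrca(labels)]

    def copy(self) -> "Timetree":
        return Timetree(
            children={v: list(c) for v, c in self.children.items()},
            parent=dict(self.parent),
            age=dict(self.age),
            label=dict(self.label),
            root=self.root,
        )

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_cherry(cls, a: str, b: str, age: float) -> "Timetree":
        return cls(
            children={0: [1, 2], 1: [], 2: []},
            parent={0: None, 1: 0, 2: 0},
            age={0: float(age), 1: 0.0, 2: 0.0},
            label={1: a, 2: b},
            root=0,
        )

    def restrict_to(self, keep: Iterable[str]) -> "Timetree":
        """Leaf-restriction: prune to ``keep``, suppressing unary nodes.

        Node ages are preserved, so the result is an exact restriction of
        this tree's chronology (the age of every retained divergence is the
        age of the corresponding MRCA in the full tree).
        """
        keep = set(keep)
        missing = keep - set(self._leaf_node)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        if len(keep) < 1:
            raise ValueError("cannot restrict to an empty leaf set")

        # bottom-up rebuild
        new_children: Dict[int, List[int]] = {}
        new_age: Dict[int, float] = {}
        new_label: Dict[int, str] = {}
        counter = [0]

        def fresh() -> int:
            counter[0] += 1
            return counter[0] - 1

        def rec(v: int) -> Optional[int]:
            if self.is_leaf(v):
                if self.label[v] in keep:
                    u = fresh()
                    new_children[u] = []
                    new_age[u] = self.age[v]
                    new_label[u] = self.label[v]
                    return u
                return None
            kids = [rec(c) for c in self.children[v]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]  # suppress unary node, keep child age
            u = fresh()
            new_children[u] = kids
            new_age[u] = self.age[v]
            return u

        new_root = rec(self.root)
        assert new_root is not None
        new_parent: Dict[int, Optional[int]] = {new_root: None}
        for v, kids in new_children.items():
            for k in kids:
                new_parent[k] = v
        return Timetree(new_children, new_parent, new_age, new_label, new_root)


def _timetree_from_dendropy(
    dtree: dendropy.Tree,
    ultrametric_tolerance: float,
    force: bool,
) -> Timetree:
    children: Dict[int, List[int]] = {}
    parent: Dict[int, Optional[int]] = {}
    depth: Dict[int, float] = {}
    label: Dict[int, str] = {}
    ids: Dict[int, int] = {}

    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[id(nd)] = i
        children[i] = []
        if nd.parent_node is None:
            parent[i] = None
            depth[i] = 0.0
        else:
            p = ids[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                name = nd.taxon.label if nd.taxon is not None else f"node #{i}"
                raise TimetreeError(
                    f"missing branch length on the edge above {name!r}"
                )
            if nd.edge.length < 0:
                raise TimetreeError(f"negative branch length above node #{i}")
            depth[i] = depth[p] + float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is None or nd.taxon.label is None:
                raise TimetreeError("leaf without a taxon label")
            label[i] = normalize_label(nd.taxon.label)

    labs = list(label.values())
    if len(set(labs)) != len(labs):
        dupes = sorted({x for x in labs if labs.count(x) > 1})
        raise TimetreeError(f"duplicate leaf labels after normalization: {dupes}")

    root_age = max(depth[v] for v in label)  # deepest tip defines age 0
    age = {v: root_age - d for v, d in depth.items()}
    tol = ultrametric_tolerance * root_age if root_age > 0 else ultrametric_tolerance
    bad = {label[v]: age[v] for v in label if abs(age[v]) > tol}
    if bad and not force:
        worst = max(bad.items(), key=lambda kv: abs(kv[1]))
        raise NonUltrametricError(
            f"non-ultrametric input: tip {worst[0]!r} sits at age {worst[1]:.6g} "
            f"(tolerance {tol:.3g}); pass force_ultrametric=True to snap tips to 0"
        )
    if bad and force:
        warnings.warn(
            f"snapping {len(bad)} tip(s) to age 0 (max deviation "
            f"{max(abs(a) for a in bad.values()):.6g})",
            stacklevel=3,
        )
    for v in label:
        age[v] = 0.0

    root = 0
    tt = Timetree(children, parent, age, label, root)
    if len(tt.children[root]) > 2:
        warnings.warn(
            "basal polytomy (possibly unrooted Newick) treated as a rooted "
            "multifurcation at the root",
            stacklevel=3,
        )
    return tt


def parse_timetree(
    newick_text: str,
    ultrametric_tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
    force_ultrametric: bool = False,
) -> Timetree:
    """Parse a single Newick string into a :class:`Timetree`.

    Node ages are root age minus root-to-node path length, with the root age
    fixed so that the deepest tip sits at age 0.  Tips whose implied age
    deviates from 0 by more than ``ultrametric_tolerance`` x root age raise
    :class:`NonUltrametricError` unless ``force_ultrametric`` is set, in
    which case they are snapped to 0 with a warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TimetreeError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or dtree.seed_node.is_leaf():
        raise TimetreeError("tree must contain at least two leaves")
    return _timetree_from_dendropy(dtree, ultrametric_tolerance, force_ultrametric)


def parse_timetrees(
    text: str,
    ultrametric_tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
    force_ultrametric: bool = False,
) -> List[Timetree]:
    """Parse a multi-tree Newick document (one tree per line/statement)."""
    out = []
    for chunk in text.split(";"):
        if chunk.strip():
            out.append(
                parse_timetree(chunk + ";", ultrametric_tolerance, force_ultrametric)
            )
    if not out:
        raise TimetreeError("no trees found in input")
    return out


def read_timetrees(
    paths: Sequence[str],
    ultrametric_tolerance: float = DEFAULT_ULTRAMETRIC_TOLERANCE,
    force_ultrametric: bool = False,
) -> List[Timetree]:
    trees: List[Timetree] = []
    for p in paths:
        with open(p, "r", encoding="utf-8") as fh:
            trees.extend(
                parse_timetrees(fh.read(), ultrametric_tolerance, force_ultrametric)
            )
    return trees


def node_age_matrix(tree: Timetree):
    """Pairwise divergence-time matrix of one tree.

    Entry (x, y) is the age of the MRCA of leaves x and y; the diagonal is 0.
    Every pair within the tree is present (no missing entries).  Returns a
    :class:`chronosta.distance_core.PartialTimeMatrix`.
    """
    from .distance_core import PartialTimeMatrix

    labels = sorted(tree.leaf_labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n), dtype=float)

    # for each internal node, pairs of leaves drawn from distinct children
    # have their MRCA exactly there
    below: Dict[int, List[int]] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            below[v] = [idx[tree.label[v]]]
        else:
            groups = [below[c] for c in tree.children[v]]
            a = tree.age[v]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for x in groups[gi]:
                        for y in groups[gj]:
                            D[x, y] = a
                            D[y, x] = a
            merged: List[int] = []
            for g in groups:
                merged.extend(g)
            below[v] = merged
    return PartialTimeMatrix(labels=labels, D=D, origin=None)


def _to_dendropy(tree: Timetree, decimals: int) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(v: int, dnode: dendropy.Node) -> None:
        for c in tree.children[v]:
            blen = tree.age[v] - tree.age[c]
            if blen < -1e-12 * max(1.0, abs(tree.root_age)):
                raise TimetreeError(
                    f"negative branch length implied (child age {tree.age[c]:.6g} "
                    f"> parent age {tree.age[v]:.6g}); smooth the tree first"
                )
            child = dnode.new_child(edge_length=round(max(blen, 0.0), decimals))
            if tree.is_leaf(c):
                child.taxon = taxa.new_taxon(tree.label[c])
            else:
                build(c, child)

    build(tree.root, dtree.seed_node)
    return dtree


def write_newick(tree: Timetree, decimals: int = 6) -> str:
    """Serialize to Newick with branch lengths age(parent) - age(child).

    Raises :class:`TimetreeError` if any implied branch length is negative
    (a sign that ultrametric smoothing was skipped).
    """
    dtree = _to_dendropy(tree, decimals)
    return dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{decimals}f",
    ).strip()
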