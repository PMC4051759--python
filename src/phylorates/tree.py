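"""Calibrated phylogenies: Newick I/O, age smoothing, pruning, distances.

The central container is :class:`CalibratedTree`, a rooted tree with branch
lengths in millions of years (Myr).  Every node carries a stable label (tips
keep their taxon names; unlabeled internal nodes are auto-named ``nd<i>`` by
preorder index) so that age constraints, stochastic character maps and regime
covariances can address branches by the label of the node below them.

Newick parsing is delegated to dendropy; serialization is done here so that
output is canonical (children ordered lexicographically by their smallest
descendant tip label, full float precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "Node",
    "CalibratedTree",
    "DistanceMatrix",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "read_age_constraints",
    "bladj_smooth",
    "resolve_polytomies",
    "prune_to",
    "cophenetic_matrix",
    "vcv_matrix",
]


class TreeError(ValueError):
    """Raised for malformed trees, inconsistent constraints or bad labels."""


class Node:
    """A tree node: ``label``, ``length`` (branch above, Myr), links."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: List[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, length={self.length})"


class CalibratedTree:
    """Rooted tree with branch lengths in Myr and stable node labels."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._autoname()
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    def _autoname(self) -> None:
        used = {n.label for n in self.root.preorder() if n.label is not None}
        counter = 0
        for node in self.root.preorder():
            if node.label is None:
                while f"nd{counter}" in used:
                    counter += 1
                node.label = f"nd{counter}"
                used.add(node.label)
                counter += 1

    def _validate(self) -> None:
        seen: set = set()
        tips: set = set()
        for node in self.root.preorder():
            if node.length < 0:
                raise TreeError(f"negative branch length at node {node.label!r}")
            if node.label in seen:
                raise TreeError(f"duplicate node label {node.label!r}")
            seen.add(node.label)
            if node.is_leaf():
                if node.label in tips:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                tips.add(node.label)
            for child in node.children:
                if child.parent is not node:
                    raise TreeError("inconsistent parent link")
        if self.root.parent is not None:
            raise TreeError("root must not have a parent")

    # -- basic queries --------------------------------------------------------

    @property
    def nodes(self) -> List[Node]:
        return list(self.root.preorder())

    @property
    def tips(self) -> List[Node]:
        return [n for n in self.root.preorder() if n.is_leaf()]

    @property
    def tip_labels(self) -> List[str]:
        """Tip labels in sorted order (the canonical matrix ordering)."""
        return sorted(n.label for n in self.tips)

    def __len__(self) -> int:
        return len(self.tips)

    def node(self, label: str) -> Node:
        for n in self.root.preorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def depths(self) -> Dict[str, float]:
        """Root-to-node path length for every node (root depth 0)."""
        depth: Dict[str, float] = {}
        for node in self.root.preorder():
            if node.parent is None:
                depth[node.label] = 0.0
            else:
                depth[node.label] = depth[node.parent.label] + node.length
        return depth

    @property
    def root_age(self) -> float:
        """Age of the root = maximum tip depth (Myr before present)."""
        depth = self.depths()
        return max(depth[t.label] for t in self.tips)

    def ages(self) -> Dict[str, float]:
        """Node ages in Myr before present (tips at 0 when ultrametric)."""
        depth = self.depths()
        root_age = max(depth[t.label] for t in self.tips)
        return {lab: root_age - d for lab, d in depth.items()}

    def total_length(self) -> float:
        return sum(n.length for n in self.root.preorder() if n.parent is not None)

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depth = self.depths()
        tip_depths = [depth[t.label] for t in self.tips]
        dmax = max(tip_depths)
        if dmax == 0:
            return True
        return (dmax - min(tip_depths)) <= rtol * dmax

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.root.preorder())

    def copy(self) -> "CalibratedTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return CalibratedTree(clone(self.root), validate=False)

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "CalibratedTree":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)

    # -- matrices -------------------------------------------------------------

    def mrca_depths(self) -> "PhyloCovariance":
        return vcv_matrix(self)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise tip-to-tip path distances (Myr)."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeError("distance matrix shape does not match labels")

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class PhyloCovariance:
    """Shared root-to-MRCA path lengths C (Brownian motion covariance / σ²)."""

    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeError("covariance shape does not match labels")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(text: str) -> CalibratedTree:
    """Parse a Newick string into a :class:`CalibratedTree`.

    Branch lengths default to 0 when absent (topology-only input is allowed
    for age smoothing); unlabeled internal nodes receive deterministic
    ``nd<i>`` names by preorder index.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific parse errors
        raise TreeError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        node = Node(label, length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0 if dtree.seed_node.edge.length is None else float(
        dtree.seed_node.edge.length
    )
    tree = CalibratedTree(root)
    if not tree.tips:
        raise TreeError("tree has no tips")
    return tree


def _min_tip_label(node: Node, cache: Dict[int, str]) -> str:
    key = id(node)
    if key not in cache:
        if node.is_leaf():
            cache[key] = node.label
        else:
            cache[key] = min(_min_tip_label(c, cache) for c in node.children)
    return cache[key]


def write_newick(tree: CalibratedTree) -> str:
    """Serialize with deterministic child order and full float precision."""
    cache: Dict[int, str] = {}

    def fmt_len(x: float) -> str:
        return repr(float(x))

    def render(node: Node) -> str:
        if node.is_leaf():
            return f"{node.label}:{fmt_len(node.length)}"
        kids = sorted(node.children, key=lambda c: _min_tip_label(c, cache))
        inner = ",".join(render(c) for c in kids)
        label = "" if node.label.startswith("nd") else node.label
        if node.parent is None:
            return f"({inner}){label}"
        return f"({inner}){label}:{fmt_len(node.length)}"

    root = tree.root
    if root.is_leaf():
        return f"({root.label}:{fmt_len(root.length)});"
    return render(root) + ";"


def read_age_constraints(path) -> Dict[str, float]:
    """Read a 2-column CSV (node_label, age_myr) into a constraint map."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TreeError("age constraint table needs 2 columns (label, age)")
    labels = df.iloc[:, 0].astype(str)
    ages = df.iloc[:, 1].astype(float)
    if (ages < 0).any():
        raise TreeError("negative age in constraint table")
    return dict(zip(labels, ages))


# ---------------------------------------------------------------------------
# Age smoothing (BLADJ-style even interpolation)
# ---------------------------------------------------------------------------


def bladj_smooth(
    tree: CalibratedTree, constraints: Mapping[str, float]
) -> CalibratedTree:
    """Assign ages to unconstrained internal nodes by even interpolation.

    Each unconstrained internal node is aged by linear interpolation between
    its nearest constrained ancestor and its nearest constrained descendant,
    measured in topological steps; extant tips count as age-0 constraints.
    When several constrained descendants are equally near, the oldest is used
    (keeps ancestors old).  Branch lengths are recomputed from the ages, so
    the output is ultrametric.

    The root must be constrained, and no constrained descendant may be older
    than a constrained ancestor.
    """
    tree = tree.copy()
    if tree.root.label not in constraints:
        raise TreeError("root age must be constrained for smoothing")
    labels = {n.label for n in tree.root.preorder()}
    for lab in constraints:
        if lab not in labels:
            raise TreeError(f"constraint on unknown node {lab!r}")

    def fixed_age(node: Node) -> Optional[float]:
        if node.label in constraints:
            return float(constraints[node.label])
        if node.is_leaf():
            return 0.0
        return None

    # consistency: constrained descendant never older than constrained ancestor
    for node in tree.root.preorder():
        a = fixed_age(node)
        if a is None:
            continue
        anc = node.parent
        steps_up = 1
        while anc is not None:
            aa = fixed_age(anc)
            if aa is not None and a > aa + 1e-12:
                raise TreeError(
                    f"constraint conflict: {node.label!r} (age {a}) older than "
                    f"ancestor {anc.label!r} (age {aa})"
                )
            anc = anc.parent
            steps_up += 1

    def nearest_constrained_descendant(node: Node):
        # BFS over descendants; at the minimal depth take the maximum age.
        frontier = list(node.children)
        steps = 1
        while frontier:
            ages_here = [fixed_age(n) for n in frontier]
            fixed_here = [a for a in ages_here if a is not None]
            if fixed_here:
                return max(fixed_here), steps
            frontier = [c for n in frontier for c in n.children]
            steps += 1
        raise TreeError(f"no constrained descendant below {node.label!r}")

    age: Dict[str, float] = {}
    for node in tree.root.preorder():
        fa = fixed_age(node)
        if fa is not None:
            age[node.label] = fa
            continue
        anc_age = a_steps = None
        steps = 1
        cur = node.parent
        while cur is not None:
            aa = fixed_age(cur)
            if aa is not None:
                anc_age, a_steps = aa, steps
                break
            cur = cur.parent
            steps += 1
        desc_age, d_steps = nearest_constrained_descendant(node)
        age[node.label] = anc_age - (anc_age - desc_age) * a_steps / (
            a_steps + d_steps
        )

    # preorder clamp: a child can never be older than its parent
    for node in tree.root.preorder():
        if node.parent is not None and age[node.label] > age[node.parent.label]:
            age[node.label] = age[node.parent.label]

    for node in tree.root.preorder():
        if node.parent is None:
            node.length = 0.0
        else:
            node.length = age[node.parent.label] - age[node.label]
            if node.length < 0:
                node.length = 0.0
    return CalibratedTree(tree.root)


# ---------------------------------------------------------------------------
# Topology operations
# ---------------------------------------------------------------------------


def resolve_polytomies(tree: CalibratedTree, seed: int) -> CalibratedTree:
    """Randomly resolve multifurcations with zero-length internal branches.

    Mirrors ape's ``multi2di``: at each polytomy, pairs of children are joined
    under new zero-length nodes until the node is binary.  Tip depths (and
    hence all cophenetic distances) are unchanged.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    for node in list(tree.root.preorder()):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            new = Node(None, 0.0)
            node.children = [c for c in node.children if c is not a and c is not b]
            new.add_child(a)
            new.add_child(b)
            node.add_child(new)
    return CalibratedTree(tree.root)


def prune_to(tree: CalibratedTree, taxa) -> CalibratedTree:
    """Induced subtree on ``taxa``; unifurcations suppressed, lengths summed.

    The returned tree is rooted at the MRCA of the retained taxa, so pairwise
    path distances among them are exactly preserved.
    """
    taxa = set(taxa)
    tip_set = {t.label for t in tree.tips}
    missing = sorted(taxa - tip_set)
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    if not taxa:
        raise TreeError("cannot prune to an empty taxon set")

    def induced(node: Node) -> Optional[Node]:
        if node.is_leaf():
            if node.label in taxa:
                return Node(node.label, node.length)
            return None
        kept = [k for k in (induced(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        new = Node(node.label if not node.label.startswith("nd") else None,
                   node.length)
        for k in kept:
            new.add_child(k)
        return new

    new_root = induced(tree.root)
    assert new_root is not None
    if not new_root.is_leaf():
        new_root.length = 0.0  # root the result at the MRCA of retained taxa
    else:
        single = Node(None, 0.0)
        single.add_child(new_root)
        new_root = single
    return CalibratedTree(new_root)


# ---------------------------------------------------------------------------
# Distance and covariance matrices
# ---------------------------------------------------------------------------


def _tip_index_and_depths(tree: CalibratedTree):
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    depth = tree.depths()
    return labels, index, depth


def cophenetic_matrix(tree: CalibratedTree) -> DistanceMatrix:
    """Pairwise tip-to-tip path-length distances (Myr)."""
    labels, index, depth = _tip_index_and_depths(tree)
    n = len(labels)
    dist = np.zeros((n, n))
    tipsets: Dict[int, List[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            tipsets[id(node)] = [node.label]
            continue
        kids = [tipsets[id(c)] for c in node.children]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    ia, da = index[la], depth[la]
                    for lb in kids[b]:
                        ib = index[lb]
                        d = da + depth[lb] - 2.0 * depth[node.label]
                        dist[ia, ib] = dist[ib, ia] = d
        tipsets[id(node)] = [t for k in kids for t in k]
    return DistanceMatrix(labels, dist)


def vcv_matrix(tree: CalibratedTree) -> PhyloCovariance:
    """Brownian covariance C: shared root-to-MRCA path length per tip pair."""
    labels, index, depth = _tip_index_and_depths(tree)
    n = len(labels)
    C = np.zeros((n, n))
    tipsets: Dict[int, List[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            tipsets[id(node)] = [node.label]
            C[index[node.label], index[node.label]] = depth[node.label]
            continue
        kids = [tipsets[id(c)] for c in node.children]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    ia = index[la]
                    for lb in kids[b]:
                        ib = index[lb]
                        C[ia, ib] = C[ib, ia] = depth[node.label]
        tipsets[id(node)] = [t for k in kids for t in k]
    return PhyloCovariance(labels, C)
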