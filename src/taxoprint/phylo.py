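"""Corroborating phylogenetics: distances, Neighbour-Joining, Newick.

Character-based assignments are cross-checked with a distance tree: if the
query clusters with the assigned taxon's reference and database sequences,
the fingerprint call is corroborated.  Distances default to the p-distance
with pairwise deletion of gaps and ambiguities; the Kimura two-parameter
correction is available for more divergent sets.  Trees are built with the
canonical Neighbour-Joining iteration (Saitou-Nei criterion in the
Studier-Keppler O(n^3) form) and serialized as Newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import BASES, GAP, Alignment, AlignedRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def _comparable_sites(a: str, b: str) -> list[tuple[str, str]]:
    return [(x, y) for x, y in zip(a, b) if x in BASES and y in BASES]


def p_distance(a: AlignedRecord | str, b: AlignedRecord | str) -> float:
    """Proportion of differing sites, pairwise-deleting gaps/ambiguities."""
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    if len(sa) != len(sb):
        raise ValueError("sequences differ in length")
    sites = _comparable_sites(sa, sb)
    if not sites:
        raise ValueError("no comparable sites between the two sequences")
    diff = sum(1 for x, y in sites if x != y)
    return diff / len(sites)


def k2p_distance(a: AlignedRecord | str, b: AlignedRecord | str) -> float:
    """Kimura two-parameter distance.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the
    transition and transversion proportions over comparable sites.
    Saturated pairs (a log argument <= 0) raise ``ValueError``.
    """
    sa = a if isinstance(a, str) else a.residues
    sb = b if isinstance(b, str) else b.residues
    if len(sa) != len(sb):
        raise ValueError("sequences differ in length")
    sites = _comparable_sites(sa, sb)
    if not sites:
        raise ValueError("no comparable sites between the two sequences")
    n = len(sites)
    transitions = sum(
        1 for x, y in sites if x != y
        and ({x, y} <= PURINES or {x, y} <= PYRIMIDINES))
    transversions = sum(
        1 for x, y in sites if x != y
        and not ({x, y} <= PURINES or {x, y} <= PYRIMIDINES))
    P, Q = transitions / n, transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError("saturated distance (log argument <= 0)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix has a non-zero diagonal")

    def to_phylip(self) -> str:
        """PHYLIP square format."""
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            name = lab.replace(" ", "_")[:30]
            lines.append(name.ljust(32)
                         + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def distance_matrix(alignment: Alignment, model: str = "p"
                    ) -> DistanceMatrix:
    """All-pairs distances over the alignment's records."""
    dist = {"p": p_distance, "k2p": k2p_distance}[model]
    recs = alignment.records
    n = len(recs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(recs[i], recs[j])
    return DistanceMatrix(labels=tuple(r.id for r in recs), d=d)


@dataclass
class TreeNode:
    """Node of an unrooted tree (represented with a trifurcating root)."""

    name: str = ""
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


@dataclass
class Tree:
    """Unrooted NJ tree plus a log of clamped negative branch lengths."""

    root: TreeNode
    clamped: tuple[tuple[str, float], ...] = ()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def patristic(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf labels and the matrix of path lengths between leaves."""
        paths: dict[str, dict[str, float]] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: dict[str, float] = {}
            child_maps = []
            for ch in node.children:
                cm = {k: v + ch.length for k, v in walk(ch).items()}
                child_maps.append(cm)
                below.update(cm)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for a, da in child_maps[i].items():
                        for b, db in child_maps[j].items():
                            paths.setdefault(a, {})[b] = da + db
                            paths.setdefault(b, {})[a] = da + db
            return below

        walk(self.root)
        labels = tuple(self.leaf_names())
        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = paths[a][b]
        return labels, mat


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbour-Joining tree from a distance matrix (n >= 3).

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; limb lengths by
    the standard formulas.  Ties pick the lowest pair in input order.
    Negative branch lengths are clamped to zero and logged with the deficit.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("Neighbour-Joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))
    clamped: list[tuple[str, float]] = []

    def clamp(node: TreeNode, raw: float) -> None:
        if raw < 0:
            clamped.append((node.name or "internal", raw))
            node.length = 0.0
        else:
            node.length = raw

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        clamp(ni, li)
        clamp(nj, lj)
        parent.children = [ni, nj]
        # distances from the new node u to every other active k
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, raw in ((i, li), (j, lj), (k, lk)):
        clamp(nodes[idx], raw)
        root.children.append(nodes[idx])
    return Tree(root=root, clamped=tuple(clamped))


def _newick_label(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode, with_length: bool) -> str:
    if node.is_leaf:
        body = _newick_label(node.name)
    else:
        inner = ",".join(_newick_node(ch, True) for ch in node.children)
        body = f"({inner})" + (_newick_label(node.name) if node.name else "")
    if with_length:
        body += f":{node.length:.6f}"
    return body


def to_newick(tree: Tree) -> str:
    """Newick serialization with 6-decimal branch lengths.

    Labels containing spaces or Newick metacharacters are single-quoted.
    Re-parsing reproduces topology and branch lengths to 1e-6.
    """
    inner = ",".join(_newick_node(ch, True) for ch in tree.root.children)
    return f"({inner});\n"


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Re-root the (unrooted) tree so ``outgroup`` branches off first.

    Display convenience only: the outgroup leaf must be a child of some
    node; the tree is re-hung so the outgroup and the rest form the two
    top-level clades.
    """
    if outgroup not in tree.leaf_names():
        raise KeyError(f"outgroup {outgroup!r} is not a leaf of the tree")

    # build parent links
    parent: dict[int, TreeNode | None] = {id(tree.root): None}

    def index(node: TreeNode) -> None:
        for ch in node.children:
            parent[id(ch)] = node
            index(ch)

    index(tree.root)
    target = next(l for l in tree.root.leaves() if l.name == outgroup)

    # walk from the outgroup's parent to the old root, reversing edges
    path = [target]
    node = parent[id(target)]
    while node is not None:
        path.append(node)
        node = parent[id(node)]
    new_root = TreeNode()
    og_parent = path[1]
    og_parent.children = [c for c in og_parent.children if c is not target]
    # reverse the chain og_parent -> ... -> old_root
    prev = og_parent
    prev_len = og_parent.length
    for nxt in path[2:]:
        nxt.children = [c for c in nxt.children if c is not prev]
        prev.children.append(nxt)
        nxt.length, prev_len = prev_len, nxt.length
        prev = nxt
    half = target.length / 2.0
    target = TreeNode(name=target.name, length=half, children=[])
    og_parent_node = TreeNode(name=og_parent.name, length=half,
                              children=og_parent.children)
    new_root.children = [target, og_parent_node]
    return Tree(root=new_root, clamped=tree.clamped)
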