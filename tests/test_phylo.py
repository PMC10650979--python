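"""Distances, Neighbour-Joining and Newick serialization."""

import math

import numpy as np
import pytest

from taxoprint.phylo import (
    DistanceMatrix,
    TreeNode,
    distance_matrix,
    k2p_distance,
    nj_tree,
    p_distance,
    root_with_outgroup,
    to_newick,
)

from conftest import make_alignment


# --- distances ----------------------------------------------------------

def test_p_distance_examples():
    assert p_distance("ACGT", "ACGT") == 0.0
    assert p_distance("ACGT", "ACGA") == 0.25
    assert p_distance("AC-T", "ACGT") == 0.0  # 3 comparable sites


def test_p_distance_no_comparable_sites():
    with pytest.raises(ValueError):
        p_distance("AC--", "--GT")


def test_p_distance_is_a_metric(rng):
    """Identity, symmetry and triangle inequality on gap-free strings."""
    seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(6)]
    for a in seqs:
        assert p_distance(a, a) == 0.0
        for b in seqs:
            assert p_distance(a, b) == p_distance(b, a)
            for c in seqs:
                assert p_distance(a, c) <= \
                    p_distance(a, b) + p_distance(b, c) + 1e-12


def test_k2p_identical_is_zero():
    assert k2p_distance("ACGT" * 5, "ACGT" * 5) == 0.0


def test_k2p_closed_form():
    # 20 sites, exactly 2 transitions (A<->G) and 1 transversion (A<->C)
    a = "AAGGCCTTAAGGCCTTAAGG"
    b = "GAAGCCTTAAGGCCTTAACG"
    # verify composition first
    ts = sum(1 for x, y in zip(a, b) if x != y and {x, y} <= {"A", "G"})
    tv = sum(1 for x, y in zip(a, b)
             if x != y and not ({x, y} <= {"A", "G"}
                                or {x, y} <= {"C", "T"}))
    assert (ts, tv) == (2, 1)
    P, Q = 0.10, 0.05
    expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)


def test_k2p_saturation_error():
    # P = 0.5, Q = 0: log argument hits zero
    a = "AAAA"
    b = "GGAA"
    assert p_distance(a, b) == 0.5
    with pytest.raises(ValueError, match="saturated"):
        k2p_distance(a, b)


# --- distance matrix ----------------------------------------------------

def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=("a", "b"),
                       d=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(labels=("a", "b"),
                       d=np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_distance_matrix_from_alignment():
    aln = make_alignment(["ACGT", "ACGA", "ACGT"])
    dm = distance_matrix(aln)
    assert dm.d[0, 1] == 0.25
    assert dm.d[0, 2] == 0.0


def test_phylip_export_parses():
    dm = DistanceMatrix(labels=("a a", "b", "c"),
                        d=np.array([[0, .1, .2], [.1, 0, .3],
                                    [.2, .3, 0.0]]))
    text = dm.to_phylip()
    assert text.splitlines()[0].strip() == "3"
    assert "a_a" in text


# --- neighbour joining --------------------------------------------------

def test_nj_four_taxon_additive():
    """Recovers ((A:2,B:3):1,(C:4,D:5)) from its additive matrix."""
    d = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                  [7, 8, 0, 9], [8, 9, 9, 0]], float)
    dm = DistanceMatrix(labels=("A", "B", "C", "D"), d=d)
    tree = nj_tree(dm)
    labs, pat = tree.patristic()
    idx = [labs.index(l) for l in "ABCD"]
    assert np.allclose(pat[np.ix_(idx, idx)], d, atol=1e-9)


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    dm = DistanceMatrix(labels=("A", "B", "C"), d=d)
    tree = nj_tree(dm)
    lengths = {ch.name: ch.length for ch in tree.root.children}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                       "C": pytest.approx(3.0)}


def test_nj_equidistant_tie_break_deterministic():
    d = np.full((4, 4), 2.0)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(labels=("A", "B", "C", "D"), d=d)
    first = to_newick(nj_tree(dm))
    second = to_newick(nj_tree(dm))
    assert first == second
    assert "(A:1.000000,B:1.000000)" in first  # first pair in input order


def test_nj_too_small():
    dm = DistanceMatrix(labels=("A", "B"),
                        d=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError):
        nj_tree(dm)


def _random_additive(rng, n_leaves):
    """Random binary tree -> its additive leaf distance matrix."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    lengths = {id(n): 0.0 for n in nodes}
    members = [[n] for n in nodes]
    dist = {(a.name, a.name): 0.0 for a in nodes}
    d = np.zeros((n_leaves, n_leaves))
    # agglomerate random pairs with random branch lengths
    active = list(range(len(nodes)))
    leaf_depth = {n.name: 0.0 for n in nodes}
    depth = {i: {nodes[i].name: 0.0} for i in active}
    while len(active) > 1:
        i, j = sorted(rng.choice(active, size=2, replace=False).tolist())
        li = float(rng.uniform(0.5, 2.0))
        lj = float(rng.uniform(0.5, 2.0))
        for a, da in depth[i].items():
            for b, db in depth[j].items():
                ia, ib = int(a[1:]), int(b[1:])
                d[ia, ib] = d[ib, ia] = da + li + db + lj
        merged = {a: da + li for a, da in depth[i].items()}
        merged.update({b: db + lj for b, db in depth[j].items()})
        new = len(nodes)
        nodes.append(TreeNode())
        depth[new] = merged
        active = [k for k in active if k not in (i, j)] + [new]
    return DistanceMatrix(labels=tuple(f"L{i}" for i in range(n_leaves)),
                          d=d)


def test_nj_recovers_random_additive_matrices(rng):
    """Patristic distances reproduce additive inputs to 1e-9."""
    for _ in range(60):
        n = int(rng.integers(4, 9))
        dm = _random_additive(rng, n)
        tree = nj_tree(dm)
        labs, pat = tree.patristic()
        idx = [labs.index(l) for l in dm.labels]
        assert np.allclose(pat[np.ix_(idx, idx)], dm.d, atol=1e-9)


def _splits(tree):
    """Canonical set of non-trivial leaf bipartitions of an unrooted tree."""
    all_leaves = frozenset(tree.leaf_names())

    out = set()

    def walk(node):
        below = frozenset(l.name for l in node.leaves())
        if 1 < len(below) < len(all_leaves) - 1:
            out.add(min(below, all_leaves - below, key=sorted))
        for ch in node.children:
            walk(ch)

    for ch in tree.root.children:
        walk(ch)
    return out


def test_nj_topology_stable_under_small_perturbation(rng):
    """Within the NJ consistency radius the generating topology survives.

    Perturbations are capped at 10% of the shortest branch (0.5 here),
    well inside the l_min/4 consistency radius.
    """
    for _ in range(30):
        n = int(rng.integers(4, 9))
        dm = _random_additive(rng, n)
        clean = _splits(nj_tree(dm))
        noise = rng.uniform(-0.05, 0.05, size=dm.d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        noisy = DistanceMatrix(labels=dm.labels, d=np.abs(dm.d + noise))
        assert _splits(nj_tree(noisy)) == clean


def test_nj_agrees_with_skbio(rng):
    """Independent cross-check against scikit-bio's NJ implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj
    from skbio import DistanceMatrix as SkDM
    for seed in range(5):
        r = np.random.default_rng(seed)
        dm = _random_additive(r, 6)
        ours = nj_tree(dm)
        labs, pat = ours.patristic()
        sk_tree = skbio_nj(SkDM(dm.d, ids=list(dm.labels)))
        for a_i, a in enumerate(labs):
            for b_j, b in enumerate(labs):
                if a_i < b_j:
                    sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                    assert pat[a_i, b_j] == pytest.approx(sk_d, abs=1e-6)


def test_negative_branches_clamped_and_logged():
    # non-additive matrix known to give a negative NJ branch
    d = np.array([[0, 1, 4, 4], [1, 0, 4, 4],
                  [4, 4, 0, 0.1], [4, 4, 0.1, 0]], float)
    dm = DistanceMatrix(labels=("A", "B", "C", "D"), d=d)
    tree = nj_tree(dm)

    def lengths(node):
        out = [node.length]
        for ch in node.children:
            out.extend(lengths(ch))
        return out

    assert all(l >= 0 for l in lengths(tree.root))
    if tree.clamped:
        assert all(raw < 0 for _, raw in tree.clamped)


# --- newick -------------------------------------------------------------

def test_newick_three_leaf_star():
    d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
    dm = DistanceMatrix(labels=("A", "B", "C"), d=d)
    text = to_newick(nj_tree(dm))
    assert text.startswith("(") and text.rstrip().endswith(");")
    assert text.count(":") == 3


def test_newick_quotes_spaced_labels():
    d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
    dm = DistanceMatrix(labels=("Nerium oleander", "B", "C"), d=d)
    assert "'Nerium oleander'" in to_newick(nj_tree(dm))


def test_newick_round_trip_patristic(rng):
    """dendropy re-parse reproduces the patristic matrix to 1e-6."""
    dendropy = pytest.importorskip("dendropy")
    dm = _random_additive(rng, 5)
    tree = nj_tree(dm)
    labs, pat = tree.patristic()
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    pdm = parsed.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in parsed.taxon_namespace}
    for i, a in enumerate(labs):
        for j, b in enumerate(labs):
            if i < j:
                got = pdm.patristic_distance(taxa[a], taxa[b])
                # each branch is serialized to 6 decimals; a leaf-to-leaf
                # path sums several rounded branches
                assert got == pytest.approx(pat[i, j], abs=5e-6)


def test_outgroup_rooting_preserves_leaves():
    d = np.array([[0, 5, 7, 8], [5, 0, 8, 9],
                  [7, 8, 0, 9], [8, 9, 9, 0]], float)
    dm = DistanceMatrix(labels=("A", "B", "C", "D"), d=d)
    tree = nj_tree(dm)
    rooted = root_with_outgroup(tree, "D")
    assert sorted(rooted.leaf_names()) == ["A", "B", "C", "D"]
    assert len(rooted.root.children) == 2
    first = rooted.root.children[0]
    assert first.is_leaf and first.name == "D"
    with pytest.raises(KeyError):
        root_with_outgroup(tree, "Z")
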