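"""Gap filtering, distances, neighbor joining and pruning likelihood.

Oracles: brute-force column scans, closed-form three-point formulas,
least-squares fits over the three unrooted four-taxon topologies, exhaustive
enumeration of internal states for the likelihood, and scikit-bio's own NJ
implementation as an independent cross-check.
"""

import itertools

import numpy as np
import pytest

from pgm_paralogs import (
    DistanceMatrix,
    Msa,
    complete_deletion,
    neighbor_joining,
    protein_distance,
    read_newick,
    tree_loglik,
    write_newick,
)
from pgm_paralogs import jtt
from pgm_paralogs.phylo import PhyloTree, TreeNode


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def splits(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions (as the smaller-side leaf set label sets)."""
    all_leaves = frozenset(tree.leaf_names())
    out = set()

    def walk(node: TreeNode):
        names = frozenset(node.leaf_names())
        if 2 <= len(names) <= len(all_leaves) - 2:
            side = min(names, all_leaves - names, key=lambda s: (len(s), sorted(s)))
            out.add(frozenset(side))
        for c in node.children:
            walk(c)

    for c in tree.root.children:
        walk(c)
    return out


def random_additive(rng: np.random.Generator, n: int) -> tuple[DistanceMatrix, PhyloTree]:
    """Random binary tree with positive branch lengths and its path metric."""
    labels = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=l, length=float(rng.uniform(0.1, 1.0))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode(length=float(rng.uniform(0.1, 1.0)), children=[b, a]))
    tree = PhyloTree(root=TreeNode(children=nodes))

    # path lengths by leaf-to-root traversal
    paths = {}

    def depths(node, depth, acc):
        if node.is_leaf:
            acc[node.name] = depth
            return
        for c in node.children:
            depths(c, depth + c.length, acc)

    groups = []
    for c in tree.root.children:
        acc = {}
        depths(c, c.length, acc)
        groups.append(acc)
    dm = {a: {} for a in labels}
    for g1, g2 in itertools.combinations(groups, 2):
        for a, da in g1.items():
            for b, db in g2.items():
                dm[a][b] = dm[b][a] = da + db

    def within(node, depth, acc):
        # distances inside one child subtree
        if node.is_leaf:
            return [(node.name, depth)]
        below = []
        subgroups = [within(c, depth + c.length, acc) for c in node.children]
        for s1, s2 in itertools.combinations(subgroups, 2):
            for a, da in s1:
                for b, db in s2:
                    acc[a][b] = acc[b][a] = da + db - 2 * depth
        for s in subgroups:
            below.extend(s)
        return below

    for c in tree.root.children:
        within(c, c.length, dm)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = dm[a][b]
    return DistanceMatrix(labels=labels, values=m), tree


# ---------------------------------------------------------------------------
# complete deletion
# ---------------------------------------------------------------------------

def test_complete_deletion_hand_case():
    msa = Msa.from_gapped({"a": "AC-T", "b": "AGGT"})
    fa = complete_deletion(msa)
    assert fa.columns == [0, 1, 3]
    assert fa.ncols == 3


def test_complete_deletion_ungapped_keeps_all():
    msa = Msa.from_gapped({"a": "ACDT", "b": "AGGT"})
    assert complete_deletion(msa).ncols == 4


def test_complete_deletion_drops_ambiguity_and_errors_when_empty():
    msa = Msa.from_gapped({"a": "AX", "b": "AG"})
    assert complete_deletion(msa).columns == [0]
    with pytest.raises(ValueError):
        complete_deletion(Msa.from_gapped({"a": "-X", "b": "A-"}))


def test_complete_deletion_matches_bruteforce_scan(bundle):
    fa = complete_deletion(bundle.msa)
    rows = [r.gapped for r in bundle.msa.rows]
    expect = [
        c for c in range(bundle.msa.ncols)
        if all(row[c] in set(jtt.AA_ORDER) for row in rows)
    ]
    assert fa.columns == expect


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_distances_identical_rows_zero():
    msa = Msa.from_gapped({"a": "ACDTACDT", "b": "ACDTACDT"})
    fa = complete_deletion(msa)
    for model in ("p_distance", "poisson", "jtt_ml_pair"):
        assert protein_distance(fa, model).values[0, 1] == pytest.approx(0.0, abs=1e-6)


def test_poisson_closed_form():
    msa = Msa.from_gapped({"a": "ACDTACDT", "b": "ACDTGHKW"})
    fa = complete_deletion(msa)
    assert protein_distance(fa, "p_distance").values[0, 1] == pytest.approx(0.5)
    assert protein_distance(fa, "poisson").values[0, 1] == pytest.approx(
        -np.log(0.5), rel=1e-9
    )


def test_poisson_saturated_is_infinite():
    msa = Msa.from_gapped({"a": "AAAA", "b": "CCCC"})
    fa = complete_deletion(msa)
    with pytest.warns(UserWarning):
        assert np.isinf(protein_distance(fa, "poisson").values[0, 1])


def test_jtt_ml_pair_recovers_simulated_time():
    rng = np.random.default_rng(11)
    model = jtt.default_model()
    t_true = 0.5
    n = 5000
    anc = rng.choice(20, size=n, p=model.pi)
    p = model.transition_matrix(t_true)
    cum = np.cumsum(p, axis=1)
    der = (rng.random(n)[:, None] > cum[anc]).sum(axis=1)
    seqs = {"a": jtt.decode(anc), "b": jtt.decode(der)}
    fa = complete_deletion(Msa.from_gapped(seqs))
    est = protein_distance(fa, "jtt_ml_pair").values[0, 1]
    assert est == pytest.approx(t_true, rel=0.12)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    dm = DistanceMatrix(labels=["a", "b", "c"], values=m)
    tree = neighbor_joining(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["a"] == pytest.approx(0.5 * (5 + 9 - 10))
    assert lengths["b"] == pytest.approx(0.5 * (5 + 10 - 9))
    assert lengths["c"] == pytest.approx(0.5 * (9 + 10 - 5))


def test_nj_additive_four_taxa_exact_vs_topology_scan():
    # additive metric on ((a:1,b:2):1,(c:3,d:4)) with central edge 1
    labels = ["a", "b", "c", "d"]
    m = np.array(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 5 + 2, 0]], dtype=float
    )
    m[3, 2] = 7.0
    m[2, 3] = 7.0
    dm = DistanceMatrix(labels=labels, values=m)
    tree = neighbor_joining(dm)
    # oracle: least-squares over the three unrooted topologies
    best = None
    for pair in (("a", "b"), ("a", "c"), ("a", "d")):
        rest = [x for x in labels if x not in pair]
        i, j = (labels.index(x) for x in pair)
        k, l = (labels.index(x) for x in rest)
        # four-point: internal edge for split ij|kl
        e = 0.5 * (
            (m[i, k] + m[j, l] + m[i, l] + m[j, k]) / 2.0 - m[i, j] - m[k, l]
        )
        best = min(best or (np.inf, None), (abs(min(e, 0)) - e, frozenset(pair)))
    assert frozenset(["a", "b"]) in splits(tree)
    # branch lengths are exact on additive input: path distances reproduce m
    def path_lengths(tree):
        import itertools as it

        acc = {a: {} for a in labels}

        def walk(node, depth, found):
            if node.is_leaf:
                return [(node.name, depth)]
            below = []
            gs = [walk(c, depth + c.length, found) for c in node.children]
            for g1, g2 in it.combinations(gs, 2):
                for a, da in g1:
                    for b, db in g2:
                        acc[a][b] = acc[b][a] = da + db - 2 * depth
            for g in gs:
                below.extend(g)
            return below

        walk(tree.root, 0.0, acc)
        return acc

    acc = path_lengths(tree)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                assert acc[a][b] == pytest.approx(m[i, j], abs=1e-9)


def test_nj_recovers_random_additive_trees():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        dm, true_tree = random_additive(rng, n)
        tree = neighbor_joining(dm)
        assert splits(tree) == splits(true_tree)


def test_nj_agrees_with_skbio_on_random_matrix():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(3)
    n = 7
    dm, _ = random_additive(rng, n)
    ours = neighbor_joining(dm)
    sk = sk_nj(SkDM(dm.values, ids=dm.labels))
    sk_splits = set()
    for node in sk.non_tips():
        names = frozenset(t.name for t in node.tips())
        allset = frozenset(dm.labels)
        if 2 <= len(names) <= n - 2:
            sk_splits.add(min(names, allset - names,
                              key=lambda s: (len(s), sorted(s))))
    assert splits(ours) == sk_splits


def test_nj_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0.0]]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def brute_force_loglik(tree: PhyloTree, fa, model) -> float:
    """Sum over all internal-state assignments (<= 2 internal nodes)."""
    leaves = {name: fa.matrix[i] for i, name in enumerate(fa.ids)}
    root = tree.root
    internal_child = [c for c in root.children if not c.is_leaf]
    leaf_children = [c for c in root.children if c.is_leaf]
    total = 0.0
    for site in range(fa.ncols):
        site_l = 0.0
        for x in range(20):
            term = model.pi[x]
            for c in leaf_children:
                term *= model.transition_matrix(c.length)[x, leaves[c.name][site]]
            for c in internal_child:
                inner = 0.0
                for y in range(20):
                    t = model.transition_matrix(c.length)[x, y]
                    for g in c.children:
                        t *= model.transition_matrix(g.length)[y, leaves[g.name][site]]
                    inner += t
                term *= inner
            site_l += term
        total += np.log(site_l)
    return total


@pytest.fixture(scope="module")
def four_taxon_case():
    rng = np.random.default_rng(17)
    seqs = {
        name: "".join(jtt.AA_ORDER[i] for i in rng.choice(20, size=10))
        for name in "ABCD"
    }
    fa = complete_deletion(Msa.from_gapped(seqs))
    tree = read_newick("(A:0.2,B:0.4,(C:0.3,D:0.1):0.25);")
    return tree, fa


def test_pruning_matches_exhaustive_enumeration(four_taxon_case):
    tree, fa = four_taxon_case
    model = jtt.default_model()
    assert tree_loglik(tree, fa, model) == pytest.approx(
        brute_force_loglik(tree, fa, model), abs=1e-9
    )


def test_loglik_invariant_under_rerooting(four_taxon_case):
    _, fa = four_taxon_case
    t1 = read_newick("(A:0.2,B:0.4,(C:0.3,D:0.1):0.25);")
    t2 = read_newick("(C:0.3,D:0.1,(A:0.2,B:0.4):0.25);")
    assert abs(tree_loglik(t1, fa) - tree_loglik(t2, fa)) < 1e-8


def test_zero_length_star_identical_sequences_closed_form():
    seq = "ACDEFGHIKL"
    msa = Msa.from_gapped({n: seq for n in "ABC"})
    fa = complete_deletion(msa)
    tree = read_newick("(A:0.0,B:0.0,C:0.0);")
    model = jtt.default_model()
    expect = sum(np.log(model.pi[jtt.AA_ORDER.index(c)]) for c in seq)
    assert tree_loglik(tree, fa, model) == pytest.approx(expect, abs=1e-9)


def test_loglik_decreases_away_from_better_branch_length():
    rng = np.random.default_rng(23)
    model = jtt.default_model()
    # simulate a pair at t=0.3 and scan a two-leaf "tree" likelihood
    n = 400
    anc = rng.choice(20, size=n, p=model.pi)
    p = model.transition_matrix(0.3)
    cum = np.cumsum(p, axis=1)
    der = (rng.random(n)[:, None] > cum[anc]).sum(axis=1)
    seqs = {"a": jtt.decode(anc), "b": jtt.decode(der), "c": jtt.decode(anc)}
    fa = complete_deletion(Msa.from_gapped(seqs))

    def ll(t):
        tree = read_newick(f"(a:0.0,c:0.0,b:{t});")
        return tree_loglik(tree, fa, model)

    lls = [ll(t) for t in (0.05, 0.3, 1.5)]
    assert lls[1] > lls[0] and lls[1] > lls[2]


def test_leaf_mismatch_rejected(four_taxon_case):
    tree, fa = four_taxon_case
    bad = read_newick("(A:0.1,B:0.1,(C:0.1,X:0.1):0.1);")
    with pytest.raises(ValueError):
        tree_loglik(bad, fa)


# ---------------------------------------------------------------------------
# newick round trip
# ---------------------------------------------------------------------------

def test_newick_parse_example():
    tree = read_newick("(A:1,B:1,(C:1,D:1):1);")
    assert sorted(tree.leaf_names()) == ["A", "B", "C", "D"]
    internal = [c for c in tree.root.children if not c.is_leaf]
    assert len(internal) == 1 and len(internal[0].children) == 2


def test_newick_round_trip_random_trees():
    rng = np.random.default_rng(9)
    for _ in range(10):
        n = int(rng.integers(4, 10))
        _, tree = random_additive(rng, n)
        text = write_newick(tree)
        again = read_newick(text)
        assert splits(again) == splits(tree)
        assert write_newick(again) == text


def test_newick_malformed_rejected():
    from pgm_paralogs.phylo import NewickParseError

    with pytest.raises(NewickParseError):
        read_newick("(A:1,B:1")


def test_distance_matrix_file_round_trip(tmp_path):
    from pgm_paralogs.phylo import read_distance_matrix, write_distance_matrix

    rng = np.random.default_rng(31)
    dm, _ = random_additive(rng, 5)
    path = tmp_path / "dm.tsv"
    write_distance_matrix(dm, path)
    again = read_distance_matrix(path)
    assert again.labels == dm.labels
    assert np.allclose(again.values, dm.values)
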