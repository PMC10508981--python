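import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltrarch.phylo import (
    LineageFlags,
    MultipleAlignment,
    SupportedTree,
    TreeNode,
    align_pair,
    bootstrap_support,
    compute_lineage_flags,
    concat_alignment,
    credible_clusters,
    distance_matrix,
    filter_lineages,
    fitch_parsimony,
    nj_tree,
    pairwise_identity,
    parse_newick,
    progressive_align,
    test_monophyly as monophyly,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# random-tree helpers (test-side oracles)

def random_binary_tree(taxa, rng, blmin=0.1, blmax=1.0):
    nodes = [TreeNode(name=t, length=float(rng.uniform(blmin, blmax))) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        merged = TreeNode(children=[b, a], length=float(rng.uniform(blmin, blmax)))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes)
    return SupportedTree(root=root)


def path_distances(tree, taxa):
    """Tip-to-tip path length matrix via per-tip root paths (oracle)."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                pa, pb = paths[a], paths[b]
                shared = 0
                for x, y in zip(pa, pb):
                    if x is y:
                        shared += 1
                    else:
                        break
                d = sum(nd.length for nd in pa[shared:]) + sum(nd.length for nd in pb[shared:])
                D[i, j] = D[j, i] = d
    return D


def fitch_bruteforce(tree, tip_states, labels):
    """Exhaustive minimum over all internal-node labelings."""
    internals = [n for n in tree.root.postorder() if not n.is_leaf]
    tips = [n for n in tree.root.postorder() if n.is_leaf]
    best = None
    for assignment in itertools.product(labels, repeat=len(internals)):
        state = dict(zip([id(n) for n in internals], assignment))
        cost = 0
        for n in internals:
            for c in n.children:
                if c.is_leaf:
                    cost += min(t != state[id(n)] for t in tip_states[c.name])
                else:
                    cost += state[id(c)] != state[id(n)]
        if best is None or cost < best:
            best = cost
    return best


# ---------------------------------------------------------------------------

class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        aln = progressive_align({"a": "MKVLI", "b": "MKVLI"})
        assert aln.rows == ("MKVLI", "MKVLI")

    def test_single_gap_opposite_deletion(self):
        aln = progressive_align({"a": "ACDEFG", "b": "ACEFG"})
        ra, rb = aln.row("a"), aln.row("b")
        assert ra == "ACDEFG"
        assert rb.replace("-", "") == "ACEFG"
        assert rb.count("-") == 1
        assert rb[ra.index("D")] == "-"

    def test_column_count_at_least_max_length(self):
        seqs = {"a": "MKVLIACDEF", "b": "MKVACDEF", "c": "MKVLIACD"}
        aln = progressive_align(seqs)
        assert aln.n_cols >= max(len(s) for s in seqs.values())

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "MKV"})

    def test_pairwise_score_matches_oracle(self):
        # align_pair must reproduce the optimal NW score (independent DP)
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list(AA), int(rng.integers(5, 40))))
            b = "".join(rng.choice(list(AA), int(rng.integers(5, 40))))
            ra, rb = align_pair(a, b)
            score = sum(
                -4.0 if "-" in (x, y) else blosum[x][y] for x, y in zip(ra, rb)
            )
            n, m = len(a), len(b)
            dp = np.full((n + 1, m + 1), -np.inf)
            dp[0, :] = -4.0 * np.arange(m + 1)
            dp[:, 0] = -4.0 * np.arange(n + 1)
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    dp[i, j] = max(dp[i - 1, j - 1] + blosum[a[i - 1]][b[j - 1]],
                                   dp[i - 1, j] - 4.0, dp[i, j - 1] - 4.0)
            assert score == pytest.approx(dp[n, m])


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("MKVLI", "MKVLI") == 100.0

    def test_one_mismatch_in_ten(self):
        assert pairwise_identity("AAAAAAAAAA", "AAAAAAAAAC") == 90.0

    def test_all_gap_overlap(self):
        assert pairwise_identity("AA--", "--AA") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("AA", "AAA")


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        aln = MultipleAlignment(ids=("a", "b", "c"), rows=("MKV", "MKV", "MKV"))
        assert np.allclose(distance_matrix(aln), 0.0)

    def test_two_in_ten(self):
        aln = MultipleAlignment(
            ids=("a", "b", "c"),
            rows=("AAAAAAAAAA", "AAAAAAAACC", "AAAAAAAAAA"),
        )
        D = distance_matrix(aln)
        assert D[0, 1] == pytest.approx(0.2)

    def test_symmetry_on_star_family(self):
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list(AA), 100))
        rows = []
        for _ in range(6):
            chars = [AA[rng.integers(20)] if rng.random() < 0.1 else c for c in base]
            rows.append("".join(chars))
        aln = MultipleAlignment(ids=tuple("abcdef"), rows=tuple(rows))
        D = distance_matrix(aln)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_zero_comparable_pair_filled(self):
        aln = MultipleAlignment(ids=("a", "b", "c"), rows=("AA--", "--AA", "AAAA"))
        D = distance_matrix(aln)
        assert D[0, 1] == pytest.approx(0.1)  # max observed (0.0) + 0.1


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        tree = nj_tree(D, ["A", "B", "C"])
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_four_taxon_additive(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1) by hand
        D = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = nj_tree(D, ["A", "B", "C", "D"])
        assert frozenset({"C", "D"}) in tree.bipartitions() or frozenset({"A", "B"}) in tree.bipartitions()
        taxa = ["A", "B", "C", "D"]
        assert np.allclose(path_distances(tree, taxa), D, atol=1e-12)

    def test_identical_taxa_zero_cherry(self):
        D = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 2], [1, 1, 2, 0]], float)
        tree = nj_tree(D, ["A", "B", "C", "D"])
        bip = tree.bipartitions()
        cherry = frozenset({"C", "D"}) if frozenset({"C", "D"}) in bip else frozenset({"A", "B"})
        assert cherry in bip

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(D, ["A", "B", "C"])

    def test_additive_recovery_100_random_6_taxon(self):
        taxa = ["t0", "t1", "t2", "t3", "t4", "t5"]
        for seed in range(100):
            rng = np.random.default_rng(seed)
            true = random_binary_tree(taxa, rng)
            D = path_distances(true, taxa)
            est = nj_tree(D, taxa)
            assert set(est.bipartitions()) == set(true.bipartitions())
            assert np.allclose(path_distances(est, taxa), D, atol=1e-9)


def two_clade_alignment(seed=0, n_cols=150, per=4, deep=0.3, shallow=0.05):
    """Alignment simulated on a known two-clade tree (test-side generator)."""
    rng = np.random.default_rng(seed)
    root = "".join(rng.choice(list(AA), n_cols))
    mut = lambda s, r: "".join(AA[rng.integers(20)] if rng.random() < r else c for c in s)
    a_anc, b_anc = mut(root, deep), mut(root, deep)
    rows = {f"a{i}": mut(a_anc, shallow) for i in range(per)}
    rows |= {f"b{i}": mut(b_anc, shallow) for i in range(per)}
    return MultipleAlignment(ids=tuple(rows), rows=tuple(rows.values()))


class TestBootstrap:

    def test_clear_split_high_support(self):
        aln = two_clade_alignment()
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        ok, support = monophyly(tree, {"a0", "a1", "a2", "a3"})
        assert ok and support >= 95

    def test_single_replicate_supports_binary(self):
        aln = two_clade_alignment(seed=3)
        tree = bootstrap_support(aln, n_reps=1, seed=1)
        sups = {n.support for n in tree.root.postorder() if n.support is not None}
        assert sups <= {0.0, 100.0}

    def test_seed_determinism(self):
        aln = two_clade_alignment(seed=4)
        t1 = bootstrap_support(aln, n_reps=25, seed=9)
        t2 = bootstrap_support(aln, n_reps=25, seed=9)
        assert t1.newick() == t2.newick()

    def test_taxon_order_invariance(self):
        aln = two_clade_alignment(seed=8)
        perm = np.random.default_rng(0).permutation(len(aln.ids))
        shuffled = MultipleAlignment(
            ids=tuple(aln.ids[i] for i in perm), rows=tuple(aln.rows[i] for i in perm)
        )
        t1 = bootstrap_support(aln, n_reps=25, seed=2)
        t2 = bootstrap_support(shuffled, n_reps=25, seed=2)
        assert t1.newick() == t2.newick()

    def test_nonpositive_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(two_clade_alignment(), n_reps=0, seed=0)


class TestCredibleClusters:
    @staticmethod
    def _tree_with_supports(supports):
        aln = two_clade_alignment(seed=11, per=3)
        tree = bootstrap_support(aln, n_reps=10, seed=0)
        nodes = [n for n in tree.root.postorder() if n.support is not None]
        for n, s in zip(nodes, supports):
            n.support = s
        for n in nodes[len(supports):]:
            n.support = 0.0
        return tree

    def test_all_100_returns_all(self):
        aln = two_clade_alignment(seed=12)
        tree = bootstrap_support(aln, n_reps=10, seed=0)
        for n in tree.root.postorder():
            if n.support is not None:
                n.support = 100.0
        assert len(credible_clusters(tree, 95)) == len(tree.bipartitions())

    def test_boundary_inclusive(self):
        tree = self._tree_with_supports([94.0, 95.0, 96.0])
        n_internal = len(tree.bipartitions())
        assert n_internal >= 3
        got = credible_clusters(tree, 95)
        assert len(got) == 2

    def test_star_tree_empty(self):
        root = TreeNode(children=[TreeNode(name=t) for t in "abcd"])
        assert credible_clusters(SupportedTree(root=root), 95) == []


class TestMonophyly:
    def test_true_clade(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ok, _ = monophyly(tree, {"A", "B"})
        assert ok

    def test_false_clade(self):
        tree = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        ok, _ = monophyly(tree, {"A", "B"})
        assert not ok

    def test_tips_outside_tree_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ValueError):
            monophyly(tree, {"A", "Z"})

    def test_simulated_arh_clade(self):
        aln = two_clade_alignment(seed=21)
        tree = bootstrap_support(aln, n_reps=100, seed=3)
        ok, support = monophyly(tree, {f"b{i}" for i in range(4)})
        assert ok and support >= 95


class TestConcat:
    def test_same_ids_column_sum(self):
        a = MultipleAlignment(ids=("x", "y", "z"), rows=("AAA", "CCC", "GGG"))
        b = MultipleAlignment(ids=("x", "y", "z"), rows=("TT", "TT", "TT"))
        cat = concat_alignment(a, b)
        assert cat.n_cols == 5
        assert cat.partition_boundary == 3

    def test_partial_overlap(self):
        a = MultipleAlignment(ids=("A", "B", "C"), rows=("AA", "CC", "GG"))
        b = MultipleAlignment(ids=("B", "C", "D"), rows=("TT", "TT", "TT"))
        assert concat_alignment(a, b).ids == ("B", "C")

    def test_empty_intersection_rejected(self):
        a = MultipleAlignment(ids=("A",), rows=("AA",))
        b = MultipleAlignment(ids=("B",), rows=("TT",))
        with pytest.raises(ValueError):
            concat_alignment(a, b)

    def test_concat_tree_recovers_topology(self):
        a = two_clade_alignment(seed=31)
        b = two_clade_alignment(seed=32)
        cat = concat_alignment(a, b)
        tree = bootstrap_support(cat, n_reps=50, seed=1)
        ok, support = monophyly(tree, {f"a{i}" for i in range(4)})
        assert ok and support >= 95


class TestFilterLineages:
    @pytest.mark.parametrize(
        "c1,c2,c3,removed",
        [
            (False, False, False, False),
            (True, False, False, False),
            (False, True, False, False),
            (False, False, True, False),
            (True, True, False, True),
            (True, False, True, True),
            (False, True, True, True),
            (True, True, True, True),
        ],
    )
    def test_truth_table(self, c1, c2, c3, removed):
        flags = LineageFlags("x", c1, c2, c3)
        assert flags.removed is removed
        retained, out = filter_lineages([flags])
        assert (len(out) == 1) is removed

    def test_monotonicity(self):
        for bits in itertools.product([False, True], repeat=3):
            base = LineageFlags("x", *bits)
            for k in range(3):
                flipped = list(bits)
                flipped[k] = True
                up = LineageFlags("x", *flipped)
                assert not (base.removed and not up.removed)

    def test_compute_flags_c1_c2(self):
        flags = compute_lineage_flags(
            lineage_ids=["a", "b", "c"],
            clusters=[frozenset({"a", "b"})],
            taxon_group={"a": "g1", "b": "g1", "c": "g1"},
            structures={"a": "S1", "b": "S1", "c": "S2"},
            artifact_flags={"c": True},
        )
        by = {f.lineage_id: f for f in flags}
        assert not by["a"].c1_discordant_clustering
        assert by["c"].c1_discordant_clustering
        assert by["c"].c2_unique_structure and by["c"].c3_whole_contig_or_no_ltr
        assert by["c"].removed and not by["a"].removed


class TestFitch:
    def test_all_identical_zero_changes(self):
        tree = parse_newick("((a,b),(c,d));")
        changes, _ = fitch_parsimony(tree, {t: {"S1"} for t in "abcd"})
        assert changes == 0

    def test_two_clades_one_change(self):
        tree = parse_newick("((a,b),(c,d));")
        changes, _ = fitch_parsimony(
            tree, {"a": {"S1"}, "b": {"S1"}, "c": {"S2"}, "d": {"S2"}}
        )
        assert changes == 1

    def test_missing_tip_state_rejected(self):
        tree = parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            fitch_parsimony(tree, {"a": {"S1"}, "b": {"S1"}, "c": {"S2"}})

    def test_matches_bruteforce_50_seeds(self):
        labels = ["S1", "S2", "S3"]
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 7))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(taxa, rng)
            tip_states = {
                t: set(rng.choice(labels, size=int(rng.integers(1, 3)), replace=False))
                for t in taxa
            }
            got, _ = fitch_parsimony(tree, tip_states)
            assert got == fitch_bruteforce(tree, tip_states, labels)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_changes_bounded_by_tips(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(5)]
        tree = random_binary_tree(taxa, rng)
        tip_states = {t: {str(rng.integers(4))} for t in taxa}
        changes, _ = fitch_parsimony(tree, tip_states)
        assert 0 <= changes <= len(taxa) - 1


class TestNewickIO:
    def test_round_trip_supports(self):
        aln = two_clade_alignment(seed=41, per=3)
        tree = bootstrap_support(aln, n_reps=20, seed=7)
        text = tree.newick()
        re_read = parse_newick(text)
        assert re_read.tips() == tree.tips()
        assert set(re_read.bipartitions()) == set(tree.bipartitions())
        for key, node in tree.bipartitions().items():
            assert re_read.bipartitions()[key].support == pytest.approx(node.support)
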