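import math

import numpy as np
import pytest
from scipy import stats

from fmo_roadmap.core_io import AA20, MultipleAlignment
from fmo_roadmap.phylo import (
    DistanceMatrix,
    SaturationError,
    alignment_distance_matrix,
    annotate_support,
    bootstrap_alignment,
    branch_support,
    midpoint_root,
    neighbor_joining,
    poisson_distance,
    read_newick,
    tree_splits,
    write_newick,
)

from oracles import brute_force_transfer_distance


def random_tree(rng, n_leaves, min_len=0.1, max_len=1.0):
    """Random binary topology by sequential joining, uniform branch lengths."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(min_len, max_len))
        b.length = float(rng.uniform(min_len, max_len))
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    for node in nodes:
        node.length = float(rng.uniform(min_len, max_len))
    return TreeNode(children=nodes)


def tip_distance_matrix(tree):
    dm = tree.tip_tip_distances()
    labels = tuple(dm.ids)
    return DistanceMatrix(labels=labels, values=np.asarray(dm.data, dtype=float))


class TestPoissonDistance:
    def test_identical_rows_give_zero(self):
        assert poisson_distance("ACDEF", "ACDEF") == 0.0

    def test_half_mismatch_closed_form(self):
        assert poisson_distance("AAAA", "AACC") == pytest.approx(math.log(2), abs=1e-4)

    def test_gap_and_x_columns_skipped(self, rng):
        # distances must agree with a direct column count
        for _ in range(20):
            cols = rng.integers(0, 22, size=(2, 60))
            chars = AA20 + "X-"
            a = "".join(chars[i] for i in cols[0])
            b = "".join(chars[i] for i in cols[1])
            scored = [
                (ca, cb) for ca, cb in zip(a, b)
                if ca not in "X-" and cb not in "X-"
            ]
            if not scored:
                with pytest.raises(ValueError):
                    poisson_distance(a, b)
                continue
            p = sum(ca != cb for ca, cb in scored) / len(scored)
            if p >= 0.95:
                with pytest.raises(SaturationError):
                    poisson_distance(a, b)
            else:
                assert poisson_distance(a, b) == pytest.approx(-math.log(1 - p))

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            poisson_distance("AAAAAAAAAAAAAAAAAAAA", "CCCCCCCCCCCCCCCCCCCC")

    def test_matrix_route_matches_scalar_route(self, rng):
        rows = tuple(
            (f"r{i}", "".join(AA20[j] for j in rng.integers(0, 4, size=80)))
            for i in range(5)
        )
        msa = MultipleAlignment(rows=rows)
        dm = alignment_distance_matrix(msa)
        for i in range(5):
            for j in range(5):
                expected = poisson_distance(rows[i][1], rows[j][1]) if i != j else 0.0
                assert dm.values[i, j] == pytest.approx(expected)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["A"] == pytest.approx(0.05, abs=1e-12)
        assert lengths["B"] == pytest.approx(0.15, abs=1e-12)
        assert lengths["C"] == pytest.approx(0.25, abs=1e-12)

    def test_four_taxon_additive_matrix_recovers_split_and_lengths(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(labels=("A", "B", "C", "D"), values=d))
        assert tree_splits(tree) == {frozenset({"A", "B"})}
        recovered = tip_distance_matrix(tree)
        order = [recovered.labels.index(x) for x in ("A", "B", "C", "D")]
        assert np.allclose(recovered.values[np.ix_(order, order)], d, atol=1e-9)

    def test_exact_on_random_additive_matrices(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            true_tree = random_tree(rng, n)
            dm = tip_distance_matrix(true_tree)
            nj = neighbor_joining(dm)
            recovered = tip_distance_matrix(nj)
            order = [recovered.labels.index(x) for x in dm.labels]
            assert np.allclose(recovered.values[np.ix_(order, order)], dm.values, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(labels=("A", "B"), values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="3"):
            neighbor_joining(dm)


class TestMidpointRoot:
    def test_two_leaf_tree_balances(self):
        tree = read_newick("(A:1,B:3);")
        rooted = midpoint_root(tree)
        depths = sorted(rooted.distance(t) for t in rooted.tips())
        assert depths == pytest.approx([2.0, 2.0])

    def test_four_taxon_example_roots_on_longest_path(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(labels=("A", "B", "C", "D"), values=d))
        rooted = midpoint_root(tree)
        depths = {t.name: rooted.distance(t) for t in rooted.tips()}
        assert depths["B"] == pytest.approx(3.5)
        assert depths["D"] == pytest.approx(3.5)

    def test_balances_random_trees(self, rng):
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 10)))
            rooted = midpoint_root(tree)
            depths = sorted(rooted.distance(t) for t in rooted.tips())
            assert abs(depths[-1] - depths[-2]) < 1e-9

    def test_all_zero_lengths_rejected(self):
        tree = read_newick("(A:0,B:0,(C:0,D:0):0);")
        with pytest.raises(ValueError, match="zero"):
            midpoint_root(tree)


class TestBootstrap:
    def test_replicates_preserve_shape(self):
        msa = MultipleAlignment(rows=(("a", "ACDE"), ("b", "ACDF")))
        reps = bootstrap_alignment(msa, 5, seed=3)
        assert len(reps) == 5
        assert all(r.n_rows == 2 and r.n_columns == 4 for r in reps)

    def test_same_seed_reproduces_replicates(self):
        msa = MultipleAlignment(rows=(("a", "ACDE"), ("b", "ACDF")))
        r1 = bootstrap_alignment(msa, 10, seed=7)
        r2 = bootstrap_alignment(msa, 10, seed=7)
        assert [r.rows for r in r1] == [r.rows for r in r2]

    def test_column_sampling_is_uniform(self):
        # 4 distinguishable columns; chi-square on sampled frequencies
        msa = MultipleAlignment(rows=(("a", "ACDE"),))
        counts = {c: 0 for c in "ACDE"}
        for rep in bootstrap_alignment(msa, 10_000, seed=11):
            for ch in rep.rows[0][1]:
                counts[ch] += 1
        observed = np.array([counts[c] for c in "ACDE"])
        _, pvalue = stats.chisquare(observed)
        assert pvalue > 0.01


class TestBranchSupport:
    def test_branch_in_every_replicate_has_full_support(self):
        ref = read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        reps = [read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);") for _ in range(10)]
        sv = branch_support(ref, reps)
        for support in sv.supports.values():
            assert support.classical == 1.0 and support.tbe == 1.0

    def test_moved_leaf_zeroes_cherry_support(self):
        ref = read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        rep = read_newick("((A:1,B:1):1,(C:1,E:1):1,D:1);")
        sv = branch_support(ref, [rep])
        de = sv.supports[frozenset({"D", "E"})]
        assert de.classical == 0.0 and de.tbe == 0.0

    def test_tbe_equals_classical_on_cherries(self, rng):
        ref = random_tree(rng, 8)
        reps = [random_tree(rng, 8) for _ in range(20)]
        sv = branch_support(ref, reps)
        for split, support in sv.supports.items():
            if support.p == 2:
                assert support.tbe == pytest.approx(support.classical)

    def test_tbe_at_least_classical_everywhere(self, rng):
        ref = random_tree(rng, 10)
        reps = [random_tree(rng, 10) for _ in range(25)]
        sv = branch_support(ref, reps)
        assert sv.supports
        for support in sv.supports.values():
            assert support.tbe >= support.classical - 1e-12

    def test_transfer_distance_matches_bruteforce_oracle(self, rng):
        from fmo_roadmap.phylo import _transfer_distance

        for _ in range(10):
            ref = random_tree(rng, 9)
            rep = random_tree(rng, 9)
            rep_splits = tree_splits(rep, include_trivial=True)
            for split in tree_splits(ref):
                got = _transfer_distance(split, rep_splits, 9)
                assert got == brute_force_transfer_distance(split, rep)

    def test_support_invariant_under_replicate_permutation(self, rng):
        ref = random_tree(rng, 7)
        reps = [random_tree(rng, 7) for _ in range(9)]
        sv1 = branch_support(ref, reps)
        sv2 = branch_support(ref, list(reversed(reps)))
        assert sv1.supports == sv2.supports

    def test_leaf_set_mismatch_names_difference(self):
        ref = read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        rep = read_newick("((A:1,B:1):1,C:1,(D:1,F:1):1);")
        with pytest.raises(ValueError, match="E") as err:
            branch_support(ref, [rep])
        assert "F" in str(err.value)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_and_labels(self, rng):
        ref = random_tree(rng, 8)
        reps = [random_tree(rng, 8) for _ in range(5)]
        annotated = annotate_support(midpoint_root(ref), branch_support(ref, reps))
        text = write_newick(annotated)
        back = read_newick(text)
        assert tree_splits(back) == tree_splits(annotated)
        d1 = tip_distance_matrix(annotated)
        d2 = tip_distance_matrix(back)
        order = [d2.labels.index(x) for x in d1.labels]
        assert np.allclose(d2.values[np.ix_(order, order)], d1.values, atol=1e-6)
        labels = {n.name for n in back.non_tips(include_self=False) if n.name}
        assert labels == {n.name for n in annotated.non_tips(include_self=False) if n.name}
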