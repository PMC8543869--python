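import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from itemclust import (
    SimulationConfig,
    agglomerate,
    association_matrix,
    cut,
    diana,
    export_newick,
    fanny,
    simulate_dataset,
    to_dissimilarity,
)
from itemclust.cluster import LINKAGE_METHODS, MergeTree, Partition, _fanny_objective
from oracles import naive_agglomerate, random_symmetric


class TestAgglomerate:
    def test_forced_merge_complete(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        tree = agglomerate(d, "complete")
        assert tree.merges[0][:2] == (0, 1)
        assert tree.merges[0][2] == pytest.approx(0.1)
        assert tree.merges[1][2] == pytest.approx(0.9)

    def test_forced_merge_average(self):
        d = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        tree = agglomerate(d, "average")
        assert tree.merges[1][2] == pytest.approx(0.9)

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_naive_oracle_small_instances(self, method):
        rng = np.random.default_rng(hash(method) % 2**32)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            mat = random_symmetric(rng, n)
            tree = agglomerate(mat, method)
            oracle = naive_agglomerate(mat, method)
            for (a, b, h), (oa, ob, oh) in zip(tree.merges, oracle):
                assert (a, b) == (oa, ob)
                assert h == pytest.approx(oh, abs=1e-9)

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_monotone_heights(self, method, rng):
        mat = random_symmetric(rng, 12)
        heights = agglomerate(mat, method).heights
        assert np.all(np.diff(heights) >= -1e-12)

    @pytest.mark.parametrize("method", LINKAGE_METHODS)
    def test_permutation_equivariance(self, method, rng):
        mat = random_symmetric(rng, 10)
        perm = rng.permutation(10)
        permuted = mat[np.ix_(perm, perm)]
        for k in range(1, 11):
            base = cut(agglomerate(mat, method), k).assignment
            shuffled = cut(agglomerate(permuted, method), k).assignment
            assert adjusted_rand_score(base[perm], shuffled) == pytest.approx(1.0)

    def test_complete_merge_order_invariant_to_monotone_transform(self, rng):
        mat = random_symmetric(rng, 9)
        base = agglomerate(mat, "complete")
        transformed = agglomerate(mat**3, "complete")  # strictly increasing on [0, 1]
        assert [m[:2] for m in base.merges] == [m[:2] for m in transformed.merges]

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            agglomerate(np.array([[0, 1.0], [2.0, 0]]), "complete")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            agglomerate(np.array([[0, -1.0], [-1.0, 0]]), "complete")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            agglomerate(np.zeros((2, 2)), "single")


class TestDiana:
    def test_two_tight_pairs_split_first(self):
        d = np.full((4, 4), 0.95)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.05
        np.fill_diagonal(d, 0.0)
        tree = diana(d)
        part = cut(tree, 2)
        assert part.assignment[0] == part.assignment[1]
        assert part.assignment[2] == part.assignment[3]
        assert part.assignment[0] != part.assignment[2]

    def test_two_items(self):
        tree = diana(np.array([[0, 0.3], [0.3, 0]]))
        assert tree.merges == [(0, 1, 0.3)]

    def test_all_identical_zero_heights(self):
        tree = diana(np.zeros((5, 5)))
        assert np.all(tree.heights == 0.0)
        assert cut(tree, 1).k == 1

    def test_split_criterion_exhaustive_n4(self, rng):
        # first DIANA split of a 4-item two-pair geometry matches the best
        # 2-subset split by the within-diameter criterion
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        part = cut(diana(d), 2)
        groups = frozenset(frozenset(np.where(part.assignment == c)[0]) for c in (1, 2))
        assert groups == frozenset([frozenset({0, 1}), frozenset({2, 3})])

    def test_recovers_planted_blocks(self, planted_assoc):
        ds, truth, _, dis = planted_assoc
        part = cut(diana(dis), 7)
        truth_vec = [truth[l] for l in part.labels]
        assert adjusted_rand_score(truth_vec, part.assignment) == pytest.approx(1.0)


class TestFanny:
    def test_duplicated_pairs_beat_alternative_partitions(self):
        d = np.full((4, 4), 0.95)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.05
        np.fill_diagonal(d, 0.0)
        fm = fanny(d, 2)
        hard = fm.harden()
        assert hard.assignment[0] == hard.assignment[1] != hard.assignment[2]
        # objective of the recovered split beats the 2 other balanced hard splits
        for split in ([0, 1, 0, 1], [0, 1, 1, 0]):
            u = np.zeros((4, 2))
            u[np.arange(4), split] = 1.0
            assert fm.objective < _fanny_objective(u, d, 2.0)

    def test_zero_matrix_uniform(self):
        fm = fanny(np.zeros((5, 5)), 2)
        assert fm.objective == 0.0
        np.testing.assert_allclose(fm.u, np.full((5, 2), 0.5))

    def test_row_sums_one(self, planted_assoc):
        _, _, _, dis = planted_assoc
        fm = fanny(dis, 7)
        np.testing.assert_allclose(fm.u.sum(axis=1), 1.0, atol=1e-9)
        assert 0.0 <= fm.dunn <= 1.0

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            fanny(np.zeros((4, 4)), 4)
        with pytest.raises(ValueError):
            fanny(np.zeros((4, 4)), 1)


class TestCut:
    def test_k1_and_kn(self, rng):
        mat = random_symmetric(rng, 8)
        tree = agglomerate(mat, "ward_d2")
        assert cut(tree, 1).k == 1
        singles = cut(tree, 8)
        assert singles.k == 8
        assert sorted(singles.assignment) == list(range(1, 9))

    @pytest.mark.parametrize("k", range(1, 11))
    def test_every_k_has_k_clusters(self, k, rng):
        mat = random_symmetric(rng, 10)
        for method in LINKAGE_METHODS:
            assert cut(agglomerate(mat, method), k).k == k

    def test_out_of_range(self, rng):
        tree = agglomerate(random_symmetric(rng, 5), "complete")
        with pytest.raises(ValueError):
            cut(tree, 0)
        with pytest.raises(ValueError):
            cut(tree, 6)

    def test_deterministic_labelling_by_first_leaf(self, rng):
        mat = random_symmetric(rng, 7)
        part = cut(agglomerate(mat, "average"), 3)
        seen = []
        for a in part.assignment:
            if a not in seen:
                seen.append(a)
        assert seen == sorted(seen)

    def test_planted_recovery_ward(self):
        hits = 0
        for seed in range(20):
            ds, truth = simulate_dataset(SimulationConfig(seed=seed))
            dis = to_dissimilarity(association_matrix(ds))
            part = cut(agglomerate(dis, "ward_d2"), 7)
            truth_vec = [truth[l] for l in part.labels]
            if adjusted_rand_score(truth_vec, part.assignment) == 1.0:
                hits += 1
        assert hits >= 19


class TestNewick:
    def test_two_leaf_shape(self):
        tree = MergeTree(labels=["A", "B"], merges=[(0, 1, 0.4)], method="complete")
        assert export_newick(tree) == "(A:0.2,B:0.2);"

    def test_leaf_count_29(self, planted_assoc):
        _, _, _, dis = planted_assoc
        nwk = export_newick(agglomerate(dis, "ward_d2"))
        import dendropy

        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(t.leaf_nodes()) == 29

    def test_roundtrip_topology(self, rng):
        import dendropy

        for _ in range(10):
            n = int(rng.integers(3, 10))
            mat = random_symmetric(rng, n)
            tree = agglomerate(mat, "average")
            parsed = dendropy.Tree.get(data=export_newick(tree), schema="newick", preserve_underscores=True)
            leaf_names = sorted(l.taxon.label for l in parsed.leaf_nodes())
            assert leaf_names == sorted(tree.labels)
            # compare clades (topology up to rotation)
            clades = set()
            for node in parsed.postorder_node_iter():
                if not node.is_leaf():
                    clades.add(frozenset(l.taxon.label for l in node.leaf_iter()))
            expected = set()
            for step in range(len(tree.merges)):
                leaves = tree.leaves_under(n + step)
                expected.add(frozenset(tree.labels[i] for i in leaves))
            assert clades == expected


class TestPartitionType:
    def test_invalid_assignment_rejected(self):
        with pytest.raises(ValueError):
            Partition(labels=["a", "b"], assignment=np.array([1, 3]), k=2)

    def test_members(self):
        p = Partition(labels=["a", "b", "c"], assignment=np.array([1, 2, 1]), k=2)
        assert p.members(1) == ["a", "c"]
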