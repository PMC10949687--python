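"""Hierarchical domain detection, multi-resolution cuts, auto selection."""

import numpy as np
import pytest

from nichespan import (
    DistanceMatrix,
    MultiSliceSet,
    ari,
    auto_domain_number,
    backtrack_to_slices,
    cut_domains,
    detect_domains,
    domain_profile,
    hierarchical_cluster,
    pairwise_distances,
    simulate_multislice,
)
from nichespan.embedding import NicheEmbedding
from nichespan.scenarios import homogeneous_slice, separated_discs, tls_multislice

from conftest import make_slice, random_simplex


def two_blob_rows(rng, n1=20, n2=20):
    """Simplex rows in two tight, well-separated blobs."""
    a = np.abs(rng.normal([0.8, 0.15, 0.05], 0.01, size=(n1, 3)))
    b = np.abs(rng.normal([0.05, 0.15, 0.8], 0.01, size=(n2, 3)))
    x = np.vstack([a, b])
    return x / x.sum(axis=1, keepdims=True), np.array([1] * n1 + [2] * n2)


class TestHierarchicalCluster:
    def test_two_observations_single_merge_at_distance(self):
        d = DistanceMatrix(np.array([[0, 0.3], [0.3, 0]]), "jsd")
        tree = hierarchical_cluster(d)
        assert tree.n_leaves == 2
        assert tree.heights[0] == pytest.approx(0.3)

    def test_three_point_ultrametric_merge_order(self):
        # d(0,1)=0.1 < d(0,2)=d(1,2)=0.5: first merge must be {0,1}
        v = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        tree = hierarchical_cluster(DistanceMatrix(v, "jsd"))
        assert sorted(tree.linkage[0, :2].astype(int).tolist()) == [0, 1]
        assert tree.heights[0] == pytest.approx(0.1)
        assert tree.heights[1] == pytest.approx(0.5)

    def test_separated_blobs_merge_within_first(self, rng):
        x, membership = two_blob_rows(rng)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        # the first n-2 merges never join the two blobs
        n = len(x)
        cluster_side = {i: membership[i] for i in range(n)}
        for m, (a, b, _, _) in enumerate(tree.linkage):
            sa, sb = cluster_side[int(a)], cluster_side[int(b)]
            if m < n - 2:
                assert sa == sb
            cluster_side[n + m] = sa if sa == sb else 0

    def test_single_observation_errors(self):
        d = DistanceMatrix(np.zeros((1, 1)), "jsd")
        with pytest.raises(ValueError, match="two observations"):
            hierarchical_cluster(d)


class TestCutDomains:
    def test_single_domain_names(self, rng):
        x, _ = two_blob_rows(rng, 3, 3)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        a = cut_domains(tree, 1)
        assert set(a.names) == {"Domain_1_1"}

    def test_full_resolution_singletons(self, rng):
        x, _ = two_blob_rows(rng, 3, 3)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        a = cut_domains(tree, 6)
        assert len(set(a.labels.tolist())) == 6

    def test_two_blob_cut_matches_membership_larger_first(self, rng):
        x, membership = two_blob_rows(rng, n1=15, n2=25)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        a = cut_domains(tree, 2)
        assert ari(a.labels, membership) == 1.0
        # bigger blob (the second) must be Domain_2_1
        assert set(a.names[membership == 2]) == {"Domain_2_1"}
        assert set(a.names[membership == 1]) == {"Domain_2_2"}

    def test_nested_resolutions_refine(self, rng):
        x = random_simplex(rng, 60, 4)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        coarse = cut_domains(tree, 3).labels
        fine = cut_domains(tree, 7).labels
        # every fine cluster sits inside exactly one coarse cluster
        for f in np.unique(fine):
            assert len(np.unique(coarse[fine == f])) == 1

    def test_partition_invariant_to_type_renaming(self, rng):
        x, _ = two_blob_rows(rng)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        a = cut_domains(tree, 2)
        x_perm = x[:, ::-1]  # renaming cell types permutes columns
        tree_p = hierarchical_cluster(pairwise_distances(x_perm, "jsd"))
        a_p = cut_domains(tree_p, 2)
        assert ari(a.labels, a_p.labels) == 1.0

    def test_out_of_range_errors(self, rng):
        x, _ = two_blob_rows(rng, 3, 3)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        with pytest.raises(ValueError, match="n_domains"):
            cut_domains(tree, 0)
        with pytest.raises(ValueError, match="n_domains"):
            cut_domains(tree, 7)

    @pytest.mark.parametrize("metric", ["jsd", "manhattan", "euclidean", "cosine", "pearson", "spearman"])
    def test_metric_substitutability_on_two_blobs(self, rng, metric):
        x, membership = two_blob_rows(rng)
        tree = hierarchical_cluster(pairwise_distances(x, metric))
        assert ari(cut_domains(tree, 2).labels, membership) == 1.0


class TestAutoDomainNumber:
    def _auto(self, config, n_cut_hint=None, k=30):
        mset, _ = simulate_multislice(config)
        from nichespan import embed_multislice

        emb = embed_multislice(mset, k=k)
        dist = pairwise_distances(emb)
        tree = hierarchical_cluster(dist)
        return auto_domain_number(tree, dist)

    def test_three_separated_blobs_returns_three(self):
        assert self._auto(separated_discs(3, seed=2, n_obs_per_domain=50)) == 3

    def test_homogeneous_blob_returns_one(self):
        assert self._auto(homogeneous_slice(seed=2)) == 1

    def test_small_blob_absorbed(self):
        import nichespan as ns

        types = ("A", "B", "C", "D", "E")
        comps = [[1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0], [0, 0, 0, 1, 0]]
        doms = tuple(
            ns.DomainSpec(f"d{i}", np.array(c), ns.Disc((i % 3) * 200, (i // 3) * 200, 30), n)
            for i, (c, n) in enumerate(zip(comps, [50, 50, 50, 5]))
        )
        cfg = ns.SimulationConfig(cell_types=types, domains=doms, seed=5)
        assert self._auto(cfg, k=4) == 3

    def test_too_few_observations_errors(self, rng):
        x = random_simplex(rng, 3, 3)
        dist = pairwise_distances(x)
        tree = hierarchical_cluster(dist)
        with pytest.raises(ValueError, match="manually"):
            auto_domain_number(tree, dist)


class TestBacktrackAndProfile:
    def _embedding(self, values, slice_of):
        n = len(values)
        return NicheEmbedding(
            values, ("A", "B"), tuple(f"o{i}" for i in range(n)), tuple(slice_of)
        )

    def test_domain_absent_from_slice_has_no_rows(self):
        s1 = make_slice([[0, 0], [1, 0]], ["A", "B"], slice_id="s1")
        s2 = make_slice([[0, 0]], ["A"], slice_id="s2")
        mset = MultiSliceSet.harmonized([s1, s2])
        from nichespan.domains import DomainAssignment

        a = DomainAssignment(
            np.array([1, 2, 1]),
            np.array(["Domain_2_1", "Domain_2_2", "Domain_2_1"], dtype=object),
            2,
        )
        per_slice = backtrack_to_slices(a, mset)
        assert set(per_slice["s2"]["domain_name"]) == {"Domain_2_1"}
        assert (per_slice["s2"]["domain_name"] == "Domain_2_2").sum() == 0

    def test_single_slice_is_identity(self):
        s1 = make_slice([[0, 0], [1, 0]], ["A", "B"], slice_id="s1")
        mset = MultiSliceSet((s1,))
        from nichespan.domains import DomainAssignment

        a = DomainAssignment(
            np.array([1, 1]), np.array(["Domain_1_1", "Domain_1_1"], dtype=object), 1
        )
        per_slice = backtrack_to_slices(a, mset)
        assert list(per_slice["s1"]["domain_label"]) == [1, 1]

    def test_profile_of_identical_rows(self):
        from nichespan.domains import DomainAssignment

        emb = self._embedding(np.array([[0.6, 0.4], [0.6, 0.4]]), ["s1", "s1"])
        a = DomainAssignment(
            np.array([1, 1]), np.array(["Domain_1_1", "Domain_1_1"], dtype=object), 1
        )
        prof = domain_profile(a, emb)
        np.testing.assert_allclose(prof.compositions, [[0.6, 0.4]])
        assert prof.counts.tolist() == [2]

    def test_profile_averages_opposed_rows(self):
        from nichespan.domains import DomainAssignment

        emb = self._embedding(np.array([[1.0, 0.0], [0.0, 1.0]]), ["s1", "s1"])
        a = DomainAssignment(
            np.array([1, 1]), np.array(["Domain_1_1", "Domain_1_1"], dtype=object), 1
        )
        prof = domain_profile(a, emb)
        np.testing.assert_allclose(prof.compositions, [[0.5, 0.5]])


class TestRareDomainScenario:
    def test_rare_domain_present_in_four_of_five_slices(self):
        mset, truths = simulate_multislice(tls_multislice(seed=11))
        assignment, emb, tree = detect_domains(mset, n_domains="auto", k=30)
        assert assignment.n_domains == 3
        prof = domain_profile(assignment, emb)
        bt_mass = prof.compositions[:, :3].sum(axis=1)  # B + T types
        tls_name = prof.domain_names[int(np.argmax(bt_mass))]
        assert bt_mass.max() > 0.8
        per_slice = backtrack_to_slices(assignment, mset)
        presence = [
            int((per_slice[sid]["domain_name"] == tls_name).any())
            for sid in mset.slice_ids
        ]
        assert presence == [1, 1, 1, 1, 0]


class TestNewick:
    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        x, _ = two_blob_rows(rng, 4, 4)
        tree = hierarchical_cluster(pairwise_distances(x, "jsd"))
        nwk = tree.to_newick([f"L{i}" for i in range(8)])
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == sorted(
            f"L{i}" for i in range(8)
        )
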