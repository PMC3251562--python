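import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dendropy

from chipcatch import (
    AlignmentResult,
    CatchError,
    CatchParams,
    ClusterNode,
    ClusterStats,
    Placement,
    Profile,
    align_pair,
    catch_cluster,
    cut_tree,
    cut_tree_nodes,
    generate_planted_dataset,
    merge_profiles,
    prune_profile,
    reproject_profiles,
    to_newick,
)
from chipcatch import adjusted_rand_index
from conftest import planted_spec_two_clusters, random_profile
from oracles import brute_reproject


def profile(pid, values, **kw):
    return Profile(id=pid, values=values, **kw)


class TestMergeProfiles:
    def test_identical_at_zero_shift(self, rng):
        v = rng.normal(size=(2, 5))
        a = AlignmentResult(r=0, mirrored=False, score=0.0, n_overlap=5, n_total=5)
        merged = merge_profiles(profile("a", v), profile("b", v.copy()), a)
        assert np.allclose(merged.values, v)
        assert merged.weight == 2
        assert list(merged.coverage) == [2] * 5

    def test_coverage_weighted_mean(self):
        p1 = profile("a", [[0.0]])
        p2 = Profile(id="b", values=[[2.0]], weight=3, coverage=[3])
        a = AlignmentResult(r=0, mirrored=False, score=0.0, n_overlap=1, n_total=1)
        merged = merge_profiles(p1, p2, a)
        assert merged.values[0, 0] == pytest.approx(1.5)  # (1*0 + 3*2) / 4
        assert merged.weight == 4 and merged.coverage[0] == 4

    def test_flanking_bins_and_total_length(self, rng):
        # shift leaving 2 flanking bins per side: n_total = L1 + L2 - n_overlap
        v1, v2 = rng.normal(size=(1, 6)), rng.normal(size=(1, 6))
        r = -2  # p2 moved right by 2
        a = AlignmentResult(r=r, mirrored=False, score=1.0, n_overlap=4, n_total=8)
        merged = merge_profiles(profile("a", v1), profile("b", v2), a)
        assert merged.n_bins == 6 + 6 - 4
        assert list(merged.coverage) == [1, 1, 2, 2, 2, 2, 1, 1]
        # against the per-leaf re-projection oracle
        oracle_vals, oracle_cov = brute_reproject(
            {"a": v1.tolist(), "b": v2.tolist()},
            {"a": (0, False), "b": (2, False)},
        )
        assert np.allclose(merged.values, oracle_vals)
        assert list(merged.coverage) == oracle_cov

    def test_mirrored_merge_matches_oracle(self, rng):
        v1, v2 = rng.normal(size=(2, 5)), rng.normal(size=(2, 7))
        a = AlignmentResult(r=1, mirrored=True, score=0.5, n_overlap=5, n_total=7)
        merged = merge_profiles(profile("a", v1), profile("b", v2), a)
        oracle_vals, oracle_cov = brute_reproject(
            {"a": v1.tolist(), "b": v2.tolist()},
            {"a": (1, False), "b": (0, True)},  # d = -r = -1 → p1 sits at +1
        )
        assert np.allclose(merged.values, oracle_vals)
        assert list(merged.coverage) == oracle_cov

    def test_no_overlap_rejected(self):
        a = AlignmentResult(r=10, mirrored=False, score=0.0, n_overlap=1, n_total=1)
        with pytest.raises(CatchError):
            merge_profiles(profile("a", [[1.0, 2.0]]), profile("b", [[1.0, 2.0]]), a)


class TestPruneProfile:
    def make(self, coverage, weight):
        values = np.arange(len(coverage), dtype=float)[None, :]
        return Profile(id="p", values=values, weight=weight, coverage=coverage)

    def test_zero_fraction_is_noop(self):
        p = self.make([1, 2, 4, 4, 2, 1], 4)
        out, left, right = prune_profile(p, 0.0)
        assert (left, right) == (0, 0)
        assert out is p

    def test_edge_trimming(self):
        p = self.make([1, 2, 4, 4, 2, 1], 4)
        out, left, right = prune_profile(p, 0.5)
        assert (left, right) == (1, 1)
        assert list(out.coverage) == [2, 4, 4, 2]
        assert np.allclose(out.values, [[1, 2, 3, 4]])

    def test_interior_low_coverage_kept(self):
        p = self.make([4, 1, 4], 4)
        out, left, right = prune_profile(p, 0.5)
        assert (left, right) == (0, 0)
        assert out.n_bins == 3

    def test_max_coverage_fallback(self):
        p = self.make([1, 1], 4)
        out, left, right = prune_profile(p, 0.5)
        assert (left, right) == (0, 0)
        assert out.n_bins == 2

    def test_fallback_keeps_contiguous_maximum(self):
        p = self.make([1, 2, 2, 1], 8)
        out, left, right = prune_profile(p, 0.9)
        assert (left, right) == (1, 1)
        assert list(out.coverage) == [2, 2]


class TestCatchCluster:
    def test_two_identical_profiles(self, rng, plain_params):
        v = rng.normal(size=(1, 8))
        root = catch_cluster(
            [profile("a", v), profile("b", v.copy())], plain_params
        )
        assert root.height == 0.0
        assert root.placements["a"] == Placement(0, False, 8)
        assert root.placements["b"] == Placement(0, False, 8)

    def test_single_profile_is_root(self, plain_params):
        p = profile("only", [[1.0, 2.0]])
        root = catch_cluster([p], plain_params)
        assert root.is_leaf and root.node_id == "only"

    def test_empty_input(self, plain_params):
        with pytest.raises(CatchError):
            catch_cluster([], plain_params)

    def test_duplicate_ids_rejected(self, plain_params):
        p = profile("x", [[1.0, 2.0]])
        with pytest.raises(CatchError):
            catch_cluster([p, p.copy()], plain_params)

    def test_two_plus_two_topology(self, rng, plain_params):
        # 2 noisy copies of pattern A and 2 of pattern B: the first two
        # merges must join (A, A) and (B, B)
        idx = np.arange(30)
        pat_a = np.exp(-((idx - 8.0) ** 2) / 6.0)
        pat_b = np.exp(-((idx - 22.0) ** 2) / 20.0) * 2.0
        profiles = [
            profile("a1", [pat_a + rng.normal(0, 0.01, 30)]),
            profile("b1", [pat_b + rng.normal(0, 0.01, 30)]),
            profile("a2", [pat_a + rng.normal(0, 0.01, 30)]),
            profile("b2", [pat_b + rng.normal(0, 0.01, 30)]),
        ]
        stats = ClusterStats()
        root = catch_cluster(profiles, plain_params, stats=stats)
        first_two = {frozenset(m[1:3]) for m in stats.merges[:2]}
        assert first_two == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
        assert {frozenset(s) for s in cut_tree(root, k=2)} == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
        }

    def test_brute_force_pool_loop_equivalence(self, rng, plain_params):
        # independent re-implementation of the pool loop on the same input
        profiles = [random_profile(rng, f"p{i}", 2, 10) for i in range(6)]

        def brute_pool(items):
            pool = {i: p for i, p in enumerate(items)}
            merges = []
            nxt = len(pool)
            while len(pool) > 1:
                best = None
                keys = sorted(pool)
                for ai, i in enumerate(keys):
                    for j in keys[ai + 1 :]:
                        a = align_pair(pool[i], pool[j], plain_params)
                        key = (a.score, i, j)
                        if best is None or key < best[0]:
                            best = (key, i, j, a)
                _, i, j, a = best
                merges.append((frozenset({pool[i].id, pool[j].id}), a.score))
                merged = merge_profiles(pool[i], pool[j], a).copy(id=f"N{nxt}")
                del pool[i], pool[j]
                pool[nxt] = merged
                nxt += 1
            return merges

        stats = ClusterStats()
        catch_cluster(profiles, plain_params, stats=stats)
        expected = brute_pool(profiles)
        got = [(frozenset({m[1], m[2]}), m[3].score) for m in stats.merges]
        assert [g[0] for g in got] == [e[0] for e in expected]
        for g, e in zip(got, expected):
            assert g[1] == pytest.approx(e[1], rel=1e-12, abs=1e-12)

    def test_schematic_four_profile_two_track_merge_order(self, plain_params):
        # four 2-track profiles where the most similar pair is known by
        # construction: p1/p2 nearly identical, p3 close to them, p4 far.
        idx = np.arange(20)
        red = np.exp(-((idx - 6.0) ** 2) / 4.0)
        blue = np.exp(-((idx - 13.0) ** 2) / 4.0)
        profiles = [
            profile("p1", [red, blue]),
            profile("p2", [red * 1.02, blue * 0.98]),
            profile("p3", [red * 1.4, blue * 0.6]),
            profile("p4", [blue * 2.0, red * 0.1]),
        ]
        stats = ClusterStats()
        catch_cluster(profiles, plain_params, stats=stats)
        assert {stats.merges[0][1], stats.merges[0][2]} == {"p1", "p2"}
        assert {stats.merges[1][1], stats.merges[1][2]} == {"N4", "p3"}

    def test_leaf_conservation(self, plain_params, rng):
        profiles = [random_profile(rng, f"p{i}", 1, 12) for i in range(9)]
        root = catch_cluster(profiles, plain_params)
        assert root.leaf_ids() == {p.id for p in profiles}
        for k in (1, 3, 9):
            parts = cut_tree(root, k=k)
            assert sum(len(s) for s in parts) == 9
            assert set().union(*parts) == {p.id for p in profiles}

    def test_representative_weight_invariant(self, plain_params, rng):
        profiles = [random_profile(rng, f"p{i}", 1, 12) for i in range(7)]
        root = catch_cluster(profiles, plain_params)
        for node in root.iter_nodes():
            node.validate()

    def test_representative_matches_leaf_reprojection(self, rng, plain_params):
        spec = planted_spec_two_clusters(seed=3, members=5)
        profiles, _ = generate_planted_dataset(spec)
        root = catch_cluster(profiles, plain_params)
        mats = {p.id: p.values.tolist() for p in profiles}
        for node in root.iter_nodes():
            if node.is_leaf:
                continue
            placements = {
                leaf: (pl.offset, pl.mirrored) for leaf, pl in node.placements.items()
            }
            oracle_vals, oracle_cov = brute_reproject(mats, placements)
            assert np.allclose(
                node.representative.values, oracle_vals, rtol=1e-9, atol=1e-12
            )
            assert list(node.representative.coverage) == oracle_cov

    def test_determinism_bitwise(self, rng, plain_params):
        profiles = [random_profile(rng, f"p{i}", 2, 15) for i in range(8)]
        r1 = catch_cluster([p.copy() for p in profiles], plain_params)
        r2 = catch_cluster([p.copy() for p in profiles], plain_params)
        assert to_newick(r1) == to_newick(r2)
        assert r1.placements == r2.placements
        assert np.array_equal(r1.representative.values, r2.representative.values)

    def test_worker_count_invariance(self, rng, plain_params):
        profiles = [random_profile(rng, f"p{i}", 2, 15) for i in range(8)]
        r1 = catch_cluster([p.copy() for p in profiles], plain_params, n_workers=1)
        r4 = catch_cluster([p.copy() for p in profiles], plain_params, n_workers=4)
        assert to_newick(r1) == to_newick(r4)
        assert r1.placements == r4.placements

    def test_quadratic_align_call_count(self, rng, plain_params):
        # cache policy: initial C(N,2) pairs + (pool-1) per merge = (N-1)^2
        for n in (5, 9):
            profiles = [random_profile(rng, f"p{i}", 1, 10) for i in range(n)]
            stats = ClusterStats()
            catch_cluster(profiles, plain_params, stats=stats)
            assert stats.align_calls == (n - 1) ** 2

    def test_pruning_during_clustering_trims_edges(self, rng):
        params = CatchParams(normalization="none", prune_fraction=0.6)
        spec = planted_spec_two_clusters(seed=11, members=4)
        profiles, _ = generate_planted_dataset(spec)
        root = catch_cluster(profiles, params)
        # pruned representative cannot be longer than the union frame
        assert root.representative.n_bins <= 40 + 2 * spec.max_shift
        threshold = params.prune_fraction * root.representative.weight
        assert root.representative.coverage[0] >= threshold
        assert root.representative.coverage[-1] >= threshold


class TestCutTree:
    def build(self, rng, n=6):
        params = CatchParams(normalization="none", prune_fraction=0.0)
        profiles = [random_profile(rng, f"p{i}", 1, 10) for i in range(n)]
        return catch_cluster(profiles, params)

    def test_k_equals_leaves_gives_singletons(self, rng):
        root = self.build(rng)
        parts = cut_tree(root, k=6)
        assert sorted(map(len, parts)) == [1] * 6

    def test_k_one_gives_everything(self, rng):
        root = self.build(rng)
        assert cut_tree(root, k=1) == [root.leaf_ids()]
        assert cut_tree(root, k=1)[0] == {f"p{i}" for i in range(6)}

    def test_k_too_large(self, rng):
        with pytest.raises(CatchError):
            cut_tree(self.build(rng), k=7)

    def test_requires_exactly_one_criterion(self, rng):
        root = self.build(rng)
        with pytest.raises(CatchError):
            cut_tree(root)
        with pytest.raises(CatchError):
            cut_tree(root, k=2, max_height=1.0)

    def test_height_cut_extremes(self, rng):
        root = self.build(rng)
        assert cut_tree(root, max_height=np.inf) == [root.leaf_ids()]
        parts = cut_tree(root, max_height=-0.0)
        assert sum(len(s) for s in parts) == 6

    def test_partition_disjoint_exhaustive(self, rng):
        root = self.build(rng, n=8)
        for k in range(1, 9):
            parts = cut_tree(root, k=k)
            assert len(parts) == k
            union = set().union(*parts)
            assert union == root.leaf_ids()
            assert sum(len(s) for s in parts) == len(union)

    def test_planted_three_cluster_recovery(self):
        from conftest import planted_spec_three_clusters

        spec = planted_spec_three_clusters(seed=5, members=5, noise_sd=0.02)
        profiles, truth = generate_planted_dataset(spec)
        params = CatchParams(normalization="none", prune_fraction=0.25)
        root = catch_cluster(profiles, params)
        parts = cut_tree(root, k=3)
        planted = [
            {pid for pid, t in truth.items() if t.cluster == c} for c in range(3)
        ]
        assert adjusted_rand_index(parts, planted) == 1.0


class TestNewick:
    def test_single_leaf(self):
        leaf = ClusterNode(
            node_id="p1",
            representative=Profile(id="p1", values=[[1.0]]),
            placements={"p1": Placement(0, False, 1)},
        )
        assert to_newick(leaf) == "p1;"

    def test_two_leaves_with_branch_lengths(self):
        leaves = [
            ClusterNode(
                node_id=f"p{i}",
                representative=Profile(id=f"p{i}", values=[[1.0]]),
                placements={f"p{i}": Placement(0, False, 1)},
            )
            for i in (1, 2)
        ]
        rep = Profile(id="n", values=[[1.0]], weight=2, coverage=[2])
        root = ClusterNode(
            node_id="n",
            representative=rep,
            children=(leaves[0], leaves[1]),
            height=0.5,
            placements={
                "p1": Placement(0, False, 1),
                "p2": Placement(0, False, 1),
            },
        )
        assert to_newick(root) == "(p1:0.5,p2:0.5);"

    def test_negative_branch_length_floored(self):
        # centroid inversions (child height > parent) must not emit
        # negative branch lengths
        leaf = lambda i: ClusterNode(
            node_id=f"p{i}",
            representative=Profile(id=f"p{i}", values=[[1.0]]),
            placements={f"p{i}": Placement(0, False, 1)},
        )
        inner = ClusterNode(
            node_id="inner",
            representative=Profile(id="i", values=[[1.0]], weight=2, coverage=[2]),
            children=(leaf(1), leaf(2)),
            height=2.0,
            placements={"p1": Placement(0, False, 1), "p2": Placement(0, False, 1)},
        )
        root = ClusterNode(
            node_id="root",
            representative=Profile(id="r", values=[[1.0]], weight=3, coverage=[3]),
            children=(inner, leaf(3)),
            height=1.0,  # inversion
            placements={f"p{i}": Placement(0, False, 1) for i in (1, 2, 3)},
        )
        assert ":0," in to_newick(root) or ":0)" in to_newick(root)

    def test_parse_back_topology(self, rng, plain_params):
        profiles = [random_profile(rng, f"leaf{i}", 1, 10) for i in range(7)]
        root = catch_cluster(profiles, plain_params)
        tree = dendropy.Tree.get(data=to_newick(root), schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == {f"leaf{i}" for i in range(7)}
        # bipartitions of the parsed tree match cut_tree partitions
        parts2 = {frozenset(s) for s in cut_tree(root, k=2)}
        internal_bips = set()
        for node in tree.preorder_node_iter():
            labels = frozenset(l.taxon.label for l in node.leaf_iter())
            internal_bips.add(labels)
        assert all(p in internal_bips for p in parts2)


class TestReproject:
    def test_round_trip_identity(self, rng):
        p = random_profile(rng, "p", 2, 6)
        out = reproject_profiles({"p": p}, {"p": Placement(0, False, 6)})
        assert np.allclose(out.values, p.values)

    def test_mirrored_placement(self, rng):
        p = random_profile(rng, "p", 1, 5)
        out = reproject_profiles({"p": p}, {"p": Placement(0, True, 5)})
        assert np.allclose(out.values, p.values[:, ::-1])

    def test_length_mismatch_rejected(self, rng):
        p = random_profile(rng, "p", 1, 5)
        with pytest.raises(CatchError):
            reproject_profiles({"p": p}, {"p": Placement(0, False, 4)})
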