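import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ciliascreen.clustering import (
    NoSubtreeError,
    adjusted_rand_index,
    extract_bait_cluster,
    hierarchical_cluster,
    pairwise_distances,
)
from ciliascreen.correlation_screen import BaitSet
from ciliascreen.expression_io import normalize_profiles
from ciliascreen.synthetic_data import (
    default_config,
    simulate_matrix,
    truth_bait_set,
)
from ciliascreen.expression_io import collapse_isoforms

from conftest import make_matrix
from oracles import ari_oracle, linkage_oracle, subtree_extraction_oracle


def random_points(n, d=7, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, d))


class TestPairwiseDistances:
    def test_identical_profiles_have_zero_distance(self):
        m = make_matrix({"a": [1, 2, 3, 4, 5, 6, 7], "b": [1, 2, 3, 4, 5, 6, 7]})
        assert pairwise_distances(m)[0] == 0.0

    def test_three_four_five(self):
        m = make_matrix({"a": [0, 0, 0, 0, 0, 0, 0], "b": [3, 4, 0, 0, 0, 0, 0]})
        assert pairwise_distances(m)[0] == pytest.approx(5.0)

    def test_matches_per_pair_recomputation(self, random_matrix):
        d = squareform(pairwise_distances(random_matrix))
        vals = random_matrix.values
        for i, j in itertools.combinations(range(len(vals)), 2):
            expected = np.sqrt(((vals[i] - vals[j]) ** 2).sum())
            assert d[i, j] == pytest.approx(expected)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances(make_matrix({"a": [1, 2, 3, 4, 5, 6, 7]}))


class TestHierarchicalCluster:
    @pytest.mark.parametrize("method", ["single", "average", "complete"])
    def test_merge_heights_match_brute_force_recurrences(self, method):
        pts = random_points(8, seed=3)
        dm = squareform(pdist(pts))
        dendro = hierarchical_cluster(pdist(pts), method)
        oracle_merges = linkage_oracle(dm, method)
        # generic input: heights and the sequence of merged leaf-sets agree
        np.testing.assert_allclose(
            dendro.Z[:, 2], [h for _, _, h in oracle_merges], rtol=1e-10
        )
        sets = dendro.node_leafsets()
        merged = [sets[8 + i] for i in range(7)]
        oracle_sets = [a | b for a, b, _ in oracle_merges]
        assert merged == oracle_sets

    def test_two_far_groups_split_at_final_complete_merge(self):
        pts = np.vstack([random_points(5, seed=1) * 0.1,
                         random_points(5, seed=2) * 0.1 + 50])
        dendro = hierarchical_cluster(pdist(pts), "complete")
        sets = dendro.node_leafsets()
        root_children_sizes = sorted(
            len(sets[int(i)]) for i in dendro.Z[-1, :2]
        )
        assert root_children_sizes == [5, 5]
        assert sets[int(dendro.Z[-1, 0])] in (
            frozenset(range(5)), frozenset(range(5, 10))
        )

    def test_duplicate_profiles_merge_first_at_height_zero(self):
        pts = random_points(5, seed=4)
        pts[1] = pts[0]
        dendro = hierarchical_cluster(pdist(pts), "average")
        assert dendro.Z[0, 2] == 0.0
        assert {int(dendro.Z[0, 0]), int(dendro.Z[0, 1])} == {0, 1}

    def test_heights_non_decreasing_for_all_linkages(self):
        for method in ("single", "average", "complete"):
            dendro = hierarchical_cluster(pdist(random_points(20, seed=5)), method)
            assert (np.diff(dendro.Z[:, 2]) >= 0).all()

    def test_unknown_linkage_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pdist(random_points(4)), "ward-ish")

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        dendro = hierarchical_cluster(
            pdist(random_points(6, seed=6)), "complete",
            leaves=[f"g{i}" for i in range(6)],
        )
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {
            f"g{i}" for i in range(6)
        }


class TestExtractBaitCluster:
    def make_dendro(self, n=12, seed=7, planted=None):
        pts = random_points(n, seed=seed)
        if planted:
            pts[list(planted)] *= 0.05  # a tight planted clump
        return hierarchical_cluster(
            pdist(pts), "complete", leaves=[f"g{i}" for i in range(n)]
        )

    @pytest.mark.parametrize("rule", ["coverage", "hypergeom"])
    def test_matches_exhaustive_subtree_enumeration(self, rule):
        for seed in range(6):
            dendro = self.make_dendro(n=12, seed=seed)
            baits = BaitSet((f"g{seed % 3}", f"g{seed % 3 + 3}", "g11"))
            result = extract_bait_cluster(
                dendro, baits, min_size=2, max_size=None, rule=rule
            )
            oracle = subtree_extraction_oracle(
                dendro, set(baits), 2, None, rule
            )
            assert result.extracted_cluster == oracle

    def test_all_baits_in_leaves_returns_root(self):
        dendro = self.make_dendro(n=10, seed=8)
        baits = BaitSet(tuple(dendro.leaves))
        result = extract_bait_cluster(dendro, baits, min_size=2)
        assert result.extracted_cluster == frozenset(dendro.leaves)
        assert result.bait_recall == 1.0

    def test_two_archetype_planted_cluster_recovered(self):
        """All baits planted in one tight archetype at sigma 0: the
        extracted cluster is exactly the archetype."""
        cfg = default_config(seed=0, noise_sigma=0.0, n_baits=5)
        table, truth = simulate_matrix(cfg)
        matrix = collapse_isoforms(table)
        keep = truth.index[truth["archetype"] != "housekeeping"]
        normed, _ = normalize_profiles(matrix.subset(set(keep)), "max")
        dendro = hierarchical_cluster(
            pairwise_distances(normed), "complete", normed.genes
        )
        baits = truth_bait_set(truth)
        result = extract_bait_cluster(dendro, baits, min_size=5)
        planted = set(truth.index[truth["archetype"] == "ciliary"])
        assert set(result.extracted_cluster) == planted
        assert result.bait_recall == 1.0

    def test_leaf_order_invariance(self):
        pts = random_points(12, seed=9)
        names = [f"g{i}" for i in range(12)]
        baits = BaitSet(("g1", "g4", "g7"))
        base = extract_bait_cluster(
            hierarchical_cluster(pdist(pts), "complete", names), baits, min_size=2
        )
        perm = np.random.default_rng(1).permutation(12)
        shuffled = extract_bait_cluster(
            hierarchical_cluster(
                pdist(pts[perm]), "complete", [names[i] for i in perm]
            ),
            baits,
            min_size=2,
        )
        assert base.extracted_cluster == shuffled.extracted_cluster

    def test_size_bounds_can_exclude_everything(self):
        dendro = self.make_dendro(n=6, seed=10)
        with pytest.raises(NoSubtreeError):
            extract_bait_cluster(
                dendro, BaitSet(tuple(dendro.leaves)), min_size=2, max_size=3
            )

    def test_no_bait_among_leaves_rejected(self):
        dendro = self.make_dendro(n=6, seed=11)
        with pytest.raises(ValueError):
            extract_bait_cluster(dendro, BaitSet(("absent",)), min_size=2)


class TestAdjustedRandIndex:
    def test_identical_labelings_score_one(self):
        labels = {f"g{i}": i % 3 for i in range(12)}
        assert adjusted_rand_index(labels, dict(labels)) == pytest.approx(1.0)

    def test_single_cluster_scores_zero(self):
        a = {f"g{i}": i % 3 for i in range(12)}
        b = {f"g{i}": 0 for i in range(12)}
        assert adjusted_rand_index(a, b) == pytest.approx(0.0)

    def test_matches_pair_count_oracle_on_random_labelings(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = {f"g{i}": int(rng.integers(4)) for i in range(30)}
            b = {f"g{i}": int(rng.integers(4)) for i in range(30)}
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_oracle(a, b), abs=1e-12
            )

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index({"a": 1}, {"b": 1})


def test_planted_two_archetype_recovery_ari_at_sigma_03():
    """Complete linkage on a noisy two-archetype mix recovers the planted
    partition with ARI >= 0.9."""
    cfg = default_config(seed=5, noise_sigma=0.3, n_baits=20)
    table, truth = simulate_matrix(cfg)
    matrix = collapse_isoforms(table)
    keep = set(truth.index[truth["archetype"] != "chemosensory"])
    normed, flagged = normalize_profiles(matrix.subset(keep), "max")
    normed = normed.subset(set(normed.genes) - set(flagged))
    dendro = hierarchical_cluster(
        pairwise_distances(normed), "complete", normed.genes
    )
    result = extract_bait_cluster(dendro, truth_bait_set(truth), min_size=10)
    found = {
        g: ("in" if g in result.extracted_cluster else "out") for g in normed.genes
    }
    planted = {
        g: truth.loc[g, "archetype"] for g in normed.genes
    }
    assert adjusted_rand_index(found, planted) >= 0.9
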