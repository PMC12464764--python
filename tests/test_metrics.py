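"""Cluster statistics: size, median within-cluster degree, purity, summaries."""

import itertools

import pytest

from npclust.metrics import cluster_stats, dataset_summary
from npclust.network import ClusterAssignment, SimilarityEdge, cluster_compounds
from npclust.records import CompoundRecord, CompoundSet


def _set_of(ids, kingdom="bacterium", kingdoms=None):
    records = []
    for i, cid in enumerate(ids):
        kd = kingdoms[i] if kingdoms else kingdom
        # distinct alkanes; structures are irrelevant to the metrics
        records.append(
            CompoundRecord.from_fields(cid, "C" * (i + 1), kingdom=kd)
        )
    return CompoundSet(records)


def _clique_edges(ids):
    return [
        SimilarityEdge(*sorted([a, b]), score=0.9)
        for a, b in itertools.combinations(ids, 2)
    ]


class TestClusterStats:
    def test_complete_clique_median_is_size_minus_one(self):
        ids = list("abcde")
        asg = ClusterAssignment({c: 1 for c in ids})
        stats = cluster_stats(asg, _clique_edges(ids), _set_of(ids))
        assert stats[0].size == 5
        assert stats[0].median_edge_count == 4

    def test_path_graph_median(self):
        ids = ["a", "b", "c"]
        edges = [SimilarityEdge("a", "b", 0.8), SimilarityEdge("b", "c", 0.8)]
        asg = ClusterAssignment({c: 1 for c in ids})
        stats = cluster_stats(asg, edges, _set_of(ids))
        assert stats[0].median_edge_count == 1  # degrees 1, 2, 1

    def test_singleton_has_zero_median(self):
        asg = ClusterAssignment({"a": 1})
        stats = cluster_stats(asg, [], _set_of(["a"]))
        assert stats[0].size == 1 and stats[0].median_edge_count == 0

    def test_purity_19_of_20_passes_inclusive_threshold(self):
        ids = [f"c{i}" for i in range(20)]
        kingdoms = ["bacterium"] * 19 + ["fungus"]
        asg = ClusterAssignment({c: 1 for c in ids})
        stats = cluster_stats(
            asg, _clique_edges(ids), _set_of(ids, kingdoms=kingdoms)
        )
        assert stats[0].dominant_kingdom == "bacterium"
        assert stats[0].purity == pytest.approx(0.95)
        assert stats[0].purity >= 0.95

    def test_unknown_kingdom_excluded_from_purity_denominator(self):
        ids = ["a", "b", "c", "d"]
        kingdoms = ["fungus", "fungus", "unknown", "unknown"]
        asg = ClusterAssignment({c: 1 for c in ids})
        stats = cluster_stats(asg, _clique_edges(ids), _set_of(ids, kingdoms=kingdoms))
        assert stats[0].purity == 1.0
        assert stats[0].n_unknown_kingdom == 2

    def test_all_unknown_purity_undefined(self):
        ids = ["a", "b"]
        asg = ClusterAssignment({c: 1 for c in ids})
        stats = cluster_stats(
            asg, _clique_edges(ids), _set_of(ids, kingdom="unknown")
        )
        assert stats[0].purity is None and stats[0].dominant_kingdom is None

    def test_median_bounded_by_size_minus_one(self, std_dataset, std_fps):
        compounds, _ = std_dataset
        edges, asg = cluster_compounds(std_fps)
        for s in cluster_stats(asg, edges, compounds):
            assert s.median_edge_count <= s.size - 1

    def test_conservation_of_compounds(self, std_dataset, std_fps):
        compounds, _ = std_dataset
        edges, asg = cluster_compounds(std_fps)
        stats = cluster_stats(asg, edges, compounds)
        assert sum(s.size for s in stats) == len(compounds)


def _sizes_to_stats(sizes, kingdom="bacterium"):
    """Build minimal per-cluster stats with given sizes (clique medians)."""
    stats = []
    cid = 0
    for size in sizes:
        cid += 1
        ids = [f"k{cid}_{i}" for i in range(size)]
        asg = ClusterAssignment({c: cid for c in ids})
        # renumbering inside cluster_stats is keyed on the assignment ids
        stats.extend(
            cluster_stats(asg, _clique_edges(ids), _set_of(ids, kingdom=kingdom))
        )
    return stats


class TestDatasetSummary:
    def test_mixed_sizes_hand_computed(self):
        summary = dataset_summary(_sizes_to_stats([4, 2, 1]))
        assert summary.n_compounds == 7
        assert summary.n_clusters_ge2 == 2
        assert summary.n_singletons == 1
        assert summary.pct_singletons == 14.3
        assert summary.pct_in_clusters == 85.7

    def test_all_singletons(self):
        summary = dataset_summary(_sizes_to_stats([1, 1, 1]))
        assert summary.n_clusters_ge2 == 0
        assert summary.pct_singletons == 100.0
        assert summary.median_cluster_size_ge2 is None

    def test_median_over_clusters_ge2_and_ge5_count(self):
        summary = dataset_summary(_sizes_to_stats([2, 3, 5]))
        assert summary.median_cluster_size_ge2 == 3
        assert summary.n_clusters_ge5 == 1

    def test_pure_cluster_count_requires_microbial_dominance(self):
        stats = _sizes_to_stats([3, 3], kingdom="other")
        assert dataset_summary(stats).n_pure_clusters == 0
        stats = _sizes_to_stats([3, 3], kingdom="fungus")
        assert dataset_summary(stats).n_pure_clusters == 2

    def test_percentages_complementary(self, std_dataset, std_fps):
        compounds, _ = std_dataset
        edges, asg = cluster_compounds(std_fps)
        summary = dataset_summary(cluster_stats(asg, edges, compounds))
        assert summary.pct_in_clusters + summary.pct_singletons == pytest.approx(
            100.0, abs=0.1
        )
        assert (
            summary.n_compounds_in_clusters_ge2 + summary.n_singletons
            == summary.n_compounds
        )
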