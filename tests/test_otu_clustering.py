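"""Furthest-neighbor OTU clustering, partitions, and diversity statistics."""

import numpy as np
import pytest

from protistdiv.errors import InputError
from protistdiv.otu_clustering import (
    GroupDiversityStats,
    cluster_furthest_neighbor,
    clustering_pattern,
    group_diversity_stats,
    group_report,
    max_corrected_distance,
    partition_at,
    write_list_file,
)
from protistdiv.distances import distance_matrix
from protistdiv.seq_regions import GroupAlignment

from conftest import brute_force_complete_linkage, make_matrix, random_matrix


class TestClusterFurthestNeighbor:
    def test_three_element_example(self):
        m = make_matrix(
            ["A", "B", "C"], {("A", "B"): 0.01, ("A", "C"): 0.10, ("B", "C"): 0.10}
        )
        dend = cluster_furthest_neighbor(m)
        assert dend.merges == [
            (0.01, frozenset({"A", "B"})),
            (0.10, frozenset({"A", "B", "C"})),
        ]

    def test_all_zero_distances(self):
        m = make_matrix(["A", "B", "C"], {})
        dend = cluster_furthest_neighbor(m)
        assert [h for h, _ in dend.merges] == [0.0, 0.0]
        assert dend.merges[-1][1] == frozenset({"A", "B", "C"})

    def test_tie_resolution_does_not_change_final_height(self):
        # complete linkage: whichever 0.04 pair merges first, the last
        # merge is governed by the 0.12 pair
        m = make_matrix(
            ["A", "B", "C"], {("A", "B"): 0.04, ("B", "C"): 0.04, ("A", "C"): 0.12}
        )
        dend = cluster_furthest_neighbor(m)
        assert dend.merges[-1][0] == pytest.approx(0.12)

    def test_precision_grid_rounding(self):
        # 0.00004 rounds to 0.0 on the 1/10000 grid; 0.00005 rounds half-up
        m = make_matrix(["A", "B"], {("A", "B"): 0.00004})
        assert cluster_furthest_neighbor(m).merges[0][0] == 0.0
        m = make_matrix(["A", "B"], {("A", "B"): 0.00005})
        assert cluster_furthest_neighbor(m).merges[0][0] == pytest.approx(0.0001)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        m = random_matrix(rng, n)
        got = cluster_furthest_neighbor(m).merges
        want = brute_force_complete_linkage(m)
        assert got == want


class TestPartitionAt:
    @pytest.fixture
    def dend(self):
        m = make_matrix(
            ["A", "B", "C"], {("A", "B"): 0.01, ("A", "C"): 0.10, ("B", "C"): 0.10}
        )
        return cluster_furthest_neighbor(m)

    def test_cut_between_merges(self, dend):
        part = partition_at(dend, 0.05)
        assert sorted(part.otus, key=min) == [frozenset({"A", "B"}), frozenset({"C"})]

    def test_cutoff_zero_separates_distinct(self, dend):
        assert partition_at(dend, 0.0).n_otus == 3

    def test_cutoff_closed_at_merge_height(self, dend):
        assert partition_at(dend, 0.01).n_otus == 2

    def test_cutoff_above_final_merge(self, dend):
        assert partition_at(dend, 0.5).n_otus == 1

    def test_counts_non_increasing_and_refining(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_matrix(rng, int(rng.integers(4, 12)))
            dend = cluster_furthest_neighbor(m)
            cutoffs = [0.0, 0.01, 0.03, 0.05, 0.1, 0.3]
            parts = [partition_at(dend, c) for c in cutoffs]
            for fine, coarse in zip(parts, parts[1:]):
                assert fine.n_otus >= coarse.n_otus
                # refinement: every fine OTU sits inside one coarse OTU
                for otu in fine.otus:
                    assert any(otu <= big for big in coarse.otus)

    def test_complete_linkage_guarantee(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            m = random_matrix(rng, 10)
            dend = cluster_furthest_neighbor(m)
            grid = np.floor(m.d * dend.precision + 0.5) / dend.precision
            for c in (0.0, 0.05, 0.1):
                for otu in partition_at(dend, c).otus:
                    idx = [m.names.index(x) for x in otu]
                    assert grid[np.ix_(idx, idx)].max() <= c + 1e-12


class TestMaxCorrected:
    def test_outlier_discounted(self):
        names = [f"s{i}" for i in range(10)]
        pairs = {(names[i], names[9]): 0.30 for i in range(9)}
        m = make_matrix(names, pairs)
        dend = cluster_furthest_neighbor(m)
        # nine identical sequences already hold 90% at cutoff 0
        assert max_corrected_distance(dend, 0.9) == 0.0
        assert max_corrected_distance(dend, 1.0) == pytest.approx(0.30)

    def test_requires_all_when_fraction_exceeds_subset(self):
        names = ["a", "b", "c", "d"]
        pairs = {(x, y): 0.10 for i, x in enumerate(names) for y in names[i + 1:]}
        dend = cluster_furthest_neighbor(make_matrix(names, pairs))
        # 0.9 * 4 = 3.6 sequences needed: only the full merge qualifies
        assert max_corrected_distance(dend, 0.9) == pytest.approx(0.10)

    def test_bounded_by_max_distance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_matrix(rng, int(rng.integers(3, 12)))
            dend = cluster_furthest_neighbor(m)
            mc = max_corrected_distance(dend)
            rounded_max = np.floor(m.d.max() * 10_000 + 0.5) / 10_000
            assert mc <= rounded_max + 1e-12

    def test_invalid_fraction(self):
        m = make_matrix(["a", "b"], {("a", "b"): 0.1})
        with pytest.raises(InputError):
            max_corrected_distance(cluster_furthest_neighbor(m), 0.0)


class TestClusteringPattern:
    def test_survey_percentages(self):
        """Counts like Labyrinthulida's 26 OTUs at distance 0 and 17 at
        0.05 give 65% (nearest integer) remaining at 0.05."""
        stats = GroupDiversityStats(
            group_id="Labyrinthulida", n_seq=29, avg=0.17, max=0.35,
            max_corrected=0.34, otu_counts={0.0: 26, 0.01: 19, 0.05: 17},
        )
        pattern = clustering_pattern(stats, [0.0, 0.05])
        assert pattern[0.0] == 100.0
        assert round(pattern[0.05]) == 65

    def test_low_rank_diversity_group(self):
        stats = GroupDiversityStats(
            group_id="MAST-4", n_seq=92, avg=0.03, max=0.07,
            max_corrected=0.06, otu_counts={0.0: 60, 0.01: 24, 0.05: 3},
        )
        assert clustering_pattern(stats, [0.05])[0.05] == pytest.approx(5.0)

    def test_missing_cutoff(self):
        stats = GroupDiversityStats("g", 5, 0, 0, 0, {0.0: 5})
        with pytest.raises(InputError):
            clustering_pattern(stats, [0.05])


class TestGroupReport:
    def test_identical_pair_group(self):
        m = distance_matrix(GroupAlignment("g", ["a", "b"], ["ACGT", "ACGT"]))
        stats = group_diversity_stats(m, "g", cutoffs=(0.0, 0.01, 0.05))
        assert (stats.avg, stats.max, stats.max_corrected) == (0.0, 0.0, 0.0)
        assert list(stats.otu_counts.values()) == [1, 1, 1]

    def test_totals_row_sums_counts(self):
        groups = [
            GroupDiversityStats("g1", 5, 0.1, 0.2, 0.2, {0.0: 5, 0.01: 3}),
            GroupDiversityStats("g2", 6, 0.1, 0.2, 0.2, {0.0: 6, 0.01: 4}),
        ]
        df = group_report(groups)
        total = df[df.Group == "Total"].iloc[0]
        assert total["OTUs_0.01"] == 7
        assert total["Seq"] == 11

    def test_stable_column_order(self):
        df = group_report(
            [GroupDiversityStats("g", 2, 0, 0, 0, {0.0: 1, 0.05: 1})]
        )
        assert list(df.columns) == ["Group", "Seq", "Avg", "Max", "Max_c",
                                    "OTUs_0", "OTUs_0.05"]


def test_list_file_format(tmp_path):
    m = make_matrix(
        ["A", "B", "C"], {("A", "B"): 0.01, ("A", "C"): 0.10, ("B", "C"): 0.10}
    )
    dend = cluster_furthest_neighbor(m)
    out = tmp_path / "otus.list"
    write_list_file(dend, (0.0, 0.05), out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == ["0", "3", "A", "B", "C"]
    assert lines[1].split("\t") == ["0.05", "2", "A,B", "C"]
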