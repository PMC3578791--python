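"""Tree statistics: ultrametricization, LTT, gamma, MPD, trunks, intergroup."""

import dendropy
import numpy as np
import pytest

from protistdiv.errors import InputError, MonophylyError
from protistdiv.phylo_structure import (
    branching_times,
    extract_group_tree,
    gamma_from_branching_times,
    gamma_statistic,
    intergroup_distances,
    ltt_curve,
    make_ultrametric,
    min_intergroup,
    mpd,
    patristic_matrix,
    read_newick,
    tree_from_string,
    trunk_length,
)
from protistdiv.synthetic_data import simulate_yule_tree

from conftest import brute_force_patristic

BASIC = "((a:1,b:1):1,c:2);"


class TestReadNewick:
    def test_basic_tree(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(BASIC + "\n")
        t = read_newick(p)
        assert sorted(t.tip_names()) == ["a", "b", "c"]
        assert len(t.tree.seed_node.child_nodes()) == 2

    def test_missing_lengths_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((a,b),c);\n")
        with pytest.raises(InputError):
            read_newick(p)

    def test_roundtrip(self, tmp_path):
        t = tree_from_string(BASIC, {"a": "G", "b": "G", "c": "H"})
        p = tmp_path / "t.nwk"
        t.write_newick(p)
        m = tmp_path / "g.tsv"
        t.write_group_map(m)
        back = read_newick(p, m)
        assert sorted(back.tip_names()) == sorted(t.tip_names())
        assert back.group_of == t.group_of
        assert branching_times(back) == branching_times(t)

    def test_group_map_must_name_tree_tips(self):
        with pytest.raises(InputError, match="ghost"):
            tree_from_string(BASIC, {"ghost": "G"})


class TestMakeUltrametric:
    def test_fixed_point_on_ultrametric(self):
        t = tree_from_string(BASIC)
        out = make_ultrametric(t)
        assert branching_times(out) == pytest.approx(branching_times(t), abs=1e-9)

    def test_equalizes_tip_depths(self):
        out = make_ultrametric(tree_from_string("((a:1,b:3):1,c:4);"))
        times = branching_times(out)  # would raise if depths unequal
        assert times[0] == pytest.approx(10 / 3)

    def test_star_with_equal_branches_unchanged(self):
        out = make_ultrametric(tree_from_string("(a:2,b:2,c:2);"))
        assert branching_times(out) == pytest.approx([2.0, 2.0])

    def test_total_length_stays_close_under_perturbation(self):
        """Smoothing a mildly perturbed ultrametric tree should not change
        total tree length by more than 20%."""
        rng = np.random.default_rng(5)
        for rep in range(10):
            t = simulate_yule_tree(12, 1.0, rep)
            pert = t.clone()
            for node in pert.tree.preorder_node_iter():
                if node.edge.length is not None:
                    node.edge.length *= float(rng.uniform(0.9, 1.1))
            before = sum(
                n.edge.length or 0 for n in pert.tree.preorder_node_iter()
            )
            out = make_ultrametric(pert)
            after = sum(
                n.edge.length or 0 for n in out.tree.preorder_node_iter()
            )
            assert abs(after - before) / before < 0.2


class TestBranchingTimes:
    def test_path_arithmetic(self):
        assert branching_times(tree_from_string(BASIC)) == [2.0, 1.0]

    def test_binary_tree_yields_n_minus_1(self):
        t = simulate_yule_tree(9, 1.0, 3)
        assert len(branching_times(t)) == 8

    def test_zero_length_internal_branch_duplicates_time(self):
        t = tree_from_string("(((a:1,b:1):0,c:1):1,d:2);")
        times = branching_times(t)
        assert times == [2.0, 1.0, 1.0]

    def test_polytomy_counts_multiple_events(self):
        t = tree_from_string("(a:2,b:2,c:2,d:2);")
        assert branching_times(t) == [2.0, 2.0, 2.0]

    def test_non_ultrametric_rejected(self):
        with pytest.raises(InputError):
            branching_times(tree_from_string("((a:1,b:2):1,c:2);"))


class TestLTT:
    def test_three_tip_curve(self):
        curve = ltt_curve(tree_from_string(BASIC))
        assert curve.points == [
            (-1.0, pytest.approx(200 / 3)),
            (-0.5, 100.0),
            (0.0, 100.0),
        ]

    def test_two_tip_flat(self):
        curve = ltt_curve(tree_from_string("(a:1,b:1);"))
        assert curve.points == [(-1.0, 100.0), (0.0, 100.0)]

    def test_comb_evenly_spaced(self):
        t = tree_from_string("(((a:1,b:1):1,c:2):1,d:3);")
        curve = ltt_curve(t)
        assert [p[0] for p in curve.points] == pytest.approx([-1, -2 / 3, -1 / 3, 0])
        assert [p[1] for p in curve.points] == pytest.approx([50, 75, 100, 100])

    def test_monotone_and_ends_at_100(self):
        for seed in range(5):
            curve = ltt_curve(simulate_yule_tree(20, 1.0, seed))
            pcts = [p[1] for p in curve.points]
            assert pcts == sorted(pcts)
            assert curve.points[-1] == (0.0, 100.0)
            # binary tree without ties: n-1 steps plus the closing endpoint
            assert len(curve.points) == 20


class TestGamma:
    def test_hand_example(self):
        gamma, g, T = gamma_from_branching_times([2.0, 1.0])
        assert g == [1.0, 1.0]
        assert T == 5.0
        assert gamma == pytest.approx(-0.346410, abs=1e-4)

    def test_matches_dendropy_reference(self):
        """Cross-check against an independent implementation on Yule trees."""
        from dendropy.calculate import treemeasure

        for seed in range(10):
            t = simulate_yule_tree(25, 1.0, seed)
            ours = gamma_statistic(t).gamma
            ref = treemeasure.pybus_harvey_gamma(t.tree)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_null_calibration_small(self):
        gs = [gamma_statistic(simulate_yule_tree(50, 1.0, s)).gamma for s in range(200)]
        assert abs(np.mean(gs)) < 0.25
        assert 0.8 < np.std(gs) < 1.2

    def test_one_tailed_p_follows_sign(self):
        res = gamma_statistic(tree_from_string(BASIC))
        assert res.gamma < 0
        assert 0 < res.p_one_tailed < 0.5
        assert res.classification() == "zero"  # |gamma| small, n = 3

    def test_too_few_tips(self):
        with pytest.raises(InputError):
            gamma_statistic(tree_from_string("(a:1,b:1);"))


class TestPatristic:
    def test_mpd_example(self):
        t = tree_from_string(BASIC, {"a": "G", "b": "G", "c": "G"})
        assert mpd(t, "G") == pytest.approx(10 / 3)

    def test_two_tip_group(self):
        t = tree_from_string(BASIC, {"a": "G", "b": "G"})
        assert mpd(t, "G") == pytest.approx(2.0)

    def test_matches_path_enumeration_oracle(self):
        for seed in range(5):
            t = simulate_yule_tree(15, 1.0, seed)
            pm = patristic_matrix(t)
            oracle = brute_force_patristic(t.tree)
            for (a, b), want in oracle.items():
                assert pm.loc[a, b] == pytest.approx(want)

    def test_matches_dendropy_reference(self):
        t = simulate_yule_tree(12, 1.0, 42)
        pdm = t.tree.phylogenetic_distance_matrix()
        pm = patristic_matrix(t)
        for t1 in t.tree.taxon_namespace:
            for t2 in t.tree.taxon_namespace:
                if t1.label < t2.label:
                    assert pm.loc[t1.label, t2.label] == pytest.approx(
                        pdm.patristic_distance(t1, t2)
                    )


class TestTrunk:
    def test_read_off_stem(self):
        t = tree_from_string("((a:1,b:1):3,c:4);", {"a": "G", "b": "G", "c": "H"})
        assert trunk_length(t, "G") == 3.0

    def test_non_monophyletic_group(self):
        t = tree_from_string("((a:1,b:1):3,c:4);", {"a": "G", "c": "G", "b": "H"})
        with pytest.raises(MonophylyError):
            trunk_length(t, "G")

    def test_single_tip_group_uses_terminal_branch(self):
        t = tree_from_string("((a:1,b:1):3,c:4);", {"c": "H"})
        assert trunk_length(t, "H") == 4.0

    def test_whole_tree_group_has_no_stem(self):
        t = tree_from_string(BASIC, {"a": "G", "b": "G", "c": "G"})
        with pytest.raises(InputError):
            trunk_length(t, "G")


class TestIntergroup:
    def test_path_sum_example(self):
        t = tree_from_string(BASIC, {"a": "G", "b": "G", "c": "H"})
        inter = intergroup_distances(t)
        assert inter.loc["G", "H"] == pytest.approx(4.0)
        assert min_intergroup(inter)["G"] == pytest.approx(4.0)

    def test_single_tip_groups(self):
        t = tree_from_string("(a:1,b:2);", {"a": "G", "b": "H"})
        assert intergroup_distances(t).loc["G", "H"] == pytest.approx(3.0)

    def test_needs_two_groups(self):
        t = tree_from_string(BASIC, {"a": "G", "b": "G"})
        with pytest.raises(InputError):
            intergroup_distances(t)


class TestExtractGroupTree:
    def test_extracts_crown_clade(self):
        t = tree_from_string(
            "(((a:1,b:1):1,c:2):3,d:5);", {"a": "G", "b": "G", "c": "G", "d": "H"}
        )
        sub = extract_group_tree(t, "G")
        assert sorted(sub.tip_names()) == ["a", "b", "c"]
        assert branching_times(sub) == [2.0, 1.0]

    def test_monophyly_enforced(self):
        t = tree_from_string(BASIC, {"a": "G", "c": "G", "b": "H"})
        with pytest.raises(MonophylyError):
            extract_group_tree(t, "G")
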