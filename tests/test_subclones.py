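import numpy as np
import pytest

from mmclonal.errors import DomainError
from mmclonal.subclones import (
    CloneTree,
    ClusterConfig,
    build_clone_tree,
    clone_proportions,
    cluster_mutations,
    detect_parallel_evolution,
    detect_sweeps,
)
from mmclonal.types import SampleMeta, Subclone

from conftest import make_ccf_matrix


def _metas(sample_ids):
    classes = ["iliac_crest_left", "iliac_crest_right", "focal_lesion"]
    return [
        SampleMeta(s, "P1", classes[i % 3], i, 1.0)
        for i, s in enumerate(sample_ids)
    ]


class TestClustering:
    def test_two_planted_clusters_recovered_with_tight_centroids(self):
        rng = np.random.default_rng(7)
        rows = [(1.0, 1.0)] * 50 + [(0.4, 0.05)] * 50
        m = make_ccf_matrix(rows, ["A", "B"], depth=100, rng=rng)
        subclones = cluster_mutations(m, _metas(["A", "B"]))
        assert len(subclones) == 2
        cents = sorted(
            [(sc.centroid["A"], sc.centroid["B"]) for sc in subclones]
        )
        assert cents[0][0] == pytest.approx(0.4, abs=0.05)
        assert cents[0][1] == pytest.approx(0.05, abs=0.05)
        assert cents[1][0] == pytest.approx(1.0, abs=0.05)
        assert cents[1][1] == pytest.approx(1.0, abs=0.05)

    def test_all_clonal_mutations_give_one_cluster(self):
        rng = np.random.default_rng(3)
        m = make_ccf_matrix([(1.0, 1.0)] * 60, ["A", "B"], depth=100, rng=rng)
        subclones = cluster_mutations(m, _metas(["A", "B"]))
        assert len(subclones) == 1

    def test_membership_is_a_partition(self):
        rng = np.random.default_rng(11)
        rows = [(1.0, 1.0)] * 40 + [(0.5, 0.5)] * 30 + [(0.2, 0.7)] * 30
        m = make_ccf_matrix(rows, ["A", "B"], depth=150, rng=rng)
        subclones = cluster_mutations(m, _metas(["A", "B"]))
        members = [v for sc in subclones for v in sc.members]
        assert len(members) == len(set(members)) == 100

    def test_singleton_cluster_merged_by_evidence_rule(self):
        # one extreme outlier cannot stand as a subclone on its own
        rng = np.random.default_rng(5)
        rows = [(1.0, 1.0)] * 40
        m = make_ccf_matrix(rows, ["A", "B"], depth=100, rng=rng)
        outlier = make_ccf_matrix([(0.35, 0.35)], ["A", "B"], depth=100)
        outlier["variant_id"] = "OUT1"
        import pandas as pd

        m = pd.concat([m, outlier], ignore_index=True)
        subclones = cluster_mutations(m, _metas(["A", "B"]))
        assert len(subclones) == 1
        assert "OUT1" in subclones[0].members

    def test_shallow_variants_assigned_post_hoc(self):
        rng = np.random.default_rng(9)
        rows = [(1.0, 1.0)] * 30 + [(0.4, 0.4)] * 30
        m = make_ccf_matrix(rows, ["A", "B"], depth=100, rng=rng)
        shallow = make_ccf_matrix([(0.4, 0.4)], ["A", "B"], depth=40)
        shallow["variant_id"] = "SHALLOW"
        import pandas as pd

        m = pd.concat([m, shallow], ignore_index=True)
        subclones = cluster_mutations(m, _metas(["A", "B"]))
        home = next(sc for sc in subclones if "SHALLOW" in sc.members)
        assert home.centroid["A"] == pytest.approx(0.4, abs=0.07)

    def test_cna_evidence_keeps_single_mutation_cluster(self):
        rng = np.random.default_rng(5)
        m = make_ccf_matrix([(1.0, 1.0)] * 40, ["A", "B"], depth=100, rng=rng)
        outlier = make_ccf_matrix([(0.35, 0.35)], ["A", "B"], depth=100)
        outlier["variant_id"] = "OUT1"
        import pandas as pd

        m = pd.concat([m, outlier], ignore_index=True)
        subclones = cluster_mutations(
            m, _metas(["A", "B"]),
            cna_profiles={"del13": {"A": 0.35, "B": 0.35}},
        )
        by_size = sorted(subclones, key=lambda sc: sc.n_mutations)
        if len(subclones) == 2:  # the CNA rescued the singleton
            assert by_size[0].cna_members == ["del13"]


def _subclone(sid, centroid):
    return Subclone(id=sid, members=[f"{sid}-m1", f"{sid}-m2"], centroid=centroid)


class TestCloneTree:
    def test_nested_centroids_form_a_chain(self):
        tree = build_clone_tree(
            [
                _subclone("CL", {"A": 1.0, "B": 1.0}),
                _subclone("SUB", {"A": 0.4, "B": 0.3}),
            ]
        )
        assert tree.parent == {"CL": None, "SUB": "CL"}
        assert not tree.violations

    def test_crossing_ccf_vectors_forced_onto_separate_branches(self):
        tree = build_clone_tree(
            [
                _subclone("CL", {"A": 1.0, "B": 1.0}),
                _subclone("X", {"A": 0.6, "B": 0.1}),
                _subclone("Y", {"A": 0.3, "B": 0.8}),
            ]
        )
        assert tree.parent["X"] == "CL" and tree.parent["Y"] == "CL"
        assert not tree.violations

    def test_sibling_sum_rule_separates_overfull_children(self):
        # children sum to 1.1 > 1.0 in sample A: cannot be siblings; the
        # only violation-free arrangement nests one under the other
        tree = build_clone_tree(
            [
                _subclone("CL", {"A": 1.0, "B": 1.0}),
                _subclone("P", {"A": 0.6, "B": 0.5}),
                _subclone("Q", {"A": 0.5, "B": 0.45}),
            ]
        )
        assert tree.parent["Q"] == "P" and tree.parent["P"] == "CL"
        assert not tree.violations

    def test_inconsistent_geometry_returns_violation_report(self):
        # crossing vectors too large to be siblings: every arrangement breaks
        # either the pigeonhole or the sibling-sum rule
        tree = build_clone_tree(
            [
                _subclone("CL", {"A": 1.0, "B": 1.0}),
                _subclone("P", {"A": 0.8, "B": 0.1}),
                _subclone("Q", {"A": 0.7, "B": 0.2}),
            ],
            tol=0.05,
        )
        assert tree.violations

    def test_root_only(self):
        tree = build_clone_tree([_subclone("CL", {"A": 1.0})])
        assert tree.parent == {"CL": None}


class TestProportions:
    def test_simple_subtraction(self):
        tree = build_clone_tree(
            [_subclone("CL", {"A": 1.0}), _subclone("S", {"A": 0.4})]
        )
        props = clone_proportions(tree, "A")
        assert props == {"CL": pytest.approx(0.6), "S": pytest.approx(0.4)}

    def test_two_children(self):
        tree = build_clone_tree(
            [
                _subclone("CL", {"A": 1.0, "B": 1.0}),
                _subclone("X", {"A": 0.6, "B": 0.1}),
                _subclone("Y", {"A": 0.3, "B": 0.8}),
            ]
        )
        props = clone_proportions(tree, "A")
        assert props["CL"] == pytest.approx(0.1)
        assert props["X"] == pytest.approx(0.6)
        assert props["Y"] == pytest.approx(0.3)

    def test_child_exceeding_parent_is_floored_not_negative(self):
        tree = CloneTree(
            {
                "CL": _subclone("CL", {"A": 0.95}),
                "S": _subclone("S", {"A": 1.0}),
            },
            {"CL": None, "S": "CL"},
            "CL",
            ["A"],
        )
        props = clone_proportions(tree, "A")
        assert props["CL"] == 0.0
        assert props["S"] == pytest.approx(0.95)
        assert all(v >= 0 for v in props.values())

    def test_proportions_sum_to_root_centroid(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sub = [_subclone("CL", {"A": 1.0, "B": 1.0})]
            vals = np.sort(rng.uniform(0, 0.45, size=(2, 2)), axis=0)[::-1]
            sub.append(_subclone("S1", {"A": vals[0, 0], "B": vals[0, 1]}))
            sub.append(_subclone("S2", {"A": vals[1, 0], "B": vals[1, 1]}))
            tree = build_clone_tree(sub)
            for s in ("A", "B"):
                total = sum(clone_proportions(tree, s).values())
                assert total <= 1.0 + 1e-9


def _fixed_tree(centroid_by_node, parent):
    nodes = {
        n: Subclone(id=n, members=[f"{n}1", f"{n}2"], centroid=c)
        for n, c in centroid_by_node.items()
    }
    root = next(n for n, p in parent.items() if p is None)
    samples = sorted(next(iter(centroid_by_node.values())))
    return CloneTree(nodes, parent, root, samples)


class TestSweeps:
    def test_single_sweep_detected(self):
        tree = _fixed_tree(
            {
                "CL": {"t1": 1.0, "t2": 1.0},
                "A": {"t1": 0.7, "t2": 0.0},
                "B": {"t1": 0.1, "t2": 0.8},
            },
            {"CL": None, "A": "CL", "B": "CL"},
        )
        events = detect_sweeps(tree, [(0, "t1"), (1, "t2")], "P1")
        assert len(events) == 1
        assert events[0].rising == "B" and events[0].displaced == ["A"]

    def test_stable_composition_no_sweep(self):
        tree = _fixed_tree(
            {"CL": {"t1": 1.0, "t2": 1.0}, "A": {"t1": 0.7, "t2": 0.7}},
            {"CL": None, "A": "CL"},
        )
        assert detect_sweeps(tree, [(0, "t1"), (1, "t2")], "P1") == []

    def test_three_successive_dominants_give_two_sweeps(self):
        tree = _fixed_tree(
            {
                "CL": {"t1": 1.0, "t2": 1.0, "t3": 1.0},
                "A": {"t1": 0.7, "t2": 0.05, "t3": 0.05},
                "B": {"t1": 0.1, "t2": 0.8, "t3": 0.1},
                "C": {"t1": 0.05, "t2": 0.05, "t3": 0.85},
            },
            {"CL": None, "A": "CL", "B": "CL", "C": "CL"},
        )
        events = detect_sweeps(tree, [(0, "t1"), (1, "t2"), (2, "t3")], "P1")
        assert [(e.rising, e.displaced) for e in events] == [("B", ["A"]), ("C", ["B"])]

    def test_single_timepoint_empty(self):
        tree = _fixed_tree({"CL": {"t1": 1.0}}, {"CL": None})
        assert detect_sweeps(tree, [(0, "t1")], "P1") == []


class TestParallelEvolution:
    def _tree(self):
        return _fixed_tree(
            {
                "CL": {"A": 1.0},
                "B1": {"A": 0.5},
                "B2": {"A": 0.4},
            },
            {"CL": None, "B1": "CL", "B2": "CL"},
        )

    def test_gene_on_two_sibling_branches_flagged(self):
        flagged = detect_parallel_evolution(
            self._tree(), {"B1": {"TP53"}, "B2": {"TP53"}, "CL": set()}
        )
        assert flagged == {"TP53"}

    def test_single_clonal_event_not_flagged(self):
        flagged = detect_parallel_evolution(
            self._tree(), {"CL": {"TP53"}, "B1": set(), "B2": set()}
        )
        assert flagged == set()

    def test_ancestral_shared_event_suppresses_the_flag(self):
        flagged = detect_parallel_evolution(
            self._tree(), {"CL": {"TP53"}, "B1": {"TP53"}, "B2": {"TP53"}}
        )
        assert flagged == set()

    def test_family_mode_joins_kdm_and_kmt(self):
        flagged = detect_parallel_evolution(
            self._tree(),
            {"B1": {"KDM4B"}, "B2": {"KMT2D"}, "CL": set()},
            families={"KDM/KMT": ("KDM", "KMT")},
        )
        assert "KDM/KMT" in flagged and "KDM4B" not in flagged
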