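import networkx as nx
import pytest

from lshclust.align import ClusterCriteria, PairAligner
from lshclust.alphabet import SequenceRecord
from lshclust.graph import (
    Community,
    assemble_clustering,
    build_graph,
    cascade_cluster,
    detect_communities,
    greedy_cluster_community,
    sparsify_by_degree,
)


def path_graph(n):
    ids = [f"{i:02d}" for i in range(1, n + 1)]
    return build_graph(ids, list(zip(ids, ids[1:])))


class TestSparsify:
    def test_low_degree_graph_unchanged(self):
        g = path_graph(6)
        out = sparsify_by_degree(g, cap=10)
        assert set(out.edges) == set(g.edges)

    def test_star_survives_via_leaves(self):
        hub = "hub"
        leaves = [f"leaf{i:03d}" for i in range(100)]
        g = build_graph([hub] + leaves, [(hub, l) for l in leaves])
        out = sparsify_by_degree(g, cap=10)
        # every leaf retains its only edge, so the star is intact
        assert out.number_of_edges() == 100
        assert set(out.nodes) == set(g.nodes)

    def test_dense_clique_thinned(self):
        ids = [f"n{i:02d}" for i in range(30)]
        g = build_graph(ids, [(a, b) for a in ids for b in ids if a < b])
        out = sparsify_by_degree(g, cap=5)
        assert out.number_of_edges() < g.number_of_edges()
        # either-endpoint survival keeps at least cap edges per node
        assert all(d >= 5 for _, d in out.degree)


class TestCommunities:
    def test_chain_broken_into_bounded_pieces(self):
        # path 1..7, T=2: min-label propagation gives {1,2,3} and singletons
        coms = detect_communities(path_graph(7), rounds=2)
        groups = sorted(sorted(c.members) for c in coms)
        assert groups == [["01", "02", "03"], ["04"], ["05"], ["06"], ["07"]]

    def test_star_is_one_community(self):
        hub = "a_hub"
        leaves = [f"leaf{i}" for i in range(10)]
        g = build_graph([hub] + leaves, [(hub, l) for l in leaves])
        coms = detect_communities(g, rounds=1)
        assert len(coms) == 1 and coms[0].members == frozenset([hub] + leaves)

    def test_disconnected_edges_stay_separate(self):
        g = build_graph(list("abcd"), [("a", "b"), ("c", "d")])
        coms = detect_communities(g, rounds=3)
        assert sorted(sorted(c.members) for c in coms) == [["a", "b"], ["c", "d"]]

    @pytest.mark.parametrize("n,rounds", [(25, 1), (25, 2), (25, 3)])
    def test_diameter_bound_2t_on_long_chains(self, n, rounds):
        g = path_graph(n)
        for com in detect_communities(g, rounds=rounds):
            members = sorted(com.members)
            dist = nx.diameter(g.subgraph(com.members)) if len(members) > 1 else 0
            assert dist <= 2 * rounds

    def test_labels_partition_nodes(self):
        g = path_graph(10)
        coms = detect_communities(g, rounds=3)
        all_members = [m for c in coms for m in c.members]
        assert sorted(all_members) == sorted(g.nodes)


class _FakeAligner:
    """Acceptance by lookup table: align_fn oracle for greedy tests."""

    def __init__(self, accepted_pairs):
        self.accepted = {tuple(sorted(p)) for p in accepted_pairs}

    def __call__(self, a, b):
        class R:
            accepted = tuple(sorted((a, b))) in self.accepted

        return R


class TestGreedy:
    def _records(self, lengths):
        return {
            sid: SequenceRecord(sid, "A" * n) for sid, n in lengths.items()
        }

    def test_identical_sequences_form_one_cluster(self):
        crit = ClusterCriteria(0.9, 0.8)
        records = {
            sid: SequenceRecord(sid, "MKVLATTPESGQWLRD" * 4)
            for sid in ("a", "b", "c")
        }
        com = Community("a", frozenset(records))
        assignment = greedy_cluster_community(com, records, PairAligner(crit))
        assert assignment == {"a": "a", "b": "a", "c": "a"}

    def test_member_linked_only_to_nonrep_starts_new_cluster(self):
        # A longest; B accepts vs A; C accepts only vs B -> {A,B} and {C}
        records = self._records({"A": 30, "B": 20, "C": 10})
        fake = _FakeAligner([("A", "B"), ("B", "C")])
        com = Community("A", frozenset("ABC"))
        assignment = greedy_cluster_community(com, records, None, align_fn=fake)
        assert assignment == {"A": "A", "B": "A", "C": "C"}

    def test_longest_first_with_id_tie_break(self):
        records = self._records({"b": 20, "a": 20, "c": 10})
        fake = _FakeAligner([("a", "b"), ("a", "c")])
        com = Community("a", frozenset("abc"))
        assignment = greedy_cluster_community(com, records, None, align_fn=fake)
        assert assignment["a"] == "a" and assignment["b"] == "a"
        assert assignment["c"] == "a"

    def test_empty_community_yields_nothing(self):
        com = Community("x", frozenset())
        assert greedy_cluster_community(com, {}, None, align_fn=_FakeAligner([])) == {}


class TestAssemble:
    def test_union_plus_singletons(self):
        clustering = assemble_clustering(
            [{"a": "a", "b": "a"}], ["a", "b", "c"]
        )
        assert clustering.assignment == {"a": "a", "b": "a", "c": "c"}
        clustering.validate_partition(["a", "b", "c"])

    def test_overlapping_partials_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            assemble_clustering([{"a": "a"}, {"a": "b"}], ["a", "b"])

    def test_empty_input_gives_empty_clustering(self):
        clustering = assemble_clustering([], [])
        assert clustering.assignment == {}


class TestCascade:
    def _records(self):
        return {
            sid: SequenceRecord(sid, seq)
            for sid, seq in [
                ("a", "MKVLATTPESGQWLRD" * 5),
                ("b", "MKVLATTPESGQWLRD" * 5),
                ("c", "WDNPHASTRELIKGFC" * 5),
            ]
        }

    @staticmethod
    def _threshold_cluster(records, crit):
        aligner = PairAligner(crit)
        com = Community("x", frozenset(records))
        part = greedy_cluster_community(com, records, aligner)
        return assemble_clustering([part], records.keys(), criteria=crit)

    def test_single_stage_equals_plain_run(self):
        records = self._records()
        stages, composed = cascade_cluster(
            records, [ClusterCriteria(0.9, 0.8)], self._threshold_cluster
        )
        assert len(stages) == 1
        assert composed == stages[0].assignment

    def test_two_stage_composition_total_and_monotone(self):
        records = self._records()
        stages, composed = cascade_cluster(
            records,
            [ClusterCriteria(0.9, 0.8), ClusterCriteria(0.3, 0.8)],
            self._threshold_cluster,
        )
        assert set(composed) == set(records)
        assert len(stages[1].representatives) <= len(stages[0].representatives)
        # composed representative is a fixed point
        for rep in set(composed.values()):
            assert composed[rep] == rep

    def test_non_decreasing_stages_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            cascade_cluster(
                self._records(),
                [ClusterCriteria(0.3, 0.8), ClusterCriteria(0.9, 0.8)],
                self._threshold_cluster,
            )
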