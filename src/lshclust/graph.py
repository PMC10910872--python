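"""Candidate graph simplification, community detection, greedy clustering.

Accepted alignment edges form an undirected graph over sequence ids.  Raw
single-linkage components of this graph can chain distant sequences
together (A~B~C with A far from C), so the graph is first sparsified by a
degree-aware cap, then cut into communities by *bounded* min-label
propagation: after T synchronous rounds each node carries the minimum id
within graph distance T, so co-members of a community are within distance
2T — a provable chain-breaking guarantee.  Within each community a greedy,
longest-first clustering (CD-HIT style) assigns every member to a
representative it verifiably matches under the clustering criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .align import AlignmentResult, ClusterCriteria, PairAligner
from .alphabet import SequenceRecord

__all__ = [
    "Community",
    "Clustering",
    "build_graph",
    "sparsify_by_degree",
    "detect_communities",
    "greedy_cluster_community",
    "assemble_clustering",
    "cascade_cluster",
]


@dataclass(frozen=True)
class Community:
    label: str
    members: frozenset[str]


@dataclass
class Clustering:
    """A partition of sequence ids into representative-labelled clusters."""

    assignment: dict[str, str]
    criteria: ClusterCriteria | None = None

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for member, rep in sorted(self.assignment.items()):
            out.setdefault(rep, []).append(member)
        return out

    @property
    def representatives(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for rep in self.assignment.values():
            sizes[rep] = sizes.get(rep, 0) + 1
        return sizes

    def validate_partition(self, expected_ids: Iterable[str]) -> None:
        """Every expected id assigned exactly once; reps map to themselves."""
        ids = set(expected_ids)
        got = set(self.assignment)
        if got != ids:
            missing, extra = ids - got, got - ids
            raise ValueError(
                f"assignment is not a partition: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
        for rep in set(self.assignment.values()):
            if self.assignment.get(rep) != rep:
                raise ValueError(f"representative {rep!r} not fixed point")


def build_graph(
    node_ids: Iterable[str], edges: Iterable[tuple[str, str]]
) -> nx.Graph:
    """Undirected graph over all ids (isolated nodes included)."""
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    for a, b in edges:
        if a == b:
            continue
        if a not in g or b not in g:
            raise ValueError(f"edge ({a}, {b}) references unknown node")
        g.add_edge(a, b)
    return g


def sparsify_by_degree(graph: nx.Graph, cap: int = 10) -> nx.Graph:
    """Let each node retain at most ``cap`` neighbors, ranked by (neighbor
    degree descending, id ascending); an edge survives if *either* endpoint
    retains it.

    Leaf attachments always survive (the leaf retains its only edge), so
    hubs keep their stars while heavily meshed regions are thinned.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    deg = dict(graph.degree())
    keep: set[tuple[str, str]] = set()
    for node in graph.nodes:
        ranked = sorted(graph.neighbors(node), key=lambda u: (-deg[u], u))
        for u in ranked[:cap]:
            keep.add((node, u) if node < u else (u, node))
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(keep)
    return out


def detect_communities(graph: nx.Graph, rounds: int = 3) -> list[Community]:
    """Synchronous min-label propagation for a fixed number of rounds.

    Each node starts labelled with its own id; each round every node adopts
    the minimum label among itself and its neighbors.  After T rounds a
    node's label is the minimum id within distance T, hence any two
    co-labelled nodes are within graph distance 2T.  Deterministic and
    seedless.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    labels = {n: n for n in graph.nodes}
    for _ in range(rounds):
        new = {}
        for n in graph.nodes:
            m = labels[n]
            for u in graph.neighbors(n):
                if labels[u] < m:
                    m = labels[u]
            new[n] = m
        if new == labels:
            break
        labels = new
    groups: dict[str, set[str]] = {}
    for n, lab in labels.items():
        groups.setdefault(lab, set()).add(n)
    return [
        Community(label=lab, members=frozenset(members))
        for lab, members in sorted(groups.items())
    ]


def greedy_cluster_community(
    community: Community,
    records: Mapping[str, SequenceRecord],
    aligner: PairAligner,
    align_fn: Callable[[str, str], AlignmentResult] | None = None,
) -> dict[str, str]:
    """Longest-first greedy clustering within one community.

    Repeatedly promote the longest unassigned member (ties: smaller id) to
    representative and assign every remaining unassigned member whose
    alignment against it satisfies the criteria; members matching no
    representative become representatives themselves, so the loop
    terminates in at most |community| rounds.  All members are re-aligned
    against candidate representatives even where bucketing produced no
    edge — communities are small after chain-breaking, and this recovers
    pairs the hashing missed.
    """
    if align_fn is None:
        align_fn = lambda a, b: aligner.align(records[a], records[b])
    pending = sorted(community.members, key=lambda s: (-records[s].length, s))
    assignment: dict[str, str] = {}
    while pending:
        rep = pending[0]
        assignment[rep] = rep
        rest = []
        for m in pending[1:]:
            res = align_fn(m, rep)
            if res.accepted:
                assignment[m] = rep
            else:
                rest.append(m)
        pending = rest
    return assignment


def assemble_clustering(
    partials: Sequence[Mapping[str, str]],
    all_seq_ids: Iterable[str],
    criteria: ClusterCriteria | None = None,
) -> Clustering:
    """Union of per-community assignments plus singletons for leftovers.

    Sequences never assigned (too short to hash, unbucketed, isolated)
    become their own singleton clusters.  Overlapping partials indicate an
    internal error and are rejected.
    """
    assignment: dict[str, str] = {}
    for part in partials:
        for member, rep in part.items():
            if member in assignment:
                raise ValueError(f"sequence {member!r} assigned twice")
            assignment[member] = rep
    for sid in all_seq_ids:
        if sid not in assignment:
            assignment[sid] = sid
    return Clustering(assignment=assignment, criteria=criteria)


def cascade_cluster(
    records: Mapping[str, SequenceRecord],
    stages: Sequence[ClusterCriteria],
    cluster_fn: Callable[[Mapping[str, SequenceRecord], ClusterCriteria], Clustering],
) -> tuple[list[Clustering], dict[str, str]]:
    """Iterative clustering at decreasing identity thresholds.

    Stage 1 clusters all records; each later stage clusters the previous
    stage's representatives.  The composed assignment chains every original
    sequence to its final deep representative.  Composed member-to-deep-rep
    identity is not re-validated (standard cascaded-clustering semantics).
    """
    if not stages:
        raise ValueError("at least one stage required")
    idents = [s.min_identity for s in stages]
    if any(b >= a for a, b in zip(idents, idents[1:])):
        raise ValueError(
            f"stages must be strictly decreasing in min_identity, got {idents}"
        )
    stage_outputs: list[Clustering] = []
    current = dict(records)
    for crit in stages:
        clustering = cluster_fn(current, crit)
        clustering.validate_partition(current.keys())
        stage_outputs.append(clustering)
        current = {rep: records[rep] for rep in clustering.representatives}
    composed: dict[str, str] = {}
    for sid in records:
        rep = sid
        for st in stage_outputs:
            rep = st.assignment[rep]
        composed[sid] = rep
    return stage_outputs, composed
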