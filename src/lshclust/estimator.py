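"""Sklearn-style clusterer wiring the full LSH pipeline together.

``LSHClusterer.fit`` runs: normalize -> reduce alphabet -> extract kmers ->
design (or load) the zero-false-negative mask family -> bucket masked
kmers -> two representatives per bucket -> candidate pairs -> alignment
validation -> degree-aware sparsification -> bounded label-propagation
communities -> greedy longest-first clustering -> assembled partition.
"""

from __future__ import annotations

import random
import time
from concurrent.futures import ThreadPoolExecutor
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .alphabet import (
    KmerOccurrence,
    ReducedAlphabet,
    SequenceRecord,
    extract_kmers,
    get_alphabet,
    normalize_residues,
)
from .align import AlignmentResult, ClusterCriteria, PairAligner
from .bucketing import (
    build_buckets,
    candidate_pairs,
    fast_candidate_pairs,
    select_representatives,
)
from .graph import (
    Clustering,
    assemble_clustering,
    build_graph,
    detect_communities,
    greedy_cluster_community,
    sparsify_by_degree,
)
from .lsh import MaskFamily, optimize_family, uncovered_subsets

__all__ = ["LSHClusterer", "coerce_records"]


def coerce_records(X) -> list[SequenceRecord]:
    """Accept records, (id, residues) pairs, an id->residues mapping, or bare
    strings (auto-numbered ids); normalize residues; reject duplicate ids."""
    records: list[SequenceRecord] = []
    if isinstance(X, Mapping):
        items: Iterable = X.items()
    else:
        items = X
    for i, item in enumerate(items):
        if isinstance(item, SequenceRecord):
            rec = SequenceRecord(item.id, normalize_residues(item.residues))
        elif isinstance(item, str):
            rec = SequenceRecord(f"seq{i:06d}", normalize_residues(item))
        else:
            sid, residues = item
            rec = SequenceRecord(str(sid), normalize_residues(residues))
        records.append(rec)
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


class LSHClusterer(BaseEstimator, ClusterMixin):
    """Greedy deep clustering of protein sequences via masking LSH.

    Parameters
    ----------
    min_identity, min_coverage : float
        Clustering criteria; identity over all alignment columns, coverage
        required of both sequences.  The 0.9 / 0.5 / 0.3 / 0.25 operating
        points correspond to redundancy reduction down to deep clustering.
    k, d, n_tables, radius : int
        Kmer length, dropped positions per hash function, number of hash
        tables L, and tolerated kmer mismatches r.  The defaults (12, 3,
        24, 2) give a family with no false negatives at 2 mismatches.
    alphabet : str
        Builtin reduced-alphabet name ('murphy10', 'identity') or a path to
        a class file.
    mask_family : MaskFamily or None
        Pre-designed family; when None one is designed from ``seed``.
    rounds : int
        Label-propagation rounds T; community co-members end within graph
        distance 2T.
    degree_cap : int
        Neighbors retained per node during sparsification.
    max_bucket : int or None
        Optional cap on bucket membership (seeded subsampling) for
        memory-constrained runs.
    skip_ambiguous : bool
        Drop kmers overlapping ambiguity symbols (X) from hashing.
    n_jobs : int
        Threads for alignment validation; results are identical for any
        value.
    seed : int
        Seeds family design and any subsampling.

    Attributes
    ----------
    records_ : list of SequenceRecord (normalized input order)
    mask_family_ : the MaskFamily used
    assignment_ : dict member id -> representative id
    clustering_ : Clustering
    labels_ : ndarray of int cluster labels in input order
    representatives_ : sorted representative ids
    report_ : dict of stage counts and timings
    """

    def __init__(
        self,
        min_identity: float = 0.3,
        min_coverage: float = 0.8,
        k: int = 12,
        d: int = 3,
        n_tables: int = 24,
        radius: int = 2,
        alphabet: str = "murphy10",
        mask_family: MaskFamily | None = None,
        alignment_mode: str = "local",
        rounds: int = 3,
        degree_cap: int = 10,
        max_bucket: int | None = None,
        skip_ambiguous: bool = False,
        n_jobs: int = 1,
        seed: int = 0,
    ):
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self.k = k
        self.d = d
        self.n_tables = n_tables
        self.radius = radius
        self.alphabet = alphabet
        self.mask_family = mask_family
        self.alignment_mode = alignment_mode
        self.rounds = rounds
        self.degree_cap = degree_cap
        self.max_bucket = max_bucket
        self.skip_ambiguous = skip_ambiguous
        self.n_jobs = n_jobs
        self.seed = seed

    # ------------------------------------------------------------------

    def _criteria(self) -> ClusterCriteria:
        return ClusterCriteria(
            min_identity=self.min_identity,
            min_coverage=self.min_coverage,
            alignment_mode=self.alignment_mode,
        )

    def _validate_params(self) -> None:
        if not 0 <= self.radius <= self.d < self.k:
            raise ValueError(
                f"need radius <= d < k, got r={self.radius}, d={self.d}, "
                f"k={self.k}"
            )
        self._criteria()  # validates thresholds

    def _resolve_family(self) -> MaskFamily:
        if self.mask_family is not None:
            fam = self.mask_family
            if fam.k != self.k or fam.d != self.d:
                raise ValueError(
                    f"mask family (k={fam.k}, d={fam.d}) does not match "
                    f"estimator (k={self.k}, d={self.d})"
                )
            return fam
        fam = optimize_family(
            self.k, self.d, self.n_tables, self.radius, seed=self.seed
        )
        n_unc, _ = uncovered_subsets(fam, self.radius)
        if n_unc:
            raise RuntimeError(
                f"mask family design left {n_unc} uncovered "
                f"{self.radius}-subsets; increase n_tables"
            )
        return fam

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Cluster the sequences in X.

        X may be SequenceRecords, (id, residues) pairs, an id->residues
        mapping, or bare residue strings.
        """
        self._validate_params()
        t0 = time.perf_counter()
        timings: dict[str, float] = {}
        records = coerce_records(X)
        self.records_ = records
        by_id = {r.id: r for r in records}
        criteria = self._criteria()
        aligner = PairAligner(criteria)
        alph: ReducedAlphabet = get_alphabet(self.alphabet)

        long_records = [r for r in records if r.length >= self.k]
        short_ids = sorted(r.id for r in records if r.length < self.k)
        timings["read"] = time.perf_counter() - t0

        # -- mask family -------------------------------------------------
        t = time.perf_counter()
        self.mask_family_ = self._resolve_family()
        timings["design_family"] = time.perf_counter() - t

        # -- reduce + kmers + buckets + representatives -------------------
        t = time.perf_counter()
        lengths = {r.id: r.length for r in records}
        reduced_by_id = {r.id: alph.reduce(r.residues) for r in long_records}
        timings["kmers"] = time.perf_counter() - t
        t = time.perf_counter()
        rng = random.Random(self.seed + 1)
        if self.skip_ambiguous:
            # reference bucket path: windows overlapping X are droppable
            occurrences: list[KmerOccurrence] = []
            for rec in long_records:
                occs = extract_kmers(rec.id, reduced_by_id[rec.id], self.k)
                xpos = [i for i, c in enumerate(rec.residues) if c == "X"]
                if xpos:
                    occs = [
                        o for o in occs
                        if not any(o.position <= p < o.position + self.k
                                   for p in xpos)
                    ]
                occurrences.extend(occs)
            buckets = build_buckets(occurrences, self.mask_family_)
            if self.max_bucket is not None:
                for b in buckets:
                    if len(b.members) > self.max_bucket:
                        b.members = set(
                            rng.sample(sorted(b.members), self.max_bucket)
                        )
            for b in buckets:
                select_representatives(b, lengths)
            pair_set = candidate_pairs(buckets)
            n_buckets = len(buckets)
        else:
            pair_set, n_buckets = fast_candidate_pairs(
                reduced_by_id, self.mask_family_, lengths,
                max_bucket=self.max_bucket, rng=rng,
            )
        pairs = sorted(pair_set)
        timings["bucket"] = time.perf_counter() - t

        # -- alignment validation ----------------------------------------
        t = time.perf_counter()
        cache: dict[tuple[str, str], AlignmentResult] = {}

        def _align_cached(a: str, b: str) -> AlignmentResult:
            key = (a, b) if a < b else (b, a)
            res = cache.get(key)
            if res is None:
                res = cache[key] = aligner.align(by_id[key[0]], by_id[key[1]])
            return res

        if self.n_jobs and self.n_jobs > 1:
            with ThreadPoolExecutor(max_workers=self.n_jobs) as ex:
                results = list(
                    ex.map(lambda p: aligner.align(by_id[p[0]], by_id[p[1]]),
                           pairs)
                )
            for p, res in zip(pairs, results):
                cache[p] = res
        else:
            for a, b in pairs:
                _align_cached(a, b)
        edges = [p for p in pairs if cache[p].accepted]
        timings["align"] = time.perf_counter() - t

        # -- graph -> communities -> greedy ------------------------------
        t = time.perf_counter()
        bucketed_ids = sorted({r.id for r in long_records})
        graph = build_graph(bucketed_ids, edges)
        graph = sparsify_by_degree(graph, cap=self.degree_cap)
        communities = detect_communities(graph, rounds=self.rounds)
        timings["communities"] = time.perf_counter() - t

        t = time.perf_counter()
        partials = [
            greedy_cluster_community(
                com, by_id, aligner, align_fn=_align_cached
            )
            for com in communities
        ]
        clustering = assemble_clustering(
            partials, (r.id for r in records), criteria=criteria
        )
        clustering.validate_partition(r.id for r in records)
        timings["greedy"] = time.perf_counter() - t

        # -- fitted attributes -------------------------------------------
        self.clustering_ = clustering
        self.assignment_ = clustering.assignment
        self.representatives_ = clustering.representatives
        rep_index = {rep: i for i, rep in enumerate(self.representatives_)}
        self.labels_ = np.array(
            [rep_index[clustering.assignment[r.id]] for r in records],
            dtype=int,
        )
        sizes = clustering.sizes()
        self.report_ = {
            "n_input": len(records),
            "n_short": len(short_ids),
            "n_buckets": n_buckets,
            "n_candidate_pairs": len(pairs),
            "n_alignments": len(cache),
            "n_accepted_edges": len(edges),
            "n_communities": len(communities),
            "n_clusters": len(sizes),
            "n_singletons": sum(1 for v in sizes.values() if v == 1),
            "timings_s": {k_: round(v, 4) for k_, v in timings.items()},
            "params": {
                "min_identity": self.min_identity,
                "min_coverage": self.min_coverage,
                "k": self.k, "d": self.d, "L": self.mask_family_.L,
                "radius": self.radius, "alphabet": self.alphabet,
                "rounds": self.rounds, "degree_cap": self.degree_cap,
                "seed": self.seed,
            },
        }
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
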