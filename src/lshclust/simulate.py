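"""Synthetic protein families, brute-force oracles, benchmark statistics.

The generator emulates a UniRef-like input: families of homologs at a
controlled pairwise identity plus unrelated singletons.  Family members are
derived from a random root by independent per-site substitution (uniform
over the 19 alternative residues); the substitution rate p is calibrated so
that the *expected pairwise identity between two members* hits the target t:

    (1 - p)^2 + p^2 / 19 = t
    =>  p = (19/20) * (1 - sqrt(1 - (20/19) (1 - t)))

Substitution-only by default (indel rate 0) so the calibration is
analytic; indels are available for robustness tests.  Ground truth (the
generating family of every sequence) supports pairwise recall/precision,
and an exhaustive all-vs-all alignment oracle supplies each sequence's
nearest-neighbor identity — the x-axis of the clustered-fraction curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import STANDARD_RESIDUES, SequenceRecord
from .align import ClusterCriteria, PairAligner
from .graph import Clustering

__all__ = [
    "FamilySpec",
    "benchmark_spec",
    "generate_families",
    "substitution_rate_for_identity",
    "nn_identity_oracle",
    "clustered_fraction_curve",
    "inter_representative_identities",
    "truth_recall_precision",
]

_RESIDUES = np.frombuffer(STANDARD_RESIDUES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic benchmark set.

    ``target_identity`` may be a single value or a (low, high) range from
    which each family draws its own target.  Root lengths are normal
    (mean, sd) clamped to [min, max]; members keep the root length when
    ``indel_rate`` is 0.
    """

    n_families: int = 20
    members_per_family: int = 10
    geometric_members: bool = False  # draw sizes ~ Geometric(1/mean) instead
    target_identity: float | tuple[float, float] = 0.9
    length_mean: float = 275.0
    length_sd: float = 60.0
    length_min: int = 150
    length_max: int = 400
    indel_rate: float = 0.0
    n_singletons: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        t = self.target_identity
        lo, hi = (t, t) if isinstance(t, (int, float)) else t
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError(f"target identity must lie in (0, 1], got {t}")
        if self.length_min < 1 or self.length_min > self.length_max:
            raise ValueError("need 1 <= length_min <= length_max")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must be in [0, 1)")


def benchmark_spec(seed: int = 0) -> FamilySpec:
    """The standard desk-scale benchmark set: 20 families x 10 members plus
    100 unrelated singletons, lengths 150-400.

    Families are generated at target pairwise identity 0.95 — comfortably
    above the 0.9 redundancy-reduction threshold — so that the ground-truth
    partition and ideal threshold clustering coincide and recall/precision
    measure candidate-generation quality, not boundary effects of pairs
    sitting exactly at the threshold.
    """
    return FamilySpec(
        n_families=20,
        members_per_family=10,
        target_identity=0.95,
        n_singletons=100,
        length_min=150,
        length_max=400,
        seed=seed,
    )


def substitution_rate_for_identity(target: float) -> float:
    """Per-site substitution rate p so two mutated copies of a root have
    expected identity ``target`` (substitution uniform over 19 alternatives,
    so both copies may coincide by chance)."""
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target must be in (0, 1], got {target}")
    disc = 1.0 - (20.0 / 19.0) * (1.0 - target)
    if disc < 0:
        raise ValueError(f"target {target} below the 2-copy identity floor")
    return (19.0 / 20.0) * (1.0 - math.sqrt(disc))


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _RESIDUES[rng.integers(0, 20, size=length)]


def _mutate(root: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, uniformly over the 19
    alternative residues."""
    out = root.copy()
    hit = np.flatnonzero(rng.random(root.size) < p)
    for i in hit:
        alt = _RESIDUES[_RESIDUES != root[i]]
        out[i] = alt[rng.integers(0, 19)]
    return out


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Single-residue insertions/deletions at the given per-site rate."""
    out: list[int] = []
    for ch in seq:
        u = rng.random()
        if u < rate / 2:
            continue  # deletion
        out.append(int(ch))
        if rate / 2 <= u < rate:
            out.append(int(_RESIDUES[rng.integers(0, 20)]))  # insertion
    return np.array(out or [int(_RESIDUES[0])], dtype=np.uint8)


def _draw_length(spec: FamilySpec, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(spec.length_mean, spec.length_sd)))
    return int(min(max(n, spec.length_min), spec.length_max))


def generate_families(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate the benchmark set and its ground truth.

    Returns records in a canonical order (families then singletons) and a
    total map seq_id -> family label (singletons get unique labels).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.target_identity
    lo, hi = (t, t) if isinstance(t, (int, float)) else t
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for f in range(spec.n_families):
        label = f"F{f:04d}"
        if spec.geometric_members:
            size = int(rng.geometric(1.0 / spec.members_per_family))
            size = max(2, size)
        else:
            size = spec.members_per_family
        target = float(rng.uniform(lo, hi)) if hi > lo else lo
        p = substitution_rate_for_identity(target)
        root = _random_sequence(rng, _draw_length(spec, rng))
        for m in range(size):
            seq = _mutate(root, p, rng)
            if spec.indel_rate > 0:
                seq = _apply_indels(seq, spec.indel_rate, rng)
            sid = f"{label}_M{m:03d}"
            records.append(SequenceRecord(sid, seq.tobytes().decode()))
            truth[sid] = label
    for s in range(spec.n_singletons):
        sid = f"S{s:05d}"
        seq = _random_sequence(rng, _draw_length(spec, rng))
        records.append(SequenceRecord(sid, seq.tobytes().decode()))
        truth[sid] = f"U_{sid}"
    return records, truth


def write_truth(truth: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, label in sorted(truth.items()):
            fh.write(f"{sid}\t{label}\n")


def read_truth(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln:
                sid, label = ln.split("\t")
                out[sid] = label
    return out


# ---------------------------------------------------------------------------
# Oracles and benchmark statistics
# ---------------------------------------------------------------------------


def nn_identity_oracle(
    records: Sequence[SequenceRecord],
    criteria: ClusterCriteria | None = None,
    max_n: int = 5000,
    force: bool = False,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Exhaustive all-vs-all alignment: nearest-neighbor identity per
    sequence plus the full pairwise identity table.

    Quadratic by construction; refuses more than ``max_n`` sequences unless
    ``force``.  Uses the same aligner settings as clustering; the NN
    *identity statistic* is identical residues over the shorter sequence
    length (the CD-HIT/MMseqs2 convention for pairwise similarity), since
    per-column identity of a short high-scoring local segment is inflated
    for unrelated sequences and would not rank neighbors meaningfully.
    Column identity is kept in the returned pair table.  A lone sequence
    gets NN identity NaN (undefined).
    """
    if len(records) > max_n and not force:
        raise ValueError(
            f"{len(records)} sequences exceeds the all-vs-all guard "
            f"({max_n}); pass force=True to override"
        )
    aligner = PairAligner(criteria or ClusterCriteria())
    nn = {r.id: float("nan") for r in records}
    rows = []
    for a, b in combinations(records, 2):
        res = aligner.align(a, b)
        sim = res.identity_shorter(a.length, b.length)
        rows.append((a.id, b.id, sim, res.identity, res.coverage_a,
                     res.coverage_b, res.accepted))
        for sid in (a.id, b.id):
            if math.isnan(nn[sid]) or sim > nn[sid]:
                nn[sid] = sim
    table = pd.DataFrame(
        rows, columns=["id_a", "id_b", "identity", "column_identity",
                       "coverage_a", "coverage_b", "accepted"]
    )
    return nn, table


def clustered_fraction_curve(
    clustering: Clustering,
    nn: Mapping[str, float],
    bin_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Fraction of sequences in clusters of size >= 2, per nearest-neighbor
    identity bin.

    Bins default to width 0.05 over [0.25, 1.0] (right edge inclusive in
    the last bin).  Empty bins report NaN.
    """
    ids = set(clustering.assignment)
    if set(nn) != ids:
        raise ValueError("clustering and NN table cover different ids")
    if bin_edges is None:
        bin_edges = [0.25 + 0.05 * i for i in range(16)]
    sizes = clustering.sizes()
    in_big = {
        sid: sizes[rep] >= 2 for sid, rep in clustering.assignment.items()
    }
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        members = [
            sid for sid, v in nn.items()
            if not math.isnan(v)
            and (lo <= v < hi or (hi == bin_edges[-1] and v == hi))
        ]
        frac = (
            sum(in_big[s] for s in members) / len(members) if members
            else float("nan")
        )
        rows.append((lo, hi, len(members), frac))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n", "fraction"])


def inter_representative_identities(
    clustering: Clustering,
    records: Mapping[str, SequenceRecord],
    criteria: ClusterCriteria | None = None,
    sample_size: int = 2000,
    exhaustive_below: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Pairwise identities among cluster representatives.

    Exhaustive below ``exhaustive_below`` representatives, otherwise a
    seeded sample of ``sample_size`` pairs.  Identity is identical residues
    over the shorter sequence (the pairwise-similarity convention, see
    :func:`nn_identity_oracle`).  Returns the identities and the fraction
    exceeding the clustering identity threshold — well-separated
    clusterings keep representatives below it (representatives tend to stay
    mutually dissimilar beyond the clustering radius).
    """
    reps = clustering.representatives
    if len(reps) < 2:
        return np.array([]), float("nan")
    crit = criteria or clustering.criteria or ClusterCriteria()
    aligner = PairAligner(crit)
    all_pairs = list(combinations(reps, 2))
    if len(reps) >= exhaustive_below and len(all_pairs) > sample_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_pairs), size=sample_size, replace=False)
        pairs = [all_pairs[i] for i in sorted(idx)]
    else:
        pairs = all_pairs
    idents = np.array(
        [
            aligner.align(records[a], records[b]).identity_shorter(
                records[a].length, records[b].length
            )
            for a, b in pairs
        ]
    )
    frac_exceeding = float(np.mean(idents > crit.min_identity))
    return idents, frac_exceeding


def truth_recall_precision(
    clustering: Clustering, truth: Mapping[str, str]
) -> tuple[float, float]:
    """Pairwise recall and precision of the clustering against ground truth.

    Over unordered pairs: recall = same-family pairs co-clustered /
    same-family pairs; precision = co-clustered pairs same-family /
    co-clustered pairs.  Computed from the cluster-by-family contingency
    (no quadratic pair enumeration).  Precision is NaN when nothing is
    co-clustered; recall is NaN when all families are singletons.
    """
    if set(clustering.assignment) != set(truth):
        raise ValueError("clustering and truth cover different ids")
    cont: dict[tuple[str, str], int] = {}
    fam_sizes: dict[str, int] = {}
    clu_sizes: dict[str, int] = {}
    for sid, rep in clustering.assignment.items():
        fam = truth[sid]
        cont[(rep, fam)] = cont.get((rep, fam), 0) + 1
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
        clu_sizes[rep] = clu_sizes.get(rep, 0) + 1
    pairs = lambda n: n * (n - 1) // 2
    tp = sum(pairs(n) for n in cont.values())
    same_family = sum(pairs(n) for n in fam_sizes.values())
    co_clustered = sum(pairs(n) for n in clu_sizes.values())
    recall = tp / same_family if same_family else float("nan")
    precision = tp / co_clustered if co_clustered else float("nan")
    return recall, precision
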