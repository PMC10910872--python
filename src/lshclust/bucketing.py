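"""Bucketing of masked kmers and bucket-representative candidate pairs.

For each of the L tables, every kmer is reduced to its masked key (the
retained positions, in order).  Sequences sharing a key form a bucket.  To
keep per-bucket work linear, only two representatives are designated per
bucket (the two longest members, ids breaking ties) and candidate pairs are
member-vs-representative only — never all-vs-all within a bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from operator import itemgetter
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alphabet import KmerOccurrence
from .lsh import MaskFamily

__all__ = [
    "BucketKey",
    "Bucket",
    "masked_key",
    "build_buckets",
    "select_representatives",
    "candidate_pairs",
    "fast_candidate_pairs",
]


@dataclass(frozen=True)
class BucketKey:
    table_index: int
    masked_kmer: str


@dataclass
class Bucket:
    key: BucketKey
    members: set[str]
    representatives: tuple[str, ...] = field(default_factory=tuple)


def masked_key(mask: Iterable[int], kmer: str, table_index: int, k: int) -> BucketKey:
    """Key = kmer symbols at positions outside the mask, in original order."""
    if len(kmer) != k:
        raise ValueError(f"kmer length {len(kmer)} != k={k}")
    dropped = set(mask)
    if any(p < 0 or p >= k for p in dropped):
        raise ValueError(f"mask positions outside [0, {k})")
    return BucketKey(
        table_index, "".join(kmer[i] for i in range(k) if i not in dropped)
    )


def build_buckets(
    occurrences: Sequence[KmerOccurrence], family: MaskFamily
) -> list[Bucket]:
    """Group sequences by (table, masked kmer).

    A sequence counts once per bucket no matter how many of its kmers hit
    the same key.  Buckets are returned in canonical (table, key) order so
    downstream steps are independent of input order.
    """
    k = family.k
    table: dict[tuple[int, str], set[str]] = {}
    for t, retained in enumerate(family.retained()):
        getter = itemgetter(*retained) if retained else (lambda km: ())
        for occ in occurrences:
            if len(occ.kmer) != k:
                raise ValueError(
                    f"kmer {occ.kmer!r} from {occ.seq_id} has length "
                    f"{len(occ.kmer)} != k={k}"
                )
            key = (t, "".join(getter(occ.kmer)))
            table.setdefault(key, set()).add(occ.seq_id)
    return [
        Bucket(key=BucketKey(t, mk), members=members)
        for (t, mk), members in sorted(table.items())
    ]


def select_representatives(
    bucket: Bucket, lengths: Mapping[str, int]
) -> Bucket:
    """Designate the longest and second-longest members (ties: smaller id)."""
    if not bucket.members:
        raise ValueError("bucket has no members")
    ranked = sorted(bucket.members, key=lambda s: (-lengths[s], s))
    bucket.representatives = tuple(ranked[: min(2, len(ranked))])
    return bucket


def candidate_pairs(buckets: Iterable[Bucket]) -> set[tuple[str, str]]:
    """Globally de-duplicated member-vs-representative pairs.

    Per bucket at most 2*(|members|-1) pairs, so total candidate count is
    linear in total bucket membership, never quadratic in bucket size.
    """
    pairs: set[tuple[str, str]] = set()
    for b in buckets:
        if not b.representatives:
            raise ValueError(f"bucket {b.key} has no representatives assigned")
        for rep in b.representatives:
            for m in b.members:
                if m != rep:
                    pairs.add((m, rep) if m < rep else (rep, m))
    return pairs


def fast_candidate_pairs(
    reduced_by_id: Mapping[str, str],
    family: MaskFamily,
    lengths: Mapping[str, int],
    max_bucket: int | None = None,
    rng=None,
) -> tuple[set[tuple[str, str]], int]:
    """Candidate pairs straight from reduced sequences, bypassing Bucket
    objects.

    Vectorizes masked-key extraction (length k-d windows viewed as raw
    bytes) and skips singleton buckets, which can never yield a pair.
    Produces exactly the pairs of ``build_buckets`` + representative
    selection + :func:`candidate_pairs`; also returns the total bucket
    count (singletons included) for reporting.
    """
    k = family.k
    retained = [np.array(r, dtype=np.intp) for r in family.retained()]
    width = k - family.d
    # per-table map masked-key-bytes -> member seq_ids (dups possible)
    tables: list[dict] = [dict() for _ in range(family.L)]
    for sid in sorted(reduced_by_id):
        reduced = reduced_by_id[sid]
        arr = np.frombuffer(reduced.encode(), dtype=np.uint8)
        if arr.size < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, k)
        for t, ret in enumerate(retained):
            sub = np.ascontiguousarray(win[:, ret])
            # tolist() on a void view yields one bytes key per kmer window
            keys = sub.view(f"V{width}").ravel().tolist()
            tab = tables[t]
            for key in keys:
                hit = tab.get(key)
                if hit is None:
                    tab[key] = sid
                elif isinstance(hit, str):
                    if hit != sid:
                        tab[key] = [hit, sid]
                elif hit[-1] != sid:
                    hit.append(sid)
    n_buckets = sum(len(t) for t in tables)
    pairs: set[tuple[str, str]] = set()
    for tab in tables:
        for members in tab.values():
            if isinstance(members, str):
                continue
            uniq = sorted(set(members), key=lambda s: (-lengths[s], s))
            if max_bucket is not None and len(uniq) > max_bucket:
                uniq = sorted(
                    rng.sample(sorted(uniq), max_bucket),
                    key=lambda s: (-lengths[s], s),
                )
            for rep in uniq[:2]:
                for m in uniq:
                    if m != rep:
                        pairs.add((m, rep) if m < rep else (rep, m))
    return pairs, n_buckets
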