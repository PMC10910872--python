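"""Masking locality-sensitive hash families and their MCMC design.

A masking hash function deletes a fixed set of d positions from a length-k
kmer; two kmers collide in its table iff they agree on the k-d retained
positions.  A family of L such functions has *no false negatives at radius
r* exactly when every r-subset of the k positions is contained in some
function's dropped set — i.e. the dropped sets form a covering design
C(k, d, r).  This module designs such families by simulated-annealing
Metropolis MCMC, verifies the covering property by exhaustive enumeration,
and computes the collision-probability profile as a function of the number
of mismatches.

At the operating point k=12, d=3, L=24, r=2 the minimal covering has
exactly 24 blocks (the Schönheim bound ceil(12/3 * ceil(11/2)) = 24 is
attained), so 24 tables suffice for a zero-false-negative family tolerating
2 mismatches.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

__all__ = [
    "MaskFamily",
    "CoverageReport",
    "random_family",
    "optimize_family",
    "uncovered_subsets",
    "collision_profile",
    "coverage_report",
    "minimal_covering_l",
    "schonheim_bound",
]


@dataclass(frozen=True)
class MaskFamily:
    """L masking hash functions for length-k kmers, each dropping d positions.

    ``masks`` is an ordered tuple of sorted position-tuples; duplicates are
    removed at construction (duplicate tables waste work and count once for
    coverage).
    """

    k: int
    d: int
    masks: tuple[tuple[int, ...], ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.d < self.k:
            raise ValueError(f"need 0 <= d < k, got d={self.d}, k={self.k}")
        seen: dict[tuple[int, ...], None] = {}
        for m in self.masks:
            t = tuple(sorted(m))
            if len(set(t)) != self.d or any(p < 0 or p >= self.k for p in t):
                raise ValueError(f"mask {m} is not a d-subset of [0, {self.k})")
            seen.setdefault(t, None)
        object.__setattr__(self, "masks", tuple(seen))

    @property
    def L(self) -> int:
        return len(self.masks)

    def retained(self) -> list[tuple[int, ...]]:
        """Per table, the positions kept by the mask, in order."""
        return [
            tuple(p for p in range(self.k) if p not in set(m)) for m in self.masks
        ]

    # -- plain-text serialization (bit-exact round trip) ------------------

    def to_text(self, r: int | None = None) -> str:
        lines = [f"k={self.k}", f"d={self.d}", f"L={self.L}"]
        if r is not None:
            lines.append(f"r={r}")
        if self.seed is not None:
            lines.append(f"seed={self.seed}")
        lines += [",".join(str(p) for p in m) for m in self.masks]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MaskFamily":
        header: dict[str, int] = {}
        masks: list[tuple[int, ...]] = []
        for ln in text.splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if "=" in ln:
                key, val = ln.split("=", 1)
                header[key.strip()] = int(val)
            else:
                masks.append(tuple(int(p) for p in ln.split(",")) if ln else ())
        for req in ("k", "d"):
            if req not in header:
                raise ValueError(f"mask family text lacks {req}=")
        return cls(
            k=header["k"], d=header["d"], masks=tuple(masks),
            seed=header.get("seed"),
        )

    def save(self, path, r: int | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text(r=r))

    @classmethod
    def load(cls, path) -> "MaskFamily":
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass(frozen=True)
class CoverageReport:
    """Exhaustive verification of the zero-false-negative claim at radius r."""

    r: int
    uncovered: int
    total_r_subsets: int
    uncovered_examples: tuple[tuple[int, ...], ...]
    profile: tuple[float, ...]  # collision probability per mismatch count 0..k


def random_family(k: int, d: int, L: int, seed: int) -> MaskFamily:
    """L dropped-position sets sampled uniformly from the d-subsets of [0, k)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 <= d < k:
        raise ValueError(f"need 0 <= d < k, got d={d}, k={k}")
    rng = random.Random(seed)
    masks = tuple(tuple(sorted(rng.sample(range(k), d))) for _ in range(L))
    return MaskFamily(k=k, d=d, masks=masks, seed=seed)


def uncovered_subsets(
    family: MaskFamily, r: int
) -> tuple[int, list[tuple[int, ...]]]:
    """Count (and enumerate) r-subsets of positions contained in no mask.

    Exhaustive over all C(k, r) subsets; a zero count certifies that kmer
    pairs with <= r mismatches always share at least one bucket.
    """
    if not 0 <= r <= family.k:
        raise ValueError(f"need 0 <= r <= k, got r={r}")
    mask_sets = [frozenset(m) for m in family.masks]
    missing = [
        s
        for s in combinations(range(family.k), r)
        if not any(ms.issuperset(s) for ms in mask_sets)
    ]
    return len(missing), missing


def collision_profile(
    family: MaskFamily,
    enumeration_cap: int = 5_000_000,
    mc_draws: int = 100_000,
    mc_seed: int = 0,
) -> list[float]:
    """For each mismatch count m in 0..k, the probability that two kmers
    differing at a uniformly random m-subset of positions collide in at
    least one table.

    Exact by enumeration while C(k, m) <= ``enumeration_cap``; Monte-Carlo
    above it (never triggered for k=12, where C(12, 6)=924 is the maximum).
    """
    k = family.k
    mask_sets = [frozenset(m) for m in family.masks]
    out: list[float] = []
    for m in range(k + 1):
        if m > family.d:
            out.append(0.0)  # a d-mask cannot contain m > d positions
            continue
        total = math.comb(k, m)
        if total <= enumeration_cap:
            covered = sum(
                1
                for s in combinations(range(k), m)
                if any(ms.issuperset(s) for ms in mask_sets)
            )
            out.append(covered / total)
        else:
            rng = random.Random(mc_seed)
            hits = sum(
                1
                for _ in range(mc_draws)
                if any(
                    ms.issuperset(rng.sample(range(k), m)) for ms in mask_sets
                )
            )
            out.append(hits / mc_draws)
    return out


def coverage_report(family: MaskFamily, r: int) -> CoverageReport:
    n_unc, examples = uncovered_subsets(family, r)
    return CoverageReport(
        r=r,
        uncovered=n_unc,
        total_r_subsets=math.comb(family.k, r),
        uncovered_examples=tuple(examples[:20]),
        profile=tuple(collision_profile(family)),
    )


def schonheim_bound(k: int, d: int, r: int) -> int:
    """Recursive lower bound on the size of a covering design C(k, d, r)."""
    b = 1
    for i in range(r):
        b = math.ceil((k - r + 1 + i) * b / (d - r + 1 + i))
    return b


# ---------------------------------------------------------------------------
# Simulated-annealing designer
# ---------------------------------------------------------------------------


class _CoverState:
    """Mask family under optimization, with incremental coverage bookkeeping.

    Energy = (# uncovered r-subsets) + lam * (# covered (r+1)-subsets) /
    C(k, r+1).  The primary term drives toward zero false negatives; the
    tiny secondary term breaks ties toward families that bucket fewer
    (r+1)-mismatch pairs, i.e. fewer false positives just past the radius.
    """

    def __init__(self, k: int, d: int, r: int, masks: list[list[int]], lam: float):
        self.k, self.d, self.r, self.lam = k, d, r, lam
        self.masks = [sorted(m) for m in masks]
        self.cov_r: dict[tuple[int, ...], int] = {}
        self.cov_r1: dict[tuple[int, ...], int] = {}
        for m in self.masks:
            for s in combinations(m, r):
                self.cov_r[s] = self.cov_r.get(s, 0) + 1
            for s in combinations(m, r + 1):
                self.cov_r1[s] = self.cov_r1.get(s, 0) + 1
        self.n_covered_r = sum(1 for v in self.cov_r.values() if v > 0)
        self.total_r = math.comb(k, r)
        self.total_r1 = max(1, math.comb(k, r + 1))
        self.n_covered_r1 = sum(1 for v in self.cov_r1.values() if v > 0)

    @property
    def uncovered(self) -> int:
        return self.total_r - self.n_covered_r

    def energy(self) -> float:
        return self.uncovered + self.lam * self.n_covered_r1 / self.total_r1

    def _apply(self, idx: int, new_mask: list[int], sign_old: int) -> None:
        """Remove the old mask's subsets (sign -1) then add the new one's."""
        for s in combinations(self.masks[idx], self.r):
            v = self.cov_r[s] = self.cov_r.get(s, 0) - 1
            if v == 0:
                self.n_covered_r -= 1
        for s in combinations(self.masks[idx], self.r + 1):
            v = self.cov_r1[s] = self.cov_r1.get(s, 0) - 1
            if v == 0:
                self.n_covered_r1 -= 1
        for s in combinations(new_mask, self.r):
            v = self.cov_r[s] = self.cov_r.get(s, 0) + 1
            if v == 1:
                self.n_covered_r += 1
        for s in combinations(new_mask, self.r + 1):
            v = self.cov_r1[s] = self.cov_r1.get(s, 0) + 1
            if v == 1:
                self.n_covered_r1 += 1
        self.masks[idx] = new_mask

    def propose_and_maybe_accept(self, rng: random.Random, temp: float) -> None:
        """Metropolis step: swap one dropped position of one mask."""
        idx = rng.randrange(len(self.masks))
        mask = self.masks[idx]
        drop = mask[rng.randrange(len(mask))]
        in_mask = set(mask)
        add = rng.randrange(self.k)
        while add in in_mask:
            add = rng.randrange(self.k)
        new_mask = sorted(p for p in mask if p != drop) + [add]
        new_mask.sort()
        e0 = self.energy()
        old_mask = mask
        self._apply(idx, new_mask, -1)
        de = self.energy() - e0
        if de > 0 and rng.random() >= math.exp(-de / temp):
            self._apply(idx, old_mask, -1)  # revert


def optimize_family(
    k: int,
    d: int,
    L: int,
    r: int,
    seed: int = 0,
    max_iterations: int = 60_000,
    restarts: int = 8,
    lam: float = 0.01,
    t_initial: float = 1.5,
    t_final: float = 0.02,
) -> MaskFamily:
    """Design a mask family aiming for zero uncovered r-subsets.

    Simulated-annealing Metropolis over families of L dropped-position sets
    with geometric cooling and restarts; returns as soon as a full covering
    is found, otherwise the best family seen within budget (its residual
    uncovered count is available via :func:`uncovered_subsets`).  Fully
    deterministic given ``seed``.
    """
    if not 0 <= r <= d:
        raise ValueError(
            f"need r <= d for a zero-false-negative family, got r={r}, d={d}"
        )
    if not 0 <= d < k:
        raise ValueError(f"need 0 <= d < k, got d={d}, k={k}")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = random.Random(seed)
    cool = (t_final / t_initial) ** (1.0 / max(1, max_iterations - 1))
    best_masks: list[list[int]] | None = None
    best_energy = math.inf
    for _ in range(restarts):
        masks = [sorted(rng.sample(range(k), d)) for _ in range(L)]
        state = _CoverState(k, d, r, masks, lam)
        temp = t_initial
        for _ in range(max_iterations):
            if state.uncovered == 0:
                break
            state.propose_and_maybe_accept(rng, temp)
            temp *= cool
        if state.energy() < best_energy:
            best_energy = state.energy()
            best_masks = [list(m) for m in state.masks]
        if state.uncovered == 0:
            break
    assert best_masks is not None
    return MaskFamily(
        k=k, d=d, masks=tuple(tuple(m) for m in best_masks), seed=seed
    )


def minimal_covering_l(
    k: int,
    d: int,
    r: int,
    seed: int = 0,
    l_start: int | None = None,
    max_iterations: int = 60_000,
    restarts: int = 8,
) -> tuple[int, MaskFamily]:
    """Smallest L for which the designer reaches a full covering.

    Starts from ``l_start`` (default: a greedy covering's size) and
    decrements L while the annealer still achieves zero uncovered
    r-subsets; stops at the first failure or when L would fall below the
    Schönheim lower bound, below which no covering exists.
    """
    if l_start is None:
        l_start = len(_greedy_cover(k, d, r))
    bound = schonheim_bound(k, d, r)
    best_l: int | None = None
    best_family: MaskFamily | None = None
    L = l_start
    while L >= bound:
        fam = optimize_family(
            k, d, L, r, seed=seed + L, max_iterations=max_iterations,
            restarts=restarts,
        )
        if uncovered_subsets(fam, r)[0] != 0:
            break
        best_l, best_family = fam.L, fam  # L after de-duplication
        L = best_l - 1
    if best_family is None:
        raise RuntimeError(
            f"designer found no covering at any L in [{bound}, {l_start}]"
        )
    return best_l, best_family


def _greedy_cover(k: int, d: int, r: int) -> list[tuple[int, ...]]:
    """Greedy covering design: repeatedly add the d-subset covering the most
    still-uncovered r-subsets (deterministic tie-break by lexicographic
    order).  Used only to seed the minimal-L search with an upper bound."""
    uncovered = set(combinations(range(k), r))
    blocks: list[tuple[int, ...]] = []
    all_blocks = list(combinations(range(k), d))
    while uncovered:
        best = max(
            all_blocks,
            key=lambda b: (sum(1 for s in combinations(b, r) if s in uncovered),
                           [-x for x in b]),
        )
        gain = sum(1 for s in combinations(best, r) if s in uncovered)
        if gain == 0:
            raise RuntimeError("greedy cover stalled (should be impossible)")
        blocks.append(best)
        uncovered -= set(combinations(best, r))
    return blocks
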