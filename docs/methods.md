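# Methods

## Problem and approach

Clustering N protein sequences down to 25–30% pairwise identity normally
requires all-vs-all comparison, which is quadratic in N. `lshclust` avoids
this with locality-sensitive hashing (LSH): it spends alignment work only on
pairs that collide in at least one of L hash tables, and the hash family is
constructed so that no sufficiently similar kmer pair is ever missed. The
stages are:

1. **Alphabet reduction.** Residues are mapped to a reduced amino acid
   alphabet so conservative substitutions do not break kmer matches. The
   default is a Murphy-style 10-class grouping
   ({LVIM}{C}{A}{G}{ST}{P}{FYW}{EDNQ}{KR}{H}) with ambiguity symbol X as an
   11th class; the identity (no-reduction) alphabet and arbitrary class
   files are also supported. The reduction affects only candidate
   generation — every acceptance decision is made on the original residues.
2. **Masked kmer hashing.** All length-k windows (default k = 12) of the
   reduced sequence are hashed through L masking hash functions; function i
   deletes a fixed set of d positions (default d = 3) from the window, so
   two kmers collide in table i iff they agree on the k−d retained
   positions.
3. **Bucket representatives.** Sequences sharing a (table, masked-kmer) key
   form a bucket. Only the two longest members (ties broken by smaller id)
   act as representatives; candidate pairs are member-vs-representative
   only, bounding per-bucket work to 2(|bucket|−1) instead of
   C(|bucket|, 2).
4. **Alignment validation.** Each candidate pair is aligned
   (Smith–Waterman, BLOSUM62, gap open 11 / extend 1) and accepted when
   identity ≥ τ and bidirectional coverage ≥ c (defaults τ = 0.3, c = 0.8).
5. **Graph simplification and communities.** Accepted edges form a graph
   that is sparsified by a per-node degree cap and cut by bounded min-label
   propagation, which provably breaks long similarity chains.
6. **Greedy clustering.** Within each community, the longest unassigned
   sequence becomes a representative and captures every remaining member
   that passes the criteria against it (CD-HIT-style), until all members
   are assigned.
7. **Cascade (optional).** Clustering at a strict threshold (e.g. 0.9),
   then re-clustering the representatives at a looser one (e.g. 0.3),
   composing assignments member → rep90 → rep30.

## The zero-false-negative mask family

A pair of kmers differing at the position set S collides in table i iff
S ⊆ mask_i. A family therefore has *no false negatives at radius r* exactly
when every r-subset of {0,…,k−1} is contained in some mask — i.e. the
dropped sets form a covering design C(k, d, r). The designer is a
simulated-annealing Metropolis sampler over families of L d-subsets:

* **proposal** — replace one dropped position of one uniformly chosen mask
  with a uniformly chosen retained position;
* **energy** — (number of uncovered r-subsets) + λ·(covered
  (r+1)-subsets)/C(k, r+1) with λ = 0.01. The primary term drives toward
  zero false negatives; the tiny secondary term breaks ties toward families
  that bucket fewer pairs just past the radius (fewer false positives);
* **schedule** — geometric cooling from T = 1.5 to 0.02 over 60 000
  iterations, up to 8 restarts, stopping as soon as the primary term hits
  zero. Coverage counts are maintained incrementally, so a step costs
  O(C(d, r)). Fully deterministic given the seed.

At the standard operating point (k = 12, d = 3, r = 2) the Schönheim bound
gives ⌈12/3·⌈11/2⌉⌉ = 24, and the annealer reliably finds a 24-mask
covering of all 66 position pairs in under a second. The minimal-L search
decrements L from a greedy-covering upper bound while the designer still
succeeds, stopping at the first failure or when L would fall below the
Schönheim bound; it therefore *computes* L = 24 rather than assuming it.
`uncovered_subsets` verifies any family by exhaustive enumeration, and
`collision_profile` reports the exact collision probability per mismatch
count (enumeration while C(k, m) ≤ 5·10⁶, seeded Monte-Carlo with 10⁵ draws
above that — never needed for k = 12).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| k | 12 | kmer length; window of the hash functions |
| d | 3 | positions dropped per function; a single table absorbs ≤ d mismatches |
| L | 24 | number of tables; minimal covering size at (12, 3, 2) |
| r | 2 | tolerated kmer mismatches with zero false negatives (needs r ≤ d) |
| min_identity τ | 0.3 | per-column alignment identity threshold (0.9 for redundancy reduction) |
| min_coverage c | 0.8 | aligned span / length, required of both sequences |
| rounds T | 3 | label-propagation rounds; community co-members lie within graph distance 2T |
| degree_cap | 10 | neighbors retained per node during sparsification; leaf edges always survive |
| seed | 0 | drives family design and any subsampling; outputs are byte-identical given it |

## Identity conventions

Two notions of identity are used deliberately:

* **Acceptance identity** (thresholded by τ): identical aligned pairs /
  total alignment columns, gap columns included, on the best local
  alignment. This is the stricter of common conventions.
* **Similarity statistics** (nearest-neighbor identity, inter-representative
  identities): identical residues / shorter sequence length. Raw column
  identity of a short best-scoring local segment averages ≈ 0.3 even for
  unrelated random proteins, so it cannot rank neighbors or demonstrate
  representative separation; the shorter-length normalization (the
  CD-HIT/MMseqs2 convention) measures unrelated pairs at ≈ 0.05 and
  homologous pairs at their true identity.

## Synthetic benchmark generator

`generate_families` emulates a UniRef-like input: per family, a root
sequence drawn uniformly over the 20 residues (length normal(275, 60)
clamped to [150, 400]) and members derived by independent per-site
substitution, uniform over the 19 alternatives; unrelated singletons are
drawn the same way. The substitution rate p is calibrated analytically so
the expected pairwise identity between two members equals the target t:
(1−p)² + p²/19 = t. Indels (single-residue, symmetric) are off by default
so this calibration stays exact; they are switched on only in robustness
tests.

The standard benchmark set (`benchmark_spec`) is 20 families × 10 members
plus 100 singletons at target identity 0.95 — comfortably above the 0.9
clustering threshold, so the ground-truth partition and ideal threshold
clustering coincide and pairwise recall/precision measure what the LSH
stage can lose, not boundary effects of pairs sitting exactly at the
threshold. (At target exactly 0.9, about half of all member pairs genuinely
fall below 0.9, capping recall near 0.5 for *any* threshold clusterer —
a property of the statistic, not of the hashing.)

What the generator does **not** emulate: domain architecture (no partial
homology or domain shuffling, so the bidirectional-coverage rule is never
truly stressed), compositional bias and low-complexity regions, realistic
indel length distributions, and family size/length distributions of real
databases. Passing benchmarks therefore demonstrate correctness of the
machinery and zero-false-negative candidate generation, not real-database
clustering quality.

## Numerical and procedural choices

* Alignment: biopython's `PairwiseAligner` (C implementation). Pairs with
  no positive-scoring local alignment are rejected with identity 0. Global
  mode (free end gaps) is selectable; the default path is full local DP
  with no banding.
* Determinism: buckets, candidate pairs, communities and greedy order are
  canonically sorted before every tie-sensitive step; representative ties
  break by (length desc, id asc). Thread count changes only wall time,
  never output bytes.
* Short sequences (< k) cannot be hashed and become singleton clusters,
  counted in the run report.
* Duplicate masks are de-duplicated at family construction (they waste
  tables and count once for coverage).
* Quadratic oracles guard against > 5000 sequences unless forced.
* Desk-scale problem sizes: the test suite clusters 300-sequence benchmark
  sets (three seeds) with exhaustive ~45 000-alignment oracles, and the
  scaling log uses 400 vs 800 sequences; these sizes keep the full suite in
  a few minutes while leaving every statistic well away from small-sample
  noise.

## Known limitations

* The greedy stage re-aligns community members against representatives even
  when bucketing produced no edge; communities are small after
  chain-breaking, but a pathological community could still cost
  O(|community|²) alignments.
* Cascaded assignments are composed without re-validation, so a member's
  identity to its final deep representative may fall below the deep
  threshold (standard cascaded-clustering semantics).
* Single-machine only; the intended scale is up to ~10⁵ sequences in
  memory, not database scale.
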