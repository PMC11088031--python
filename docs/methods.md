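# Methods

## Problem and approach

Paired-end Illumina sequencing reads the two ends of a DNA fragment; the
*insert size* is the fragment's total span, so the unsequenced gap between
the mates is `insert − 2·readlen`.  When the insert exceeds twice the read
length, joining a pair into a *pseudo-long read* is a small targeted
assembly problem: starting from one read, the gap must be reconstructed
from other reads sequenced over the same region, until the mate is reached.

`plrex` solves this by iterated consensus extension over indel-free
multiple sequence alignments (MSAs).  The growing contig keeps a sliding
*anchor window* `S` of original-read length at its 3' end.  Each iteration:

1. **Candidate retrieval.**  The minhash signature of `S` — the minimum,
   under each of `h` seeded 64-bit hash functions, over all canonical
   k-mers of `S` — is looked up in `h` hash tables built once over all
   input reads.  Reads sharing a k-mer with `S` collide with high
   probability.  Canonical k-mers (the smaller of a k-mer's 2-bit packing
   and that of its reverse complement) make one query cover both strands.
2. **Placement.**  Every retrieved read is slid along `S` at every
   non-negative shift, in both orientations, counting mismatches
   (no indels: Illumina errors are dominated by substitutions).
   Admissible placements overlap at least half the candidate and mismatch
   at most 5 positions; candidates starting left of `S` are useless for 3'
   extension and are rejected.  Ties break by fewest mismatches, largest
   overlap, smallest shift, forward orientation — fixing determinism.
3. **Filtering.**  A candidate whose mate appears in the partner task's
   batch (see below) is kept unconditionally.  The remaining, unpaired
   candidates are kept only if their relative overlap `O_i` reaches the top
   occupied decile `T = max_i(⌊O_i·10⌋/10)`.  `O_i` is the candidate's
   aligned extent divided by `|S|`: since admissible placements never start
   left of the window and the MSA is open to the right, the aligned extent
   is the whole candidate.  For uniform-length reads all `O_i` coincide and
   the rule keeps everything; for length-trimmed inputs it prunes
   substantially shorter candidates unless their pairing vouches for them.
   (Normalizing instead by the window-clipped overlap would systematically
   discard exactly the right-hanging candidates that supply the extension
   columns: measured on 30x data, the MSA frontier then starves in ~6% of
   iterations and barely a third of primary tasks survive a 400 bp gap —
   incompatible with the connection rates this method is designed to
   achieve, or with its behavior on wide-insert libraries where paired
   rescue is geometrically rare.)
4. **MSA and refinement.**  Kept candidates are stacked column-wise at
   their shifts (no gap characters).  A column-content filter removes whole
   candidate rows that look like bleed-through from inexact repeats: in any
   anchor-covered column where a non-consensus base `x` reaches
   `0.3 × coverage`, either the candidates carrying `x` are removed, or —
   if the anchor itself carries `x` — the candidates *not* carrying `x`.
   Counts are updated immediately, so later columns see the refined MSA;
   only members covering the column are candidates for removal, and the
   anchor row is never removed.  One pass is made by default
   (configurable); the procedure is guarded so a column that removes
   nothing terminates.
5. **Extension.**  Per-column majority consensus (ties lexicographic,
   A<C<G<T).  The appended run spans the columns beyond the anchor that
   are contiguously covered by at least `m = 3` rows, capped at
   `stepsize = 20` bases; the window slides right by the same amount.  If
   the first column beyond the anchor is missing or under-covered, the
   task fails.  For equal-length reads coverage beyond the anchor is
   non-increasing, so requiring contiguity is equivalent to the plain
   "maximal j with coverage ≥ m" reading.
6. **Mate check.**  After each successful extension a primary task scans
   new placements of its mate target (ascending positions, never
   revisiting): a placement is accepted when the pseudo-long read length
   would fall within the admissible window and the hamming distance is at
   most `⌈0.05·|mate|⌉`.  The *first* admissible placement wins — the
   documented source of length errors on wide-insert libraries, where an
   inexact repeat can offer an earlier, wrong placement.

### Four tasks per pair

For a pair (S1, S2) with reverse complements (RC1, RC2), four tasks run in
lockstep: T1 extends S1 toward RC2 and T3 extends S2 toward RC1 (primary);
T2 starts from RC2 and T4 from RC1 (auxiliary).  T2/T4 windows track the
regions where the mates of T1/T3's candidates lie, which is what makes the
paired-candidate rescue in step 3 well defined; their surplus bases also
feed the optional outward extension.  An auxiliary task stops as soon as
its primary partner stops; any task stops when its contig reaches the
maximum length.  The admissible length window defaults to
`[max(2·readlen, μ − 4σ), μ + 4σ]` for user-supplied insert mean μ and
standard deviation σ — the lower bound deliberately excludes overlapping
pairs, which are a different (and simpler) problem.

### Finalization (strict modes)

- **Mode 2** connects a pair only if both primary tasks found the mate,
  their filled gaps have equal length, and the hamming distance between
  T1's gap and the reverse complement of T3's gap is at most `x`
  (default 0).  T3's gap is oriented onto T1's strand before comparison —
  the only orientation under which agreement is expected.
- **Mode 1** additionally accepts a single successful direction if the
  other task's partial extension, mapped onto the same coordinates,
  overlaps the filled gap by at least 50% of the gap size with at least
  95% matching bases in the overlap.  The 95% is read as a fraction of the
  overlap's positions (configurable); the alternative reading (fraction of
  the gap size) would make the threshold unreachable for any overlap
  shorter than 95% of the gap.
- **Mode 0** accepts any successful direction (T1 preferred when both
  succeed, fixed for determinism), and otherwise tries to merge the two
  partial extensions: a suffix of T1's contig against a prefix of the
  reverse complement of T3's contig, overlap ≥ 40 bases, ≤ 5% mismatches,
  merged length within the admissible window, longest admissible overlap
  chosen.

Output is always reported on read 1's strand; when T3 alone produced the
connection its contig is reverse complemented as a whole, which maps RC1
back to S1 verbatim.  Positions covered by the original reads always carry
the original bases — the finalizer re-stamps them after merging.  Optional
outward extension prepends the reverse complement of T4's surplus bases
and appends T2's surplus bases directly (T2 already walks read 1's
strand), each side truncated at a cap that defaults to the insert size —
which keeps outputs in the vicinity of the roughly
`1.9 × (insert + 4σ)` average lengths observed for outward-extended runs
without allowing unbounded growth.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 20 | k-mer length for minhashing (≤ 32, 2-bit packed) |
| `h` | 48 | hash functions / tables; more tables, higher recall |
| `cap` | 1000 | per-key id-list truncation, bounds repeat blow-up |
| `max_mismatches` | 5 | absolute mismatch cap per placement |
| `min_overlap_frac` | 0.5 | admissible overlap, fraction of candidate |
| `stepsize` | 20 | max consensus bases appended per iteration |
| `min_coverage` (m) | 3 | rows required per appended column |
| `refine_frac` | 0.3 | column-filter trigger, fraction of coverage (≥, inclusive) |
| `refine_passes` | 1 | sweeps of the column filter |
| `mate_max_mismatch_frac` | 0.05 | mate acceptance, fraction of mate length |
| `strict` | 0 | finalization mode (2 most restrictive) |
| `x`, `y_frac`, `z_frac` | 0, 0.5, 0.95 | strict-2 / strict-1 thresholds |
| merge overlap / mismatch | 40 bp / 5% | mode-0 partial merge rule |
| length window | μ±4σ (min ≥ 2·readlen) | admissible pseudo-read lengths |

The mate tolerance of 5% is of the same order as the hamming-distance-9
criterion (on 150 bp reads, 6%) used by the evaluation's ambiguity
analysis.

## Synthetic data and what passing tests show

The bundled simulator generates a uniform-random genome (optionally with
injected inexact repeats), places fragments uniformly on both strands,
draws insert sizes from a truncated normal, emits fixed-length reads
(read 2 reverse complemented from the fragment's 3' end), and applies
i.i.d. substitution errors.  It does **not** emulate position- or
motif-dependent Illumina error profiles, quality-score structure, indel
errors, coverage biases (GC, mappability), or the repeat structure of real
genomes.  Consequently the bundled evaluations demonstrate correctness of
the machinery (retrieval, alignment, consensus, termination, strict-mode
logic) and behavior under substitution noise and insert-size variance;
connection rates and error rates on real libraries will be worse and are
dominated by genomic repeats, which a random genome under-represents by
construction.  The repeat-injection option exists precisely to probe that
failure mode (ambiguous mate placements, category-A pairs).

Coverage at the simulated genome's edges ramps down because fragments are
placed wholly inside it, so a small fraction of pairs near the ends cannot
be connected; quoted connection rates include those pairs.

## Numerical and engineering choices

- Bases are 2-bit codes (A=0..T=3); complement is `3 − code`; all
  coordinates 0-based half-open; ambiguity codes map deterministically to
  the lexicographically smallest compatible base on input.
- Hash family: murmur3's 64-bit finalizer applied to `canonical_kmer XOR
  seed`, with `h` distinct seeds derived from the run seed via a counter
  RNG.  The `h` tables live in one CSR structure keyed by
  `(min_value << 6) | table_index`; queries binary-search the sorted key
  array.  Identical seeds and reads give bitwise-identical tables.
- The per-pair driver is compiled (numba); a pure-Python reference driver
  composed from the documented per-step operations is kept and asserted
  equivalent on simulations, so the compiled path cannot silently diverge
  from the documented semantics.  Auxiliary tasks are skipped when
  provably inert (uniform read lengths and no outward extension) — the
  decile filter then keeps every candidate regardless of the paired
  rescue, so the skip is an optimization, not a behavior change (also
  asserted in tests).
- Pairs are processed independently and sequentially in input order;
  results are a pure function of input and seed, so reruns and any thread
  setting produce byte-identical outputs.
- Evaluation edit distance is full Levenshtein (edlib); the *modified*
  edit distance subtracts the absolute produced-vs-expected length
  difference, isolating substitution errors from length errors.
- Degenerate inputs: reads shorter than k are never indexed and their
  pairs are reported unconnected; empty candidate sets fail the extension
  (no fabricated sequence); a zero-length gap (insert = 2·readlen) is a
  legal connection.

## Problem sizes used by the bundled checks

The acceptance checks run scaled-down analogues of whole-genome
experiments: a 200 kbp genome at 30x with read length 150 and insert
N(500, 150) for the connection-rate claim, a 1 Mbp genome at 30x with read
length 100 and insert N(500, 10) for the gap-error-rate claims, and a
noiseless 100 kbp dataset for exact-recovery checks.  On one CPU these
complete in roughly 1, 9 and 1 minutes respectively.

## Known limitations

- No indel-aware alignment: a single sequencing indel inside a candidate
  read misplaces its tail; such reads are usually rejected by the
  5-mismatch cap rather than misassembled, at some cost in coverage.
- Repeats longer than the insert size cannot be resolved; the first-mate-
  position rule then biases produced lengths short, as reflected in the
  category-A error analysis.
- The index is built in one pass in memory; no on-disk persistence and no
  memory-capped batched construction.
- Qualities are parsed and passed through for unconnected pairs but not
  used in consensus and not emitted for consensus bases.
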