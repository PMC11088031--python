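"""Synthetic paired-end data with known truth, and gap-accuracy metrics.

The simulator emulates Illumina-like paired-end sequencing: a uniform-random
reference (optionally with injected inexact repeats), fragments placed
uniformly on either strand, insert sizes drawn from a truncated normal
distribution, fixed-length reads from the fragment ends (read 2 reverse
complemented), and i.i.d. per-base substitution errors.  Insert size is the
total fragment span including both reads, so the true gap length is
insert - 2 * readlen; the lower insert bound excludes overlapping pairs.

Evaluation follows the gap-accuracy metrics used for read extension: the
edit distance between the filled gap and the true gap, the modified edit
distance (subtracting the absolute produced-vs-expected length difference,
which isolates substitution errors from length errors), the aggregate error
rate (sum of edits over the sum of produced gap lengths), and a
stratification of pairs by mate-placement ambiguity: a pair whose mate
admits multiple placements inside the allowed length window (hamming
distance <= 9) is "category A", the dominant source of length errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from ._kernels import count_placements
from .seqcore import EncodedSequence, decode_codes, revcomp_codes, ReadStore
from .task_engine import LengthWindow


@dataclass(frozen=True)
class RepeatSpec:
    """Inexact repeats injected into a random genome (for stress tests)."""

    count: int
    length: int
    divergence: float = 0.0   # per-base substitution rate between the copies


def simulate_genome(length: int, seed: int,
                    repeat_spec: RepeatSpec | None = None) -> EncodedSequence:
    """Uniform-random ACGT genome; optional duplicated segments.

    Each repeat copies a random source segment to a random destination
    (overwriting), mutating the copy at the given per-base divergence.
    Deterministic for a fixed seed.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    if repeat_spec is not None:
        if repeat_spec.length > length:
            raise ValueError("repeat longer than the genome")
        for _ in range(repeat_spec.count):
            src = int(rng.integers(0, length - repeat_spec.length + 1))
            dst = int(rng.integers(0, length - repeat_spec.length + 1))
            copy = codes[src:src + repeat_spec.length].copy()
            if repeat_spec.divergence > 0:
                mut = rng.random(repeat_spec.length) < repeat_spec.divergence
                copy[mut] = (copy[mut] + rng.integers(1, 4, size=int(mut.sum()),
                                                      dtype=np.uint8)) % 4
            codes[dst:dst + repeat_spec.length] = copy
    return EncodedSequence(codes)


TRUTH_COLUMNS = ["pair_id", "start", "end", "insert", "strand",
                 "n_err_read1", "n_err_read2"]


@dataclass
class SimulatedPairs:
    """Reads plus ground truth.  Reads are interleaved in the store: pair p
    occupies ids 2p (read 1) and 2p + 1 (read 2)."""

    store: ReadStore
    truth: pd.DataFrame
    read_len: int
    genome: EncodedSequence

    @property
    def n_pairs(self) -> int:
        return len(self.store) // 2

    def read1_codes(self, p: int) -> np.ndarray:
        return self.store.get_codes(2 * p)

    def read2_codes(self, p: int) -> np.ndarray:
        return self.store.get_codes(2 * p + 1)


def true_gap_codes(genome: EncodedSequence, start: int, end: int, strand: int,
                   read_len: int) -> np.ndarray:
    """True gap bases on read 1's strand for a fragment [start, end)."""
    inner = genome.codes[start + read_len:end - read_len]
    return inner if strand > 0 else revcomp_codes(inner)


def simulate_pairs(genome: EncodedSequence, coverage: float, read_len: int,
                   insert_mu: float, insert_sd: float,
                   insert_bounds: tuple, subs_rate: float,
                   seed: int) -> SimulatedPairs:
    """Simulate ceil(coverage * |genome| / (2 * read_len)) read pairs.

    Fragment starts are uniform, strands equiprobable, insert sizes drawn
    from N(mu, sd) truncated to `insert_bounds` by resampling.  Read 2 is
    the reverse complement of the fragment's 3' end.  Substitution errors
    are i.i.d. per base at `subs_rate`; error counts are recorded per read.
    """
    lo, hi = int(insert_bounds[0]), int(insert_bounds[1])
    if lo < 2 * read_len + 1:
        raise ValueError("insert lower bound must exceed 2 * read_len "
                         "(overlapping pairs are out of scope)")
    g = genome.codes
    if hi > g.shape[0]:
        raise ValueError("genome shorter than the maximal insert size")
    n_pairs = math.ceil(coverage * g.shape[0] / (2 * read_len))
    rng = np.random.Generator(np.random.PCG64(seed))

    inserts = np.rint(rng.normal(insert_mu, insert_sd, size=n_pairs)).astype(np.int64)
    bad = (inserts < lo) | (inserts > hi)
    while bad.any():
        inserts[bad] = np.rint(rng.normal(insert_mu, insert_sd,
                                          size=int(bad.sum()))).astype(np.int64)
        bad = (inserts < lo) | (inserts > hi)
    starts = (rng.random(n_pairs) * (g.shape[0] - inserts + 1)).astype(np.int64)
    strands = np.where(rng.random(n_pairs) < 0.5, 1, -1).astype(np.int64)

    total = n_pairs * 2 * read_len
    codes = np.empty(total, np.uint8)
    offsets = np.arange(0, total + read_len, read_len, dtype=np.int64)
    n_err = np.zeros((n_pairs, 2), np.int64)
    for p in range(n_pairs):
        s = starts[p]
        e = s + inserts[p]
        if strands[p] > 0:
            r1 = g[s:s + read_len].copy()
            r2 = revcomp_codes(g[e - read_len:e])
        else:
            r1 = revcomp_codes(g[e - read_len:e])
            r2 = g[s:s + read_len].copy()
        codes[2 * p * read_len:(2 * p + 1) * read_len] = r1
        codes[(2 * p + 1) * read_len:(2 * p + 2) * read_len] = r2
    if subs_rate > 0:
        err_mask = rng.random(total) < subs_rate
        n_hits = int(err_mask.sum())
        codes[err_mask] = (codes[err_mask]
                           + rng.integers(1, 4, size=n_hits, dtype=np.uint8)) % 4
        per_read = np.add.reduceat(err_mask, offsets[:-1])
        n_err = per_read.reshape(n_pairs, 2)

    truth = pd.DataFrame({
        "pair_id": np.arange(n_pairs, dtype=np.int64),
        "start": starts,
        "end": starts + inserts,
        "insert": inserts,
        "strand": strands,
        "n_err_read1": n_err[:, 0],
        "n_err_read2": n_err[:, 1],
    })
    store = ReadStore(codes, offsets)
    return SimulatedPairs(store=store, truth=truth, read_len=read_len,
                          genome=genome)


def gap_edit_distance(produced, true) -> int:
    """Levenshtein distance between a produced and the true gap sequence."""
    a = produced if isinstance(produced, str) else decode_codes(
        produced.codes if isinstance(produced, EncodedSequence) else produced)
    b = true if isinstance(true, str) else decode_codes(
        true.codes if isinstance(true, EncodedSequence) else true)
    if len(a) == 0:
        return len(b)
    if len(b) == 0:
        return len(a)
    return int(edlib.align(a, b, task="distance")["editDistance"])


def modified_gap_edit_distance(edit_distance: int, gap_len_expected: int,
                               gap_len_produced: int) -> int:
    """Edit distance minus the absolute expected-vs-produced length
    difference; never negative, since an edit distance is bounded below by
    the length difference."""
    return edit_distance - abs(gap_len_expected - gap_len_produced)


def ambiguous_mate_positions(genome: EncodedSequence, read1_codes, read2_codes,
                             start: int, end: int, strand: int,
                             window: LengthWindow, max_hamming: int = 9) -> int:
    """Admissible mate placements inside the allowed length window.

    For each extension direction, the mate read (reverse complemented onto
    the anchoring read's strand) is slid over every genome position at which
    the resulting pseudo-long read length would fall in [min_len, max_len];
    positions with hamming distance <= max_hamming count as placements.
    The reported count is the maximum over the two directions, so a pair is
    ambiguous (category A) when either direction admits more than one
    placement.
    """
    g = genome.codes
    n = g.shape[0]
    gr = revcomp_codes(g)
    l1 = read1_codes.shape[0]
    l2 = read2_codes.shape[0]
    if strand > 0:
        fs_fwd = start          # read 1's 5' end on its strand
        fs_rev = n - end        # read 2's 5' end on its strand
        g1, g2 = g, gr
    else:
        fs_fwd = n - end
        fs_rev = start
        g1, g2 = gr, g
    mate1 = revcomp_codes(np.asarray(read2_codes, np.uint8))
    mate2 = revcomp_codes(np.asarray(read1_codes, np.uint8))
    c1 = count_placements(g1, mate1, fs_fwd + window.min_len - l2,
                          fs_fwd + window.max_len - l2, max_hamming)
    c2 = count_placements(g2, mate2, fs_rev + window.min_len - l1,
                          fs_rev + window.max_len - l1, max_hamming)
    return int(max(c1, c2))


@dataclass
class GapEval:
    """Aggregate and per-pair gap accuracy of a run against simulator truth."""

    per_pair: pd.DataFrame
    n_connected: int
    n_error_free: int
    error_rate: float
    modified_error_rate: float
    by_category: dict

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"category": "all", "n_connected": self.n_connected,
                 "n_error_free": self.n_error_free,
                 "error_rate": self.error_rate,
                 "modified_error_rate": self.modified_error_rate}]
        for cat, d in sorted(self.by_category.items()):
            rows.append({"category": cat, **d})
        return pd.DataFrame(rows)


def _rate(edits: int, lengths: int) -> float:
    return edits / lengths if lengths > 0 else 0.0


def evaluate_run(results, sim: SimulatedPairs, window: LengthWindow,
                 max_hamming: int = 9, stratify: bool = True) -> GapEval:
    """Score connected pseudo-long reads against the simulator's truth.

    `results` is an iterable of PseudoLongRead keyed by pair_id.  For each
    connected pair the filled gap (codes[gap_start:gap_end], read 1 strand)
    is compared with the true gap; error rates aggregate the edits over the
    produced gap lengths.  With `stratify`, pairs are split into ambiguity
    categories A (multiple admissible mate placements) and B (unique).
    """
    truth = sim.truth.set_index("pair_id")
    rows = []
    for plr in results:
        if plr.status != "connected":
            continue
        if plr.pair_id not in truth.index:
            raise KeyError(f"no truth record for pair {plr.pair_id}")
        t = truth.loc[plr.pair_id]
        tg = true_gap_codes(sim.genome, int(t["start"]), int(t["end"]),
                            int(t["strand"]), sim.read_len)
        pg = plr.codes[plr.gap_start:plr.gap_end]
        ed = gap_edit_distance(pg, tg)
        med = modified_gap_edit_distance(ed, tg.shape[0], pg.shape[0])
        if stratify:
            amb = ambiguous_mate_positions(
                sim.genome, sim.read1_codes(plr.pair_id),
                sim.read2_codes(plr.pair_id), int(t["start"]), int(t["end"]),
                int(t["strand"]), window, max_hamming)
        else:
            amb = -1
        rows.append((plr.pair_id, ed, pg.shape[0], tg.shape[0], med, amb))
    per_pair = pd.DataFrame(
        rows, columns=["pair_id", "edit_distance", "gap_len_produced",
                       "gap_len_expected", "modified_edit_distance",
                       "n_mate_positions"])
    n_connected = len(per_pair)
    n_error_free = int((per_pair["edit_distance"] == 0).sum())
    error_rate = _rate(int(per_pair["edit_distance"].sum()),
                       int(per_pair["gap_len_produced"].sum()))
    modified_rate = _rate(int(per_pair["modified_edit_distance"].sum()),
                          int(per_pair["gap_len_produced"].sum()))
    by_category = {}
    if stratify and n_connected:
        cats = np.where(per_pair["n_mate_positions"] > 1, "A", "B")
        for cat in ("A", "B"):
            sub = per_pair[cats == cat]
            by_category[cat] = {
                "n_connected": len(sub),
                "n_error_free": int((sub["edit_distance"] == 0).sum()),
                "error_rate": _rate(int(sub["edit_distance"].sum()),
                                    int(sub["gap_len_produced"].sum())),
                "modified_error_rate": _rate(
                    int(sub["modified_edit_distance"].sum()),
                    int(sub["gap_len_produced"].sum())),
            }
    return GapEval(per_pair=per_pair, n_connected=n_connected,
                   n_error_free=n_error_free, error_rate=error_rate,
                   modified_error_rate=modified_rate, by_category=by_category)


def write_truth_tsv(sim: SimulatedPairs, path) -> None:
    sim.truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth file lacks columns: {sorted(missing)}")
    return df


def write_fastq_pair(sim: SimulatedPairs, prefix: str) -> tuple:
    """Write the simulated pairs as two mate FASTQ files (constant quality)."""
    p1 = f"{prefix}_1.fastq"
    p2 = f"{prefix}_2.fastq"
    qual = "I" * sim.read_len
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for p in range(sim.n_pairs):
            f1.write(f"@pair{p}/1\n{decode_codes(sim.read1_codes(p))}\n+\n{qual}\n")
            f2.write(f"@pair{p}/2\n{decode_codes(sim.read2_codes(p))}\n+\n{qual}\n")
    return p1, p2
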