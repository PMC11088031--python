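"""Per-pair orchestration of the four extension tasks.

For a read pair (S1, S2) with reverse complements (RC1, RC2), four tasks
are created: T1 extends S1 toward RC2 and T3 extends S2 toward RC1 (the
primary tasks); T2 starts from RC2 and T4 from RC1 (auxiliary tasks whose
candidate batches supply the paired-candidate rescue for T1 and T3, and
whose surplus bases feed the optional outward extension).  Partner pairs
are T1/T2 and T3/T4; partners advance in lockstep so that each filter step
sees a same-iteration partner batch.

`run_pair` offers two engines with identical semantics: a pure-Python
reference built from the documented per-step operations, and a compiled
driver that runs the whole pair inside one numba kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .minhash_index import HashFamily, KmerHashTables, query_candidates
from .msa_engine import (STATUS_FAILED, ExtendParams, build_msa, extend_window,
                         refine_msa)
from .pairwise_align import AlignParams, ShiftAlignment, best_alignment
from .seqcore import EncodedSequence, ReadStore, revcomp_codes

ACTIVE = "active"
MATE_FOUND = "mate_found"
FAILED = "failed"
STOPPED = "stopped"

_STATUS_FROM_CODE = {
    _kernels.ST_ACTIVE: ACTIVE,
    _kernels.ST_MATE_FOUND: MATE_FOUND,
    _kernels.ST_FAILED: FAILED,
    _kernels.ST_STOPPED: STOPPED,
}

PRIMARY = "primary"
AUXILIARY = "auxiliary"


@dataclass(frozen=True)
class LengthWindow:
    """Admissible pseudo-long read length range [min_len, max_len]."""

    min_len: int
    max_len: int

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")

    @classmethod
    def from_insert(cls, insert_mu: float, insert_sd: float,
                    read_len: int) -> "LengthWindow":
        """Default window: [max(2*readlen, mu - 4*sd), mu + 4*sd]."""
        return cls(min_len=int(max(2 * read_len, insert_mu - 4 * insert_sd)),
                   max_len=int(insert_mu + 4 * insert_sd))


@dataclass
class ExtensionTask:
    role: str                 # PRIMARY or AUXILIARY
    label: str                # T1 | T2 | T3 | T4
    contig: np.ndarray        # accumulated codes; starts as the start read
    start_len: int            # window length == start read length
    partner_label: str
    mate_target: np.ndarray | None = None   # primary only (RC2 for T1, RC1 for T3)
    state: str = ACTIVE
    mate_pos: int = -1
    pair_id: int = -1
    source_ids: tuple = (-1, -1)            # own-pair read ids (excluded hits)
    next_mate_scan_pos: int = 0

    @property
    def window(self) -> np.ndarray:
        """The last |start read| bases of the contig (the anchor S)."""
        return self.contig[len(self.contig) - self.start_len:]

    @property
    def extension_codes(self) -> np.ndarray:
        """Bases appended beyond the starting sequence."""
        return self.contig[self.start_len:]

    @property
    def gap_codes(self) -> np.ndarray:
        """Filled gap between the start read and the mate (primary, found)."""
        if self.state != MATE_FOUND:
            raise ValueError("gap defined only for mate_found tasks")
        return self.contig[self.start_len:self.mate_pos]


@dataclass
class CandidateEntry:
    read_id: int
    codes: np.ndarray                # read bases, forward orientation
    alignment: ShiftAlignment
    is_paired_rescue: bool
    relative_overlap: float          # O: aligned candidate extent / |S|


@dataclass
class CandidateBatch:
    entries: list = field(default_factory=list)

    def ids(self):
        return {e.read_id for e in self.entries}

    def __len__(self):
        return len(self.entries)


def make_tasks(s1, s2, pair_id: int = -1,
               read_ids: tuple = (-1, -1)) -> tuple:
    """Create the four extension tasks (T1..T4) for a read pair."""
    c1 = s1.codes if isinstance(s1, EncodedSequence) else np.asarray(s1, np.uint8)
    c2 = s2.codes if isinstance(s2, EncodedSequence) else np.asarray(s2, np.uint8)
    rc1 = revcomp_codes(c1)
    rc2 = revcomp_codes(c2)
    common = dict(pair_id=pair_id, source_ids=tuple(read_ids))
    t1 = ExtensionTask(role=PRIMARY, label="T1", contig=c1.copy(),
                       start_len=len(c1), partner_label="T2",
                       mate_target=rc2, **common)
    t2 = ExtensionTask(role=AUXILIARY, label="T2", contig=rc2.copy(),
                       start_len=len(c2), partner_label="T1", **common)
    t3 = ExtensionTask(role=PRIMARY, label="T3", contig=c2.copy(),
                       start_len=len(c2), partner_label="T4",
                       mate_target=rc1, **common)
    t4 = ExtensionTask(role=AUXILIARY, label="T4", contig=rc1.copy(),
                       start_len=len(c1), partner_label="T3", **common)
    return t1, t2, t3, t4


def gather_candidates(task: ExtensionTask, idx: KmerHashTables,
                      fam: HashFamily, align_params: AlignParams,
                      store: ReadStore) -> CandidateBatch:
    """Retrieve, align, and annotate candidates for the task's window.

    Reads with no admissible alignment are dropped; the task's own pair
    reads never appear.  Each entry carries the relative overlap
    O = (candidate's aligned extent) / |S|.  Since admissible placements
    never start left of the window and the MSA span is open to the right,
    the aligned extent is the whole candidate, so O = |candidate| / |S|:
    the downstream decile filter compares candidate completeness (relevant
    for length-trimmed input), not the window-clipped overlap — clipping at
    the window's right edge would systematically disfavor exactly the
    right-hanging candidates that supply the extension columns.
    """
    window = task.window
    if window.shape[0] < fam.k:
        task.state = FAILED
        return CandidateBatch()
    ids = query_candidates(EncodedSequence(window), idx, fam)
    batch = CandidateBatch()
    wlen = window.shape[0]
    for rid in ids:
        rid = int(rid)
        if rid in task.source_ids:
            continue
        codes = store.get_codes(rid)
        aln = best_alignment(window, codes, align_params)
        if aln is None:
            continue
        batch.entries.append(CandidateEntry(
            read_id=rid, codes=codes, alignment=aln, is_paired_rescue=False,
            relative_overlap=codes.shape[0] / wlen))
    return batch


def filter_candidates(batch: CandidateBatch,
                      partner_batch: CandidateBatch | None,
                      pairing=None) -> CandidateBatch:
    """Keep paired candidates unconditionally; apply the T rule to the rest.

    T = max_i(floor(O_i * 10) / 10) over the unpaired entries; unpaired
    entries with O_i < T are dropped.  `pairing` maps a read id to its mate
    id (default: id ^ 1).  When the partner task is not active
    (partner_batch is None), every entry is treated as unpaired.
    """
    if pairing is None:
        pairing = lambda i: i ^ 1
    partner_ids = partner_batch.ids() if partner_batch is not None else set()
    out = CandidateBatch()
    unpaired = []
    for e in batch.entries:
        if pairing(e.read_id) in partner_ids:
            out.entries.append(CandidateEntry(
                e.read_id, e.codes, e.alignment, True, e.relative_overlap))
        else:
            unpaired.append(e)
    if unpaired:
        thr = max(math.floor(e.relative_overlap * 10) / 10 for e in unpaired)
        for e in unpaired:
            if e.relative_overlap >= thr:
                out.entries.append(e)
    return out


def check_mate(task: ExtensionTask, window: LengthWindow,
               mate_max_mismatch_frac: float = 0.05) -> str:
    """Scan new mate placements in ascending order; first admissible wins.

    A placement p is admissible when min_len <= p + |mate| <= max_len, the
    mate fits inside the contig, and the hamming distance to the contig
    segment is at most ceil(frac * |mate|).  On success the contig is
    truncated at the mate's end and the mate's original bases are written
    over the tail.  Previously scanned placements are never revisited.
    """
    if task.role != PRIMARY or task.mate_target is None:
        raise ValueError("mate check applies to primary tasks only")
    mate = task.mate_target
    lm = mate.shape[0]
    max_mm = math.ceil(mate_max_mismatch_frac * lm)
    lo = max(task.next_mate_scan_pos, window.min_len - lm, 0)
    hi = min(len(task.contig), window.max_len) - lm
    for p in range(lo, hi + 1):
        mm = int(np.count_nonzero(task.contig[p:p + lm] != mate))
        if mm <= max_mm:
            task.state = MATE_FOUND
            task.mate_pos = p
            contig = task.contig[:p + lm].copy()
            contig[p:] = mate
            task.contig = contig
            task.next_mate_scan_pos = p
            return "found"
    task.next_mate_scan_pos = max(hi + 1, task.next_mate_scan_pos)
    return "not-found"


@dataclass(frozen=True)
class ExtenderParams:
    """Bundle of all per-pair extension parameters."""

    window: LengthWindow
    align: AlignParams = AlignParams()
    extend: ExtendParams = ExtendParams()
    mate_max_mismatch_frac: float = 0.05


def _run_pair_reference(tasks, idx, fam, store, params: ExtenderParams):
    """Lockstep reference driver built from the per-step operations."""
    tasks = list(tasks)
    by_label = {t.label: t for t in tasks}
    w = params.window
    for _ in range(w.max_len + 1):
        active = [t for t in tasks if t.state == ACTIVE]
        if not active:
            break
        batches = {}
        for t in tasks:
            if t.state == ACTIVE:
                batches[t.label] = gather_candidates(t, idx, fam, params.align, store)
        for t in tasks:
            if t.state != ACTIVE or t.label not in batches:
                continue
            partner = by_label[t.partner_label]
            pbatch = batches.get(partner.label) if partner.state == ACTIVE else None
            kept = filter_candidates(batches[t.label], pbatch)
            window_seq = EncodedSequence(t.window.copy())
            placed = [(EncodedSequence(e.codes), e.alignment, e.read_id)
                      for e in kept.entries]
            msa = build_msa(window_seq, placed)
            msa = refine_msa(msa, window_seq, params.extend)
            outcome = extend_window(msa, window_seq, params.extend)
            if outcome.status == STATUS_FAILED:
                t.state = FAILED
                continue
            from .seqcore import encode_codes
            t.contig = np.concatenate([t.contig, encode_codes(outcome.appended)])
            if t.role == PRIMARY:
                if check_mate(t, w, params.mate_max_mismatch_frac) == "found":
                    continue
            if len(t.contig) >= w.max_len:
                t.state = FAILED if t.role == PRIMARY else STOPPED
        for prim, aux in (("T1", "T2"), ("T3", "T4")):
            if by_label[prim].state != ACTIVE and by_label[aux].state == ACTIVE:
                by_label[aux].state = STOPPED
    return tuple(tasks)


def _run_pair_compiled(tasks, idx, fam, store, params: ExtenderParams,
                       run_aux: bool = True):
    id1, id2 = tasks[0].source_ids
    if id1 < 0 or id2 < 0:
        raise ValueError("compiled engine needs tasks carrying store read ids")
    status, contigs, clen, mate_pos = _kernels.run_pair_kernel(
        id1, id2, store.codes, store.rc_codes, store.offsets,
        idx.keys_sorted, idx.key_starts, idx.ids, idx.cap,
        fam.k, fam.seeds,
        params.align.max_mismatches, params.align.min_overlap_frac,
        params.extend.stepsize, params.extend.min_coverage,
        params.extend.refine_frac, params.extend.refine_passes,
        params.window.min_len, params.window.max_len,
        params.mate_max_mismatch_frac, 1 if run_aux else 0)
    out = []
    for t, task in enumerate(tasks):
        task.state = _STATUS_FROM_CODE[int(status[t])]
        task.contig = contigs[t, :clen[t]].copy()
        task.mate_pos = int(mate_pos[t])
        out.append(task)
    return tuple(out)


def run_pair(tasks, idx: KmerHashTables, fam: HashFamily, store: ReadStore,
             params: ExtenderParams, engine: str = "compiled",
             run_aux: bool = True):
    """Process the four tasks of a pair in lockstep until all terminate.

    An auxiliary task stops as soon as its primary partner stops; any task
    fails when window extension fails; any contig reaching max_len ends its
    task (primary without mate: failed; auxiliary: stopped).

    `run_aux=False` skips the auxiliary tasks; this is only sound when
    their outputs cannot influence the result (all reads of equal length,
    so the decile filter keeps every candidate with or without the paired
    rescue, and outward extension is disabled).
    """
    if any(t.start_len < fam.k for t in tasks):
        for t in tasks:
            t.state = FAILED
        return tuple(tasks)
    if engine == "compiled":
        return _run_pair_compiled(tasks, idx, fam, store, params, run_aux)
    if engine == "reference":
        return _run_pair_reference(tasks, idx, fam, store, params)
    raise ValueError(f"unknown engine {engine!r}")
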