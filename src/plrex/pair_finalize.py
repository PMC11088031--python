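"""Combine the four finished tasks of a pair into a pseudo-long read.

Strict mode 2 demands that both primary tasks found the mate and filled
gaps that agree (equal length, hamming distance <= x after orienting T3's
gap onto T1's strand).  Mode 1 additionally accepts a single successful
primary task whose gap is corroborated by the partner direction's partial
extension.  Mode 0 accepts any successful primary task and, failing that,
attempts to merge the two partial extensions when an overlap of at least
40 bases (<= 5% mismatches) yields a length compatible with the insert
size.  Output is always reported on read 1's strand; positions covered by
the original reads carry the original bases verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import best_merge_overlap, hamming_kernel
from .seqcore import decode_codes, revcomp_codes
from .task_engine import MATE_FOUND, ExtensionTask, LengthWindow

CONNECTED = "connected"
UNCONNECTED = "unconnected"


@dataclass(frozen=True)
class StrictParams:
    mode: int = 0
    x: int = 0                          # strict-2 max hamming between gaps
    y_frac: float = 0.5                 # strict-1 min overlap, fraction of gap size s
    z_frac: float = 0.95                # strict-1 min match fraction in the overlap
    merge_min_overlap: int = 40
    merge_max_mismatch_frac: float = 0.05
    outward: bool = False
    outward_cap: int | None = None      # default: insert size, set by the pipeline

    def __post_init__(self):
        if self.mode not in (0, 1, 2):
            raise ValueError("mode must be 0, 1, or 2")
        if self.x < 0 or self.merge_min_overlap < 1:
            raise ValueError("x >= 0 and merge_min_overlap >= 1 required")
        if not (0 < self.y_frac <= 1 and 0 < self.z_frac <= 1):
            raise ValueError("y_frac and z_frac must be in (0, 1]")


@dataclass
class PseudoLongRead:
    pair_id: int
    status: str                         # CONNECTED or UNCONNECTED
    codes: np.ndarray | None = None     # read 1 strand
    gap_start: int = -1                 # filled-gap coordinates within codes
    gap_end: int = -1
    outward_left_len: int = 0           # bases contributed by T4
    outward_right_len: int = 0          # bases contributed by T2
    strict_mode_used: int = 0
    provenance: str = ""                # rule that produced the connection

    @property
    def sequence(self) -> str:
        return decode_codes(self.codes) if self.codes is not None else ""

    def __len__(self) -> int:
        return 0 if self.codes is None else self.codes.shape[0]


def _read_lengths(t1: ExtensionTask, t3: ExtensionTask):
    return t1.start_len, t3.start_len


def _from_t1(t1: ExtensionTask, t3: ExtensionTask, provenance: str,
             p: StrictParams) -> PseudoLongRead:
    l1, l2 = _read_lengths(t1, t3)
    return PseudoLongRead(pair_id=t1.pair_id, status=CONNECTED,
                          codes=t1.contig.copy(), gap_start=l1,
                          gap_end=len(t1.contig) - l2,
                          strict_mode_used=p.mode, provenance=provenance)


def _from_t3(t1: ExtensionTask, t3: ExtensionTask, provenance: str,
             p: StrictParams) -> PseudoLongRead:
    # T3's contig lives on read 2's strand; emit its reverse complement so
    # the product starts with read 1 verbatim.
    l1, l2 = _read_lengths(t1, t3)
    codes = revcomp_codes(t3.contig)
    return PseudoLongRead(pair_id=t3.pair_id, status=CONNECTED,
                          codes=codes, gap_start=l1,
                          gap_end=codes.shape[0] - l2,
                          strict_mode_used=p.mode, provenance=provenance)


def _strict2_agree(t1: ExtensionTask, t3: ExtensionTask, p: StrictParams) -> bool:
    if t1.state != MATE_FOUND or t3.state != MATE_FOUND:
        return False
    g1 = t1.gap_codes
    g3 = revcomp_codes(t3.gap_codes)
    if g1.shape[0] != g3.shape[0]:
        return False
    return hamming_kernel(g1, g3) <= p.x


def _strict1_corroborated(found: ExtensionTask, other: ExtensionTask,
                          p: StrictParams) -> bool:
    """One-sided rule: the partner direction's partial extension must
    overlap the filled gap by >= y_frac * s positions with >= z_frac
    matching bases in the overlap (both gaps oriented onto one strand)."""
    gap = found.gap_codes
    s = gap.shape[0]
    ext = revcomp_codes(other.extension_codes)
    e = ext.shape[0]
    ov = min(e, s)
    if ov < p.y_frac * s:
        return False
    if ov == 0:
        return True
    a = gap[s - ov:]
    b = ext[e - ov:]
    matches = ov - hamming_kernel(a, b)
    return matches >= p.z_frac * ov


def merge_partial(t1: ExtensionTask, t3: ExtensionTask, p: StrictParams,
                  w: LengthWindow) -> np.ndarray | None:
    """Merge two partial extensions into one pseudo-long read, if possible.

    A suffix of T1's contig must overlap a prefix of the reverse complement
    of T3's contig by at least merge_min_overlap positions with at most
    merge_max_mismatch_frac mismatches, at a merged length compatible with
    the insert size window.  The longest admissible overlap wins.  Original
    read bases are restored verbatim at both ends of the merge.
    """
    a = t1.contig
    b = revcomp_codes(t3.contig)
    ov = best_merge_overlap(a, b, p.merge_min_overlap,
                            p.merge_max_mismatch_frac, w.min_len, w.max_len)
    if ov < 0:
        return None
    merged = np.concatenate([a, b[ov:]])
    l1, l2 = _read_lengths(t1, t3)
    merged[:l1] = t1.contig[:l1]
    merged[merged.shape[0] - l2:] = b[b.shape[0] - l2:]
    return merged


def finalize_pair(tasks, p: StrictParams, w: LengthWindow) -> PseudoLongRead:
    """Build the pseudo-long read of a pair under the selected strict mode."""
    t1, t2, t3, t4 = tasks
    plr = None
    if _strict2_agree(t1, t3, p):
        plr = _from_t1(t1, t3, "strict2-agree", p)
    elif p.mode == 1:
        if t1.state == MATE_FOUND and t3.state != MATE_FOUND:
            if _strict1_corroborated(t1, t3, p):
                plr = _from_t1(t1, t3, "strict1-corroborated", p)
        elif t3.state == MATE_FOUND and t1.state != MATE_FOUND:
            if _strict1_corroborated(t3, t1, p):
                plr = _from_t3(t1, t3, "strict1-corroborated", p)
    elif p.mode == 0:
        if t1.state == MATE_FOUND:
            plr = _from_t1(t1, t3, "mate-found", p)
        elif t3.state == MATE_FOUND:
            plr = _from_t3(t1, t3, "mate-found", p)
        else:
            merged = merge_partial(t1, t3, p, w)
            if merged is not None:
                l1, l2 = _read_lengths(t1, t3)
                plr = PseudoLongRead(pair_id=t1.pair_id, status=CONNECTED,
                                     codes=merged, gap_start=l1,
                                     gap_end=merged.shape[0] - l2,
                                     strict_mode_used=p.mode,
                                     provenance="merged-partials")
    if plr is None:
        return PseudoLongRead(pair_id=t1.pair_id, status=UNCONNECTED,
                              strict_mode_used=p.mode)
    if p.outward:
        cap = p.outward_cap if p.outward_cap is not None else w.max_len
        plr = apply_outward(plr, t2, t4, cap)
    return plr


def apply_outward(plr: PseudoLongRead, t2: ExtensionTask, t4: ExtensionTask,
                  cap: int) -> PseudoLongRead:
    """Grow a connected pseudo-long read beyond the 5' ends of the pair.

    T4 extends beyond RC1 on read 2's strand: its appended bases, reverse
    complemented, continue the molecule left of read 1.  T2 extends beyond
    RC2 already on read 1's strand: its appended bases continue the molecule
    to the right.  Each side is truncated at `cap` bases (the bases nearest
    the core are kept).
    """
    if plr.status != CONNECTED:
        return plr
    ext4 = t4.extension_codes
    ext2 = t2.extension_codes
    left = revcomp_codes(ext4[:cap]) if ext4.shape[0] else np.empty(0, np.uint8)
    right = ext2[:cap]
    if left.shape[0] == 0 and right.shape[0] == 0:
        return plr
    codes = np.concatenate([left, plr.codes, right])
    return PseudoLongRead(
        pair_id=plr.pair_id, status=plr.status, codes=codes,
        gap_start=plr.gap_start + left.shape[0],
        gap_end=plr.gap_end + left.shape[0],
        outward_left_len=int(left.shape[0]),
        outward_right_len=int(right.shape[0]),
        strict_mode_used=plr.strict_mode_used, provenance=plr.provenance)
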