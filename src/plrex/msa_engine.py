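"""Indel-free multiple sequence alignment around the anchor window.

Filtered candidates are stacked column-wise at their alignment shifts (no
gap characters).  The MSA is refined by a column-content filter that evicts
whole candidate rows originating from inexact repeats, the per-column
majority consensus is computed, and the window is slid right by appending a
consensus run of at most `stepsize` sufficiently covered columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .pairwise_align import REVCOMP, ShiftAlignment
from .seqcore import EncodedSequence, decode_codes, revcomp_codes

STATUS_EXTENDED = "extended"
STATUS_FAILED = "failed"


@dataclass(frozen=True)
class ExtendParams:
    stepsize: int = 20       # max bases appended per iteration
    min_coverage: int = 3    # m: minimum column coverage for appending
    refine_frac: float = 0.3
    refine_passes: int = 1

    def __post_init__(self):
        if self.stepsize < 1 or self.min_coverage < 1:
            raise ValueError("stepsize and min_coverage must be >= 1")
        if not 0 < self.refine_frac < 1:
            raise ValueError("refine_frac must be in (0, 1)")


@dataclass
class MsaMember:
    candidate_id: int
    shift: int
    orientation: str
    codes: np.ndarray  # bases in aligned orientation


@dataclass
class Msa:
    """Column-wise base-count matrix anchored at the current window."""

    anchor: np.ndarray                     # anchor row codes
    members: list = field(default_factory=list)

    @property
    def anchor_len(self) -> int:
        return self.anchor.shape[0]

    @property
    def n_columns(self) -> int:
        n = self.anchor_len
        for m in self.members:
            n = max(n, m.shift + m.codes.shape[0])
        return n

    def _member_arrays(self):
        nm = len(self.members)
        offs = np.zeros(nm + 1, np.int64)
        shifts = np.empty(nm, np.int64)
        for i, m in enumerate(self.members):
            offs[i + 1] = offs[i] + m.codes.shape[0]
            shifts[i] = m.shift
        flat = (np.concatenate([m.codes for m in self.members])
                if nm else np.empty(0, np.uint8))
        return flat.astype(np.uint8), offs, shifts

    def counts(self) -> np.ndarray:
        """4 x n_columns base-count matrix (anchor row included)."""
        flat, offs, shifts = self._member_arrays()
        alive = np.ones(len(self.members), np.bool_)
        return _kernels.msa_counts_kernel(self.anchor, flat, offs, shifts,
                                          alive, self.n_columns)

    def coverage(self) -> np.ndarray:
        return self.counts().sum(axis=0)


def build_msa(anchor, placed) -> Msa:
    """Overlay the anchor and each placed candidate into an MSA.

    `placed` is a list of (candidate, ShiftAlignment) or
    (candidate, ShiftAlignment, candidate_id) tuples; candidates aligned in
    reverse-complement orientation contribute their reverse-complement
    bases.  All shifts must be >= 0.
    """
    a = anchor.codes if isinstance(anchor, EncodedSequence) else np.asarray(anchor, np.uint8)
    members = []
    for entry in placed:
        cand, aln = entry[0], entry[1]
        cid = entry[2] if len(entry) > 2 else -1
        if not isinstance(aln, ShiftAlignment):
            raise TypeError("expected a ShiftAlignment per candidate")
        if aln.shift < 0:
            raise ValueError("candidate shift must be >= 0")
        codes = cand.codes if isinstance(cand, EncodedSequence) else np.asarray(cand, np.uint8)
        if aln.orientation == REVCOMP:
            codes = revcomp_codes(codes)
        members.append(MsaMember(candidate_id=cid, shift=aln.shift,
                                 orientation=aln.orientation, codes=codes))
    return Msa(anchor=a.copy(), members=members)


def refine_msa(msa: Msa, anchor=None,
               p: ExtendParams = ExtendParams()) -> Msa:
    """Column-content filter removing candidates from inexact repeats.

    For each anchor-covered column with a non-consensus base x reaching
    refine_frac * coverage: if the anchor itself carries x there, members
    covering that column without x are removed; otherwise the members
    carrying x are removed.  Counts are updated immediately, so subsequent
    columns see the refined alignment.  The anchor row is never removed.
    """
    if anchor is not None:
        a = anchor.codes if isinstance(anchor, EncodedSequence) else np.asarray(anchor, np.uint8)
        if a.shape[0] != msa.anchor_len or not np.array_equal(a, msa.anchor):
            raise ValueError("anchor does not match the MSA's anchor row")
    flat, offs, shifts = msa._member_arrays()
    alive = np.ones(len(msa.members), np.bool_)
    counts = _kernels.msa_counts_kernel(msa.anchor, flat, offs, shifts, alive,
                                        msa.n_columns)
    _kernels.refine_kernel(msa.anchor, flat, offs, shifts, alive, counts,
                           p.refine_frac, p.refine_passes)
    kept = [m for m, a_ in zip(msa.members, alive) if a_]
    return Msa(anchor=msa.anchor, members=kept)


def consensus(msa: Msa) -> str:
    """Per-column majority base; ties break lexicographically (A<C<G<T)."""
    return decode_codes(_kernels.consensus_kernel(msa.counts()))


@dataclass(frozen=True)
class ExtendOutcome:
    status: str                      # STATUS_EXTENDED or STATUS_FAILED
    appended: str = ""               # consensus substring of length n
    new_window: str = ""             # S' (same length as the old window)


def extend_window(msa: Msa, window, p: ExtendParams = ExtendParams()) -> ExtendOutcome:
    """Slide the window right along the consensus of a refined MSA.

    With i the first column beyond the anchor, the appended run spans
    columns [i, j] where every column reaches coverage >= min_coverage,
    the run is contiguous, and n = j + 1 - i <= stepsize.  The new window
    is S' = S[n:] + consensus[i:j+1].  Fails when column i does not exist
    or is under-covered.
    """
    w = window.codes if isinstance(window, EncodedSequence) else np.asarray(window, np.uint8)
    if w.shape[0] != msa.anchor_len or not np.array_equal(w, msa.anchor):
        raise ValueError("window does not match the MSA's anchor row")
    counts = msa.counts()
    j = _kernels.extend_scan(counts, msa.anchor_len, p.stepsize, p.min_coverage)
    if j < 0:
        return ExtendOutcome(status=STATUS_FAILED)
    cons = _kernels.consensus_kernel(counts)
    i = msa.anchor_len
    appended = decode_codes(cons[i:j + 1])
    n = j + 1 - i
    new_window = decode_codes(w[n:]) + appended
    return ExtendOutcome(status=STATUS_EXTENDED, appended=appended,
                         new_window=new_window)
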