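"""Indel-free (shifted hamming) placement of candidate reads on an anchor.

A candidate is slid along the anchor window at every non-negative shift, in
both orientations, and compared position-by-position.  Placements must keep
at least half the candidate inside the overlap (configurable) and mismatch
in at most 5 positions (configurable).  The candidate may never start left
of the anchor, because extension only proceeds at the 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._kernels import best_alignment_kernel
from .seqcore import EncodedSequence, revcomp_codes

FORWARD = "forward"
REVCOMP = "revcomp"


@dataclass(frozen=True)
class AlignParams:
    min_overlap_frac: float = 0.5
    max_mismatches: int = 5

    def __post_init__(self):
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class ShiftAlignment:
    """A candidate placed at `shift` columns right of the anchor start."""

    shift: int
    overlap_len: int
    mismatches: int
    orientation: str  # FORWARD or REVCOMP


def best_alignment(anchor, cand, p: AlignParams = AlignParams()) -> ShiftAlignment | None:
    """Best admissible placement of `cand` against `anchor`, or None.

    Every shift in [0, |anchor|) is evaluated for both orientations.
    Admissible placements satisfy overlap >= min_overlap_frac * |cand| and
    mismatches <= max_mismatches.  Ties break deterministically: fewest
    mismatches, then largest overlap, then smallest shift, then forward
    orientation.
    """
    a = anchor.codes if isinstance(anchor, EncodedSequence) else anchor
    c = cand.codes if isinstance(cand, EncodedSequence) else cand
    if a.shape[0] == 0 or c.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    mm, ov, sh, orient = best_alignment_kernel(
        a, c, revcomp_codes(c), p.max_mismatches, p.min_overlap_frac)
    if mm < 0:
        return None
    return ShiftAlignment(shift=int(sh), overlap_len=int(ov), mismatches=int(mm),
                          orientation=FORWARD if orient == 0 else REVCOMP)
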