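"""DNA sequence representation and elementary operations.

Sequences are held as numpy arrays of 2-bit base codes (A=0, C=1, G=2, T=3).
All coordinates throughout the package are 0-based, half-open.  Parsing is
case-insensitive; IUPAC ambiguity codes are replaced deterministically by the
lexicographically smallest compatible base (N->A, R->A, Y->C, ...), so that
encoding is a pure function of the input text.
"""

from __future__ import annotations

import numpy as np

from ._kernels import hamming_kernel

BASES = "ACGT"

# IUPAC code -> lexicographically smallest compatible base.
_IUPAC_TO_BASE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}

# Byte-level lookup tables (256 entries) for fast encode/decode.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _b in _IUPAC_TO_BASE.items():
    _ENCODE_LUT[ord(_c)] = BASES.index(_b)
    _ENCODE_LUT[ord(_c.lower())] = BASES.index(_b)

_DECODE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


class InvalidSequenceError(ValueError):
    """Raised for empty input or characters outside the IUPAC alphabet."""


class EncodedSequence:
    """A DNA sequence over {A,C,G,T} stored as 2-bit base codes.

    Parameters
    ----------
    codes:
        uint8 array with values in {0,1,2,3}.
    """

    __slots__ = ("codes",)

    def __init__(self, codes: np.ndarray):
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)

    @classmethod
    def from_string(cls, text: str) -> "EncodedSequence":
        return encode_sequence(text)

    def __len__(self) -> int:
        return self.codes.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EncodedSequence):
            return NotImplemented
        return len(self) == len(other) and bool(np.all(self.codes == other.codes))

    def __hash__(self):
        return hash(self.codes.tobytes())

    def __getitem__(self, item) -> "EncodedSequence":
        if isinstance(item, slice):
            return EncodedSequence(self.codes[item])
        raise TypeError("EncodedSequence supports slicing only")

    def __str__(self) -> str:
        return decode_codes(self.codes)

    def __repr__(self) -> str:
        s = str(self)
        if len(s) > 40:
            s = s[:37] + "..."
        return f"EncodedSequence({s!r}, length={len(self)})"

    def reverse_complement(self) -> "EncodedSequence":
        return reverse_complement(self)


def encode_codes(text: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array, replacing ambiguity codes."""
    if not text:
        raise InvalidSequenceError("empty sequence")
    raw = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if np.any(codes == 255):
        bad = int(np.argmax(codes == 255))
        raise InvalidSequenceError(
            f"non-IUPAC character {text[bad]!r} at position {bad}"
        )
    return codes


def decode_codes(codes: np.ndarray) -> str:
    return _DECODE_LUT[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def encode_sequence(text: str) -> EncodedSequence:
    """Encode ``text`` (IUPAC alphabet, case-insensitive) into 2-bit codes.

    Ambiguous nucleotides are deterministically replaced by the
    lexicographically smallest compatible base; the result has the same
    length as the input.  Idempotent on plain ACGT input.
    """
    return EncodedSequence(encode_codes(text))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (complement is 3 - code)."""
    return np.ascontiguousarray((3 - codes[::-1]).astype(np.uint8))


def reverse_complement(s: EncodedSequence) -> EncodedSequence:
    return EncodedSequence(revcomp_codes(s.codes))


def hamming(a, b) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    ca = a.codes if isinstance(a, EncodedSequence) else np.asarray(a, dtype=np.uint8)
    cb = b.codes if isinstance(b, EncodedSequence) else np.asarray(b, dtype=np.uint8)
    if ca.shape[0] != cb.shape[0]:
        raise InvalidSequenceError(
            f"hamming distance requires equal lengths ({ca.shape[0]} != {cb.shape[0]})"
        )
    return int(hamming_kernel(ca, cb))


class ReadStore:
    """Flat storage for a collection of reads.

    Reads are concatenated into one code array with an offsets table, the
    layout used by the indexing and extension kernels.  Read ``i`` occupies
    ``codes[offsets[i]:offsets[i + 1]]``.
    """

    __slots__ = ("codes", "offsets", "_rc_codes")

    def __init__(self, codes: np.ndarray, offsets: np.ndarray):
        self.codes = np.ascontiguousarray(codes, dtype=np.uint8)
        self.offsets = np.ascontiguousarray(offsets, dtype=np.int64)
        self._rc_codes = None

    @classmethod
    def from_strings(cls, reads) -> "ReadStore":
        arrs = [encode_codes(r) for r in reads]
        offsets = np.zeros(len(arrs) + 1, dtype=np.int64)
        np.cumsum([len(a) for a in arrs], out=offsets[1:])
        codes = np.concatenate(arrs) if arrs else np.empty(0, dtype=np.uint8)
        return cls(codes, offsets)

    @classmethod
    def from_sequences(cls, reads) -> "ReadStore":
        arrs = [r.codes if isinstance(r, EncodedSequence) else np.asarray(r, np.uint8)
                for r in reads]
        offsets = np.zeros(len(arrs) + 1, dtype=np.int64)
        np.cumsum([len(a) for a in arrs], out=offsets[1:])
        codes = np.concatenate(arrs) if arrs else np.empty(0, dtype=np.uint8)
        return cls(codes, offsets)

    def __len__(self) -> int:
        return self.offsets.shape[0] - 1

    def length_of(self, i: int) -> int:
        return int(self.offsets[i + 1] - self.offsets[i])

    def get_codes(self, i: int) -> np.ndarray:
        return self.codes[self.offsets[i]:self.offsets[i + 1]]

    def get(self, i: int) -> EncodedSequence:
        return EncodedSequence(self.get_codes(i))

    @property
    def rc_codes(self) -> np.ndarray:
        """Per-read reverse complements at the same offsets (cached)."""
        if self._rc_codes is None:
            from ._kernels import rc_store_kernel
            self._rc_codes = rc_store_kernel(self.codes, self.offsets)
        return self._rc_codes

    def uniform_read_length(self) -> int | None:
        """The common read length, or None if lengths vary (or store empty)."""
        if len(self) == 0:
            return None
        lens = np.diff(self.offsets)
        return int(lens[0]) if np.all(lens == lens[0]) else None
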