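"""Minhash k-mer index over the read set.

Each read contributes one key per hash function: the minimum hash value of
its canonical k-mers under that function.  Querying a sequence retrieves,
from every table, the reads filed under the query's own minima — reads that
share a k-mer with the query collide with high probability.  Canonical
k-mers (the lexicographic minimum under the 2-bit integer order of a k-mer
and its reverse complement) make a single query find candidates from both
strands; each retrieved candidate is afterwards aligned in both
orientations.

All h tables live in one CSR structure: a sorted array of 64-bit keys
``(min_value << 6) | table_index``, per-key offsets, and a flat id list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .seqcore import EncodedSequence, ReadStore

DEFAULT_H = 48
DEFAULT_K = 20
DEFAULT_CAP = 1000


class SequenceTooShortError(ValueError):
    """Query or read shorter than the k-mer size."""


def _derive_seeds(seed: int, h: int) -> np.ndarray:
    """h distinct 64-bit hash seeds from one base seed (splitmix stream)."""
    rng = np.random.Generator(np.random.Philox(seed))
    while True:
        seeds = rng.integers(0, 2**64, size=h, dtype=np.uint64)
        if len(np.unique(seeds)) == h:
            return seeds


@dataclass(frozen=True)
class HashFamily:
    """h seeded 64-bit mixers applied to 2-bit-packed canonical k-mers."""

    h: int = DEFAULT_H
    k: int = DEFAULT_K
    seeds: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if not 1 <= self.k <= 32:
            raise ValueError("k must be in [1, 32]")
        if self.seeds is None:
            object.__setattr__(self, "seeds", _derive_seeds(0, self.h))
        if self.seeds.shape[0] != self.h:
            raise ValueError("need exactly h seeds")

    @classmethod
    def from_seed(cls, seed: int, h: int = DEFAULT_H, k: int = DEFAULT_K) -> "HashFamily":
        return cls(h=h, k=k, seeds=_derive_seeds(seed, h))


@dataclass(frozen=True)
class Signature:
    """Ordered minhash minima (m_1, ..., m_h) of one sequence."""

    values: np.ndarray

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class KmerHashTables:
    """CSR layout of the h minhash tables plus bookkeeping."""

    keys_sorted: np.ndarray        # uint64, ascending
    key_starts: np.ndarray         # int64, len == len(keys_sorted) + 1
    ids: np.ndarray                # int32 read ids, grouped by key
    fam: HashFamily
    n_reads: int
    n_skipped: int                 # reads shorter than k (never indexed)
    cap: int = DEFAULT_CAP

    @property
    def read_count(self) -> int:
        return self.n_reads


def _codes_of(s) -> np.ndarray:
    return s.codes if isinstance(s, EncodedSequence) else np.asarray(s, np.uint8)


def compute_signature(s, fam: HashFamily) -> Signature:
    """Minhash signature of a sequence; error when shorter than k."""
    codes = _codes_of(s)
    out = np.empty(fam.h, np.uint64)
    ok = _kernels.signature_into(codes, 0, codes.shape[0], fam.k, fam.seeds, out)
    if not ok:
        raise SequenceTooShortError(
            f"sequence of length {codes.shape[0]} shorter than k={fam.k}")
    return Signature(out)


def build_index(reads, fam: HashFamily, cap: int = DEFAULT_CAP) -> KmerHashTables:
    """Index a read collection: one (min value, read id) entry per table.

    `reads` may be a ReadStore or any iterable of EncodedSequence / code
    arrays.  Reads shorter than k are skipped (counted in n_skipped).
    Per-key id lists are stored in ascending read-id order and truncated at
    `cap` ids on query.
    """
    store = reads if isinstance(reads, ReadStore) else ReadStore.from_sequences(reads)
    if len(store) == 0:
        raise ValueError("empty read set")
    keys, rids, valid = _kernels.signature_keys(
        store.codes, store.offsets, fam.k, fam.seeds)
    mask = np.repeat(valid, fam.h)
    keys = keys[mask]
    rids = rids[mask]
    order = np.argsort(keys, kind="stable")
    keys_s = keys[order]
    ids_s = np.ascontiguousarray(rids[order])
    if keys_s.shape[0] == 0:
        uniq = np.empty(0, np.uint64)
        starts = np.zeros(1, np.int64)
    else:
        new_key = np.empty(keys_s.shape[0], bool)
        new_key[0] = True
        np.not_equal(keys_s[1:], keys_s[:-1], out=new_key[1:])
        starts_head = np.flatnonzero(new_key).astype(np.int64)
        uniq = np.ascontiguousarray(keys_s[new_key])
        starts = np.empty(starts_head.shape[0] + 1, np.int64)
        starts[:-1] = starts_head
        starts[-1] = keys_s.shape[0]
    return KmerHashTables(
        keys_sorted=uniq, key_starts=starts, ids=ids_s, fam=fam,
        n_reads=len(store), n_skipped=int((~valid).sum()), cap=cap)


def query_candidates(s, idx: KmerHashTables, fam: HashFamily | None = None) -> np.ndarray:
    """Read ids likely to share a k-mer with `s` (sorted, deduplicated).

    A read's own full sequence always retrieves its own id: the read and the
    query produce the identical signature, so every table hits.
    """
    fam = fam or idx.fam
    sig = compute_signature(s, fam)
    return _kernels.query_ids(sig.values, idx.keys_sorted, idx.key_starts,
                              idx.ids, idx.cap)
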