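"""Sequence input, index serialization, and memory accounting.

The on-disk "KFMI" v1 format mirrors the in-memory packing: each vertex
record is ``sigma + 1`` bits (in-edge flags by letter code, then the
group-end flag), ``floor(64 / (sigma+1))`` records per little-endian 64-bit
word, low bits first; the previous-position store follows as bit-packed low
values (``ceil(lg q)`` bits each), the delta bit stream, and raw 64-bit
checkpoints.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from math import ceil, log2
from typing import Iterable, Iterator

import numpy as np

from ._bits import pack_uint, unpack_uint
from .alphabet import DNA, Alphabet
from .core import KFMIndex, PrevPosStore

__all__ = ["read_sequences", "add_reverse_complements", "serialize",
           "deserialize", "MemoryEstimate", "memory_estimate"]

_MAGIC = b"KFMI"
_VERSION = 1
_HEADER = struct.Struct("<4sBBIQII")


class FormatError(ValueError):
    """Raised for malformed KFMI files; the message names the bad offset."""


# ---------------------------------------------------------------------------
# sequence input


_RC = str.maketrans("ACGT", "TGCA")


def read_sequences(path: str, quality_threshold: int = 30) -> Iterator[str]:
    """Yield high-quality fragments of each read in a FASTA/FASTQ file.

    Reads are split at bases with Phred quality below ``quality_threshold``
    (FASTQ only) and at symbols outside ACGT; a threshold of 0 disables
    quality filtering.  Fragments may be arbitrarily short; the indexer
    drops those below ``k-1``.
    """
    import pysam

    with pysam.FastxFile(path) as fh:
        for rec_no, entry in enumerate(fh):
            seq = entry.sequence.upper()
            if not seq:
                raise FormatError(f"empty sequence in record {rec_no}")
            bad = bytearray(len(seq))
            for i, ch in enumerate(seq):
                if ch not in "ACGT":
                    bad[i] = 1
            if entry.quality is not None and quality_threshold > 0:
                for i, qc in enumerate(entry.quality):
                    if ord(qc) - 33 < quality_threshold:
                        bad[i] = 1
            frag_start = None
            for i, b in enumerate(bad):
                if b:
                    if frag_start is not None:
                        yield seq[frag_start:i]
                        frag_start = None
                elif frag_start is None:
                    frag_start = i
            if frag_start is not None:
                yield seq[frag_start:]


def add_reverse_complements(stream: Iterable[str]) -> Iterator[str]:
    """Yield each fragment followed by its reverse complement (DNA only)."""
    for seq in stream:
        yield seq
        yield seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# serialization


def serialize(index: KFMIndex, path: str) -> None:
    """Write the index in KFMI v1 format (bit-exact round trip)."""
    sigma = index.alphabet.sigma
    store = index.prev_store
    n = index.n
    header = _HEADER.pack(_MAGIC, _VERSION, sigma, index.k, n, store.q, store.w)
    rpw = 64 // (sigma + 1)
    rec = (index.eta.astype(np.uint64)
           << np.arange(sigma, dtype=np.uint64)).sum(axis=1, dtype=np.uint64)
    rec |= index.f.astype(np.uint64) << np.uint64(sigma)
    words = np.zeros((n + rpw - 1) // rpw, dtype=np.uint64)
    i = np.arange(n, dtype=np.int64)
    np.bitwise_or.at(words, i // rpw,
                     rec << ((i % rpw).astype(np.uint64) * np.uint64(sigma + 1)))
    ub = (store.q - 1).bit_length()
    low_words = pack_uint(store.low, ub)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(index.alphabet.letters.encode("ascii"))
        fh.write(words.tobytes())
        fh.write(low_words.tobytes())
        fh.write(store.delta_words.tobytes())
        fh.write(store.checkpoints.astype(np.int64).tobytes())


def deserialize(path: str) -> KFMIndex:
    """Read a KFMI v1 file back into an index."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size or raw[:4] != _MAGIC:
        raise FormatError("bad magic at offset 0")
    magic, version, sigma, k, n, q, w = _HEADER.unpack_from(raw, 0)
    if version != _VERSION:
        raise FormatError(f"unsupported version {version} at offset 4")
    off = _HEADER.size
    letters = raw[off:off + sigma].decode("ascii")
    off += sigma
    alphabet = DNA if letters == "ACGT" else Alphabet(letters)
    rpw = 64 // (sigma + 1)
    nw = (n + rpw - 1) // rpw
    zeta = -(-n // q)
    nk = sigma * zeta + 1
    ub = (q - 1).bit_length()
    sizes = [8 * nw, 8 * ((nk * ub + 63) // 64), 8 * ((nk + 63) // 64),
             8 * ((nk - 1) // w + 1)]
    if len(raw) != off + sum(sizes):
        raise FormatError(f"truncated file: expected {off + sum(sizes)} bytes, "
                          f"got {len(raw)} (arrays start at offset {off})")
    words = np.frombuffer(raw, dtype="<u8", count=nw, offset=off)
    off += sizes[0]
    low = unpack_uint(np.frombuffer(raw, dtype="<u8", count=sizes[1] // 8, offset=off),
                      ub, nk).astype(np.uint32)
    off += sizes[1]
    delta_words = np.frombuffer(raw, dtype="<u8", count=sizes[2] // 8, offset=off).copy()
    off += sizes[2]
    checkpoints = np.frombuffer(raw, dtype="<i8", count=sizes[3] // 8, offset=off).copy()

    i = np.arange(n, dtype=np.int64)
    rec = (words[i // rpw] >> ((i % rpw).astype(np.uint64) * np.uint64(sigma + 1)))
    eta = ((rec[:, None] >> np.arange(sigma, dtype=np.uint64)) & np.uint64(1)).astype(bool)
    f = ((rec >> np.uint64(sigma)) & np.uint64(1)).astype(bool)
    store = PrevPosStore(q, w, n, sigma, low, delta_words, checkpoints)
    return KFMIndex(alphabet, k, eta, f, prev_store=store)


# ---------------------------------------------------------------------------
# memory accounting


@dataclass(frozen=True)
class MemoryEstimate:
    """Analytic per-vertex bit costs of the index."""

    bits_core_per_vertex: float      # sigma + 1 (edge flags + group-end flag)
    bits_store_per_vertex: float     # sigma * (lg q + 2) / q
    packing_overhead_per_vertex: float
    bits_total_per_vertex: float

    @property
    def bits_core_packed_per_vertex(self) -> float:
        return self.bits_core_per_vertex + self.packing_overhead_per_vertex


def memory_estimate(n: int, sigma: int = 4, q: int = 32,
                    word_size: int = 64) -> MemoryEstimate:
    """Per-vertex memory of the packed records plus the sparse rho store.

    The store term counts ``lg q`` bits for each low value, one delta bit,
    and one bit amortizing a full-word checkpoint every ``word_size``
    values; the packed-core term charges the unused bits of each word to
    its ``floor(word_size / (sigma+1))`` resident records.
    """
    if n < 1 or q < 1:
        raise ValueError("need n >= 1 and q >= 1")
    core = sigma + 1
    rpw = word_size // (sigma + 1)
    packing = word_size / rpw - core
    store = sigma * (ceil(log2(q)) + 2) / q if q > 1 else sigma * 2.0
    return MemoryEstimate(
        bits_core_per_vertex=float(core),
        bits_store_per_vertex=store,
        packing_overhead_per_vertex=packing,
        bits_total_per_vertex=word_size / rpw + store,
    )
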