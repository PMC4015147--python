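"""Index construction from strings or read code arrays.

Edge words (k-substrings plus sentinel-padded completion words) are encoded
as fixed-width integers in base ``sigma + 1`` with ``$ = 0`` and letters
``1 .. sigma``, keyed by (target vertex, in-letter) so that a single integer
sort produces the order the index needs.  Vertices are the union of targets
and sources of the sorted word list, which covers in-degree-zero string
starts without extra bookkeeping.  Large inputs are split into partitions,
indexed independently, and reduced by balanced pairwise merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import DNA, Alphabet
from .core import KFMIndex

logger = logging.getLogger(__name__)

__all__ = ["BuildConfig", "edge_words_from_string", "build_from_sorted_words",
           "build_prev_store", "build", "build_from_read_matrix"]


@dataclass
class BuildConfig:
    """Parameters for :func:`build`."""

    k: int
    q: int = 32
    w: int = 64
    partition_size: int = 2 ** 63 - 1  # max edge words per in-memory partition
    prune_policy: str = "final_only"   # final_only | every_merge | never
    rng_seed: int = 0
    alphabet: Alphabet = field(default_factory=lambda: DNA)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.partition_size < 1:
            raise ValueError("partition_size must be >= 1")
        if self.prune_policy not in ("final_only", "every_merge", "never"):
            raise ValueError(f"unknown prune_policy {self.prune_policy!r}")
        _check_width(self.alphabet, self.k)


def _check_width(alphabet: Alphabet, k: int):
    if (alphabet.sigma + 1) ** k > 2 ** 63:
        raise ValueError(
            f"k = {k} too large for 64-bit word encoding with sigma = {alphabet.sigma}")


# ---------------------------------------------------------------------------
# word encoding


def word_key(word: str, k: int, alphabet: Alphabet = DNA) -> int:
    """Integer sort key (target vertex, in-letter) of a k-symbol edge word."""
    if len(word) != k:
        raise ValueError(f"edge word must have length k = {k}")
    base = alphabet.sigma + 1
    digits = [0 if ch == "$" else alphabet.code(ch) + 1 for ch in word]
    target = 0
    for d in digits[1:]:
        target = target * base + d
    return target * base + digits[0]


def key_word(key: int, k: int, alphabet: Alphabet = DNA) -> str:
    """Inverse of :func:`word_key`."""
    base = alphabet.sigma + 1
    target, letter = divmod(key, base)
    digits = []
    for _ in range(k - 1):
        target, d = divmod(target, base)
        digits.append(d)
    syms = ["$" if d == 0 else alphabet.char(d - 1) for d in reversed(digits)]
    first = "$" if letter == 0 else alphabet.char(letter - 1)
    return first + "".join(syms)


def edge_words_from_string(s: str, k: int, alphabet: Alphabet = DNA) -> list[str]:
    """All k-substrings of ``s`` plus the ``k-1`` sentinel completion words.

    The completions are the k-substrings of ``v + '$'*(k-1)`` where ``v`` is
    the ``(k-1)``-suffix of ``s``.  Strings shorter than ``k-1`` yield
    nothing (logged); duplicates are kept and removed at sort time.
    """
    if len(s) < k - 1:
        logger.warning("skipping string of length %d < k-1 = %d", len(s), k - 1)
        return []
    for ch in s:
        alphabet.code(ch)  # raises on out-of-alphabet symbols
    words = [s[p:p + k] for p in range(len(s) - k + 1)]
    v = s[len(s) - k + 1:]
    words.extend(v[t:] + "$" * (t + 1) for t in range(k - 1))
    return words


def _keys_from_codes(codes: np.ndarray, k: int, base: int) -> np.ndarray:
    """Edge-word keys for one code array (1-D uint8) of length >= k-1."""
    d = codes.astype(np.int64) + 1
    L = d.shape[0]
    top = base ** (k - 1)
    out = []
    if L >= k:
        win = np.lib.stride_tricks.sliding_window_view(d, k)
        powers = base ** np.arange(k - 1, -1, -1, dtype=np.int64)
        enc = win @ powers
        out.append((enc % top) * base + enc // top)
    # completion words from the (k-1)-suffix v: word_t = v[t:] + '$'*(t+1)
    v = d[L - k + 1:]
    pw = base ** np.arange(k - 2, -1, -1, dtype=np.int64)
    h = np.cumsum((v * pw)[::-1])[::-1]           # h[t] = encode(v[t:]) << (k-2-t)
    w_full = h * base ** np.arange(1, k, dtype=np.int64)
    out.append((w_full % top) * base + w_full // top)
    return np.concatenate(out)


def _keys_from_matrix(mat: np.ndarray, k: int, base: int) -> np.ndarray:
    """Edge-word keys for a (reads, length) code matrix, Horner-encoded."""
    nr, L = mat.shape
    if L < k - 1:
        raise ValueError("reads shorter than k-1")
    d = mat.astype(np.int64) + 1
    top = base ** (k - 1)
    out = []
    if L >= k:
        nw = L - k + 1
        enc = np.zeros((nr, nw), dtype=np.int64)
        for j in range(k):
            enc *= base
            enc += d[:, j:j + nw]
        out.append(((enc % top) * base + enc // top).ravel())
    v = d[:, L - k + 1:]
    pw = base ** np.arange(k - 2, -1, -1, dtype=np.int64)
    h = np.cumsum((v * pw)[:, ::-1], axis=1)[:, ::-1]
    w_full = h * base ** np.arange(1, k, dtype=np.int64)
    out.append(((w_full % top) * base + w_full // top).ravel())
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# index assembly from sorted words


def _index_from_keys(keys: np.ndarray, k: int, alphabet: Alphabet,
                     q: int, w: int = 64) -> KFMIndex:
    """Build vertex records from sorted, deduplicated word keys."""
    base = alphabet.sigma + 1
    keys = np.asarray(keys, dtype=np.int64)
    targets = keys // base
    letters = keys % base
    em = letters > 0
    sources = letters[em] * base ** (k - 2) + targets[em] // base
    vcodes = np.unique(np.concatenate((targets, sources)))
    if vcodes.size == 0 or vcodes[0] != 0:
        vcodes = np.concatenate(([0], vcodes))  # the final vertex is always present
    n = vcodes.size
    eta = np.zeros((n, alphabet.sigma), dtype=bool)
    eta[np.searchsorted(vcodes, targets[em]), letters[em] - 1] = True
    pref = vcodes // base
    f = np.empty(n, dtype=bool)
    f[:-1] = pref[:-1] != pref[1:]
    f[-1] = True
    return KFMIndex(alphabet, k, eta, f, q=q, w=w)


def build_from_sorted_words(words, k: int, alphabet: Alphabet = DNA,
                            q: int = 32, w: int = 64) -> KFMIndex:
    """Build an index from a sorted, deduplicated edge-word list.

    ``words`` may be word strings or integer keys; they must be strictly
    increasing under the (target vertex, in-letter) order or a
    ``ValueError`` is raised.  Each distinct target collapses to one vertex
    record; sources of the listed words (string starts) become records with
    empty in-edge sets; the final vertex is inserted if absent.
    """
    _check_width(alphabet, k)
    if isinstance(words, np.ndarray) and words.dtype.kind in "iu":
        keys = words.astype(np.int64)
    else:
        keys = np.array([word_key(wd, k, alphabet) for wd in words], dtype=np.int64)
    if keys.size and np.any(np.diff(keys) <= 0):
        raise ValueError("edge words must be sorted and deduplicated")
    return _index_from_keys(keys, k, alphabet, q, w)


def build_prev_store(eta: np.ndarray, f: np.ndarray, q: int = 32, w: int = 64):
    """Build the sparse previous-position store from finalized flags."""
    from .core import PrevPosStore

    return PrevPosStore.from_flags(np.asarray(eta, dtype=bool),
                                   np.asarray(f, dtype=bool), q=q, w=w)


# ---------------------------------------------------------------------------
# high-level builds


def _string_keys(s, k: int, alphabet: Alphabet) -> np.ndarray:
    codes = s if isinstance(s, np.ndarray) else alphabet.encode(s)
    if codes.shape[0] < k - 1:
        logger.warning("skipping string of length %d < k-1 = %d", codes.shape[0], k - 1)
        return np.empty(0, dtype=np.int64)
    return _keys_from_codes(codes, k, alphabet.sigma + 1)


def _reduce_merge(parts: list[KFMIndex], prune_each: bool) -> KFMIndex:
    from .merge import merge
    from .prune import prune as prune_fn

    round_no = 0
    while len(parts) > 1:
        round_no += 1
        nxt = []
        for i in range(0, len(parts) - 1, 2):
            m = merge(parts[i], parts[i + 1])
            if prune_each:
                m = prune_fn(m)
            nxt.append(m)
        if len(parts) % 2:
            nxt.append(parts[-1])
        logger.info("merge round %d: %d -> %d partial indexes", round_no,
                    len(parts), len(nxt))
        parts = nxt
    return parts[0]


def build(strings: Iterable, config: BuildConfig) -> KFMIndex:
    """Build a kFM-index from strings (or uint8 code arrays).

    The word stream is cut into partitions of at most
    ``config.partition_size`` words, each partition is indexed by an
    in-memory sort, and the partial indexes are reduced by balanced pairwise
    merging; pruning follows ``config.prune_policy``.  The result represents
    the same k-mer set as a single-pass build.
    """
    from .prune import prune as prune_fn

    alphabet, k = config.alphabet, config.k
    parts: list[KFMIndex] = []
    buf: list[np.ndarray] = []
    buffered = 0

    def flush():
        nonlocal buf, buffered
        if not buf:
            return
        keys = np.unique(np.concatenate(buf))
        sub = _index_from_keys(keys, k, alphabet, config.q, config.w)
        if config.prune_policy == "every_merge":
            sub = prune_fn(sub)
        parts.append(sub)
        buf, buffered = [], 0

    for s in strings:
        keys = _string_keys(s, k, alphabet)
        if keys.size == 0:
            continue
        if buffered and buffered + keys.size > config.partition_size:
            flush()
        buf.append(keys)
        buffered += keys.size
        while buffered > config.partition_size:
            # a single long string can exceed the partition on its own
            flush()
    flush()

    if not parts:
        return _index_from_keys(np.empty(0, dtype=np.int64), k, alphabet,
                                config.q, config.w)
    result = _reduce_merge(parts, prune_each=(config.prune_policy == "every_merge"))
    if config.prune_policy == "final_only":
        result = prune_fn(result)
    return result


def build_from_read_matrix(reads: np.ndarray, k: int, alphabet: Alphabet = DNA,
                           q: int = 32, w: int = 64, add_rc: bool = True,
                           do_prune: bool = True, chunk: int = 50_000) -> KFMIndex:
    """Fast monolithic build from an (n_reads, read_length) uint8 code matrix.

    Equal-length reads are Horner-encoded in chunks; with ``add_rc`` the
    reverse complements (DNA only) are indexed as well.  Equivalent to
    :func:`build` on the decoded strings, but vectorized end to end.
    """
    _check_width(alphabet, k)
    base = alphabet.sigma + 1
    pieces = []
    for lo in range(0, reads.shape[0], chunk):
        part = reads[lo:lo + chunk]
        pieces.append(_keys_from_matrix(part, k, base))
        if add_rc:
            if alphabet.letters != "ACGT":
                raise ValueError("reverse complements require the DNA alphabet")
            pieces.append(_keys_from_matrix(
                (3 - part[:, ::-1]).astype(np.uint8), k, base))
    keys = np.unique(np.concatenate(pieces)) if pieces else np.empty(0, np.int64)
    del pieces
    idx = _index_from_keys(keys, k, alphabet, q, w)
    if do_prune:
        from .prune import prune as prune_fn

        idx = prune_fn(idx)
    return idx
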