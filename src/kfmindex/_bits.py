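"""Fixed-width bit packing into little-endian 64-bit words."""

from __future__ import annotations

import numpy as np

_ONE = np.uint64(1)
_SIXTYFOUR = np.uint64(64)


def pack_uint(values: np.ndarray, width: int) -> np.ndarray:
    """Pack ``values`` (each < 2**width) at ``width`` bits into uint64 words."""
    count = len(values)
    if width == 0 or count == 0:
        return np.zeros(0, dtype=np.uint64)
    v = values.astype(np.uint64)
    offs = np.arange(count, dtype=np.uint64) * np.uint64(width)
    wi = (offs >> np.uint64(6)).astype(np.int64)
    sh = offs & np.uint64(63)
    nwords = int((count * width + 63) // 64)
    words = np.zeros(nwords, dtype=np.uint64)
    np.bitwise_or.at(words, wi, (v << sh))  # low parts (shifts < 64)
    spill = sh + np.uint64(width) > _SIXTYFOUR
    if spill.any():
        np.bitwise_or.at(words, wi[spill] + 1,
                         v[spill] >> (_SIXTYFOUR - sh[spill]))
    return words


def unpack_uint(words: np.ndarray, width: int, count: int) -> np.ndarray:
    """Inverse of :func:`pack_uint`."""
    if width == 0 or count == 0:
        return np.zeros(count, dtype=np.uint64)
    offs = np.arange(count, dtype=np.uint64) * np.uint64(width)
    wi = (offs >> np.uint64(6)).astype(np.int64)
    sh = offs & np.uint64(63)
    out = words[wi] >> sh
    spill = sh + np.uint64(width) > _SIXTYFOUR
    if spill.any():
        out[spill] |= words[wi[spill] + 1] << (_SIXTYFOUR - sh[spill])
    mask = (_ONE << np.uint64(width)) - _ONE if width < 64 else np.uint64(0xFFFFFFFFFFFFFFFF)
    return out & mask
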