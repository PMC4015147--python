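"""Ordered alphabets with low/high sentinels.

Vertices and edges of the graph are strings over an ordered alphabet of at
most 62 letters.  Two virtual sentinels bracket the letter order: ``$``
sorts strictly before every letter (used to pad final-completing vertices)
and the high sentinel sorts strictly after every letter (used only as an
implicit query terminator).  Neither sentinel is ever stored in the edge
flags; ``$`` appears only in reconstructed vertex strings.
"""

from __future__ import annotations

import numpy as np

SENTINEL_LOW = "$"
SENTINEL_HIGH = "∞"  # "infinity" high sentinel

#: letter code used to represent ``$`` where a code is required (e.g. the
#: result of inverting the previous-position map at the final vertex).
SENTINEL_CODE = -1


class Alphabet:
    """An ordered set of distinct symbols with codes ``0 .. sigma-1``.

    Parameters
    ----------
    letters:
        The symbols in sort order.  Must be distinct, must not contain the
        sentinels, and there may be at most 62 of them so that a vertex
        record of ``sigma + 1`` bits fits into a 64-bit word.
    """

    __slots__ = ("letters", "sigma", "_code")

    def __init__(self, letters: str):
        if not 1 <= len(letters) <= 62:
            raise ValueError("alphabet size must be between 1 and 62")
        if len(set(letters)) != len(letters):
            raise ValueError("alphabet letters must be distinct")
        if SENTINEL_LOW in letters or SENTINEL_HIGH in letters:
            raise ValueError("sentinels cannot be alphabet letters")
        self.letters = letters
        self.sigma = len(letters)
        self._code = {ch: i for i, ch in enumerate(letters)}

    @property
    def sentinel_low(self) -> str:
        return SENTINEL_LOW

    @property
    def sentinel_high(self) -> str:
        return SENTINEL_HIGH

    def code(self, ch: str) -> int:
        """Code of a letter; raises ``ValueError`` for unknown symbols."""
        try:
            return self._code[ch]
        except KeyError:
            raise ValueError(f"symbol {ch!r} not in alphabet {self.letters!r}") from None

    def char(self, code: int) -> str:
        """Letter for a code; ``SENTINEL_CODE`` maps to ``$``."""
        if code == SENTINEL_CODE:
            return SENTINEL_LOW
        return self.letters[code]

    def encode(self, s: str) -> np.ndarray:
        """Encode a string over the alphabet as a uint8 code array."""
        return np.fromiter((self.code(ch) for ch in s), dtype=np.uint8, count=len(s))

    def decode(self, codes) -> str:
        return "".join(self.char(int(c)) for c in codes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.letters == other.letters

    def __hash__(self) -> int:
        return hash(self.letters)

    def __repr__(self) -> str:
        return f"Alphabet({self.letters!r})"


#: The default DNA alphabet, A < C < G < T.
DNA = Alphabet("ACGT")
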