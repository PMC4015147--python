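"""The kFM-index: a succinct, walkable k-mer de Bruijn subgraph.

The index stores, for every vertex (a ``(k-1)``-string, lexicographically
sorted), the set of in-edge letters (``sigma`` bits) and a group-end flag
(one bit) marking the last vertex of each run sharing a ``(k-2)``-prefix.
Vertex strings themselves are never stored; they are reconstructed by
backtracking through in-edges.  The previous-position map ``rho`` plays the
role of the FM-index occurrence table: ``rho(a, i)`` is the index of the
origin vertex of a potential ``a`` in-edge to vertex ``i``.  A sparse,
delta-compressed subset of ``rho`` values is kept (:class:`PrevPosStore`);
everything else is recomputed on demand by scanning at most ``q`` vertex
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .alphabet import DNA, SENTINEL_CODE, Alphabet

__all__ = ["VertexInterval", "PrevPosStore", "KFMIndex"]


@dataclass(frozen=True)
class VertexInterval:
    """Half-open range ``[alpha, beta)`` of vertex indices sharing a prefix."""

    alpha: int
    beta: int

    def __post_init__(self):
        if not 0 <= self.alpha <= self.beta:
            raise ValueError(f"invalid interval [{self.alpha}, {self.beta})")

    @property
    def empty(self) -> bool:
        return self.alpha == self.beta

    def __len__(self) -> int:
        return self.beta - self.alpha

    def __iter__(self) -> Iterator[int]:
        return iter(range(self.alpha, self.beta))


class PrevPosStore:
    """Checkpointed, delta-compressed table of stored ``rho(a, i_r)`` values.

    Values are stored at positions ``i_r = min(r*q, n)`` for
    ``r = 0 .. zeta`` where ``zeta = ceil(n/q)``, flattened to a single
    non-decreasing array ``kappa(a*zeta + r) = rho(a, i_r)`` (the seam
    entries coincide: ``rho(a, n) == rho(a+1, 0)``).  Each value is split as
    ``kappa(j) = u_j + q*U_j`` with ``0 <= u_j < q``; the ``u_j`` are kept
    directly, the ``U_j`` only through their 0/1 increments ``dU_j`` plus a
    full checkpoint every ``w``-th entry, so any ``kappa(j)`` is
    reconstructed exactly from one checkpoint and a popcount.
    """

    __slots__ = ("q", "w", "n", "sigma", "zeta", "low", "delta_words", "checkpoints")

    def __init__(self, q: int, w: int, n: int, sigma: int,
                 low: np.ndarray, delta_words: np.ndarray, checkpoints: np.ndarray):
        self.q = int(q)
        self.w = int(w)
        self.n = int(n)
        self.sigma = int(sigma)
        self.zeta = -(-self.n // self.q)  # ceil(n/q)
        self.low = low                    # uint32[sigma*zeta + 1]
        self.delta_words = delta_words    # uint64 bit-packed dU_j (bit j of the stream)
        self.checkpoints = checkpoints    # int64 U_{w*r}
        if len(low) != self.sigma * self.zeta + 1:
            raise ValueError("low_values length mismatch")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_flags(cls, eta: np.ndarray, f: np.ndarray, q: int = 32, w: int = 64) -> "PrevPosStore":
        """Build the store from finalized edge flags and group-end flags.

        One vectorized pass: per-letter group presence, exclusive cumulative
        counts, then gather at the stored positions.
        """
        if q < 1 or w < 1:
            raise ValueError("q and w must be >= 1")
        n, sigma = eta.shape
        if n < 1 or not f[n - 1]:
            raise ValueError("malformed flags: need n >= 1 and f[n-1] set")
        zeta = -(-n // q)
        kappa = np.empty(sigma * zeta + 1, dtype=np.int64)
        starts = np.flatnonzero(np.concatenate(([True], f[:-1])))
        gidx = np.concatenate(([0], np.cumsum(f[:-1], dtype=np.int64)))
        ngroups = int(f.sum())
        positions = np.minimum(np.arange(zeta + 1, dtype=np.int64) * q, n)
        pos_g = np.empty(zeta + 1, dtype=np.int64)
        pos_g[:-1] = gidx[positions[:-1]]
        pos_g[-1] = ngroups
        offset = 1
        for a in range(sigma):
            gpres = np.logical_or.reduceat(eta[:, a], starts)
            cex = np.concatenate(([0], np.cumsum(gpres, dtype=np.int64)))
            kappa[a * zeta: (a + 1) * zeta + 1] = offset + cex[pos_g]
            offset += int(cex[ngroups])
        big = kappa // q
        low = (kappa - big * q).astype(np.uint32)
        d = np.diff(big)
        if d.size and (d.min() < 0 or d.max() > 1):
            raise AssertionError("kappa increments out of [0, q]")
        nwords = (len(kappa) + 63) // 64
        delta_words = np.zeros(nwords, dtype=np.uint64)
        j = np.flatnonzero(d).astype(np.uint64) + 1  # bit index of each unit increment
        np.bitwise_or.at(delta_words, (j >> np.uint64(6)).astype(np.int64),
                         np.uint64(1) << (j & np.uint64(63)))
        checkpoints = big[::w].astype(np.int64).copy()
        return cls(q, w, n, sigma, low, delta_words, checkpoints)

    # -- queries ------------------------------------------------------------

    def position(self, r: int) -> int:
        """Stored vertex position ``i_r = min(r*q, n)``."""
        return min(r * self.q, self.n)

    def _count_delta(self, lo: int, hi: int) -> int:
        """Popcount of delta bits with index in ``(lo, hi]``."""
        if hi <= lo:
            return 0
        words = self.delta_words
        w0, w1 = (lo + 1) >> 6, hi >> 6
        if w0 == w1:
            mask = ((1 << ((hi & 63) + 1)) - 1) & ~((1 << ((lo + 1) & 63)) - 1)
            return (int(words[w0]) & mask).bit_count()
        total = (int(words[w0]) & ~((1 << ((lo + 1) & 63)) - 1)).bit_count()
        for wi in range(w0 + 1, w1):
            total += int(words[wi]).bit_count()
        total += (int(words[w1]) & ((1 << ((hi & 63) + 1)) - 1)).bit_count()
        return total

    def kappa(self, j: int) -> int:
        """Reconstruct the stored value ``kappa(j) = rho(a, i_r)``."""
        r0 = j // self.w
        big = int(self.checkpoints[r0]) + self._count_delta(r0 * self.w, j)
        return int(self.low[j]) + self.q * big

    def search_le(self, value: int) -> int:
        """Rightmost ``j`` with ``kappa(j) <= value`` (kappa is non-decreasing)."""
        lo, hi = 0, self.sigma * self.zeta  # invariant: kappa(lo) <= value
        if self.kappa(0) > value:
            raise ValueError("value below kappa(0)")
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if self.kappa(mid) <= value:
                lo = mid
            else:
                hi = mid - 1
        return lo

    def stored_rho(self, a: int, r: int) -> int:
        return self.kappa(a * self.zeta + r)


class KFMIndex:
    """In-memory kFM-index over ``n`` lexicographically sorted vertices.

    Parameters
    ----------
    alphabet:
        Letter order; DNA (``A<C<G<T``) by default.
    k:
        Edge (k-mer) length; vertices are ``(k-1)``-strings.
    eta:
        ``(n, sigma)`` boolean matrix of in-edge flags, ``eta[i, a]`` true
        iff the edge ``a + v_i`` is present.
    f:
        Length-``n`` boolean group-end flags; ``f[n-1]`` is always set.
    """

    def __init__(self, alphabet: Alphabet, k: int, eta: np.ndarray, f: np.ndarray,
                 q: int = 32, w: int = 64, prev_store: Optional[PrevPosStore] = None):
        if k < 2:
            raise ValueError("k must be >= 2")
        eta = np.ascontiguousarray(eta, dtype=bool)
        f = np.ascontiguousarray(f, dtype=bool)
        if eta.ndim != 2 or eta.shape[1] != alphabet.sigma or eta.shape[0] != f.shape[0]:
            raise ValueError("eta/f shape mismatch")
        if eta.shape[0] < 1 or not f[-1]:
            raise ValueError("index must contain the final vertex and f[n-1] must be set")
        self.alphabet = alphabet
        self.k = int(k)
        self.eta = eta
        self.f = f
        self.prev_store = prev_store if prev_store is not None \
            else PrevPosStore.from_flags(eta, f, q=q, w=w)
        self.rho_calls = 0  # diagnostic counter
        self._tau: Optional[np.ndarray] = None

    # -- basic accessors ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.eta.shape[0]

    @property
    def q(self) -> int:
        return self.prev_store.q

    def vertex_record(self, i: int) -> tuple[set[int], bool]:
        """In-edge letter codes and group-end flag of vertex ``i``."""
        self._check_vertex(i)
        return set(int(a) for a in np.flatnonzero(self.eta[i])), bool(self.f[i])

    def letter_group_count(self, a: int) -> int:
        """tau(a): number of vertex groups containing an ``a`` in-edge."""
        if not 0 <= a < self.alphabet.sigma:
            raise IndexError(f"letter code {a} out of range")
        if self._tau is None:
            z = self.prev_store.zeta
            self._tau = np.array(
                [self.prev_store.kappa((b + 1) * z) - self.prev_store.kappa(b * z)
                 for b in range(self.alphabet.sigma)], dtype=np.int64)
        return int(self._tau[a])

    def _check_vertex(self, i: int):
        if not 0 <= i < self.n:
            raise IndexError(f"vertex index {i} out of range [0, {self.n})")

    # -- previous position --------------------------------------------------

    def prev_position(self, a: int, i: int) -> int:
        """rho(a, i): origin position of a potential ``a`` in-edge at ``i``.

        Reconstructed from the nearest stored value at or below ``i`` by
        counting, per vertex group, whether any member has an ``a``
        in-edge; the group containing ``v_i`` is excluded.
        """
        if not 0 <= a < self.alphabet.sigma:
            raise IndexError(f"letter code {a} out of range")
        if not 0 <= i <= self.n:
            raise IndexError(f"position {i} out of range [0, {self.n}]")
        self.rho_calls += 1
        store = self.prev_store
        if i == self.n:
            return store.kappa(a * store.zeta + store.zeta)
        r = i // store.q
        base = store.kappa(a * store.zeta + r)
        ir = store.position(r)
        if ir == i:
            return base
        eta_a, f = self.eta[:, a], self.f
        s = ir
        while s > 0 and not f[s - 1]:  # back up to the start of i_r's group
            s -= 1
        count = 0
        has = False
        for j in range(s, i):
            if eta_a[j]:
                has = True
            if f[j]:  # a group ends strictly before i
                if has:
                    count += 1
                has = False
        return base + count

    def prev_position_inverse(self, i: int) -> tuple[int, int]:
        """rho_inv(i) = (a, j) with rho(a, j) = i and rho(a, j+1) = i + 1.

        ``a`` is the first letter of ``v_i`` (``SENTINEL_CODE`` for the
        final vertex) and ``j`` the last vertex of the group sharing
        ``v_i``'s ``(k-2)``-suffix.  Binary search over the stored kappa
        values followed by a stepwise scan within one stride.
        """
        self._check_vertex(i)
        if i == 0:
            return (SENTINEL_CODE, 0)
        store = self.prev_store
        m = store.search_le(i)
        if m >= self.alphabet.sigma * store.zeta:
            raise AssertionError("rho_inverse search fell off the table")
        a, r = divmod(m, store.zeta)
        cur = store.kappa(m)
        j = store.position(r)
        eta_a, f = self.eta[:, a], self.f
        s = j
        while s > 0 and not f[s - 1]:
            s -= 1
        has = bool(eta_a[s:j].any())
        while j <= self.n:
            if j == self.n:
                raise AssertionError(f"rho_inverse({i}) not found; malformed index")
            if eta_a[j]:
                has = True
            nxt = cur + 1 if (f[j] and has) else cur
            if cur == i and nxt == i + 1:
                return (a, j)
            if f[j]:
                has = False
            cur = nxt
            j += 1
        raise AssertionError("unreachable")

    # -- backward search ----------------------------------------------------

    def gamma(self, x: str, i0: int) -> int:
        """Fold rho right-to-left over ``x`` starting from ``i0``.

        ``i0 = 0`` encodes an implicit trailing ``$`` terminator, ``i0 = n``
        an implicit high sentinel; ``gamma('', i) == i``.
        """
        i = i0
        for ch in reversed(x):
            i = self.prev_position(self.alphabet.code(ch), i)
        return i

    def prefix_interval(self, x: str) -> VertexInterval:
        """Indices of all vertices with prefix ``x`` (``|x| < k``).

        Equal to ``[gamma(x, 0), gamma(x, n))``; the two folds share state
        so the work halves once the interval has collapsed.
        """
        if len(x) > self.k - 1:
            raise ValueError(f"prefix longer than k-1 = {self.k - 1}")
        lo, hi = 0, self.n
        for ch in reversed(x):
            c = self.alphabet.code(ch)
            if lo == hi:
                lo = hi = self.prev_position(c, lo)
            else:
                lo = self.prev_position(c, lo)
                hi = self.prev_position(c, hi)
        return VertexInterval(lo, hi)

    def contains_path(self, x: str) -> tuple[bool, Optional[int]]:
        """Whether every k-substring of ``x`` (``|x| >= k``) is an edge.

        Starts at the ``(k-1)``-suffix and backtracks one in-edge per
        remaining letter.  On success the second element is the vertex
        index of ``x``'s ``(k-1)``-prefix.
        """
        if len(x) < self.k:
            raise ValueError("string shorter than k; use prefix_interval")
        iv = self.prefix_interval(x[len(x) - self.k + 1:])
        if iv.empty:
            return (False, None)
        i = iv.alpha
        for pos in range(len(x) - self.k, -1, -1):
            c = self.alphabet.code(x[pos])
            if not self.eta[i, c]:
                return (False, None)
            i = self.prev_position(c, i)
        return (True, i)

    # -- string reconstruction ----------------------------------------------

    def vertex_string(self, i: int) -> str:
        """Reconstruct ``v_i`` by iterating rho_inv ``k-1`` times."""
        self._check_vertex(i)
        out = []
        j = i
        for _ in range(self.k - 1):
            a, j = self.prev_position_inverse(j)
            out.append(self.alphabet.char(a))
        return "".join(out)

    def vertex_strings(self) -> list[str]:
        return [self.vertex_string(i) for i in range(self.n)]

    def kmer_set(self) -> set[str]:
        """All sentinel-free k-mers (edges) represented by the index."""
        out = set()
        for i, v in enumerate(self.vertex_strings()):
            if "$" in v:
                continue
            for a in np.flatnonzero(self.eta[i]):
                out.add(self.alphabet.char(int(a)) + v)
        return out

    # -- bulk (vectorized) helpers ------------------------------------------

    def group_index(self) -> np.ndarray:
        """Group number of each vertex (0-based, increasing)."""
        return np.concatenate(([0], np.cumsum(self.f[:-1], dtype=np.int64)))

    def rho_table(self) -> np.ndarray:
        """Dense ``(sigma, n+1)`` table of rho(a, i), one vectorized sweep.

        Semantically identical to :meth:`prev_position`; used by bulk
        operations (pruning, pre-assembly, statistics) where per-call
        reconstruction would dominate.
        """
        n, sigma = self.eta.shape
        dtype = np.int32 if n < 2 ** 31 - 1 else np.int64
        table = np.empty((sigma, n + 1), dtype=dtype)
        starts = np.flatnonzero(np.concatenate(([True], self.f[:-1])))
        gidx = self.group_index()
        ngroups = int(self.f.sum())
        offset = 1
        for a in range(sigma):
            gpres = np.logical_or.reduceat(self.eta[:, a], starts)
            cex = np.concatenate(([0], np.cumsum(gpres, dtype=np.int64)))
            table[a, :n] = offset + cex[gidx]
            table[a, n] = offset + cex[ngroups]
            offset += int(cex[ngroups])
        return table

    def in_degrees(self) -> np.ndarray:
        return self.eta.sum(axis=1, dtype=np.int64)

    # -- comparison ----------------------------------------------------------

    def structural_equal(self, other: "KFMIndex") -> bool:
        """Record-for-record equality (alphabet, k, edge flags, group flags)."""
        return (self.alphabet == other.alphabet and self.k == other.k
                and self.n == other.n
                and bool(np.array_equal(self.eta, other.eta))
                and bool(np.array_equal(self.f, other.f)))

    def __repr__(self) -> str:
        return (f"<KFMIndex k={self.k} n={self.n} sigma={self.alphabet.sigma} "
                f"q={self.prev_store.q}>")
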