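"""Removal of superfluous sentinel-padded (final-completing) vertices.

The sentinel-padded vertices form a tree rooted at the final vertex.  Two
rules apply, evaluated depth-first (deepest trailing-``$`` level last):

* an in-edge ``a + u$`` of a single-``$`` vertex is redundant when another
  vertex ``u + b`` in the same group also has an ``a`` in-edge (the origin
  remains reachable through that vertex);
* a sentinel-padded vertex with no (remaining) in-edges is removed together
  with its out-edge.

Marks are collected against the original arrays and applied in one
compaction pass, because the previous-position map depends on group
in-edge composition; the set of sentinel-free k-mers is unchanged.
"""

from __future__ import annotations

import numpy as np

from .core import KFMIndex

__all__ = ["prune", "vertex_removable", "sentinel_levels", "sentinel_mask"]


def sentinel_levels(index: KFMIndex, rho: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Vertex indices with exactly ``l`` trailing sentinels, ``l = 1 .. k-2``.

    Found by walking the sentinel tree down from the final vertex (which is
    not included; it has ``k-1`` sentinels).
    """
    if rho is None:
        rho = index.rho_table()
    levels: dict[int, np.ndarray] = {}
    cur = np.array([0], dtype=np.int64)
    for level in range(index.k - 2, 0, -1):
        rows, cols = np.nonzero(index.eta[cur])
        cur = rho[cols, cur[rows]].astype(np.int64)
        levels[level] = cur
        if cur.size == 0:
            break
    return {l: v for l, v in levels.items() if v.size}


def sentinel_mask(index: KFMIndex, rho: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of final-completing vertices (including the final vertex)."""
    mask = np.zeros(index.n, dtype=bool)
    mask[0] = True
    for verts in sentinel_levels(index, rho).values():
        mask[verts] = True
    return mask


def _group_letter_counts(index: KFMIndex) -> np.ndarray:
    """(ngroups, sigma) count of in-edges per letter within each group."""
    starts = np.flatnonzero(np.concatenate(([True], index.f[:-1])))
    return np.add.reduceat(index.eta.astype(np.int64), starts, axis=0)


def prune(index: KFMIndex) -> KFMIndex:
    """Drop unneeded final-completing vertices and edges; rebuild the store."""
    rho = index.rho_table()
    levels = sentinel_levels(index, rho)
    removed_v = np.zeros(index.n, dtype=bool)
    removed_e = np.zeros_like(index.eta)
    gidx = index.group_index()
    gcounts = _group_letter_counts(index)

    for level in sorted(levels):  # deepest (fewest $) first: depth-first order
        verts = levels[level]
        if level == 1:
            # same-group redundancy: another group member shares the in-letter
            redundant = index.eta[verts] & (gcounts[gidx[verts]] >= 2)
            removed_e[verts] = redundant
        else:
            for a in range(index.alphabet.sigma):
                m = index.eta[verts, a]
                children = rho[a, verts[m]]
                hit = removed_v[children]
                removed_e[verts[m][hit], a] = True
        removed_v[verts] = ~(index.eta[verts] & ~removed_e[verts]).any(axis=1)

    for a in range(index.alphabet.sigma):  # the root sheds edges from removed children
        if index.eta[0, a] and removed_v[rho[a, 0]]:
            removed_e[0, a] = True

    if not removed_v.any() and not removed_e.any():
        return index
    keep = ~removed_v
    eta = (index.eta & ~removed_e)[keep]
    f = index.f[keep]
    return KFMIndex(index.alphabet, index.k, eta, f,
                    q=index.prev_store.q, w=index.prev_store.w)


def vertex_removable(index: KFMIndex, i: int) -> bool:
    """Whether sentinel-padded vertex ``i`` would be pruned away.

    Evaluates the depth-first marking on the whole index and reports the
    verdict for ``i``; raises when ``v_i`` has no trailing sentinel.
    """
    if i == 0:
        return False  # the final vertex roots the sentinel tree
    rho = index.rho_table()
    levels = sentinel_levels(index, rho)
    member = {int(v) for verts in levels.values() for v in verts}
    if i not in member:
        raise ValueError(f"vertex {i} is not final-completing")
    removed_v = np.zeros(index.n, dtype=bool)
    removed_e = np.zeros_like(index.eta)
    gidx = index.group_index()
    gcounts = _group_letter_counts(index)
    for level in sorted(levels):
        verts = levels[level]
        if level == 1:
            removed_e[verts] = index.eta[verts] & (gcounts[gidx[verts]] >= 2)
        else:
            for a in range(index.alphabet.sigma):
                m = index.eta[verts, a]
                children = rho[a, verts[m]]
                removed_e[verts[m][removed_v[children]], a] = True
        removed_v[verts] = ~(index.eta[verts] & ~removed_e[verts]).any(axis=1)
    return bool(removed_v[i])
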