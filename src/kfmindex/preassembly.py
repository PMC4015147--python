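"""Degree classification and extraction of uniquely determined paths.

A vertex is *simple* when both its in-degree (set in-edge flags) and its
out-degree (edges it originates) equal one; runs of simple vertices between
non-simple endpoints form uniquely determined paths (unitigs).  Paths are
anchored at their downstream endpoint and walked backward through the
single in-edges; only the anchor's string is materialized, the remaining
sequence accrues from the in-edge letters.  Paths made solely of
sentinel-padded vertices are dropped and sentinels are trimmed from the
emitted sequences.

The paper leaves cycles of all-simple vertices unspecified; they are
detected by a visited-mark sweep and emitted as one circular path each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import SENTINEL_CODE
from .core import KFMIndex
from .prune import sentinel_mask

__all__ = ["PathRecord", "classify_vertices", "extract_paths", "estimate_path_count"]


@dataclass
class PathRecord:
    """A uniquely determined path: sequence plus endpoint vertex indices."""

    sequence: str
    start_vertex: int
    end_vertex: int
    length: int  # vertices on the path
    circular: bool = False


def _degrees(index: KFMIndex, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    indeg = index.in_degrees()
    rows, cols = np.nonzero(index.eta)
    sources = rho[cols, rows]
    outdeg = np.bincount(sources, minlength=index.n)
    return indeg, outdeg


def classify_vertices(index: KFMIndex, rho: np.ndarray | None = None) -> np.ndarray:
    """Indices of all vertices with in-degree or out-degree different from one."""
    if rho is None:
        rho = index.rho_table()
    indeg, outdeg = _degrees(index, rho)
    return np.flatnonzero((indeg != 1) | (outdeg != 1))


def estimate_path_count(index: KFMIndex, rho: np.ndarray | None = None) -> int:
    """Upper estimate: summed in-degrees of the non-simple vertices.

    May exceed the emitted count by the number of sentinel-only paths.
    """
    if rho is None:
        rho = index.rho_table()
    indeg, outdeg = _degrees(index, rho)
    nonsimple = (indeg != 1) | (outdeg != 1)
    return int(indeg[nonsimple].sum())


def _anchor_strings(index: KFMIndex, anchors: np.ndarray, rho: np.ndarray) -> list[str]:
    """Vectorized multi-vertex string reconstruction (rho-inverse per round).

    For a batch of indices the inverting letter is found from the per-letter
    rho ranges and the group-end position by a searchsorted per letter;
    iterated ``k-1`` times as in the single-vertex algorithm.
    """
    sigma = index.alphabet.sigma
    m = anchors.size
    codes = np.empty((m, index.k - 1), dtype=np.int8)
    bounds = rho[:, 0]  # rho(a, 0) per letter: first position mapped by letter a
    cur = anchors.astype(np.int64)
    for round_ in range(index.k - 1):
        letter = np.full(m, SENTINEL_CODE, dtype=np.int8)
        nxt = np.zeros(m, dtype=np.int64)
        live = cur > 0
        la = (np.searchsorted(bounds, cur[live], side="right") - 1).astype(np.int8)
        letter[live] = la
        pos = np.empty(int(live.sum()), dtype=np.int64)
        for a in range(sigma):
            sel = la == a
            if sel.any():
                pos[sel] = np.searchsorted(rho[a], cur[live][sel], side="right") - 1
        nxt[live] = pos
        codes[:, round_] = letter
        cur = nxt
    alpha = index.alphabet
    return ["".join(alpha.char(int(c)) for c in row) for row in codes]


def extract_paths(index: KFMIndex, include_circular: bool = True) -> list[PathRecord]:
    """All uniquely determined paths between non-simple vertices."""
    rho = index.rho_table()
    indeg, outdeg = _degrees(index, rho)
    simple = (indeg == 1) & (outdeg == 1)
    sent = sentinel_mask(index, rho)
    # single in-edge letter and its origin, valid where indeg == 1
    inletter = np.argmax(index.eta, axis=1)
    prev = rho[inletter, np.arange(index.n)].astype(np.int64)
    nonsimple_idx = np.flatnonzero(~simple)
    anchor_strs = _anchor_strings(index, nonsimple_idx, rho)

    letters = index.alphabet.letters
    simple_l = simple
    visited = np.zeros(index.n, dtype=bool)
    paths: list[PathRecord] = []
    for t, vt in zip(nonsimple_idx.tolist(), anchor_strs):
        trimmed = vt.rstrip("$")
        for a in np.flatnonzero(index.eta[t]):
            walked = [letters[int(a)]]
            j = int(rho[a, t])
            while simple_l[j]:
                visited[j] = True
                walked.append(letters[int(inletter[j])])
                j = int(prev[j])
            if sent[j]:
                continue  # every vertex on this path is final-completing
            walked.reverse()
            paths.append(PathRecord("".join(walked) + trimmed,
                                    start_vertex=j, end_vertex=int(t),
                                    length=len(walked) + 1))
    if include_circular:
        # all-simple cycles are unreachable from any anchor; linearize each
        # once, starting (arbitrarily) at its lowest-index vertex
        for j0 in np.flatnonzero(simple & ~visited).tolist():
            if visited[j0]:
                continue
            walked = []
            j = j0
            while True:
                visited[j] = True
                walked.append(letters[int(inletter[j])])
                j = int(prev[j])
                if j == j0:
                    break
            walked.reverse()
            anchor = index.vertex_string(j0)
            paths.append(PathRecord("".join(walked) + anchor,
                                    start_vertex=j0, end_vertex=j0,
                                    length=len(walked), circular=True))
    return paths
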