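"""Merging two kFM-indexes into the union of their k-mer sets.

The merge is planned first: a joint recursion over letter-prefix intervals
of both indexes (extending prefixes one letter at a time, sentinel-padded
vertices carried alongside) locates, for every vertex ``i`` of the smaller
index ``A``, its position ``i + alpha_B(v_i)`` in the interleaved list of
``n_A + n_B`` records, marks vertices present in both, and marks merged
group positions whose group-end flag must be dropped.  A single sequential
pass then emits the merged records, OR-ing duplicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KFMIndex

__all__ = ["MergePlan", "plan_merge", "apply_merge", "merge"]


@dataclass
class MergePlan:
    """Bit arrays describing an interleaved merge of indexes A and B.

    ``source_flags[p]`` is true when merged position ``p`` holds an A
    record; ``duplicate_flags[i]`` is true when A's vertex ``i`` also occurs
    in B (the B twin immediately follows it); ``groupend_clear_flags[p]``
    marks merged positions whose group-end flag must be cleared.
    """

    source_flags: np.ndarray
    duplicate_flags: np.ndarray
    groupend_clear_flags: np.ndarray

    @property
    def n_duplicates(self) -> int:
        return int(self.duplicate_flags.sum())


def _compatible(a: KFMIndex, b: KFMIndex):
    if a.k != b.k:
        raise ValueError(f"cannot merge indexes with k = {a.k} and k = {b.k}")
    if a.alphabet != b.alphabet:
        raise ValueError("cannot merge indexes over different alphabets")


def plan_merge(A: KFMIndex, B: KFMIndex) -> MergePlan:
    """Plan the merge of ``A`` into ``B`` (``A`` should be the smaller)."""
    _compatible(A, B)
    k = A.k
    sigma = A.alphabet.sigma
    nA, nB = A.n, B.n
    source = np.zeros(nA + nB, dtype=bool)
    dup = np.zeros(nA, dtype=bool)
    clear = np.zeros(nA + nB, dtype=bool)

    # Node state: prefix depth p, whether the sentinel-padded vertex
    # x + '$'*(k-1-p) exists in A / B (it sits at the interval start when it
    # does), and the half-open intervals of vertices prefixed by x.
    def visit(depth, sentA, aA, bA, sentB, aB, bB):
        if depth == k - 1:
            hasA, hasB = aA < bA, aB < bB
        else:
            hasA, hasB = sentA, sentB
        if hasA:
            source[aA + aB] = True
            if hasB:
                dup[aA] = True
        if depth == k - 2:
            if aA < bA and aB < bB:
                clear[aA + aB: bA + bB - 1] = True
        elif depth < k - 2:
            if hasA and hasB:
                clear[aA + aB] = True  # singleton sentinel group present in both
        if depth >= k - 1:
            return
        for a in range(sigma):
            sA2 = bool(sentA and A.eta[aA, a])
            sB2 = bool(sentB and B.eta[aB, a])
            aA2 = A.prev_position(a, aA)
            bA2 = aA2 if bA == aA else A.prev_position(a, bA)
            aB2 = B.prev_position(a, aB)
            bB2 = aB2 if bB == aB else B.prev_position(a, bB)
            if sA2 or sB2 or aA2 < bA2 or aB2 < bB2:
                visit(depth + 1, sA2, aA2, bA2, sB2, aB2, bB2)

    visit(0, True, 0, nA, True, 0, nB)
    assert int(source.sum()) == nA
    return MergePlan(source, dup, clear)


def apply_merge(A: KFMIndex, B: KFMIndex, plan: MergePlan) -> KFMIndex:
    """Emit the merged index in one sequential pass over the plan."""
    _compatible(A, B)
    nA, nB = A.n, B.n
    if (len(plan.source_flags) != nA + nB or len(plan.duplicate_flags) != nA
            or len(plan.groupend_clear_flags) != nA + nB):
        raise ValueError("merge plan does not match index sizes")
    n_out = nA + nB - plan.n_duplicates
    sigma = A.alphabet.sigma
    eta = np.empty((n_out, sigma), dtype=bool)
    f = np.empty(n_out, dtype=bool)
    src, dup, clear = plan.source_flags, plan.duplicate_flags, plan.groupend_clear_flags
    iA = iB = o = p = 0
    while p < nA + nB:
        if src[p]:
            rec = A.eta[iA]
            flag = bool(A.f[iA]) and not clear[p]
            if dup[iA]:
                rec = rec | B.eta[iB]
                flag = flag or (bool(B.f[iB]) and not clear[p + 1])
                iB += 1
                p += 2
            else:
                p += 1
            iA += 1
        else:
            rec = B.eta[iB]
            flag = bool(B.f[iB]) and not clear[p]
            iB += 1
            p += 1
        eta[o] = rec
        f[o] = flag
        o += 1
    if iA != nA or iB != nB or o != n_out:
        raise ValueError("merge plan is inconsistent with its indexes")
    return KFMIndex(A.alphabet, A.k, eta, f, q=A.prev_store.q, w=A.prev_store.w)


def merge(A: KFMIndex, B: KFMIndex) -> KFMIndex:
    """Union of two indexes; the smaller is recursed over, per the plan."""
    _compatible(A, B)
    if A.n > B.n:
        A, B = B, A
    return apply_merge(A, B, plan_merge(A, B))
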