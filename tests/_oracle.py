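"""Brute-force reference model of the final-completed de Bruijn subgraph.

Everything here is computed from explicit string lists and definitional
formulas (sorted vertex strings, direct lexicographic minimization for the
previous-position map), independently of the index implementation.
"""

from __future__ import annotations

HIGH = "￿"  # sorts after every letter we use


class NaiveGraph:
    def __init__(self, strings, k, letters="ACGT"):
        self.k = k
        self.letters = letters
        words: set[str] = set()
        for s in strings:
            if len(s) < k - 1:
                continue
            for p in range(len(s) - k + 1):
                words.add(s[p:p + k])
            v = s[len(s) - k + 1:]
            for t in range(k - 1):
                words.add(v[t:] + "$" * (t + 1))
        self.words = words
        verts = {w[1:] for w in words} | {w[:-1] for w in words} | {"$" * (k - 1)}
        self.vertices = sorted(verts)  # '$' < any ASCII letter
        self.n = len(self.vertices)
        self.pos = {v: i for i, v in enumerate(self.vertices)}
        self.in_edges = [sorted({w[0] for w in words if w[1:] == v})
                         for v in self.vertices]
        self.f = [i == self.n - 1 or self.vertices[i][:-1] != self.vertices[i + 1][:-1]
                  for i in range(self.n)]
        self.kmers = {w for w in words if "$" not in w}
        self.out_edges = {}
        for w in words:
            self.out_edges.setdefault(w[:-1], set()).add(w)

    def rho(self, a: str, i: int) -> int:
        """Eq-style definition: min{ j : v_j >= a + v_i[:-1], or j = n }."""
        prefix = self.vertices[i][:self.k - 2] if i < self.n else HIGH * (self.k - 2)
        t = a + prefix
        for j, v in enumerate(self.vertices):
            if v >= t:
                return j
        return self.n

    def tau(self, a: str) -> int:
        groups = set()
        for i, edges in enumerate(self.in_edges):
            if a in edges:
                groups.add(self.vertices[i][:-1])
        return len(groups)

    def prefix_interval(self, x: str) -> tuple[int, int]:
        hits = [i for i, v in enumerate(self.vertices) if v.startswith(x)]
        if not hits:
            # insertion point of x in the sorted vertex list
            j = sum(1 for v in self.vertices if v < x)
            return (j, j)
        return (hits[0], hits[-1] + 1)

    def contains_path(self, x: str) -> bool:
        return all(x[p:p + self.k] in self.kmers for p in range(len(x) - self.k + 1))

    def gamma_floor(self, x: str) -> int:
        """min{ i : x <= v_i + z realizable in the graph } (brute force)."""
        for i, v in enumerate(self.vertices):
            if x <= v:
                return i
            if self._extends_at_least(v, x):
                return i
        return self.n

    def _extends_at_least(self, v: str, x: str) -> bool:
        # can v be extended along graph edges to a string >= x?
        if len(v) >= len(x):
            return v >= x
        if x[:len(v)] < v:
            return True
        if x[:len(v)] > v:
            return False
        stack = [v]
        seen = set()
        while stack:
            w = stack.pop()
            if len(w) >= len(x):
                if w >= x:
                    return True
                continue
            if w > x[:len(w)]:
                return True
            if w < x[:len(w)]:
                continue
            for e in self.out_edges.get(w[-(self.k - 1):], ()):  # extend one edge
                if e[-1] == "$":
                    continue  # z ranges over sentinel-free strings only
                nxt = w + e[-1]
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False
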