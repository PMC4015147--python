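import numpy as np
import pytest

from kfmindex import BuildConfig, KFMIndex, build
from kfmindex.alphabet import DNA

from _oracle import NaiveGraph

TOY1_STRINGS = ["ACGT"]
TOY2_STRINGS = ["ACG", "CGT", "CGA"]


def build_strings(strings, k=3, q=32, prune_policy="final_only", **kw):
    return build(strings, BuildConfig(k=k, q=q, prune_policy=prune_policy, **kw))


@pytest.fixture(scope="session")
def toy1():
    return build_strings(TOY1_STRINGS)


@pytest.fixture(scope="session")
def toy2():
    return build_strings(TOY2_STRINGS)


def random_strings(rng, n_strings=6, min_len=4, max_len=30, letters="ACGT"):
    out = []
    for _ in range(n_strings):
        ln = int(rng.integers(min_len, max_len + 1))
        out.append("".join(letters[c] for c in rng.integers(0, len(letters), ln)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def letters_of(index, i):
    """In-edge letters of vertex i as characters."""
    codes, _ = index.vertex_record(i)
    return {index.alphabet.char(c) for c in codes}


def check_against_oracle(index: KFMIndex, oracle: NaiveGraph):
    """Full-table comparison: vertices, in-edges, flags, and all rho values."""
    assert index.n == oracle.n
    assert index.vertex_strings() == oracle.vertices
    for i in range(index.n):
        assert sorted(letters_of(index, i)) == oracle.in_edges[i], f"vertex {i}"
        assert bool(index.f[i]) == oracle.f[i], f"flag {i}"
    for a, ch in enumerate(index.alphabet.letters):
        for i in range(index.n + 1):
            assert index.prev_position(a, i) == oracle.rho(ch, i), (ch, i)
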