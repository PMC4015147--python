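"""Edge-word enumeration, sorted-word assembly, and partitioned builds."""

import logging

import numpy as np
import pytest

from kfmindex import BuildConfig, build, build_from_read_matrix
from kfmindex.construct import (build_from_sorted_words, edge_words_from_string,
                                key_word, word_key)

from _oracle import NaiveGraph
from conftest import build_strings, letters_of, random_strings


class TestEdgeWords:
    def test_basic(self):
        assert set(edge_words_from_string("ACGT", 3)) == {"ACG", "CGT", "GT$", "T$$"}

    def test_exact_k(self):
        assert set(edge_words_from_string("ACG", 3)) == {"ACG", "CG$", "G$$"}

    def test_length_k_minus_one(self):
        assert set(edge_words_from_string("AC", 3)) == {"AC$", "C$$"}

    def test_short_string_skipped(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert edge_words_from_string("A", 3) == []
        assert "skipping" in caplog.text

    def test_bad_symbol(self):
        with pytest.raises(ValueError):
            edge_words_from_string("ACNG", 3)

    def test_duplicates_kept(self):
        words = edge_words_from_string("AAAA", 3)
        assert len(words) == 4 and len(set(words)) == 3

    def test_key_roundtrip(self):
        for w in ("ACG", "GT$", "T$$", "AAA", "TTT"):
            assert key_word(word_key(w, 3), 3) == w

    def test_key_order_is_target_then_letter(self):
        # CGT targets GT; GT$ targets T$ which sorts after GT
        assert word_key("CGT", 3) < word_key("GT$", 3)
        assert word_key("AA$", 3) < word_key("AAA", 3) < word_key("TAA", 3)


class TestBuildFromSortedWords:
    def test_toy1_table(self):
        words = sorted(["ACG", "CGT", "GT$", "T$$"], key=lambda w: word_key(w, 3))
        idx = build_from_sorted_words(words, 3)
        assert idx.n == 5
        assert idx.vertex_strings() == ["$$", "AC", "CG", "GT", "T$"]
        assert [sorted(letters_of(idx, i)) for i in range(5)] == \
            [["T"], [], ["A"], ["C"], ["G"]]
        assert idx.f.all()

    def test_toy2_table(self, toy2):
        words = set()
        for s in ("ACG", "CGT", "CGA"):
            words.update(edge_words_from_string(s, 3))
        keys = np.unique([word_key(w, 3) for w in words])
        idx = build_from_sorted_words(keys, 3)
        # unpruned build has the extra G$ vertex; after pruning it matches TOY2
        from kfmindex.prune import prune
        assert prune(idx).structural_equal(toy2)

    def test_empty(self):
        idx = build_from_sorted_words([], 3)
        assert idx.n == 1
        assert idx.vertex_string(0) == "$$"
        assert not idx.eta.any()

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            build_from_sorted_words(["CGT", "ACG"], 3)

    def test_duplicate_raises(self):
        with pytest.raises(ValueError):
            build_from_sorted_words(["ACG", "ACG"], 3)

    def test_k_too_large_for_words(self):
        with pytest.raises(ValueError):
            build_from_sorted_words([], 28)  # 5**28 exceeds the 64-bit key


class TestBuild:
    def test_partitioned_equals_monolithic(self, rng):
        strings = random_strings(rng, n_strings=8, min_len=6, max_len=30)
        mono = build_strings(strings, k=4)
        for psize in (1, 50, 200):
            part = build(strings, BuildConfig(k=4, partition_size=psize))
            assert part.structural_equal(mono), psize

    def test_partition_policies(self, rng):
        strings = random_strings(rng, n_strings=6, min_len=6, max_len=25)
        a = build(strings, BuildConfig(k=4, partition_size=40, prune_policy="every_merge"))
        b = build(strings, BuildConfig(k=4, prune_policy="final_only"))
        assert a.structural_equal(b)

    def test_order_insensitive(self, rng):
        strings = random_strings(rng, n_strings=6, max_len=25)
        a = build_strings(strings, k=4)
        b = build_strings(strings[::-1], k=4)
        assert a.structural_equal(b)
        assert np.array_equal(a.prev_store.low, b.prev_store.low)

    def test_empty_build(self):
        idx = build([], BuildConfig(k=5))
        assert idx.n == 1

    def test_kmers_match_naive(self, rng):
        strings = random_strings(rng, n_strings=20, min_len=50, max_len=50)
        idx = build_strings(strings, k=23)
        assert idx.kmer_set() == NaiveGraph(strings, 23).kmers

    def test_sentinel_vertices_have_inedges(self, rng):
        # after pruning, no sentinel-padded vertex except the root survives
        # without an in-edge
        strings = random_strings(rng, n_strings=6, max_len=30)
        idx = build_strings(strings, k=4)
        for i, v in enumerate(idx.vertex_strings()):
            if i > 0 and "$" in v:
                assert idx.eta[i].any(), v

    def test_build_from_read_matrix_equals_string_build(self, rng):
        reads = rng.integers(0, 4, size=(30, 12), dtype=np.uint8)
        decoded = ["".join("ACGT"[c] for c in row) for row in reads]
        rc = [s.translate(str.maketrans("ACGT", "TGCA"))[::-1] for s in decoded]
        fast = build_from_read_matrix(reads, k=5)
        slow = build_strings(decoded + rc, k=5)
        assert fast.structural_equal(slow)

    def test_build_accepts_code_arrays(self, rng):
        reads = rng.integers(0, 4, size=(5, 10), dtype=np.uint8)
        decoded = ["".join("ACGT"[c] for c in row) for row in reads]
        a = build(list(reads), BuildConfig(k=4))
        b = build(decoded, BuildConfig(k=4))
        assert a.structural_equal(b)
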