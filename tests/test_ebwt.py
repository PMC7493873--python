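"""eBWT construction, inversion and FM-index navigation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ebwtcall as ec
from ebwtcall.ebwt import ALPHABET, CODE, MalformedIndexError, SAInterval

import oracles

read_st = st.text(alphabet="ACGT", min_size=1, max_size=80)
collection_st = st.lists(read_st, min_size=1, max_size=50)


@pytest.mark.parametrize("reads,expected", [
    (["ACG"], "G$AC"),
    (["A"], "A$"),
    (["AA", "AA"], "AAAA$$"),
])
def test_build_matches_definition(reads, expected):
    index = ec.build_ebwt(ec.SequenceCollection(reads))
    assert index.ebwt == expected == oracles.brute_ebwt_string(
        ec.SequenceCollection(reads))


def test_build_agrees_with_brute_oracle(rng):
    for _ in range(30):
        coll = oracles.random_collection(rng, max_reads=10, max_len=25)
        assert ec.build_ebwt(coll).ebwt == oracles.brute_ebwt_string(coll)


@pytest.mark.parametrize("reads", [["ACG"], ["A"], ["TTT", "T", "GATTACA"]])
def test_invert_examples(reads):
    coll = ec.SequenceCollection(reads)
    assert ec.invert_ebwt(ec.build_ebwt(coll)).reads == reads


@settings(max_examples=100, deadline=None, derandomize=True)
@given(collection_st)
def test_roundtrip_identity(reads):
    coll = ec.SequenceCollection(reads)
    assert ec.invert_ebwt(ec.build_ebwt(coll)) == coll


def test_multiset_conservation(rng):
    for _ in range(20):
        coll = oracles.random_collection(rng, max_reads=8, max_len=30)
        counts = ec.build_ebwt(coll).counts
        assert counts["$"] == coll.m
        joined = "".join(coll.reads)
        for b in "ACGT":
            assert counts[b] == joined.count(b)


def test_lf_fl_mutual_inverses(rng):
    for _ in range(20):
        coll = oracles.random_collection(rng, max_reads=8, max_len=30)
        index = ec.build_ebwt(coll)
        for i in range(index.n):
            assert index.fl(index.lf(i)) == i
            assert index.lf(index.fl(i)) == i


def test_backward_extend_full_interval_counts(rng):
    coll = oracles.random_collection(rng, max_reads=6, max_len=30)
    index = ec.build_ebwt(coll)
    joined = "".join(coll.reads)
    for c in "ACGT":
        iv = index.backward_extend(index.full_interval(), c)
        assert len(iv) == joined.count(c)


def test_backward_extend_examples():
    index = ec.build_ebwt(ec.SequenceCollection(["ACG"]))
    iv = index.backward_extend(index.full_interval(), "G")
    assert len(index.backward_extend(iv, "C")) == 1  # suffix CG$
    empty = SAInterval(0, 0)
    assert index.backward_extend(empty, "A").is_empty


def test_backward_extend_vs_naive_counting(rng):
    """Backward search equals naive occurrence counting, patterns <= 4."""
    patterns = ["".join(p) for k in range(1, 5)
                for p in itertools.product("ACGT", repeat=k)]
    for _ in range(8):
        coll = oracles.random_collection(rng, max_reads=6, max_len=25)
        index = ec.build_ebwt(coll)
        for pat in patterns:
            iv = index.full_interval()
            for c in reversed(pat):
                iv = index.backward_extend(iv, c)
            assert len(iv) == oracles.naive_pattern_interval_size(coll, pat)


def test_symbol_counts(rng):
    index = ec.build_ebwt(ec.SequenceCollection(["ACG"]))
    assert index.symbol_counts(SAInterval(0, 0)) == dict.fromkeys("$ACGT", 0)
    assert index.symbol_counts(index.full_interval()) == {
        "$": 1, "A": 1, "C": 1, "G": 1, "T": 0}
    coll = oracles.random_collection(rng, max_reads=5, max_len=20)
    idx2 = ec.build_ebwt(coll)
    iv = SAInterval(2, idx2.n - 1)
    counts = idx2.symbol_counts(iv)
    assert sum(counts.values()) == len(iv)
    assert counts == {a: idx2.ebwt[iv.lo:iv.hi].count(a) for a in ALPHABET}


def test_figure_cluster_symbol_counts(figure_setup, figure_cluster):
    _, index, _ = figure_setup
    counts = index.symbol_counts(figure_cluster.interval)
    assert counts["T"] == 2 and counts["C"] == 3
    assert index.ebwt[figure_cluster.interval.lo:figure_cluster.interval.hi] == "TCCTC"


def test_extract_right_context_vs_suffix_table(rng):
    for _ in range(25):
        coll = oracles.random_collection(rng, max_reads=6, max_len=25)
        index = ec.build_ebwt(coll)
        table = oracles.sorted_suffix_table(coll)
        for r in range(index.n):
            assert index.extract_right_context(r, 0) == ""
            for k in (1, 3, 100):
                assert index.extract_right_context(r, k) == table[r][0][:k]


@pytest.mark.parametrize("reads,err", [
    ([], ValueError),
    ([""], ValueError),
    (["ACGN"], ValueError),
    (["ACGX"], ValueError),
])
def test_collection_errors(reads, err):
    with pytest.raises(err):
        ec.SequenceCollection(reads)


def test_fasta_reader_drops_n_reads(tmp_path):
    path = tmp_path / "reads.fasta"
    path.write_text(">a\nACGT\nACGT\n>b\nACNT\n>c\nacgt\n")
    coll = ec.read_fasta_collection(path)
    assert coll.reads == ["ACGTACGT", "ACGT"]  # b dropped, c case-folded


def test_index_save_load_roundtrip(tmp_path, rng):
    coll = oracles.random_collection(rng, max_reads=8, max_len=30)
    index = ec.build_ebwt(coll)
    index.save(tmp_path / "idx")
    loaded = ec.EBWTIndex.load(tmp_path / "idx")
    assert loaded.ebwt == index.ebwt
    assert loaded.dollar_reads.tolist() == index.dollar_reads.tolist()
    assert ec.invert_ebwt(loaded) == coll
    # rebuild is byte-identical
    index.save(tmp_path / "idx2")
    assert (tmp_path / "idx.ebwt").read_bytes() == (tmp_path / "idx2.ebwt").read_bytes()


def test_malformed_index_rejected():
    index = ec.build_ebwt(ec.SequenceCollection(["ACG"]))
    broken = ec.EBWTIndex(codes=index.codes.copy(),
                          dollar_reads=np.array([1], dtype=np.int64))
    with pytest.raises(MalformedIndexError):
        ec.invert_ebwt(broken)
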