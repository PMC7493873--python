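"""Consensus construction, right-anchored alignment and cluster calling."""

import itertools

import numpy as np
import pytest

import ebwtcall as ec
from ebwtcall import calling
from ebwtcall.clusters import Cluster
from ebwtcall.ebwt import SAInterval

import oracles


def _counts_cluster(counts, dollars=0):
    size = sum(counts.values()) + dollars
    full = {b: counts.get(b, 0) for b in "ACGT"}
    return Cluster(interval=SAInterval(0, size), counts=full,
                   dollars=dollars, has_right_anchor=True)


def test_params_defaults_and_derived():
    p = calling.CallerParams()
    assert (p.k_min, p.k_left, p.k_right, p.max_indel, p.min_cov,
            p.max_edits) == (16, 31, 30, 10, 6, 2)
    assert p.M == p.k_left + p.max_indel == 41
    with pytest.raises(ValueError):
        calling.CallerParams(min_cov=0)


@pytest.mark.parametrize("counts,min_cov,expected", [
    ({"T": 2, "C": 3}, 2, [("C", "T")]),
    ({"A": 10}, 6, []),
    ({"A": 6, "C": 6, "G": 6}, 6, [("A", "C"), ("A", "G"), ("C", "G")]),
])
def test_eligible_pairs(counts, min_cov, expected):
    params = calling.CallerParams(min_cov=min_cov)
    cluster = _counts_cluster(counts)
    assert calling.eligible_pairs(cluster, params) == expected


def test_eligible_pairs_ordering():
    params = calling.CallerParams(min_cov=2)
    cluster = _counts_cluster({"A": 9, "C": 2, "G": 5})
    # pairs sorted by combined coverage; more frequent symbol first
    assert calling.eligible_pairs(cluster, params) == [
        ("A", "G"), ("A", "C"), ("G", "C")]


def test_consensus_worked_example(figure_setup, figure_cluster, figure_params):
    _, index, _ = figure_setup
    assert calling.consensus_left(index, figure_cluster, "T",
                                  figure_params.M) == "AT"
    assert calling.consensus_left(index, figure_cluster, "C",
                                  figure_params.M) == "ATGC"


def test_consensus_m1_is_single_symbol(figure_setup, figure_cluster):
    _, index, _ = figure_setup
    assert calling.consensus_left(index, figure_cluster, "C", 1) == "C"


def test_consensus_recovers_true_left_context(errorfree_sim):
    """Error-free simulation: the consensus equals the planted genome's
    left context at every isolated SNP (forward strand)."""
    truth, _, index, bv, params = errorfree_sim
    from ebwtcall.clusters import cluster_intervals, _cluster_at
    los, his = cluster_intervals(bv)
    checked = 0
    for v in truth.snps:
        p = v.pos - 1
        ctx = truth.genome[p + 1: p + 1 + params.k_min]
        iv = index.full_interval()
        for c in reversed(ctx):
            iv = index.backward_extend(iv, c)
        hits = [(lo, hi) for lo, hi in zip(los, his)
                if lo <= iv.lo and iv.hi <= hi]
        if not hits:
            continue
        cluster = _cluster_at(index, bv, int(hits[0][0]), int(hits[0][1]))
        if cluster.counts.get(v.ref, 0) < params.min_cov:
            continue
        got = calling.consensus_left(index, cluster, v.ref, params.M)
        expected = (truth.genome[max(0, p + 1 - params.M): p] + v.ref)[-len(got):]
        assert got == expected
        checked += 1
    assert checked >= 3


def test_right_context_worked_example(figure_setup, figure_cluster):
    _, index, bv = figure_setup
    assert calling.right_context_for_cluster(index, figure_cluster, bv, 2) \
        == ("GC", True)
    assert calling.right_context_for_cluster(index, figure_cluster, bv, 0) \
        == ("", True)


def test_right_context_matches_suffix_table(rng):
    for _ in range(20):
        coll = oracles.random_collection(rng, max_reads=6, max_len=20)
        index = ec.build_ebwt(coll)
        bv = ec.lcp_bitvectors_from_ebwt(index, 2, 2)
        table = oracles.sorted_suffix_table(coll)
        for cluster in ec.find_clusters(bv, index):
            seq, anchored = calling.right_context_for_cluster(
                index, cluster, bv, 2)
            lo, hi = cluster.interval.lo, cluster.interval.hi
            if anchored:
                rows = [r for r in range(lo + 1, hi) if bv.K_right[r]]
                assert seq == table[rows[0]][0][:2]
            else:
                assert len(seq) < 2


@pytest.mark.parametrize("L1,L2,expected", [
    ("AT", "ATGC", (2, 2, 1)),     # delete GC from the longer consensus
    ("ACGA", "ACGT", (0, None, 1)),  # pure SNP
    ("ATGC", "AT", (2, 1, 1)),
])
def test_align_right_anchored_examples(L1, L2, expected):
    assert calling.align_right_anchored(L1, L2, 5) == expected


def test_align_right_anchored_exhaustive_binary():
    """Agreement with the restricted-DP oracle on all binary-alphabet
    pairs up to length 5 whose last characters differ."""
    strings = ["".join(p) for k in range(1, 6)
               for p in itertools.product("AC", repeat=k)]
    for L1 in strings:
        for L2 in strings:
            if L1[-1] == L2[-1]:
                continue
            for g in (1, 3):
                got = calling.align_right_anchored(L1, L2, g)
                exp = oracles.brute_right_anchored(L1, L2, g)
                assert got == exp, (L1, L2, g)


def test_align_right_anchored_random_quaternary(rng):
    for _ in range(500):
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 12))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 12))))
        if a[-1] == b[-1]:
            continue
        assert calling.align_right_anchored(a, b, 4) == \
            oracles.brute_right_anchored(a, b, 4)


def test_call_cluster_worked_example(figure_setup, figure_cluster,
                                     figure_params):
    _, index, bv = figure_setup
    calls = calling.call_cluster(index, figure_cluster, bv, figure_params)
    assert len(calls) == 1
    call = calls[0]
    assert {call.frag1, call.frag2} == {"ATGC", "ATGCGC"}
    assert call.kind == "DEL" and call.event_len == 2
    assert {call.cov1, call.cov2} == {2, 3}
    assert call.edits == 1


def test_single_allele_cluster_yields_nothing(figure_setup, figure_params):
    _, index, bv = figure_setup
    cluster = _counts_cluster({"A": 10})
    assert calling.call_cluster(index, cluster, bv, figure_params) == []


def test_call_invariants(errorfree_sim):
    truth, _, index, bv, params = errorfree_sim
    calls, stats = calling.call_all(index, bv, params)
    assert calls
    for call in calls:
        assert call.edits <= params.max_edits
        assert min(call.cov1, call.cov2) >= params.min_cov
        assert call.frag1.endswith(call.frag1[call.event_pos1 + 1:])
        # both fragments end with the identical right context
        r1 = call.frag1[call.event_pos1 + 1:]
        r2 = call.frag2[call.event_pos2 + 1:]
        assert r1 == r2
        if call.kind == "SNP":
            assert len(call.frag1) == len(call.frag2)
        else:
            assert abs(len(call.frag1) - len(call.frag2)) == call.event_len


def test_raising_min_cov_shrinks_call_set(errorfree_sim):
    truth, _, index, bv, params = errorfree_sim
    prev = None
    for m in (6, 10, 14, 1000):
        p = calling.CallerParams(min_cov=m)
        calls, _ = calling.call_all(index, bv, p)
        frags = {(c.frag1, c.frag2) for c in calls}
        if prev is not None:
            assert frags <= prev
        prev = frags
    assert prev == set()  # absurd coverage demand empties the output
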