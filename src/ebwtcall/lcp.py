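"""LCP structures derived from the eBWT alone.

The cluster detector does not need the full LCP array — only three length-n
bitvectors:

* ``K_min[i]   = 1  iff  lcp[i] >= k_min``
* ``K_right[i] = 1  iff  lcp[i] >= k_right``
* ``localMin[i] = 1 iff  lcp[i-1] >= lcp[i] < lcp[i+1]``

where ``lcp[i]`` is the longest common prefix length between the (i-1)-th
and i-th lexicographically smallest suffixes and end-markers of distinct
reads never match each other.  Positions 0 and n-1 have ``localMin = 0``
(no out-of-range neighbours).

``lcp_bitvectors_from_ebwt`` computes these from the eBWT only, with an
interval-queue BFS that simulates a breadth-first visit of the generalized
suffix tree: every left-extension of a pattern interval induces the LCP
value at the interval's right boundary.  String collections need one extra
rule beyond the classic single-string induction: runs of suffixes that are
equal up to their (distinct) end-markers have interior LCP equal to the
pattern length, and those positions are never the right boundary of any
pattern interval.  They are filled from the suffix-length profile, itself
derived from the eBWT via LF-walks.

``lcp_brute`` is the quadratic definitional oracle used by the tests.

At desk scale the traversal keeps a plain int32 LCP array internally; the
succinct-space variants of these structures are a non-goal here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ebwt import EBWTIndex, SequenceCollection, SIGMA, _sorted_suffixes


@dataclass
class LCPArray:
    """Full LCP array (testing oracle only in production pipelines)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        if len(self.values) and self.values[0] != 0:
            raise ValueError("lcp[0] must be 0")


@dataclass
class LCPBitvectors:
    """The three bitvectors driving positional clustering."""

    K_min: np.ndarray
    localMin: np.ndarray
    K_right: np.ndarray
    k_min: int
    k_right: int

    @property
    def n(self) -> int:
        return len(self.K_min)


def lcp_brute(collection: SequenceCollection) -> LCPArray:
    """LCP by direct pairwise comparison of adjacent sorted suffixes.

    End-markers of distinct reads are treated as different characters, so
    two suffixes equal in base content share exactly their base length.
    """
    suffixes = _sorted_suffixes(collection)
    n = len(suffixes)
    lcp = np.zeros(n, dtype=np.int32)
    for i in range(1, n):
        a, b = suffixes[i - 1][0], suffixes[i][0]
        k = 0
        for x, y in zip(a, b):
            if x != y:
                break
            k += 1
        lcp[i] = k
    return LCPArray(lcp)


def suffix_lengths(index: EBWTIndex) -> np.ndarray:
    """Base length of each row's suffix, from the eBWT via parallel LF-walks.

    Row k < m holds the bare end-marker of read k (length 0); walking LF
    from there visits the rows of progressively longer suffixes of read k.
    """
    n, m = index.n, index.m
    lengths = np.zeros(n, dtype=np.int32)
    # Current *positions*: start at the marker rows; codes[row k] is the
    # last character of read k.
    pos = np.arange(m, dtype=np.int64)
    step = 0
    while pos.size:
        alive = index.codes[pos] != 0
        pos = pos[alive]
        if not pos.size:
            break
        pos = index.lf_vec(pos)
        step += 1
        lengths[pos] = step
    return lengths


def _concat_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(s, s+c) for each (s, c) pair; vectorized."""
    counts = np.maximum(counts, 0)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    reps = np.repeat(starts, counts)
    excl = np.concatenate(([0], np.cumsum(counts)[:-1]))
    return reps + (np.arange(total, dtype=np.int64) - np.repeat(excl, counts))


def lcp_from_ebwt(index: EBWTIndex, lengths: np.ndarray | None = None) -> np.ndarray:
    """Full int32 LCP array induced from the eBWT only (no suffix access).

    Interval-queue BFS over pattern intervals (left-extensions by A,C,G,T):
    when the interval of a length-d pattern is first generated, the LCP at
    its right boundary is induced to d-1; rows whose suffix is exactly the
    pattern (length profile == d) occupy the head of the interval and force
    interior LCP values of d.  An interval is explored further only if it
    induced at least one new value.
    """
    n, m = index.n, index.m
    occ, C = index.occ, index.C
    lcp = np.full(n, -1, dtype=np.int32)
    # Every boundary at or before the block of end-marker rows is 0:
    # distinct markers never match, and the marker block starts the axis.
    lcp[: min(m + 1, n)] = 0

    if lengths is None:
        lengths = suffix_lengths(index)
    order = np.argsort(lengths, kind="stable")
    sorted_lens = lengths[order]
    # rows_with_len(d) == rows_by_len[searchsorted bounds], rows ascending.
    def rows_with_len(d: int) -> np.ndarray:
        a = np.searchsorted(sorted_lens, d, side="left")
        b = np.searchsorted(sorted_lens, d, side="right")
        return np.sort(order[a:b])

    los = np.array([0], dtype=np.int64)
    his = np.array([n], dtype=np.int64)
    depth = 0
    while los.size:
        depth += 1
        exact_rows = rows_with_len(depth)
        next_los: list[np.ndarray] = []
        next_his: list[np.ndarray] = []
        for c in range(1, SIGMA):
            lo2 = C[c] + occ[los, c]
            hi2 = C[c] + occ[his, c]
            nonempty = lo2 < hi2
            lo2, hi2 = lo2[nonempty], hi2[nonempty]
            if not lo2.size:
                continue
            # Right-boundary rule: lcp[hi] = depth - 1 if still unset.
            inb = hi2 < n
            ends = hi2[inb]
            fresh_end = lcp[ends] < 0
            lcp[ends[fresh_end]] = depth - 1
            end_new = np.zeros(len(lo2), dtype=bool)
            end_new[np.flatnonzero(inb)[fresh_end]] = True
            # Interior rule: suffixes equal to the pattern head the
            # interval; boundaries between them (and to the first longer
            # suffix) carry lcp == depth.
            t = (np.searchsorted(exact_rows, hi2) -
                 np.searchsorted(exact_rows, lo2))
            starts = lo2 + 1
            stops = np.minimum(lo2 + t, hi2 - 1) + 1
            interior = _concat_ranges(starts, stops - starts)
            if interior.size:
                lcp[interior] = depth
            keep = end_new | (stops - starts > 0)
            next_los.append(lo2[keep])
            next_his.append(hi2[keep])
        los = np.concatenate(next_los) if next_los else np.empty(0, np.int64)
        his = np.concatenate(next_his) if next_his else np.empty(0, np.int64)

    if np.any(lcp < 0):
        raise AssertionError("LCP induction left unset entries")
    return lcp


def bitvectors_from_lcp(lcp: np.ndarray, k_min: int, k_right: int,
                        lengths: np.ndarray | None = None) -> LCPBitvectors:
    """Threshold/local-minimum bitvectors from an explicit LCP array.

    Shared by the production path and the brute-force testing mode.

    A local minimum is a *valley* of the LCP profile: the last entry of a
    maximal constant run that is entered by a strict descent and left by a
    strict ascent (the strict pattern lcp[i-1] > lcp[i] < lcp[i+1] is the
    run-length-one case).  Demanding only a non-strict descent would also
    fire inside monotonically ascending stretches whenever two adjacent
    entries are equal — which happens at every pair of reads ending at the
    same text position and would split a cluster between rows that no
    context can separate.
    ``lengths`` is the per-row suffix base-length profile; when given, a
    boundary between two suffixes that are identical up to their distinct
    end-markers (lcp equal to both suffix lengths) is additionally exempt:
    identical suffixes share every context.
    """
    lcp = np.asarray(lcp)
    n = len(lcp)
    K_min = lcp >= k_min
    K_right = lcp >= k_right
    localMin = np.zeros(n, dtype=bool)
    if n >= 3:
        change = np.empty(n, dtype=bool)
        change[0] = True
        change[1:] = lcp[1:] != lcp[:-1]
        idx = np.arange(n)
        run_start = np.maximum.accumulate(np.where(change, idx, 0))
        ascent = np.zeros(n, dtype=bool)
        ascent[:-1] = lcp[:-1] < lcp[1:]
        descent = np.zeros(n, dtype=bool)
        inner = run_start >= 1
        descent[inner] = lcp[run_start[inner] - 1] > lcp[inner]
        localMin = ascent & descent
        localMin[0] = localMin[n - 1] = False
        if lengths is not None:
            identical = np.zeros(n, dtype=bool)
            identical[1:] = (lcp[1:] == lengths[1:]) & (lengths[1:] == lengths[:-1])
            localMin &= ~identical
    return LCPBitvectors(K_min=K_min, localMin=localMin, K_right=K_right,
                         k_min=k_min, k_right=k_right)


def lcp_bitvectors_from_ebwt(index: EBWTIndex, k_min: int, k_right: int) -> LCPBitvectors:
    """K_min, localMin and K_right computed from the eBWT alone."""
    if k_min <= 0 or k_right <= 0:
        raise ValueError("thresholds must be positive")
    lengths = suffix_lengths(index)
    return bitvectors_from_lcp(lcp_from_ebwt(index, lengths), k_min, k_right,
                               lengths=lengths)


def lcp_bitvectors_brute(collection: SequenceCollection, k_min: int,
                         k_right: int) -> LCPBitvectors:
    """Brute-force derivation from the collection; testing oracle only."""
    suffixes = _sorted_suffixes(collection)
    lengths = np.array([len(s) for s, _, _ in suffixes], dtype=np.int32)
    return bitvectors_from_lcp(lcp_brute(collection).values, k_min, k_right,
                               lengths=lengths)
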