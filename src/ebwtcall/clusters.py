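"""Positional clustering: the maximal eBWT intervals eligible for calling.

A positional cluster is a maximal interval of the sorted-suffix axis whose
suffixes all share a right-context of at least ``k_min`` characters and
whose internal LCP profile contains no local minimum.  Its eBWT symbols are
the sequenced copies of (the position preceding) one genome position; a
cluster holding two well-covered distinct bases is the signature of a
variant.

The LCP entry at boundary r couples rows r-1 and r, so the conditions are
imposed strictly *inside* an interval: constraining the entry at the left
edge would couple the cluster with its left neighbour and wrongly merge
adjacent clusters.  The quadratic LCP-scan oracle in the test-suite pins
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .ebwt import ALPHABET, BASES, EBWTIndex, SAInterval, SIGMA
from .lcp import LCPBitvectors


@dataclass
class Cluster:
    """A maximal eligible interval with its per-symbol composition.

    ``counts`` tallies the four bases; end-markers inside the interval are
    counted separately (``dollars``) and never treated as alleles.
    """

    interval: SAInterval
    counts: dict[str, int]
    dollars: int
    has_right_anchor: bool

    def __post_init__(self) -> None:
        if self.interval.is_empty:
            raise ValueError("cluster interval must be non-empty")
        total = sum(self.counts.values()) + self.dollars
        if total != len(self.interval):
            raise ValueError("cluster counts do not sum to interval size")


def cluster_intervals(bv: LCPBitvectors) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized cluster boundaries: parallel arrays (los, his), half-open.

    An LCP boundary r (coupling rows r-1, r) is *good* when K_min[r] and
    not localMin[r]; clusters are maximal runs of rows connected by good
    boundaries, hence always of size >= 2.
    """
    n = bv.n
    if n < 2:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    # Boundary axis r = 1..n-1; arr[i] describes boundary r = i+1.
    arr = (bv.K_min & ~bv.localMin)[1:]
    padded = np.concatenate(([False], arr, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)   # arr index of first good boundary
    ends = np.flatnonzero(d == -1)    # arr index one past last good boundary
    # A run of good boundaries r = s+1 .. e spans rows [s, e+1).
    los = starts.astype(np.int64)
    his = ends.astype(np.int64) + 1
    return los, his


def _cluster_at(index: EBWTIndex, bv: LCPBitvectors, lo: int, hi: int) -> Cluster:
    diff = index.occ[hi] - index.occ[lo]
    counts = {ALPHABET[c]: int(diff[c]) for c in range(1, SIGMA)}
    anchored = bool(np.any(bv.K_right[lo + 1:hi]))
    return Cluster(interval=SAInterval(int(lo), int(hi)), counts=counts,
                   dollars=int(diff[0]), has_right_anchor=anchored)


def find_clusters(bv: LCPBitvectors, index: EBWTIndex) -> Iterator[Cluster]:
    """Yield every positional cluster left-to-right.

    Clusters are disjoint, maximal, and of size >= 2.
    """
    los, his = cluster_intervals(bv)
    for lo, hi in zip(los, his):
        yield _cluster_at(index, bv, int(lo), int(hi))
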