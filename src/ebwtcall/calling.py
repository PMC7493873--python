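"""Turn positional clusters into SNP/INDEL calls.

For each cluster holding two distinct bases c1, c2 each covered at least
``min_cov`` times, the caller reconstructs, via backward search, the
consensus left-contexts L1 and L2 (most frequent string preceding each
allele, up to M = k_left + max_indel characters), extracts a shared right
context R of ``k_right`` characters through the FL mapping, and aligns L1
against L2 allowing at most one insertion/deletion — only at the right end
of the two strings, where the event is known to sit.  A gap-free optimum is
a SNP; a gap of length g <= max_indel is an INDEL of that length.
Alignments that need more than ``max_edits`` differences (the central event
included) are discarded: such clusters are left borders of long repeats,
not variants.

The two reported fragments L1·R and L2·R end with the identical right
context, so INDELs called from forward-strand reads are left-shifted (and
right-shifted from the reverse strand); downstream VCF normalization
reconciles the two representations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .clusters import Cluster, cluster_intervals, _cluster_at
from .ebwt import BASES, CODE, EBWTIndex, SAInterval
from .lcp import LCPBitvectors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the caller (flags follow the CLI).

    k_min    -- minimum shared context inside a cluster (-k)
    k_left   -- consensus left-context length (-L)
    k_right  -- reported right-context length (-R)
    max_indel-- largest callable INDEL (-g)
    min_cov  -- minimum per-allele coverage inside a cluster (-m)
    max_edits-- maximum differences in the optimal alignment, central
                SNP/INDEL included (-v)
    """

    k_min: int = 16
    k_left: int = 31
    k_right: int = 30
    max_indel: int = 10
    min_cov: int = 6
    max_edits: int = 2

    def __post_init__(self) -> None:
        for name in ("k_min", "k_left", "k_right", "max_indel", "min_cov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_edits < 1:
            raise ValueError("max_edits must be >= 1")

    @property
    def M(self) -> int:
        """Maximum consensus length."""
        return self.k_left + self.max_indel


@dataclass
class VariantCall:
    """A called event as a pair of fragments L1·R / L2·R.

    ``event_pos*`` is the 0-based offset of the event's last base in each
    fragment (the last character of the respective consensus); for an INDEL
    the fragment length difference equals ``event_len``.  ``kind`` is
    measured relative to allele 1, the more frequent one: INS means allele 2
    carries extra bases, DEL means it lacks them.
    """

    kind: str  # SNP | INS | DEL
    frag1: str
    frag2: str
    event_pos1: int
    event_pos2: int
    event_len: int
    cov1: int
    cov2: int
    edits: int
    anchored: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "INS", "DEL"):
            raise ValueError(f"bad kind {self.kind!r}")
        if self.frag1 == self.frag2:
            raise ValueError("fragments must differ")
        if self.kind == "SNP" and len(self.frag1) != len(self.frag2):
            raise ValueError("SNP fragments must have equal length")
        if self.kind != "SNP" and abs(len(self.frag1) - len(self.frag2)) != self.event_len:
            raise ValueError("INDEL length does not match fragments")

    @property
    def min_cov(self) -> int:
        return min(self.cov1, self.cov2)


def eligible_pairs(cluster: Cluster, params: CallerParams) -> list[tuple[str, str]]:
    """Unordered pairs of distinct bases each covered >= min_cov.

    Within a pair the first symbol is the more frequent one (lexicographic
    tie-break); pairs come in order of descending combined coverage.
    """
    covered = [b for b in BASES if cluster.counts.get(b, 0) >= params.min_cov]
    pairs = []
    for a, b in itertools.combinations(covered, 2):
        if cluster.counts[b] > cluster.counts[a]:
            a, b = b, a
        pairs.append((a, b))
    pairs.sort(key=lambda p: (-(cluster.counts[p[0]] + cluster.counts[p[1]]), p))
    return pairs


def consensus_left(index: EBWTIndex, cluster: Cluster, c: str, M: int) -> str:
    """Most frequent string (length <= M, ending in c) preceding allele c.

    Backward search: left-extend the cluster interval by c, then M-1 times
    by the most frequent base of the current interval (lexicographically
    smallest on ties).  Extension stops early when only end-markers remain.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if cluster.counts.get(c, 0) < 1:
        raise ValueError(f"symbol {c!r} does not occur in the cluster")
    iv = index.backward_extend(cluster.interval, c)
    out = [c]
    for _ in range(M - 1):
        if iv.is_empty:
            break
        counts = index.symbol_counts(iv)
        best, best_n = None, 0
        for b in BASES:  # lexicographic scan => smallest wins ties
            if counts[b] > best_n:
                best, best_n = b, counts[b]
        if best is None:  # only end-markers remain
            break
        iv = index.backward_extend(iv, best)
        out.append(best)
    return "".join(reversed(out))


def right_context_for_cluster(index: EBWTIndex, cluster: Cluster,
                              bv: LCPBitvectors, k_right: int) -> tuple[str, bool]:
    """Shared right context R of the cluster, and whether it is anchored.

    Anchored: some in-cluster boundary r has lcp[r] >= k_right; the
    k_right-prefix of the suffix at the smallest such r is returned.
    Otherwise the longest suffix-prefix available from any in-cluster
    boundary row is returned (truncated at k_right) and flagged short.
    """
    if k_right == 0:
        return "", True
    lo, hi = cluster.interval.lo, cluster.interval.hi
    for r in range(lo + 1, hi):
        if bv.K_right[r]:
            return index.extract_right_context(r, k_right), True
    best = ""
    for r in range(lo + 1, hi):
        ctx = index.extract_right_context(r, k_right)
        if len(ctx) > len(best):
            best = ctx
    return best, False


def align_right_anchored(L1: str, L2: str, max_indel: int) -> tuple[int, int | None, int]:
    """Optimal right-anchored alignment of the two consensi.

    At most one gap, of length g in [0, max_indel], placed at the right end
    of one string (the event's known location); elsewhere only mismatches.
    Returns (gap, gapped, edits) where gapped in {1, 2, None} names the
    string whose last g characters are unmatched and
    edits = mismatches-in-overlap + (1 if gap else 0).  Ties prefer smaller
    g, then gapping the longer string.
    """
    if not L1 or not L2:
        raise ValueError("consensi must be non-empty")

    def mismatches(a: str, b: str) -> int:
        k = min(len(a), len(b))
        return sum(x != y for x, y in zip(a[-k:], b[-k:])) if k else 0

    best: tuple[int, int | None, int] | None = None
    candidates: list[tuple[int, int | None]] = [(0, None)]
    order = (1, 2) if len(L1) >= len(L2) else (2, 1)
    for g in range(1, max_indel + 1):
        for who in order:
            candidates.append((g, who))
    for g, who in candidates:
        if who == 1:
            if len(L1) <= g:
                continue
            a, b = L1[:len(L1) - g], L2
        elif who == 2:
            if len(L2) <= g:
                continue
            a, b = L1, L2[:len(L2) - g]
        else:
            a, b = L1, L2
        edits = mismatches(a, b) + (1 if g else 0)
        if best is None or edits < best[2]:
            best = (g, who, edits)
    assert best is not None
    return best


def call_cluster(index: EBWTIndex, cluster: Cluster, bv: LCPBitvectors,
                 params: CallerParams) -> list[VariantCall]:
    """All calls emitted by one cluster (one per eligible allele pair)."""
    pairs = eligible_pairs(cluster, params)
    if not pairs:
        return []
    R, anchored = right_context_for_cluster(index, cluster, bv, params.k_right)
    calls: list[VariantCall] = []
    for c1, c2 in pairs:
        L1 = consensus_left(index, cluster, c1, params.M)
        L2 = consensus_left(index, cluster, c2, params.M)
        gap, gapped, edits = align_right_anchored(L1, L2, params.max_indel)
        if edits > params.max_edits:
            continue
        # Keep only the aligned region: any leading excess of the longer
        # consensus was never compared and is unsupported.
        if gapped == 1:
            ov = min(len(L1) - gap, len(L2))
            L1, L2 = L1[len(L1) - ov - gap:], L2[len(L2) - ov:]
        elif gapped == 2:
            ov = min(len(L1), len(L2) - gap)
            L1, L2 = L1[len(L1) - ov:], L2[len(L2) - ov - gap:]
        else:
            ov = min(len(L1), len(L2))
            L1, L2 = L1[-ov:], L2[-ov:]
        frag1, frag2 = L1 + R, L2 + R
        if gap == 0:
            kind = "SNP"
        else:
            kind = "INS" if len(frag2) > len(frag1) else "DEL"
        calls.append(VariantCall(
            kind=kind, frag1=frag1, frag2=frag2,
            event_pos1=len(L1) - 1, event_pos2=len(L2) - 1,
            event_len=1 if gap == 0 else gap,
            cov1=cluster.counts[c1], cov2=cluster.counts[c2],
            edits=edits, anchored=anchored,
        ))
    return calls


def call_all(index: EBWTIndex, bv: LCPBitvectors, params: CallerParams,
             ) -> tuple[list[VariantCall], dict[str, int]]:
    """Run the caller over every cluster; returns (calls, summary stats).

    Cluster eligibility (two bases covered >= min_cov) is pre-screened with
    vectorized rank arithmetic so only candidate clusters are materialized.
    """
    los, his = cluster_intervals(bv)
    stats = {"clusters": int(len(los)), "clusters_called": 0,
             "SNP": 0, "INS": 0, "DEL": 0}
    if len(los) == 0:
        return [], stats
    base_counts = (index.occ[his, 1:] - index.occ[los, 1:]).astype(np.int64)
    candidate = (base_counts >= params.min_cov).sum(axis=1) >= 2
    calls: list[VariantCall] = []
    for lo, hi in zip(los[candidate], his[candidate]):
        cluster = _cluster_at(index, bv, int(lo), int(hi))
        emitted = call_cluster(index, cluster, bv, params)
        if emitted:
            stats["clusters_called"] += 1
        for call in emitted:
            stats[call.kind] += 1
        calls.extend(emitted)
    logger.info("clusters=%d called=%d SNP=%d INS=%d DEL=%d",
                stats["clusters"], stats["clusters_called"],
                stats["SNP"], stats["INS"], stats["DEL"])
    return calls, stats
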