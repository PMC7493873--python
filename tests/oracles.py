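"""Independent brute-force oracles used across the test suite.

Every oracle here recomputes a quantity from first principles (direct
suffix sorting, naive substring counting, exhaustive enumeration) and is
kept independent of the code paths it checks: no rank arrays, no interval
queues, no vectorized run-finding.
"""

from __future__ import annotations

import itertools

import numpy as np

from ebwtcall.ebwt import SequenceCollection
from ebwtcall.lcp import LCPBitvectors


def sorted_suffix_table(collection: SequenceCollection) -> list[tuple[str, int, int]]:
    """All suffixes as (text, read_idx, offset), sorted with the
    distinct-end-marker convention (prefix first, ties by read index)."""
    rows = []
    for idx, read in enumerate(collection.reads):
        for off in range(len(read) + 1):
            rows.append((read[off:], idx, off))
    rows.sort(key=lambda t: (t[0], t[1]))
    return rows


def brute_ebwt_string(collection: SequenceCollection) -> str:
    """eBWT by definition: predecessors of the sorted suffixes."""
    out = []
    for _, idx, off in sorted_suffix_table(collection):
        out.append("$" if off == 0 else collection.reads[idx][off - 1])
    return "".join(out)


def brute_lcp(collection: SequenceCollection) -> np.ndarray:
    rows = sorted_suffix_table(collection)
    lcp = np.zeros(len(rows), dtype=np.int64)
    for i in range(1, len(rows)):
        a, b = rows[i - 1][0], rows[i][0]
        k = 0
        while k < min(len(a), len(b)) and a[k] == b[k]:
            k += 1
        lcp[i] = k
    return lcp


def naive_pattern_interval_size(collection: SequenceCollection, pattern: str) -> int:
    """Number of suffixes (within reads) starting with ``pattern``."""
    count = 0
    for read in collection.reads:
        for off in range(len(read)):
            if read[off:off + len(pattern)] == pattern and off + len(pattern) <= len(read):
                count += 1
    return count


def brute_clusters(collection: SequenceCollection, bv: LCPBitvectors,
                   ) -> list[tuple[int, int]]:
    """Quadratic scan over all intervals of the (oracle-derived) boundary
    predicate: an interval [i, j) of size >= 2 is a cluster iff every
    boundary r in (i, j) is good and neither extension keeps that true."""
    n = bv.n
    good = [bool(bv.K_min[r] and not bv.localMin[r]) for r in range(n)]

    def is_candidate(i: int, j: int) -> bool:
        return j - i >= 2 and all(good[r] for r in range(i + 1, j))

    found = []
    for i in range(n):
        for j in range(i + 2, n + 1):
            if not is_candidate(i, j):
                continue
            left_ext = i > 0 and is_candidate(i - 1, j)
            right_ext = j < n and is_candidate(i, j + 1)
            if not left_ext and not right_ext:
                found.append((i, j))
    return found


def brute_right_anchored(L1: str, L2: str, max_indel: int) -> tuple[int, int | None, int]:
    """Restricted edit alignment by exhaustive configuration enumeration,
    written independently of the production scorer (explicit index loops)."""
    best = None
    for g in range(0, max_indel + 1):
        whos: tuple[int | None, ...]
        if g == 0:
            whos = (None,)
        elif len(L1) >= len(L2):
            whos = (1, 2)
        else:
            whos = (2, 1)
        for who in whos:
            if who == 1:
                a, b = L1[: len(L1) - g], L2
            elif who == 2:
                a, b = L1, L2[: len(L2) - g]
            else:
                a, b = L1, L2
            if not a or not b:
                continue
            ov = min(len(a), len(b))
            mism = 0
            for k in range(1, ov + 1):
                if a[len(a) - k] != b[len(b) - k]:
                    mism += 1
            edits = mism + (1 if g > 0 else 0)
            if best is None or edits < best[2]:
                best = (g, who, edits)
    return best


def all_collections(alphabet: str, max_total: int):
    """Every collection over ``alphabet`` with total base length <= max_total."""
    for n in range(1, max_total + 1):
        for cuts in range(2 ** (n - 1)):
            lens, cur = [], 1
            for i in range(n - 1):
                if cuts >> i & 1:
                    lens.append(cur)
                    cur = 1
                else:
                    cur += 1
            lens.append(cur)
            for seq in itertools.product(alphabet, repeat=n):
                s = "".join(seq)
                reads, off = [], 0
                for ln in lens:
                    reads.append(s[off:off + ln])
                    off += ln
                yield reads


def random_collection(rng: np.random.Generator, max_reads: int = 30,
                      max_len: int = 60, min_reads: int = 1,
                      min_len: int = 1) -> SequenceCollection:
    m = int(rng.integers(min_reads, max_reads + 1))
    reads = ["".join(rng.choice(list("ACGT"), int(rng.integers(min_len, max_len + 1))))
             for _ in range(m)]
    return SequenceCollection(reads)
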