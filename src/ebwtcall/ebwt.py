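"""Extended Burrows-Wheeler transform of a read collection.

The extended BWT (eBWT) generalizes the BWT to a collection of strings
``R_1 .. R_m``: each read is logically terminated by a *distinct* end-marker
``$_1 < $_2 < ... < $_m``, all smaller than any base, the suffixes of all
reads are sorted lexicographically, and the characters preceding them are
concatenated.  The transform is reversible and supports the FM-index
primitives (rank, LF, FL/Psi, backward search) that the downstream cluster
detection and consensus construction rely on.

End-markers are stored as a single ``$`` symbol; their formal distinctness
is realized by breaking ties between suffixes that are equal up to their
end-markers by read index.  This matches the order ``$_1 < ... < $_m``
without enlarging the alphabet.

Intervals over the sorted-suffix axis are 0-based and half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

logger = logging.getLogger(__name__)

#: Alphabet in sorted order; integer codes are indices into this string.
ALPHABET = "$ACGT"
BASES = "ACGT"
CODE = {c: i for i, c in enumerate(ALPHABET)}
SIGMA = len(ALPHABET)

_INDEX_FORMAT_VERSION = 1

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over ACGT."""
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedIndexError(ValueError):
    """Raised when an EBWTIndex fails its structural invariants."""


@dataclass
class SequenceCollection:
    """An ordered collection of reads over {A,C,G,T}.

    Each read is logically terminated by a distinct end-marker; ``n`` counts
    one marker per read on top of the base content.
    """

    reads: list[str]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("empty collection")
        for i, r in enumerate(self.reads):
            if not r:
                raise ValueError(f"read {i} is empty")
            if set(r) - set(BASES):
                bad = sorted(set(r) - set(BASES))
                raise ValueError(f"read {i} contains illegal symbols {bad}")

    @property
    def m(self) -> int:
        return len(self.reads)

    @property
    def n(self) -> int:
        return sum(len(r) for r in self.reads) + self.m

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SequenceCollection) and self.reads == other.reads

    def __len__(self) -> int:
        return self.m


def read_fasta_collection(path: str | Path) -> SequenceCollection:
    """Load reads from a (multi-line) FASTA file.

    Sequences are case-folded to upper case.  Reads containing ``N`` are
    dropped (with a logged count); any other non-ACGT symbol is an error.
    """
    from Bio import SeqIO

    reads: list[str] = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "N" in seq:
            dropped += 1
            continue
        reads.append(seq)
    if dropped:
        logger.info("dropped %d reads containing N", dropped)
    if not reads:
        raise ValueError(f"no usable reads in {path}")
    return SequenceCollection(reads)


def write_fasta(reads: list[str] | SequenceCollection, path: str | Path,
                prefix: str = "read") -> None:
    """Write plain (single-line records) FASTA."""
    seqs = reads.reads if isinstance(reads, SequenceCollection) else reads
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f">{prefix}{i}\n{seq}\n")


@dataclass(frozen=True)
class SAInterval:
    """Half-open interval [lo, hi) over the sorted-suffix axis."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 0 <= self.lo <= self.hi:
            raise ValueError(f"invalid interval [{self.lo}, {self.hi})")

    def __len__(self) -> int:
        return self.hi - self.lo

    @property
    def is_empty(self) -> bool:
        return self.lo == self.hi


@dataclass
class EBWTIndex:
    """eBWT string with rank/select support, LF/FL mappings and backward search.

    ``codes`` holds the transform as integer codes into :data:`ALPHABET`.
    ``dollar_reads[j]`` is the read index owning the j-th ``$`` occurrence in
    eBWT order; it makes LF a true permutation at end-marker positions.
    """

    codes: np.ndarray
    dollar_reads: np.ndarray

    # Lazily-built support structures.
    _occ: np.ndarray | None = field(default=None, repr=False)
    _C: np.ndarray | None = field(default=None, repr=False)
    _positions: list[np.ndarray] | None = field(default=None, repr=False)
    _dollar_pos_by_read: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def m(self) -> int:
        return len(self.dollar_reads)

    @property
    def ebwt(self) -> str:
        """The transform as a string over '$ACGT'."""
        return "".join(ALPHABET[c] for c in self.codes)

    # -- rank / select support --------------------------------------------

    @property
    def occ(self) -> np.ndarray:
        """Cumulative symbol counts: occ[i, c] = # occurrences of c in codes[:i]."""
        if self._occ is None:
            onehot = np.zeros((self.n + 1, SIGMA), dtype=np.int32)
            np.add.at(onehot, (np.arange(1, self.n + 1), self.codes), 1)
            self._occ = np.cumsum(onehot, axis=0, dtype=np.int32)
        return self._occ

    @property
    def C(self) -> np.ndarray:
        """C[c] = number of suffixes starting with a symbol smaller than c."""
        if self._C is None:
            totals = np.bincount(self.codes, minlength=SIGMA)
            self._C = np.concatenate(([0], np.cumsum(totals))).astype(np.int64)
        return self._C

    @property
    def counts(self) -> dict[str, int]:
        """Per-symbol totals of the whole transform."""
        totals = np.bincount(self.codes, minlength=SIGMA)
        return {ALPHABET[c]: int(totals[c]) for c in range(SIGMA)}

    def rank(self, c: int, i: int) -> int:
        """Occurrences of symbol code ``c`` in codes[0:i]."""
        return int(self.occ[i, c])

    def _symbol_positions(self, c: int) -> np.ndarray:
        if self._positions is None:
            self._positions = [np.flatnonzero(self.codes == k) for k in range(SIGMA)]
        return self._positions[c]

    @property
    def dollar_pos_by_read(self) -> np.ndarray:
        """eBWT position of read k's end-marker."""
        if self._dollar_pos_by_read is None:
            pos = self._symbol_positions(0)
            inv = np.empty(self.m, dtype=np.int64)
            inv[self.dollar_reads] = pos
            self._dollar_pos_by_read = inv
        return self._dollar_pos_by_read

    # -- navigation --------------------------------------------------------

    def f_char(self, row: int) -> int:
        """Code of the first character of the row-th smallest suffix."""
        return int(np.searchsorted(self.C, row, side="right")) - 1

    def lf(self, i: int) -> int:
        """Map eBWT position i to the rank of suffix ebwt[i]·(suffix i)."""
        c = int(self.codes[i])
        if c == 0:
            return int(self.dollar_reads[self.rank(0, i)])
        return int(self.C[c]) + self.rank(c, i)

    def lf_vec(self, pos: np.ndarray) -> np.ndarray:
        """Vectorized LF restricted to positions holding base symbols."""
        c = self.codes[pos].astype(np.int64)
        if np.any(c == 0):
            raise ValueError("lf_vec does not accept end-marker positions")
        return self.C[c] + self.occ[pos, c]

    def fl(self, row: int) -> int:
        """Inverse of LF: step one character forward along the text."""
        c = self.f_char(row)
        if c == 0:
            return int(self.dollar_pos_by_read[row])
        return int(self._symbol_positions(c)[row - self.C[c]])

    def backward_extend(self, iv: SAInterval, c: str) -> SAInterval:
        """Interval of suffixes prefixed by ``c·p`` given the interval of ``p``.

        One backward-search step; O(1) rank operations.
        """
        code = CODE.get(c)
        if code is None or code == 0:
            raise ValueError(f"cannot extend with symbol {c!r}")
        lo = int(self.C[code]) + self.rank(code, iv.lo)
        hi = int(self.C[code]) + self.rank(code, iv.hi)
        return SAInterval(lo, hi)

    def full_interval(self) -> SAInterval:
        return SAInterval(0, self.n)

    def symbol_counts(self, iv: SAInterval) -> dict[str, int]:
        """Counts of each of $,A,C,G,T inside ebwt[lo:hi)."""
        diff = self.occ[iv.hi] - self.occ[iv.lo]
        return {ALPHABET[c]: int(diff[c]) for c in range(SIGMA)}

    def extract_right_context(self, r: int, k: int) -> str:
        """First min(k, distance-to-end-marker) characters of the r-th suffix.

        Walks the FL mapping; never includes an end-marker.
        """
        if not 0 <= r < self.n:
            raise ValueError(f"row {r} out of range")
        out: list[str] = []
        row = r
        for _ in range(k):
            c = self.f_char(row)
            if c == 0:
                break
            out.append(ALPHABET[c])
            row = self.fl(row)
        return "".join(out)

    # -- integrity ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise MalformedIndexError on failure."""
        m = self.m
        if m == 0 or self.n < 2 * m:
            raise MalformedIndexError("implausible n/m")
        if int(np.sum(self.codes == 0)) != m:
            raise MalformedIndexError("end-marker count does not match m")
        if sorted(self.dollar_reads.tolist()) != list(range(m)):
            raise MalformedIndexError("dollar_reads is not a permutation of reads")
        # LF must be a permutation of [0, n).
        lf_all = np.empty(self.n, dtype=np.int64)
        base_pos = np.flatnonzero(self.codes != 0)
        lf_all[base_pos] = self.lf_vec(base_pos)
        lf_all[self._symbol_positions(0)] = self.dollar_reads
        if len(np.unique(lf_all)) != self.n:
            raise MalformedIndexError("LF is not a permutation")

    # -- serialization -----------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Serialize as <prefix>.ebwt (single text line over $ACGT) plus
        <prefix>.meta.json (format version, n, m, end-marker read ids)."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".ebwt"), "w") as fh:
            fh.write(self.ebwt)
            fh.write("\n")
        meta = {
            "format_version": _INDEX_FORMAT_VERSION,
            "n": self.n,
            "m": self.m,
            "dollar_reads": self.dollar_reads.tolist(),
        }
        with open(prefix.with_suffix(".meta.json"), "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, prefix: str | Path) -> "EBWTIndex":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".ebwt")) as fh:
            text = fh.readline().strip()
        with open(prefix.with_suffix(".meta.json")) as fh:
            meta = json.load(fh)
        if meta.get("format_version") != _INDEX_FORMAT_VERSION:
            raise MalformedIndexError("unsupported index format version")
        codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.uint8)
        for ch, code in CODE.items():
            lut[ord(ch)] = code
        bad = set(text) - set(ALPHABET)
        if bad or len(text) != meta["n"]:
            raise MalformedIndexError("corrupt eBWT payload")
        index = cls(codes=lut[codes], dollar_reads=np.asarray(meta["dollar_reads"], dtype=np.int64))
        if index.m != meta["m"]:
            raise MalformedIndexError("metadata m does not match payload")
        return index


def _sorted_suffixes(collection: SequenceCollection) -> list[tuple[bytes, int, int]]:
    """All suffixes as (suffix, read_index, offset), lexicographically sorted.

    A suffix compares as its base content with the end-marker implicit: a
    proper prefix sorts first ($ < bases) and full ties break by read index
    ($_1 < ... < $_m).  The empty suffix of read i stands for the marker $_i.
    """
    items: list[tuple[bytes, int, int]] = []
    for idx, read in enumerate(collection.reads):
        rb = read.encode("ascii")
        for off in range(len(rb) + 1):
            items.append((rb[off:], idx, off))
    items.sort(key=lambda t: (t[0], t[1]))
    return items


def build_ebwt(collection: SequenceCollection) -> EBWTIndex:
    """Construct the eBWT of a read collection.

    ``ebwt[j]`` is the symbol preceding the j-th smallest suffix; the symbol
    preceding a read's first character is that read's end-marker.
    """
    suffixes = _sorted_suffixes(collection)
    n = len(suffixes)
    codes = np.empty(n, dtype=np.uint8)
    dollar_reads: list[int] = []
    for j, (_, idx, off) in enumerate(suffixes):
        if off == 0:
            codes[j] = 0
            dollar_reads.append(idx)
        else:
            codes[j] = CODE[collection.reads[idx][off - 1]]
    return EBWTIndex(codes=codes, dollar_reads=np.asarray(dollar_reads, dtype=np.int64))


def invert_ebwt(index: EBWTIndex) -> SequenceCollection:
    """Reconstruct the original reads, in original order, from the eBWT.

    Read k is recovered by an LF-walk starting at row k (the row of marker
    $_k), collecting characters back-to-front.  All m walks advance in
    lockstep, one vectorized LF step per character.
    """
    index.validate()
    n, m = index.n, index.m
    rows = np.arange(m, dtype=np.int64)
    read_ids = np.arange(m, dtype=np.int64)
    rev_chars: list[list[str]] = [[] for _ in range(m)]
    steps = 0
    while rows.size:
        chars = index.codes[rows]
        alive = chars != 0
        for rid, c in zip(read_ids[alive], chars[alive]):
            rev_chars[rid].append(ALPHABET[c])
        rows, read_ids = rows[alive], read_ids[alive]
        if rows.size:
            rows = index.lf_vec(rows)
        steps += 1
        if steps > n:
            raise MalformedIndexError("LF walk did not terminate")
    reads = ["".join(reversed(ch)) for ch in rev_chars]
    return SequenceCollection(reads)
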