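"""Serialization and post-processing: call FASTA, coverage filter, SAM→VCF,
duplicate removal, reverse-complement augmentation, INDEL left-alignment.

The caller emits pairs of fragments; when a reference genome is available
the fragments can be aligned against it (with any aligner) and the
resulting SAM converted to VCF: every mismatch becomes a SNP record and
every I/D CIGAR event an INDEL record anchored on the preceding reference
base.  Because the method analyses the read set and its reverse complement,
the same variant is often called on both strands with opposite INDEL
shifts; left-normalization followed by coordinate sort + duplicate removal
collapses the two representations.

VCF dialect: minimal VCFv4.2, no genotype columns — the tool calls
variants, not genotypes.  All VCF coordinates are 1-based; everything
internal is 0-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .calling import VariantCall
from .ebwt import revcomp

logger = logging.getLogger(__name__)

#: Header grammar for call FASTA entries (two per call, allele index 1|2).
_HEADER_RE = re.compile(
    r">ID_(?P<id>\d+)_(?P<allele>[12])\|(?P<kind>SNP|INS|DEL)"
    r"\|pos:(?P<pos>\d+)\|len:(?P<len>\d+)\|cov:(?P<cov>\d+)"
    r"(?:\|edits:(?P<edits>\d+))?(?:\|anchored:(?P<anch>[01]))?$")


def augment_reverse_complement(reads: list[str]) -> list[str]:
    """Original reads followed by their reverse complements."""
    return list(reads) + [revcomp(r) for r in reads]


def write_calls(calls: Iterable[VariantCall], path: str | Path) -> None:
    """Serialize calls as FASTA: two entries per call.

    Header grammar (versioned with the package):
    ``>ID_<id>_<allele>|<kind>|pos:<p>|len:<g>|cov:<c>|edits:<e>|anchored:<0|1>``
    """
    with open(path, "w") as fh:
        for i, call in enumerate(calls):
            for allele in (1, 2):
                frag = call.frag1 if allele == 1 else call.frag2
                pos = call.event_pos1 if allele == 1 else call.event_pos2
                cov = call.cov1 if allele == 1 else call.cov2
                fh.write(f">ID_{i}_{allele}|{call.kind}|pos:{pos}|len:{call.event_len}"
                         f"|cov:{cov}|edits:{call.edits}|anchored:{int(call.anchored)}\n")
                fh.write(frag + "\n")


def read_calls(path: str | Path) -> list[VariantCall]:
    """Parse a call FASTA back into VariantCall objects (lossless)."""
    entries: dict[int, dict[int, tuple[dict, str]]] = {}
    header: dict | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                mo = _HEADER_RE.match(line)
                if mo is None:
                    raise ValueError(f"{path}:{lineno}: malformed call header {line!r}")
                header = {k: v for k, v in mo.groupdict().items()}
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence without header")
                cid, allele = int(header["id"]), int(header["allele"])
                entries.setdefault(cid, {})[allele] = (header, line)
                header = None
    calls = []
    for cid in sorted(entries):
        pair = entries[cid]
        if set(pair) != {1, 2}:
            raise ValueError(f"call {cid}: missing allele entry")
        (h1, f1), (h2, f2) = pair[1], pair[2]
        calls.append(VariantCall(
            kind=h1["kind"], frag1=f1, frag2=f2,
            event_pos1=int(h1["pos"]), event_pos2=int(h2["pos"]),
            event_len=int(h1["len"]), cov1=int(h1["cov"]), cov2=int(h2["cov"]),
            edits=int(h1["edits"] or 0),
            anchored=bool(int(h1["anch"] or 1)),
        ))
    return calls


def filter_by_coverage(calls: Iterable[VariantCall], threshold: int) -> list[VariantCall]:
    """Keep calls whose weaker allele is covered at least ``threshold`` times."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [c for c in calls if c.min_cov >= threshold]


# ---------------------------------------------------------------------------
# VCF records


@dataclass(frozen=True, order=True)
class VcfRecord:
    """One variant line: 1-based pos; INDELs share their first (anchor) base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: str = "."

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def to_line(self) -> str:
        return f"{self.chrom}\t{self.pos}\t.\t{self.ref}\t{self.alt}\t.\tPASS\t{self.info}"


def write_vcf(records: Iterable[VcfRecord], path: str | Path,
              contigs: Mapping[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ebwtcall\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_vcf(path: str | Path) -> list[VcfRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            records.append(VcfRecord(chrom=fields[0], pos=int(fields[1]),
                                     ref=fields[3], alt=fields[4],
                                     info=fields[7] if len(fields) > 7 else "."))
    return records


# ---------------------------------------------------------------------------
# Reference handling


def load_reference(reference: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Accept a FASTA path or an in-memory {contig: sequence} mapping."""
    if isinstance(reference, Mapping):
        return {k: v.upper() for k, v in reference.items()}
    from pyfaidx import Fasta

    fa = Fasta(str(reference))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


# ---------------------------------------------------------------------------
# SAM -> VCF


def sam_to_vcf(sam_path: str | Path,
               reference: str | Path | Mapping[str, str]) -> list[VcfRecord]:
    """Convert aligned call fragments to VCF records.

    Walks each alignment's CIGAR against the reference: one SNP record per
    mismatch, one INDEL record per I/D event anchored on the preceding
    reference base.  Unmapped, secondary and supplementary alignments are
    skipped, as are I/D events with no preceding aligned reference base.
    Mismatches are derived from CIGAR + reference lookup, independent of
    aligner tag conventions.
    """
    import pysam

    ref = load_reference(reference)
    records: list[VcfRecord] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            if chrom not in ref:
                raise ValueError(f"contig {chrom!r} missing from reference")
            refseq = ref[chrom]
            query = aln.query_sequence
            if query is None:
                continue
            qlen_cigar = sum(n for op, n in aln.cigartuples if op in (0, 1, 4, 7, 8))
            if qlen_cigar != len(query):
                raise ValueError(f"CIGAR/sequence length mismatch for {aln.query_name}")
            rpos = aln.reference_start  # 0-based
            qpos = 0
            for op, length in aln.cigartuples:
                if op in (0, 7, 8):  # M / = / X
                    for k in range(length):
                        rb = refseq[rpos + k]
                        qb = query[qpos + k]
                        if rb != qb:
                            records.append(VcfRecord(chrom, rpos + k + 1, rb, qb))
                    rpos += length
                    qpos += length
                elif op == 1:  # insertion to the reference
                    if rpos > 0:
                        anchor = refseq[rpos - 1]
                        records.append(VcfRecord(
                            chrom, rpos, anchor, anchor + query[qpos:qpos + length]))
                    qpos += length
                elif op == 2:  # deletion from the reference
                    if rpos > 0:
                        anchor = refseq[rpos - 1]
                        records.append(VcfRecord(
                            chrom, rpos, anchor + refseq[rpos:rpos + length], anchor))
                    rpos += length
                elif op == 4:  # soft clip
                    qpos += length
                elif op == 3:  # skipped region
                    rpos += length
                elif op == 5 or op == 6:  # hard clip / pad
                    continue
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
    return records


def dedup_vcf(records: Iterable[VcfRecord]) -> list[VcfRecord]:
    """Sort by (chrom, pos, ref, alt) and collapse exact duplicates."""
    return sorted(set(records))


# ---------------------------------------------------------------------------
# INDEL left-normalization


def normalize_record(record: VcfRecord, reference: Mapping[str, str]) -> VcfRecord:
    """Minimal left-aligned representation of a variant (vt-style fixpoint).

    Repeatedly trims a shared trailing base (re-anchoring on the reference
    base to the left when an allele would empty), then trims shared leading
    bases.  SNPs come back unchanged; the operation is idempotent.
    """
    refseq = reference[record.chrom]
    pos, ref, alt = record.pos, record.ref, record.alt
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= 1:
                    # cannot extend left of the contig; re-anchor and stop
                    base = refseq[pos - 1]
                    ref, alt = base + ref, base + alt
                    break
                pos -= 1
                base = refseq[pos - 1]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    return VcfRecord(record.chrom, pos, ref, alt, record.info)


def left_normalize_indel(record: VcfRecord,
                         reference: Mapping[str, str] | str | Path) -> VcfRecord:
    """Left-shift an INDEL record to its leftmost equivalent representation."""
    return normalize_record(record, load_reference(reference))


def normalize_all(records: Iterable[VcfRecord],
                  reference: Mapping[str, str]) -> list[VcfRecord]:
    return [normalize_record(r, reference) for r in records]
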