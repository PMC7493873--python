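"""Synthetic diploid benchmark: planted truth, read simulation, scoring.

Emulates, at desk scale, a heterozygous-variant discovery experiment: a
haploid genome is mutated into a second haplotype by applying one allele of
each planted variant (haplotype A is the reference itself, haplotype B
carries every alternate allele), 100-bp reads are drawn uniformly from both
haplotypes at a chosen total coverage, and uniform substitution errors are
layered on.  Calls are scored against the planted truth with an exact
(pos, ref, alt) match after left-normalization — stricter than
haplotype-resolution comparison engines, so reported sensitivity/precision
are conservative.

The default error model is substitution-only (no simulated indel errors),
a stand-in for a short-read substitution-dominated error profile.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import calling, clusters, ebwt, lcp, pipeline
from .pipeline import VcfRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class TruthSet:
    """A haploid genome plus planted heterozygous variants.

    ``variants`` are VCF-style records against the genome (haplotype A);
    applying all alternate alleles yields haplotype B.
    """

    genome: str
    variants: list[VcfRecord]
    contig: str = "ref"

    @property
    def hap_a(self) -> str:
        return self.genome

    @property
    def hap_b(self) -> str:
        out = []
        cursor = 0
        for v in sorted(self.variants, key=lambda r: r.pos):
            start = v.pos - 1
            if start < cursor:
                raise ValueError("overlapping variants")
            out.append(self.genome[cursor:start])
            out.append(v.alt)
            cursor = start + len(v.ref)
        out.append(self.genome[cursor:])
        return "".join(out)

    @property
    def snps(self) -> list[VcfRecord]:
        return [v for v in self.variants if v.is_snp]

    @property
    def indels(self) -> list[VcfRecord]:
        return [v for v in self.variants if not v.is_snp]

    def reference(self) -> dict[str, str]:
        return {self.contig: self.genome}


def generate_truth(length: int, snp_rate: float, indel_rate: float,
                   max_indel_len: int = 10, min_spacing: int = 150,
                   seed: int = 0) -> TruthSet:
    """Random genome with uniformly placed, spaced heterozygous variants.

    Counts are round(length*rate); variant positions are a uniform sample
    of spaced positions (every pair at least ``min_spacing`` apart); INDEL
    lengths are uniform on [1, max_indel_len] with insertion/deletion kinds
    equiprobable.
    """
    if snp_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    genome = "".join(rng.choice(_BASES, size=length))
    n_snp = round(length * snp_rate)
    n_indel = round(length * indel_rate)
    n_var = n_snp + n_indel
    if n_var == 0:
        return TruthSet(genome=genome, variants=[])
    # Uniform spaced placement: sample sorted positions in the shrunk space
    # then re-inflate.  Keep min_spacing clear of both contig ends so every
    # variant has full read-length context and deletions stay in range.
    lo, hi = min_spacing, length - min_spacing
    span = hi - lo - (n_var - 1) * min_spacing
    if span <= n_var:
        raise ValueError("variant density infeasible for min_spacing")
    base = np.sort(rng.choice(span, size=n_var, replace=False))
    positions = base + lo + np.arange(n_var) * min_spacing
    kinds = np.array(["SNP"] * n_snp + ["INDEL"] * n_indel)
    rng.shuffle(kinds)
    variants: list[VcfRecord] = []
    for pos0, kind in zip(positions, kinds):
        pos0 = int(pos0)
        if kind == "SNP":
            ref = genome[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(VcfRecord("ref", pos0 + 1, ref, alt))
        else:
            glen = int(rng.integers(1, max_indel_len + 1))
            anchor = genome[pos0]
            if rng.random() < 0.5:  # insertion
                ins = "".join(rng.choice(_BASES, size=glen))
                variants.append(VcfRecord("ref", pos0 + 1, anchor, anchor + ins))
            else:  # deletion
                variants.append(VcfRecord("ref", pos0 + 1,
                                          genome[pos0:pos0 + glen + 1], anchor))
    return TruthSet(genome=genome, variants=variants)


def simulate_reads(truth: TruthSet, read_len: int = 100, coverage: float = 30.0,
                   sub_error_rate: float = 0.001, seed: int = 0) -> list[str]:
    """Uniform reads from both haplotypes at the stated *total* coverage.

    Each base is flipped to a uniformly chosen different base with
    probability ``sub_error_rate``; no indel errors are simulated.
    """
    rng = np.random.default_rng(seed)
    haps = [truth.hap_a, truth.hap_b]
    if any(read_len > len(h) for h in haps):
        raise ValueError("read_len exceeds haplotype length")
    n_reads = int(round(coverage * len(truth.genome) / read_len))
    reads: list[str] = []
    for _ in range(n_reads):
        hap = haps[int(rng.integers(2))]
        start = int(rng.integers(len(hap) - read_len + 1))
        seq = hap[start:start + read_len]
        errs = np.flatnonzero(rng.random(read_len) < sub_error_rate)
        if errs.size:
            chars = list(seq)
            for e in errs:
                chars[e] = str(rng.choice([b for b in "ACGT" if b != chars[e]]))
            seq = "".join(chars)
        reads.append(seq)
    return reads


@dataclass
class EvalReport:
    """Sensitivity/precision/F1 over matched variant records."""

    tp: int
    fp: int
    fn: int
    precision_defined: bool = True

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0


def evaluate_calls(records: Iterable[VcfRecord], truth: Iterable[VcfRecord],
                   reference: Mapping[str, str], kind: str | None = None,
                   ) -> EvalReport:
    """Exact-allele matching after left-normalization of both sides.

    Call records are normalized and deduplicated first (forward/reverse
    strand double-calls collapse here); a call matches a truth variant iff
    (chrom, pos, ref, alt) agree.  ``kind`` restricts scoring to "SNP" or
    "INDEL" records (classified after normalization).
    """
    def keep(rec: VcfRecord) -> bool:
        if kind is None:
            return True
        return rec.is_snp if kind == "SNP" else not rec.is_snp

    call_set = {r for r in pipeline.normalize_all(records, reference) if keep(r)}
    truth_set = {r for r in pipeline.normalize_all(truth, reference) if keep(r)}
    tp = len(call_set & truth_set)
    fp = len(call_set - truth_set)
    fn = len(truth_set - call_set)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision_defined=bool(call_set))


# ---------------------------------------------------------------------------
# Fragment alignment (bwa-mem) and the end-to-end benchmark


def align_fragments(calls_fasta: str | Path, reference_fasta: str | Path,
                    out_sam: str | Path) -> Path:
    """Align call fragments against the reference with bwa-mem.

    The conversion step consumes SAM from any aligner; bwa-mem is the
    conventional choice for short fragments and is driven here through a
    subprocess (no Python bindings required).
    """
    if shutil.which("bwa") is None:
        raise RuntimeError("bwa not found on PATH; provide a SAM produced "
                           "by another aligner and call sam_to_vcf directly")
    reference_fasta = Path(reference_fasta)
    subprocess.run(["bwa", "index", str(reference_fasta)], check=True,
                   capture_output=True)
    with open(out_sam, "w") as fh:
        subprocess.run(["bwa", "mem", "-v", "1", str(reference_fasta),
                        str(calls_fasta)], check=True, stdout=fh,
                       stderr=subprocess.DEVNULL)
    return Path(out_sam)


@dataclass
class BenchmarkResult:
    """Per-kind reports at the selected coverage-filter threshold."""

    snp: EvalReport
    indel: EvalReport
    threshold: int
    sweep: dict[int, tuple[EvalReport, EvalReport]]
    n_calls: int
    stats: dict[str, int]


def run_benchmark(seed: int = 42, length: int = 100_000, snp_rate: float = 1e-3,
                  indel_rate: float = 5e-4, max_indel_len: int = 10,
                  min_spacing: int = 150, read_len: int = 100,
                  coverage: float = 30.0, sub_error_rate: float = 0.001,
                  params: calling.CallerParams | None = None,
                  thresholds: Sequence[int] = (3, 4, 5),
                  workdir: str | Path | None = None) -> BenchmarkResult:
    """Full pipeline on a synthetic diploid dataset, scored per kind.

    build eBWT (reads + reverse complements) -> LCP bitvectors -> clusters
    -> calls -> coverage-filter sweep -> bwa-mem -> SAM->VCF -> dedup ->
    evaluation; the reported threshold is the one maximizing the mean of
    the SNP and INDEL F1 scores.
    """
    params = params or calling.CallerParams()
    truth = generate_truth(length, snp_rate, indel_rate, max_indel_len,
                           min_spacing, seed=seed)
    reads = simulate_reads(truth, read_len, coverage, sub_error_rate,
                           seed=seed + 1)
    reads = pipeline.augment_reverse_complement(reads)
    collection = ebwt.SequenceCollection(reads)
    logger.info("building eBWT: m=%d n=%d", collection.m, collection.n)
    index = ebwt.build_ebwt(collection)
    bv = lcp.lcp_bitvectors_from_ebwt(index, params.k_min, params.k_right)
    calls, stats = calling.call_all(index, bv, params)
    reference = truth.reference()

    def score(filtered: list[calling.VariantCall], tmp: Path,
              tag: int) -> tuple[EvalReport, EvalReport]:
        calls_fa = tmp / f"calls_{tag}.fasta"
        pipeline.write_calls(filtered, calls_fa)
        sam = align_fragments(calls_fa, tmp / "ref.fasta", tmp / f"aln_{tag}.sam")
        records = pipeline.dedup_vcf(pipeline.sam_to_vcf(sam, reference))
        return (evaluate_calls(records, truth.variants, reference, kind="SNP"),
                evaluate_calls(records, truth.variants, reference, kind="INDEL"))

    own_tmp = tempfile.TemporaryDirectory() if workdir is None else None
    tmp = Path(own_tmp.name) if own_tmp else Path(workdir)
    tmp.mkdir(parents=True, exist_ok=True)
    try:
        with open(tmp / "ref.fasta", "w") as fh:
            fh.write(f">{truth.contig}\n{truth.genome}\n")
        sweep: dict[int, tuple[EvalReport, EvalReport]] = {}
        for thr in thresholds:
            filtered = pipeline.filter_by_coverage(calls, thr)
            sweep[thr] = score(filtered, tmp, thr)
        best = max(sweep, key=lambda t: (sweep[t][0].f1 + sweep[t][1].f1) / 2)
    finally:
        if own_tmp:
            own_tmp.cleanup()
    snp_rep, indel_rep = sweep[best]
    logger.info("threshold=%d SNP sens=%.3f prec=%.3f | INDEL sens=%.3f prec=%.3f",
                best, snp_rep.sensitivity, snp_rep.precision,
                indel_rep.sensitivity, indel_rep.precision)
    return BenchmarkResult(snp=snp_rep, indel=indel_rep, threshold=best,
                           sweep=sweep, n_calls=len(calls), stats=stats)
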