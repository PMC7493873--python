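# Methods

## Model

`ebwtcall` detects heterozygous SNPs and small INDELs in a collection of
sequencing reads without a reference and without alignment. The object it
works on is the extended Burrows-Wheeler transform (eBWT) of the reads:
every read is logically terminated by a distinct end-marker
(`$_1 < … < $_m`, all smaller than `A < C < G < T`), the suffixes of all
reads are sorted lexicographically, and the characters preceding them are
concatenated. Distinct markers are realized implicitly — a single `$`
symbol with ties between suffixes that are equal up to their markers
broken by read index — which reproduces the formal order without
enlarging the alphabet. All intervals over the sorted-suffix axis are
0-based and half-open.

The central observation: the symbols preceding all suffixes that share a
right-context `w` are contiguous in the eBWT. If `w` is long enough to
occur at a single genome locus, that run (*positional cluster*) contains
exactly the sequenced copies of the base preceding that locus, and a
heterozygous site appears as a cluster with two well-covered symbols.
Context length is data-driven (variable-order): it is whatever the LCP
structure supports at that locus, not a fixed k.

## From the eBWT to clusters

The cluster scan needs only three length-n bitvectors over LCP boundaries
(`lcp[i]` couples rows `i-1` and `i`; end-markers of distinct reads never
match):

* `K_min[i] = 1` iff `lcp[i] >= k_min`,
* `K_right[i] = 1` iff `lcp[i] >= k_right`,
* `localMin[i] = 1` iff boundary `i` is a local minimum of the LCP
  profile (below).

They are computed **from the eBWT alone** in two passes:

1. *Suffix-length profile.* The base length of every row's suffix is
   induced by m parallel LF-walks starting at the marker rows (one
   vectorized LF step per character; ~read-length steps in total).
2. *LCP induction.* A breadth-first interval-queue traversal of pattern
   intervals: starting from the interval of the empty pattern, every left
   extension by a base maps an interval to the interval of the extended
   pattern via rank arithmetic. When the interval of a length-d pattern is
   first produced, the LCP at its right boundary is d-1 (first-set wins —
   BFS order guarantees minimality); additionally, rows whose suffix
   *equals* the pattern (length profile = d) occupy the head of the
   interval, and the boundaries among them and to the first longer suffix
   carry LCP exactly d. The second rule is what string collections add
   over a single text: those positions are never the right boundary of
   any pattern interval and would otherwise stay unset. Intervals are
   explored further only if they set at least one new value, which bounds
   the work by O(n·σ). The traversal keeps a plain int32 LCP array
   internally; succinct-space variants of the same structures exist but
   are out of scope at desk scale, and the full array is never part of
   the public result — only the three bitvectors are.

The test-suite validates the traversal against a quadratic definitional
oracle (`lcp_brute`) exhaustively on small collections and on hundreds of
random ones.

### What counts as a local minimum

A local minimum is a **valley**: the last entry of a maximal constant run
of LCP values that is entered by a strict descent and left by a strict
ascent. The strict pattern `lcp[i-1] > lcp[i] < lcp[i+1]` is the
run-length-one case; flat-bottomed valleys split at the end of the flat
run. Two refinements matter in practice:

* A *non-strict* descent condition (`>=`) would also fire inside
  monotonically ascending stretches whenever two adjacent entries are
  equal. Inside a cluster the suffixes are prefixes of one underlying
  string, so their LCP profile ascends with the suffix lengths — and two
  reads ending at the same text position produce exactly such an equal
  adjacent pair. At realistic coverage this happens at nearly every
  cluster; treating it as a minimum would split clusters between rows
  that **no context can separate** (a cluster is by definition a set of
  suffixes sharing a context, and a prefix chain cannot be
  context-partitioned). Measured on the standard synthetic conditions,
  the non-strict reading drops SNP sensitivity from 98% to 45%.
* A boundary between two suffixes *identical up to their end-markers*
  (LCP equal to both suffix lengths) is never a split point, for the same
  reason.

Clusters are then the maximal runs of rows connected by boundaries with
`K_min = 1` and `localMin = 0`; the conditions apply strictly inside an
interval (constraining the left-edge entry would couple a cluster with
its neighbour), and only intervals of size ≥ 2 qualify. End-markers
inside a cluster are tallied but never treated as alleles.

## Calling

For every unordered pair of distinct bases `(c1, c2)` with in-cluster
counts ≥ `min_cov` (`c1` the more frequent; pairs in descending combined
coverage; multi-allelic clusters may yield several pairs):

* **Left consensus.** Backward search left-extends the cluster interval
  by `c_t`, then up to `M-1 = k_left + max_indel - 1` more times by the
  most frequent base of the current interval (lexicographically smallest
  on ties — a deterministic choice on which nothing downstream depends),
  stopping early when only end-markers remain. The result is the most
  frequent string preceding the allele, at most `M` characters, ending in
  `c_t`.
* **Right context.** If some in-cluster boundary has `K_right = 1`, the
  `k_right`-character prefix of the suffix at the smallest such boundary
  is read off via the FL mapping (any qualifying row is equivalent; the
  smallest is a determinism choice). Otherwise the longest available
  suffix-prefix in the cluster is used and the call is flagged
  un-anchored rather than dropped — short-context clusters keep their
  sensitivity and the flag travels with the call.
* **Right-anchored alignment.** `L1` and `L2` are aligned allowing at
  most one gap, of length `g ∈ [0, max_indel]`, at their right end only
  (the event's known location): right-align, leave the last `g`
  characters of the gapped string unmatched, count mismatches in the
  overlap; `edits = mismatches + (1 if g > 0)`, so the central SNP or
  INDEL always counts one. Ties prefer `g = 0` (parsimony: SNP over
  INDEL) and then gapping the longer string. If `edits > max_edits` the
  pair is discarded — clusters at the left border of long repeats have
  divergent left-contexts and are removed by exactly this filter.
* **Fragments.** The reported fragments are `L1·R` and `L2·R`, trimmed to
  the aligned region (a consensus that stopped early at read starts can
  leave leading excess on the other side that was never compared and is
  unsupported). SNP fragments therefore have equal length; INDEL
  fragments differ by exactly the gap. INDEL kind is measured relative to
  allele 1 (the more frequent): `INS` if allele 2 carries extra bases,
  `DEL` if it lacks them — with no reference there is no absolute
  ref/alt. Forward-strand INDEL calls come out left-shifted, reverse
  right-shifted; VCF normalization reconciles them.

## Parameters

| name        | default | flag | meaning                                                    |
|-------------|---------|------|------------------------------------------------------------|
| `k_min`     | 16      | `-k` | minimum context (bases) shared inside a cluster            |
| `k_left`    | 31      | `-L` | consensus left-context length                              |
| `k_right`   | 30      | `-R` | reported right-context length                              |
| `max_indel` | 10      | `-g` | largest callable INDEL (bases); also bounds consensus slack |
| `min_cov`   | 6       | `-m` | minimum per-allele coverage inside a cluster               |
| `max_edits` | 2       | `-v` | max alignment differences, central event included          |

Raising `min_cov` (or the post-hoc coverage filter, which keeps calls
whose weaker allele has ≥ t supporting reads) trades sensitivity for
precision monotonically.

## Synthetic benchmark

The benchmark emulates a heterozygous-variant discovery experiment at
desk scale. Its defaults are the study conditions used throughout:
a 100 kb uniform-random genome; `round(length × rate)` variants with
SNP rate 1e-3 and INDEL rate 5e-4 (≈100 SNPs, ≈50 INDELs), placed
uniformly with ≥ 150 bp spacing (isolated with respect to the 100 bp
reads) and kept 150 bp clear of the contig ends; INDEL lengths uniform on
[1, 10], insertions and deletions equiprobable; haplotype A is the genome,
haplotype B carries every alternate allele; 100 bp reads at 30x *total*
coverage drawn uniformly from the two haplotypes; substitution errors at
rate 0.1% (uniform across positions and target bases), no indel errors.
Reverse complements are appended before indexing — each variant then gets
two independent chances (forward and reverse context clusters) of being
called.

What this generator does **not** emulate, and what passing it therefore
does not show: the long repeat families, segmental duplications and GC
biases of real chromosomes (a uniform-random genome has almost no
repeated 16-mers at 100 kb, so the repeat-border filter is barely
exercised and accuracy here is an upper bound relative to real genomes);
position- and motif-dependent error profiles; indel sequencing errors;
non-uniform fragment sampling. Accuracy on real data should be expected
to be lower, mostly through repeat-induced precision loss.

Scoring is an exact `(chrom, pos, ref, alt)` match after both call and
truth records are left-normalized (vt-style fixpoint: trim shared
trailing base, re-anchor leftward when an allele empties, then trim
shared leading bases), with call records deduplicated first. This is
stricter than haplotype-resolution comparison engines: a call
representing the right variant in a different but equivalent composition
would count as a miss, so reported sensitivity/precision are
conservative. Fragment-to-reference alignment in the benchmark uses
`bwa mem` via subprocess; the SAM→VCF converter itself consumes SAM from
any aligner and derives mismatches from CIGAR plus reference lookup,
independent of aligner tag conventions.

The benchmark sweeps the coverage filter over {3, 4, 5} and reports the
threshold maximizing the mean of SNP and INDEL F1 — with the default
`min_cov = 6` at calling time the sweep is a no-op on these conditions,
but it is part of the protocol and stays.

## Numerical and degenerate-input choices

* Boundary conventions: `lcp[0] = 0`; `localMin` is 0 at positions 0 and
  n-1 (no out-of-range neighbour).
* `K_min` uses `>=` (the threshold is inclusive).
* Construction sorts plain `(suffix, read_index)` keys; at the package's
  target scale (≤ ~10 Mbp) this builds in well under a minute. The index
  serializes as a single text line over `$ACGT` plus a JSON sidecar
  (format version, n, m, and the read identity of each end-marker
  occurrence — the latter is required for a byte-exact round trip, since
  the single-`$` text alone does not determine which marker belongs to
  which read). Equal reads keep input order (affects eBWT byte identity
  only, never calls).
* Reads containing `N` are dropped at FASTA load (logged count); any
  other non-ACGT symbol is an error.
* Empty backward-search results are legal empty intervals; extending an
  empty interval stays empty.
* The consensus loop stops when only end-markers remain in the range;
  `$` is never a consensus symbol and never an allele.
* `sam_to_vcf` skips unmapped/secondary/supplementary alignments and I/D
  events with no preceding aligned reference base; a missing contig or a
  CIGAR/sequence length disagreement is an error.
* Precision over an empty call set is reported as 0 with
  `precision_defined = False`.

## Known limitations

* Single-process, plain-array implementation: memory is a small constant
  times n (about 1.5 GB at n ≈ 6 M including rank tables), far from the
  7-bits-per-base working space that succinct structures would give.
  Desk-scale datasets are the design point.
* Homozygous variants are invisible by construction (a cluster with one
  symbol is indistinguishable from a non-variant position); ploidy,
  genotype likelihoods and quality scores are out of scope.
* INDELs longer than `max_indel` and variants closer together than the
  consensus window interact and are not modelled.
* The caller emits fragment pairs, not genotypes; turning them into VCF
  requires a reference and an external aligner.
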