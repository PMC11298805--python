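# Methods

## Coordinates and formats

All intervals are 0-based half-open internally (the BED convention). VCF and
GFF3, which are 1-based inclusive on disk, are converted at the I/O boundary
and nowhere else. For structural-variant VCF records the END INFO key is
authoritative for the right breakpoint; records lacking END fall back to
POS + |SVLEN|, and records with neither are rejected and counted. We read
END from the raw INFO field (via cyvcf2) rather than from htslib's computed
record end, because htslib reconciles END and SVLEN under a different
convention for symbolic alleles and can shift the breakpoint by one base.
Chromosome names are taken verbatim; an optional rename map can be supplied
to the VCF reader. Strand is ignored for CNV intervals — they are
unstranded dosage events.

## Call filtering

A call is kept iff it is breakpoint-precise (no IMPRECISE flag), at least
50 bp long, and — when a supporting-read count is recorded — supported by
at least 4 reads. Calls with no support count pass the support rule:
depth-based callers do not emit one, and the rule targets read-evidence
callers. Rejections are tallied under the first failing rule in the fixed
order precise → length → support, so the tally partitions the rejected set.
All three thresholds are parameters with these defaults.

## CNVR merging

Merging is single-linkage over ≥ 1 bp interval overlap on the same
chromosome, with transitive chaining: connected components of the overlap
graph become CNVRs. This is the weakest reading of "merge overlapping
calls" and matches the classical CNVR construction of population CNV
surveys. Zero-length contact between half-open intervals (end == start) is
not overlap. A `min_reciprocal` option switches to requiring the overlap to
be at least that fraction of *both* call lengths (union-find over
sweep-bounded candidate pairs), for callers with sloppy breakpoints; the
default is 0 (off). Output is sorted by (chrom, start) and ids are assigned
positionally (CNVR_1…CNVR_n), so input order never affects the result.

Type classification: all-DUP members → `dup`, all-DEL → `del`, mixed →
`both`. Length ceilings are applied after classification: `del`/`both`
regions are kept up to and including 50 kb, `dup` regions strictly below
500 kb. The inclusive/exclusive asymmetry is deliberate and matches the
convention this rule set comes from; both ceilings are parameters.

Cross-caller consensus is handled by the same overlap merge (caller of
origin is retained on member calls); no separate consensus algorithm is
implemented.

## Gene annotation

Genes overlapping a CNVR by ≥ 1 bp are its primary annotation (`min_overlap`
exposes a stricter reading). With no overlapping gene, the nearest gene on
the chromosome is assigned, with ties broken toward the lower start
coordinate and then gene id, deterministically. Genes within 1 kb that hold
neither role are reported as proximal — the three roles are disjoint, so a
gene is never listed twice for one CNVR.

Genomic context uses the precedence exonic > intronic > other-genic >
upstream/downstream > intergenic. A CNVR touching any exon by ≥ 1 bp is
exonic; one inside a gene body without touching an exon is intronic (or
"other-genic" when the gene model carries no exon structure). The
up/downstream windows extend 1 kb beyond the gene span and are
strand-aware; the same 1 kb constant is used for the proximal-gene rule to
keep the rule set coherent.

Overrepresentation analysis is a one-sided hypergeometric test per gene set
(upper tail, P(X ≥ k)), with Benjamini–Hochberg adjustment across tested
terms; both raw and adjusted p-values are emitted. Gene sets are read from
GMT files; no curated ontology ships with the package.

## QTL overlap

QTL confidence intervals are equated with their published genomic spans.
Intervals with span ≥ 5 Mb are dropped (strict), as too wide to implicate a
specific CNVR; a CNVR–QTL pair qualifies when the intervals share strictly
more than 1 kb. Trait tallies count distinct CNVRs per trait string. The
module assumes CNVRs and QTLs are in compatible coordinates; no liftover is
performed.

## Copy-number matrix and Vst

Cell (r, s) of the matrix is the mean copy number of sample s's member
calls inside CNVR r; a call without an explicit copy number contributes a
type default (DEL → 1, DUP → 3). Samples with no call in a region are
imputed with the diploid baseline 2 rather than dropped: Vst for a CNVR is
defined across all individuals, and dropping non-carriers would inflate
within-population variance asymmetrically.

Vst = (Vt − Vs)/Vt with Vs the population-size-weighted mean of the two
within-population variances. All variances use denominator N (population
variance), applied consistently; this convention makes complete fixation
return exactly 1 and the identical-populations case exactly 0. Vst is
defined as 0 when Vt = 0. Negative raw values (possible when within-group
variance exceeds total variance) are clamped to 0; the raw value is
retained in the report. Each population must contribute at least 2 samples.

Candidate selection flags the ⌈0.10·n⌉ highest-Vst regions (ties broken by
cnvr_id for determinism) and, separately, regions with Vst strictly above
0.5. Percentile ranks use the nearest-rank method (rank = count of values
≤ x, percentile = 100·rank/n).

## Synthetic cohorts

The generator emulates a two-breed resequencing cohort at desk scale. Study
conditions (the defaults): 11 + 10 samples; 5 chromosomes of 10 Mb; 300
true CNVRs, non-overlapping by construction; type mix 58 % dup / 38 % del /
4 % both; log-normal lengths with mode 1.5 kb and σ = 0.25, clipped to
[200 bp, 45 kb], which places ~76 % of regions in the 1–2 kb band — the
length profile these surveys report; carrier frequency ~ Beta(2, 5);
20 regions planted at target Vst 0.8; 50 bp Gaussian breakpoint jitter; 5 %
call dropout. Copy numbers are integers in {0..4} (diploid baseline 2, DEL
carriers 0/1, DUP carriers 3/4), which makes analytic Vst targets exact.
A single integer seed drives one explicit numpy Generator; identical
configurations give byte-identical files.

Differentiated regions are calibrated by exhaustive enumeration over
(carriers in pop 1, carriers in pop 2, carrier copy number), picking the
configuration whose exact Vst — computed with plain two-pass arithmetic
independent of the `vst_divergence` module it later validates — is closest
to the target, preferring asymmetric configurations; the generator refuses
if nothing lands within ±0.05. Which population carries the shift is
randomized by calibrating with the group sizes in either order. "Both"-type
regions assign gains to some carriers and losses to others, reproducing the
duplication-deletion category mechanistically.

Every carrier emits one call per region unless dropped; jittered breakpoints
are truncated to the chromosome with a 50 bp minimum length. Annotation
fixtures are planted relative to the truth: a quarter of the gene budget
overlaps recorded regions, a quarter sits within (0, 1 kb], the rest is
placed > 2 kb from every region; the QTL set contains one interval fully
containing a region (> 1 kb overlap), one overlapping a region by < 1 kb,
and one wider than 5 Mb, all recorded in the ground truth so the QTL
module's boundary behavior is testable.

What the generator does **not** emulate: read-level noise, caller-specific
error profiles beyond jitter/dropout, overlapping true regions, genuinely
continuous copy-number estimates, linkage between regions, or realistic
gene density. Passing tests therefore demonstrate correctness of the
pipeline's logic and statistics under known truth, not caller performance
on real sequencing data.

## Problem sizes and determinism

The test and acceptance runs use the study-condition cohort (300 regions,
21 samples, ~1,800 calls), 100-fixture merge-oracle sweeps at ≤ 200
intervals, 1,000 random Vst matrices, and exhaustive enrichment enumeration
up to universe size 30; the full suite and the acceptance script each
complete in well under a minute. Ground-truth recovery is always scored by
coordinates (maximum overlap), never by positional ids, since jitter can
fuse adjacent regions and shift downstream ids. All randomness flows from
explicit seeds; pipeline outputs are byte-deterministic given identical
inputs, and the run manifest records config and content hashes for every
input and output so this can be checked.

## Known limitations

- The per-CNVR copy number of a multi-call sample is the unweighted mean of
  its member calls; no length weighting is applied.
- Vst has no attached significance test beyond the label-permutation
  property exercised in the suite.
- The CNVR BED round-trip preserves extents, types and carrier counts but
  not member calls, so stages needing the copy-number matrix re-merge from
  the call files.
- The enrichment test treats gene sets as unstructured; no ontology
  topology or term redundancy handling.
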