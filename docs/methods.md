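# Methods

## Coordinate conventions

Every interval in the package is 0-based half-open on a named chromosome
with an explicit strand, the BED convention. GFF3/GTF input (1-based
inclusive) is converted on read; BED is read and written natively. All
overlap tests are strand-aware unless documented otherwise: CLIP signal is
strand-specific, so a footprint never matches an annotation feature or a
background footprint on the opposite strand.

## Transcript models and 5′UTR extraction

A transcript is its ordered exons plus (for coding genes) CDS intervals;
explicit `five_prime_UTR`/`three_prime_UTR` features are used when present,
otherwise UTRs are derived from exon/CDS geometry: exonic bases 5′ of the
CDS span are 5′UTR, bases 3′ of it are 3′UTR, strand-aware. The CDS is
assumed to include the stop codon (the GFF3 convention), so the stop-codon
anchor is the first base of the CDS's final codon; the start anchor is the
5′-most CDS base in transcript orientation.

5′UTR records keep only UTRs of at least 10 nt (inclusive — "at least"
thresholds are inclusive throughout the package) and, by default, the
longest 5′UTR isoform per gene, with ties broken by lexicographically
smallest transcript id so output is deterministic. Sequences are spliced
(intron-free), reverse-complemented for − strand genes, and end immediately
before the ATG. An optional spliced-leader sequence can be stripped from
the 5′ end before length/GC computation; the record flags the removal.

GC content is (#G + #C)/length; characters outside A/C/G/T/U are rejected
by default (surfacing data problems early), with an N-tolerant mode that
counts N as non-GC. Positional GC uses 10-nt bins walking 5′-ward from the
ATG; the final (5′-most) bin may be partial and reports its true length, so
the length-weighted mean of the bins always equals the total GC (this
invariant is tested to 1e-12).

## Clusters, RPM, replicate agreement

Reads on one strand merge into a cluster when they overlap or lie within
`min_gap` bp (default 0, which also joins abutting reads); a cluster's
count is its number of constituent reads, and counts are conserved —
cluster counts always sum to the input read count. RPM is
count / total mapped reads × 10⁶. The merge stands in for an external
peak caller; pre-built cluster BED files (name = `sample:replicate`,
score = count) can be imported so real peak-caller output slots in
unchanged.

Replicate agreement is the Pearson correlation of log2(count + 1) over
clusters detected in both replicates, matched by ≥ 1 bp same-strand
overlap with overlapping groups unioned into a consensus interval. The +1
pseudocount avoids log 0; no transform is imposed on callers who want raw
counts, which remain on the cluster records.

## Footprint calling

The retention rule: a cluster is a footprint iff it is present (≥ 1 read)
in both replicates, and in at least one replicate carries at least
`min_reads` (default 20) reads together with at least `min_fc` (default
1.5) fold enrichment over INPUT. Enrichment is computed on RPM with a
pseudocount (default 1 RPM): `(clip + pc) / (input + pc)`, so zero-input
windows stay finite and equal signal gives exactly 1 for any pseudocount.
INPUT is always counted over the CLIP cluster's consensus interval rather
than over independently called input clusters, so numerator and denominator
share a window. A `threshold_scope="both_replicates"` mode requires the
count/enrichment condition in both replicates; the default
(`either_replicate`) requires it in one, with presence still required in
both.

Background subtraction removes any footprint overlapping (≥ 1 bp, same
strand) a footprint called in a control sample, and is idempotent and
anti-monotone in the background set. Footprint unions for target-gene
counting and WT-vs-mutant signal comparison also use strict ≥ 1 bp overlap
(abutting footprints stay distinct), and signal comparisons report
log2(RPM + pseudocount) with RPM 0 for a footprint absent from one sample.
Raising either threshold can only shrink the called set; a brute-force
filter that applies the rule sentence-literally, cluster by cluster, is
kept in the test suite as an independent oracle.

## Feature categories and metagene coverage

Categories follow the grouping used for this data: anything overlapping a
5′UTR *or* a CDS is "5′UTR proximal" (in these experiments CDS clusters sit
almost always within 200 nt of a 5′UTR), then 3′UTR, then intron, then
non-coding gene, then intergenic. Within the winning category the gene with
the largest overlapped base count is assigned, ties to the smaller gene id.

Metagene profiles accumulate each footprint's RPM at every
spliced-transcript base it covers within a window around the start or stop
codon of its gene's representative transcript — the same
longest-5′UTR-isoform choice used for UTR extraction, for cross-module
consistency. Offsets are transcript-space (introns excluded) and
strand-aware, so negative is always 5′ of the anchor. The default window
(−300, +300) nt covers the empirically interesting (−150, +200) span with
margin. Coverage is computed from footprint intervals, not from the
underlying reads; profile mass therefore equals Σ footprint RPM × covered
in-window offsets exactly, which the tests assert.

## UTR group statistics and trans-splicing

Length and GC comparisons use the two-sided Mann–Whitney U test: exact
enumeration when the combined sample is ≤ 25 without ties, otherwise the
normal approximation with tie and continuity correction
(`scipy.stats.mannwhitneyu`). Medians are the standard
midpoint-of-order-statistics median, and box-plot summaries report the
5/25/50/75/95 percentiles.

The trans-splice join counts a target gene as spliced iff it appears in the
supplied spliced-leader event table; genes absent from the table count as
not spliced (the table records annotated events). The percentage is
rounded to the nearest integer. Mature UTR lengths of the spliced targets
are returned for downstream median comparisons.

## Polysome quantification

Region areas use composite Simpson's rule on the uniformly sampled,
baseline-subtracted absorbance; with an odd number of intervals the final
interval is integrated by the trapezoid rule and added — standard, bounded
error, no resampling. Region boundaries are snapped to the nearest sample
point (logged). The baseline defaults to 0; optionally it is set to the
minimum absorbance in a user-named blank region, and post-subtraction
negative values are clipped at 0 so integration noise below baseline cannot
produce negative area. The P/M ratio is the polysome area divided by the
monosome (80S) area and requires a positive monosome area. Simpson is
exact for polynomials up to degree 3 on even-interval grids and recovers
Gaussian-peak areas to < 0.1% at a sampling step of σ/10, both asserted in
tests.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the pipeline targets:
target 5′UTRs with median 93 nt and 42% GC versus a background of 69 nt
and 39% GC, two replicates of four sample types (WT, C130Y point mutant,
ΔRRM deletion control, IgG no-transgene control) with CLIP and INPUT
libraries, 4-fold CLIP enrichment over an input mean of 15 reads per
cluster, and ~60% of genes trans-spliced.

Choices where the design was open:

- **UTR lengths** are log-normal (shape 0.6): positive, right-skewed,
  matching the qualitative shape of 5–95-percentile UTR-length box plots.
  GC is realized per-base Bernoulli at the gene's GC probability.
- **Counts** are negative-binomial (Poisson-gamma, size k = 10, so
  var = m + m²/k), the field default for overdispersed read counts. Each
  cluster site carries a log-normal expression factor (σ = 0.5, mean 1)
  shared by both replicates and all samples; this is what makes replicate
  counts correlate, as real libraries do, while leaving the expected
  CLIP/INPUT ratio at the configured enrichment.
- **Geometry**: one chromosome; each gene is an intergenic gap (200 nt),
  5′UTR, single-exon CDS (300 nt, ATG…TAA, no internal stops), 3′UTR
  (100 nt); strands alternate. Planted footprints span the 30 UTR nt
  immediately upstream of the ATG plus the first 20 CDS nt, i.e. the 5′UTR
  proximal zone. Nonspecific background clusters sit in the CDS interior of
  a configurable fraction of non-target genes and receive the same enriched
  CLIP signal in *every* sample, so the control samples call them and
  background subtraction removes them.
- **Determinism**: one global seed expands into independent substreams
  (genome, trans-splice assignment, counts) via `numpy.random.SeedSequence`
  spawning, so stages can be regenerated independently and identical seeds
  give byte-identical FASTA/GFF3 output.

Deliberately not modeled: raw FASTQ, UMIs and PCR duplication, alignment
and mappability artifacts, crosslink-site nucleotide bias, multi-isoform
genes, and introns (splice-aware code paths are exercised by hand-built
multi-exon fixtures in the tests instead). Passing recovery tests on this
generator therefore shows the calling logic is correct under a clean,
well-specified noise model — not that the thresholds are optimal for any
particular real library.

Problem sizes used in the shipped checks: recovery runs use 400-gene
genomes with 200 planted footprints over five seeds; UTR statistics use
150 targets versus 2000 background records; null-calibration uses 200
simulations of 60-vs-60 samples; oracle-equivalence fixtures use up to 100
clusters across 30 random configurations.

## Known limitations

- The footprint caller evaluates INPUT over CLIP-defined windows only;
  independently clustered INPUT is not implemented (import pre-built
  clusters if that is needed).
- Background subtraction supports any-overlap only at the CLI; reciprocal
  overlap fractions would need the library API.
- Gene assignment takes the single best-overlapping gene; footprints
  spanning two genes are not split.
- `join_trans_splice` trusts the supplied table; it does not validate SL
  sequences against the genome.
- Metagene coverage is footprint-interval based; read-level profiles within
  footprints are out of scope.
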