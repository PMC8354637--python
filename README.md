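# seclipkit

Tools for calling protein–RNA footprints from single-end enhanced CLIP
(seCLIP) experiments and analysing the 5′UTR features of the target mRNAs,
with a companion module for polysome-profile quantification.

The package was built around a neuron-type seCLIP study of the *C. elegans*
translation initiation factor EIF-3.G in cholinergic motor neurons, where
footprints of the RNA-binding protein concentrate within or near mRNA
5′UTRs and the target transcripts carry longer, GC-richer 5′ leaders than
the surrounding transcriptome. All of the operations are generic: they
apply to any CLIP-vs-INPUT design with two biological replicates, any
GFF3/GTF annotation, and any gradient absorbance trace.

## What it computes

**Footprint calling.** Mapped reads are merged into clusters per replicate;
a cluster becomes a *footprint* when it

1. appears (≥ 1 read) in **both** biological replicates (overlap-matched,
   consensus interval = union), and
2. in **at least one** replicate has ≥ 20 reads and ≥ 1.5-fold enrichment
   over the paired INPUT library, measured as
   `FC = (RPM_CLIP + pc) / (RPM_INPUT + pc)` over the cluster's own window
   (`RPM = count / library size × 10⁶`, pseudocount `pc = 1`).

Footprints also called in the no-transgene (IgG) or RNA-binding-deficient
(ΔRRM) control samples are background and are subtracted by ≥ 1 bp
same-strand overlap. Both thresholds are inclusive, and a stricter
"both replicates must pass" mode is available.

**Feature analysis.** Footprints overlapping a 5′UTR *or* CDS are grouped
into one "5′UTR proximal" category (precedence: 5′UTR proximal > 3′UTR >
intron > non-coding > intergenic); cumulative RPM coverage is profiled in
spliced-transcript coordinates around the start or stop codon. 5′UTRs
(≥ 10 nt, longest isoform per gene) are scored for length and total %GC
plus %GC in 10-nt bins walking 5′-ward from the ATG, and compared between
target and background gene sets with the two-sided Mann–Whitney U test.
Trans-splicing status is joined from a spliced-leader event table.

**Polysome profiles.** Region areas under gradient absorbance traces are
computed by composite Simpson's rule (trapezoid tail for an odd interval
count) and summarized as the polysome:monosome (P/M) area ratio.

**Synthetic data.** `seclipkit.simulate` generates a single-chromosome
genome with controllable 5′UTR length/GC distributions, plants footprints
in target genes, draws negative-binomial CLIP/INPUT counts with a shared
per-site expression factor, and builds sum-of-Gaussian absorbance traces
with closed-form region areas — so every stage of the pipeline can be
tested against known ground truth.

## Worked example

```python
from seclipkit import (SimulationConfig, simulate_genome, simulate_clip,
                       FootprintCallConfig, call_footprints, subtract_background,
                       annotate_footprints, category_proportions, metagene_coverage,
                       extract_five_prime_utrs, compare_utr_feature, join_trans_splice)

cfg = SimulationConfig(seed=42, n_genes=400, n_target_genes=150)
annotation, sequences, sl_table, truth = simulate_genome(cfg)
libraries = simulate_clip(annotation, truth, cfg)

def call(sample):
    return call_footprints(
        {r: libraries[(sample, "CLIP", r)] for r in (1, 2)},
        {r: libraries[(sample, "INPUT", r)] for r in (1, 2)},
        FootprintCallConfig(min_reads=20, min_fc=1.5),
    )

specific = subtract_background(call("WT"), [call("dRRM"), call("IgG")])
annotate_footprints(specific, annotation)
print(f"specific footprints: {len(specific)}")
print(category_proportions(specific).to_string(index=False))

profile = metagene_coverage(specific, annotation, anchor="start", window=(300, 300))
frac = profile.coverage[(profile.offsets >= -150) & (profile.offsets <= 200)].sum() \
       / profile.coverage.sum()
print(f"metagene mass in [-150, +200] of the ATG: {frac:.3f}")

utrs = extract_five_prime_utrs(annotation, sequences, min_len=10)
target_ids = {f.gene_id for f in specific}
targets = [u for u in utrs if u.gene_id in target_ids]
background = [u for u in utrs if u.gene_id not in target_ids]
for feature in ("length", "gc"):
    res = compare_utr_feature(targets, background, feature=feature)
    print(f"{feature}: target median {res.median_targets:.1f} vs background "
          f"{res.median_background:.1f}, p = {res.p_value:.2e}")

n_spliced, n_total, percent, _ = join_trans_splice(sorted(target_ids), sl_table)
print(f"trans-spliced targets: {n_spliced}/{n_total} ({percent}%)")
```

Output:

```
specific footprints: 148
           category  count  fraction
five_prime_proximal    148       1.0
    three_prime_utr      0       0.0
             intron      0       0.0
         non_coding      0       0.0
         intergenic      0       0.0
metagene mass in [-150, +200] of the ATG: 1.000
length: target median 92.0 vs background 67.5, p = 1.13e-05
gc: target median 41.5 vs background 38.8, p = 3.46e-05
trans-spliced targets: 89/148 (60%)
```

148 of the 150 planted target footprints survive calling and background
subtraction; all are 5′UTR proximal by construction (they straddle the
ATG), the metagene profile places all signal inside the biologically
expected window around the start codon, and the target 5′UTR population is
recovered as significantly longer and GC-enriched than the background.

A `seclipkit` console command exposes the same steps for shell pipelines
(`seclipkit simulate`, `utr-extract`, `clusters-build`, `clusters-corr`,
`footprints-call`, `footprints-subtract`, `annotate`, `metagene`,
`utr-compare`, `utr-transsplice`, `polysome-auc`); see `seclipkit --help`.

## Layout

- `seclipkit.intervals` / `seclipkit.genome` — interval arithmetic,
  GFF3/GTF transcript models, 5′UTR extraction, GC metrics
- `seclipkit.clusters` — read-cluster construction, RPM, replicate
  correlation, BED/TSV I/O
- `seclipkit.footprints` — the footprint retention rule, background
  subtraction, target-gene counting, WT-vs-mutant signal comparison
- `seclipkit.features` — feature categories and metagene coverage
- `seclipkit.utr_stats` — Mann–Whitney comparisons, trans-splice joins,
  percentile summaries
- `seclipkit.polysome` — Simpson areas and P/M ratios
- `seclipkit.simulate` — the synthetic-data generator
- `docs/methods.md` — the model, parameter choices, and limitations
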