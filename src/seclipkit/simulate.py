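"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates a two-replicate CLIP-vs-INPUT experiment across four
sample types (WT, C130Y, dRRM, IgG): a single-chromosome genome whose genes
carry 5'UTRs with controllable length/GC distributions, planted
5'UTR-proximal footprints in a target gene subset, negative-binomial read
counts with CLIP enrichment at planted sites, nonspecific background
clusters shared by all samples (the dRRM/IgG controls), and Gaussian-peak
polysome traces with closed-form region areas.

Default UTR population parameters (target median 93 nt / 42% GC, background
69 nt / 39% GC) match the neuronal study conditions the pipeline is designed
for; counts default to 4-fold CLIP enrichment over an input mean of 15 reads
per cluster.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import erf

from .genome import GenomeAnnotation, TranscriptModel, UTRRecord, gc_content
from .intervals import GenomicInterval
from .clusters import SampleLibrary
from .polysome import AbsorbanceTrace
from .utr_stats import TransSpliceTable

SAMPLES = ("WT", "C130Y", "dRRM", "IgG")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    seed: int = 0
    n_genes: int = 500
    n_target_genes: int = 150
    target_len_median: float = 93.0
    target_gc: float = 0.42
    background_len_median: float = 69.0
    background_gc: float = 0.39
    len_sigma: float = 0.6  # log-normal shape for UTR lengths
    cds_length: int = 300
    utr3_length: int = 100
    intergenic_gap: int = 200
    enrichment: float = 4.0
    input_mean: float = 15.0
    dispersion: float = 10.0  # NB size parameter k; var = m + m^2/k
    expression_sigma: float = 0.5  # per-site log-normal expression spread (mean 1)
    library_size: int = 1_000_000
    background_rate: float = 0.1
    frac_trans_spliced: float = 0.6
    read_length: int = 30
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_target_genes < 0:
            raise ValueError("gene counts must be >= 1 (targets >= 0)")
        if self.n_target_genes > self.n_genes:
            raise ValueError("n_target_genes cannot exceed n_genes")
        for p in (self.target_gc, self.background_gc, self.background_rate,
                  self.frac_trans_spliced):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.target_len_median <= 0 or self.background_len_median <= 0:
            raise ValueError("length medians must be > 0")


@dataclass
class GroundTruth:
    """What the generator planted, for recall/precision scoring."""

    target_genes: set[str]
    planted_footprints: dict[str, GenomicInterval]  # gene_id -> interval
    background_clusters: list[GenomicInterval]
    enrichment: float

    def to_json(self, path: str) -> None:
        payload = {
            "target_genes": sorted(self.target_genes),
            "enrichment": self.enrichment,
            "planted_footprints": {
                g: [iv.chrom, iv.start, iv.end, iv.strand]
                for g, iv in sorted(self.planted_footprints.items())
            },
            "background_clusters": [
                [iv.chrom, iv.start, iv.end, iv.strand] for iv in self.background_clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _substreams(seed: int, n: int = 4) -> list[np.random.Generator]:
    """One global seed expands into independent per-stage streams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _random_utr_length(rng: np.random.Generator, median: float, sigma: float,
                       min_len: int = 12) -> int:
    return max(min_len, int(round(rng.lognormal(mean=math.log(median), sigma=sigma))))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    """Per-base Bernoulli GC; G/C and A/T chosen with equal probability."""
    is_gc = rng.random(length) < gc
    half = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(half, "G", "C"), np.where(half, "A", "T"))
    return "".join(bases)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG ... stop(TAA); internal codons avoid in-frame stops by construction."""
    if length % 3 or length < 9:
        raise ValueError("cds_length must be a multiple of 3 and >= 9")
    n_internal = length // 3 - 2
    codons = ["ATG"]
    alphabet = "ACGT"
    for _ in range(n_internal):
        c = "".join(alphabet[i] for i in rng.integers(0, 4, size=3))
        if c in ("TAA", "TAG", "TGA"):
            c = "TGG"
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_utr_records(
    n: int,
    length_median: float,
    gc: float,
    rng: np.random.Generator,
    len_sigma: float = 0.6,
    min_len: int = 10,
    prefix: str = "g",
) -> list[UTRRecord]:
    """Stand-alone 5'UTR population with log-normal lengths and Bernoulli GC."""
    out = []
    for i in range(n):
        length = _random_utr_length(rng, length_median, len_sigma, min_len=min_len)
        seq = _random_seq(rng, length, gc)
        out.append(
            UTRRecord(
                gene_id=f"{prefix}{i:05d}",
                transcript_id=f"{prefix}{i:05d}.1",
                length=length,
                sequence=seq,
                gc_fraction=gc_content(seq),
            )
        )
    return out


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], TransSpliceTable, GroundTruth]:
    """Build a single-chromosome genome of single-exon genes.

    Each gene is laid out as intergenic gap, 5'UTR (sampled length/GC), CDS,
    3'UTR; strands alternate deterministically with gene index. The first
    ``n_target_genes`` genes draw UTRs from the target distribution and
    receive a planted footprint spanning the 30 nt of UTR immediately
    upstream of the ATG plus the first 20 nt of CDS. A configurable fraction
    of non-target genes carries a nonspecific background cluster in its CDS
    interior, present in every sample.
    """
    rng_genome, rng_ts, _, _ = _substreams(config.seed)
    import pandas as pd

    chrom_parts: list[str] = []
    pos = 0
    transcripts: dict[str, TranscriptModel] = {}
    genes: dict[str, list[str]] = {}
    truth = GroundTruth(
        target_genes=set(),
        planted_footprints={},
        background_clusters=[],
        enrichment=config.enrichment,
    )
    ts_rows = []

    for i in range(config.n_genes):
        gid = f"gene{i:05d}"
        tid = f"{gid}.1"
        is_target = i < config.n_target_genes
        strand = "+" if i % 2 == 0 else "-"
        if is_target:
            utr_len = _random_utr_length(rng_genome, config.target_len_median, config.len_sigma)
            utr_seq = _random_seq(rng_genome, utr_len, config.target_gc)
        else:
            utr_len = _random_utr_length(
                rng_genome, config.background_len_median, config.len_sigma
            )
            utr_seq = _random_seq(rng_genome, utr_len, config.background_gc)
        cds_seq = _random_cds(rng_genome, config.cds_length)
        utr3_seq = _random_seq(rng_genome, config.utr3_length, 0.35)
        tx_seq = utr_seq + cds_seq + utr3_seq

        gap = _random_seq(rng_genome, config.intergenic_gap, 0.35)
        chrom_parts.append(gap)
        pos += config.intergenic_gap
        g_start = pos
        g_end = g_start + len(tx_seq)
        if strand == "+":
            chrom_parts.append(tx_seq)
            utr5 = [GenomicInterval(config.chrom, g_start, g_start + utr_len, strand)]
            cds = [
                GenomicInterval(
                    config.chrom, g_start + utr_len, g_start + utr_len + config.cds_length, strand
                )
            ]
            utr3 = [GenomicInterval(config.chrom, g_end - config.utr3_length, g_end, strand)]
            start_codon = g_start + utr_len
            stop_codon = g_start + utr_len + config.cds_length - 3
        else:
            chrom_parts.append(_revcomp(tx_seq))
            utr5 = [GenomicInterval(config.chrom, g_end - utr_len, g_end, strand)]
            cds = [
                GenomicInterval(
                    config.chrom, g_end - utr_len - config.cds_length, g_end - utr_len, strand
                )
            ]
            utr3 = [GenomicInterval(config.chrom, g_start, g_start + config.utr3_length, strand)]
            start_codon = g_end - utr_len - 1
            stop_codon = g_end - utr_len - config.cds_length + 2
        pos = g_end
        exons = [GenomicInterval(config.chrom, g_start, g_end, strand)]
        transcripts[tid] = TranscriptModel(
            gene_id=gid,
            transcript_id=tid,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            start_codon_pos=start_codon,
            stop_codon_pos=stop_codon,
        )
        genes[gid] = [tid]

        if is_target:
            truth.target_genes.add(gid)
            up = min(30, utr_len)
            if strand == "+":
                fp = GenomicInterval(config.chrom, start_codon - up, start_codon + 20, strand)
            else:
                fp = GenomicInterval(config.chrom, start_codon - 19, start_codon + up + 1, strand)
            truth.planted_footprints[gid] = fp
        elif rng_genome.random() < config.background_rate:
            # nonspecific sticky site in the CDS interior, well away from the ATG zone
            c = cds[0]
            mid = (c.start + c.end) // 2
            truth.background_clusters.append(
                GenomicInterval(config.chrom, mid - 25, mid + 25, strand)
            )

        if rng_ts.random() < config.frac_trans_spliced:
            sl = "SL1" if rng_ts.random() < 0.8 else "SL2"
            ts_rows.append(
                {
                    "gene_id": gid,
                    "transcript_id": tid,
                    "sl_type": sl,
                    "utr_length": utr_len,
                }
            )

    sequences = {config.chrom: "".join(chrom_parts)}
    annotation = GenomeAnnotation(transcripts=transcripts, genes=genes)
    ts_table = TransSpliceTable(
        pd.DataFrame(ts_rows, columns=["gene_id", "transcript_id", "sl_type", "utr_length"])
    )
    return annotation, sequences, ts_table, truth


def _tile_reads(
    interval: GenomicInterval, count: int, read_length: int
) -> list[GenomicInterval]:
    """``count`` reads of fixed length tiling the cluster interval."""
    if count <= 0:
        return []
    L = min(read_length, len(interval))
    span = len(interval) - L
    out = []
    for i in range(count):
        off = (i * span) // max(count - 1, 1) if span > 0 else 0
        out.append(
            GenomicInterval(
                interval.chrom, interval.start + off, interval.start + off + L, interval.strand
            )
        )
    return out


def _nb(rng: np.random.Generator, mean: float, k: float) -> int:
    """Negative binomial (Poisson-gamma) with mean ``mean`` and size ``k``."""
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def simulate_clip(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[tuple[str, str, int], SampleLibrary]:
    """Read libraries for (WT, C130Y, dRRM, IgG) x (CLIP, INPUT) x 2 replicates.

    Planted footprints get CLIP counts with mean enrichment x input mean in
    the WT and C130Y samples only; background clusters get the same enriched
    CLIP signal in every sample (so the controls call them and they are
    subtracted); INPUT libraries carry the input mean everywhere.
    """
    _, _, rng_counts, _ = _substreams(config.seed)
    if config.enrichment <= 1.0:
        import warnings

        warnings.warn("enrichment <= 1: planted footprints will rarely be detectable")

    sites: list[tuple[GenomicInterval, bool]] = [
        (iv, True) for _, iv in sorted(truth.planted_footprints.items())
    ] + [(iv, False) for iv in truth.background_clusters]

    libs: dict[tuple[str, str, int], SampleLibrary] = {}
    reads: dict[tuple[str, str, int], list[GenomicInterval]] = {
        (s, a, r): [] for s in SAMPLES for a in ("CLIP", "INPUT") for r in (1, 2)
    }
    s2 = config.expression_sigma
    for iv, is_planted in sites:
        # per-site expression level (mean 1), shared by replicates and samples,
        # so replicate counts co-vary as real libraries do
        expr = float(rng_counts.lognormal(-(s2**2) / 2.0, s2)) if s2 > 0 else 1.0
        input_mean = config.input_mean * expr
        clip_mean = config.enrichment * input_mean
        for s in SAMPLES:
            specific = s in ("WT", "C130Y")
            for r in (1, 2):
                n_in = _nb(rng_counts, input_mean, config.dispersion)
                reads[(s, "INPUT", r)].extend(_tile_reads(iv, n_in, config.read_length))
                if is_planted:
                    n_clip = (
                        _nb(rng_counts, clip_mean, config.dispersion) if specific else 0
                    )
                else:
                    n_clip = _nb(rng_counts, clip_mean, config.dispersion)
                reads[(s, "CLIP", r)].extend(_tile_reads(iv, n_clip, config.read_length))

    for (s, a, r), rlist in reads.items():
        libs[(s, a, r)] = SampleLibrary(
            sample=f"{s}_{a}",
            replicate=r,
            total_mapped_reads=config.library_size,
            reads=rlist,
        )
    return libs


def simulate_polysome_trace(
    peaks: Sequence[tuple[float, float, float]],
    regions: Mapping[str, tuple[float, float]],
    baseline: float = 0.0,
    step: float = 0.05,
    span: tuple[float, float] = (0.0, 10.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[AbsorbanceTrace, dict[str, float]]:
    """Sum-of-Gaussians gradient trace plus each region's closed-form area.

    ``peaks`` are (center, amplitude, width sigma). The analytic area of a
    peak over [a, b] is A*sigma*sqrt(2*pi) * (Phi((b-c)/sigma) - Phi((a-c)/sigma)),
    accumulated per region and excluding baseline and noise.
    """
    if step <= 0:
        raise ValueError("sampling step must be > 0")
    lo, hi = span
    for c, _, w in peaks:
        if not (lo <= c <= hi) or w <= 0:
            raise ValueError("peak centers must lie within the span with width > 0")
    x = np.arange(lo, hi + step / 2, step)
    y = np.full_like(x, float(baseline))
    for c, a, w in peaks:
        y += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=len(x))
    trace = AbsorbanceTrace(positions=x, absorbance=y, regions=dict(regions), baseline=baseline)

    def _phi(z: float) -> float:
        return 0.5 * (1.0 + erf(z / math.sqrt(2.0)))

    analytic = {}
    for name, (a_, b_) in regions.items():
        area = 0.0
        for c, amp, w in peaks:
            area += amp * w * math.sqrt(2 * math.pi) * (_phi((b_ - c) / w) - _phi((a_ - c) / w))
        analytic[name] = area
    return trace, analytic


# ---------------------------------------------------------------------------
# Writers (the exact formats the pipeline reads)


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    """GFF3 with gene/mRNA/exon/CDS features (1-based inclusive on write).

    UTRs are deliberately left implicit so readers must derive them from the
    exon/CDS geometry, as with typical compact annotations.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(annotation.genes):
            for tid in sorted(annotation.genes[gid]):
                tx = annotation.transcripts[tid]
                g_start = tx.exons[0].start + 1
                g_end = tx.exons[-1].end
                s = tx.strand
                c = tx.chrom
                fh.write(f"{c}\tsim\tgene\t{g_start}\t{g_end}\t.\t{s}\t.\tID={gid}\n")
                fh.write(
                    f"{c}\tsim\tmRNA\t{g_start}\t{g_end}\t.\t{s}\t.\tID={tid};Parent={gid}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{c}\tsim\texon\t{ex.start + 1}\t{ex.end}\t.\t{s}\t.\tParent={tid}\n"
                    )
                for cd in tx.cds:
                    fh.write(
                        f"{c}\tsim\tCDS\t{cd.start + 1}\t{cd.end}\t.\t{s}\t0\tParent={tid}\n"
                    )


def write_reads_bed(libs: Mapping[tuple[str, str, int], SampleLibrary], path: str) -> None:
    """All libraries' reads as BED6, name = sample:replicate."""
    with open(path, "w") as fh:
        for key in sorted(libs):
            lib = libs[key]
            for r in lib.reads:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{lib.sample}:{lib.replicate}\t1\t{r.strand}\n"
                )
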