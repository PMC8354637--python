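"""Footprint calling: threshold filtering, replicate reproducibility, input
enrichment, and background subtraction.

A footprint is a CLIP read cluster detected in both biological replicates
that, in at least one replicate, carries at least ``min_reads`` reads and at
least ``min_fc`` fold enrichment over the paired INPUT library; footprints
also called in the IgG or deletion-control samples are background and are
subtracted. INPUT enrichment is always evaluated over the CLIP cluster's own
interval so numerator and denominator share a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals
from .clusters import (
    ClusterRecord,
    SampleLibrary,
    build_clusters,
    count_reads_in_interval,
    match_replicate_clusters,
    rpm,
)

logger = logging.getLogger(__name__)


@dataclass
class FootprintCallConfig:
    """Retention thresholds for footprint calling.

    ``threshold_scope`` selects whether the (min_reads AND min_fc) condition
    must hold in at least one replicate ("either_replicate", default) or in
    both ("both_replicates"); cluster presence in both replicates is required
    in either mode.
    """

    min_reads: int = 20
    min_fc: float = 1.5
    pseudocount: float = 1.0
    require_both_replicates: bool = True
    threshold_scope: str = "either_replicate"

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if self.min_fc <= 0:
            raise ValueError("min_fc must be > 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.threshold_scope not in {"either_replicate", "both_replicates"}:
            raise ValueError(f"unknown threshold_scope {self.threshold_scope!r}")


@dataclass
class Footprint:
    """A retained cluster with its per-replicate evidence."""

    interval: GenomicInterval
    sample: str
    clip_counts: dict[int, int]
    clip_rpm: dict[int, float]
    input_rpm: dict[int, float]
    fold_change: dict[int, float]
    passing_replicates: list[int]
    category: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def mean_rpm(self) -> float:
        return float(np.mean(list(self.clip_rpm.values())))


def enrichment_fc(clip_rpm: float, input_rpm: float, pseudocount: float) -> float:
    """Pseudocounted CLIP/INPUT fold change: (clip + pc) / (input + pc)."""
    if clip_rpm < 0 or input_rpm < 0:
        raise ValueError("RPM values must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return (clip_rpm + pseudocount) / (input_rpm + pseudocount)


def call_footprints(
    clip_libraries: Mapping[int, SampleLibrary],
    input_libraries: Mapping[int, SampleLibrary],
    config: FootprintCallConfig = FootprintCallConfig(),
    min_gap: int = 0,
) -> list[Footprint]:
    """Call footprints for one sample from its two CLIP replicates and their
    replicate-matched INPUT libraries.

    Clusters are built per replicate by overlap merge, matched across
    replicates by >= 1 bp same-strand overlap (consensus interval = union),
    and retained per the configured thresholds (inclusive, "at least").
    """
    reps = sorted(clip_libraries)
    if len(reps) != 2:
        raise ValueError(f"need exactly 2 CLIP replicates, got {reps}")
    for r in reps:
        if r not in input_libraries:
            raise ValueError(f"missing INPUT library for replicate {r}")
    sample = clip_libraries[reps[0]].sample

    per_rep_clusters = {r: build_clusters(clip_libraries[r], min_gap=min_gap) for r in reps}
    matched = match_replicate_clusters(per_rep_clusters[reps[0]], per_rep_clusters[reps[1]])

    footprints = []
    n_presence = 0
    for consensus, c1, c2 in matched:
        present = {reps[0]: c1 is not None, reps[1]: c2 is not None}
        if config.require_both_replicates and not all(present.values()):
            continue
        if not any(present.values()):
            continue
        n_presence += 1
        clip_counts, clip_rpms, input_rpms, fcs = {}, {}, {}, {}
        passing = []
        for r in reps:
            n_clip = count_reads_in_interval(clip_libraries[r], consensus)
            n_input = count_reads_in_interval(input_libraries[r], consensus)
            cr = rpm(n_clip, clip_libraries[r].total_mapped_reads)
            ir = rpm(n_input, input_libraries[r].total_mapped_reads)
            fc = enrichment_fc(cr, ir, config.pseudocount)
            clip_counts[r], clip_rpms[r], input_rpms[r], fcs[r] = n_clip, cr, ir, fc
            if n_clip >= config.min_reads and fc >= config.min_fc:
                passing.append(r)
        ok = (
            len(passing) >= 1
            if config.threshold_scope == "either_replicate"
            else len(passing) == len(reps)
        )
        if not ok:
            continue
        footprints.append(
            Footprint(
                interval=consensus,
                sample=sample,
                clip_counts=clip_counts,
                clip_rpm=clip_rpms,
                input_rpm=input_rpms,
                fold_change=fcs,
                passing_replicates=passing,
            )
        )
    logger.info(
        "%s: %d clusters present in both replicates, %d passed thresholds",
        sample,
        n_presence,
        len(footprints),
    )
    return footprints


def subtract_background(
    footprints: Sequence[Footprint],
    background_sets: Sequence[Sequence[Footprint]],
) -> list[Footprint]:
    """Remove footprints overlapping (>= 1 bp, same strand) any background
    footprint; survivors are returned unchanged."""
    bg = [b.interval for s in background_sets for b in s]
    out = []
    for fp in footprints:
        if any(fp.interval.overlaps(b) for b in bg):
            continue
        out.append(fp)
    return out


def merge_footprint_intervals(footprints: Iterable[Footprint]) -> list[GenomicInterval]:
    """Union footprints from any samples into maximal merged intervals.

    Merging requires a strict >= 1 bp overlap (min_gap=-1), matching the
    overlap criterion used everywhere else; abutting footprints stay separate.
    """
    ivs = [fp.interval for fp in footprints]
    return merge_intervals(ivs, min_gap=-1) if ivs else []


def count_target_genes(footprints: Sequence[Footprint]) -> tuple[int, int]:
    """(number of merged footprints, number of unique genes) over the union of
    the given footprint sets; overlapping footprints count once."""
    merged = merge_footprint_intervals(footprints)
    genes = set()
    for fp in footprints:
        if fp.gene_id is None:
            logger.warning("footprint %s has no gene assignment", fp.interval)
            genes.add("unassigned")
        else:
            genes.add(fp.gene_id)
    return len(merged), len(genes)


def compare_signal(
    wt: Sequence[Footprint],
    c130y: Sequence[Footprint],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-footprint signal comparison between two samples as log2(RPM + pc).

    Footprints are matched by interval overlap (consensus = union); a
    footprint absent from one sample contributes RPM 0 there before the
    pseudocount.
    """
    tagged = [(fp, "a") for fp in wt] + [(fp, "b") for fp in c130y]
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.strand, t[0].interval.start))
    rows = []
    group: list[tuple[Footprint, str]] = []
    cur_end = None
    cur_key = None

    def flush(group):
        if not group:
            return
        iv = group[0][0].interval
        for fp, _ in group[1:]:
            iv = iv.union_span(fp.interval)
        rpm_a = sum(fp.mean_rpm for fp, t in group if t == "a")
        rpm_b = sum(fp.mean_rpm for fp, t in group if t == "b")
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "strand": iv.strand,
                "log2_rpm_wt": float(np.log2(rpm_a + pseudocount)),
                "log2_rpm_c130y": float(np.log2(rpm_b + pseudocount)),
            }
        )

    for fp, tag in tagged:
        iv = fp.interval
        key = (iv.chrom, iv.strand)
        if group and key == cur_key and iv.start < cur_end:
            group.append((fp, tag))
            cur_end = max(cur_end, iv.end)
        else:
            flush(group)
            group = [(fp, tag)]
            cur_key, cur_end = key, iv.end
    flush(group)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def write_footprints_bed(footprints: Sequence[Footprint], path: str) -> None:
    """BED6+: name = gene_id|category, score = max replicate read count."""
    with open(path, "w") as fh:
        for fp in sorted(footprints, key=lambda f: (f.interval.chrom, f.interval.start)):
            name = f"{fp.gene_id or 'unassigned'}|{fp.category or 'NA'}"
            score = max(fp.clip_counts.values())
            fh.write(
                f"{fp.interval.chrom}\t{fp.interval.start}\t{fp.interval.end}"
                f"\t{name}\t{score}\t{fp.interval.strand}\n"
            )


def footprints_to_frame(footprints: Sequence[Footprint]) -> pd.DataFrame:
    rows = []
    for fp in footprints:
        row = {
            "chrom": fp.interval.chrom,
            "start": fp.interval.start,
            "end": fp.interval.end,
            "strand": fp.interval.strand,
            "sample": fp.sample,
            "gene_id": fp.gene_id,
            "category": fp.category,
            "passing_replicates": ",".join(map(str, fp.passing_replicates)),
        }
        for r in sorted(fp.clip_counts):
            row[f"clip_count_rep{r}"] = fp.clip_counts[r]
            row[f"clip_rpm_rep{r}"] = fp.clip_rpm[r]
            row[f"input_rpm_rep{r}"] = fp.input_rpm[r]
            row[f"fold_change_rep{r}"] = fp.fold_change[r]
        rows.append(row)
    return pd.DataFrame(rows)
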