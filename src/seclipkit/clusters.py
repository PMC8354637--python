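"""Read-cluster construction, RPM normalization, and replicate agreement.

Clustering is a simple overlap merge standing in for an external peak
caller; pre-built cluster BED files can be imported instead, so real
peak-caller output can be substituted at any point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, merge_intervals

SAMPLES = ("WT", "C130Y", "dRRM", "IgG")
ASSAYS = ("CLIP", "INPUT")


@dataclass
class SampleLibrary:
    """One sequencing library: mapped read intervals plus its total depth."""

    sample: str  # e.g. "WT_CLIP"
    replicate: int
    total_mapped_reads: int
    reads: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be > 0")
        if self.total_mapped_reads < len(self.reads):
            raise ValueError("total_mapped_reads smaller than number of reads")


@dataclass
class ClusterRecord:
    """A merged read cluster with per-(sample, replicate) counts and RPM."""

    interval: GenomicInterval
    counts: dict[tuple[str, int], int] = field(default_factory=dict)
    rpm: dict[tuple[str, int], float] = field(default_factory=dict)

    def count(self, sample: str, replicate: int) -> int:
        return self.counts.get((sample, replicate), 0)


def rpm(count: float, library_size: float) -> float:
    """Reads per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count / library_size * 1e6


def build_clusters(library: SampleLibrary, min_gap: int = 0) -> list[ClusterRecord]:
    """Merge overlapping same-strand reads (within ``min_gap`` bp) into maximal
    clusters; each cluster's count is its number of constituent reads."""
    if not library.reads:
        return []
    merged = merge_intervals(library.reads, min_gap=min_gap)
    # assign each read to the unique merged cluster containing it
    out = []
    key = (library.sample, library.replicate)
    by_cs: dict[tuple[str, str], list[GenomicInterval]] = {}
    for r in library.reads:
        by_cs.setdefault((r.chrom, r.strand), []).append(r)
    for (chrom, strand), reads in by_cs.items():
        reads.sort(key=lambda x: (x.start, x.end))
    for m in merged:
        reads = by_cs[(m.chrom, m.strand)]
        n = sum(1 for r in reads if r.start < m.end and m.start < r.end)
        out.append(
            ClusterRecord(
                interval=m,
                counts={key: n},
                rpm={key: rpm(n, library.total_mapped_reads)},
            )
        )
    return out


def count_reads_in_interval(
    library: SampleLibrary, interval: GenomicInterval, stranded: bool = True
) -> int:
    """Number of library reads overlapping an interval by >= 1 bp."""
    return sum(1 for r in library.reads if r.overlaps(interval, stranded=stranded))


def match_replicate_clusters(
    rep1: Sequence[ClusterRecord], rep2: Sequence[ClusterRecord]
) -> list[tuple[GenomicInterval, Optional[ClusterRecord], Optional[ClusterRecord]]]:
    """Match clusters across two replicates by >= 1 bp same-strand overlap.

    Overlapping groups are unioned into a consensus interval. Returns
    (consensus interval, rep1 cluster or None, rep2 cluster or None); a
    replicate slot is None when no cluster of that replicate overlaps.
    """
    tagged = [(c, 1) for c in rep1] + [(c, 2) for c in rep2]
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.strand, t[0].interval.start))
    out = []
    group: list[tuple[ClusterRecord, int]] = []

    def flush(group):
        if not group:
            return
        iv = group[0][0].interval
        for c, _ in group[1:]:
            iv = iv.union_span(c.interval)
        r1 = [c for c, tag in group if tag == 1]
        r2 = [c for c, tag in group if tag == 2]
        out.append((iv, r1[0] if r1 else None, r2[0] if r2 else None))

    cur_end = None
    cur_key = None
    for c, tag in tagged:
        iv = c.interval
        key = (iv.chrom, iv.strand)
        if group and key == cur_key and iv.start < cur_end:
            group.append((c, tag))
            cur_end = max(cur_end, iv.end)
        else:
            flush(group)
            group = [(c, tag)]
            cur_key, cur_end = key, iv.end
    flush(group)
    return out


def replicate_correlation(
    clusters_rep1: Sequence[ClusterRecord],
    clusters_rep2: Sequence[ClusterRecord],
    sample: str,
) -> tuple[float, int]:
    """Pearson correlation of log2(count+1) over clusters detected in both
    replicates of one sample; returns (r, n shared clusters)."""
    matched = match_replicate_clusters(clusters_rep1, clusters_rep2)
    x, y = [], []
    for _, c1, c2 in matched:
        if c1 is None or c2 is None:
            continue
        n1 = sum(v for (s, _), v in c1.counts.items() if s == sample)
        n2 = sum(v for (s, _), v in c2.counts.items() if s == sample)
        x.append(np.log2(n1 + 1))
        y.append(np.log2(n2 + 1))
    if len(x) < 2:
        raise ValueError(f"need >= 2 shared clusters, found {len(x)}")
    r = stats.pearsonr(x, y).statistic
    return float(r), len(x)


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str) -> list[GenomicInterval]:
    """Read intervals from BED6 (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: need >= 3 BED fields")
            strand = fields[5] if len(fields) >= 6 else "+"
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def read_bed_clusters(path: str) -> list[ClusterRecord]:
    """Import pre-built clusters from BED6: name = 'sample:replicate', score = count."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")[:6]
            sample, rep = name.rsplit(":", 1)
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            out.append(ClusterRecord(interval=iv, counts={(sample, int(rep)): int(score)}))
    return out


def write_cluster_table(clusters: Sequence[ClusterRecord], path: str) -> None:
    import pandas as pd

    rows = []
    for c in clusters:
        for (sample, rep), n in sorted(c.counts.items()):
            rows.append(
                {
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "strand": c.interval.strand,
                    "sample": sample,
                    "replicate": rep,
                    "count": n,
                    "rpm": c.rpm.get((sample, rep), float("nan")),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
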