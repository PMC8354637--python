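"""Independent brute-force re-implementations used only as test oracles.

These deliberately avoid the package's sort-merge/matching code paths:
clustering is union-find over pairwise read overlaps, and the footprint
rule is applied literally, cluster by cluster.
"""

from __future__ import annotations

from seclipkit.intervals import GenomicInterval


def _pairwise_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return (
        a.chrom == b.chrom
        and a.strand == b.strand
        and a.start < b.end
        and b.start < a.end
    )


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def brute_force_clusters(reads, min_gap: int = 0):
    """Union-find clustering over pairwise overlaps (within min_gap).

    Returns a list of (interval, count) sorted by position.
    """
    n = len(reads)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and a.start <= b.end + min_gap
                and b.start <= a.end + min_gap
            ):
                uf.union(i, j)
    groups: dict[int, list[GenomicInterval]] = {}
    for i, r in enumerate(reads):
        groups.setdefault(uf.find(i), []).append(r)
    out = []
    for members in groups.values():
        iv = GenomicInterval(
            members[0].chrom,
            min(m.start for m in members),
            max(m.end for m in members),
            members[0].strand,
        )
        out.append((iv, len(members)))
    out.sort(key=lambda t: (t[0].chrom, t[0].strand, t[0].start, t[0].end))
    return out


def brute_force_call(clip_libs, input_libs, min_reads=20, min_fc=1.5, pseudocount=1.0,
                     scope="either_replicate"):
    """Literal footprint rule: a cluster appearing in both replicates, with
    >= min_reads reads and >= min_fc input enrichment in at least one.

    Returns sorted consensus intervals of retained footprints.
    """
    reps = sorted(clip_libs)
    clusters = {r: brute_force_clusters(clip_libs[r].reads) for r in reps}
    # pairwise cross-replicate matching, then transitive grouping
    items = [(r, iv, n) for r in reps for iv, n in clusters[r]]
    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if _pairwise_overlap(items[i][1], items[j][1]):
                uf.union(i, j)
    groups: dict[int, list] = {}
    for i, it in enumerate(items):
        groups.setdefault(uf.find(i), []).append(it)
    retained = []
    for members in groups.values():
        present = {r for r, _, _ in members}
        if set(reps) - present:
            continue
        iv = GenomicInterval(
            members[0][1].chrom,
            min(m[1].start for m in members),
            max(m[1].end for m in members),
            members[0][1].strand,
        )
        passing = 0
        for r in reps:
            n_clip = sum(1 for rd in clip_libs[r].reads if _pairwise_overlap(rd, iv))
            n_in = sum(1 for rd in input_libs[r].reads if _pairwise_overlap(rd, iv))
            clip_rpm = n_clip / clip_libs[r].total_mapped_reads * 1e6
            in_rpm = n_in / input_libs[r].total_mapped_reads * 1e6
            fc = (clip_rpm + pseudocount) / (in_rpm + pseudocount)
            if n_clip >= min_reads and fc >= min_fc:
                passing += 1
        ok = passing >= 1 if scope == "either_replicate" else passing == len(reps)
        if ok:
            retained.append(iv)
    retained.sort(key=lambda v: (v.chrom, v.strand, v.start, v.end))
    return retained


def brute_force_subtract(intervals, background):
    """Drop every interval overlapping any background interval pairwise."""
    return [
        iv for iv in intervals if not any(_pairwise_overlap(iv, b) for b in background)
    ]
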