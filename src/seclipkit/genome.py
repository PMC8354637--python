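"""Annotation and sequence data model: transcript structure, 5'UTR extraction, GC metrics.

Transcript models are loaded from GFF3/GTF via :mod:`gffutils`; when a file
annotates only exons and CDS, the 5'/3' UTRs are derived from the exon/CDS
geometry (strand-aware). Internally every coordinate is 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

from .intervals import GenomicInterval, total_length


class AnnotationError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """Genomic structure of one transcript.

    ``start_codon_pos`` is the genomic coordinate of the A of the ATG;
    ``stop_codon_pos`` is the first base of the stop codon (the CDS is taken
    to include the stop codon, the GFF3 convention). Both are ``None`` for
    non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    start_codon_pos: Optional[int] = None
    stop_codon_pos: Optional[int] = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def utr5_length(self) -> int:
        return total_length(self.utr5)

    def transcript_position(self, genomic_pos: int) -> Optional[int]:
        """Spliced (transcript-space) offset of a genomic base, 5'->3'.

        Returns ``None`` for intronic/outside positions.
        """
        upstream = 0
        for ex in self.exons:
            if ex.start <= genomic_pos < ex.end:
                within = genomic_pos - ex.start
                if self.strand == "+":
                    return upstream + within
                # minus strand: count from transcript 5' end (genomic right)
                before = sum(len(e) for e in self.exons if e.start > ex.start)
                return before + (ex.end - 1 - genomic_pos)
            upstream += len(ex)
        return None


@dataclass
class GenomeAnnotation:
    """Collection of transcripts with a gene index."""

    transcripts: dict[str, TranscriptModel]
    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        for tid, tx in self.transcripts.items():
            if tx.transcript_id != tid:
                raise AnnotationError(f"transcript key {tid} != id {tx.transcript_id}")
            if tx.gene_id not in self.genes or tid not in self.genes[tx.gene_id]:
                raise AnnotationError(f"gene index missing {tx.gene_id}/{tid}")

    def select_transcript(self, gene_id: str) -> TranscriptModel:
        """Representative transcript per gene: longest 5'UTR, ties by smallest id."""
        tids = self.genes[gene_id]
        best = min(
            (self.transcripts[t] for t in tids),
            key=lambda tx: (-tx.utr5_length, tx.transcript_id),
        )
        return best


@dataclass
class UTRRecord:
    """One gene's selected 5'UTR: spliced sequence 5'->3' ending just before ATG."""

    gene_id: str
    transcript_id: str
    length: int
    sequence: str
    gc_fraction: float
    trans_spliced: bool = False
    sl_leader_excluded: bool = False

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("UTR length must equal sequence length")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Annotation loading


def _prescan(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed record at line {lineno} (expected 9 tab-separated fields)"
                )


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR", "UTR5"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR", "UTR3"}
_TX_TYPES = {"mRNA", "transcript", "ncRNA", "snoRNA", "snRNA", "tRNA", "rRNA",
             "lincRNA", "lnc_RNA", "miRNA", "pseudogenic_transcript"}


def _derive_utrs(exons, cds):
    """Exonic bases 5' of the CDS become utr5, 3' of it utr3 (strand-aware)."""
    strand = exons[0].strand
    cds_start = min(c.start for c in cds)
    cds_end = max(c.end for c in cds)
    left = [
        GenomicInterval(e.chrom, e.start, min(e.end, cds_start), e.strand)
        for e in exons
        if e.start < cds_start
    ]
    right = [
        GenomicInterval(e.chrom, max(e.start, cds_end), e.end, e.strand)
        for e in exons
        if e.end > cds_end
    ]
    if strand == "+":
        return left, right
    return right, left


def load_annotation(path: str, dialect: str = "gff3") -> GenomeAnnotation:
    """Load a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    Coordinates are converted to 0-based half-open. When a transcript carries
    exons and CDS but no explicit UTR features, UTRs are derived from the
    exon/CDS geometry.
    """
    if dialect not in {"gff3", "gtf"}:
        raise ValueError(f"dialect must be 'gff3' or 'gtf', got {dialect!r}")
    _prescan(path)
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    tid2gene: dict[str, str] = {}
    for f in db.all_features():
        if f.featuretype in _TX_TYPES:
            tid = f.attributes.get("ID", [None])[0] or f.attributes.get(
                "transcript_id", [None]
            )[0]
            gene = (
                f.attributes.get("Parent", [None])[0]
                or f.attributes.get("gene_id", [None])[0]
            )
            if tid and gene:
                tid2gene[tid] = gene

    parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    genes_of: dict[str, str] = {}
    for f in db.all_features():
        ft = f.featuretype
        if ft == "exon":
            slot = "exons"
        elif ft == "CDS":
            slot = "cds"
        elif ft in _UTR5_TYPES:
            slot = "utr5"
        elif ft in _UTR3_TYPES:
            slot = "utr3"
        else:
            continue
        if dialect == "gtf":
            tids = f.attributes.get("transcript_id", [])
            gene = f.attributes.get("gene_id", [None])[0]
        else:
            tids = f.attributes.get("Parent", []) or f.attributes.get("transcript_id", [])
            gene = None
        if not tids:
            raise AnnotationError(
                f"{path}: {ft} feature at {f.seqid}:{f.start} lacks a transcript attribute"
            )
        iv = GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        for tid in tids:
            d = parts.setdefault(tid, {"exons": [], "cds": [], "utr5": [], "utr3": []})
            d[slot].append(iv)
            g = gene or tid2gene.get(tid, tid)
            genes_of.setdefault(tid, g)

    transcripts: dict[str, TranscriptModel] = {}
    genes: dict[str, list[str]] = {}
    for tid, d in parts.items():
        exons = sorted(d["exons"], key=lambda x: x.start)
        cds = sorted(d["cds"], key=lambda x: x.start)
        if cds and not exons:
            raise AnnotationError(f"transcript {tid} has CDS but no exons")
        if not exons:
            continue
        utr5 = sorted(d["utr5"], key=lambda x: x.start)
        utr3 = sorted(d["utr3"], key=lambda x: x.start)
        if cds and not utr5 and not utr3:
            utr5, utr3 = _derive_utrs(exons, cds)
        start_pos = stop_pos = None
        if cds:
            if exons[0].strand == "+":
                start_pos = min(c.start for c in cds)
                stop_pos = max(c.end for c in cds) - 3
            else:
                start_pos = max(c.end for c in cds) - 1
                stop_pos = min(c.start for c in cds) + 2
        gene = genes_of[tid]
        tx = TranscriptModel(
            gene_id=gene,
            transcript_id=tid,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            start_codon_pos=start_pos,
            stop_codon_pos=stop_pos,
        )
        transcripts[tid] = tx
        genes.setdefault(gene, []).append(tid)
    return GenomeAnnotation(transcripts=transcripts, genes=genes)


# ---------------------------------------------------------------------------
# Sequence operations


def gc_content(sequence: str, n_tolerant: bool = False) -> float:
    """Fraction of G+C bases; N is tolerated (counted non-GC) only if requested."""
    if not sequence:
        raise ValueError("cannot compute GC of an empty sequence")
    allowed = set("ACGTU") | ({"N"} if n_tolerant else set())
    seq = sequence.upper()
    gc = 0
    for i, base in enumerate(seq):
        if base not in allowed:
            raise ValueError(f"disallowed character {base!r} at position {i}")
        if base in "GC":
            gc += 1
    return gc / len(seq)


def binned_gc(
    utr: "UTRRecord | str", bin_size: int = 10
) -> list[tuple[int, int, float]]:
    """Per-bin GC walking 5'-ward from the ATG.

    Bin 1 covers the ``bin_size`` bases immediately upstream of the start
    codon, bin 2 the next ``bin_size`` further 5', and so on; the final
    (5'-most) bin may be partial and reports its true length. The
    length-weighted mean of the bins equals the total GC.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    seq = utr.sequence if isinstance(utr, UTRRecord) else utr
    if not seq:
        raise ValueError("UTR sequence is empty")
    out = []
    idx = 1
    end = len(seq)
    while end > 0:
        start = max(0, end - bin_size)
        chunk = seq[start:end]
        out.append((idx, len(chunk), gc_content(chunk)))
        end = start
        idx += 1
    return out


def _spliced_sequence(fasta: Fasta, intervals: Sequence[GenomicInterval]) -> str:
    pieces = []
    for iv in sorted(intervals, key=lambda x: x.start):
        if iv.chrom not in fasta:
            raise AnnotationError(
                f"chromosome {iv.chrom!r} not in FASTA (available: {list(fasta.keys())})"
            )
        if iv.end > len(fasta[iv.chrom]):
            raise AnnotationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence end "
                f"({len(fasta[iv.chrom])})"
            )
        pieces.append(str(fasta[iv.chrom][iv.start : iv.end]))
    seq = "".join(pieces).upper()
    if intervals[0].strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def extract_five_prime_utrs(
    annotation: GenomeAnnotation,
    sequences: "Fasta | str",
    min_len: int = 10,
    longest_per_gene: bool = True,
    trans_spliced_genes: Optional[Iterable[str]] = None,
    sl_sequence: Optional[str] = None,
    n_tolerant: bool = False,
) -> list[UTRRecord]:
    """Extract spliced 5'UTR sequences, keeping UTRs of at least ``min_len`` nt
    and (by default) only the longest 5'UTR isoform per gene.

    Ties for longest are broken by lexicographically smallest transcript id.
    If ``sl_sequence`` is given, a matching spliced-leader prefix is stripped
    before length/GC computation and flagged in the record.
    """
    fasta = Fasta(sequences) if isinstance(sequences, (str, os.PathLike)) else sequences
    ts_genes = set(trans_spliced_genes or ())

    candidates: list[TranscriptModel] = []
    for gid, tids in sorted(annotation.genes.items()):
        txs = [annotation.transcripts[t] for t in tids if annotation.transcripts[t].utr5]
        if not txs:
            continue
        if longest_per_gene:
            txs = [min(txs, key=lambda tx: (-tx.utr5_length, tx.transcript_id))]
        candidates.extend(txs)

    records = []
    for tx in candidates:
        seq = _spliced_sequence(fasta, tx.utr5)
        stripped = False
        if sl_sequence and seq.startswith(sl_sequence.upper()):
            seq = seq[len(sl_sequence) :]
            stripped = True
        if len(seq) < min_len:
            continue
        records.append(
            UTRRecord(
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                length=len(seq),
                sequence=seq,
                gc_fraction=gc_content(seq, n_tolerant=n_tolerant),
                trans_spliced=tx.gene_id in ts_genes,
                sl_leader_excluded=stripped,
            )
        )
    return records


def write_utr_table(records: Sequence[UTRRecord], path: str) -> None:
    """UTR feature table as TSV: gene_id, transcript_id, length, gc_percent, trans_spliced."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "length": [r.length for r in records],
            "gc_percent": [round(100 * r.gc_fraction, 4) for r in records],
            "trans_spliced": [r.trans_spliced for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
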