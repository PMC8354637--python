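"""Group comparisons of 5'UTR features and trans-splice annotation joins.

Length and GC comparisons between a target gene set and a background
transcriptome use the two-sided Mann-Whitney U test (exact for small
tie-free samples, normal approximation with tie/continuity correction
otherwise). Trans-splicing status comes from an external compilation of
spliced-leader events joined on gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import UTRRecord

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 25


@dataclass
class TransSpliceTable:
    """Compilation of trans-splice events: gene, transcript, SL type, mature UTR length."""

    frame: pd.DataFrame  # columns: gene_id, transcript_id, sl_type, utr_length

    REQUIRED = ("gene_id", "transcript_id", "sl_type", "utr_length")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trans-splice table missing columns: {missing}")

    @classmethod
    def from_tsv(cls, path: str) -> "TransSpliceTable":
        return cls(pd.read_csv(path, sep="\t"))

    def spliced_genes(self) -> set[str]:
        return set(self.frame["gene_id"].astype(str))


@dataclass
class GroupComparison:
    feature: str
    n_targets: int
    n_background: int
    median_targets: float
    median_background: float
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _feature_values(records: Sequence[UTRRecord], feature: str) -> np.ndarray:
    if feature == "length":
        return np.asarray([r.length for r in records], dtype=float)
    if feature == "gc":
        return np.asarray([100.0 * r.gc_fraction for r in records], dtype=float)
    raise ValueError(f"feature must be 'length' or 'gc', got {feature!r}")


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: exact when combined n <= 25 without ties,
    else normal approximation with continuity and tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= _EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def compare_utr_feature(
    targets: Sequence[UTRRecord] | np.ndarray,
    background: Sequence[UTRRecord] | np.ndarray,
    feature: str = "length",
) -> GroupComparison:
    """Compare one 5'UTR feature (length in nt, or GC in percent) between a
    target set and a background set."""
    if len(targets) < 2 or len(background) < 2:
        raise ValueError("each group needs >= 2 records")
    def _values(group):
        first = group[0] if len(group) else None
        if isinstance(first, UTRRecord):
            return _feature_values(group, feature)
        return np.asarray(group, dtype=float)

    x, y = _values(targets), _values(background)
    stat, p, method = mann_whitney(x, y)
    return GroupComparison(
        feature=feature,
        n_targets=len(x),
        n_background=len(y),
        median_targets=float(np.median(x)),
        median_background=float(np.median(y)),
        statistic=stat,
        p_value=p,
        method=method,
    )


def join_trans_splice(
    target_gene_ids: Iterable[str], table: TransSpliceTable
) -> tuple[int, int, int, np.ndarray]:
    """Fraction of target genes annotated as trans-spliced.

    Returns (n_spliced, n_total, percent rounded to nearest integer, mature
    UTR lengths of the spliced targets). Target genes absent from the table
    count as not trans-spliced.
    """
    targets = list(dict.fromkeys(str(g) for g in target_gene_ids))
    if not targets:
        raise ValueError("empty target gene list")
    spliced = table.spliced_genes()
    hit = [g for g in targets if g in spliced]
    n_spliced, n_total = len(hit), len(targets)
    percent = int(round(100.0 * n_spliced / n_total))
    sub = table.frame[table.frame["gene_id"].astype(str).isin(hit)]
    lengths = sub.groupby("gene_id")["utr_length"].max().to_numpy(dtype=float)
    return n_spliced, n_total, percent, lengths


def summarize_utrs(records: Sequence[UTRRecord]) -> dict:
    """n, median length, median GC percent, and a 5/25/50/75/95 percentile table."""
    if not records:
        raise ValueError("no UTR records to summarize")
    lengths = np.asarray([r.length for r in records], dtype=float)
    gc = np.asarray([100.0 * r.gc_fraction for r in records], dtype=float)
    qs = [5, 25, 50, 75, 95]
    return {
        "n": len(records),
        "median_length": float(np.median(lengths)),
        "median_gc_percent": float(np.median(gc)),
        "percentiles": pd.DataFrame(
            {
                "percentile": qs,
                "length": np.percentile(lengths, qs),
                "gc_percent": np.percentile(gc, qs),
            }
        ),
    }
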