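"""Xenograft RNA-seq post-processing.

A graft sample sequenced from a human tumor grown in a mouse contains a
mixture of human and mouse reads.  Each read pair is aligned to both
genomes and assigned to one of four classes — human-only, mouse-only,
common, unaligned — by comparing, in order, the alignment score (higher
wins), the mismatch count (lower wins), and the matched-segment length
(higher wins), each summed over the two mates.  Reads from the human-only
and common classes are retained for quantification.

Downstream, per-gene expression is summarized as FPKM and the
differential-expression table is filtered with the standard three-part
rule: |log2 fold change| > 1, mean FPKM > 1, and Benjamini-Hochberg
adjusted p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ASSIGNMENT_CLASSES = ("human_only", "mouse_only", "common", "unaligned")

READ_SUMMARY_COLUMNS = ["read_id", "score_h", "nm_h", "mlen_h",
                        "score_m", "nm_m", "mlen_m"]


@dataclass
class ReadPairSummary:
    """Per-genome alignment metrics for one read pair (mates summed)."""

    read_id: str
    aligned_h: bool = False
    score_h: float = 0.0
    mismatches_h: int = 0
    matchlen_h: int = 0
    aligned_m: bool = False
    score_m: float = 0.0
    mismatches_m: int = 0
    matchlen_m: int = 0

    def __post_init__(self) -> None:
        if self.matchlen_h < 0 or self.matchlen_m < 0:
            raise ValueError("matched length must be >= 0")


@dataclass
class GeneRecord:
    gene_id: str
    length_bp: int
    mean_fpkm: float
    log2fc: float
    pvalue: float
    padj: float = math.nan
    call: str = "unchanged"


@dataclass
class ResponderGrouping:
    """Partition of xenograft models into good (CR/MCR) and poor (PR/SD/PD)
    responders for group-level differential expression."""

    good: frozenset
    poor: frozenset

    def __post_init__(self) -> None:
        self.good = frozenset(self.good)
        self.poor = frozenset(self.poor)
        if not self.good or not self.poor:
            raise ValueError("both responder groups must be non-empty")
        if self.good & self.poor:
            raise ValueError(f"groups overlap: {sorted(self.good & self.poor)}")


def assign_read(pair: ReadPairSummary, tolerance: float = 0.0) -> str:
    """Assign one read pair to human_only / mouse_only / common / unaligned.

    When both genomes align, the comparison is lexicographic — score
    (descending), mismatches (ascending), matched length (descending) —
    and a pair whose metrics all tie within ``tolerance`` is "common".
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if not pair.aligned_h and not pair.aligned_m:
        return "unaligned"
    if pair.aligned_h and not pair.aligned_m:
        return "human_only"
    if pair.aligned_m and not pair.aligned_h:
        return "mouse_only"
    for h, m, better_high in (
        (pair.score_h, pair.score_m, True),
        (pair.mismatches_h, pair.mismatches_m, False),
        (pair.matchlen_h, pair.matchlen_m, True),
    ):
        if abs(h - m) > tolerance:
            human_wins = (h > m) if better_high else (h < m)
            return "human_only" if human_wins else "mouse_only"
    return "common"


def assign_reads(table: pd.DataFrame, tolerance: float = 0.0) -> pd.Series:
    """Vector version of :func:`assign_read` over a read-summary table.

    Missing (NaN) metrics for a genome mean the pair did not align there.
    """
    out = []
    for row in table.itertuples():
        pair = ReadPairSummary(
            read_id=str(row.read_id),
            aligned_h=not pd.isna(row.score_h),
            score_h=0.0 if pd.isna(row.score_h) else float(row.score_h),
            mismatches_h=0 if pd.isna(row.nm_h) else int(row.nm_h),
            matchlen_h=0 if pd.isna(row.mlen_h) else int(row.mlen_h),
            aligned_m=not pd.isna(row.score_m),
            score_m=0.0 if pd.isna(row.score_m) else float(row.score_m),
            mismatches_m=0 if pd.isna(row.nm_m) else int(row.nm_m),
            matchlen_m=0 if pd.isna(row.mlen_m) else int(row.mlen_m),
        )
        out.append(assign_read(pair, tolerance))
    return pd.Series(out, index=table.index, name="assignment")


def retained_for_quantification(assignments: pd.Series) -> pd.Series:
    """Boolean mask of reads kept for graft quantification: the
    human-only and common classes (mouse contamination removed)."""
    return assignments.isin(["human_only", "common"])


def read_summary_table(path) -> pd.DataFrame:
    """Read the TSV read-summary format (optional true_origin column)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in READ_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def fpkm(counts, gene_length_bp, total_assigned_reads) -> np.ndarray | float:
    """Fragments per kilobase of transcript per million assigned reads:
    counts * 1e9 / (gene_length_bp * total_assigned_reads)."""
    counts = np.asarray(counts, dtype=float)
    if np.any(np.asarray(gene_length_bp) <= 0):
        raise ValueError("gene length must be positive")
    if total_assigned_reads <= 0:
        raise ValueError("library size must be positive")
    out = counts * 1e9 / (np.asarray(gene_length_bp, dtype=float) * total_assigned_reads)
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    padj_(i) = min over j >= i of p_(j) * n / j on the sorted vector,
    capped at 1; order-preserving and idempotent.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def de_filter(records: list[GeneRecord],
              log2fc_min: float = 1.0,
              fpkm_min: float = 1.0,
              padj_max: float = 0.05) -> list[GeneRecord]:
    """Apply the up/down-regulation filter, setting ``padj`` and ``call``.

    A gene is called "up" when log2fc > log2fc_min, "down" when
    log2fc < -log2fc_min, in both cases requiring mean FPKM > fpkm_min
    and BH-adjusted p < padj_max; all inequalities are strict.  The input
    list is not modified; the returned records carry the adjusted p.
    """
    if not records:
        return []
    padj = bh_adjust([r.pvalue for r in records])
    out = []
    for rec, q in zip(records, padj):
        call = "unchanged"
        if rec.mean_fpkm > fpkm_min and q < padj_max:
            if rec.log2fc > log2fc_min:
                call = "up"
            elif rec.log2fc < -log2fc_min:
                call = "down"
        out.append(GeneRecord(gene_id=rec.gene_id, length_bp=rec.length_bp,
                              mean_fpkm=rec.mean_fpkm, log2fc=rec.log2fc,
                              pvalue=rec.pvalue, padj=float(q), call=call))
    return out


def de_filter_table(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """DataFrame front-end for :func:`de_filter`.

    Requires columns gene_id, length_bp, mean_fpkm, log2fc, pvalue; adds
    padj and call.
    """
    records = [
        GeneRecord(gene_id=str(r.gene_id), length_bp=int(r.length_bp),
                   mean_fpkm=float(r.mean_fpkm), log2fc=float(r.log2fc),
                   pvalue=float(r.pvalue))
        for r in df.itertuples()
    ]
    filtered = de_filter(records, **kwargs)
    out = df.copy()
    out["padj"] = [r.padj for r in filtered]
    out["call"] = [r.call for r in filtered]
    return out
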