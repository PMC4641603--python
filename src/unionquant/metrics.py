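"""RPKM and TPM expression measures.

Three gene-level RPKM modes are distinguished:

``fc_rpkm``
    union-exon counts divided by the union-exon length — the partial-overlap
    counter's gene RPKM.
``rsem_rpkm``
    EM-derived gene counts (sum of per-transcript expected counts) divided
    by the same union-exon length.
``rsem_txSum_rpkm``
    per-transcript RPKM computed first (transcript counts over spliced
    transcript lengths), then summed within each gene.

For a feature with count c, length L (bp) and N total counted reads in the
sample, RPKM = c / ((L/1000) · (N/10⁶)).  TPM rescales the per-base rates
c/L so they sum to 10⁶ within each sample; within a sample TPM is
proportional to RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import Annotation

__all__ = [
    "ExpressionTable",
    "rpkm",
    "gene_rpkm_union",
    "transcript_rpkm",
    "gene_rpkm_txsum",
    "tpm",
    "log_shift",
]

RPKM_MODES = ("fc_rpkm", "rsem_rpkm", "rsem_txSum_rpkm", "tx_rpkm", "tpm")


@dataclass
class ExpressionTable:
    """A feature × sample expression matrix with its normalization metadata."""

    values: pd.DataFrame
    mode: str
    lengths: pd.Series | None = None
    total_reads: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in RPKM_MODES:
            raise ValueError(f"unknown expression mode {self.mode!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


def rpkm(count: float, length_bp: float, total_reads: float) -> float:
    """RPKM for a single feature: count / ((length/1e3) · (total/1e6))."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count / ((length_bp / 1e3) * (total_reads / 1e6))


def _resolve_totals(
    counts: pd.DataFrame, total_reads: pd.Series | float | None
) -> pd.Series:
    if total_reads is None:
        totals = counts.sum(axis=0).astype(float)
    elif np.isscalar(total_reads):
        totals = pd.Series(float(total_reads), index=counts.columns)
    else:
        totals = pd.Series(total_reads).astype(float).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("total_reads must be positive for every sample")
    return totals


def _rpkm_frame(
    counts: pd.DataFrame, lengths: pd.Series, totals: pd.Series
) -> pd.DataFrame:
    if (lengths < 1).any():
        raise ValueError("feature lengths must be >= 1 bp")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def gene_rpkm_union(
    counts: pd.DataFrame,
    union_lengths: pd.Series | Annotation,
    total_reads: pd.Series | float | None = None,
    source: str = "fc",
) -> ExpressionTable:
    """Gene RPKM over union-exon lengths from either counting source.

    ``source`` tags the table ``fc_rpkm`` (union-exon counter) or
    ``rsem_rpkm`` (EM-derived gene counts).  ``total_reads`` defaults to the
    per-sample column sums — the reads counted by that same method; pass a
    shared value for cross-method comparability.
    """
    if source not in ("fc", "rsem"):
        raise ValueError("source must be 'fc' or 'rsem'")
    if isinstance(union_lengths, Annotation):
        union_lengths = union_lengths.union_lengths()
    lengths = pd.Series(union_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"no union length for genes: {missing}")
    totals = _resolve_totals(counts, total_reads)
    values = _rpkm_frame(counts, lengths, totals)
    return ExpressionTable(values, f"{source}_rpkm", lengths, totals)


def transcript_rpkm(
    tx_counts: pd.DataFrame,
    tx_lengths: pd.Series | Annotation,
    total_reads: pd.Series | float | None = None,
) -> ExpressionTable:
    """Per-transcript RPKM over spliced transcript lengths."""
    if isinstance(tx_lengths, Annotation):
        tx_lengths = tx_lengths.transcript_lengths()
    lengths = pd.Series(tx_lengths).reindex(tx_counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index)
        raise ValueError(f"no length for transcripts: {missing}")
    totals = _resolve_totals(tx_counts, total_reads)
    values = _rpkm_frame(tx_counts, lengths, totals)
    return ExpressionTable(values, "tx_rpkm", lengths, totals)


def gene_rpkm_txsum(
    tx_rpkm_table: ExpressionTable | pd.DataFrame,
    tx_to_gene: Mapping[str, str] | Annotation,
) -> ExpressionTable:
    """Sum per-transcript RPKMs within genes (the transcript-based gene RPKM)."""
    if isinstance(tx_rpkm_table, ExpressionTable):
        values = tx_rpkm_table.values
        totals = tx_rpkm_table.total_reads
    else:
        values = tx_rpkm_table
        totals = None
    if isinstance(tx_to_gene, Annotation):
        tx_to_gene = tx_to_gene.transcript_to_gene
    unknown = sorted(set(values.index) - set(tx_to_gene))
    if unknown:
        raise ValueError(f"transcripts without a gene mapping: {unknown}")
    gene_of = pd.Series({t: tx_to_gene[t] for t in values.index})
    summed = values.groupby(gene_of).sum()
    summed.index.name = "gene_id"
    return ExpressionTable(summed, "rsem_txSum_rpkm", None, totals)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionTable:
    """Transcripts-per-million: per-base rates rescaled to sum to 10⁶."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every feature needs a length >= 1 bp")
    rates = counts.div(lengths, axis=0)
    denom = rates.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("cannot compute TPM for a sample with zero counts")
    values = rates.div(denom, axis=1) * 1e6
    return ExpressionTable(values, "tpm", lengths, None)


def log_shift(values, pseudo: float = 0.5):
    """log2(value + pseudo), the transform used for expression scatter plots."""
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return np.log2(values + pseudo)
    out = np.log2(np.asarray(values, dtype=float) + pseudo)
    return float(out) if out.ndim == 0 else out
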