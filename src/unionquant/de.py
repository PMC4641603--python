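"""Gene- and transcript-level differential expression and set intersection.

A feature is called differentially expressed (DE) when its fold change
reaches 1.5× and its Benjamini-Hochberg adjusted p-value falls below 0.05,
jointly.  The default test is a deliberately simple two-sample t-test on
log2(CPM + 0.5); the interface is pluggable so p-values from an external
negative-binomial or precision-weighted model can be supplied instead — the
analysis of interest here is the set comparison between the DE gene list
from gene-level testing (DE_Gene_Gene) and the genes owning at least one DE
transcript (DE_Tx_Gene), which exposes isoform switches and minor-isoform
changes that gene-level totals mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Annotation

__all__ = [
    "bh_adjust",
    "de_flags",
    "de_call",
    "intersect_de_sets",
    "DEResult",
    "DESetComparison",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_flags(
    log2fc: Sequence[float],
    padj: Sequence[float],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> np.ndarray:
    """Joint DE call: |log2FC| >= log2(fc_threshold) and adjusted p < alpha."""
    lfc = np.asarray(list(log2fc), dtype=float)
    q = np.asarray(list(padj), dtype=float)
    return (np.abs(lfc) >= np.log2(fc_threshold)) & (q < alpha)


@dataclass
class DEResult:
    """Per-feature differential-expression table at one level."""

    table: pd.DataFrame  # columns: log2fc, pvalue, padj, de
    level: str  # "gene" or "transcript"

    @property
    def de_features(self) -> set[str]:
        return set(self.table.index[self.table["de"]])


def _default_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sample t-test on the log-scale matrices."""
    res = stats.ttest_ind(a, b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance rows: equal means -> no evidence; unequal -> certain
    nan = np.isnan(p)
    if nan.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[nan & equal] = 1.0
        p[nan & ~equal] = 0.0
    return p


def de_call(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    level: str = "gene",
    test_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudo: float = 0.5,
) -> DEResult:
    """Two-group DE analysis of a count table (group B relative to group A).

    Counts are scaled to CPM per sample; fold changes come from the group
    mean CPMs (with ``pseudo`` guarding zeros) and p-values from ``test_fn``
    applied to log2(CPM + pseudo) matrices (default: two-sample t-test).
    Requires at least two replicates per group.
    """
    if level not in ("gene", "transcript"):
        raise ValueError("level must be 'gene' or 'transcript'")
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    missing = [s for s in group_a + group_b if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from counts: {missing}")
    lib = counts[group_a + group_b].sum(axis=0)
    if (lib <= 0).any():
        raise ValueError(
            f"zero library size in samples: {list(lib.index[lib <= 0])}"
        )
    cpm = counts[group_a + group_b].div(lib, axis=1) * 1e6
    mean_a = cpm[group_a].mean(axis=1)
    mean_b = cpm[group_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    log_a = np.log2(cpm[group_a].to_numpy() + pseudo)
    log_b = np.log2(cpm[group_b].to_numpy() + pseudo)
    test = test_fn or _default_test
    pvals = np.asarray(test(log_a, log_b), dtype=float)
    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "de": de_flags(log2fc, padj, fc_threshold, alpha),
        },
        index=counts.index,
    )
    return DEResult(table, level)


@dataclass(frozen=True)
class DESetComparison:
    """Intersection of gene-level DE calls with genes owning DE transcripts."""

    de_gene_gene: frozenset
    de_tx_gene: frozenset

    @property
    def shared(self) -> frozenset:
        return self.de_gene_gene & self.de_tx_gene

    @property
    def gene_only(self) -> frozenset:
        return self.de_gene_gene - self.de_tx_gene

    @property
    def tx_only(self) -> frozenset:
        return self.de_tx_gene - self.de_gene_gene

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "gene_only": len(self.gene_only),
            "tx_only": len(self.tx_only),
        }


def intersect_de_sets(
    gene_level: DEResult, tx_level: DEResult, annotation: Annotation
) -> DESetComparison:
    """Group DE transcripts to their genes and intersect with gene-level DE."""
    if gene_level.level != "gene" or tx_level.level != "transcript":
        raise ValueError("expected one gene-level and one transcript-level result")
    de_gene_gene = frozenset(gene_level.de_features)
    de_tx_gene = frozenset(
        annotation.transcript_to_gene[t] for t in tx_level.de_features
    )
    return DESetComparison(de_gene_gene, de_tx_gene)
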