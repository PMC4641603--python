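"""Union-exon gene-level read counting.

Implements partial-overlap counting against flattened union exons: a read is
assigned to a gene when the total number of its aligned bases falling in the
gene's union exons, summed over alignment blocks, reaches a minimum overlap
threshold (default 18 bp).  Reads qualifying for two or more genes are
ambiguous and excluded; reads qualifying for none are unassigned.  Strand
matching follows the library protocol (default: reverse-stranded, so a read
must be antisense to the gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import Annotation
from .reads import AlignedRead

__all__ = [
    "AMBIGUOUS",
    "NO_FEATURE",
    "UnionIndex",
    "UnionCountResult",
    "assign_read_union",
    "count_union",
]

#: Assignment outcome for reads qualifying for two or more genes.
AMBIGUOUS = "__AMBIGUOUS__"
#: Assignment outcome for reads qualifying for no gene.
NO_FEATURE = "__NO_FEATURE__"


class UnionIndex:
    """Interval index over all genes' union exons, per chromosome."""

    def __init__(self, annotation: Annotation):
        self._trees: dict[str, IntervalTree] = {}
        self._gene_strand = {g.gene_id: g.strand for g in annotation}
        for gene in annotation:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            for exon in gene.union_exons:
                tree.addi(exon.start, exon.end, gene.gene_id)

    def gene_overlaps(self, read: AlignedRead) -> dict[str, int]:
        """Per-gene total overlap (bp) between the read's blocks and union exons."""
        tree = self._trees.get(read.chrom)
        if tree is None:
            return {}
        overlaps: dict[str, int] = {}
        for bstart, bend in read.blocks:
            for iv in tree.overlap(bstart, bend):
                bp = min(bend, iv.end) - max(bstart, iv.begin)
                overlaps[iv.data] = overlaps.get(iv.data, 0) + bp
        return overlaps

    def strand_compatible(self, read: AlignedRead, gene_id: str, mode: str) -> bool:
        gene_strand = self._gene_strand[gene_id]
        if mode == "unstranded":
            return True
        if mode == "forward":
            return read.strand == gene_strand
        if mode == "reverse":
            return read.strand != gene_strand
        raise ValueError(f"unknown strand mode {mode!r}")


def assign_read_union(
    read: AlignedRead,
    index: UnionIndex | Annotation,
    min_overlap_bp: int = 18,
    strand_mode: str = "reverse",
) -> str:
    """Assign one read: a gene_id, :data:`AMBIGUOUS`, or :data:`NO_FEATURE`.

    A gene qualifies iff the read's summed union-exon overlap reaches
    ``min_overlap_bp`` and the strand is compatible under ``strand_mode``.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if isinstance(index, Annotation):
        index = UnionIndex(index)
    overlaps = index.gene_overlaps(read)
    qualifying = [
        g
        for g, bp in overlaps.items()
        if bp >= min_overlap_bp and index.strand_compatible(read, g, strand_mode)
    ]
    if len(qualifying) == 1:
        return qualifying[0]
    if len(qualifying) >= 2:
        return AMBIGUOUS
    return NO_FEATURE


@dataclass
class UnionCountResult:
    """Per-gene fragment counts and per-sample assignment tallies."""

    counts: pd.DataFrame  # gene × sample, integer
    summary: pd.DataFrame  # sample × {assigned, ambiguous, no_feature, *_pct}

    def __post_init__(self) -> None:
        totals = self.summary[["assigned", "ambiguous", "no_feature"]].sum(axis=1)
        processed = self.summary["total"]
        if not (totals == processed).all():
            raise ValueError("assignment tallies do not sum to reads processed")


def count_union(
    reads: Iterable[AlignedRead],
    annotation: Annotation,
    min_overlap_bp: int = 18,
    strand_mode: str = "reverse",
    samples: Sequence[str] | None = None,
) -> UnionCountResult:
    """Count fragments per gene against union exons for every sample.

    Summary percentages mirror a counting-report layout: the share of
    processed reads that were assigned, ambiguous, or overlapped no feature.
    """
    index = UnionIndex(annotation)
    reads = list(reads)
    sample_names = (
        list(samples)
        if samples is not None
        else sorted({r.sample for r in reads})
    ) or ["sample1"]
    gene_ids = annotation.gene_ids
    counts = {s: dict.fromkeys(gene_ids, 0) for s in sample_names}
    tallies = {
        s: {"assigned": 0, "ambiguous": 0, "no_feature": 0} for s in sample_names
    }
    for read in reads:
        outcome = assign_read_union(read, index, min_overlap_bp, strand_mode)
        t = tallies[read.sample]
        if outcome == AMBIGUOUS:
            t["ambiguous"] += 1
        elif outcome == NO_FEATURE:
            t["no_feature"] += 1
        else:
            t["assigned"] += 1
            counts[read.sample][outcome] += 1
    counts_df = pd.DataFrame(counts, dtype=int).loc[gene_ids, sample_names]
    counts_df.index.name = "gene_id"
    summary = pd.DataFrame(tallies).T.loc[sample_names]
    summary["total"] = summary.sum(axis=1)
    denom = summary["total"].astype(float).replace(0.0, float("nan"))
    for col in ("assigned", "ambiguous", "no_feature"):
        summary[f"{col}_pct"] = (100.0 * summary[col] / denom).fillna(0.0)
    summary.index.name = "sample"
    return UnionCountResult(counts=counts_df, summary=summary)
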