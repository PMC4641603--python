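"""Gene models, union-exon flattening, and gene filtering.

A gene is represented as a set of transcript isoforms, each an ordered chain
of exons on one chromosome and strand.  For gene-level counting the exons of
all isoforms are flattened into *union exons*: the maximal set of disjoint
intervals covering every exonic base of the gene.  The total union-exon
length is the "gene length" used by union-exon RPKM, while each transcript
keeps its own spliced length for transcript-level RPKM.

Coordinates are 0-based half-open throughout; GTF's 1-based inclusive
coordinates are converted at the parsing boundary.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils
import pandas as pd

VALID_STRANDS = frozenset({"+", "-"})

__all__ = [
    "AnnotationError",
    "GTFParseError",
    "GenomicInterval",
    "Transcript",
    "Gene",
    "Annotation",
    "FilterConfig",
    "merge_intervals",
    "read_gtf",
    "filter_genes",
    "structural_features",
]


class AnnotationError(ValueError):
    """Invalid annotation structure or inputs."""


class GTFParseError(AnnotationError):
    """Malformed GTF input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """One spliced isoform: an ordered chain of disjoint exons."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length_bp(self) -> int:
        """Spliced transcript length (sum of exon lengths)."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


@dataclass(frozen=True)
class Gene:
    """A gene with its isoforms and derived union exons."""

    gene_id: str
    transcripts: tuple[Transcript, ...]
    union_exons: tuple[GenomicInterval, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(f"gene {self.gene_id} mixes chromosomes/strands")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} belongs to {t.gene_id}, "
                    f"not {self.gene_id}"
                )
        all_exons = [e for t in self.transcripts for e in t.exons]
        object.__setattr__(self, "union_exons", tuple(merge_intervals(all_exons)))

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def union_length_bp(self) -> int:
        """Total union-exon length, the gene length of union-exon RPKM."""
        return sum(e.length for e in self.union_exons)

    @property
    def n_union_exons(self) -> int:
        return len(self.union_exons)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.union_exons[0].start, self.union_exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between union exons (bases intronic in every isoform)."""
        out = []
        for a, b in zip(self.union_exons, self.union_exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)


class Annotation:
    """A collection of genes indexed by gene_id."""

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    @functools.cached_property
    def transcripts(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for g in self for t in g.transcripts}

    @functools.cached_property
    def transcript_to_gene(self) -> dict[str, str]:
        return {t.transcript_id: g.gene_id for g in self for t in g.transcripts}

    def gene_of_transcript(self, transcript_id: str) -> Gene:
        return self._genes[self.transcript_to_gene[transcript_id]]

    def subset(self, gene_ids: Iterable[str]) -> "Annotation":
        return Annotation(self._genes[g] for g in gene_ids)

    def union_lengths(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.union_length_bp for g in self}, name="union_length_bp"
        )

    def transcript_lengths(self) -> pd.Series:
        return pd.Series(
            {t.transcript_id: t.length_bp for t in self.transcripts.values()},
            name="length_bp",
        )

    def feature_table(self) -> pd.DataFrame:
        """Per-gene structural features as a data frame."""
        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "union_length_bp": g.union_length_bp,
                "n_union_exons": g.n_union_exons,
                "n_transcripts": g.n_transcripts,
            }
            for g in self
        ]
        return pd.DataFrame(rows).set_index("gene_id")


def merge_intervals(
    intervals: Sequence[GenomicInterval],
) -> list[GenomicInterval]:
    """Flatten intervals into a sorted, disjoint union.

    Overlapping and touching (end == start) intervals are merged; the set of
    covered base positions is preserved exactly.  All intervals must lie on
    one chromosome.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise AnnotationError(f"cannot merge intervals across chromosomes: {chroms}")
    strand = intervals[0].strand
    merged: list[list[int]] = []
    for iv in sorted(intervals, key=lambda i: (i.start, i.end)):
        if merged and iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom = intervals[0].chrom
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise GTFParseError(
                    f"malformed GTF line {lineno}: invalid coordinates "
                    f"{start}..{end}"
                )


def read_gtf(path: str) -> Annotation:
    """Parse a GTF file (GENCODE attribute dialect) into an Annotation.

    Only ``exon`` features are used; transcripts are grouped by
    ``transcript_id`` and genes by ``gene_id``.  GTF 1-based inclusive
    coordinates become 0-based half-open intervals.
    """
    _validate_gtf_lines(str(path))
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_to_gene: dict[str, str] = {}
    for f in db.features_of_type("exon"):
        if "transcript_id" not in f.attributes:
            raise GTFParseError(
                f"rejected exon record at {f.seqid}:{f.start}-{f.end}: "
                "missing transcript_id attribute"
            )
        if "gene_id" not in f.attributes:
            raise GTFParseError(
                f"rejected exon record at {f.seqid}:{f.start}-{f.end}: "
                "missing gene_id attribute"
            )
        tx_id = f.attributes["transcript_id"][0]
        gene_id = f.attributes["gene_id"][0]
        if tx_to_gene.setdefault(tx_id, gene_id) != gene_id:
            raise GTFParseError(
                f"transcript {tx_id} assigned to multiple genes"
            )
        exons_by_tx.setdefault(tx_id, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
    tx_by_gene: dict[str, list[Transcript]] = {}
    for tx_id, exons in exons_by_tx.items():
        gene_id = tx_to_gene[tx_id]
        tx_by_gene.setdefault(gene_id, []).append(
            Transcript(tx_id, gene_id, tuple(exons))
        )
    genes = [
        Gene(gene_id, tuple(sorted(txs, key=lambda t: t.transcript_id)))
        for gene_id, txs in tx_by_gene.items()
    ]
    return Annotation(sorted(genes, key=lambda g: (g.chrom, g.span.start, g.gene_id)))


@dataclass(frozen=True)
class FilterConfig:
    """Gene exclusion rules applied before the quantification comparison.

    Genes are removed if they (a) sit on a mitochondrial chromosome, (b) have
    union exons overlapping another gene's union exons on the same strand,
    (c) never reach ``min_count`` reads in any sample, or (d) have a union
    length below ``min_union_length_bp``.
    """

    min_count: int = 100
    min_union_length_bp: int = 500
    mito_chrom_names: frozenset[str] = frozenset({"chrM", "MT"})
    exclude_same_strand_overlap: bool = True

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_union_length_bp < 0:
            raise AnnotationError("filter thresholds must be non-negative")


def _same_strand_overlapping_genes(annotation: Annotation) -> set[str]:
    """Gene ids whose union exons overlap another gene's on the same strand."""
    by_key: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for g in annotation:
        for e in g.union_exons:
            by_key.setdefault((g.chrom, g.strand), []).append(
                (e.start, e.end, g.gene_id)
            )
    flagged: set[str] = set()
    for items in by_key.values():
        items.sort()
        # sweep: track the furthest-reaching open interval from another gene
        prev_end = -1
        prev_gene = None
        for start, end, gid in items:
            if prev_gene is not None and start < prev_end and gid != prev_gene:
                flagged.add(gid)
                flagged.add(prev_gene)
            if end > prev_end:
                prev_end = end
                prev_gene = gid
    return flagged


def filter_genes(
    annotation: Annotation,
    counts: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[Annotation, dict[str, int]]:
    """Apply the exclusion rules; return surviving genes and a removal tally.

    ``counts`` is a gene × sample table covering every gene in ``annotation``.
    Rules are applied with fixed precedence mito → same-strand overlap →
    low count → short, so each removed gene is tallied exactly once.  A gene
    survives rule (c) iff its count reaches ``min_count`` in at least one
    sample.
    """
    missing = sorted(set(annotation.gene_ids) - set(counts.index))
    if missing:
        raise AnnotationError(
            f"genes missing from counts table: {', '.join(missing)}"
        )
    overlapping = (
        _same_strand_overlapping_genes(annotation)
        if cfg.exclude_same_strand_overlap
        else set()
    )
    tally = {"mito": 0, "same_strand_overlap": 0, "low_count": 0, "short": 0}
    kept: list[Gene] = []
    for g in annotation:
        if g.chrom in cfg.mito_chrom_names:
            tally["mito"] += 1
        elif g.gene_id in overlapping:
            tally["same_strand_overlap"] += 1
        elif counts.loc[g.gene_id].max() < cfg.min_count:
            tally["low_count"] += 1
        elif g.union_length_bp < cfg.min_union_length_bp:
            tally["short"] += 1
        else:
            kept.append(g)
    return Annotation(kept), tally


def structural_features(gene: Gene) -> tuple[int, int]:
    """(number of union exons, number of annotated transcripts) for binning."""
    return gene.n_union_exons, gene.n_transcripts
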