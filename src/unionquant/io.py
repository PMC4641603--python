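"""Plain-text readers and writers: GTF, BED6/BED12, SAM, TSV tables.

Spliced reads are exchanged as BED12, where blockCount/blockSizes/
blockStarts encode the aligned segments, the name column carries the read
id, and the strand column the read strand; or as SAM with N CIGAR
operations for the spanned introns.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pysam

from .annotation import Annotation
from .reads import AlignedRead, SimulatedRead

__all__ = [
    "write_gtf",
    "write_union_bed",
    "write_feature_table",
    "write_bed12",
    "read_bed12",
    "write_sam",
    "write_truth",
    "read_truth",
    "read_counts_tsv",
    "write_counts_tsv",
]


def write_gtf(annotation: Annotation, path: str, source: str = "unionquant") -> None:
    """Write transcripts and exons as GENCODE-dialect GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in annotation:
            for tx in gene.transcripts:
                attrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                span = tx.span
                fh.write(
                    f"{tx.chrom}\t{source}\ttranscript\t{span.start + 1}\t"
                    f"{span.end}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
                for exon in tx.exons:
                    fh.write(
                        f"{exon.chrom}\t{source}\texon\t{exon.start + 1}\t"
                        f"{exon.end}\t.\t{exon.strand}\t.\t{attrs}\n"
                    )


def write_union_bed(annotation: Annotation, path: str) -> None:
    """Union exons as BED6, one record per union exon, name = gene_id."""
    with open(path, "w") as fh:
        for gene in annotation:
            for exon in gene.union_exons:
                fh.write(
                    f"{exon.chrom}\t{exon.start}\t{exon.end}\t"
                    f"{gene.gene_id}\t0\t{exon.strand}\n"
                )


def write_feature_table(annotation: Annotation, path: str) -> None:
    annotation.feature_table().to_csv(path, sep="\t")


def write_bed12(
    reads: Iterable[AlignedRead | SimulatedRead], path: str
) -> None:
    with open(path, "w") as fh:
        for item in reads:
            read = item.read if isinstance(item, SimulatedRead) else item
            start, end = read.start, read.end
            sizes = ",".join(str(e - s) for s, e in read.blocks)
            starts = ",".join(str(s - start) for s, _ in read.blocks)
            fh.write(
                f"{read.chrom}\t{start}\t{end}\t{read.name}\t0\t{read.strand}\t"
                f"{start}\t{end}\t0,0,0\t{len(read.blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed12(path: str, sample: str | None = None) -> list[AlignedRead]:
    """Read spliced alignments from BED12; the sample label defaults to the
    file stem."""
    if sample is None:
        stem = str(path).rsplit("/", 1)[-1]
        sample = stem.rsplit(".", 1)[0]
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: BED12 needs 12 fields, "
                    f"got {len(fields)}"
                )
            chrom, chrom_start, name, strand = (
                fields[0],
                int(fields[1]),
                fields[3],
                fields[5],
            )
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: inconsistent block fields")
            blocks = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            )
            reads.append(AlignedRead(name, chrom, blocks, strand, sample))
    return reads


def _cigar(read: AlignedRead) -> list[tuple[int, int]]:
    ops = []
    prev_end = None
    for s, e in read.blocks:
        if prev_end is not None:
            ops.append((3, s - prev_end))  # N: skipped intron
        ops.append((0, e - s))  # M
        prev_end = e
    return ops


def write_sam(
    reads: Sequence[AlignedRead | SimulatedRead],
    path: str,
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write single-end SAM with N CIGAR operations for spliced gaps."""
    plain = [r.read if isinstance(r, SimulatedRead) else r for r in reads]
    if chrom_sizes is None:
        chrom_sizes = {}
        for r in plain:
            chrom_sizes[r.chrom] = max(chrom_sizes.get(r.chrom, 0), r.end + 1000)
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": chrom_sizes[c]} for c in chroms],
    }
    ref_id = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in plain:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = ref_id[r.chrom]
            a.reference_start = r.start
            a.cigartuples = _cigar(r)
            a.flag = 16 if r.strand == "-" else 0
            a.mapping_quality = 255
            a.query_sequence = "N" * r.aligned_bp
            out.write(a)


def write_truth(reads: Iterable[SimulatedRead], path: str) -> None:
    """Ground-truth TSV: read_id, sample, transcript_id | INTRON_RETENTION."""
    with open(path, "w") as fh:
        fh.write("read_id\tsample\ttruth\n")
        for r in reads:
            fh.write(f"{r.read.name}\t{r.read.sample}\t{r.truth}\n")


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t")
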