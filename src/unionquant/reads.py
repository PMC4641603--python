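"""Aligned-read containers.

An :class:`AlignedRead` is one sequenced fragment as an ordered tuple of
genomic blocks (aligned segments), the fragment strand, and a sample label.
Spliced alignments have one block per exon segment; the gaps between blocks
are the introns spanned by the alignment.  A paired-end fragment is
represented as a single read whose blocks are the union of both mates'
aligned segments, so counting is at the fragment level.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AlignedRead", "SimulatedRead", "INTRON_RETENTION"]

#: Truth label for reads sampled from unspliced pre-mRNA.
INTRON_RETENTION = "INTRON_RETENTION"


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped fragment as sorted, disjoint genomic blocks."""

    name: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    sample: str = "sample1"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.name} has no blocks")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.name}: invalid strand {self.strand!r}")
        prev_end = None
        for start, end in self.blocks:
            if start >= end:
                raise ValueError(f"read {self.name}: empty block [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"read {self.name}: blocks unsorted or overlapping"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def aligned_bp(self) -> int:
        """Total aligned bases across blocks."""
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class SimulatedRead:
    """An aligned read plus its ground truth: the originating transcript id,
    or :data:`INTRON_RETENTION` for pre-mRNA reads."""

    read: AlignedRead
    truth: str
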