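"""Synthetic annotations, expression profiles, and stranded spliced reads.

The generator emulates the statistical structure of a stranded two-group
reference-RNA experiment: multi-isoform genes with varying exon structure,
fragments sampled uniformly along expressed transcript molecules, a tunable
fraction of intron-retention (IR) reads drawn from unspliced pre-mRNA, and
2-vs-2 replicate designs.  Every read carries its ground-truth transcript of
origin (or an IR flag), so downstream counting and EM estimates can be
checked against truth.

Generative model
----------------
An :class:`ExpressionProfile` gives molecule fractions θ_t per transcript.
Under uniform fragmentation a molecule of effective length
ℓ̃_t = L_t − f + 1 (f = fragment length) yields fragments in proportion to
ℓ̃_t, so the transcript of origin of each emitted fragment is drawn with
probability ∝ θ_t · ℓ̃_t and its start uniformly over the ℓ̃_t valid
positions.  Fragment coordinates are projected through the exon chain to
genomic blocks, producing exon-exon junction reads whenever a fragment
crosses an intron.

With probability ``intron_retention_rate`` a fragment is instead drawn from
its gene's unspliced span, rejection-sampled until it covers at least one
intronic base (a fully exonic draw would be indistinguishable from a spliced
read).  IR reads carry no transcript truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .annotation import Annotation, Gene, GenomicInterval, Transcript
from .reads import INTRON_RETENTION, AlignedRead, SimulatedRead

__all__ = [
    "SimConfig",
    "ExpressionProfile",
    "Scenario",
    "simulate_annotation",
    "simulate_reads",
    "scenario_presets",
    "short_intron_annotation",
    "PRESET_NAMES",
]

PRESET_NAMES = ("fig1", "fig9", "short_dominant", "isoform_switch", "mixed")


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-protocol parameters for the read simulator.

    ``strand_protocol`` follows stranded library conventions: under
    ``reverse`` (dUTP-style, the default) reads are antisense to their
    transcript; ``forward`` reads share the transcript strand; ``unstranded``
    assigns strands at random.
    """

    seed: int = 42
    read_length_bp: int = 75
    paired: bool = False
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    strand_protocol: str = "reverse"
    intron_retention_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length_bp < 1:
            raise ValueError("read_length_bp must be >= 1")
        if not 0.0 <= self.intron_retention_rate <= 1.0:
            raise ValueError("intron_retention_rate must be in [0, 1]")
        if self.strand_protocol not in ("unstranded", "forward", "reverse"):
            raise ValueError(f"unknown strand_protocol {self.strand_protocol!r}")

    @property
    def fragment_span_bp(self) -> int:
        """Nominal span of one fragment along the transcript."""
        if self.paired:
            return int(round(self.fragment_length_mean))
        return self.read_length_bp


@dataclass(frozen=True)
class ExpressionProfile:
    """True molecule fractions θ_t per transcript for one sample."""

    sample: str
    theta: Mapping[str, float]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        vals = np.asarray(list(self.theta.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("theta values must be non-negative")
        total = vals.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"theta must sum to 1, got {total:.6f}")


def _read_strand(gene_strand: str, protocol: str, rng: np.random.Generator) -> str:
    if protocol == "forward":
        return gene_strand
    if protocol == "reverse":
        return "-" if gene_strand == "+" else "+"
    return "+" if rng.random() < 0.5 else "-"


def _default_isoform_counts(rng: np.random.Generator) -> int:
    # mean ~7 isoforms per multi-isoform gene, matching a GENCODE-like census
    return 1 + min(int(rng.poisson(6)), 11)


def simulate_annotation(
    n_genes: int,
    isoform_count_distribution: Callable[[np.random.Generator], int] | None = None,
    exon_length_menu: Sequence[int] = (150, 300, 500, 1000, 2000),
    intron_length_menu: Sequence[int] = (200, 500, 1500),
    seed: int = 42,
    chrom: str = "chrS",
    gene_gap_bp: int = 10_000,
) -> Annotation:
    """Generate a synthetic annotation on one virtual chromosome.

    Genes are laid out left to right with ``gene_gap_bp`` between them so no
    two genes overlap on the same strand.  Each gene has an exon chain with
    lengths drawn from ``exon_length_menu``; its first isoform is the full
    chain and further isoforms keep the terminal exons and drop internal
    exons at random, so all isoforms share a subset of the gene's exon chain.
    Deterministic under a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    iso_dist = isoform_count_distribution or _default_isoform_counts
    rng = np.random.default_rng(seed)
    cursor = 10_000
    genes = []
    for gi in range(n_genes):
        gene_id = f"SIMG{gi + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_iso = max(1, int(iso_dist(rng)))
        n_exons = 1 if (n_iso == 1 and rng.random() < 0.25) else int(rng.integers(2, 11))
        if n_exons == 1:
            n_iso = 1
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.choice(exon_length_menu))
            exons.append(GenomicInterval(chrom, pos, pos + length, strand))
            pos += length + int(rng.choice(intron_length_menu))
        chains: list[tuple[int, ...]] = [tuple(range(n_exons))]
        attempts = 0
        while len(chains) < n_iso and attempts < 50:
            attempts += 1
            keep = [0] + [
                i for i in range(1, n_exons - 1) if rng.random() < 0.65
            ] + ([n_exons - 1] if n_exons > 1 else [])
            chain = tuple(sorted(set(keep)))
            length = sum(exons[i].length for i in chain)
            if chain not in chains and length >= 200:
                chains.append(chain)
        transcripts = tuple(
            Transcript(
                f"{gene_id}.T{ti + 1}",
                gene_id,
                tuple(exons[i] for i in chain),
            )
            for ti, chain in enumerate(chains)
        )
        genes.append(Gene(gene_id, transcripts))
        cursor = exons[-1].end + gene_gap_bp
    return Annotation(genes)


def short_intron_annotation(
    n_genes: int = 5,
    exon_length_bp: int = 1000,
    intron_length_bp: int = 40,
    n_exons: int = 3,
    read_length_bp: int = 75,
    min_overlap_bp: int = 18,
    chrom: str = "chrS",
) -> Annotation:
    """Single-isoform genes whose introns are short enough that every
    intron-overlapping read keeps >= ``min_overlap_bp`` exonic bases.

    With intron length below ``read_length_bp - min_overlap_bp`` every IR
    read is counted by the union-exon counter yet incompatible with the
    spliced transcript, isolating the counting asymmetry between the two
    quantification routes.
    """
    if intron_length_bp > read_length_bp - min_overlap_bp:
        raise ValueError(
            "introns must be shorter than read_length_bp - min_overlap_bp"
        )
    genes = []
    cursor = 10_000
    for gi in range(n_genes):
        gene_id = f"IRG{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        pos = cursor
        for _ in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + exon_length_bp, strand))
            pos += exon_length_bp + intron_length_bp
        tx = Transcript(f"{gene_id}.T1", gene_id, tuple(exons))
        genes.append(Gene(gene_id, (tx,)))
        cursor = exons[-1].end + 10_000
    return Annotation(genes)


def _project_to_blocks(
    transcript: Transcript, tx_start: int, tx_end: int
) -> tuple[tuple[int, int], ...]:
    """Map a transcript-coordinate window [tx_start, tx_end) to genomic blocks."""
    blocks = []
    offset = 0
    for exon in transcript.exons:
        exon_lo = offset
        exon_hi = offset + exon.length
        lo = max(tx_start, exon_lo)
        hi = min(tx_end, exon_hi)
        if lo < hi:
            blocks.append((exon.start + lo - exon_lo, exon.start + hi - exon_lo))
        offset = exon_hi
        if offset >= tx_end:
            break
    return tuple(blocks)


def _merge_touching(blocks: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    out: list[list[int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return tuple((s, e) for s, e in out)


def _fragment_blocks(
    transcript: Transcript, start: int, cfg: SimConfig, frag_len: int
) -> tuple[tuple[int, int], ...]:
    """Genomic blocks of a fragment starting at transcript coordinate ``start``."""
    read_len = cfg.read_length_bp
    if not cfg.paired or frag_len <= 2 * read_len:
        window = min(frag_len, transcript.length_bp - start)
        return _project_to_blocks(transcript, start, start + window)
    left = _project_to_blocks(transcript, start, start + read_len)
    right = _project_to_blocks(
        transcript, start + frag_len - read_len, start + frag_len
    )
    return _merge_touching(list(left) + list(right))


def _gene_intron_positions(gene: Gene) -> list[tuple[int, int]]:
    return [(iv.start, iv.end) for iv in gene.introns]


def _draw_ir_read(
    gene: Gene, cfg: SimConfig, rng: np.random.Generator, max_tries: int = 10_000
) -> tuple[tuple[int, int], ...]:
    """A single-block read on the unspliced span covering >= 1 intron base."""
    span = gene.span
    read_len = cfg.read_length_bp
    if span.length < read_len:
        raise ValueError(f"gene {gene.gene_id} span shorter than read length")
    introns = _gene_intron_positions(gene)
    if not introns:
        raise ValueError(f"gene {gene.gene_id} has no introns for IR sampling")
    for _ in range(max_tries):
        s = int(rng.integers(span.start, span.end - read_len + 1))
        e = s + read_len
        if any(s < ie and istart < e for istart, ie in introns):
            return ((s, e),)
    raise RuntimeError(
        f"could not place an intron-overlapping read on gene {gene.gene_id}"
    )


def simulate_reads(
    annotation: Annotation,
    profile: ExpressionProfile,
    cfg: SimConfig = SimConfig(),
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Emit exactly ``profile.library_size`` reads with ground truth.

    Transcript of origin is drawn with probability ∝ θ_t·ℓ̃_t and the
    fragment start uniformly over the transcript's valid positions; genomic
    blocks are obtained by projecting the fragment through the exon chain.
    With probability ``cfg.intron_retention_rate`` a read is instead an IR
    read on its gene's unspliced span.  Deterministic under ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tx_lookup = annotation.transcripts
    unknown = sorted(set(profile.theta) - set(tx_lookup))
    if unknown:
        raise ValueError(f"profile transcripts not in annotation: {unknown}")

    frag_span = cfg.fragment_span_bp
    tx_ids, weights = [], []
    for tx_id, theta in sorted(profile.theta.items()):
        if theta <= 0:
            continue
        tx = tx_lookup[tx_id]
        eff = tx.length_bp - frag_span + 1
        if eff < 1:
            warnings.warn(
                f"transcript {tx_id} (length {tx.length_bp}) shorter than the "
                f"fragment span {frag_span}; skipped and its mass re-drawn",
                stacklevel=2,
            )
            continue
        tx_ids.append(tx_id)
        weights.append(theta * eff)
    if not tx_ids:
        raise ValueError("no expressed transcript is long enough to sequence")
    probs = np.asarray(weights, dtype=float)
    probs /= probs.sum()

    n_total = profile.library_size
    n_ir = int(rng.binomial(n_total, cfg.intron_retention_rate))
    n_main = n_total - n_ir
    per_tx = rng.multinomial(n_main, probs)

    # IR reads come from genes that actually have introns, weighted as above
    ir_gene_ids: list[str] = []
    if n_ir > 0:
        has_intron = np.array(
            [
                len(annotation.gene_of_transcript(t).introns) > 0
                for t in tx_ids
            ]
        )
        if not has_intron.any():
            raise ValueError(
                "intron_retention_rate > 0 but no expressed gene has introns"
            )
        ir_probs = probs * has_intron
        ir_probs /= ir_probs.sum()
        ir_tx_counts = rng.multinomial(n_ir, ir_probs)
        for t, c in zip(tx_ids, ir_tx_counts):
            ir_gene_ids.extend([annotation.transcript_to_gene[t]] * c)

    reads: list[SimulatedRead] = []
    serial = 0
    for tx_id, count in zip(tx_ids, per_tx):
        if count == 0:
            continue
        tx = tx_lookup[tx_id]
        gene_strand = tx.strand
        n_valid = tx.length_bp - frag_span + 1
        starts = rng.integers(0, n_valid, size=count)
        if cfg.paired:
            frag_lens = np.clip(
                rng.normal(cfg.fragment_length_mean, cfg.fragment_length_sd, count),
                cfg.read_length_bp,
                tx.length_bp,
            ).astype(int)
        else:
            frag_lens = np.full(count, cfg.read_length_bp)
        for s, fl in zip(starts, frag_lens):
            blocks = _fragment_blocks(tx, int(s), cfg, int(fl))
            serial += 1
            read = AlignedRead(
                name=f"{profile.sample}_read{serial:07d}",
                chrom=tx.chrom,
                blocks=blocks,
                strand=_read_strand(gene_strand, cfg.strand_protocol, rng),
                sample=profile.sample,
            )
            reads.append(SimulatedRead(read, tx_id))
    for gene_id in ir_gene_ids:
        gene = annotation[gene_id]
        blocks = _draw_ir_read(gene, cfg, rng)
        serial += 1
        read = AlignedRead(
            name=f"{profile.sample}_read{serial:07d}",
            chrom=gene.chrom,
            blocks=blocks,
            strand=_read_strand(gene.strand, cfg.strand_protocol, rng),
            sample=profile.sample,
        )
        reads.append(SimulatedRead(read, INTRON_RETENTION))
    assert len(reads) == n_total
    return reads


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation scenario: annotation, per-condition
    replicate expression profiles, and a sequencing configuration."""

    name: str
    annotation: Annotation
    conditions: Mapping[str, tuple[ExpressionProfile, ...]]
    config: SimConfig

    def simulate(self, seed: int | None = None) -> dict[str, list[SimulatedRead]]:
        """Simulate every sample; per-sample seeds derive from ``seed``."""
        base = self.config.seed if seed is None else seed
        out: dict[str, list[SimulatedRead]] = {}
        offset = 0
        for profiles in self.conditions.values():
            for profile in profiles:
                offset += 1
                cfg = replace(self.config, seed=(base + 7919 * offset) % (2**31))
                out[profile.sample] = simulate_reads(
                    self.annotation, profile, cfg
                )
        return out


def _gene_from_chains(
    gene_id: str,
    chrom: str,
    strand: str,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    chains: Sequence[Sequence[int]],
    origin: int = 10_000,
) -> Gene:
    exons = []
    pos = origin
    for i, length in enumerate(exon_lengths):
        exons.append(GenomicInterval(chrom, pos, pos + length, strand))
        pos += length
        if i < len(exon_lengths) - 1:
            pos += intron_lengths[i]
    txs = tuple(
        Transcript(f"{gene_id}.T{ti + 1}", gene_id, tuple(exons[i] for i in chain))
        for ti, chain in enumerate(chains)
    )
    return Gene(gene_id, txs)


def _replicates(
    condition: str, theta: Mapping[str, float], library_size: int, n: int = 2
) -> tuple[ExpressionProfile, ...]:
    return tuple(
        ExpressionProfile(f"{condition}_rep{i + 1}", dict(theta), library_size)
        for i in range(n)
    )


def scenario_presets(
    name: str,
    seed: int = 42,
    library_size: int | None = None,
    intron_retention_rate: float = 0.0,
    n_genes: int = 200,
) -> Scenario:
    """Named scenarios exercising the quantification pipeline.

    - ``fig1``: one gene; isoform #1 has exons of 2/1/2 kb and isoform #2
      skips the middle exon, so flattening yields union exons of 2/1/2 kb.
    - ``fig9``: one gene; isoform #a (exons 2 kb + 1 kb) skips exon #2 of
      isoform #b (2/2/1 kb); condition A expresses only #a, condition B only
      #b.
    - ``short_dominant``: a 3-isoform gene whose shortest isoform carries
      85% of the molecules while a long isoform dominates the union length.
    - ``isoform_switch``: a two-isoform gene with θ = (1, 0) in condition A
      and (0.25, 0.75) in condition B over near-equal-length isoforms (gene
      totals stay matched), plus stable single-isoform background genes.
    - ``mixed``: a random multi-gene annotation with Dirichlet expression,
      identical in both conditions.

    Each scenario carries a 2-vs-2 replicate design.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    cfg = SimConfig(seed=seed, intron_retention_rate=intron_retention_rate)

    if name == "fig1":
        gene = _gene_from_chains(
            "FIG1G", "chr1", "+",
            exon_lengths=(2000, 1000, 2000),
            intron_lengths=(1000, 1000),
            chains=((0, 1, 2), (0, 2)),
        )
        ann = Annotation([gene])
        theta = {"FIG1G.T1": 0.5, "FIG1G.T2": 0.5}
        lib = library_size or 10_000
        conditions = {
            "A": _replicates("A", theta, lib),
            "B": _replicates("B", theta, lib),
        }
        return Scenario(name, ann, conditions, cfg)

    if name == "fig9":
        # exon #1 and #2 twice as long as exon #3; isoform a skips exon #2
        gene = _gene_from_chains(
            "FIG9G", "chr1", "+",
            exon_lengths=(2000, 2000, 1000),
            intron_lengths=(1000, 1000),
            chains=((0, 2), (0, 1, 2)),  # T1 = isoform a, T2 = isoform b
        )
        ann = Annotation([gene])
        lib = library_size or 10_000
        conditions = {
            "A": _replicates("A", {"FIG9G.T1": 1.0, "FIG9G.T2": 0.0}, lib),
            "B": _replicates("B", {"FIG9G.T1": 0.0, "FIG9G.T2": 1.0}, lib),
        }
        return Scenario(name, ann, conditions, cfg)

    if name == "short_dominant":
        gene = _gene_from_chains(
            "SDOMG", "chr1", "+",
            exon_lengths=(500, 350, 3800),
            intron_lengths=(700, 700),
            chains=((0,), (1,), (0, 1, 2)),
        )
        ann = Annotation([gene])
        # T2 (350 bp) is the shortest isoform and dominates expression
        theta = {"SDOMG.T1": 0.10, "SDOMG.T2": 0.85, "SDOMG.T3": 0.05}
        lib = library_size or 30_000
        conditions = {
            "A": _replicates("A", theta, lib),
            "B": _replicates("B", theta, lib),
        }
        return Scenario(name, ann, conditions, cfg)

    if name == "isoform_switch":
        switch = _gene_from_chains(
            "SWCHG", "chr1", "+",
            exon_lengths=(1500, 100, 1500),
            intron_lengths=(800, 800),
            chains=((0, 1, 2), (0, 2)),  # T1 = long, T2 = short (skips exon 2)
        )
        background = simulate_annotation(
            n_genes=30,
            isoform_count_distribution=lambda rng: 1,
            exon_length_menu=(1000, 2000),
            seed=seed,
            chrom="chrS",
        )
        ann = Annotation([switch, *background])
        bg_txs = [t for t in ann.transcripts if not t.startswith("SWCHG")]
        bg_theta = {t: 0.75 / len(bg_txs) for t in bg_txs}
        theta_a = {"SWCHG.T1": 0.25, "SWCHG.T2": 0.0, **bg_theta}
        theta_b = {"SWCHG.T1": 0.0625, "SWCHG.T2": 0.1875, **bg_theta}
        lib = library_size or 10_000
        conditions = {
            "A": _replicates("A", theta_a, lib),
            "B": _replicates("B", theta_b, lib),
        }
        return Scenario(name, ann, conditions, cfg)

    # mixed
    ann = simulate_annotation(n_genes=n_genes, seed=seed)
    rng = np.random.default_rng(seed + 1)
    tx_ids = sorted(ann.transcripts)
    theta_vals = rng.dirichlet(np.ones(len(tx_ids)))
    theta = dict(zip(tx_ids, theta_vals))
    lib = library_size or 50_000
    conditions = {
        "A": _replicates("A", theta, lib),
        "B": _replicates("B", theta, lib),
    }
    return Scenario(name, ann, conditions, cfg)
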