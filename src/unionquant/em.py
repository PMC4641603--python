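"""Transcript-level abundance estimation by expectation-maximization.

Reads are first assigned to transcripts under strict compatibility: a read
is compatible with an isoform iff every alignment block lies within the
isoform's exons and every gap between consecutive blocks coincides exactly
with one of its introns (and the strand matches the library protocol).
Reads compatible with no isoform — intron-retention reads in particular —
are dropped.

The EM then treats each read as drawn from a mixture over its compatible
transcripts with per-read density θ_t/ℓ̃_t, where ℓ̃_t is the transcript's
effective length.  Starting from uniform abundances, the E-step splits each
read fractionally across its compatible transcripts in proportion to
θ_t/ℓ̃_t, the M-step re-estimates θ from the fractional counts, and the two
steps repeat until the abundances stop moving.  Expected counts ĉ_t are the
final fractional read assignments; they conserve the number of compatible
reads exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotation import Annotation, Transcript
from .counting import UnionIndex
from .reads import AlignedRead

__all__ = [
    "CompatibilityMatrix",
    "IsoformEstimate",
    "effective_length",
    "is_compatible",
    "build_compatibility",
    "em_quantify",
    "gene_counts_from_isoforms",
]


def effective_length(
    length_bp: int, fragment_length_bp: int = 75, mode: str = "corrected"
) -> float:
    """Effective transcript length ℓ̃.

    ``corrected`` (default) counts valid fragment start positions,
    max(1, L − f + 1); ``plain`` returns L itself, matching RPKM arithmetic
    that divides by the annotated transcript length.
    """
    if mode == "plain":
        return float(max(1, length_bp))
    if mode == "corrected":
        return float(max(1, length_bp - fragment_length_bp + 1))
    raise ValueError(f"unknown effective-length mode {mode!r}")


def is_compatible(read: AlignedRead, transcript: Transcript) -> bool:
    """Strict containment: blocks within exons, gaps exactly the introns."""
    exons = transcript.exons
    # locate the exon containing each block
    exon_idx: list[int] = []
    for bstart, bend in read.blocks:
        hit = -1
        for i, exon in enumerate(exons):
            if exon.start <= bstart and bend <= exon.end:
                hit = i
                break
        if hit < 0:
            return False
        exon_idx.append(hit)
    for (b1, b2), (i1, i2) in zip(
        zip(read.blocks, read.blocks[1:]), zip(exon_idx, exon_idx[1:])
    ):
        # a gap must be exactly the intron between consecutive exons
        if i2 != i1 + 1:
            return False
        if b1[1] != exons[i1].end or b2[0] != exons[i2].start:
            return False
    return True


@dataclass
class CompatibilityMatrix:
    """Reads collapsed into equivalence classes of compatible-transcript sets.

    ``classes`` maps a frozenset of transcript ids to the number of reads
    with exactly that compatible set; ``eff_lengths`` covers every transcript
    in the quantification universe.  Reads with an empty compatible set are
    dropped and tallied in ``n_dropped``.
    """

    classes: dict[frozenset, int]
    eff_lengths: dict[str, float]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for cls in self.classes:
            if not cls:
                raise ValueError("empty compatibility class must be dropped")
            unknown = set(cls) - set(self.eff_lengths)
            if unknown:
                raise ValueError(f"class references unknown transcripts: {unknown}")
        if any(l < 1 for l in self.eff_lengths.values()):
            raise ValueError("effective lengths must be >= 1")

    @property
    def n_reads(self) -> int:
        """Number of compatible (non-dropped) reads."""
        return sum(self.classes.values())


def build_compatibility(
    reads: Iterable[AlignedRead],
    annotation: Annotation,
    strand_mode: str = "reverse",
    eff_length_mode: str = "corrected",
    fragment_length_bp: int = 75,
) -> CompatibilityMatrix:
    """Compute each read's compatible-transcript set against the annotation.

    Candidate genes are found by union-exon overlap; each candidate gene's
    isoforms are tested for strict compatibility and strand agreement.
    """
    index = UnionIndex(annotation)
    classes: dict[frozenset, int] = {}
    n_dropped = 0
    for read in reads:
        compatible: list[str] = []
        for gene_id in index.gene_overlaps(read):
            if not index.strand_compatible(read, gene_id, strand_mode):
                continue
            for tx in annotation[gene_id].transcripts:
                if is_compatible(read, tx):
                    compatible.append(tx.transcript_id)
        if compatible:
            key = frozenset(compatible)
            classes[key] = classes.get(key, 0) + 1
        else:
            n_dropped += 1
    eff_lengths = {
        t.transcript_id: effective_length(
            t.length_bp, fragment_length_bp, eff_length_mode
        )
        for t in annotation.transcripts.values()
    }
    return CompatibilityMatrix(classes, eff_lengths, n_dropped)


@dataclass
class IsoformEstimate:
    """EM output: abundances θ̂, expected counts ĉ, and convergence state.

    ``theta`` holds molecule-fraction abundances, obtained from the fitted
    mixture weights by dividing out effective length and renormalizing
    (θ̂_t ∝ ĉ_t/ℓ̃_t); ``read_fractions`` holds the raw mixture weights
    ĉ_t/N themselves.  Both sum to one over the transcript universe.
    """

    theta: pd.Series
    read_fractions: pd.Series
    expected_counts: pd.Series
    eff_lengths: pd.Series
    n_iterations: int
    converged: bool
    log_likelihood_trace: tuple[float, ...] = field(default=(), repr=False)


def em_quantify(
    cm: CompatibilityMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> IsoformEstimate:
    """Run the EM to convergence (max |Δθ| < ``tol``) or ``max_iter``.

    Initialization is uniform over the transcript universe; iteration order
    is deterministic, so results are reproducible.  If ``max_iter`` is
    reached the estimate is still returned with ``converged=False``.
    """
    if not cm.classes:
        raise ValueError("no read with a non-empty compatibility set")
    tx_ids = sorted(cm.eff_lengths)
    tx_index = {t: i for i, t in enumerate(tx_ids)}
    n_tx = len(tx_ids)
    class_items = sorted(cm.classes.items(), key=lambda kv: sorted(kv[0]))
    n_cls = len(class_items)
    counts = np.array([c for _, c in class_items], dtype=float)
    rows, cols = [], []
    for ci, (cls, _) in enumerate(class_items):
        for t in cls:
            rows.append(ci)
            cols.append(tx_index[t])
    membership = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cls, n_tx)
    )
    inv_len = 1.0 / np.array([cm.eff_lengths[t] for t in tx_ids])
    n_reads = counts.sum()

    alpha = np.full(n_tx, 1.0 / n_tx)  # mixture weight = expected read share
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rho = alpha * inv_len
        dens = membership @ rho  # per-class mixture density
        trace.append(float(counts @ np.log(dens)))
        expected = rho * (membership.T @ (counts / dens))
        new_alpha = expected / n_reads
        delta = np.max(np.abs(new_alpha - alpha))
        alpha = new_alpha
        if delta < tol:
            converged = True
            break
    rho = alpha * inv_len
    dens = membership @ rho
    trace.append(float(counts @ np.log(dens)))
    expected = rho * (membership.T @ (counts / dens))
    theta = alpha * inv_len
    theta = theta / theta.sum()
    return IsoformEstimate(
        theta=pd.Series(theta, index=tx_ids, name="theta"),
        read_fractions=pd.Series(alpha, index=tx_ids, name="read_fraction"),
        expected_counts=pd.Series(expected, index=tx_ids, name="expected_count"),
        eff_lengths=pd.Series(
            [cm.eff_lengths[t] for t in tx_ids], index=tx_ids, name="eff_length"
        ),
        n_iterations=n_iter,
        converged=converged,
        log_likelihood_trace=tuple(trace),
    )


def gene_counts_from_isoforms(
    estimates: IsoformEstimate | Mapping[str, float] | pd.Series,
    annotation: Annotation,
) -> pd.Series:
    """Sum per-transcript expected counts into per-gene counts.

    Genes with no estimated transcript get zero.
    """
    if isinstance(estimates, IsoformEstimate):
        tx_counts = estimates.expected_counts
    else:
        tx_counts = pd.Series(dict(estimates), dtype=float)
    out = dict.fromkeys(annotation.gene_ids, 0.0)
    for tx_id, count in tx_counts.items():
        out[annotation.transcript_to_gene[tx_id]] += float(count)
    series = pd.Series(out, name="rsem_count")
    series.index.name = "gene_id"
    return series
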