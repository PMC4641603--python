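# Methods

## Annotation model and union-exon flattening

Genes are sets of transcript isoforms; each isoform is an ordered chain of
disjoint exons on one chromosome and strand. All coordinates are 0-based
half-open internally; GTF's 1-based inclusive convention is converted at
the parsing boundary so length arithmetic is unambiguous. Union exons are
the merged, disjoint cover of all exonic bases of a gene; touching
intervals (end == start) merge, since zero-length gaps are annotation
artifacts rather than introns. GTF parsing is delegated to gffutils with
an in-memory database; only `exon` features with `gene_id` and
`transcript_id` attributes are used.

Gene filtering applies four exclusion rules with fixed precedence
(mitochondrial chromosome → same-strand union-exon overlap with another
gene → low count → short union length), so each removed gene is tallied
under exactly one rule. The low-count rule keeps a gene iff its count
reaches `min_count` (default 100) in at least one sample — the most
literal reading of "no appreciable expression in any sample" — and the
length boundary keeps genes at exactly `min_union_length_bp` (default
500). Same-strand overlap means ≥ 1 shared exonic base between two genes'
union exons; both members of an overlapping pair are removed, because a
partial-overlap counter cannot attribute reads between them.

## Read simulator

The simulator emulates a stranded, deeply sequenced two-group reference
RNA experiment with 2 + 2 replicates: 75 bp reads, reverse-stranded
protocol (reads antisense to their transcript), uniquely mapped fragments
only. It makes no attempt to model sequencing error, positional/GC bias,
or multi-mapping reads; conclusions from the test suite therefore concern
the counting and estimation semantics, not robustness to alignment noise.

Expression is parameterized by molecule fractions θ_t per transcript.
Under uniform fragmentation, a molecule of effective length
ℓ̃_t = L_t − f + 1 (f = fragment span; 75 bp single-end by default)
yields fragments in proportion to ℓ̃_t, so each fragment's transcript of
origin is drawn ∝ θ_t·ℓ̃_t and its start uniformly over the ℓ̃_t valid
positions; transcript coordinates are projected through the exon chain to
genomic blocks, producing junction-spanning reads. Paired-end fragments
are represented as a single read whose blocks are the union of both
mates' segments, so all counting is at fragment level. Transcripts
shorter than the fragment span are skipped with a warning and their mass
re-drawn from the remaining transcripts.

Intron-retention (IR) reads are emitted with probability
`intron_retention_rate`: a single-block read placed uniformly on the
gene's unspliced span, rejection-sampled until it covers at least one
intronic base — a fully exonic placement would be indistinguishable from
a spliced read, and an IR read is by definition one with intronic aligned
bases. IR reads carry no transcript truth. The exact library size is
always emitted, and all randomness flows through one seeded generator, so
outputs are byte-identical across runs at a fixed seed.

`short_intron_annotation` provides a geometry (1 kb exons, 40 bp introns,
single-isoform genes) in which every intron-overlapping read retains at
least 75 − 40 = 35 exonic bases, hence is union-counted at the 18 bp
threshold while remaining incompatible with the spliced transcript. On
that geometry the union/EM total-count ratio has expectation exactly
1/(1 − IR rate), isolating the intron-retention counting asymmetry.

Preset scenarios fix the structures used throughout the tests: a
three-exon gene (2/1/2 kb) with a skipped middle exon; a two-isoform gene
whose short form skips a 2 kb internal exon (exons #1 and #2 twice the
length of exon #3); a three-isoform gene whose shortest isoform carries
85% of molecules while a 4.65 kb isoform sets the union length; an
isoform-switch gene whose two near-equal-length isoforms (differing by a
100 bp cassette exon) swap dominance between conditions while gene-level
read totals stay matched, on top of 30 stable single-isoform background
genes; and a 200-gene random annotation with Dirichlet expression. Default
library sizes (10–50 k reads per sample; 100 k where an accuracy bound is
asserted) keep the full suite under half a minute on one CPU while leaving
binomial sampling error well inside the asserted tolerances.

## Union-exon counting

A read's overlap with a gene is the number of aligned bases falling in
the gene's union exons, summed over alignment blocks. A gene qualifies
iff this overlap reaches `min_overlap_bp` (default 18) and the strand is
compatible with the library protocol (default reverse). Exactly one
qualifying gene assigns the read; two or more make it ambiguous
(excluded); none leaves it unassigned. The ambiguity rule requires each
competing gene to independently meet the threshold — a dialect choice
consistent with the qualification rule. Raising the threshold can only
shrink counts (asserted as a property test), and the implementation is
checked read-for-read against a per-base set-intersection oracle.

## EM isoform quantification

Compatibility is strict containment: every block inside the isoform's
exons, and every inter-block gap exactly one of its introns. Reads with
empty compatible sets (IR reads, in particular) are dropped, which is the
second counting asymmetry against the union route: union totals exceed EM
totals whenever IR reads overlap exons sufficiently.

Reads are collapsed into equivalence classes by compatible set. The EM is
the standard mixture fit: mixture weight α_t (expected read share) with
per-read density α_t/ℓ̃_t, uniform initialization, E-step
responsibilities ∝ α_t/ℓ̃_t over the read's compatible set, M-step
α_t = ĉ_t/N. Iteration stops when max|Δα| < 1e-8 (default) or after
1000 iterations, returning `converged=False` in the latter case; the
observed-data log-likelihood is recorded every iteration and is
non-decreasing. Reported abundances are molecule fractions
θ̂_t ∝ ĉ_t/ℓ̃_t (the length-normalized mixture weights), matching the
simulator's parameterization; the raw read shares are also exposed.
Expected counts conserve the number of compatible reads exactly at every
iteration. Effective length defaults to max(1, L − f + 1) and can be
switched to plain L for textbook RPKM arithmetic. No random restarts are
used — with deterministic iteration order the fit is reproducible — and
posterior sampling, credibility intervals and multi-mapping handling are
out of scope.

One numerical caveat: when the likelihood maximizer sits on the boundary
of the simplex (e.g. all reads explainable by one isoform with no unique
evidence for the other), EM approaches the boundary sublinearly; the
oracle-agreement tests therefore raise `max_iter` rather than loosening
the default tolerance.

## Expression measures and comparisons

RPKM and TPM follow their defining formulas; per-sample totals N default
to the respective method's own counted total (a method-specific
denominator), with any shared value accepted where cross-method
comparability matters. The transcript-sum gene RPKM is at least the
union-length gene RPKM for every gene and sample (union length ≥ each
transcript length), with equality for single-isoform genes — both
asserted numerically.

Expression ratios add a 0.01 background to numerator and denominator
before dividing (avoiding 0/0 and division by zero) and are printed at
two decimals while all internal math stays at full precision. Scatter
transforms use log2(RPKM + 0.5). Structural binning sorts genes by a
feature (union-exon count or isoform count) and cuts quantile bins that
never split ties; 10 bins is the default. The underestimation test is a
paired two-sided t-test on per-sample mean RPKMs — the package's own
choice of test, with degenerate zero-variance differences mapped to
(statistic 0, p 1) for identical vectors. No between-sample normalization
(TMM, quantile) is applied anywhere: all compared quantities are
within-sample.

## Differential expression

The DE caller is deliberately simple: CPM scaling, fold change from group
mean CPMs with a 0.5 pseudo-value, a two-sample t-test on
log2(CPM + 0.5), Benjamini-Hochberg adjustment (via statsmodels, checked
against an explicit min-over-suffix oracle), and the joint call
|log2FC| ≥ log2(1.5) and adjusted p < 0.05 on raw (unshrunken) fold
changes. It is a stand-in for count-model testing (negative-binomial or
precision-weighted fits), and `test_fn` is pluggable so externally
computed p-values can drive the same thresholds and set intersection. The
quantity of interest is the intersection analysis: the gene-level DE set
versus the set of genes owning at least one DE transcript, whose
asymmetric difference captures isoform switches and minor-isoform changes
that cancel in gene totals.

## Known limitations

- The simulator's uniform-fragment model understates the EM's difficulty
  on real libraries with coverage bias; recovery bounds (|θ̂ − θ| < 0.02
  at 10⁵ reads) hold for the modeled conditions only.
- The EM does not use junction-read counts or coverage patterns beyond
  what strict compatibility encodes, so low-expressed isoforms of
  structure-sharing genes absorb spillover reads at low depth.
- The t-test DE stand-in with two replicates per group is underpowered
  and not variance-moderated; it suffices for the large simulated effects
  but is not a recommendation for real data.
- Multi-chromosome genes, CDS/UTR features and gene biotypes are not
  modeled.
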