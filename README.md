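# unionquant

RNA-seq gene expression is usually summarized one of two ways. The
*union-exon* route flattens all isoforms of a gene into merged "union
exons", counts every read that overlaps them sufficiently, and divides by
the total union-exon length. The *transcript-based* route first distributes
reads among isoforms with an EM algorithm, computes per-isoform RPKM over
each isoform's own spliced length, and sums those within the gene. The two
answers can differ several-fold: whenever a short isoform carries most of a
gene's expression, dividing its reads by the much longer union length
systematically underestimates the gene's mRNA abundance. The two routes
also treat reads differently — partial-overlap counters keep
intron-retention reads that strict isoform quantifiers drop — and
gene-level differential testing can mask isoform switches that
transcript-level testing exposes.

`unionquant` implements both quantification routes side by side, the
expression measures that compare them, and a spliced-read simulator with
ground truth so every claim is testable in silico. It is aimed at
bioinformaticians who want to understand (or demonstrate) how the choice of
gene-quantification strategy shapes expression estimates and downstream
differential calls.

## What it computes

For a gene *g* with union-exon length *L_g*, isoforms *t* with spliced
lengths *ℓ_t*, read counts *c* and *N* total counted reads in a sample
(RPKM = c / ((L/10³)·(N/10⁶))):

- **fc_rpkm** — union-exon counts (18 bp minimum overlap, summed across
  alignment blocks; ambiguous reads excluded; stranded) over *L_g*.
- **rsem_rpkm** — EM-derived gene counts (Σ_t ĉ_t) over the same *L_g*.
- **rsem_txSum_rpkm** — Σ_t RPKM_t with each isoform's own *ℓ_t*;
  always ≥ rsem_rpkm since *L_g* ≥ every *ℓ_t*.
- **TPM** — length-normalized rates rescaled to sum to 10⁶ per sample
  (proportional to RPKM within a sample; the mean is always 10⁶/n).
- **Expression ratio** r = (rsem_txSum_rpkm + b)/(rsem_rpkm + b) with
  background b = 0.01, its cumulative distribution, and its binning by
  gene structure (number of union exons, number of isoforms).
- **DE comparison** — gene- and transcript-level differential calls
  (|FC| ≥ 1.5 and Benjamini-Hochberg adjusted p < 0.05) and the
  intersection of the gene-level DE set with the genes owning ≥ 1 DE
  transcript.

The EM follows the standard mixture formulation: starting from uniform
abundances, each read compatible with several isoforms is split in
proportion to θ_t/ℓ̃_t (ℓ̃ = effective length), abundances are
re-estimated from the fractional counts, and the procedure repeats until
convergence. A read is compatible with an isoform only if every alignment
block lies inside its exons and every block gap matches one of its introns
exactly, so intron-retention reads are dropped — the key counting
asymmetry against the union-exon route.

## Worked example

A gene with three isoforms (500 bp, 350 bp, 4650 bp; union length
4650 bp) whose *shortest* isoform carries 85% of the transcript molecules:

```python
import unionquant as uq

scenario = uq.scenario_presets("short_dominant", seed=1)
ann = scenario.annotation
profile = scenario.conditions["A"][0]          # 30,000 reads
reads = uq.simulate_reads(ann, profile, scenario.config)

cm = uq.build_compatibility([r.read for r in reads], ann)
est = uq.em_quantify(cm)
gene_counts = uq.gene_counts_from_isoforms(est, ann).to_frame(profile.sample)
totals = gene_counts.sum(axis=0)

rsem = uq.gene_rpkm_union(gene_counts, ann, totals, source="rsem")
txsum = uq.gene_rpkm_txsum(
    uq.transcript_rpkm(est.expected_counts.to_frame(profile.sample), ann, totals),
    ann,
)
ratio = uq.ratio_table(txsum, rsem)

print("theta:", est.theta.round(3).to_dict())
print("rsem_rpkm:", round(rsem.values.loc["SDOMG", profile.sample], 2))
print("rsem_txSum_rpkm:", round(txsum.values.loc["SDOMG", profile.sample], 2))
print("ratio:", round(ratio.loc["SDOMG", profile.sample], 2))
```

Output:

```
theta: {'SDOMG.T1': 0.101, 'SDOMG.T2': 0.851, 'SDOMG.T3': 0.049}
rsem_rpkm: 215053.76
rsem_txSum_rpkm: 1609030.69
ratio: 7.48
```

The EM recovers the simulated abundances (0.10/0.85/0.05) almost exactly,
yet the union-exon RPKM is 7.5× smaller than the transcript-sum RPKM: the
dominant short isoform's reads are being divided by a gene length 13×
its own. For single-isoform genes the ratio is exactly 1.

A command-line surface mirrors the library
(`unionquant simulate|flatten|filter|count-union|quant-em|metrics|compare|de-compare`).

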