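"""Annotation parsing, union-exon flattening, and gene filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unionquant.annotation import (
    AnnotationError,
    FilterConfig,
    GenomicInterval,
    GTFParseError,
    filter_genes,
    merge_intervals,
    read_gtf,
    structural_features,
)
from unionquant.simulate import scenario_presets

from conftest import make_gene


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestReadGtf:
    def test_round_trip_structure(self, toy_gtf):
        ann = read_gtf(toy_gtf)
        assert len(ann) == 2
        g1 = ann["G1"]
        assert g1.n_transcripts == 2
        assert {t.transcript_id for t in g1.transcripts} == {"G1.T1", "G1.T2"}
        assert ann["G2"].n_transcripts == 1

    def test_one_based_inclusive_becomes_half_open(self, tmp_path):
        path = tmp_path / "one.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "G.T";\n'
        )
        ann = read_gtf(str(path))
        exon = ann["G"].transcripts[0].exons[0]
        assert (exon.start, exon.end) == (0, 100)
        assert exon.length == 100

    def test_opposite_strand_genes_at_same_locus_stay_separate(self, tmp_path):
        lines = [
            'chr1\tx\texon\t101\t900\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T";',
            'chr1\tx\texon\t1001\t1800\t.\t+\t.\tgene_id "GA"; transcript_id "GA.T";',
            'chr1\tx\texon\t101\t900\t.\t-\t.\tgene_id "GB"; transcript_id "GB.T";',
            'chr1\tx\texon\t1001\t1800\t.\t-\t.\tgene_id "GB"; transcript_id "GB.T";',
        ]
        path = tmp_path / "two.gtf"
        path.write_text("\n".join(lines) + "\n")
        ann = read_gtf(str(path))
        assert len(ann) == 2
        assert ann["GA"].strand == "+" and ann["GB"].strand == "-"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "G.T";\n'
            "chr1\tonly_three_fields\toops\n"
        )
        with pytest.raises(GTFParseError, match="line 2"):
            read_gtf(str(path))

    def test_exon_without_transcript_id_rejected(self, tmp_path):
        path = tmp_path / "noattr.gtf"
        path.write_text('chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(GTFParseError, match="transcript_id"):
            read_gtf(str(path))


class TestMergeIntervals:
    def test_empty(self):
        assert merge_intervals([]) == []

    def test_union_exon_geometry(self):
        # two isoforms flatten to union exons of 2 kb, 1 kb and 2 kb
        iso1 = [iv(0, 2000), iv(3000, 4000), iv(5000, 7000)]
        iso2 = [iv(0, 2000), iv(5000, 7000)]
        merged = merge_intervals(iso1 + iso2)
        assert [(m.start, m.end) for m in merged] == [
            (0, 2000),
            (3000, 4000),
            (5000, 7000),
        ]
        assert [m.length for m in merged] == [2000, 1000, 2000]

    def test_overlapping_intervals_merge(self):
        merged = merge_intervals([iv(0, 100), iv(50, 150)])
        assert [(m.start, m.end) for m in merged] == [(0, 150)]

    def test_touching_intervals_merge(self):
        merged = merge_intervals([iv(0, 100), iv(100, 150)])
        assert [(m.start, m.end) for m in merged] == [(0, 150)]

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(AnnotationError, match="chromosome"):
            merge_intervals([iv(0, 10), iv(0, 10, chrom="chr2")])

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_merge_matches_brute_force_base_union(self, raw):
        intervals = [iv(s, s + l) for s, l in raw]
        merged = merge_intervals(intervals)
        covered = set()
        for i in intervals:
            covered.update(range(i.start, i.end))
        merged_bases = set()
        for m in merged:
            merged_bases.update(range(m.start, m.end))
        assert merged_bases == covered
        # disjoint, sorted, non-touching
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start
        # idempotent
        assert merge_intervals(merged) == merged


class TestGeneStructure:
    def test_single_transcript_union_equals_transcript_length(self):
        gene = make_gene("G", "chr1", "+", [[(0, 500), (700, 1200)]])
        assert gene.union_length_bp == gene.transcripts[0].length_bp == 1000

    def test_interval_invariants(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 0, 10, strand="*")

    @pytest.mark.parametrize(
        "chains, expected",
        [
            ([[(0, 1000)]], (1, 1)),
            # two isoforms, middle exon skipped: three union exons
            (
                [
                    [(0, 2000), (3000, 4000), (5000, 7000)],
                    [(0, 2000), (5000, 7000)],
                ],
                (3, 2),
            ),
            # three isoforms flattening to two union exons
            (
                [
                    [(0, 500)],
                    [(1200, 1550)],
                    [(0, 500), (1200, 1550)],
                ],
                (2, 3),
            ),
        ],
    )
    def test_structural_features(self, chains, expected):
        gene = make_gene("G", "chr1", "+", chains)
        assert structural_features(gene) == expected


class TestFilterGenes:
    def _annotation(self):
        genes = [
            make_gene("KEEP", "chr1", "+", [[(0, 400), (900, 1200)]]),
            make_gene("LOW", "chr1", "+", [[(5000, 5800)]]),
            make_gene("SHORT", "chr1", "+", [[(9000, 9499)]]),
            make_gene("MITO", "chrM", "+", [[(0, 900)]]),
            make_gene("OVL_A", "chr2", "+", [[(0, 600), (1000, 1600)]]),
            make_gene("OVL_B", "chr2", "+", [[(1400, 2200)]]),
            make_gene("ANTI_A", "chr3", "+", [[(0, 800)]]),
            make_gene("ANTI_B", "chr3", "-", [[(300, 1200)]]),
        ]
        from unionquant.annotation import Annotation

        return Annotation(genes)

    def _counts(self, ann, low_gene="LOW"):
        counts = pd.DataFrame(
            200, index=ann.gene_ids, columns=["s1", "s2", "s3", "s4"]
        )
        counts.loc[low_gene] = [99, 99, 99, 99]
        return counts

    def test_rules_and_tally(self):
        ann = self._annotation()
        counts = self._counts(ann)
        kept, tally = filter_genes(ann, counts)
        assert set(kept.gene_ids) == {"KEEP", "ANTI_A", "ANTI_B"}
        assert tally == {
            "mito": 1,
            "same_strand_overlap": 2,
            "low_count": 1,
            "short": 1,
        }
        assert sum(tally.values()) == len(ann) - len(kept)

    def test_count_rule_boundary(self):
        ann = self._annotation()
        counts = self._counts(ann)
        # reaching 100 in a single sample retains the gene
        counts.loc["LOW", "s3"] = 100
        kept, tally = filter_genes(ann, counts)
        assert "LOW" in kept
        assert tally["low_count"] == 0

    def test_union_length_boundary(self):
        cfg = FilterConfig()
        gene499 = make_gene("A", "chr1", "+", [[(0, 499)]])
        gene500 = make_gene("B", "chr1", "+", [[(10_000, 10_500)]])
        from unionquant.annotation import Annotation

        ann = Annotation([gene499, gene500])
        counts = pd.DataFrame(1000, index=ann.gene_ids, columns=["s1"])
        kept, tally = filter_genes(ann, counts, cfg)
        assert set(kept.gene_ids) == {"B"}
        assert tally["short"] == 1

    def test_missing_gene_raises_with_ids(self):
        ann = self._annotation()
        counts = self._counts(ann).drop(index=["KEEP"])
        with pytest.raises(AnnotationError, match="KEEP"):
            filter_genes(ann, counts)


def test_simulated_annotation_has_no_same_strand_overlap():
    ann = scenario_presets("mixed", seed=9, n_genes=60).annotation
    from unionquant.annotation import _same_strand_overlapping_genes

    assert _same_strand_overlapping_genes(ann) == set()
    # every transcript exon is inside the gene's union exons
    for gene in ann:
        covered = set()
        for e in gene.union_exons:
            covered.update(range(e.start, e.end))
        for tx in gene.transcripts:
            for e in tx.exons:
                assert set(range(e.start, e.end)) <= covered
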