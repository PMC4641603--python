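"""EM isoform quantification: compatibility, likelihood oracle, recovery."""

import numpy as np
import pytest

from unionquant import (
    AlignedRead,
    CompatibilityMatrix,
    ExpressionProfile,
    SimConfig,
    build_compatibility,
    count_union,
    em_quantify,
    gene_counts_from_isoforms,
    scenario_presets,
    simulate_reads,
)
from unionquant.em import effective_length, is_compatible
from unionquant.simulate import short_intron_annotation

from conftest import make_gene


def grid_search_mle(classes, eff_lengths, step=1e-4):
    """Brute-force 1-D likelihood maximizer for two transcripts."""
    (t1, t2) = sorted(eff_lengths)
    grid = np.arange(0.0, 1.0 + step, step)
    best_x, best_ll = None, -np.inf
    for x in grid:
        theta = {t1: x, t2: 1.0 - x}
        ll = 0.0
        for cls, n in classes.items():
            dens = sum(theta[t] / eff_lengths[t] for t in cls)
            if dens <= 0:
                ll = -np.inf
                break
            ll += n * np.log(dens)
        if ll > best_ll:
            best_ll, best_x = ll, x
    return {t1: best_x, t2: 1.0 - best_x}


class TestCompatibility:
    def test_shared_exon_read_compatible_with_both_isoforms(self, fig1_scenario):
        ann = fig1_scenario.annotation
        r = AlignedRead("r", "chr1", ((10_100, 10_175),), "-")
        cm = build_compatibility([r], ann)
        assert set(next(iter(cm.classes))) == {"FIG1G.T1", "FIG1G.T2"}

    def test_skipping_junction_read_unique_to_short_isoform(self, fig9_scenario):
        ann = fig9_scenario.annotation
        # isoform a joins exon #1 (ends 12000) directly to exon #3 (starts 16000)
        r = AlignedRead("r", "chr1", ((11_960, 12_000), (16_000, 16_035)), "-")
        cm = build_compatibility([r], ann)
        assert set(next(iter(cm.classes))) == {"FIG9G.T1"}

    def test_intronic_read_dropped(self, fig9_scenario):
        r = AlignedRead("r", "chr1", ((12_100, 12_175),), "-")
        cm = build_compatibility([r], fig9_scenario.annotation)
        assert cm.classes == {}
        assert cm.n_dropped == 1

    def test_gap_must_match_intron_exactly(self):
        gene = make_gene(
            "G", "chr1", "+", [[(0, 1000), (2000, 3000)], [(0, 1000), (2500, 3000)]]
        )
        t1, t2 = gene.transcripts
        spliced_t1 = AlignedRead("r", "chr1", ((960, 1000), (2000, 2035)), "-")
        assert is_compatible(spliced_t1, t1)
        assert not is_compatible(spliced_t1, t2)

    def test_effective_length_modes(self):
        assert effective_length(1000, 75, "corrected") == 926.0
        assert effective_length(50, 75, "corrected") == 1.0
        assert effective_length(1000, 75, "plain") == 1000.0
        with pytest.raises(ValueError):
            effective_length(1000, 75, "bogus")


class TestEMQuantify:
    def test_single_transcript_gets_everything(self):
        cm = CompatibilityMatrix({frozenset({"T"}): 100}, {"T": 500.0})
        est = em_quantify(cm)
        assert est.theta["T"] == pytest.approx(1.0)
        assert est.expected_counts["T"] == pytest.approx(100.0)
        assert est.converged

    def test_identical_twins_split_evenly(self):
        cm = CompatibilityMatrix(
            {frozenset({"A", "B"}): 100}, {"A": 800.0, "B": 800.0}
        )
        est = em_quantify(cm)
        assert est.expected_counts["A"] == pytest.approx(50.0)
        assert est.expected_counts["B"] == pytest.approx(50.0)

    def test_matches_grid_search_likelihood_maximizer(self):
        classes = {
            frozenset({"long"}): 30,
            frozenset({"long", "short"}): 30,
        }
        eff = {"short": 1000.0, "long": 2000.0}
        cm = CompatibilityMatrix(classes, eff)
        est = em_quantify(cm, max_iter=200_000)
        oracle = grid_search_mle(classes, eff)
        for t in eff:
            assert est.read_fractions[t] == pytest.approx(oracle[t], abs=5e-4)
        # expected counts from the same fixed point
        dens = oracle["long"] / 2000.0 + oracle["short"] / 1000.0
        c_long = 30 + 30 * (oracle["long"] / 2000.0) / dens
        assert est.expected_counts["long"] == pytest.approx(c_long, abs=0.05)

    def test_interior_optimum_matches_grid(self):
        # unique evidence for both isoforms forces an interior maximizer
        classes = {
            frozenset({"long"}): 40,
            frozenset({"short"}): 25,
            frozenset({"long", "short"}): 35,
        }
        eff = {"short": 900.0, "long": 2600.0}
        cm = CompatibilityMatrix(classes, eff)
        est = em_quantify(cm, max_iter=200_000)
        oracle = grid_search_mle(classes, eff)
        for t in eff:
            assert est.read_fractions[t] == pytest.approx(oracle[t], abs=5e-4)
        # abundances are the length-normalized mixture weights
        rho = {t: oracle[t] / eff[t] for t in eff}
        tot = sum(rho.values())
        for t in eff:
            assert est.theta[t] == pytest.approx(rho[t] / tot, abs=5e-4)

    def test_conservation_and_monotone_log_likelihood(self, fig9_scenario):
        profile = ExpressionProfile(
            "s1", {"FIG9G.T1": 0.4, "FIG9G.T2": 0.6}, 5000
        )
        reads = simulate_reads(
            fig9_scenario.annotation, profile, SimConfig(seed=31)
        )
        cm = build_compatibility([r.read for r in reads], fig9_scenario.annotation)
        est = em_quantify(cm)
        assert est.expected_counts.sum() == pytest.approx(cm.n_reads, rel=1e-12)
        ll = np.array(est.log_likelihood_trace)
        assert (np.diff(ll) >= -1e-9).all()

    def test_no_compatible_reads_raises(self):
        with pytest.raises(ValueError, match="non-empty"):
            em_quantify(CompatibilityMatrix({}, {"T": 100.0}))

    def test_max_iter_reached_flags_not_converged(self):
        cm = CompatibilityMatrix(
            {frozenset({"long"}): 30, frozenset({"long", "short"}): 30},
            {"short": 1000.0, "long": 2000.0},
        )
        est = em_quantify(cm, max_iter=5)
        assert not est.converged
        assert est.n_iterations == 5


class TestParameterRecovery:
    def test_corner_profile_recovered_at_depth(self, fig9_scenario):
        ann = fig9_scenario.annotation
        for sample, theta in [
            ("A", {"FIG9G.T1": 1.0, "FIG9G.T2": 0.0}),
            ("B", {"FIG9G.T1": 0.0, "FIG9G.T2": 1.0}),
        ]:
            profile = ExpressionProfile(sample, theta, 100_000)
            reads = simulate_reads(ann, profile, SimConfig(seed=41))
            cm = build_compatibility([r.read for r in reads], ann)
            est = em_quantify(cm)
            for t, true_theta in theta.items():
                assert abs(est.theta[t] - true_theta) < 0.02

    def test_mid_profile_recovered_at_depth(self, fig9_scenario):
        theta = {"FIG9G.T1": 0.3, "FIG9G.T2": 0.7}
        profile = ExpressionProfile("s1", theta, 100_000)
        reads = simulate_reads(fig9_scenario.annotation, profile, SimConfig(seed=43))
        cm = build_compatibility(
            [r.read for r in reads], fig9_scenario.annotation
        )
        est = em_quantify(cm)
        for t, true_theta in theta.items():
            assert abs(est.theta[t] - true_theta) < 0.02

    def test_accuracy_degrades_at_low_depth(self, fig9_scenario):
        ann = fig9_scenario.annotation
        theta = {"FIG9G.T1": 0.3, "FIG9G.T2": 0.7}

        def mean_error(library_size, n_rep=100):
            errs = []
            for k in range(n_rep):
                profile = ExpressionProfile("s1", theta, library_size)
                reads = simulate_reads(ann, profile, SimConfig(seed=1000 + k))
                cm = build_compatibility([r.read for r in reads], ann)
                est = em_quantify(cm)
                errs.append(
                    np.mean([abs(est.theta[t] - theta[t]) for t in theta])
                )
            return float(np.mean(errs))

        assert mean_error(20) > mean_error(300)


class TestGeneCounts:
    def test_sums_isoform_counts(self, fig1_scenario):
        est_counts = {"FIG1G.T1": 10.0, "FIG1G.T2": 22.0}
        gc = gene_counts_from_isoforms(est_counts, fig1_scenario.annotation)
        assert gc["FIG1G"] == pytest.approx(32.0)

    def test_empty_estimates_all_zero(self, fig1_scenario):
        gc = gene_counts_from_isoforms({}, fig1_scenario.annotation)
        assert (gc == 0).all()

    def test_union_counts_dominate_em_counts_under_ir(self):
        ann = short_intron_annotation()
        tx_ids = sorted(ann.transcripts)
        profile = ExpressionProfile(
            "s1", {t: 1 / len(tx_ids) for t in tx_ids}, 20_000
        )
        cfg = SimConfig(seed=51, intron_retention_rate=0.05)
        reads = [r.read for r in simulate_reads(ann, profile, cfg)]
        fc = count_union(reads, ann).counts["s1"]
        cm = build_compatibility(reads, ann)
        rsem = gene_counts_from_isoforms(em_quantify(cm), ann)
        assert (fc >= rsem.loc[fc.index] - 1e-9).all()
        assert fc.sum() > rsem.sum()
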