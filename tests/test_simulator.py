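import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from episeeker import (
    EpistasisModelSpec,
    calibrate,
    embed_interactions,
    ld_marker_haplotypes,
    penetrance_table,
    score_sets,
    simulate_case_control,
    simulate_null,
)
from episeeker.simulator import (
    _allelic_odds_ratio,
    _conditional_pair_dists,
    hwe_probs,
)

GRID = [(model, lam, maf)
        for model, lam in [("additive", 0.3), ("multiplicative", 0.2),
                           ("threshold", 0.2)]
        for maf in (0.1, 0.2, 0.5)]


class TestPenetranceTable:
    def test_no_effect_is_flat(self):
        spec = EpistasisModelSpec("additive", 0.3, 0.2, gamma=0.02, theta=0.0)
        np.testing.assert_allclose(penetrance_table(spec), 0.02 / 1.02)

    def test_multiplicative_needs_both_loci(self):
        spec = EpistasisModelSpec("multiplicative", 0.2, 0.2,
                                  gamma=0.01, theta=0.5)
        table = penetrance_table(spec)
        np.testing.assert_allclose(table[0, :], 0.01 / 1.01)
        np.testing.assert_allclose(table[:, 0], 0.01 / 1.01)
        assert table[2, 2] > table[1, 1] > table[0, 0]

    def test_threshold_block_structure(self):
        spec = EpistasisModelSpec("threshold", 0.2, 0.2, gamma=0.01, theta=1.0)
        table = penetrance_table(spec)
        np.testing.assert_allclose(table[0, :], 0.0099, atol=5e-5)
        np.testing.assert_allclose(table[1:, 1:], 0.0196, atol=5e-5)


class TestCalibration:
    def test_zero_effect_gives_flat_prevalence(self):
        spec = calibrate(EpistasisModelSpec("multiplicative", 0.0, 0.3))
        assert spec.theta == 0.0
        np.testing.assert_allclose(penetrance_table(spec), spec.prevalence,
                                   rtol=1e-9)

    @pytest.mark.parametrize("model,lam,maf", GRID)
    def test_prevalence_self_consistency(self, model, lam, maf):
        spec = calibrate(EpistasisModelSpec(model, lam, maf))
        pg = hwe_probs(maf)
        recomputed = float(np.outer(pg, pg).ravel()
                           @ penetrance_table(spec).ravel())
        assert recomputed == pytest.approx(spec.prevalence, abs=1e-6)

    @pytest.mark.parametrize("model,lam,maf", GRID)
    def test_marginal_per_allele_odds_ratio_hits_target(self, model, lam, maf):
        spec = calibrate(EpistasisModelSpec(model, lam, maf))
        assert _allelic_odds_ratio(spec) == pytest.approx(1 + lam, rel=1e-8)

    def test_theta_increases_with_effect_size(self):
        thetas = [calibrate(EpistasisModelSpec("threshold", lam, 0.2)).theta
                  for lam in (0.1, 0.2, 0.4)]
        assert thetas == sorted(thetas)
        assert thetas[0] > 0


class TestLdMarkers:
    def test_perfect_ld_collapses_haplotypes(self):
        h = ld_marker_haplotypes(0.3, 1.0)
        assert h[1, 1] == pytest.approx(0.3)
        assert h[1, 0] == pytest.approx(0.0, abs=1e-12)
        assert h[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_realized_allelic_correlation(self, rng):
        h = ld_marker_haplotypes(0.2, 0.7)
        draws = rng.choice(4, size=1_000_000, p=h.ravel())
        causal, marker = draws // 2, draws % 2
        corr = np.corrcoef(causal, marker)[0, 1]
        assert corr**2 == pytest.approx(0.7, abs=0.01)

    def test_marker_preserves_allele_frequency(self):
        for r2 in (0.3, 0.7, 1.0):
            h = ld_marker_haplotypes(0.25, r2)
            assert h[:, 1].sum() == pytest.approx(0.25)
            assert h[1, :].sum() == pytest.approx(0.25)


class TestNullPanels:
    def test_shape_and_truth(self):
        sim = simulate_null(30, 25, 35, rng=np.random.default_rng(1))
        assert sim.panel.n_snps == 30
        assert sim.panel.n_cases == 25 and sim.panel.n_controls == 35
        assert sim.truth == ()

    def test_maf_range_respected(self):
        sim = simulate_null(300, 500, 500, rng=np.random.default_rng(2))
        freqs = sim.panel.genotypes.mean(axis=1) / 2
        assert freqs.min() > 0.05 and freqs.max() < 0.55

    def test_background_hwe_goodness_of_fit(self):
        sim = simulate_null(200, 1000, 1000, rng=np.random.default_rng(3))
        G = sim.panel.genotypes
        pvals = []
        for row in G:
            counts = np.bincount(row, minlength=3)
            f = row.mean() / 2
            expected = hwe_probs(f) * len(row)
            if expected.min() < 5:
                continue
            pvals.append(chisquare(counts, expected, ddof=1).pvalue)
        assert min(pvals) > 1e-5  # no locus grossly violates HWE
        assert np.mean(np.array(pvals) < 0.001) < 0.02

    def test_single_snp_association_p_uniform(self):
        # 200 independent null SNPs double as 200 replicates of one SNP
        sim = simulate_null(200, 1000, 1000, rng=np.random.default_rng(4))
        sets = np.arange(200)[:, None]
        _, _, p = score_sets(sim.panel, sets)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_identical_seed_identical_panel(self):
        a = simulate_null(40, 50, 50, rng=np.random.default_rng(9))
        b = simulate_null(40, 50, 50, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.panel.genotypes, b.panel.genotypes)


class TestEpistaticPanels:
    def test_truth_is_one_sorted_pair(self, rng):
        spec = calibrate(EpistasisModelSpec("multiplicative", 0.2, 0.5))
        sim = simulate_case_control(spec, 50, 300, 300, rng)
        (pair,) = sim.truth
        assert len(pair) == 2 and pair[0] < pair[1] < 50

    def test_controls_match_population_at_low_prevalence(self):
        spec = calibrate(EpistasisModelSpec("threshold", 0.2, 0.5))
        _, p_ctrl = _conditional_pair_dists(spec)
        pg = hwe_probs(0.5)
        np.testing.assert_allclose(p_ctrl, np.outer(pg, pg).ravel(), atol=0.002)

    def test_cases_enriched_for_risk_genotypes(self, rng):
        spec = calibrate(EpistasisModelSpec("threshold", 0.2, 0.5))
        sim = simulate_case_control(spec, 10, 2000, 2000, rng)
        a, b = sim.truth[0]
        cases = sim.panel.status == 1
        risk = (sim.panel.genotypes[a] >= 1) & (sim.panel.genotypes[b] >= 1)
        hwe_block = (1 - hwe_probs(0.5)[0]) ** 2  # P(g1>=1, g2>=1) = 0.5625
        assert risk[cases].mean() > hwe_block + 0.02
        assert abs(risk[~cases].mean() - hwe_block) < 0.05

    def test_case_genotypes_follow_penetrance_by_bayes(self, rng):
        spec = calibrate(EpistasisModelSpec("multiplicative", 0.2, 0.5))
        sim = simulate_case_control(spec, 4, 4000, 4000, rng)
        a, b = sim.truth[0]
        cases = sim.panel.status == 1
        codes = sim.panel.genotypes[a][cases] * 3 + sim.panel.genotypes[b][cases]
        observed = np.bincount(codes, minlength=9) / cases.sum()
        expected, _ = _conditional_pair_dists(spec)
        np.testing.assert_allclose(observed, expected, atol=0.02)

    def test_tag_markers_dilute_association(self):
        strong = calibrate(EpistasisModelSpec("threshold", 0.2, 0.5, r2=1.0))
        tagged = calibrate(EpistasisModelSpec("threshold", 0.2, 0.5, r2=0.7))
        chis = {}
        for name, spec in (("direct", strong), ("tagged", tagged)):
            rng = np.random.default_rng(11)
            sim = simulate_case_control(spec, 10, 2000, 2000, rng)
            chi2, _, _ = score_sets(sim.panel, np.array([sim.truth[0]]))
            chis[name] = chi2[0]
        assert chis["tagged"] < chis["direct"]


class TestEmbeddedInteractions:
    def test_single_interaction_matches_simulate_case_control(self):
        spec = calibrate(EpistasisModelSpec("additive", 0.3, 0.2))
        a = simulate_case_control(spec, 30, 100, 100, np.random.default_rng(5))
        b = embed_interactions(1, [spec], 30, 100, 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a.panel.genotypes, b.panel.genotypes)
        assert a.truth == b.truth

    def test_truth_pairs_disjoint(self, rng):
        spec = calibrate(EpistasisModelSpec("threshold", 0.2, 0.2))
        sim = embed_interactions(10, [spec], 100, 300, 300, rng)
        loci = [k for pair in sim.truth for k in pair]
        assert len(loci) == len(set(loci)) == 20

    def test_infeasible_placement_rejected(self, rng):
        spec = calibrate(EpistasisModelSpec("threshold", 0.2, 0.2))
        with pytest.raises(ValueError, match="disjoint"):
            embed_interactions(6, [spec], 10, 50, 50, rng)

    def test_planted_pairs_separate_from_background(self, rng):
        spec = calibrate(EpistasisModelSpec("threshold", 0.2, 0.5))
        sim = embed_interactions(10, [spec], 300, 1000, 1000, rng)
        truth_sets = np.array([list(p) for p in sim.truth])
        _, _, p_truth = score_sets(sim.panel, truth_sets)
        occupied = {k for pair in sim.truth for k in pair}
        free = [k for k in range(300) if k not in occupied]
        bg = rng.choice(free, size=(200, 2), replace=True)
        bg = bg[bg[:, 0] != bg[:, 1]]
        _, _, p_bg = score_sets(sim.panel, np.sort(bg, axis=1))
        assert np.median(p_truth) < np.median(p_bg) / 100
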