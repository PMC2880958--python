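import numpy as np
import pytest
from scipy.stats import chi2_contingency

from episeeker import (
    ContingencyTable,
    GenotypeMatrix,
    chi2_score,
    contingency_table,
    exhaustive_pair_scan,
    score_sets,
    simulate_null,
)


def brute_force_chi2(counts):
    """Independent Pearson chi-square oracle: explicit O/E loop."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    chi2 = 0.0
    for i in range(counts.shape[0]):
        for j in range(2):
            expected = counts[i].sum() * counts[:, j].sum() / total
            chi2 += (counts[i, j] - expected) ** 2 / expected
    return chi2


class TestContingencyTable:
    def test_single_snp_counts(self):
        panel = GenotypeMatrix(("S1",), np.array([[0, 0, 1]], dtype=np.uint8),
                               np.array([0, 1, 1], dtype=np.int8))
        table = contingency_table(panel, (0,))
        np.testing.assert_array_equal(table.counts, [[1, 1], [0, 1]])

    def test_unobserved_combinations_dropped(self):
        genotypes = np.array([[0, 0, 2, 2], [0, 0, 2, 2]], dtype=np.uint8)
        panel = GenotypeMatrix(("a", "b"), genotypes,
                               np.array([0, 1, 0, 1], dtype=np.int8))
        table = contingency_table(panel, (0, 1))
        assert table.counts.shape[0] == 2  # not 9

    def test_duplicated_locus_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="duplicated"):
            contingency_table(tiny_panel, (1, 1))

    def test_empty_set_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="empty"):
            contingency_table(tiny_panel, ())


class TestChi2Score:
    def test_proportional_rows_are_independent(self):
        table = ContingencyTable(np.array([[10, 10], [5, 5], [1, 1]]), 1)
        chi2, _, p = chi2_score(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_perfect_separation_hand_value(self):
        # E = 5 in all four cells: chi2 = 4 * 25/5 = 20, df = 1
        chi2, df, p = chi2_score(ContingencyTable(np.array([[10, 0], [0, 10]]), 1))
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_zero_status_margin_is_degenerate(self):
        chi2, _, p = chi2_score(ContingencyTable(np.array([[10, 0], [3, 0]]), 1))
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 40, size=(9, 2))
        table = ContingencyTable(counts, 2)
        chi2, df, p = chi2_score(table)
        assert chi2 == pytest.approx(brute_force_chi2(counts), rel=1e-10)
        # second independent route: scipy's contingency test, no correction
        ref = chi2_contingency(counts, correction=False)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_invariant_under_row_permutation(self, rng):
        counts = rng.integers(1, 30, size=(6, 2))
        base = chi2_score(ContingencyTable(counts, 2))
        shuffled = chi2_score(ContingencyTable(counts[rng.permutation(6)], 2))
        assert base == pytest.approx(shuffled)

    @pytest.mark.parametrize("c", [1, 5])
    def test_flattening_regularization_decreases_association(self, c):
        counts = np.array([[10, 0], [0, 10]])
        chi2, _, _ = chi2_score(ContingencyTable(counts, 1))
        chi2_c, _, _ = chi2_score(ContingencyTable(counts + c, 1))
        assert chi2_c < chi2


class TestScoreSets:
    def test_agrees_with_single_table_route(self, null_panel, rng):
        sets = np.array([sorted(rng.choice(null_panel.n_snps, 3, replace=False))
                         for _ in range(20)])
        chi2, df, p = score_sets(null_panel, sets)
        for k in range(20):
            ref = chi2_score(contingency_table(null_panel, tuple(sets[k])))
            assert (chi2[k], df[k], p[k]) == pytest.approx(ref)


class TestExhaustivePairScan:
    def test_counts_all_combinations(self, null_panel):
        hits = exhaustive_pair_scan(null_panel, 2, threshold=1.0)
        L = null_panel.n_snps
        assert len(hits) == L * (L - 1) // 2
        assert all(h0.p_value <= h1.p_value for h0, h1 in zip(hits, hits[1:]))

    def test_matches_per_pair_scoring_exactly(self, null_panel):
        hits = exhaustive_pair_scan(null_panel, 2, threshold=1.0)
        by_pair = {h.loci: h for h in hits}
        # the per-pair route sums over observed rows only, so agreement is
        # to rounding; bit-exact equality is asserted against score_sets in
        # the two-stage tests instead
        for pair in [(0, 1), (3, 17), (20, 39)]:
            chi2, df, p = chi2_score(contingency_table(null_panel, pair))
            assert by_pair[pair].chi2 == pytest.approx(chi2, rel=1e-12)
            assert by_pair[pair].df == df
            assert by_pair[pair].p_value == pytest.approx(p, rel=1e-9)

    def test_triple_scan_small_panel(self, null_panel):
        sub = GenotypeMatrix(null_panel.snp_names[:6], null_panel.genotypes[:6],
                             null_panel.status)
        hits = exhaustive_pair_scan(sub, 3, threshold=1.0)
        assert len(hits) == 20  # C(6,3)

    def test_genome_scale_refusal_reports_pair_count(self):
        L = 100_000
        big = GenotypeMatrix(
            tuple(f"S{i}" for i in range(L)),
            np.zeros((L, 2), dtype=np.uint8),
            np.array([0, 1], dtype=np.int8),
        )
        with pytest.raises(ValueError, match="4999950000"):
            exhaustive_pair_scan(big, 2)

    def test_small_panel_refusal_honours_custom_limit(self, null_panel):
        with pytest.raises(ValueError, match="exceeds the limit"):
            exhaustive_pair_scan(null_panel, 2, max_combinations=2)
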