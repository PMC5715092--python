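"""Evaluation arithmetic: confusion tables, occupancy MLE, rate comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from wellcount import (
    ConfusionMatrix,
    OccupancyModel,
    category_rates,
    compare_concordance_chi2,
    confidence_separation_test,
    confusion_matrix,
    discordance_matrix,
    expected_poisson_proportions,
    fit_poisson_occupancy,
    sample_cell_counts,
)
from wellcount.stats import _censored_loglik

# technician (rows) x classifier (columns) counts of the reference experiment:
# concordant diagonal plus the published discordance pattern
REFERENCE_MATRIX = np.array(
    [
        [6420, 38, 0, 0],
        [47, 1150, 28, 0],
        [0, 15, 193, 1],
        [0, 0, 4, 24],
    ]
)


class TestConfusionMatrix:
    def test_diagonal_when_all_concordant(self):
        cm = confusion_matrix([0, 1, 2, 3, 0], [0, 1, 2, 3, 0])
        assert cm.trace == 5
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_reference_marginals(self):
        cm = ConfusionMatrix(REFERENCE_MATRIX)
        assert cm.row_totals.tolist() == [6458, 1225, 209, 28]
        assert cm.col_totals.tolist() == [6467, 1203, 225, 25]
        assert cm.n == 7920

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            confusion_matrix([0, 5], [0, 1])

    def test_assembly_matches_pair_counting(self, rng):
        t = rng.integers(0, 4, 500)
        p = rng.integers(0, 4, 500)
        cm = confusion_matrix(t, p)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == np.sum((t == i) & (p == j))


class TestCategoryRates:
    def test_reference_sensitivities_and_ppvs(self):
        r = category_rates(ConfusionMatrix(REFERENCE_MATRIX))
        assert round(r.overall_concordance, 5) == 0.98321
        assert [round(s, 5) for s in r.sensitivity] == [0.99412, 0.93878, 0.92344, 0.85714]
        assert [round(p, 5) for p in r.ppv] == [0.99273, 0.95594, 0.85778, 0.96]

    def test_rates_weight_average_to_overall(self):
        cm = ConfusionMatrix(REFERENCE_MATRIX)
        r = category_rates(cm)
        overall = float(np.nansum(r.sensitivity * cm.row_totals) / cm.n)
        assert overall == pytest.approx(r.overall_concordance)
        overall_p = float(np.nansum(r.ppv * cm.col_totals) / cm.n)
        assert overall_p == pytest.approx(r.overall_concordance)

    def test_zero_marginals_flagged_not_zero(self):
        cm = ConfusionMatrix(np.diag([3, 0, 0, 0]))
        r = category_rates(cm)
        assert r.sensitivity[0] == 1.0
        assert not r.sensitivity_defined[1:].any()
        assert np.isnan(r.sensitivity[1:]).all()

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            category_rates(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestDiscordance:
    def test_reference_total_is_133(self):
        _, _, _, total = discordance_matrix(ConfusionMatrix(REFERENCE_MATRIX))
        assert total == 133

    def test_diagonal_only_matrix_has_no_discordance(self):
        off, row_t, col_t, total = discordance_matrix(ConfusionMatrix(np.diag([5, 4, 3, 2])))
        assert total == 0 and not off.any()

    def test_totals_equal_n_minus_trace(self, rng):
        m = rng.integers(0, 50, (4, 4))
        cm = ConfusionMatrix(m)
        _, row_t, col_t, total = discordance_matrix(cm)
        assert total == cm.n - cm.trace
        assert row_t.sum() == total and col_t.sum() == total


class TestPoissonOccupancy:
    def test_all_empty_gives_zero(self):
        fit = fit_poisson_occupancy(100, 0, 0, 0)
        assert fit.lambda_hat == 0.0

    def test_parameter_recovery_from_simulated_counts(self):
        """lambda recovered within 0.01 at n=1e5; grid oracle confirms optimum."""
        counts = sample_cell_counts(
            OccupancyModel(lam=0.2, cluster_excess=0.0), 10**5, np.random.default_rng(8)
        )
        n = np.bincount(np.minimum(counts, 3), minlength=4)
        fit = fit_poisson_occupancy(*n.tolist())
        assert abs(fit.lambda_hat - 0.2) < 0.01
        grid = np.linspace(0.1, 0.3, 2001)
        ll = [_censored_loglik(l, n) for l in grid]
        assert abs(grid[int(np.argmax(ll))] - fit.lambda_hat) <= 2e-4

    def test_score_vanishes_at_optimum(self):
        fit = fit_poisson_occupancy(8000, 1700, 250, 50)
        eps = 1e-5
        counts = np.array(fit.counts)
        d = (_censored_loglik(fit.lambda_hat + eps, counts)
             - _censored_loglik(fit.lambda_hat - eps, counts)) / (2 * eps)
        assert abs(d) < 0.05  # curvature is ~n, so this pins lambda to ~1e-6

    def test_scale_invariance_of_the_mle(self):
        a = fit_poisson_occupancy(800, 170, 25, 5)
        b = fit_poisson_occupancy(2400, 510, 75, 15)
        assert a.lambda_hat == pytest.approx(b.lambda_hat, abs=1e-6)

    def test_proportions_at_zero_lambda(self):
        assert expected_poisson_proportions(0.0).tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_proportions_at_reference_lambda(self):
        lam = 0.202247
        p = expected_poisson_proportions(lam)
        assert p[0] == pytest.approx(math.exp(-lam), abs=1e-12)
        assert p[3] == pytest.approx(
            1 - math.exp(-lam) * (1 + lam + lam**2 / 2), abs=1e-12
        )
        assert p[3] == pytest.approx(0.0012, abs=3e-4)

    @given(st.floats(0.0, 5.0))
    @settings(max_examples=80, deadline=None)
    def test_proportions_normalized(self, lam):
        p = expected_poisson_proportions(lam)
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cluster_excess_inflates_multicell_wells(self):
        """Generator data with adhesion excess shows more 2/>2 wells than the
        fitted Poisson model expects (the signature seen in real plates)."""
        counts = sample_cell_counts(
            OccupancyModel(lam=0.2, cluster_excess=0.3), 10**5, np.random.default_rng(9)
        )
        n = np.bincount(np.minimum(counts, 3), minlength=4)
        fit = fit_poisson_occupancy(*n.tolist())
        expected = expected_poisson_proportions(fit.lambda_hat) * n.sum()
        assert n[2] + n[3] > expected[2] + expected[3]


class TestChiSquare:
    def test_reference_table_is_highly_significant(self):
        stat, p = compare_concordance_chi2([[87, 36], [46, 97]])
        assert p < 0.0001
        assert 87 / 133 == pytest.approx(0.65, abs=5e-3)
        assert 36 / 133 == pytest.approx(0.27, abs=5e-3)

    def test_identical_columns_give_zero_statistic(self):
        stat, p = compare_concordance_chi2([[50, 50], [50, 50]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_oracle_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 60, 4)
            stat, _ = compare_concordance_chi2([[a, b], [c, d]])
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(closed, rel=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            compare_concordance_chi2([[0, 0], [5, 3]])

    def test_continuity_correction_available(self):
        plain, _ = compare_concordance_chi2([[10, 3], [4, 9]])
        corrected, _ = compare_concordance_chi2([[10, 3], [4, 9]], correction=True)
        assert corrected < plain


class TestConfidenceSeparation:
    def test_identical_groups_not_significant(self):
        h = np.array([0.5, 0.6, 0.7, 0.8])
        _, p = confidence_separation_test(h, h)
        assert p > 0.9

    def test_fully_separated_small_groups_hit_exact_minimum(self):
        """All concordant h above all discordant h: exact two-sided p = 2/C(8,4)."""
        u, p = confidence_separation_test([0.9, 0.92, 0.95, 0.99], [0.3, 0.4, 0.5, 0.6])
        assert u == 16.0  # U at its maximum for 4x4
        assert p == pytest.approx(2 / math.comb(8, 4))

    def test_rank_statistic_invariant_under_log(self):
        a = np.array([0.9, 0.8, 0.7, 0.5])
        b = np.array([0.6, 0.4, 0.3])
        u_log, p_log = confidence_separation_test(a, b, log_transform=True)
        u_raw, p_raw = confidence_separation_test(a, b, log_transform=False)
        assert u_log == u_raw
        assert p_log == pytest.approx(p_raw)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            confidence_separation_test([], [0.5])

    def test_large_sample_separation_is_detected(self, rng):
        conc = rng.uniform(0.8, 1.0, 2000)
        disc = rng.uniform(0.3, 0.7, 60)
        _, p = confidence_separation_test(conc, disc)
        assert p < 1e-10
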