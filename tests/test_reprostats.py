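"""Reproducibility statistics: RMS CV, bootstrap comparisons, agreement, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import laflow4d as lf
from laflow4d.reprostats import rms_cv


def simulate_pairs(n, cv, rng, mean=10.0, sd=2.0):
    true = np.abs(rng.normal(mean, sd, n)) + 1e-6
    e = rng.normal(0.0, cv, (n, 2))
    return true[:, None] * (1.0 + e)


class TestWithinSubjectCV:
    def test_identical_pairs_give_zero(self):
        assert rms_cv(np.array([[10.0, 10.0], [20.0, 20.0]])) == 0.0

    def test_hand_computed_example(self):
        # pairs (9,11), (19,21): CV = sqrt(((2/100) + (2/400)) / 2) = 0.1118
        cv = rms_cv(np.array([[9.0, 11.0], [19.0, 21.0]]))
        assert cv == pytest.approx(np.sqrt((2 / 100 + 2 / 400) / 2), abs=1e-12)
        assert cv == pytest.approx(0.1118, abs=5e-5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        pairs = simulate_pairs(30, 0.1, rng)
        assert rms_cv(7.3 * pairs) == pytest.approx(rms_cv(pairs), rel=1e-12)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            rms_cv(np.array([[1.0, -2.0]]))

    def test_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(1)
        pairs = simulate_pairs(50, 0.1, rng)
        e1 = lf.within_subject_cv(pairs, n_boot=500, seed=9)
        e2 = lf.within_subject_cv(pairs, n_boot=500, seed=9)
        assert e1.ci_low <= e1.cv <= e1.ci_high
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        pairs = simulate_pairs(40, 0.1, rng)
        assert rms_cv(pairs[::-1]) == pytest.approx(rms_cv(pairs), rel=1e-12)

    def test_monte_carlo_recovery_and_coverage(self):
        hits, est_ok = 0, 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            pairs = simulate_pairs(500, 0.10, rng)
            est = lf.within_subject_cv(pairs, n_boot=300, seed=rep)
            est_ok += 0.08 <= est.cv <= 0.12
            hits += est.ci_low <= 0.10 <= est.ci_high
        assert est_ok == n_rep
        assert hits >= 0.88 * n_rep


class TestCompareCV:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(3)
        pairs = simulate_pairs(40, 0.1, rng)
        res = lf.compare_cv_independent(pairs, pairs.copy(), n_boot=1000, seed=0)
        assert res.p_value >= 0.8

    def test_distinct_cvs_detected(self):
        detected = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            a = simulate_pairs(50, 0.05, rng)
            b = simulate_pairs(50, 0.20, rng)
            res = lf.compare_cv_independent(a, b, n_boot=500, seed=rep)
            detected += res.p_value < 0.05
        assert detected >= 19

    def test_independent_ci_covers_true_delta(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(20_000 + rep)
            a = simulate_pairs(150, 0.08, rng)
            b = simulate_pairs(150, 0.12, rng)
            res = lf.compare_cv_independent(a, b, n_boot=300, seed=rep)
            hits += res.ci_low <= (0.08 - 0.12) <= res.ci_high
        assert hits >= 0.88 * n_rep

    def test_dependent_equal_inputs_give_p_one(self):
        rng = np.random.default_rng(4)
        pairs = simulate_pairs(30, 0.1, rng)
        res = lf.compare_cv_dependent(pairs, pairs.copy(), n_boot=500, seed=0)
        assert res.delta_cv == 0.0
        assert res.p_value == 1.0

    def test_dependent_detects_cv_increase(self):
        detected = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            true = np.abs(rng.normal(10, 2, 74)) + 1e-6
            a = true[:, None] * (1 + rng.normal(0, 0.10, (74, 2)))
            b = true[:, None] * (1 + rng.normal(0, 0.14, (74, 2)))
            res = lf.compare_cv_dependent(np.abs(a), np.abs(b), n_boot=1000, seed=rep)
            detected += (res.delta_cv < 0) and (res.p_value < 0.05)
        assert detected >= 11  # majority of replicates

    def test_joint_resampling_narrower_than_independent_under_correlation(self):
        rng = np.random.default_rng(5)
        true = np.abs(rng.normal(10, 2, 100)) + 1e-6
        shared = rng.normal(0, 0.08, (100, 2))
        a = true[:, None] * (1 + shared + rng.normal(0, 0.03, (100, 2)))
        b = true[:, None] * (1 + shared + rng.normal(0, 0.03, (100, 2)))
        dep = lf.compare_cv_dependent(np.abs(a), np.abs(b), n_boot=2000, seed=1)
        ind = lf.compare_cv_independent(np.abs(a), np.abs(b), n_boot=2000, seed=1)
        assert (dep.ci_high - dep.ci_low) < (ind.ci_high - ind.ci_low)

    def test_mismatched_subject_counts_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="aligned"):
            lf.compare_cv_dependent(
                simulate_pairs(10, 0.1, rng), simulate_pairs(11, 0.1, rng)
            )


class TestBlandAltman:
    def test_identical_pairs(self):
        res = lf.bland_altman(np.array([[3.0, 3.0], [5.0, 5.0]]))
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_hand_computed_limits(self):
        # diffs {-2, +2}: bias 0, SD = 2.828 (n-1), LoA = +/- 5.543
        res = lf.bland_altman(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert res.bias == 0.0
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(8.0), abs=1e-9)
        assert res.loa_high == pytest.approx(5.543, abs=1e-3)
        assert res.loa_low == pytest.approx(-5.543, abs=1e-3)

    def test_constant_shift_moves_bias_not_width(self):
        rng = np.random.default_rng(7)
        pairs = simulate_pairs(40, 0.05, rng)
        shifted = pairs.copy()
        shifted[:, 1] += 1.5
        r0, r1 = lf.bland_altman(pairs), lf.bland_altman(shifted)
        assert r1.bias == pytest.approx(r0.bias - 1.5, abs=1e-9)
        assert (r1.loa_high - r1.loa_low) == pytest.approx(
            r0.loa_high - r0.loa_low, abs=1e-9
        )


class TestAgreementPower:
    def test_no_margin_gives_no_power(self):
        # allowed limit exactly at the expected LoA: nothing to spare
        power = lf.ba_agreement_power(50, 0.01, 0.05, 0.01 + 1.96 * 0.05 + 1e-9)
        assert power < 0.01

    def test_monotone_in_n_and_limit(self):
        p_n = [lf.ba_agreement_power(n, 0.01, 0.05, 0.15) for n in (10, 30, 74, 200)]
        assert p_n == sorted(p_n)
        p_lim = [lf.ba_agreement_power(74, 0.01, 0.05, lim) for lim in (0.12, 0.15, 0.20)]
        assert p_lim == sorted(p_lim)

    def test_sample_size_inverse_consistent(self):
        n = lf.ba_sample_size(0.01, 0.05, 0.15, target_power=0.9)
        assert lf.ba_agreement_power(n, 0.01, 0.05, 0.15) >= 0.9
        if n > 2:
            assert lf.ba_agreement_power(n - 1, 0.01, 0.05, 0.15) < 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            lf.ba_agreement_power(74, 0.2, 0.05, 0.15)
        with pytest.raises(ValueError):
            lf.ba_agreement_power(74, 0.01, 0.0, 0.15)


class TestICC:
    def test_perfect_agreement(self):
        t = np.tile(np.arange(1.0, 7.0)[:, None], (1, 2))
        icc, p = lf.icc_two_way_mixed(t)
        assert icc == pytest.approx(1.0)
        assert p < 0.001

    def test_constant_rater_offset_lowers_absolute_agreement(self):
        base = np.arange(1.0, 11.0)
        t = np.column_stack([base, base + 2.0])
        icc, _ = lf.icc_two_way_mixed(t)
        assert icc < 1.0

    def test_matches_explicit_anova_oracle(self):
        # independent oracle: explicit sums of squares on random 6x2 tables
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.normal(10, 3, (6, 2))
            icc, _ = lf.icc_two_way_mixed(t)
            n, k = t.shape
            grand = t.mean()
            msr = k * ((t.mean(1) - grand) ** 2).sum() / (n - 1)
            msc = n * ((t.mean(0) - grand) ** 2).sum() / (k - 1)
            mse = (
                ((t - t.mean(1, keepdims=True) - t.mean(0, keepdims=True) + grand) ** 2)
                .sum() / ((n - 1) * (k - 1))
            )
            expected = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
            assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        t = rng.normal(10, 3, (8, 2))
        icc, _ = lf.icc_two_way_mixed(t)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "rater": np.tile(["a", "b"], 8),
                "score": t.ravel(),
            }
        )
        res = pingouin.intraclass_corr(long, "subject", "rater", "score")
        icc_a1 = res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc == pytest.approx(icc_a1, abs=1e-9)

    def test_reduces_to_pearson_without_bias(self):
        rng = np.random.default_rng(10)
        x = rng.normal(10, 3, 2000)
        noise = rng.normal(0, 1.0, (2000, 2))
        t = x[:, None] + noise
        icc, _ = lf.icc_two_way_mixed(t)
        r = np.corrcoef(t[:, 0], t[:, 1])[0, 1]
        assert icc == pytest.approx(r, abs=0.01)


class TestMcNemarAndCorrelations:
    def test_mcnemar_no_discordance(self):
        assert lf.mcnemar_test(0, 0) == 1.0

    def test_mcnemar_exact_tail(self):
        # b=10, c=0: exact two-tailed binomial p = 2 * 0.5^10
        assert lf.mcnemar_test(10, 0) == pytest.approx(2 * 0.5**10, abs=1e-9)

    def test_mcnemar_symmetric_counts(self):
        assert lf.mcnemar_test(7, 7) == 1.0

    def test_mcnemar_large_counts_use_chi_square(self):
        p_large = lf.mcnemar_test(40, 20)
        from scipy import stats as ss

        chi2 = (abs(40 - 20) - 1) ** 2 / (40 + 20)
        assert p_large == pytest.approx(ss.chi2.sf(chi2, 1), abs=1e-9)

    def test_pearson_perfectly_linear(self):
        x = np.arange(10.0)
        strata = np.array(["a"] * 5 + ["b"] * 5)
        r, (lo, hi) = lf.pearson_bootstrap(x, 2 * x, strata, n_boot=200, seed=0)
        assert r == pytest.approx(1.0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)
        r_neg, _ = lf.pearson_bootstrap(x, -x, strata, n_boot=50, seed=0)
        assert r_neg == pytest.approx(-1.0)

    def test_pearson_ci_covers_zero_for_independent_data(self):
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(30_000 + rep)
            x = rng.normal(0, 1, 100)
            y = rng.normal(0, 1, 100)
            strata = np.array(["SR"] * 70 + ["AF"] * 30)
            _, (lo, hi) = lf.pearson_bootstrap(x, y, strata, n_boot=300, seed=rep)
            hits += lo <= 0.0 <= hi
        assert hits >= 0.88 * n_rep

    def test_spearman_monotone_and_reversed(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = lf.spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_r, _ = lf.spearman(x, -(x**3))
        assert rho_r == pytest.approx(-1.0)

    def test_spearman_ties_match_explicit_rank_computation(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 5.0, 6.0, 6.0])
        rho, _ = lf.spearman(x, y)
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)


class TestBonferroni:
    def test_basic_and_capped(self):
        np.testing.assert_allclose(
            lf.bonferroni_adjust([0.01, 0.02]), [0.02, 0.04]
        )
        np.testing.assert_allclose(lf.bonferroni_adjust([0.9, 0.9]), [1.0, 1.0])
        np.testing.assert_allclose(lf.bonferroni_adjust([0.3]), [0.3])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    values=st.lists(
        st.tuples(
            st.floats(min_value=0.5, max_value=100.0),
            st.floats(min_value=0.5, max_value=100.0),
        ),
        min_size=2,
        max_size=30,
    ),
    scale=st.floats(min_value=0.01, max_value=1000.0),
)
def test_cv_scale_invariance_property(values, scale):
    pairs = np.array(values)
    assert rms_cv(scale * pairs) == pytest.approx(rms_cv(pairs), rel=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    ps=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10)
)
def test_bonferroni_bounds_property(ps):
    adj = lf.bonferroni_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0 + 1e-15)
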