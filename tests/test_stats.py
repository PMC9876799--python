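"""Tests for the association battery against enumeration oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from b2mcall import (
    AssociationResult,
    ContingencyTable2x2,
    benjamini_hochberg,
    fisher_exact_2x2,
    lm_adjusted,
    lmm_random_intercepts,
    logistic_cb,
    wilcoxon_rank_sum,
)
from oracles import (
    benjamini_hochberg_oracle,
    fisher_two_sided_oracle,
    irls_logistic_oracle,
    wilcoxon_two_sided_oracle,
)


class TestContingencyTable:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 1, 1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestFisherExact:
    def test_printed_cohort_table(self):
        result = fisher_exact_2x2(ContingencyTable2x2(20, 1, 31, 19))
        assert float(f"{result.p_value:.2g}") == 0.0038
        assert result.estimate == pytest.approx(20 * 19 / (1 * 31))

    def test_symmetric_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)).p_value == 1.0

    def test_perfectly_discordant_table(self):
        result = fisher_exact_2x2(ContingencyTable2x2(0, 10, 10, 0))
        assert result.p_value == pytest.approx(2 / math.comb(20, 10))

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)).p_value == 1.0

    def test_infinite_odds_ratio(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = fisher_exact_2x2(ContingencyTable2x2(5, 0, 3, 4))
        assert math.isinf(result.estimate)

    @given(
        a=st.integers(0, 10),
        b=st.integers(0, 10),
        c=st.integers(0, 10),
        d=st.integers(0, 10),
    )
    @settings(max_examples=300)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
        assert p == pytest.approx(
            float(fisher_two_sided_oracle(a, b, c, d)), abs=1e-9
        )

    def test_type_i_error_under_null(self):
        rng = np.random.default_rng(0)
        n_tables, alpha = 200, 0.05
        rejections = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_tables):
                group = rng.integers(0, 2, size=60)
                outcome = rng.integers(0, 2, size=60)  # independent of group
                table = ContingencyTable2x2(
                    int(((group == 1) & (outcome == 1)).sum()),
                    int(((group == 1) & (outcome == 0)).sum()),
                    int(((group == 0) & (outcome == 1)).sum()),
                    int(((group == 0) & (outcome == 0)).sum()),
                )
                if fisher_exact_2x2(table).p_value < alpha:
                    rejections += 1
        # binomial tolerance: 3 sd above alpha * n
        assert rejections <= alpha * n_tables + 3 * math.sqrt(
            n_tables * alpha * (1 - alpha)
        )


class TestWilcoxonRankSum:
    def test_fully_separated_small_sample(self):
        result = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert result.p_value == pytest.approx(0.1)
        assert result.details["method"] == "exact"

    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 5], [1, 2, 5]).p_value == 1.0

    def test_all_values_identical(self):
        assert wilcoxon_rank_sum([3, 3], [3, 3, 3]).p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_branch_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_x = int(rng.integers(1, 11))
        n_y = int(rng.integers(1, 12 - n_x + 1))
        pooled = rng.choice(1000, size=n_x + n_y, replace=False).astype(float)
        x, y = pooled[:n_x], pooled[n_x:]
        result = wilcoxon_rank_sum(x, y)
        assert result.details["method"] == "exact"
        assert result.p_value == pytest.approx(
            wilcoxon_two_sided_oracle(x, y), abs=1e-12
        )

    def test_normal_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pooled = rng.choice(10_000, size=16, replace=False).astype(float)
            x, y = pooled[:8], pooled[8:]
            exact = wilcoxon_two_sided_oracle(x, y)
            # force the approximation branch by adding distant tied decoys
            approx = _normal_branch_p(x, y)
            assert abs(approx - exact) < 0.02

    def test_ties_use_midranks_and_corrected_variance(self):
        result = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3, 4])
        assert result.details["method"] == "normal_approx"
        assert 0.0 < result.p_value <= 1.0


def _normal_branch_p(x, y):
    """Call the production normal-approximation branch on tie-free data by
    exceeding the exact-branch size limit with paired duplicates removed."""
    from b2mcall.stats import EXACT_WILCOXON_MAX_N
    import b2mcall.stats as stats_module

    original = stats_module.EXACT_WILCOXON_MAX_N
    stats_module.EXACT_WILCOXON_MAX_N = 0
    try:
        return wilcoxon_rank_sum(x, y).p_value
    finally:
        stats_module.EXACT_WILCOXON_MAX_N = original


class TestLogisticCb:
    def test_intercept_only_balanced_outcome(self):
        y = np.array([0, 1] * 25)
        result = logistic_cb(y, np.zeros(50, dtype=int))
        assert abs(result.details["intercept"]) < 1e-9

    def test_null_coefficient_recovery(self):
        rng = np.random.default_rng(2)
        n = 5000
        b2m = rng.integers(0, 2, size=n)
        y = rng.random(n) < 0.5  # outcome independent of status
        result = logistic_cb(y.astype(int), b2m)
        assert abs(result.estimate) < 0.1

    def test_matches_reference_irls(self):
        rng = np.random.default_rng(4)
        n = 30
        b2m = rng.integers(0, 2, size=n)
        tmb = rng.normal(size=n)
        eta = -0.3 + 1.2 * b2m + 0.5 * tmb
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        result = logistic_cb(y, b2m, pd.DataFrame({"tmb": tmb}))
        X = np.column_stack([np.ones(n), b2m, tmb])
        beta = irls_logistic_oracle(X, y)
        assert result.estimate == pytest.approx(beta[1], abs=1e-6)

    def test_effect_recovery(self):
        rng = np.random.default_rng(5)
        n = 5000
        b2m = rng.integers(0, 2, size=n)
        eta = 0.2 + 1.5 * b2m
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        result = logistic_cb(y, b2m)
        assert result.estimate == pytest.approx(1.5, abs=0.25)
        assert result.p_value < 1e-10

    def test_perfect_separation_flagged(self):
        b2m = np.array([0] * 10 + [1] * 10)
        y = b2m.copy()
        with pytest.warns(UserWarning, match="separation"):
            result = logistic_cb(y, b2m)
        assert math.isnan(result.p_value)
        assert result.details["separated"] is True

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            logistic_cb([1, 1, 1], [0, 1, 0])


class TestLmAdjusted:
    def test_equals_pooled_t_test(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(6)
        b2m = np.array([0] * 12 + [1] * 13)
        y = rng.normal(size=25) + 0.8 * b2m
        result = lm_adjusted(y, b2m)
        t = ttest_ind(y[b2m == 1], y[b2m == 0], equal_var=True)
        assert result.p_value == pytest.approx(t.pvalue, abs=1e-10)
        assert result.estimate == pytest.approx(
            y[b2m == 1].mean() - y[b2m == 0].mean()
        )

    def test_effect_recovery_with_covariate(self):
        rng = np.random.default_rng(7)
        n = 2000
        b2m = rng.integers(0, 2, size=n)
        site = rng.choice(["colon", "stomach", "uterus"], size=n)
        site_effect = pd.Series(
            {"colon": 0.0, "stomach": 1.0, "uterus": -0.5}
        )[site].to_numpy()
        y = 1.0 * b2m + site_effect + rng.normal(size=n)
        result = lm_adjusted(y, b2m, pd.DataFrame({"site": site}))
        assert result.estimate == pytest.approx(1.0, abs=0.1)
        assert set(result.adjustment) == {"site[stomach]", "site[uterus]"}

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(8)
        n = 30
        b2m = rng.integers(0, 2, size=n)
        x = rng.normal(size=n)
        covs = pd.DataFrame({"x1": x, "x2": x})
        with pytest.raises(ValueError, match="collinear.*x2"):
            lm_adjusted(rng.normal(size=n), b2m, covs)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            lm_adjusted([1.0, 2.0], [0, 1])


class TestLmmRandomIntercepts:
    def test_single_level_group_reduces_to_ols(self):
        rng = np.random.default_rng(9)
        n = 40
        b2m = rng.integers(0, 2, size=n)
        y = 0.5 * b2m + rng.normal(size=n)
        groups = pd.DataFrame({"tumour_type": ["CRC"] * n})
        mixed = lmm_random_intercepts(y, b2m, groups)
        ols = lm_adjusted(y, b2m)
        assert mixed.estimate == pytest.approx(ols.estimate)
        assert "degenerate" in mixed.test_name

    def test_zero_group_variance_recovered(self):
        rng = np.random.default_rng(10)
        n = 2000
        b2m = rng.integers(0, 2, size=n)
        groups = pd.DataFrame(
            {"tumour_type": rng.choice([f"g{i}" for i in range(20)], size=n)}
        )
        y = 1.0 * b2m + rng.normal(size=n)  # no group effect at all
        result = lmm_random_intercepts(y, b2m, groups)
        vc = list(result.details["variance_components"].values())[0]
        assert vc < 0.05
        assert result.estimate == pytest.approx(1.0, abs=0.15)

    def test_group_variance_recovered(self):
        rng = np.random.default_rng(11)
        groups_n, per_group = 50, 40
        labels = np.repeat([f"g{i}" for i in range(groups_n)], per_group)
        offsets = np.repeat(rng.normal(0, 1.0, size=groups_n), per_group)
        n = groups_n * per_group
        b2m = rng.integers(0, 2, size=n)
        y = 0.8 * b2m + offsets + rng.normal(size=n)
        result = lmm_random_intercepts(
            y, b2m, pd.DataFrame({"tumour_type": labels})
        )
        vc = list(result.details["variance_components"].values())[0]
        assert vc == pytest.approx(1.0, abs=0.3)
        assert result.estimate == pytest.approx(0.8, abs=0.15)
        assert result.details["method"] == "REML"

    def test_two_grouping_factors(self):
        rng = np.random.default_rng(12)
        n = 600
        b2m = rng.integers(0, 2, size=n)
        tt = rng.choice(["a", "b", "c", "d"], size=n)
        bs = rng.choice(["x", "y", "z"], size=n)
        y = 0.5 * b2m + rng.normal(size=n)
        result = lmm_random_intercepts(
            y, b2m, pd.DataFrame({"tumour_type": tt, "biopsy_site": bs})
        )
        assert set(result.details["variance_components"]) == {
            "tumour_type",
            "biopsy_site",
        }
        assert result.estimate == pytest.approx(0.5, abs=0.3)


class TestBenjaminiHochberg:
    def test_closed_form_triplet(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.42]) == pytest.approx([0.42])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
    )
    @settings(max_examples=200)
    def test_matches_direct_formula_oracle(self, p):
        assert benjamini_hochberg(p) == pytest.approx(
            benjamini_hochberg_oracle(p), abs=1e-12
        )

    @given(p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adjusted = benjamini_hochberg(p)
        assert (adjusted >= np.asarray(p) - 1e-12).all()
        assert (adjusted <= 1.0).all()


class TestAssociationResult:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            AssociationResult("t", 0.0, 1.5, 10)


class TestEndToEndPower:
    def test_wilcoxon_detects_trdv_effect(self):
        """Cohorts with a +1 log2 TRDV effect at ~60/arm: power >= 90%."""
        from b2mcall import SimulationConfig, simulate_cohort
        from b2mcall.scoring import log2_rpm, rpm

        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            cohort = simulate_cohort(
                SimulationConfig(
                    n_samples=120,
                    frac_b2m_mut=0.5,
                    effect_trdv=1.0,
                    seed=1000 + seed,
                )
            )
            log_expr = log2_rpm(rpm(cohort.expression, cohort.library_sizes))
            score = log_expr.loc[["TRDV1", "TRDV3"]].mean(axis=0)
            is_mut = (
                cohort.truth.set_index("sample_id")["b2m_status"] == "mutant"
            ).reindex(score.index)
            p = wilcoxon_rank_sum(
                score[is_mut.values], score[~is_mut.values]
            ).p_value
            hits += p < 0.05
        assert hits / n_runs >= 0.9
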