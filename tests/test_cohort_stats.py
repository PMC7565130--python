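import warnings
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cscpet import datasets
from cscpet.cohort import (
    ContingencyTable2x2,
    SeparationWarning,
    fisher_exact,
    logistic_fit,
    multivariable_pcr_fit,
    odds_ratio,
    pearson_chi2,
    univariable_or_table,
)
from cscpet.cohort import _enumerate_tables, _table_prob
from cscpet.synthetic import CohortSpec, generate_cohort


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected_or,expected_ci",
        [
            ((20, 33, 2, 27), 8.18, (1.75, 38.16)),  # T stage
            ((18, 37, 4, 23), 2.80, (0.84, 9.31)),  # ER negative
            ((1, 1, 1, 1), 1.00, None),
        ],
    )
    def test_cross_product_and_woolf_ci(self, cells, expected_or, expected_ci):
        res = odds_ratio(ContingencyTable2x2(*cells))
        assert round(res.odds_ratio, 2) == expected_or
        if expected_ci:
            assert (round(res.ci_low, 2), round(res.ci_high, 2)) == expected_ci

    def test_zero_cell_without_correction_names_cell(self):
        with pytest.raises(ValueError, match="'c'"):
            odds_ratio(ContingencyTable2x2(5, 5, 0, 5))

    def test_continuity_correction_flagged(self):
        res = odds_ratio(ContingencyTable2x2(5, 5, 0, 5), continuity_correction=True)
        assert res.corrected
        assert res.odds_ratio == pytest.approx((5.5 * 5.5) / (5.5 * 0.5))


class TestPearsonChi2:
    def test_identical_row_distributions(self):
        res = pearson_chi2([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_dual_her2_comparison_is_significant(self):
        res = pearson_chi2(datasets.dual_her2_response_table())
        assert res.df == 1
        assert res.p_value == pytest.approx(0.021, abs=0.001)

    def test_matches_brute_force_o_minus_e(self):
        rng = np.random.default_rng(2)
        table = rng.integers(1, 30, size=(3, 4)).astype(float)
        res = pearson_chi2(table)
        expected_counts = np.outer(table.sum(1), table.sum(0)) / table.sum()
        stat = ((table - expected_counts) ** 2 / expected_counts).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 6

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[5, 0], [3, 0]])


class TestFisherExact:
    def test_2x2_matches_scipy(self):
        table = np.array([[1, 9], [9, 1]])
        assert fisher_exact(table) == pytest.approx(
            stats.fisher_exact(table)[1], rel=1e-12
        )

    def test_2x2_matches_hand_enumeration(self):
        table = np.array([[1, 9], [9, 1]])
        # enumerate all 2x2 tables with margins (10,10)/(10,10) by first cell
        probs = {
            x: comb(10, x) * comb(10, 10 - x) / comb(20, 10) for x in range(11)
        }
        p_obs = probs[1]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("table", [[[5, 5], [5, 5]], [[2, 2, 2], [2, 2, 2]]])
    def test_identical_rows_give_p_one(self, table):
        assert fisher_exact(np.array(table)) == pytest.approx(1.0)

    def test_nac_regimen_comparison(self):
        assert fisher_exact(datasets.nac_regimen_response_table()) == pytest.approx(
            0.279, abs=0.001
        )

    def test_enumeration_probabilities_sum_to_one(self):
        table = np.array([[3, 1, 4], [2, 5, 1]])
        margins = table.sum(axis=0)
        r0, n = int(table[0].sum()), int(table.sum())
        total = sum(
            _table_prob(row, margins, n, r0) for row in _enumerate_tables(margins, r0)
        )
        assert total == pytest.approx(1.0, rel=1e-12)

    def test_wide_table_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            fisher_exact(np.ones((2, 6), dtype=int))


class TestLogisticFit:
    def test_2x2_identity_with_cross_product(self):
        x = np.array([1.0] * 53 + [0.0] * 29)
        y = np.array([1.0] * 20 + [0.0] * 33 + [1.0] * 2 + [0.0] * 27)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.converged
        assert fit.odds_ratios["x"] == pytest.approx(8.1818, abs=1e-3)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            logistic_fit(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 1, 1])

    def test_coefficient_recovery_at_n2000(self):
        rng = np.random.default_rng(17)
        x = rng.lognormal(0.0, 0.7, 2000)
        p = 1 / (1 + np.exp(-(1.5 - 2.0 * x)))
        y = (rng.random(2000) < p).astype(float)
        fit = logistic_fit(pd.DataFrame({"mtv_csc": x}), y)
        assert fit.converged
        assert fit.coefficients["mtv_csc"] == pytest.approx(-2.0, abs=0.15)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.random(200)})
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + X["a"] - 1.5 * X["b"])))).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ref.params.to_numpy(), rtol=1e-6
        )
        np.testing.assert_allclose(
            fit.covariance.to_numpy(), ref.cov_params().to_numpy(), rtol=1e-4
        )

    def test_separation_warns_and_flags(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = x.copy()  # perfectly separated
        with pytest.warns(SeparationWarning):
            fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert not fit.converged

    def test_loglik_nondecreasing_over_irls_iterations(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(float)
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_complete_case_counting(self):
        X = pd.DataFrame({"x": [1.0, 0.5, np.nan, 2.0, 1.5, 2.5]})
        y = [1, 0, 1, 0, 1, 0]
        fit = logistic_fit(X, y)
        assert fit.n_used == 5


class TestCohortTables:
    @pytest.fixture
    def cohort(self):
        return generate_cohort(CohortSpec(seed=3))

    def test_univariable_table_covers_encodings(self, cohort):
        table = univariable_or_table(cohort)
        for name in ("t_stage_1_2", "er_negative", "mtv_csc", "suv_max"):
            assert name in table.index
        assert (table["odds_ratio"] > 0).all()
        assert ((table["ci_low"] <= table["odds_ratio"])
                & (table["odds_ratio"] <= table["ci_high"])).all()

    def test_univariable_2x2_equivalence(self, cohort):
        """Encoded binary covariate must reproduce the cross-product OR."""
        table = univariable_or_table(cohort)
        exposed = cohort["er_status"] == "negative"
        pcr = cohort["pcr"].astype(bool)
        tab = ContingencyTable2x2(
            a=int((exposed & pcr).sum()), b=int((exposed & ~pcr).sum()),
            c=int((~exposed & pcr).sum()), d=int((~exposed & ~pcr).sum()),
        )
        assert table.loc["er_negative", "odds_ratio"] == pytest.approx(
            odds_ratio(tab).odds_ratio, rel=1e-6
        )

    def test_multivariable_er_mtvcsc_model(self, cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            fit = multivariable_pcr_fit(cohort)
        assert set(fit.coefficients.index) == {"intercept", "er_negative", "mtv_csc"}
        # lower MTVcsc favors pCR by construction of the generator
        assert fit.coefficients["mtv_csc"] < 0
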