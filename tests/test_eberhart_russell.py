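"""Joint-regression stability: indices, slopes, deviations, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from metstab import (
    SyntheticConfig,
    TraitMeans,
    cell_means,
    classify_stability,
    environment_index,
    generate,
    joint_regression,
    phenotypic_index,
)
from metstab.eberhart_russell import ERGenotypeResult
from metstab.exceptions import DegenerateDataError, InsufficientDataError
from conftest import random_means


class TestIndices:
    def test_published_environment_index(self, yield_means):
        idx = environment_index(yield_means).index
        assert idx == pytest.approx([-0.176, 0.015, 0.161], abs=6e-4)
        assert idx.sum() == pytest.approx(0.0, abs=1e-9)

    def test_identical_environments_give_zero_index(self):
        means = TraitMeans("t", ["a", "b"], ["x", "y"], [[1.0, 1.0], [3.0, 3.0]])
        assert environment_index(means).index == pytest.approx([0.0, 0.0])

    def test_index_matches_direct_computation(self, rng):
        means = random_means(rng, 5, 4)
        expected = means.matrix.mean(axis=0) - means.matrix.mean()
        assert environment_index(means).index == pytest.approx(expected, abs=1e-12)

    def test_published_phenotypic_indices(self, yield_means, dtm_means):
        pi_y = phenotypic_index(yield_means)
        assert pi_y[yield_means.genotypes.index("BRRI hybrid dhan5")] == pytest.approx(
            0.959, abs=1e-3
        )
        pi_d = phenotypic_index(dtm_means)
        assert pi_d[dtm_means.genotypes.index("Heera-2")] == pytest.approx(7.0, abs=0.05)
        assert pi_y.sum() == pytest.approx(0.0, abs=1e-9)


class TestJointRegression:
    def test_published_slope_and_deviation(self, yield_means):
        res = joint_regression(yield_means)
        by_name = {r.genotype: r for r in res}
        assert by_name["BRRI35A x BRRI36R"].bi == pytest.approx(1.714, rel=5e-3)
        assert by_name["BRRI99A x BRRI36R"].s2di_paper == pytest.approx(0.23, abs=5e-3)

    def test_mean_slope_is_one(self, rng):
        means = random_means(rng, 10, 5)
        res = joint_regression(means, classify=False)
        assert np.mean([r.bi for r in res]) == pytest.approx(1.0, abs=1e-9)

    def test_perfectly_average_genotype(self):
        # a genotype tracking the environmental index exactly has b=1, no dev
        base = np.array([[3.0, 5.0, 7.0], [5.0, 9.0, 13.0], [4.0, 7.0, 10.0]])
        means = TraitMeans("t", ["a", "b", "c"], ["x", "y", "z"], base)
        idx = environment_index(means).index
        res = joint_regression(means, classify=False)
        target = means.matrix[2] - means.matrix[2].mean()
        assert target == pytest.approx(1.0 * idx)  # row c is exactly average
        assert res[2].bi == pytest.approx(1.0, abs=1e-12)
        assert res[2].ms_dev == pytest.approx(0.0, abs=1e-20)

    def test_against_least_squares_oracle(self, rng):
        means = random_means(rng, 10, 5)
        idx = means.matrix.mean(axis=0) - means.matrix.mean()
        res = joint_regression(means, classify=False)
        for i, r in enumerate(res):
            fit = stats.linregress(idx, means.matrix[i])
            assert r.bi == pytest.approx(fit.slope, rel=1e-10)
            resid = means.matrix[i] - (fit.intercept + fit.slope * idx)
            assert r.ms_dev == pytest.approx((resid @ resid) / 3, rel=1e-9)

    def test_sum_of_squares_decomposition(self, rng):
        means = random_means(rng, 8, 6)
        idx = environment_index(means).index
        ss_idx = idx @ idx
        for r, row in zip(joint_regression(means, classify=False), means.matrix):
            dev = row - row.mean()
            assert dev @ dev == pytest.approx(
                r.bi**2 * ss_idx + r.ms_dev * (len(idx) - 2), rel=1e-12
            )

    def test_textbook_deviation_subtracts_error(self, yield_means):
        res = joint_regression(yield_means, error_ms=0.08, r=3)
        for r in res:
            assert r.s2di_textbook == pytest.approx(r.ms_dev - 0.08 / 3, rel=1e-12)
            assert r.f_dev == pytest.approx(r.ms_dev / (0.08 / 3), rel=1e-12)

    def test_too_few_environments(self):
        means = TraitMeans("t", ["a", "b", "c"], ["x", "y"], np.ones((3, 2)))
        with pytest.raises(InsufficientDataError):
            joint_regression(means)

    def test_degenerate_index(self):
        flat = TraitMeans("t", ["a", "b", "c"], ["x", "y", "z"], np.outer([1.0, 2.0, 3.0], [1, 1, 1]))
        with pytest.raises(DegenerateDataError):
            joint_regression(flat)

    @given(seed=st.integers(0, 200))
    def test_slope_recovery_on_exact_regression_data(self, seed):
        data, truth = generate(
            SyntheticConfig(
                g=6, e=4, r=2, interaction_mode="regression", error_sd=0.0, seed=seed
            )
        )
        means = cell_means(data, "yield")
        res = joint_regression(means, classify=False)
        for r, b in zip(res, truth["regression_slopes"]):
            assert r.bi == pytest.approx(b, abs=1e-9)


class TestClassification:
    @staticmethod
    def _result(pi=0.0, bi=1.0, p_bi=0.9, p_dev=0.9):
        return ERGenotypeResult(
            genotype="g", mean=10.0 + pi, pi=pi, bi=bi, se_bi=0.1,
            ms_dev=0.01, s2di_paper=0.01, s2di_textbook=None,
            t_bi_vs_1=0.0, p_bi=p_bi, f_dev=1.0, p_dev=p_dev,
        )

    def test_stable_above_average(self):
        call = classify_stability(self._result(pi=0.5))
        assert (call.label, call.desirability) == ("stable", "above_average")

    def test_negative_slope_means_poor_environments_only(self):
        call = classify_stability(self._result(pi=-0.2, bi=-0.5, p_bi=0.4))
        assert call.label == "responsive_poor"
        assert call.desirability == "below_average"

    def test_significant_deviation_is_unpredictable(self):
        assert classify_stability(self._result(p_dev=0.01)).label == "unpredictable"

    def test_significant_high_slope_prefers_favorable(self):
        call = classify_stability(self._result(bi=2.5, p_bi=0.01))
        assert call.label == "responsive_favorable"

    def test_significant_low_slope_is_location_specific(self):
        call = classify_stability(self._result(bi=0.4, p_bi=0.01))
        assert call.label == "stable_specific"

    def test_definitionally_ideal_genotype_is_stable(self):
        # Pi = 0, b = 1, zero deviation: perfect average responsiveness
        means = TraitMeans(
            "t", ["ideal", "b", "c"], ["x", "y", "z"],
            np.array([[4.0, 5.0, 6.0], [3.0, 5.0, 7.0], [5.0, 5.0, 5.0]]),
        )
        res = joint_regression(means)
        assert res[0].call.label == "stable"
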