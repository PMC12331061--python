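"""Weibull onset modelling, failure typing, binning, sex comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from faersig import (WeibullOnsetModel, classify_failure, compare_by_sex,
                     tto_distribution, weibull_mle)
from faersig.tto import _ranksum_p


class TestWeibullMle:
    def test_recovers_generative_parameters(self, rng):
        x = 187.21 * rng.weibull(0.73, 10000)
        fit = weibull_mle(x)
        assert 170 <= fit.scale <= 205
        assert 0.70 <= fit.shape <= 0.76

    def test_exponential_shape_ci_contains_one(self, rng):
        x = rng.exponential(50.0, 10000)
        fit = weibull_mle(x)
        assert fit.shape_ci[0] <= 1.0 <= fit.shape_ci[1]
        assert fit.failure_type == "random failure"

    def test_fitted_median_closed_form(self, rng):
        x = 187.21 * rng.weibull(0.73, 5000)
        fit = weibull_mle(x)
        # alpha (ln 2)^(1/beta); for the generative values ~113.3 days,
        # distinct from the empirical median of the skewed sample
        assert fit.fitted_median == pytest.approx(
            fit.scale * np.log(2) ** (1 / fit.shape))
        assert 187.21 * np.log(2) ** (1 / 0.73) == pytest.approx(113.3, abs=0.1)

    def test_refuses_small_or_nonpositive_samples(self):
        with pytest.raises(ValueError, match="at least 10"):
            weibull_mle([1.0] * 9)
        with pytest.raises(ValueError, match="positive"):
            weibull_mle([1.0] * 20 + [0.0])

    def test_profile_ci_brackets_wald(self, rng):
        x = 100.0 * rng.weibull(0.8, 800)
        wald = weibull_mle(x, ci_method="wald")
        prof = weibull_mle(x, ci_method="profile")
        for w, p in zip(wald.shape_ci + wald.scale_ci,
                        prof.shape_ci + prof.scale_ci):
            assert p == pytest.approx(w, rel=0.05)

    def test_empirical_summaries_from_data_not_fit(self, rng):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        fit = weibull_mle(x)
        assert fit.median_days == np.median(x)
        assert fit.iqr_days == tuple(np.percentile(x, [25, 75]))


class TestClassifyFailure:
    @pytest.mark.parametrize("ci,label", [
        ((0.66, 0.79), "early failure"),
        ((0.9, 1.1), "random failure"),
        ((1.2, 1.5), "wear-out failure"),
        ((1.0, 1.0), "random failure"),  # boundary: CI touching 1
    ])
    def test_rule(self, ci, label):
        assert classify_failure(ci) == label


class TestDistribution:
    def test_direct_binning(self):
        bins, curve = tto_distribution([5, 10, 400])
        by = bins.set_index("bin")["proportion"]
        assert by["0-30"] == pytest.approx(2 / 3)
        assert by[">360"] == pytest.approx(1 / 3)
        assert curve["cumulative"].iloc[-1] == 1.0

    def test_all_mass_one_bin(self):
        bins, _ = tto_distribution([31, 40, 60])
        assert bins.set_index("bin")["proportion"]["31-60"] == 1.0

    def test_bin_edges_inclusive(self):
        bins, _ = tto_distribution([30, 31, 360, 361])
        by = bins.set_index("bin")["count"]
        assert by["0-30"] == 1 and by["31-60"] == 1
        assert by["181-360"] == 1 and by[">360"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tto_distribution([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 2000, allow_nan=False), min_size=1,
                    max_size=200))
    def test_proportions_sum_to_one(self, xs):
        bins, _ = tto_distribution(xs)
        assert bins["proportion"].sum() == pytest.approx(1.0, abs=1e-12)


class TestCompareBySex:
    def test_exact_small_sample(self):
        w, p, method = _ranksum_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert method == "exact"
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p, method = _ranksum_p(np.array([5.0] * 4), np.array([5.0] * 4))
        assert method == "exact" and p == 1.0

    def test_normal_approximation_matches_reference(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.4, 1, 50)
        _, p, method = _ranksum_p(x, y)
        assert method == "normal"
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_generative_sex_shift_detected(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            onset = np.concatenate([100 * r.weibull(1.0, 500),
                                    200 * r.weibull(1.0, 500)])
            sex = ["female"] * 500 + ["male"] * 500
            cmp_ = compare_by_sex(onset, sex)
            hits += cmp_.p_two_sided < 0.01
        assert hits >= 19

    def test_unknown_sex_excluded_and_counted(self):
        cmp_ = compare_by_sex([1, 2, 3, 4, 5],
                              ["female", "female", "male", "male", "unknown"])
        assert cmp_.n_unknown == 1
        assert cmp_.median_female == 1.5 and cmp_.median_male == 3.5

    def test_empty_group_refused(self):
        with pytest.raises(ValueError, match="per sex"):
            compare_by_sex([1, 2, 3], ["female", "female", "unknown"])


class TestModelObjects:
    def test_fit_results_surface(self, rng):
        x = 150 * rng.weibull(0.7, 500)
        sex = rng.choice(["female", "male"], 500)
        res = WeibullOnsetModel(x, sex).fit()
        assert res.n == 500
        assert res.failure_type in ("early failure", "random failure")
        assert "Weibull" in res.summary()
        bins, curve = res.distribution()
        assert bins["count"].sum() == 500
        c = res.compare_by_sex()
        assert c.n_female + c.n_male == 500

    def test_sex_required_for_comparison(self, rng):
        res = WeibullOnsetModel(150 * rng.weibull(0.7, 100)).fit()
        with pytest.raises(ValueError):
            res.compare_by_sex()
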