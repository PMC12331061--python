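"""Disproportionality estimators against hand-evaluated and generative
oracles, plus the combined four-criteria decision."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersig import DisproportionalityModel, MgpsPrior, combined_signal
from faersig.signals import (DEFAULT_MGPS_INIT, _mgps_logmarg, ebgm_scores,
                             fit_mgps_prior, ic_bate, ic_noren, prr_estimate,
                             ror_estimate)


class TestRor:
    def test_worked_example(self):
        # hand evaluation: ROR = 20*90/(80*10); Woolf CI on the log scale
        ror, lo, hi = ror_estimate(20, 80, 10, 90)
        assert ror == pytest.approx(2.25)
        assert lo == pytest.approx(0.9943, abs=2e-3)
        assert hi == pytest.approx(5.0915, abs=2e-3)

    def test_independence_gives_unity(self):
        ror, lo, hi = ror_estimate(10, 10, 10, 10)
        assert ror == 1.0 and lo < 1.0 < hi

    def test_zero_cell_policy(self):
        ror, lo, hi = ror_estimate(0, 10, 10, 100)
        assert np.isfinite([ror, lo, hi]).all()  # Haldane +0.5 applied
        ror2, lo2, hi2 = ror_estimate(0, 10, 10, 100, zero_cell_correction=False)
        assert np.isnan(ror2)  # marker, not an exception


class TestPrr:
    def test_worked_example_with_yates(self):
        prr, lo, hi, chi2 = prr_estimate(20, 80, 10, 90)
        assert prr == pytest.approx(2.0)
        # Yates: 200*(|1800-800|-100)^2 / (100*100*30*170)
        assert chi2 == pytest.approx(3.17647, abs=1e-4)
        # PRR criterion fails despite PRR >= 2: chi2 < 4
        assert not (prr >= 2 and chi2 > 4)

    def test_chi2_clamped_nonnegative(self):
        _, _, _, chi2 = prr_estimate(1, 1, 1, 1)
        assert chi2 == 0.0

    def test_independence(self):
        prr, *_ = prr_estimate(10, 10, 10, 10)
        assert prr == 1.0


class TestIc:
    def test_noren_worked_example(self):
        # a=50, E=2: IC = log2(50.5/2.5)
        ic, ic025 = ic_noren(50, 2.0)
        assert ic == pytest.approx(np.log2(50.5 / 2.5), abs=1e-12)
        assert ic025 == pytest.approx(3.8663, abs=1e-3)

    def test_noren_zero_at_independence(self):
        ic, _ = ic_noren(1000, 1000.0)
        assert abs(ic) < 1e-9

    def test_bate_matches_posterior_sampling(self):
        # Monte-Carlo draws from the Beta posteriors of the BCPNN model
        rng = np.random.default_rng(0)
        a, b, c, d = 50, 100, 200, 10000
        n = a + b + c + d
        gam = (n + 2) ** 2 / ((a + b + 1) * (a + c + 1))
        m = 200_000
        pxy = rng.beta(a + 1, n - a + gam - 1, m)
        px = rng.beta(a + b + 1, n - (a + b) + 1, m)
        py = rng.beta(a + c + 1, n - (a + c) + 1, m)
        ic_draws = np.log2(pxy / (px * py))
        e_ic, ic025 = ic_bate(a, b, c, d)
        sd = (e_ic - ic025) / 2
        assert e_ic == pytest.approx(ic_draws.mean(),
                                     abs=3 * ic_draws.std() / np.sqrt(m))
        assert sd**2 == pytest.approx(ic_draws.var(), rel=0.02)

    def test_bate_first_order_form_close_for_large_counts(self):
        exact = ic_bate(200, 800, 1000, 90000)
        approx = ic_bate(200, 800, 1000, 90000, approx=True)
        assert exact[0] == pytest.approx(approx[0], abs=0.01)

    def test_ic025_below_ic(self):
        for cell in [(3, 5, 7, 500), (50, 100, 200, 10000)]:
            e, lo = ic_bate(*cell)
            assert lo < e


class TestMgps:
    def test_pure_noise_prior_mean_near_unity(self, rng):
        e = rng.uniform(0.5, 20, 5000)
        a = rng.poisson(e)
        prior = fit_mgps_prior(a, e)
        assert 0.8 <= prior.mean <= 1.2

    def test_loglik_no_worse_than_initialisation(self, rng):
        e = rng.uniform(0.5, 10, 1000)
        a = rng.poisson(2.0 * e)
        prior = fit_mgps_prior(a, e)
        ll0 = float(np.sum(_mgps_logmarg(a, e, *DEFAULT_MGPS_INIT)))
        assert prior.loglik >= ll0

    def test_duplicated_corpus_same_induced_prior(self, rng):
        # hyperparameters sit on a likelihood ridge; the induced marginal
        # likelihood and shrinkage scores are the identifiable objects
        e = rng.uniform(0.5, 20, 2000)
        a = rng.poisson(e)
        p1 = fit_mgps_prior(a, e)
        p2 = fit_mgps_prior(np.tile(a, 2), np.tile(e, 2))
        assert p1.loglik / len(a) == pytest.approx(p2.loglik / (2 * len(a)),
                                                   abs=1e-3)
        g = ([1, 5, 20], [1.0, 5.0, 20.0])
        np.testing.assert_allclose(ebgm_scores(*g, p1)[0],
                                   ebgm_scores(*g, p2)[0], rtol=1e-2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MgpsPrior(-1, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            MgpsPrior(1, 1, 1, 1, 1.5)


FIXED_PRIOR = MgpsPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class TestEbgm:
    def test_shrinkage_vanishes_for_large_counts(self):
        ebgm, _ = ebgm_scores(10000, 1000.0, FIXED_PRIOR)
        assert ebgm[0] == pytest.approx(10.0, rel=0.02)

    def test_shrinks_between_prior_gm_and_mle(self):
        from scipy.special import digamma
        prior_gm = np.exp(
            FIXED_PRIOR.p_mix * (digamma(0.2) - np.log(0.1))
            + (1 - FIXED_PRIOR.p_mix) * (digamma(2.0) - np.log(4.0)))
        ebgm, _ = ebgm_scores(1, 1.0, FIXED_PRIOR)
        assert prior_gm < ebgm[0] < 1.0

    def test_ebgm05_below_ebgm_and_positive(self):
        ebgm, ebgm05 = ebgm_scores([1, 3, 10, 50], [0.5, 3.0, 2.0, 5.0],
                                   FIXED_PRIOR)
        assert (ebgm05 < ebgm).all() and (ebgm05 > 0).all()

    def test_large_count_ic_ebgm_consistency(self):
        # for big cells the shrunken log2 O/E and log2 EBGM coincide
        ebgm, _ = ebgm_scores(1000, 100.0, FIXED_PRIOR)
        ic, _ = ic_noren(1000, 100.0)
        assert abs(ic - np.log2(ebgm[0])) < 0.1


@settings(deadline=None, derandomize=True, max_examples=60)
@given(a=st.integers(1, 200), b=st.integers(1, 500), c=st.integers(1, 500),
       d=st.integers(1, 5000))
def test_ror_at_least_prr_when_positive(a, b, c, d):
    ror, *_ = ror_estimate(a, b, c, d)
    prr, *_ = prr_estimate(a, b, c, d)
    if ror > 1:
        assert ror >= prr - 1e-12


@settings(deadline=None, derandomize=True, max_examples=40)
@given(a=st.integers(2, 50), eb=st.integers(0, 300), ec=st.integers(0, 300),
       d=st.integers(10**4, 10**6))
def test_monotone_in_observed_count(a, eb, ec, d):
    """Holding b, c, d and the prior fixed, every score rises with a.

    Restricted to the screening regime where the margins dominate the cell
    (b, c >> a, d >> everything): when a single cell makes up most of its
    own margins the expected count grows ~quadratically in a and the
    shrinkage estimators legitimately fall.
    """
    b, c = 5 * a + eb, 5 * a + ec

    def scores(ai):
        n = ai + b + c + d
        e = (ai + b) * (ai + c) / n
        return (ror_estimate(ai, b, c, d)[0], prr_estimate(ai, b, c, d)[0],
                ic_noren(ai, e)[0], ebgm_scores(ai, e, FIXED_PRIOR)[0][0])
    s1, s2 = scores(a), scores(a + 5)
    assert all(y >= x - 1e-9 for x, y in zip(s1, s2))


class TestCombinedSignal:
    def _frame(self, **over):
        base = dict(label="x", a=63, expected=0.6, ror=100.11, ror_lo=77.98,
                    ror_hi=128.53, prr=98.45, prr_lo=70.0, prr_hi=130.0,
                    chi2=6036.78, ic_bate=6.61, ic025_bate=4.92,
                    ic_noren=6.6, ic025_noren=4.9, ebgm=97.79, ebgm05=76.17)
        base.update(over)
        return pd.DataFrame([base])

    def test_all_criteria_met_is_signal(self):
        out = combined_signal(self._frame())
        assert bool(out["is_signal"].iloc[0])

    def test_single_criterion_failure_blocks(self):
        out = combined_signal(self._frame(prr=1.9))
        assert not bool(out["is_signal"].iloc[0])
        assert not bool(out["prr_positive"].iloc[0])
        assert bool(out["ror_positive"].iloc[0])

    def test_minimum_count_gate(self):
        out = combined_signal(self._frame(a=2))
        assert not bool(out["is_signal"].iloc[0])
        assert not bool(out["min_cases_met"].iloc[0])


def test_model_flags_planted_signals_only(bundle, screened):
    res = DisproportionalityModel(screened["cells"],
                                  screened["all_cells"]).fit()
    flagged = set(res.signals["label"])
    assert flagged == set(bundle.config.planted_signals)
    est = res.estimates
    assert (est["ror_lo"] <= est["ror"]).all()
    assert (est["ror"] <= est["ror_hi"]).all()
    assert (est["ic025_bate"] <= est["ic_bate"]).all()
    assert (est["ic025_noren"] <= est["ic_noren"]).all()
    assert (est["ebgm05"] <= est["ebgm"]).all()
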