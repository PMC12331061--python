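"""Disproportionality statistics and the combined signal decision.

Four classical pharmacovigilance screens over a 2x2 cell (a, b, c, d):

* ROR, reporting odds ratio ``ad/bc`` with a Woolf (log-normal) 95% CI;
* PRR, proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with its
  log-normal CI and the Yates-corrected chi-square;
* BCPNN information component, ``IC = log2`` of the shrunken
  observed-to-expected reporting ratio, in the original Bayesian
  formulation (Beta posteriors over the report proportions; exact
  digamma/trigamma posterior moments) and in the Noren expected-count
  formulation with its credibility-interval approximation;
* MGPS, the multi-item gamma-Poisson shrinker: a two-component gamma
  mixture prior over the relative reporting rate lambda, fitted by
  marginal maximum likelihood across all drug-event cells, yielding the
  empirical-Bayes geometric mean EBGM and its posterior 5th percentile
  EBGM05.

A cell is a signal when every criterion holds: ROR 95% CI lower bound > 1;
PRR >= 2 with chi-square > 4; IC025 > 0; EBGM05 > 2; and at least
``min_cases`` reports (default 3).

`DisproportionalityModel` bundles the four screens behind a
fit()/results interface: construction takes the index-drug cells (and
optionally the full drug-event cell corpus for the prior), ``fit`` returns
a `DisproportionalityResults` with the per-cell estimates, the fitted
prior, the criteria trace and ranking helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ror_estimate", "prr_estimate", "ic_bate", "ic_noren",
    "MgpsPrior", "fit_mgps_prior", "ebgm_scores", "combined_signal",
    "DisproportionalityModel", "DisproportionalityResults",
]

_LN2 = np.log(2.0)
_Z = 1.959963984540054  # two-sided 95% normal quantile


def _counts(a, b, c, d):
    return (np.asarray(a, dtype=float), np.asarray(b, dtype=float),
            np.asarray(c, dtype=float), np.asarray(d, dtype=float))


def _haldane(a, b, c, d):
    """Add 0.5 to every cell of tables containing a zero."""
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    h = np.where(zero, 0.5, 0.0)
    return a + h, b + h, c + h, d + h


def ror_estimate(a, b, c, d, zero_cell_correction: bool = True):
    """Reporting odds ratio with Woolf 95% CI.

    Tables containing a zero get the Haldane-Anscombe +0.5 on all four
    cells first; with the correction disabled such tables yield NaN (an
    undefined-estimate marker, not an exception).
    """
    a, b, c, d = _counts(a, b, c, d)
    if zero_cell_correction:
        a, b, c, d = _haldane(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = ror * np.exp(-_Z * se)
        hi = ror * np.exp(_Z * se)
        bad = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    ror, lo, hi = (np.where(bad, np.nan, x) for x in (ror, lo, hi))
    return ror, lo, hi


def prr_estimate(a, b, c, d, zero_cell_correction: bool = True, yates: bool = True):
    """Proportional reporting ratio, its 95% CI, and the chi-square.

    The chi-square is computed on the *raw* counts (Yates continuity
    correction by default, clamped at zero); the +0.5 zero-cell handling
    applies only to the ratio and its CI.
    """
    a0, b0, c0, d0 = _counts(a, b, c, d)
    n = a0 + b0 + c0 + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.abs(a0 * d0 - b0 * c0)
        if yates:
            dev = np.maximum(dev - n / 2, 0.0)
        chi2 = n * dev**2 / ((a0 + b0) * (c0 + d0) * (a0 + c0) * (b0 + d0))
    a, b, c, d = (a0, b0, c0, d0)
    if zero_cell_correction:
        a, b, c, d = _haldane(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        lo = prr * np.exp(-_Z * se)
        hi = prr * np.exp(_Z * se)
        bad = (a == 0) | (c == 0)
    prr, lo, hi = (np.where(bad, np.nan, x) for x in (prr, lo, hi))
    return prr, lo, hi, chi2


def ic_bate(a, b, c, d, *, gamma11: float = 1.0, alpha1: float = 1.0,
            beta1: float = 1.0, alpha: float = 2.0, beta: float = 2.0,
            approx: bool = False):
    """Information component of the original BCPNN, with IC025 = E - 2*SD.

    Posterior model: the joint reporting proportion p_xy and the margins
    p_x, p_y carry Beta posteriors; ``IC = log2(p_xy / (p_x p_y))``.  The
    prior count gamma of the joint cell is tied to the margins so that the
    prior IC is centred at zero.  By default the *exact* posterior mean and
    variance of IC are returned (digamma/trigamma of the Beta parameters);
    ``approx=True`` gives the historical first-order closed form instead.
    """
    a, b, c, d = _counts(a, b, c, d)
    n = a + b + c + d
    n1 = a + b  # drug margin
    n2 = a + c  # event margin
    gamma = gamma11 * (n + alpha) * (n + beta) / ((n1 + alpha1) * (n2 + beta1))
    if approx:
        e_ic = np.log2((a + gamma11) * (n + alpha) * (n + beta)
                       / ((n + gamma) * (n1 + alpha1) * (n2 + beta1)))
        v_ic = ((n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
                + (n - n1 + alpha - alpha1) / ((n1 + alpha1) * (1 + n + alpha))
                + (n - n2 + beta - beta1) / ((n2 + beta1) * (1 + n + beta))) / _LN2**2
    else:
        psi, psi1 = special.digamma, special.polygamma
        e_ic = (psi(a + gamma11) - psi(n + gamma)
                - psi(n1 + alpha1) + psi(n + alpha)
                - psi(n2 + beta1) + psi(n + beta)) / _LN2
        v_ic = (psi1(1, a + gamma11) - psi1(1, n + gamma)
                + psi1(1, n1 + alpha1) - psi1(1, n + alpha)
                + psi1(1, n2 + beta1) - psi1(1, n + beta)) / _LN2**2
    return e_ic, e_ic - 2.0 * np.sqrt(v_ic)


def ic_noren(a, expected):
    """Noren's IC with its closed-form 2.5% credibility bound.

    ``IC = log2((a + 1/2)/(E + 1/2))``;
    ``IC025 = IC - 3.3(a+1/2)^{-1/2} - 2(a+1/2)^{-3/2}``.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    ic = np.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    return ic, ic025


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior over the relative reporting rate.

    lambda ~ p * Gamma(alpha1, beta1) + (1-p) * Gamma(alpha2, beta2)
    (shape/rate), a | lambda ~ Poisson(lambda * E).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float
    loglik: float = np.nan
    converged: bool = True

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.p_mix < 1.0:
            raise ValueError("p_mix must lie in (0, 1)")

    @property
    def mean(self) -> float:
        """Prior mean of lambda."""
        return (self.p_mix * self.alpha1 / self.beta1
                + (1 - self.p_mix) * self.alpha2 / self.beta2)


DEFAULT_MGPS_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mgps_logmarg(a, e, alpha1, beta1, alpha2, beta2, p_mix):
    """log of the negative-binomial mixture marginal, per cell."""
    lp1 = stats.nbinom.logpmf(a, alpha1, beta1 / (beta1 + e))
    lp2 = stats.nbinom.logpmf(a, alpha2, beta2 / (beta2 + e))
    return np.logaddexp(np.log(p_mix) + lp1, np.log1p(-p_mix) + lp2)


def fit_mgps_prior(
    a: Sequence[float],
    expected: Sequence[float],
    init: tuple[float, float, float, float, float] = DEFAULT_MGPS_INIT,
) -> MgpsPrior:
    """Marginal maximum-likelihood fit of the gamma-mixture hyperparameters.

    Optimises in (log alpha1, log beta1, log alpha2, log beta2, logit p)
    with box bounds keeping every parameter in [e^-10, e^10]; the classical
    initialisation is (0.2, 0.1, 2, 4, 1/3).  Non-convergence returns the
    best point found with ``converged=False``.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(expected, dtype=float)
    if len(a) != len(e) or len(a) == 0:
        raise ValueError("a and expected must be equal-length, non-empty")
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")

    def unpack(z):
        return (*np.exp(z[:4]), special.expit(z[4]))

    def nll(z):
        al1, be1, al2, be2, p = unpack(z)
        return -float(np.sum(_mgps_logmarg(a, e, al1, be1, al2, be2, p)))

    z0 = np.array([np.log(init[0]), np.log(init[1]), np.log(init[2]),
                   np.log(init[3]), special.logit(init[4])])
    res = optimize.minimize(nll, z0, method="L-BFGS-B",
                            bounds=[(-10, 10)] * 4 + [(-12, 12)])
    al1, be1, al2, be2, p = unpack(res.x)
    return MgpsPrior(al1, be1, al2, be2, p, loglik=-float(res.fun),
                     converged=bool(res.success))


def _posterior_weights(a, e, prior: MgpsPrior):
    l1 = np.log(prior.p_mix) + stats.nbinom.logpmf(a, prior.alpha1,
                                                   prior.beta1 / (prior.beta1 + e))
    l2 = np.log1p(-prior.p_mix) + stats.nbinom.logpmf(a, prior.alpha2,
                                                      prior.beta2 / (prior.beta2 + e))
    return special.expit(l1 - l2)  # Q = posterior weight of component 1


def ebgm_scores(a, expected, prior: MgpsPrior):
    """Empirical-Bayes geometric mean and posterior 5th percentile.

    The posterior of lambda is the mixture
    ``Q Gamma(alpha1+a, beta1+E) + (1-Q) Gamma(alpha2+a, beta2+E)``;
    ``EBGM = exp(E[ln lambda])`` and ``EBGM05`` solves the mixture CDF at
    0.05 by bracketed root-finding.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    e = np.atleast_1d(np.asarray(expected, dtype=float))
    q = _posterior_weights(a, e, prior)
    s1, r1 = prior.alpha1 + a, prior.beta1 + e
    s2, r2 = prior.alpha2 + a, prior.beta2 + e
    ebgm = np.exp(q * (special.digamma(s1) - np.log(r1))
                  + (1 - q) * (special.digamma(s2) - np.log(r2)))

    ebgm05 = np.empty_like(ebgm)
    for i in range(len(ebgm)):
        def cdf(x):
            return (q[i] * stats.gamma.cdf(x, s1[i], scale=1 / r1[i])
                    + (1 - q[i]) * stats.gamma.cdf(x, s2[i], scale=1 / r2[i]) - 0.05)
        lo = min(stats.gamma.ppf(1e-4, s1[i], scale=1 / r1[i]),
                 stats.gamma.ppf(1e-4, s2[i], scale=1 / r2[i]))
        hi = max(stats.gamma.ppf(0.999, s1[i], scale=1 / r1[i]),
                 stats.gamma.ppf(0.999, s2[i], scale=1 / r2[i]))
        ebgm05[i] = optimize.brentq(cdf, min(lo, 1e-12), hi, xtol=1e-12, rtol=1e-12)
    return ebgm, ebgm05


CRITERIA = ("ror_positive", "prr_positive", "ic_positive", "ebgm_positive",
            "min_cases_met")


def combined_signal(est: pd.DataFrame, min_cases: int = 3,
                    ic_variant: str = "bate") -> pd.DataFrame:
    """Per-method criteria and the all-methods-positive signal flag.

    Criteria: ROR CI lower bound > 1; PRR >= 2 and chi2 > 4; IC025 > 0
    (Bate or Noren variant); EBGM05 > 2; a >= ``min_cases``.  Cells below
    the case threshold are excluded before evaluation (flag False).
    """
    ic025 = est["ic025_bate"] if ic_variant == "bate" else est["ic025_noren"]
    out = est.copy()
    out["min_cases_met"] = est["a"] >= min_cases
    out["ror_positive"] = est["ror_lo"] > 1
    out["prr_positive"] = (est["prr"] >= 2) & (est["chi2"] > 4)
    out["ic_positive"] = ic025 > 0
    out["ebgm_positive"] = est["ebgm05"] > 2
    out["is_signal"] = out[list(CRITERIA)].all(axis=1)
    return out


class DisproportionalityModel:
    """Four-method disproportionality screen over a set of 2x2 cells.

    Parameters
    ----------
    cells : DataFrame with columns label, a, b, c, d (index-drug cells);
        an ``expected`` column is recomputed if absent.
    all_cells : optional DataFrame with columns a, expected covering every
        drug-event pair of the corpus; used to fit the MGPS prior.  When
        omitted the prior is fitted on ``cells`` itself.
    """

    def __init__(self, cells: pd.DataFrame, all_cells: pd.DataFrame | None = None,
                 *, min_cases: int = 3, ic_variant: str = "bate",
                 yates: bool = True, zero_cell_correction: bool = True):
        missing = [c for c in ("label", "a", "b", "c", "d") if c not in cells.columns]
        if missing:
            raise ValueError(f"cells lacks columns {missing}")
        if ic_variant not in ("bate", "noren"):
            raise ValueError("ic_variant must be 'bate' or 'noren'")
        self.cells = cells.reset_index(drop=True).copy()
        n = (self.cells[["a", "b", "c", "d"]].sum(axis=1)).astype(float)
        self.cells["expected"] = ((self.cells["a"] + self.cells["b"])
                                  * (self.cells["a"] + self.cells["c"]) / n)
        self.all_cells = all_cells
        self.min_cases = min_cases
        self.ic_variant = ic_variant
        self.yates = yates
        self.zero_cell_correction = zero_cell_correction

    def fit(self, prior: MgpsPrior | None = None) -> "DisproportionalityResults":
        c = self.cells
        a, b, cc, d = (c[k].to_numpy(float) for k in ("a", "b", "c", "d"))
        if prior is None:
            if self.all_cells is not None:
                prior = fit_mgps_prior(self.all_cells["a"], self.all_cells["expected"])
            else:
                prior = fit_mgps_prior(a, c["expected"].to_numpy(float))
        est = pd.DataFrame({"label": c["label"], "a": c["a"],
                            "expected": c["expected"]})
        est["ror"], est["ror_lo"], est["ror_hi"] = ror_estimate(
            a, b, cc, d, self.zero_cell_correction)
        est["prr"], est["prr_lo"], est["prr_hi"], est["chi2"] = prr_estimate(
            a, b, cc, d, self.zero_cell_correction, self.yates)
        est["ic_bate"], est["ic025_bate"] = ic_bate(a, b, cc, d)
        est["ic_noren"], est["ic025_noren"] = ic_noren(a, est["expected"])
        est["ebgm"], est["ebgm05"] = ebgm_scores(a, est["expected"].to_numpy(float),
                                                 prior)
        est = combined_signal(est, self.min_cases, self.ic_variant)
        return DisproportionalityResults(self, est, prior)


class DisproportionalityResults:
    """Per-cell estimates, criteria trace and fitted prior."""

    def __init__(self, model: DisproportionalityModel, estimates: pd.DataFrame,
                 prior: MgpsPrior):
        self.model = model
        self.estimates = estimates
        self.prior = prior

    @property
    def signals(self) -> pd.DataFrame:
        return self.estimates[self.estimates["is_signal"]].reset_index(drop=True)

    def rank(self, by: str = "frequency", n: int = 30) -> pd.DataFrame:
        """Top-n signal rows ranked by case frequency or by ROR intensity.

        Ties break deterministically: frequency desc, then ROR desc, then
        label asc (and ROR desc first for ``by='ror'``).
        """
        sig = self.signals.copy()
        if by == "frequency":
            keys, asc = ["a", "ror", "label"], [False, False, True]
        elif by == "ror":
            keys, asc = ["ror", "a", "label"], [False, False, True]
        else:
            raise ValueError("by must be 'frequency' or 'ror'")
        sig = sig.sort_values(keys, ascending=asc, kind="mergesort",
                              ignore_index=True)
        return sig.head(n)

    def summary(self) -> str:
        e = self.estimates
        lines = [
            "Disproportionality screen",
            f"  cells: {len(e)}   signals (all four criteria): {int(e['is_signal'].sum())}",
            f"  MGPS prior: a1={self.prior.alpha1:.4g} b1={self.prior.beta1:.4g} "
            f"a2={self.prior.alpha2:.4g} b2={self.prior.beta2:.4g} "
            f"p={self.prior.p_mix:.4g} (loglik {self.prior.loglik:.2f}, "
            f"converged={self.prior.converged})",
            "",
            e.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)
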