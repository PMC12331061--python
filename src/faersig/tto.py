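"""Time-to-onset modelling: Weibull fit, failure typing, binned
distribution, cumulative curve and the sex-stratified rank-sum comparison.

Onset times are days from therapy initiation to adverse-event occurrence.
The two-parameter Weibull with scale alpha (days) and shape beta describes
how the reporting hazard evolves: beta < 1 means a decreasing hazard
(early failure), beta ~ 1 a constant hazard (random failure), beta > 1 an
increasing hazard (wear-out failure); the label is assigned from the 95%
CI of beta, not the point estimate.  Spontaneous reports carry no at-risk
denominators, so the cumulative curve is the plain ECDF of reported
onsets, not a survival estimate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WeibullFit", "weibull_mle", "classify_failure", "tto_distribution",
    "compare_by_sex", "SexComparison", "WeibullOnsetModel",
    "WeibullOnsetResults", "DEFAULT_BIN_EDGES",
]

# Upper edges (days, inclusive) of the conventional TTO bins:
# 0-30, 31-60, 61-90, 91-180, 181-360, >360.
DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)

_CHI2_95_1DF = 3.841458820694124


@dataclass(frozen=True)
class WeibullFit:
    """MLE of a two-parameter Weibull over observed onset days."""

    n: int
    scale: float
    scale_ci: tuple[float, float]
    shape: float
    shape_ci: tuple[float, float]
    median_days: float          # empirical, not fitted
    iqr_days: tuple[float, float]
    failure_type: str
    loglik: float

    @property
    def fitted_median(self) -> float:
        """Closed-form median of the fitted law, alpha * (ln 2)^(1/beta)."""
        return self.scale * math.log(2.0) ** (1.0 / self.shape)

    def summary(self) -> str:
        return (
            f"Weibull time-to-onset fit (n={self.n})\n"
            f"  scale alpha: {self.scale:.2f} days "
            f"(95% CI {self.scale_ci[0]:.2f} - {self.scale_ci[1]:.2f})\n"
            f"  shape beta : {self.shape:.2f} "
            f"(95% CI {self.shape_ci[0]:.2f} - {self.shape_ci[1]:.2f})\n"
            f"  empirical median (IQR): {self.median_days:.2f} "
            f"({self.iqr_days[0]:.2f}, {self.iqr_days[1]:.2f}) days\n"
            f"  failure type: {self.failure_type}\n"
            f"  log-likelihood: {self.loglik:.3f}"
        )


def _loglik(x: np.ndarray, shape: float, scale: float) -> float:
    return float(np.sum(stats.weibull_min.logpdf(x, shape, scale=scale)))


def _hessian_loglog(x: np.ndarray, shape: float, scale: float, h: float = 1e-5):
    """Observed information of the loglik in (log shape, log scale)."""
    t0 = np.array([np.log(shape), np.log(scale)])

    def f(t):
        return _loglik(x, np.exp(t[0]), np.exp(t[1]))

    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = t0.copy(); tpp[i] += h; tpp[j] += h
            tpm = t0.copy(); tpm[i] += h; tpm[j] -= h
            tmp = t0.copy(); tmp[i] -= h; tmp[j] += h
            tmm = t0.copy(); tmm[i] -= h; tmm[j] -= h
            hess[i, j] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h * h)
    return hess


def classify_failure(shape_ci: tuple[float, float]) -> str:
    """Failure mode from the shape CI: upper < 1 early, lower > 1 wear-out,
    else random."""
    lo, hi = shape_ci
    if hi < 1.0:
        return "early failure"
    if lo > 1.0:
        return "wear-out failure"
    return "random failure"


def _profile_ci(x: np.ndarray, which: str, shape: float, scale: float,
                llmax: float) -> tuple[float, float]:
    """Likelihood-ratio 95% CI by root-finding on the profile deviance."""
    target = llmax - _CHI2_95_1DF / 2.0

    if which == "shape":
        def prof(beta):
            alpha = np.mean(x ** beta) ** (1.0 / beta)  # closed-form inner MLE
            return _loglik(x, beta, alpha)
        centre = shape
    else:
        def prof(alpha):
            r = optimize.minimize_scalar(
                lambda lb: -_loglik(x, np.exp(lb), alpha),
                bounds=(np.log(shape) - 4, np.log(shape) + 4), method="bounded")
            return -r.fun
        centre = scale

    def g(v):
        return prof(v) - target

    lo_br = centre
    while g(lo_br) > 0 and lo_br > centre * 1e-4:
        lo_br /= 1.5
    hi_br = centre
    while g(hi_br) > 0 and hi_br < centre * 1e4:
        hi_br *= 1.5
    lo = optimize.brentq(g, lo_br, centre) if g(lo_br) < 0 else lo_br
    hi = optimize.brentq(g, centre, hi_br) if g(hi_br) < 0 else hi_br
    return lo, hi


def weibull_mle(onset_days, ci_method: str = "wald") -> WeibullFit:
    """Maximum-likelihood Weibull fit with 95% CIs.

    ``ci_method='wald'`` (default) builds Wald intervals on the log-scale
    of both parameters from the observed information, guaranteeing positive
    bounds; ``'profile'`` inverts the likelihood-ratio statistic instead.
    Requires n >= 10 strictly positive values.
    """
    x = np.asarray(onset_days, dtype=float)
    if len(x) < 10:
        raise ValueError(f"need at least 10 onset records, got {len(x)}")
    if not np.all(x > 0):
        raise ValueError("onset values must be strictly positive "
                         "(impute zero-day onsets upstream)")
    if ci_method not in ("wald", "profile"):
        raise ValueError("ci_method must be 'wald' or 'profile'")

    shape, _, scale = stats.weibull_min.fit(x, floc=0)
    ll = _loglik(x, shape, scale)

    if ci_method == "wald":
        info = -_hessian_loglog(x, shape, scale)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        shape_ci = (shape * math.exp(-1.959964 * se[0]),
                    shape * math.exp(1.959964 * se[0]))
        scale_ci = (scale * math.exp(-1.959964 * se[1]),
                    scale * math.exp(1.959964 * se[1]))
    else:
        shape_ci = _profile_ci(x, "shape", shape, scale, ll)
        scale_ci = _profile_ci(x, "scale", shape, scale, ll)

    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return WeibullFit(
        n=len(x), scale=float(scale), scale_ci=scale_ci,
        shape=float(shape), shape_ci=shape_ci,
        median_days=float(med), iqr_days=(float(q1), float(q3)),
        failure_type=classify_failure(shape_ci), loglik=ll,
    )


def tto_distribution(onset_days, edges=DEFAULT_BIN_EDGES):
    """Binned onset proportions plus the empirical cumulative curve.

    Bins are [0, e1], (e1, e2], ..., (e_last, inf) in days; proportions
    sum to one.  The cumulative curve is the right-continuous ECDF
    evaluated at the distinct observed onset values.
    """
    x = np.asarray(onset_days, dtype=float)
    if len(x) == 0:
        raise ValueError("no onset records")
    if np.any(x < 0):
        raise ValueError("onset values must be nonnegative")
    edges = tuple(edges)
    idx = np.searchsorted(edges, x, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    labels = []
    prev = 0
    for e in edges:
        labels.append(f"{prev}-{e}")
        prev = e + 1
    labels.append(f">{edges[-1]}")
    bins = pd.DataFrame({"bin": labels, "count": counts,
                         "proportion": counts / len(x)})

    days = np.unique(x)
    ecdf = np.searchsorted(np.sort(x), days, side="right") / len(x)
    curve = pd.DataFrame({"days": days, "cumulative": ecdf})
    return bins, curve


@dataclass(frozen=True)
class SexComparison:
    """Rank-sum comparison of onset distributions between sexes."""

    median_female: float
    median_male: float
    statistic: float        # rank sum of the female group
    p_two_sided: float
    n_female: int
    n_male: int
    n_unknown: int          # excluded records
    method: str             # 'exact' or 'normal'


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided rank-sum p for group x vs y, with midranks.

    Exact enumeration of all C(n1+n2, n1) midrank assignments when both
    groups have at most 10 records; tie-corrected normal approximation
    otherwise (p=1 when every pooled value is tied).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w = float(ranks[:n1].sum())
    e_w = n1 * (n + 1) / 2.0
    if n1 <= 10 and (n - n1) <= 10:
        obs = abs(w - e_w)
        hits = total = 0
        for comb in itertools.combinations(ranks, n1):
            total += 1
            if abs(sum(comb) - e_w) >= obs - 1e-9:
                hits += 1
        return w, hits / total, "exact"
    _, t = np.unique(pooled, return_counts=True)
    tie = (t**3 - t).sum() / (n * (n - 1))
    var = n1 * (n - n1) / 12.0 * ((n + 1) - tie)
    if var <= 0:
        return w, 1.0, "normal"
    z = (w - e_w) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(abs(z))), "normal"


def compare_by_sex(onset_days, sex_labels) -> SexComparison:
    """Wilcoxon rank-sum comparison of onsets, female vs male.

    Records whose sex is neither female nor male are excluded and counted;
    each group must contribute at least 2 records.
    """
    x = np.asarray(onset_days, dtype=float)
    sex = np.asarray([str(s).lower() for s in sex_labels])
    f = x[(sex == "female") | (sex == "f")]
    m = x[(sex == "male") | (sex == "m")]
    unknown = len(x) - len(f) - len(m)
    if len(f) < 2 or len(m) < 2:
        raise ValueError(
            f"need >= 2 records per sex, got {len(f)} female / {len(m)} male")
    w, p, method = _ranksum_p(f, m)
    return SexComparison(
        median_female=float(np.median(f)), median_male=float(np.median(m)),
        statistic=w, p_two_sided=p, n_female=len(f), n_male=len(m),
        n_unknown=unknown, method=method,
    )


class WeibullOnsetModel:
    """Time-to-onset model over a vector of onset days (optionally with sex).

    ``fit()`` returns a `WeibullOnsetResults` carrying the Weibull
    parameter estimates with CIs, the failure-type label, empirical
    summaries, and helpers for the binned distribution, cumulative curve
    and sex comparison.
    """

    def __init__(self, onset_days, sex=None):
        self.onset_days = np.asarray(onset_days, dtype=float)
        self.sex = None if sex is None else np.asarray(sex, dtype=object)
        if self.sex is not None and len(self.sex) != len(self.onset_days):
            raise ValueError("sex labels must align with onset_days")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, onset_col: str = "onset_days",
                       sex_col: str = "sex") -> "WeibullOnsetModel":
        sex = df[sex_col].to_numpy() if sex_col in df.columns else None
        return cls(df[onset_col].to_numpy(), sex)

    def fit(self, ci_method: str = "wald") -> "WeibullOnsetResults":
        fit = weibull_mle(self.onset_days, ci_method=ci_method)
        return WeibullOnsetResults(self, fit)


class WeibullOnsetResults:
    def __init__(self, model: WeibullOnsetModel, fit: WeibullFit):
        self.model = model
        self.fit_ = fit

    def __getattr__(self, name):
        return getattr(self.__dict__["fit_"], name)

    def distribution(self, edges=DEFAULT_BIN_EDGES):
        return tto_distribution(self.model.onset_days, edges)

    def compare_by_sex(self) -> SexComparison:
        if self.model.sex is None:
            raise ValueError("model was built without sex labels")
        return compare_by_sex(self.model.onset_days, self.model.sex)

    def summary(self) -> str:
        return self.fit_.summary()
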