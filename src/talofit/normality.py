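"""Normality verification: one-sample K-S test, Q-Q data and the 3-sigma rule.

The database's claim to represent a population rests on each node's heights
being plausibly normal.  Three complementary checks are provided:

* a one-sample Kolmogorov-Smirnov test of each node against a normal law
  with parameters estimated from the sample (mean, n-1 SD).  The statistic
  is the two-sided ECDF supremum

      D = max_i max( |i/n - F(x_(i))|, |(i-1)/n - F(x_(i))| )

  and the p-value comes from the asymptotic Kolmogorov distribution
  Q(lambda) = 2 sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2) evaluated at
  lambda = (sqrt(n) + 0.12 + 0.11/sqrt(n)) * D.  Estimating the parameters
  from the same sample makes this variant conservative; the Lilliefors
  correction is available via ``lilliefors=True``.
* Q-Q data: the standardized sorted sample against normal quantiles at
  plotting positions (i - 0.5)/n.
* the 3-sigma containment check: every standardized value |z| <= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import kolmogorov

from .cohort import CohortTable


class DegenerateSampleError(ValueError):
    """Raised for constant samples (SD = 0) where the tests are undefined."""


@dataclass(frozen=True)
class NormalityResult:
    node: int
    n: int
    D: float
    p_value: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0):
            raise ValueError("D must lie in [0, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def is_normal(self) -> bool:
        """True when the sample is compatible with normality at the 5% level."""
        return self.p_value > 0.05


@dataclass(frozen=True)
class QQData:
    sample_quantiles: np.ndarray
    theoretical_quantiles: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sample_quantiles, dtype=float).reshape(-1)
        t = np.asarray(self.theoretical_quantiles, dtype=float).reshape(-1)
        if s.shape != t.shape:
            raise ValueError("quantile arrays must have equal length")
        if np.any(np.diff(s) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("quantiles must be sorted ascending")
        object.__setattr__(self, "sample_quantiles", s)
        object.__setattr__(self, "theoretical_quantiles", t)


@dataclass(frozen=True)
class SigmaReport:
    z_scores: np.ndarray  # (n_cases, 9)
    max_abs_z: float
    within_3sigma: bool


def _check_sample(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).reshape(-1)
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.std(x, ddof=1) <= 0:
        raise DegenerateSampleError("constant sample: SD is zero")
    return x


def ks_statistic(values, mean: float, sd: float) -> float:
    """Two-sided ECDF supremum distance to Normal(mean, sd)."""
    x = np.sort(np.asarray(values, dtype=float).reshape(-1))
    n = len(x)
    F = stats.norm.cdf(x, loc=mean, scale=sd)
    i = np.arange(1, n + 1)
    return float(max(np.max(np.abs(i / n - F)), np.max(np.abs((i - 1) / n - F))))


def ks_normal_test(
    values,
    node: int = 0,
    mean: float | None = None,
    sd: float | None = None,
    lilliefors: bool = False,
) -> NormalityResult:
    """One-sample K-S test of normality for one node's heights.

    ``mean``/``sd`` override the sample estimates when the reference normal
    is known a priori.  With ``lilliefors=True`` the p-value accounts for
    the estimated parameters (delegated to statsmodels); by default the
    plain asymptotic Kolmogorov p-value with the small-sample correction
    lambda = (sqrt(n) + 0.12 + 0.11/sqrt(n)) D is reported.
    """
    x = _check_sample(values)
    n = len(x)
    mu = float(np.mean(x)) if mean is None else float(mean)
    sigma = float(np.std(x, ddof=1)) if sd is None else float(sd)
    if sigma <= 0:
        raise DegenerateSampleError("reference SD must be positive")
    D = ks_statistic(x, mu, sigma)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        _, p = _lf(x, dist="norm", pvalmethod="table")
    else:
        lam = (np.sqrt(n) + 0.12 + 0.11 / np.sqrt(n)) * D
        p = float(kolmogorov(lam))
    return NormalityResult(node=node, n=n, D=D, p_value=min(max(p, 0.0), 1.0), mean=mu, sd=sigma)


def qq_points(values) -> QQData:
    """Standardized sample vs normal quantiles at positions (i - 0.5)/n."""
    x = _check_sample(values)
    n = len(x)
    z = np.sort((x - np.mean(x)) / np.std(x, ddof=1))
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return QQData(sample_quantiles=z, theoretical_quantiles=q)


def three_sigma_check(cohort: CohortTable) -> SigmaReport:
    """Standardize every height per node and test 3-sigma containment."""
    m = cohort.matrix()
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise DegenerateSampleError("a node has zero SD; z-scores undefined")
    z = (m - mean) / sd
    max_abs = float(np.abs(z).max())
    return SigmaReport(z_scores=z, max_abs_z=max_abs, within_3sigma=bool(max_abs <= 3.0))


def cohort_normality(cohort: CohortTable, lilliefors: bool = False) -> list[NormalityResult]:
    """K-S normality result for each of the nine nodes of a cohort."""
    m = cohort.matrix()
    return [
        ks_normal_test(m[:, j], node=j + 1, lilliefors=lilliefors) for j in range(9)
    ]
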