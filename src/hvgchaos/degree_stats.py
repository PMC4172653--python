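"""Exponential-tail fitting of the HVG-PDF and quantile shape statistics.

The Lacasa-Toral rule posits P(kappa) ~ exp(-lambda * kappa) for both
chaotic and stochastic series, with the white-noise value lambda_c =
ln(3/2) separating chaotic (lambda < lambda_c) from correlated stochastic
(lambda > lambda_c) dynamics.  ``fit_lambda`` estimates lambda by ordinary
least squares on ln P(kappa) over an explicit scaling region — the choice
of region is the rule's main fragility and is therefore a visible parameter
recorded in the fit, never an internal default hidden from the caller.

Shape of the HVG-PDF is summarized by quantile-based (robust) skewness and
kurtosis: Bowley skewness at order p and Moors kurtosis on octiles, the
standard quantile replacements for moment skewness/kurtosis on asymmetric,
heavy-tailed discrete laws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .hvg import DegreeDistribution

__all__ = [
    "LAMBDA_WHITE_NOISE",
    "LambdaFit",
    "ShapeStats",
    "fit_lambda",
    "classify_lambda",
    "empirical_quantile",
    "quantile_skewness",
    "quantile_kurtosis",
    "shape_stats",
    "analytic_references",
    "exponential_quantile",
    "whitenoise_hvg_quantile",
    "whitenoise_hvg_probs",
    "CHAOTIC_REGION",
    "STOCHASTIC_REGION",
]

logger = logging.getLogger(__name__)

#: ln(3/2), the analytic exponential-decay rate of the iid (white-noise)
#: HVG degree law P(kappa) = (1/3) (2/3)^(kappa-2), kappa >= 2.
LAMBDA_WHITE_NOISE = math.log(1.5)

#: Default scaling regions for the log-linear fit (explicit, overridable).
CHAOTIC_REGION = (2, 12)
STOCHASTIC_REGION = (2, 20)

#: Default quantile orders: Bowley order p and Moors octile grid.
DEFAULT_P_SKEW = 0.25
DEFAULT_KURT_ORDERS = (0.125, 0.25, 0.375, 0.625, 0.75, 0.875)


@dataclass(frozen=True)
class LambdaFit:
    """OLS estimate of the exponential-tail rate with its 95% interval."""

    lambda_hat: float
    ci_low: float
    ci_high: float
    r_squared: float
    region: tuple[int, int]
    n_points: int

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


@dataclass(frozen=True)
class ShapeStats:
    """Quantile-based skewness and kurtosis of a distribution."""

    skewness: float
    kurtosis: float
    p_skew: float = DEFAULT_P_SKEW
    quantile_orders_kurt: tuple[float, ...] = DEFAULT_KURT_ORDERS


def fit_lambda(
    dist: DegreeDistribution,
    region: tuple[int, int] = STOCHASTIC_REGION,
    min_count: float = 10,
) -> LambdaFit:
    """Fit ln P(kappa) = alpha - lambda * kappa by OLS over a scaling region.

    Bins inside ``region`` with fewer than ``min_count`` nodes (and all
    zero-count bins) are excluded from the regression and logged.  The 95%
    confidence interval is the normal-theory slope interval (slope standard
    error times 1.96), matching a Gaussian linear-regression error model.

    Raises ``ValueError`` if fewer than 3 usable bins remain.
    """
    kappa_min, kappa_max = region
    mask = (dist.kappa >= kappa_min) & (dist.kappa <= kappa_max)
    usable = mask & (dist.counts >= min_count) & (dist.probs > 0)
    dropped = int(mask.sum() - usable.sum())
    if dropped:
        logger.info(
            "fit_lambda: dropped %d bins in region %s below min_count=%s",
            dropped, region, min_count,
        )
    if usable.sum() < 3:
        raise ValueError(
            f"fewer than 3 usable bins in region {region} with count >= {min_count}"
        )
    kappa = dist.kappa[usable].astype(float)
    log_p = np.log(dist.probs[usable])
    fit = sps.linregress(kappa, log_p)
    lam = -fit.slope
    half_width = 1.96 * fit.stderr
    return LambdaFit(
        lambda_hat=float(lam),
        ci_low=float(lam - half_width),
        ci_high=float(lam + half_width),
        r_squared=float(fit.rvalue**2),
        region=(int(kappa_min), int(kappa_max)),
        n_points=int(usable.sum()),
    )


def classify_lambda(fit: LambdaFit, r2_threshold: float = 0.95) -> str:
    """Classify a series by the lambda rule.

    ``chaotic`` if the whole interval lies below ln(3/2),
    ``correlated_stochastic`` if it lies above, ``uncorrelated`` if the
    interval straddles ln(3/2), and ``inconclusive`` when R² falls below
    ``r2_threshold`` — poor log-linearity voids the rule regardless of the
    point estimate.
    """
    if fit.r_squared < r2_threshold:
        return "inconclusive"
    if fit.ci_high < LAMBDA_WHITE_NOISE:
        return "chaotic"
    if fit.ci_low > LAMBDA_WHITE_NOISE:
        return "correlated_stochastic"
    return "uncorrelated"


def empirical_quantile(sample, q: float):
    """Type-1 (inverse empirical CDF, left-continuous) sample quantile."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile order must lie in [0, 1]")
    return np.quantile(sample, q, method="inverted_cdf")


def _quantile_callable(source) -> Callable[[float], float]:
    if callable(source):
        return source
    sample = np.asarray(source, dtype=float)
    return lambda q: float(empirical_quantile(sample, q))


def quantile_skewness(source, p: float = DEFAULT_P_SKEW) -> float:
    """Bowley-type quantile skewness at order p in (0, 1/2).

    SK = [Q(1-p) + Q(p) - 2 Q(1/2)] / [Q(1-p) - Q(p)], bounded in [-1, 1];
    ``source`` is either a data sample or an analytic quantile function.
    """
    if not 0.0 < p < 0.5:
        raise ValueError("skewness order p must lie in (0, 1/2)")
    quantile = _quantile_callable(source)
    lo, median, hi = quantile(p), quantile(0.5), quantile(1.0 - p)
    spread = hi - lo
    if spread == 0:
        raise ValueError(f"degenerate interquantile range at p={p}")
    return (hi + lo - 2.0 * median) / spread


def quantile_kurtosis(
    source, orders: Sequence[float] = DEFAULT_KURT_ORDERS
) -> float:
    """Moors-type quantile kurtosis on a symmetric six-order grid.

    With orders (a1, a2, a3, b3, b2, b1):
    KR = [(Q(b1) - Q(b3)) + (Q(a3) - Q(a1))] / [Q(b2) - Q(a2)];
    the default grid is the octiles (1/8, 2/8, 3/8, 5/8, 6/8, 7/8),
    normalized by the interquartile range.  Scale- and location-invariant,
    larger for heavier tails.
    """
    orders = tuple(orders)
    if len(orders) != 6 or any(not 0 < o < 1 for o in orders) or list(orders) != sorted(
        orders
    ):
        raise ValueError("orders must be 6 strictly increasing values in (0, 1)")
    a1, a2, a3, b3, b2, b1 = orders
    quantile = _quantile_callable(source)
    denominator = quantile(b2) - quantile(a2)
    if denominator == 0:
        raise ValueError("degenerate interquantile range in kurtosis denominator")
    return ((quantile(b1) - quantile(b3)) + (quantile(a3) - quantile(a1))) / denominator


def shape_stats(
    source,
    p: float = DEFAULT_P_SKEW,
    orders: Sequence[float] = DEFAULT_KURT_ORDERS,
) -> ShapeStats:
    """Quantile skewness and kurtosis of a sample or quantile function."""
    return ShapeStats(
        skewness=quantile_skewness(source, p),
        kurtosis=quantile_kurtosis(source, orders),
        p_skew=p,
        quantile_orders_kurt=tuple(orders),
    )


def exponential_quantile(q: float) -> float:
    """Quantile function of the standard exponential, Q(q) = -ln(1 - q)."""
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    return -math.log1p(-q)


def whitenoise_hvg_quantile(q: float) -> float:
    """Quantile function of the iid HVG degree law.

    The white-noise HVG-PDF is geometric: P(kappa) = (1/3)(2/3)^(kappa-2)
    for kappa >= 2, with CDF F(kappa) = 1 - (2/3)^(kappa-1).
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    if q == 0:
        return 2.0
    # smallest integer kappa >= 2 with 1 - (2/3)^(kappa-1) >= q
    target = math.log1p(-q) / math.log(2.0 / 3.0)
    kappa = 1 + math.ceil(target - 1e-12)
    return float(max(kappa, 2))


def whitenoise_hvg_probs(kappa_max: int = 60) -> DegreeDistribution:
    """The analytic iid HVG degree distribution truncated at ``kappa_max``."""
    kappa = np.arange(2, kappa_max + 1)
    probs = (1.0 / 3.0) * (2.0 / 3.0) ** (kappa - 2)
    return DegreeDistribution.from_probs(2, probs)


def analytic_references(
    distribution: str,
    p: float = DEFAULT_P_SKEW,
    orders: Sequence[float] = DEFAULT_KURT_ORDERS,
) -> ShapeStats:
    """Closed-form shape statistics of the two reference laws.

    ``exponential`` — the standard exponential density e^(-x) (invariant to
    the rate, since the quantile functionals are scale-free);
    ``whitenoise_hvg`` — the geometric iid HVG degree law.
    """
    if distribution == "exponential":
        quantile = exponential_quantile
    elif distribution == "whitenoise_hvg":
        quantile = whitenoise_hvg_quantile
    else:
        raise ValueError(
            "supported references: 'exponential', 'whitenoise_hvg'"
        )
    return shape_stats(quantile, p=p, orders=orders)
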