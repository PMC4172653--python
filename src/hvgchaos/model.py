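"""Model/Results surface tying the HVG quantifiers together.

``HVGAnalysis`` is constructed from a series (or straight from a registered
generator) and ``fit()`` returns an :class:`HVGResults` carrying the degree
distribution, the lambda tail fit with its confidence interval and
classification, the quantile shape statistics and the Shannon-Fisher plane
point, with a ``summary()`` table in the spirit of statsmodels results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import degree_stats as ds
from . import info
from .hvg import DegreeDistribution, HVGraph, build_hvg, degree_distribution
from .systems import TimeSeries, generate

__all__ = ["HVGAnalysis", "HVGResults"]


class HVGAnalysis:
    """Horizontal-visibility-graph analysis of a scalar time series.

    Parameters
    ----------
    series
        The observations, as a :class:`~hvgchaos.systems.TimeSeries`, array
        or sequence; order is time order.
    region
        Scaling region (kappa_min, kappa_max) for the lambda fit.  Defaults
        to the stochastic region (2, 20); pass the chaotic region
        ``degree_stats.CHAOTIC_REGION`` for map-like series.  The region is
        the lambda rule's main fragility and is always recorded in the fit.
    min_count
        Minimum node count for a degree bin to enter the regression.
    p_skew, kurt_orders
        Quantile orders for the Bowley skewness and Moors kurtosis.
    norm
        Entropy normalization mode: ``uniform`` or ``whitenoise_reference``.
    """

    def __init__(
        self,
        series,
        region: tuple[int, int] = ds.STOCHASTIC_REGION,
        min_count: float = 10,
        p_skew: float = ds.DEFAULT_P_SKEW,
        kurt_orders: Sequence[float] = ds.DEFAULT_KURT_ORDERS,
        norm: str = "uniform",
        label: str = "",
    ) -> None:
        if not isinstance(series, TimeSeries):
            series = TimeSeries(np.asarray(series, dtype=float))
        self.series = series
        self.region = (int(region[0]), int(region[1]))
        self.min_count = min_count
        self.p_skew = p_skew
        self.kurt_orders = tuple(kurt_orders)
        self.norm = norm
        self.label = label or (series.spec.name if series.spec else "series")

    @classmethod
    def from_system(cls, name: str, params=None, length: int = 100_000,
                    discard: int = 1_000, seed: int = 0, coordinate=0,
                    **kwargs) -> "HVGAnalysis":
        """Build the analysis from a registered synthetic system."""
        series = generate(name, params=params, length=length, discard=discard,
                          seed=seed, coordinate=coordinate)
        kwargs.setdefault("label", name)
        return cls(series, **kwargs)

    def fit(self) -> "HVGResults":
        """Build the HVG, extract P(kappa) and compute all quantifiers."""
        graph = build_hvg(self.series)
        dist = degree_distribution(graph)
        try:
            lambda_fit = ds.fit_lambda(dist, region=self.region,
                                       min_count=self.min_count)
            label = ds.classify_lambda(lambda_fit)
        except ValueError:
            lambda_fit = None
            label = "inconclusive"
        shape = ds.shape_stats(graph.degree_sequence, p=self.p_skew,
                               orders=self.kurt_orders)
        return HVGResults(
            model=self,
            graph=graph,
            distribution=dist,
            lambda_fit=lambda_fit,
            classification=label,
            shape=shape,
            h_norm=info.shannon_entropy_norm(dist, mode=self.norm),
            f_norm=info.fisher_information_norm(dist),
            complexity=info.statistical_complexity(dist),
        )


@dataclass(frozen=True)
class HVGResults:
    """Fitted HVG quantifiers for one series."""

    model: HVGAnalysis
    graph: HVGraph
    distribution: DegreeDistribution
    lambda_fit: ds.LambdaFit | None
    classification: str
    shape: ds.ShapeStats
    h_norm: float
    f_norm: float
    complexity: float

    @property
    def plane_point(self) -> info.PlanePoint:
        return info.PlanePoint(
            h_norm=self.h_norm,
            f_norm=self.f_norm,
            label=self.model.label,
            normalization_mode=self.model.norm,
        )

    def to_dict(self) -> dict:
        out = {
            "label": self.model.label,
            "n": len(self.model.series),
            "mean_degree": self.graph.mean_degree(),
            "H": self.h_norm,
            "F": self.f_norm,
            "complexity": self.complexity,
            "skewness": self.shape.skewness,
            "kurtosis": self.shape.kurtosis,
            "classification": self.classification,
        }
        if self.lambda_fit is not None:
            out.update(
                {
                    "lambda": self.lambda_fit.lambda_hat,
                    "lambda_ci_low": self.lambda_fit.ci_low,
                    "lambda_ci_high": self.lambda_fit.ci_high,
                    "r_squared": self.lambda_fit.r_squared,
                    "region": self.lambda_fit.region,
                }
            )
        else:
            out.update({"lambda": float("nan"), "lambda_ci_low": float("nan"),
                        "lambda_ci_high": float("nan"),
                        "r_squared": float("nan"),
                        "region": self.model.region})
        return out

    def summary(self) -> str:
        """Plain-text summary table of the fitted quantifiers."""
        d = self.to_dict()
        lines = [
            "HVG analysis results",
            "=" * 52,
            f"{'series':<28}{d['label']}",
            f"{'observations':<28}{d['n']}",
            f"{'graph edges':<28}{self.graph.n_edges}",
            f"{'mean degree':<28}{d['mean_degree']:.4f}",
            "-" * 52,
            f"{'lambda (tail rate)':<28}{d['lambda']:.4f}",
            f"{'95% CI':<28}[{d['lambda_ci_low']:.4f}, {d['lambda_ci_high']:.4f}]",
            f"{'R squared':<28}{d['r_squared']:.4f}",
            f"{'scaling region':<28}kappa in [{d['region'][0]}, {d['region'][1]}]",
            f"{'ln(3/2) threshold':<28}{ds.LAMBDA_WHITE_NOISE:.4f}",
            f"{'classification':<28}{d['classification']}",
            "-" * 52,
            f"{'Shannon entropy H':<28}{d['H']:.4f}  ({self.model.norm})",
            f"{'Fisher information F':<28}{d['F']:.4f}",
            f"{'statistical complexity':<28}{d['complexity']:.4f}",
            f"{'quantile skewness':<28}{d['skewness']:.4f}",
            f"{'quantile kurtosis':<28}{d['kurtosis']:.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)
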