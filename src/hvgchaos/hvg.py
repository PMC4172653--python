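"""Horizontal visibility graph construction and degree statistics.

Two observations (t_i, x_i) and (t_j, x_j) of a series are linked in the
horizontal visibility graph (HVG) iff every intermediate observation lies
strictly below both: x_n < min(x_i, x_j) for all i < n < j.  Consecutive
observations are always linked (there is no intermediate), so the HVG
contains the time path as a subgraph.  The criterion depends only on order
relations, which makes the graph invariant under x -> a x + b with a > 0.

Tie rule: an intermediate at exactly the height of the lower endpoint blocks
visibility (the strict inequality is applied literally); adjacent equal
values remain connected.  A constant series therefore maps to the path graph.

The fast builder is a single monotone-stack sweep, O(n) amortized; the
quadratic brute-force builder is retained as an independent oracle for the
test surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems import TimeSeries

__all__ = [
    "HVGraph",
    "DegreeDistribution",
    "build_hvg",
    "build_hvg_oracle",
    "degree_distribution",
    "affine_check",
]


@dataclass(frozen=True)
class HVGraph:
    """Undirected horizontal visibility graph on time-indexed nodes.

    Nodes are 0-based internally; all text I/O reports 1-based time indices.
    """

    n_nodes: int
    edges: np.ndarray  # shape (m, 2), i < j, 0-based
    degree_sequence: np.ndarray

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def edge_set_1based(self) -> set[tuple[int, int]]:
        return {(int(i) + 1, int(j) + 1) for i, j in self.edges}

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def mean_degree(self) -> float:
        return float(self.degree_sequence.mean())

    def to_networkx(self):
        """Export as a networkx.Graph with 1-based node labels."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_nodes + 1))
        g.add_edges_from((int(i) + 1, int(j) + 1) for i, j in self.edges)
        return g


def _as_values(series) -> np.ndarray:
    values = series.values if isinstance(series, TimeSeries) else np.asarray(
        series, dtype=float
    )
    if values.ndim != 1 or values.size < 2:
        raise ValueError("series must be one-dimensional with length >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("series contains non-finite values")
    return values


def _graph_from_edges(n: int, edges: list[tuple[int, int]]) -> HVGraph:
    if edges:
        arr = np.asarray(edges, dtype=np.int64)
    else:
        arr = np.empty((0, 2), dtype=np.int64)
    degrees = np.bincount(arr.ravel(), minlength=n) if arr.size else np.zeros(
        n, dtype=np.int64
    )
    return HVGraph(n_nodes=n, edges=arr, degree_sequence=degrees)


def build_hvg(series) -> HVGraph:
    """Build the HVG in a single monotone-stack sweep.

    The stack holds indices whose values strictly decrease from bottom to
    top.  A new point links to every popped smaller value and to the first
    value at least as tall; an equally tall stack entry is also popped, since
    it can never see past the new point.
    """
    x = _as_values(series)
    n = x.size
    edges: list[tuple[int, int]] = []
    stack: list[int] = []
    for j in range(n):
        xj = x[j]
        while stack and x[stack[-1]] < xj:
            edges.append((stack[-1], j))
            stack.pop()
        if stack:
            edges.append((stack[-1], j))
            if x[stack[-1]] == xj:
                stack.pop()
        stack.append(j)
    return _graph_from_edges(n, edges)


def build_hvg_oracle(series) -> HVGraph:
    """Brute-force HVG builder: check every pair against all intermediates.

    Independent of :func:`build_hvg`; guarded to short series since the scan
    is quadratic.
    """
    x = _as_values(series)
    n = x.size
    if n > 10_000:
        raise ValueError("oracle builder is quadratic; use build_hvg beyond n=1e4")
    edges: list[tuple[int, int]] = []
    for i in range(n - 1):
        edges.append((i, i + 1))
        blocking = -np.inf
        for j in range(i + 2, n):
            blocking = max(blocking, x[j - 1])
            if blocking < min(x[i], x[j]):
                edges.append((i, j))
    return _graph_from_edges(n, edges)


@dataclass(frozen=True)
class DegreeDistribution:
    """Normalized degree histogram P(kappa) on a contiguous support.

    Zero-count bins between kappa_min and kappa_max are retained so the
    Fisher gradient sum is defined on a contiguous lattice.  ``counts`` may
    be fractional when the distribution is analytic (expected counts).
    """

    kappa: np.ndarray
    counts: np.ndarray
    probs: np.ndarray
    n_nodes: float

    def __post_init__(self) -> None:
        kappa = np.asarray(self.kappa, dtype=np.int64)
        counts = np.asarray(self.counts, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", probs)
        if kappa.size == 0:
            raise ValueError("empty degree support")
        if np.any(np.diff(kappa) != 1):
            raise ValueError("degree support must be contiguous")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("degree probabilities must sum to 1")

    @property
    def n_states(self) -> int:
        return int(self.kappa.size)

    @classmethod
    def from_probs(cls, kappa_min: int, probs) -> "DegreeDistribution":
        """Analytic distribution from probabilities on a contiguous support."""
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        kappa = np.arange(kappa_min, kappa_min + probs.size)
        return cls(kappa=kappa, counts=probs, probs=probs, n_nodes=1.0)


def degree_distribution(graph: HVGraph) -> DegreeDistribution:
    """Normalized node-degree distribution of an HVG (the HVG-PDF).

    The support lattice is anchored at kappa = 1, the structural minimum
    degree of a visibility graph: only the two boundary nodes can attain
    degree 1, so whether the kappa = 1 bin is occupied at a given length is
    a coin flip on the endpoints.  Anchoring keeps the support — and with
    it the gradient sum of the Fisher information, which is sensitive to
    the support edge — stable across lengths and realizations.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    degrees = graph.degree_sequence
    kappa_min = min(int(degrees.min()), 1)
    kappa_max = int(degrees.max())
    counts = np.bincount(degrees, minlength=kappa_max + 1)[kappa_min:]
    kappa = np.arange(kappa_min, kappa_max + 1)
    probs = counts / graph.n_nodes
    return DegreeDistribution(
        kappa=kappa, counts=counts.astype(float), probs=probs, n_nodes=graph.n_nodes
    )


def affine_check(series, a: float, b: float) -> bool:
    """Report whether the HVG of ``a*x + b`` equals the HVG of ``x``.

    True for every a > 0 (the HVG invariance); a negative ``a`` (reflection)
    is accepted and generally reports False — reflections are not covered by
    the invariance.  ``a = 0`` is rejected as degenerate.
    """
    if a == 0:
        raise ValueError("scale factor a must be nonzero")
    x = _as_values(series)
    before = build_hvg(x).edge_set()
    after = build_hvg(a * x + b).edge_set()
    return before == after
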