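"""Seeded generators for chaotic maps, chaotic flows and correlated noises.

This module is the fixture factory for the whole package: every dynamical
system and stochastic process analysed downstream is produced here from a
:class:`SystemSpec`, so that an identical spec (including seed) yields a
bit-identical series.

The map registry covers the 27 standard chaotic maps (noninvertible,
dissipative and conservative families, with the book-standard parameters and
initial conditions recorded in ``data/sprott_maps.json``) plus the logistic
map and the intermittent Schuster map.  Flows (Lorenz, Roessler) are
integrated with fixed-step RK4 and reduced to map-like series by taking
successive local minima of one coordinate.  Stochastic processes are
f^-k spectrally filtered noises and fractional Brownian motion / fractional
Gaussian noise synthesised by Davies-Harte circulant embedding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "SystemSpec",
    "TimeSeries",
    "Trajectory",
    "DivergenceError",
    "MAP_REGISTRY",
    "list_systems",
    "iterate_map",
    "schuster_map",
    "integrate_flow",
    "minimum_map",
    "lorenz_minimum_series",
    "rossler_minimum_series",
    "generate_knoise",
    "generate_fgn",
    "generate_fbm",
    "contaminate",
    "generate",
]

# Kept length / transient defaults used throughout the synthetic suite.
DEFAULT_LENGTH = 100_000
DEFAULT_DISCARD = 1_000

# Orbit values beyond this magnitude are treated as numerically divergent.
_DIVERGENCE_BOUND = 1e12


class DivergenceError(RuntimeError):
    """Raised when an orbit leaves the finite range; carries the step index."""

    def __init__(self, name: str, index: int) -> None:
        super().__init__(
            f"orbit of {name!r} became non-finite or divergent at iteration {index}"
        )
        self.index = index


@dataclass(frozen=True)
class SystemSpec:
    """Full provenance of a generated series: generator, parameters, seed.

    ``length`` is the number of kept samples, ``discard`` the number of
    transient iterations dropped before recording (ignored by the noise
    generators, which have no transient).
    """

    name: str
    params: Mapping[str, float] = field(default_factory=dict)
    length: int = DEFAULT_LENGTH
    discard: int = DEFAULT_DISCARD
    seed: int = 0
    initial_state: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.discard < 0:
            raise ValueError("discard must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic sub-stream RNG derived from the spec seed."""
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((self.seed, stream)))
        )


@dataclass(frozen=True)
class TimeSeries:
    """Ordered real-valued observations with optional provenance."""

    values: np.ndarray
    spec: SystemSpec | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("time series must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Trajectory:
    """Sampled trajectory of a flow: strictly increasing times, one row per step."""

    times: np.ndarray
    states: np.ndarray
    coordinate_names: tuple[str, ...] = ("x", "y", "z")

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.atleast_2d(np.asarray(self.states, dtype=float))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if states.shape[0] != times.size:
            raise ValueError("states must have one row per time point")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    def coordinate(self, name: str | int) -> np.ndarray:
        if isinstance(name, str):
            name = self.coordinate_names.index(name)
        return self.states[:, name]


# --------------------------------------------------------------------------
# Chaotic maps
# --------------------------------------------------------------------------

_TWO_PI = 2.0 * math.pi


def _step_logistic(s, p):
    return (p["a"] * s[0] * (1.0 - s[0]),)


def _step_sine(s, p):
    return (p["a"] * math.sin(math.pi * s[0]),)


def _step_tent(s, p):
    return (p["a"] * min(s[0], 1.0 - s[0]),)


def _step_lcg(s, p):
    return ((p["a"] * s[0] + p["b"]) % p["c"],)


def _step_cubic(s, p):
    return (p["a"] * s[0] * (1.0 - s[0] * s[0]),)


def _step_ricker(s, p):
    return (p["a"] * s[0] * math.exp(-s[0]),)


def _step_gauss(s, p):
    # Continued-fraction map 1/x mod 1.  In floating point every value is
    # rational, so orbits occasionally land on an exact reciprocal and
    # collapse to 0; re-inject from a fixed irrational-like point (frac(e))
    # to keep the orbit alive, mimicking the measure-zero exact dynamics.
    x = s[0]
    if x < 1e-14:
        return (0.7182818284590452,)
    return ((1.0 / x) % 1.0,)


def _step_cusp(s, p):
    return (1.0 - p["a"] * math.sqrt(abs(s[0])),)


def _step_pinchers(s, p):
    return (abs(math.tanh(p["s"] * (s[0] - p["c"]))),)


def _step_spence(s, p):
    x = s[0]
    if x == 0.0:
        return (0.0,)
    return (abs(math.log(abs(x))),)


def _step_sine_circle(s, p):
    return ((s[0] + p["omega"] - p["k"] / _TWO_PI * math.sin(_TWO_PI * s[0])) % 1.0,)


def _step_henon(s, p):
    x, y = s
    return (1.0 - p["a"] * x * x + p["b"] * y, x)


def _step_lozi(s, p):
    x, y = s
    return (1.0 - p["a"] * abs(x) + p["b"] * y, x)


def _step_delayed_logistic(s, p):
    x, y = s
    return (p["a"] * x * (1.0 - y), x)


def _step_tinkerbell(s, p):
    x, y = s
    return (
        x * x - y * y + p["a"] * x + p["b"] * y,
        2.0 * x * y + p["c"] * x + p["d"] * y,
    )


def _step_burgers(s, p):
    x, y = s
    return (p["a"] * x - y * y, p["b"] * y + x * y)


def _step_holmes(s, p):
    x, y = s
    return (y, -p["b"] * x + p["d"] * y - y ** 3)


def _step_dissipative_standard(s, p):
    x, y = s
    y_new = (p["b"] * y + p["k"] * math.sin(x)) % _TWO_PI
    x_new = (x + y_new) % _TWO_PI
    return (x_new, y_new)


def _step_ikeda(s, p):
    x, y = s
    phi = p["beta"] - p["alpha"] / (1.0 + x * x + y * y)
    c, sn = math.cos(phi), math.sin(phi)
    return (p["gamma"] + p["mu"] * (x * c - y * sn), p["mu"] * (x * sn + y * c))


def _step_sinai(s, p):
    x, y = s
    return ((x + y + p["delta"] * math.cos(_TWO_PI * y)) % 1.0, (x + 2.0 * y) % 1.0)


def _step_predator_prey(s, p):
    x, y = s
    return (
        x * math.exp(p["r"] * (1.0 - x) - p["alpha"] * y),
        x * (1.0 - math.exp(-p["alpha"] * y)),
    )


def _step_chirikov(s, p):
    x, y = s
    y_new = (y + p["k"] * math.sin(x)) % _TWO_PI
    x_new = (x + y_new) % _TWO_PI
    return (x_new, y_new)


def _step_henon_area(s, p):
    x, y = s
    c = p["cos_alpha"]
    sn = math.sqrt(1.0 - c * c)
    w = y - x * x
    return (x * c - w * sn, x * sn + w * c)


def _step_arnold_cat(s, p):
    x, y = s
    return ((x + y) % 1.0, (x + 2.0 * y) % 1.0)


def _step_gingerbreadman(s, p):
    x, y = s
    return (1.0 - y + abs(x), x)


def _step_web(s, p):
    x, y = s
    return (-(y + p["k"] * math.sin(x)), x)


def _step_lorenz3d(s, p):
    x, y, z = s
    return (x * y - z, x, y)


_STEP_FUNCTIONS: dict[str, Callable] = {
    "logistic": _step_logistic,
    "sine": _step_sine,
    "tent": _step_tent,
    "linear_congruential": _step_lcg,
    "cubic": _step_cubic,
    "ricker": _step_ricker,
    "gauss": _step_gauss,
    "cusp": _step_cusp,
    "pinchers": _step_pinchers,
    "spence": _step_spence,
    "sine_circle": _step_sine_circle,
    "henon": _step_henon,
    "lozi": _step_lozi,
    "delayed_logistic": _step_delayed_logistic,
    "tinkerbell": _step_tinkerbell,
    "burgers": _step_burgers,
    "holmes": _step_holmes,
    "dissipative_standard": _step_dissipative_standard,
    "ikeda": _step_ikeda,
    "sinai": _step_sinai,
    "predator_prey": _step_predator_prey,
    "chirikov": _step_chirikov,
    "henon_area": _step_henon_area,
    "arnold_cat": _step_arnold_cat,
    "gingerbreadman": _step_gingerbreadman,
    "web": _step_web,
    "lorenz3d": _step_lorenz3d,
}


@dataclass(frozen=True)
class MapDefinition:
    name: str
    family: str
    step: Callable
    default_params: Mapping[str, float]
    default_x0: tuple[float, ...]
    coords: tuple[str, ...]
    note: str


def _load_registry() -> dict[str, MapDefinition]:
    raw = json.loads(
        resources.files("hvgchaos").joinpath("data/sprott_maps.json").read_text()
    )
    registry = {}
    for name, entry in raw.items():
        registry[name] = MapDefinition(
            name=name,
            family=entry["family"],
            step=_STEP_FUNCTIONS[name],
            default_params=dict(entry["params"]),
            default_x0=tuple(entry["x0"]),
            coords=tuple(entry["coords"]),
            note=entry["note"],
        )
    return registry


#: Registry of iterated maps, keyed by name.
MAP_REGISTRY: dict[str, MapDefinition] = _load_registry()


def list_systems() -> list[dict]:
    """Names, parameter schemas and defaults of all registered generators."""
    rows = [
        {
            "name": d.name,
            "kind": f"map/{d.family}",
            "params": dict(d.default_params),
            "coords": list(d.coords),
            "note": d.note,
        }
        for d in MAP_REGISTRY.values()
    ]
    rows += [
        {"name": "schuster", "kind": "map/intermittent", "params": {"z": 2.0},
         "coords": ["x"], "note": "x -> x + x^z mod 1; random start in (0, 1)"},
        {"name": "lorenz_min", "kind": "flow-minima", "params": {
            "sigma": 10.0, "r": 28.0, "b": 8.0 / 3.0, "dt": 0.01},
         "coords": ["x"], "note": "local minima of the Lorenz X coordinate"},
        {"name": "rossler_min", "kind": "flow-minima", "params": {
            "a": 0.2, "b": 0.2, "c": 5.7, "dt": 0.05},
         "coords": ["x"], "note": "local minima of the Roessler X coordinate"},
        {"name": "knoise", "kind": "noise", "params": {"k": 2.0},
         "coords": ["x"], "note": "f^-k power-spectrum noise (spectral filtering)"},
        {"name": "fgn", "kind": "noise", "params": {"hurst": 0.5},
         "coords": ["x"], "note": "fractional Gaussian noise (Davies-Harte)"},
        {"name": "fbm", "kind": "noise", "params": {"hurst": 0.5},
         "coords": ["x"], "note": "fractional Brownian motion (Davies-Harte)"},
        {"name": "logistic_noisy", "kind": "map+noise", "params": {"amplitude": 0.5},
         "coords": ["x"], "note": "fully chaotic logistic map plus A * uniform white noise"},
    ]
    return rows


def iterate_map(spec: SystemSpec, coordinate: str | int = 0) -> TimeSeries:
    """Iterate a registered map, drop transients, return one coordinate.

    Parameters
    ----------
    spec
        Generator spec; ``spec.name`` must be in :data:`MAP_REGISTRY`
        (use :func:`schuster_map` for the Schuster map, which needs a
        seeded random start).
    coordinate
        Coordinate to record for multidimensional maps, by name or index.
    """
    if spec.name not in MAP_REGISTRY:
        raise KeyError(
            f"unknown map {spec.name!r}; known maps: {sorted(MAP_REGISTRY)}"
        )
    definition = MAP_REGISTRY[spec.name]
    params = {**definition.default_params, **dict(spec.params)}
    state = tuple(spec.initial_state) if spec.initial_state else definition.default_x0
    if len(state) != len(definition.default_x0):
        raise ValueError(
            f"{spec.name}: initial state must have dimension {len(definition.default_x0)}"
        )
    if isinstance(coordinate, str):
        coordinate = definition.coords.index(coordinate)

    step = definition.step
    out = np.empty(spec.length)
    for i in range(spec.discard + spec.length):
        state = step(state, params)
        value = state[coordinate]
        if not math.isfinite(value) or abs(value) > _DIVERGENCE_BOUND:
            raise DivergenceError(spec.name, i)
        if i >= spec.discard:
            out[i - spec.discard] = value
    return TimeSeries(out, spec=spec)


def schuster_map(z: float, spec: SystemSpec | None = None, **kwargs) -> TimeSeries:
    """Intermittent Schuster map ``x -> x + x**z mod 1`` with f^-k-like bursts.

    Larger ``z`` widens the laminar (slowly creeping) phases between chaotic
    bursts.  The orbit starts from a seeded uniform random point in (0, 1)
    unless ``spec.initial_state`` is given.
    """
    if z < 1:
        raise ValueError("Schuster exponent z must be >= 1")
    if spec is None:
        spec = SystemSpec(name="schuster", params={"z": z}, **kwargs)
    if spec.initial_state is not None:
        x = float(spec.initial_state[0])
    else:
        x = float(spec.rng().uniform(0.0, 1.0))
    out = np.empty(spec.length)
    for i in range(spec.discard + spec.length):
        x = (x + x ** z) % 1.0
        if i >= spec.discard:
            out[i - spec.discard] = x
    return TimeSeries(out, spec=spec)


# --------------------------------------------------------------------------
# Chaotic flows
# --------------------------------------------------------------------------

LORENZ_PARAMS = {"sigma": 10.0, "r": 28.0, "b": 8.0 / 3.0}
ROSSLER_PARAMS = {"a": 0.2, "b": 0.2, "c": 5.7}


def _lorenz_rhs(state: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    x, y, z = state
    return np.array(
        [p["sigma"] * (y - x), x * (p["r"] - z) - y, x * y - p["b"] * z]
    )


def _rossler_rhs(state: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    x, y, z = state
    return np.array([-y - z, x + p["a"] * y, p["b"] + z * (x - p["c"])])


_FLOWS: dict[str, tuple[Callable, Mapping[str, float]]] = {
    "lorenz": (_lorenz_rhs, LORENZ_PARAMS),
    "rossler": (_rossler_rhs, ROSSLER_PARAMS),
}


def integrate_flow(
    system: str | Callable,
    params: Mapping[str, float] | None = None,
    dt: float = 0.01,
    n_steps: int = 10_000,
    x0: Sequence[float] = (0.0, 1.0, 0.0),
) -> Trajectory:
    """Fixed-step fourth-order Runge-Kutta integration of a 3D flow.

    ``system`` is ``"lorenz"``, ``"rossler"`` or any callable
    ``f(state, params) -> dstate`` (used by the convergence tests).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(system, str):
        try:
            rhs, defaults = _FLOWS[system]
        except KeyError:
            raise KeyError(f"unknown flow {system!r}; known flows: {sorted(_FLOWS)}")
        params = {**defaults, **(params or {})}
        name = system
    else:
        rhs, name = system, getattr(system, "__name__", "flow")
        params = dict(params or {})

    state = np.asarray(x0, dtype=float)
    states = np.empty((n_steps + 1, state.size))
    states[0] = state
    for i in range(n_steps):
        k1 = rhs(state, params)
        k2 = rhs(state + 0.5 * dt * k1, params)
        k3 = rhs(state + 0.5 * dt * k2, params)
        k4 = rhs(state + dt * k3, params)
        state = state + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise DivergenceError(str(name), i + 1)
        states[i + 1] = state
    times = dt * np.arange(n_steps + 1)
    names = ("x", "y", "z")[: state.size] if state.size <= 3 else tuple(
        f"x{i}" for i in range(state.size)
    )
    return Trajectory(times=times, states=states, coordinate_names=names)


def minimum_map(traj: Trajectory, coordinate: str | int = "x") -> TimeSeries:
    """Successive strict local minima of one coordinate of a trajectory.

    Converts a flow into a map-like series: ``v[t-1] > v[t] < v[t+1]``;
    endpoints and plateau points never qualify.  A monotone input yields an
    empty series (returned as a zero-length :class:`TimeSeries`).
    """
    v = traj.coordinate(coordinate)
    if v.size < 3:
        raise ValueError("trajectory must contain at least 3 samples")
    interior = v[1:-1]
    mask = (v[:-2] > interior) & (interior < v[2:])
    values = interior[mask]
    if values.size == 0:
        return TimeSeries(np.empty(0))
    return TimeSeries(values)


def _flow_minimum_series(
    flow: str,
    spec: SystemSpec,
    dt: float,
    x0: Sequence[float],
) -> TimeSeries:
    """Integrate a flow long enough to harvest ``spec.length`` X-minima."""
    params = {k: v for k, v in spec.params.items() if k != "dt"}
    x0 = tuple(spec.initial_state) if spec.initial_state else tuple(x0)
    collected = np.empty(0)
    state = np.asarray(x0, dtype=float)
    # Mean inter-minimum spacing is ~0.75 time units for Lorenz and ~6 for
    # Roessler; integrate in chunks until enough minima (plus transient
    # discard, counted in minima) are available.
    chunk_steps = max(2048, int((spec.discard + spec.length) * 1.5 / dt ** 0.5))
    needed = spec.discard + spec.length
    guard = 0
    while collected.size < needed + 1:
        traj = integrate_flow(flow, params, dt=dt, n_steps=chunk_steps, x0=state)
        state = traj.states[-1]
        minima = minimum_map(traj, "x").values
        collected = np.concatenate([collected, minima])
        guard += 1
        if guard > 200:
            raise RuntimeError(f"{flow}: could not harvest enough minima")
    return TimeSeries(collected[spec.discard : spec.discard + spec.length], spec=spec)


def lorenz_minimum_series(spec: SystemSpec) -> TimeSeries:
    dt = float(spec.params.get("dt", 0.01))
    return _flow_minimum_series("lorenz", spec, dt, (0.0, 1.0, 0.0))


def rossler_minimum_series(spec: SystemSpec) -> TimeSeries:
    dt = float(spec.params.get("dt", 0.05))
    return _flow_minimum_series("rossler", spec, dt, (1.0, 1.0, 0.0))


# --------------------------------------------------------------------------
# Stochastic processes
# --------------------------------------------------------------------------


def generate_knoise(k: float, spec: SystemSpec | None = None, **kwargs) -> TimeSeries:
    """Noise with f^-k power spectrum by spectral filtering of white noise.

    A seeded zero-mean uniform white series is Fourier transformed, the
    amplitude at frequency f is multiplied by f^(-k/2) (the DC component is
    zeroed), and the filtered spectrum is inverted.  The output is
    standardized to zero mean and unit variance; the HVG is affine-invariant
    so the scaling is free.
    """
    if k < 0:
        raise ValueError("spectral exponent k must be >= 0")
    if spec is None:
        spec = SystemSpec(name="knoise", params={"k": k}, discard=0, **kwargs)
    n = spec.length
    white = spec.rng().uniform(-0.5, 0.5, size=n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    gain = np.zeros_like(freqs)
    nonzero = freqs > 0
    gain[nonzero] = freqs[nonzero] ** (-k / 2.0)
    series = np.fft.irfft(spectrum * gain, n=n)
    series -= series.mean()
    sd = series.std()
    if sd > 0:
        series /= sd
    return TimeSeries(series, spec=spec)


def fgn_autocovariance(H: float, lags: np.ndarray | Sequence[int]) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn at integer lags.

    rho(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2, the increment
    covariance implied by the fBm covariance kernel.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def _fgn_davies_harte(H: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact-covariance fGn sample path via circulant embedding."""
    r = fgn_autocovariance(H, np.arange(n + 1))
    circ = np.concatenate([r, r[-2:0:-1]])
    eigenvalues = np.fft.fft(circ).real
    # The embedding is provably nonnegative for fGn; clip float dust.
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    m = 2 * n
    w = np.empty(m, dtype=complex)
    w[0] = rng.standard_normal()
    w[n] = rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    w[1:n] = (re + 1j * im) / math.sqrt(2.0)
    w[n + 1 :] = np.conj(w[n - 1 : 0 : -1])
    path = np.fft.fft(np.sqrt(eigenvalues) * w)[:n].real / math.sqrt(m)
    return path


def generate_fgn(H: float, spec: SystemSpec | None = None, **kwargs) -> TimeSeries:
    """Stationary fractional Gaussian noise with Hurst exponent H in (0, 1)."""
    if not 0.0 < H < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if spec is None:
        spec = SystemSpec(name="fgn", params={"hurst": H}, discard=0, **kwargs)
    values = _fgn_davies_harte(H, spec.length, spec.rng())
    return TimeSeries(values, spec=spec)


def generate_fbm(H: float, spec: SystemSpec | None = None, **kwargs) -> TimeSeries:
    """Fractional Brownian motion path: B(0) = 0, increments are fGn(H)."""
    if not 0.0 < H < 1.0:
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if spec is None:
        spec = SystemSpec(name="fbm", params={"hurst": H}, discard=0, **kwargs)
    if spec.length == 1:
        return TimeSeries(np.zeros(1), spec=spec)
    increments = _fgn_davies_harte(H, spec.length - 1, spec.rng())
    path = np.concatenate([[0.0], np.cumsum(increments)])
    return TimeSeries(path, spec=spec)


def contaminate(series: TimeSeries, A: float, seed: int = 0) -> TimeSeries:
    """Add observational noise ``A * eta`` with eta zero-mean uniform white."""
    if A < 0:
        raise ValueError("noise amplitude A must be >= 0")
    if A == 0:
        return series
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 997))))
    eta = rng.uniform(-0.5, 0.5, size=len(series))
    return TimeSeries(series.values + A * eta, spec=series.spec)


# --------------------------------------------------------------------------
# Uniform dispatch (used by the CLI and the suite runner)
# --------------------------------------------------------------------------


def generate(
    name: str,
    params: Mapping[str, float] | None = None,
    length: int = DEFAULT_LENGTH,
    discard: int = DEFAULT_DISCARD,
    seed: int = 0,
    initial_state: Sequence[float] | None = None,
    coordinate: str | int = 0,
) -> TimeSeries:
    """Generate any registered system by name.

    Accepts map names from :data:`MAP_REGISTRY` plus ``schuster``,
    ``lorenz_min``, ``rossler_min``, ``knoise``, ``fgn``, ``fbm`` and
    ``logistic_noisy``.
    """
    params = dict(params or {})
    spec = SystemSpec(
        name=name,
        params=params,
        length=length,
        discard=discard,
        seed=seed,
        initial_state=tuple(initial_state) if initial_state is not None else None,
    )
    if name in MAP_REGISTRY:
        return iterate_map(spec, coordinate=coordinate)
    if name == "schuster":
        return schuster_map(params.get("z", 2.0), spec)
    if name == "lorenz_min":
        return lorenz_minimum_series(spec)
    if name == "rossler_min":
        return rossler_minimum_series(spec)
    if name == "knoise":
        return generate_knoise(params.get("k", 2.0), replace(spec, discard=0))
    if name == "fgn":
        return generate_fgn(params.get("hurst", 0.5), replace(spec, discard=0))
    if name == "fbm":
        return generate_fbm(params.get("hurst", 0.5), replace(spec, discard=0))
    if name == "logistic_noisy":
        amplitude = params.get("amplitude", 0.5)
        base = iterate_map(
            SystemSpec(
                name="logistic",
                params={},
                length=length,
                discard=discard,
                seed=seed,
                initial_state=tuple(initial_state) if initial_state else None,
            )
        )
        noisy = contaminate(base, amplitude, seed=seed)
        return TimeSeries(noisy.values, spec=spec)
    raise KeyError(f"unknown system {name!r}; see list_systems()")
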