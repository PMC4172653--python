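"""Readers, writers, suite configuration and the corpus suite runner.

Canonical series format is plain text, one float per line, row order =
time order; CSV with a ``t,value`` header is also accepted.  The suite
runner regenerates the synthetic corpus (maps, flows, noises) from a single
master seed and emits one row of quantifiers per system — the tabular
equivalent of the Shannon-Fisher plane figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import degree_stats as ds
from .hvg import HVGraph
from .model import HVGAnalysis
from .systems import MAP_REGISTRY, TimeSeries, list_systems

__all__ = [
    "read_series",
    "write_series",
    "write_edges",
    "list_systems_table",
    "SuiteConfig",
    "run_suite",
    "plot_plane",
    "DEFAULT_SUITE_SYSTEMS",
]

logger = logging.getLogger(__name__)

#: Output schema of the suite results table (stable, versioned).
SUITE_SCHEMA_VERSION = 1
SUITE_COLUMNS = [
    "system", "params", "coordinate", "n", "seed", "H", "F", "lambda",
    "lambda_ci_low", "lambda_ci_high", "r_squared", "region",
    "classification", "skewness", "kurtosis", "mean_degree", "complexity",
]

#: Generators analysed against their lambda fit with the chaotic region.
_CHAOTIC_KINDS = set(MAP_REGISTRY) | {
    "schuster", "lorenz_min", "rossler_min", "logistic_noisy",
}


def read_series(path, format: str | None = None) -> TimeSeries:
    """Read a series from plain text (one value per line) or ``t,value`` CSV.

    Non-numeric or non-finite entries are rejected with their line number.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "txt"
    raw = path.read_text().splitlines()
    values: list[float] = []
    start = 0
    if format == "csv":
        if not raw:
            raise ValueError(f"{path}: empty file")
        header = [h.strip().lower() for h in raw[0].split(",")]
        if "value" not in header:
            raise ValueError(f"{path}: CSV must have a 'value' column")
        column = header.index("value")
        start = 1
    for lineno, line in enumerate(raw[start:], start=start + 1):
        line = line.strip()
        if not line:
            continue
        token = line.split(",")[column] if format == "csv" else line
        try:
            value = float(token)
        except ValueError:
            raise ValueError(f"{path}: non-numeric value {token!r} on line {lineno}")
        if not np.isfinite(value):
            raise ValueError(f"{path}: non-finite value on line {lineno}")
        values.append(value)
    if not values:
        raise ValueError(f"{path}: empty file")
    return TimeSeries(np.asarray(values))


def write_series(series: TimeSeries, path, format: str | None = None) -> None:
    """Write a series as plain text or ``t,value`` CSV (1-based t)."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "txt"
    if format == "csv":
        lines = ["t,value"] + [
            f"{t},{v:.17g}" for t, v in enumerate(series.values, start=1)
        ]
    else:
        lines = [f"{v:.17g}" for v in series.values]
    path.write_text("\n".join(lines) + "\n")


def write_edges(graph: HVGraph, path) -> None:
    """Write the HVG edge list as two 1-based tab-separated index columns."""
    Path(path).write_text(
        "".join(f"{i + 1}\t{j + 1}\n" for i, j in graph.edges)
    )


def list_systems_table() -> str:
    """Human-readable registry listing: names, parameter defaults, notes."""
    rows = list_systems()
    width = max(len(r["name"]) for r in rows) + 2
    lines = []
    for r in rows:
        params = ", ".join(f"{k}={v:g}" for k, v in r["params"].items()) or "-"
        lines.append(f"{r['name']:<{width}}{r['kind']:<18}{params}")
        lines.append(f"{'':<{width}}{'':<18}{r['note']}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# Suite runner
# --------------------------------------------------------------------------

#: The desk-scale default corpus: representative maps from each family, the
#: flows' minimum maps, the Schuster grid, the noise families and the
#: noise-contaminated logistic map.
DEFAULT_SUITE_SYSTEMS: list[dict] = (
    [{"name": name} for name in MAP_REGISTRY]
    + [{"name": "schuster", "params": {"z": z}} for z in (1.25, 1.5, 1.75, 2.0)]
    + [{"name": "lorenz_min"}, {"name": "rossler_min"}]
    + [{"name": "knoise", "params": {"k": k}}
       for k in (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)]
    + [{"name": "fgn", "params": {"hurst": h}} for h in (0.1, 0.3, 0.5, 0.7, 0.9)]
    + [{"name": "fbm", "params": {"hurst": h}} for h in (0.1, 0.3, 0.5, 0.7, 0.9)]
    + [{"name": "logistic_noisy", "params": {"amplitude": a}}
       for a in (0.25, 0.5, 0.75, 1.0)]
)


@dataclass
class SuiteConfig:
    """Configuration of a suite run: systems, analysis settings, outputs."""

    systems: list[dict] = field(default_factory=lambda: list(DEFAULT_SUITE_SYSTEMS))
    length: int = 100_000
    discard: int = 1_000
    master_seed: int = 0
    min_count: float = 10
    norm: str = "whitenoise_reference"
    chaotic_region: tuple[int, int] = ds.CHAOTIC_REGION
    stochastic_region: tuple[int, int] = ds.STOCHASTIC_REGION
    csv_path: str | None = None
    plot_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "SuiteConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        analysis = raw.get("analysis", {})
        output = raw.get("output", {})
        return cls(
            systems=raw.get("systems", list(DEFAULT_SUITE_SYSTEMS)),
            length=int(raw.get("length", 100_000)),
            discard=int(raw.get("discard", 1_000)),
            master_seed=int(raw.get("master_seed", 0)),
            min_count=analysis.get("min_count", 10),
            norm=analysis.get("norm", "whitenoise_reference"),
            chaotic_region=tuple(analysis.get("chaotic_region", ds.CHAOTIC_REGION)),
            stochastic_region=tuple(
                analysis.get("stochastic_region", ds.STOCHASTIC_REGION)
            ),
            csv_path=output.get("csv"),
            plot_path=output.get("plot"),
        )


def _subseed(master_seed: int, index: int) -> int:
    """Deterministic per-system seed below 2^31 derived from the master."""
    return int(
        np.random.SeedSequence((master_seed, index)).generate_state(1)[0] % (2**31)
    )


def run_suite(config: SuiteConfig) -> pd.DataFrame:
    """Regenerate the corpus and compute all quantifiers, one row per system.

    Per-system failures are logged and reported as rows with an ``error``
    column; the run continues.  The output is byte-identical across reruns
    with the same master seed.
    """
    rows = []
    for index, entry in enumerate(config.systems):
        name = entry["name"]
        params = dict(entry.get("params", {}))
        coordinate = entry.get("coordinate", 0)
        seed = _subseed(config.master_seed, index)
        kind = entry.get("kind") or (
            "chaotic" if name in _CHAOTIC_KINDS else "stochastic"
        )
        region = (
            config.chaotic_region if kind == "chaotic" else config.stochastic_region
        )
        label = entry.get("label") or _format_label(name, params, coordinate)
        try:
            analysis = HVGAnalysis.from_system(
                name,
                params=params,
                length=int(entry.get("length", config.length)),
                discard=int(entry.get("discard", config.discard)),
                seed=seed,
                coordinate=coordinate,
                region=region,
                min_count=config.min_count,
                norm=config.norm,
                label=label,
            )
            result = analysis.fit().to_dict()
            logger.info("suite: %s -> H=%.4f F=%.4f lambda=%.4f",
                        label, result["H"], result["F"], result["lambda"])
        except Exception as exc:  # noqa: BLE001 - per-system isolation
            logger.warning("suite: %s failed: %s", label, exc)
            rows.append({"system": name, "params": _format_params(params),
                         "coordinate": coordinate, "seed": seed, "error": str(exc)})
            continue
        rows.append(
            {
                "system": name,
                "params": _format_params(params),
                "coordinate": coordinate,
                "n": result["n"],
                "seed": seed,
                "H": result["H"],
                "F": result["F"],
                "lambda": result["lambda"],
                "lambda_ci_low": result["lambda_ci_low"],
                "lambda_ci_high": result["lambda_ci_high"],
                "r_squared": result["r_squared"],
                "region": f"{result['region'][0]}-{result['region'][1]}",
                "classification": result["classification"],
                "skewness": result["skewness"],
                "kurtosis": result["kurtosis"],
                "mean_degree": result["mean_degree"],
                "complexity": result["complexity"],
            }
        )
    frame = pd.DataFrame(rows)
    if config.csv_path:
        frame.to_csv(config.csv_path, index=False, float_format="%.10g")
    if config.plot_path:
        plot_plane(frame, config.plot_path)
    return frame


def _format_params(params: dict) -> str:
    return ";".join(f"{k}={v:g}" for k, v in sorted(params.items())) or "-"


def _format_label(name: str, params: dict, coordinate) -> str:
    label = name
    if params:
        label += "(" + _format_params(params) + ")"
    if coordinate not in (0, "x"):
        label += f"[{coordinate}]"
    return label


def plot_plane(frame: pd.DataFrame, path) -> None:
    """Scatter the suite table in the Shannon-Fisher plane (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ok = frame.dropna(subset=["H", "F"]) if "H" in frame else frame.iloc[0:0]
    fig, ax = plt.subplots(figsize=(7, 5))
    kinds = ok["system"].map(
        lambda s: "chaotic" if s in _CHAOTIC_KINDS else "stochastic"
    )
    for kind, marker, color in (
        ("chaotic", "o", "tab:red"),
        ("stochastic", "s", "tab:blue"),
    ):
        sub = ok[kinds == kind]
        ax.scatter(sub["H"], sub["F"], marker=marker, s=24, label=kind,
                   color=color, alpha=0.8)
    ax.set_xlabel("normalized Shannon entropy H")
    ax.set_ylabel("normalized Fisher information F")
    ax.set_title("Shannon-Fisher information plane (HVG-PDF)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
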