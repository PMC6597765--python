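"""Flat configuration files, fixtures and reproducible CSV output.

Configs are flat YAML key–value files whose keys mirror the within-host
and branching-process parameter names; the two layers use disjoint symbols
so a single namespace suffices.  Unspecified keys fall back to the model
defaults.  Every CSV written through :func:`write_table` records the
package version, the seed and the full parameter set in ``#`` header
comments so runs can be reproduced from their outputs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .branching import BranchingParams
from .within_host import SCENARIOS, WithinHostParams

__all__ = ["RunConfig", "load_config", "make_fixtures", "write_table", "read_table"]

WITHIN_HOST_KEYS = tuple(f.name for f in fields(WithinHostParams))
BRANCHING_KEYS = tuple(f.name for f in fields(BranchingParams))
EXTRA_KEYS = ("seed", "scenario", "grid_lo", "grid_hi")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one run of any module."""

    within_host: WithinHostParams
    branching: BranchingParams
    seed: int = 0
    scenario: str | None = None
    grid_lo: float | None = None
    grid_hi: float | None = None


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config, filling unspecified keys with defaults.

    Unknown keys are rejected by name; an empty file yields the full
    default parameterization of both model layers.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a flat key-value mapping, got {type(raw).__name__}")
    known = set(WITHIN_HOST_KEYS) | set(BRANCHING_KEYS) | set(EXTRA_KEYS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    wh_kwargs = {k: raw[k] for k in WITHIN_HOST_KEYS if k in raw}
    if "bottlenecks" in wh_kwargs:
        wh_kwargs["bottlenecks"] = tuple(int(n) for n in wh_kwargs["bottlenecks"])
    br_kwargs = {k: raw[k] for k in BRANCHING_KEYS if k in raw}
    scenario = raw.get("scenario")
    if scenario is not None and scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}")
    return RunConfig(
        within_host=WithinHostParams(**wh_kwargs),
        branching=BranchingParams(**br_kwargs),
        seed=int(raw.get("seed", 0)),
        scenario=scenario,
        grid_lo=raw.get("grid_lo"),
        grid_hi=raw.get("grid_hi"),
    )


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write one config per mutant-phenotype scenario plus a neutral config.

    Each scenario config carries the scenario's pathology threshold and
    grid bounds; the neutral config (equal inocula, identical strains) is
    the setting in which the closed form ``c = 1 - (1/2)**(n-1)`` holds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, sc in SCENARIOS.items():
        cfg = {
            "scenario": name,
            "phi": sc.phi,
            "grid_lo": sc.low,
            "grid_hi": sc.high,
        }
        path = out / f"{name}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        written.append(path)
    neutral = {
        "rm": 1.0,
        "z": 1.0,
        "v": 1.0,
        "x": 0.0,
        "w0": 0.5,
        "m0": 0.5,
        "bottlenecks": [1, 2, 5, 10],
    }
    path = out / "neutral.yaml"
    path.write_text(yaml.safe_dump(neutral, sort_keys=False))
    written.append(path)
    return written


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | Sequence[tuple[str, object]] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a tidy CSV with a reproducibility header.

    Header comment lines record the package version, the seed (if the run
    was stochastic) and the full parameter set.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# coemerge {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for key, value in dict(params or {}).items():
        lines.append(f"# {key}: {value}")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping header comments."""
    return pd.read_csv(path, comment="#")
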