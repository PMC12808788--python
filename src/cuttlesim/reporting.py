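"""Configuration files, summary statistics, and landscape export.

Config files are flat YAML key-value documents whose keys mirror the
scenario dataclass fields; unknown keys are rejected and all range
invariants are enforced at load time.  Quantiles use linear interpolation
(numpy's default, "type 7"), since no other convention is mandated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .memory_core import EpisodicMemory, load_memory
from .scenario_elm import ElmConfig
from .scenario_predprey import PredPreyConfig

__all__ = [
    "BoxplotSummary",
    "RunManifest",
    "load_config",
    "boxplot_summary",
    "export_landscape",
]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a batch of runs byte-for-byte."""

    scenario: str  # "elm" | "pp"
    config: dict
    base_seed: int
    run_seeds: List[int]
    artifacts: List[str]
    code_version: str

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class BoxplotSummary:
    """Quartile summary with the 1.5 x IQR whisker rule."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]
    n: int


def load_config(path: Union[str, Path], scenario: str):
    """Load an ELM or predator-prey config from a YAML key-value file.

    An empty file yields the scenario's reference defaults.  Unknown keys
    and out-of-range values raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a key-value document, got {type(raw).__name__}")
    cls = {"elm": ElmConfig, "pp": PredPreyConfig}.get(scenario)
    if cls is None:
        raise ValueError(f"scenario must be 'elm' or 'pp', got {scenario!r}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys for {scenario}: {sorted(unknown)}")
    # YAML lists become tuples where the dataclass expects them
    for key, val in list(raw.items()):
        if isinstance(val, list):
            raw[key] = tuple(val)
    return cls(**raw)


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Median/quartiles with whiskers at 1.5 x IQR, clipped to observed data."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_summary requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)]),
        n=int(v.size),
    )


def export_landscape(
    memory: Union[EpisodicMemory, str, Path], out_dir: Union[str, Path]
) -> List[Path]:
    """Write one value-landscape table per hour from a memory (or its dump).

    Each ``landscape_hour_<h>.csv`` holds the nonzero entries at that hour
    with columns what,x,y,value,magnitude.  Selecting any hour of the same
    persistent memory is what lets one inspect the expected-value
    landscape forward or backward in time.
    """
    if not isinstance(memory, EpisodicMemory):
        memory = load_memory(memory)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .memory_core import landscape as _landscape

    table = _landscape(memory)
    paths = []
    for hour in range(memory.n_when):
        sub = table[table["when"] == hour][["what", "x", "y", "value", "magnitude"]]
        p = out_dir / f"landscape_hour_{hour}.csv"
        sub.to_csv(p, index=False)
        paths.append(p)
    return paths
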