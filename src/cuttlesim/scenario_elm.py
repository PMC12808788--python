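"""Two-phase foraging experiment on an 8x8 grid.

A cuttlefish agent starts each hour at the middle of the left wall and can
hunt a crab (fixed cell, low reward), hunt a shrimp (fixed cell, high
reward), or roam.  During phase 1 both prey are available every hour;
after the phase switch the shrimp is only available at the last hour of
the day.  The agent learns (object, hour, cell) values with the delta
rule and picks actions by softmax over the per-object maxima plus a
constant roam value.

Hours are 0-based: hour index ``h`` corresponds to an ``h+1``-hour delay.

Extinction: visiting a remembered prey cell when that prey is absent
applies a zero-reward delta update (at most once per cell and hour), so
stale memories decay.  This is what lets the agent switch to the crab at
short delays in phase 2; it can be disabled in the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .gridworld import Cell, GridSpec, distance, random_step, step_toward
from .memory_core import (
    EpisodicMemory,
    LearningParams,
    argmax_cell,
    delta_update,
    make_memory,
    softmax_choice,
)

__all__ = [
    "CRAB",
    "SHRIMP",
    "ELM_ACTIONS",
    "ElmConfig",
    "HourRecord",
    "availability",
    "elm_select_action",
    "run_elm_hour",
    "run_elm",
    "choice_percentages",
]

CRAB = 0
SHRIMP = 1
_OBJECT_NAMES = ("crab", "shrimp")

ELM_ACTIONS = ("hunt_crab", "hunt_shrimp", "roam")


@dataclass(frozen=True)
class ElmConfig:
    """Parameters of the two-phase scenario (defaults are the reference values)."""

    days: int = 100
    phase2_start_day: int = 50
    hours_per_day: int = 3
    steps_per_hour: int = 100
    n_runs: int = 100
    grid_width: int = 8
    grid_height: int = 8
    cuttlefish_start: Tuple[int, int] = (0, 4)
    crab_pos: Tuple[int, int] = (7, 0)
    shrimp_pos: Tuple[int, int] = (7, 7)
    crab_reward: float = 1.0
    shrimp_reward: float = 4.0
    alpha: float = 0.10
    beta: float = 1.0
    roam_value: float = 0.5
    vision: int = 2  # exclusive Chebyshev bound
    extinction: bool = True
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.phase2_start_day < self.days):
            raise ValueError("phase2_start_day must lie strictly inside the run")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        grid = self.grid
        for name in ("cuttlefish_start", "crab_pos", "shrimp_pos"):
            cell = Cell(*getattr(self, name))
            if not grid.in_bounds(cell):
                raise ValueError(f"{name}={tuple(cell)} is out of bounds for {grid}")
        if min(self.days, self.hours_per_day, self.steps_per_hour, self.n_runs) < 1:
            raise ValueError("days, hours, steps and runs must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_width, self.grid_height)

    @property
    def params(self) -> LearningParams:
        return LearningParams(
            alpha=self.alpha,
            beta=self.beta,
            reward_by_object={"crab": self.crab_reward, "shrimp": self.shrimp_reward},
            roam_value=self.roam_value,
        )


@dataclass(frozen=True)
class HourRecord:
    """One decision-and-outcome record."""

    run: int
    day: int
    hour: int
    phase: int
    action: str
    outcome: str  # "ate_crab" | "ate_shrimp" | "none"
    end_position: Tuple[int, int]


def availability(phase: int, hour: int, obj: int) -> bool:
    """Whether an object is present: crab always; shrimp gated in phase 2."""
    if obj == CRAB:
        return True
    if obj == SHRIMP:
        return phase == 1 or hour == 2
    raise ValueError(f"unknown object {obj}")


def elm_select_action(
    mem: EpisodicMemory, hour: int, params: LearningParams, rng: np.random.Generator
) -> str:
    """Softmax over [max crab value, max shrimp value, roam constant]."""
    values = [
        float(mem.values[CRAB, hour, :].max()),
        float(mem.values[SHRIMP, hour, :].max()),
        params.roam_value,
    ]
    return ELM_ACTIONS[softmax_choice(values, params.beta, rng)]


def run_elm_hour(
    mem: EpisodicMemory,
    run: int,
    day: int,
    hour: int,
    config: ElmConfig,
    rng: np.random.Generator,
) -> HourRecord:
    """Simulate one hour: choose an action, walk, learn from encounters."""
    grid = config.grid
    phase = 1 if day < config.phase2_start_day else 2
    params = config.params
    action = elm_select_action(mem, hour, params, rng)

    prey_pos = {CRAB: Cell(*config.crab_pos), SHRIMP: Cell(*config.shrimp_pos)}
    rewards = {CRAB: config.crab_reward, SHRIMP: config.shrimp_reward}
    pos = Cell(*config.cuttlefish_start)

    target: Optional[Cell] = None
    if action == "hunt_crab":
        target = grid.cell_at(argmax_cell(mem, CRAB, hour))
    elif action == "hunt_shrimp":
        target = grid.cell_at(argmax_cell(mem, SHRIMP, hour))

    # remembered (nonzero) cells per object, frozen at hour start; extinction
    # fires at most once per cell per hour
    remembered: Dict[int, List[int]] = {
        obj: np.nonzero(mem.values[obj, hour, :])[0].tolist() for obj in (CRAB, SHRIMP)
    }
    extinguished: set = set()

    outcome = "none"
    for _ in range(config.steps_per_hour):
        if target is not None and pos != target:
            pos = step_toward(pos, target)
        else:
            pos = random_step(pos, grid, rng)

        ate = False
        for obj in (CRAB, SHRIMP):
            if availability(phase, hour, obj) and distance(pos, prey_pos[obj]) < config.vision:
                delta_update(mem, obj, hour, grid.cell_index(prey_pos[obj]), rewards[obj], config.alpha)
                outcome = f"ate_{_OBJECT_NAMES[obj]}"
                ate = True
                break
        if ate:
            break  # at most one meal per hour; agent idles afterwards

        if config.extinction:
            for obj in (CRAB, SHRIMP):
                present = availability(phase, hour, obj)
                for ci in remembered[obj]:
                    if (obj, ci) in extinguished:
                        continue
                    cell = grid.cell_at(ci)
                    if distance(pos, cell) < config.vision:
                        if present and cell == prey_pos[obj]:
                            continue  # object is there; rewarded path handles it
                        delta_update(mem, obj, hour, ci, 0.0, config.alpha)
                        extinguished.add((obj, ci))

    return HourRecord(run, day, hour, phase, action, outcome, tuple(pos))


def run_elm(
    config: ElmConfig, progress: bool = False
) -> Tuple[pd.DataFrame, List[EpisodicMemory]]:
    """Run all seeded repetitions; per-run seed = base_seed + run index.

    Returns a tidy record frame (one row per run/day/hour) and the final
    memory of each run.
    """
    rows = []
    memories: List[EpisodicMemory] = []
    iterator = range(config.n_runs)
    if progress:
        from tqdm import tqdm  # optional; only imported when asked for

        iterator = tqdm(iterator, desc="elm runs")
    for run in iterator:
        rng = np.random.default_rng(config.base_seed + run)
        mem = make_memory(2, config.hours_per_day, config.grid.n_cells, width=config.grid_width)
        for day in range(config.days):
            for hour in range(config.hours_per_day):
                rec = run_elm_hour(mem, run, day, hour, config, rng)
                rows.append(rec)
        memories.append(mem)
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df, memories


def choice_percentages(
    records: pd.DataFrame, phase: int, last_n_days: int = 10
) -> pd.DataFrame:
    """Per-run action-choice percentages over the last N days of a phase.

    Returns a tidy frame (run, hour, action, pct); for each run and hour
    the three action percentages sum to 100.
    """
    sub = records[records["phase"] == phase]
    days = sorted(sub["day"].unique())
    if len(days) < last_n_days:
        raise ValueError(
            f"phase {phase} has only {len(days)} days, need at least {last_n_days}"
        )
    keep = set(days[-last_n_days:])
    sub = sub[sub["day"].isin(keep)]
    counts = (
        sub.groupby(["run", "hour", "action"], observed=True).size().unstack(fill_value=0)
    )
    for action in ELM_ACTIONS:
        if action not in counts.columns:
            counts[action] = 0
    pct = counts[list(ELM_ACTIONS)] * (100.0 / last_n_days)
    tidy = pct.stack().rename("pct").reset_index()
    tidy.columns = ["run", "hour", "action", "pct"]
    return tidy
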