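"""Predator-prey foraging experiment on a 12x12 grid with two query modes.

Each hour the agent is placed at the top of the grid and chooses an action
from its memory.  In "what" mode the memory is queried per object (values
summed over all cells); the action set is hunt crab, hunt shrimp, hide,
roam.  In "where" mode the memory is queried per region (values summed
over all objects and cells in each 4x4 region); the action set is the nine
regions plus roam and hide.

Shrimp (reward 4) appear in region 6 during hours 2-5, crabs (reward 1)
in region 8 all day, and a predator roams the left half during hours 1-3.
Being caught writes a penalty of -8 at the agent's cell on the predator
axis; the hide action makes the agent invisible and suspends all memory
updates.  The hide action's value is the negated sum of the predator
slice at the current hour, so remembered danger makes hiding attractive.

Per hour at most one event occurs (eat one prey, or be eaten); the agent
then idles until the next hour.  Within a timestep the cuttlefish moves,
then the predator, then events resolve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .gridworld import (
    AgentState,
    Cell,
    GridSpec,
    N_REGIONS,
    distance,
    place_in_region,
    place_predator,
    random_step,
    random_step_in_region,
    region_cells,
    region_center,
    region_of,
    step_toward,
)
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
    "PREDATOR",
    "WHAT_ACTIONS",
    "WHERE_ACTIONS",
    "PredPreyConfig",
    "PpHourRecord",
    "pp_place_objects",
    "what_action_values",
    "where_action_values",
    "select_action_what",
    "select_action_where",
    "hide_value",
    "predator_step",
    "run_pp_hour",
    "run_pp",
    "outcome_means",
    "actions_per_hour",
]

CRAB = 0
SHRIMP = 1
PREDATOR = 2
_OBJECT_NAMES = ("crab", "shrimp", "predator")

WHAT_ACTIONS = ("hunt_crab", "hunt_shrimp", "hide", "roam")
WHERE_ACTIONS = tuple(f"region_{k}" for k in range(N_REGIONS)) + ("roam", "hide")

_HUNT_TARGET = {"hunt_crab": CRAB, "hunt_shrimp": SHRIMP}


@dataclass(frozen=True)
class PredPreyConfig:
    """Parameters of the predator-prey scenario (defaults are the reference values)."""

    days: int = 200
    hours_per_day: int = 6
    steps_per_hour: int = 100
    n_runs: int = 100
    grid_width: int = 12
    grid_height: int = 12
    cuttlefish_start: Tuple[int, int] = (6, 0)
    shrimp_region: int = 6
    shrimp_hours: Tuple[int, int] = (2, 5)  # inclusive window
    shrimp_reward: float = 4.0
    crab_region: int = 8
    crab_hours: Tuple[int, int] = (0, 5)
    crab_reward: float = 1.0
    predator_hours: Tuple[int, int] = (1, 3)
    predator_x_max: int = 5  # left side: x in [0, x_max]
    predator_vision: int = 4  # exclusive Chebyshev bound
    predator_penalty: float = 8.0  # magnitude; stored as -8
    catch_radius: int = 2  # exclusive, same as the prey-interaction radius
    alpha: float = 0.10
    beta: float = 1.0
    roam_value: float = 0.5
    vision: int = 2
    # Zero-reward decay of remembered prey cells seen empty.  Off by
    # default: prey availability windows are static here, so there is no
    # stale prey memory to unlearn, and the decay only suppresses the
    # region/object sums the policies rely on.
    extinction: bool = False
    # Zero-reward decay of remembered danger cells passed through safely.
    # This lets a region recover after captures poisoned its value; without
    # it a single early capture can lock the agent out of the crab region.
    predator_extinction: bool = True
    query_mode: str = "what"  # "what" | "where"
    # Offer hide (with its learned value) among the where-mode options.
    # Off by default: a learnable hide value comes to dominate the predator
    # hours and suppresses the opportunistic crab hunting this mode is
    # meant to exhibit; the reported where-mode agent hunts unhidden.
    where_hide: bool = False
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.query_mode not in ("what", "where"):
            raise ValueError(f"query_mode must be 'what' or 'where', got {self.query_mode!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("shrimp_hours", "crab_hours", "predator_hours"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi < self.hours_per_day):
                raise ValueError(f"{name}={(lo, hi)} outside 0..{self.hours_per_day - 1}")
        for name in ("shrimp_region", "crab_region"):
            if not 0 <= getattr(self, name) < N_REGIONS:
                raise ValueError(f"{name} must be a valid region id")
        if not self.grid.in_bounds(Cell(*self.cuttlefish_start)):
            raise ValueError("cuttlefish_start out of bounds")
        if self.predator_penalty < 0:
            raise ValueError("predator_penalty is a magnitude, must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_width, self.grid_height)

    @property
    def params(self) -> LearningParams:
        return LearningParams(
            alpha=self.alpha,
            beta=self.beta,
            reward_by_object={
                "crab": self.crab_reward,
                "shrimp": self.shrimp_reward,
                "predator": -self.predator_penalty,
            },
            roam_value=self.roam_value,
        )


@dataclass(frozen=True)
class PpHourRecord:
    run: int
    day: int
    hour: int
    mode: str
    action: str
    outcome: str  # "ate_crab" | "ate_shrimp" | "eaten" | "none"


def _in_window(hour: int, window: Tuple[int, int]) -> bool:
    return window[0] <= hour <= window[1]


def pp_place_objects(
    hour: int, config: PredPreyConfig, rng: np.random.Generator
) -> Dict[str, Optional[Cell]]:
    """Place shrimp, crab and predator for one hour (None when unavailable)."""
    shrimp = (
        place_in_region(config.shrimp_region, rng)
        if _in_window(hour, config.shrimp_hours)
        else None
    )
    crab = (
        place_in_region(config.crab_region, rng)
        if _in_window(hour, config.crab_hours)
        else None
    )
    predator = (
        place_predator(rng, x_max=config.predator_x_max, height=config.grid_height)
        if _in_window(hour, config.predator_hours)
        else None
    )
    return {"shrimp": shrimp, "crab": crab, "predator": predator}


def hide_value(mem: EpisodicMemory, hour: int) -> float:
    """Attractiveness of hiding: the negated predator-slice sum (>= 0)."""
    return -float(mem.values[PREDATOR, hour, :].sum())


_hide_value = hide_value


def what_action_values(mem: EpisodicMemory, hour: int, params: LearningParams) -> List[float]:
    """Per-object totals in WHAT_ACTIONS order: [crab sum, shrimp sum, hide, roam]."""
    return [
        float(mem.values[CRAB, hour, :].sum()),
        float(mem.values[SHRIMP, hour, :].sum()),
        _hide_value(mem, hour),
        params.roam_value,
    ]


def select_action_what(
    mem: EpisodicMemory, hour: int, params: LearningParams, rng: np.random.Generator
) -> str:
    """Softmax over per-object totals."""
    values = what_action_values(mem, hour, params)
    return WHAT_ACTIONS[softmax_choice(values, params.beta, rng)]


def where_action_values(
    mem: EpisodicMemory,
    hour: int,
    params: LearningParams,
    include_hide: bool = False,
) -> List[float]:
    """Per-region signed totals (all objects) in WHERE_ACTIONS order, plus roam.

    Remembered predator encounters are stored negative, so they repel the
    agent from a region.  With ``include_hide`` the hide action joins the
    choice set at its learned value (see ``PredPreyConfig.where_hide``).
    """
    grid12 = GridSpec(12, 12)
    values = []
    for k in range(N_REGIONS):
        idx = [grid12.cell_index(c) for c in region_cells(k)]
        values.append(float(mem.values[:, hour, idx].sum()))
    values.append(params.roam_value)
    if include_hide:
        values.append(_hide_value(mem, hour))
    return values


def select_action_where(
    mem: EpisodicMemory,
    hour: int,
    params: LearningParams,
    rng: np.random.Generator,
    include_hide: bool = False,
) -> str:
    """Softmax over per-region totals plus roam (and optionally hide)."""
    values = where_action_values(mem, hour, params, include_hide)
    return WHERE_ACTIONS[softmax_choice(values, params.beta, rng)]


def predator_step(
    pred: AgentState, cuttle: AgentState, grid: GridSpec, rng: np.random.Generator
) -> Cell:
    """Chase a visible (non-hidden) cuttlefish, otherwise move randomly."""
    if not cuttle.hidden and pred.sees(cuttle.position):
        return step_toward(pred.position, cuttle.position)
    return random_step(pred.position, grid, rng)


def run_pp_hour(
    mem: EpisodicMemory,
    run: int,
    day: int,
    hour: int,
    config: PredPreyConfig,
    rng: np.random.Generator,
) -> PpHourRecord:
    """Simulate one hour of the predator-prey scenario."""
    grid = config.grid
    params = config.params
    placements = pp_place_objects(hour, config, rng)

    if config.query_mode == "what":
        action = select_action_what(mem, hour, params, rng)
    else:
        action = select_action_where(mem, hour, params, rng, include_hide=config.where_hide)

    if action == "hide":
        # camouflaged: invisible to the predator, no encounters, no updates
        return PpHourRecord(run, day, hour, config.query_mode, action, "none")

    target_region: Optional[int] = None
    if action in _HUNT_TARGET:
        target_region = region_of(grid.cell_at(argmax_cell(mem, _HUNT_TARGET[action], hour)))
    elif action.startswith("region_"):
        target_region = int(action.split("_")[1])

    cuttle = AgentState(Cell(*config.cuttlefish_start), vision_radius=config.vision)
    pred: Optional[AgentState] = None
    if placements["predator"] is not None:
        pred = AgentState(placements["predator"], vision_radius=config.predator_vision, role="predator")

    prey_pos = {CRAB: placements["crab"], SHRIMP: placements["shrimp"]}
    rewards = {CRAB: config.crab_reward, SHRIMP: config.shrimp_reward}
    remembered: Dict[int, List[int]] = {
        obj: np.nonzero(mem.values[obj, hour, :])[0].tolist()
        for obj in (CRAB, SHRIMP, PREDATOR)
    }
    extinguished: set = set()

    outcome = "none"
    for _ in range(config.steps_per_hour):
        if target_region is None:
            cuttle.position = random_step(cuttle.position, grid, rng)
        elif region_of(cuttle.position) != target_region:
            cuttle.position = step_toward(cuttle.position, region_center(target_region))
        else:
            cuttle.position = random_step_in_region(cuttle.position, target_region, rng)

        if pred is not None:
            pred.position = predator_step(pred, cuttle, grid, rng)

        ate = False
        for obj in (CRAB, SHRIMP):
            p = prey_pos[obj]
            if p is not None and distance(cuttle.position, p) < config.vision:
                delta_update(mem, obj, hour, grid.cell_index(p), rewards[obj], config.alpha)
                outcome = f"ate_{_OBJECT_NAMES[obj]}"
                ate = True
                break
        if ate:
            break
        if pred is not None and distance(pred.position, cuttle.position) < config.catch_radius:
            delta_update(
                mem, PREDATOR, hour, grid.cell_index(cuttle.position),
                -config.predator_penalty, config.alpha,
            )
            outcome = "eaten"
            break

        decay_objs = []
        if config.extinction:
            decay_objs += [CRAB, SHRIMP]
        if config.predator_extinction:
            decay_objs.append(PREDATOR)
        for obj in decay_objs:
            occupant = prey_pos.get(obj) if obj != PREDATOR else (
                pred.position if pred is not None else None
            )
            for ci in remembered[obj]:
                if (obj, ci) in extinguished:
                    continue
                cell = grid.cell_at(ci)
                if distance(cuttle.position, cell) < config.vision:
                    if occupant is not None and cell == occupant:
                        continue  # the object really is there right now
                    delta_update(mem, obj, hour, ci, 0.0, config.alpha)
                    extinguished.add((obj, ci))

    return PpHourRecord(run, day, hour, config.query_mode, action, outcome)


def run_pp(
    config: PredPreyConfig, progress: bool = False
) -> Tuple[pd.DataFrame, List[EpisodicMemory]]:
    """Run all seeded repetitions; per-run seed = base_seed + run index."""
    rows = []
    memories: List[EpisodicMemory] = []
    iterator = range(config.n_runs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc=f"pp[{config.query_mode}] runs")
    for run in iterator:
        rng = np.random.default_rng(config.base_seed + run)
        mem = make_memory(3, config.hours_per_day, config.grid.n_cells, width=config.grid_width)
        for day in range(config.days):
            for hour in range(config.hours_per_day):
                rows.append(run_pp_hour(mem, run, day, hour, config, rng))
        memories.append(mem)
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df, memories


_EVENTS = ("ate_crab", "ate_shrimp", "eaten")


def outcome_means(
    records: pd.DataFrame,
    day_range: Optional[Tuple[int, int]] = None,
) -> pd.DataFrame:
    """Mean and standard error over runs of per-day event counts.

    Returns a tidy frame (day, event, mean, se); SE is sd/sqrt(n_runs).
    ``day_range`` is an inclusive (start, end) window.
    """
    sub = records
    if day_range is not None:
        sub = sub[(sub["day"] >= day_range[0]) & (sub["day"] <= day_range[1])]
    runs = sorted(records["run"].unique())
    days = sorted(sub["day"].unique())
    n_runs = len(runs)
    counts = (
        sub[sub["outcome"].isin(_EVENTS)]
        .groupby(["day", "outcome", "run"], observed=True)
        .size()
        .unstack("run", fill_value=0)
        .reindex(columns=runs, fill_value=0)
        .reindex(
            pd.MultiIndex.from_product([days, _EVENTS], names=["day", "outcome"]),
            fill_value=0,
        )
    )
    out = pd.DataFrame(
        {
            "day": counts.index.get_level_values("day"),
            "event": counts.index.get_level_values("outcome"),
            "mean": counts.mean(axis=1).to_numpy(),
            "se": (
                counts.std(axis=1, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else 0.0
            ),
        }
    ).reset_index(drop=True)
    return out


def actions_per_hour(
    records: pd.DataFrame,
    day_window: Union[str, Tuple[int, int]] = "last-20",
    window_days: int = 20,
) -> pd.DataFrame:
    """Mean and sd over runs of per-hour action counts within a day window.

    ``day_window`` is ``"first-20"``, ``"last-20"`` (20 replaced by
    ``window_days``) or an inclusive (start, end) tuple.  For each run the
    counts at one hour sum to the window length.
    """
    days = sorted(records["day"].unique())
    if day_window == f"first-{window_days}" or day_window == "first":
        keep = days[:window_days]
    elif day_window == f"last-{window_days}" or day_window == "last":
        keep = days[-window_days:]
    elif isinstance(day_window, tuple):
        keep = [d for d in days if day_window[0] <= d <= day_window[1]]
    else:
        raise ValueError(f"unrecognized day_window {day_window!r}")
    sub = records[records["day"].isin(set(keep))]

    mode = records["mode"].iloc[0]
    actions = WHAT_ACTIONS if mode == "what" else WHERE_ACTIONS
    runs = sorted(records["run"].unique())
    hours = sorted(records["hour"].unique())
    counts = (
        sub.groupby(["hour", "action", "run"], observed=True)
        .size()
        .unstack("run", fill_value=0)
        .reindex(columns=runs, fill_value=0)
        .reindex(
            pd.MultiIndex.from_product([hours, actions], names=["hour", "action"]),
            fill_value=0,
        )
    )
    return pd.DataFrame(
        {
            "hour": counts.index.get_level_values("hour"),
            "action": counts.index.get_level_values("action"),
            "mean": counts.mean(axis=1).to_numpy(),
            "sd": counts.std(axis=1, ddof=1).to_numpy() if len(runs) > 1 else 0.0,
        }
    ).reset_index(drop=True)
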