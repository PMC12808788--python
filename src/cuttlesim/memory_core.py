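"""Queryable three-dimensional value memory.

The memory is a dense real-valued array indexed by (what, when, where):
object kind, hour of day, and flattened grid cell.  Values are expected
rewards learned with the delta rule and read out by queries that fix any
subset of the three dimensions.  Action selection over queried values uses
softmax sampling.

Conventions
-----------
* The flat cell index is ``y * width + x`` (0-based, x rightward, y
  downward).
* Penalties are stored signed (a penalty of magnitude 8 is stored as -8),
  so sums over mixed slices are repelled by remembered danger.
* Softmax uses the conventional ``exp(beta * v)`` form.  With the scaled
  temperature written outside the exponent the factor cancels between
  numerator and denominator, so at ``beta = 1`` the two readings coincide;
  we implement the form that actually modulates stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpisodicMemory",
    "LearningParams",
    "ValueSlice",
    "make_memory",
    "query",
    "delta_update",
    "softmax_probs",
    "softmax_choice",
    "argmax_cell",
    "summed_value",
    "landscape",
    "save_memory",
    "load_memory",
]


@dataclass
class EpisodicMemory:
    """Dense value store over (what, when, where) tuples.

    Attributes
    ----------
    values : ndarray of shape (n_what, n_when, n_where)
        Learned expected values; zero-initialized.
    width : int or None
        Optional grid width used to translate flat cell indices back to
        (x, y) coordinates for dumps and landscapes.
    """

    values: np.ndarray
    width: Optional[int] = None

    @property
    def n_what(self) -> int:
        return self.values.shape[0]

    @property
    def n_when(self) -> int:
        return self.values.shape[1]

    @property
    def n_where(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class LearningParams:
    """Learning-rule and action-selection parameters."""

    alpha: float = 0.10
    beta: float = 1.0
    reward_by_object: Mapping[str, float] = field(
        default_factory=lambda: {"crab": 1.0, "shrimp": 4.0, "predator": -8.0}
    )
    roam_value: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not np.isfinite(self.roam_value):
            raise ValueError("roam_value must be finite")


@dataclass(frozen=True)
class ValueSlice:
    """Snapshot of memory values at a partial (what, when, where) selector.

    ``data`` is a copy: later updates to the memory do not mutate a slice.
    """

    selector: tuple[Optional[int], Optional[int], Optional[int]]
    data: np.ndarray


def make_memory(n_what: int, n_when: int, n_where: int, *, width: Optional[int] = None) -> EpisodicMemory:
    """Create a zero-initialized memory of shape (n_what, n_when, n_where)."""
    for name, n in (("n_what", n_what), ("n_when", n_when), ("n_where", n_where)):
        if int(n) != n or n < 1:
            raise ValueError(f"{name} must be a positive integer, got {n!r}")
    return EpisodicMemory(values=np.zeros((int(n_what), int(n_when), int(n_where))), width=width)


def query(
    mem: EpisodicMemory,
    what: Optional[int] = None,
    when: Optional[int] = None,
    where: Optional[int] = None,
) -> ValueSlice:
    """Read out the values over the free dimensions of a partial index.

    Fixed dimensions are given as integers; free dimensions as ``None``.
    Fixing all three yields a 0-d snapshot.  Out-of-bounds indices raise
    ``IndexError``.
    """
    idx = []
    for axis, sel in enumerate((what, when, where)):
        if sel is None:
            idx.append(slice(None))
        else:
            n = mem.values.shape[axis]
            if not 0 <= sel < n:
                raise IndexError(f"index {sel} out of bounds for axis {axis} with size {n}")
            idx.append(int(sel))
    return ValueSlice(selector=(what, when, where), data=np.array(mem.values[tuple(idx)]))


def delta_update(
    mem: EpisodicMemory, what: int, when: int, where: int, r: float, alpha: float
) -> float:
    """Apply one delta-rule step ``v <- v + alpha * (r - v)`` at a single cell.

    Returns the new stored value.  All other entries are untouched.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    old = mem.values[what, when, where]
    new = old + alpha * (r - old)
    mem.values[what, when, where] = new
    return float(new)


def softmax_probs(values: Sequence[float], beta: float = 1.0) -> np.ndarray:
    """Softmax probabilities ``exp(beta*v_i) / sum_j exp(beta*v_j)``.

    Stabilized by max subtraction so large values cannot overflow.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("softmax requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax values must be finite")
    if beta < 0.0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    z = beta * v
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_choice(values: Sequence[float], beta: float, rng: np.random.Generator) -> int:
    """Sample an index with softmax probabilities at inverse temperature beta."""
    p = softmax_probs(values, beta)
    return int(rng.choice(len(p), p=p))


def argmax_cell(mem: EpisodicMemory, what: int, when: int) -> int:
    """Flat cell index of the maximum value for an object at an hour.

    Ties break to the smallest flat index, which is deterministic across
    platforms.
    """
    return int(np.argmax(mem.values[what, when, :]))


def summed_value(mem: EpisodicMemory, what: int, when: int, cells: Iterable[int]) -> float:
    """Signed sum of stored values over a set of cells (empty set -> 0.0)."""
    idx = np.fromiter(cells, dtype=int)
    if idx.size == 0:
        return 0.0
    return float(mem.values[what, when, idx].sum())


def landscape(mem: EpisodicMemory, width: Optional[int] = None) -> pd.DataFrame:
    """Tabulate every nonzero entry as (what, when, cell, x, y, value, magnitude).

    Rows are sorted by (when, what, cell).  The ``magnitude`` column is
    ``abs(value)``, a rendering hint for marker sizes.  ``width`` defaults
    to the memory's own grid width, falling back to ``sqrt(n_where)``.
    """
    if width is None:
        width = mem.width
    if width is None:
        width = int(round(mem.n_where ** 0.5))
        if width * width != mem.n_where:
            raise ValueError("width is required for a non-square cell count")
    whats, whens, cells = np.nonzero(mem.values)
    vals = mem.values[whats, whens, cells]
    df = pd.DataFrame(
        {
            "what": whats,
            "when": whens,
            "cell": cells,
            "x": cells % width,
            "y": cells // width,
            "value": vals,
            "magnitude": np.abs(vals),
        }
    )
    return df.sort_values(["when", "what", "cell"], kind="stable").reset_index(drop=True)


def save_memory(mem: EpisodicMemory, path, *, nonzero_only: bool = False, width: Optional[int] = None) -> None:
    """Dump the memory to CSV with header ``what,when,cell,x,y,value``.

    Values are written with full float precision so a read back
    round-trips exactly.
    """
    if width is None:
        width = mem.width
    if width is None:
        width = int(round(mem.n_where ** 0.5))
        if width * width != mem.n_where:
            raise ValueError("width is required for a non-square cell count")
    if nonzero_only:
        whats, whens, cells = np.nonzero(mem.values)
    else:
        whats, whens, cells = (
            a.ravel() for a in np.indices(mem.values.shape)
        )
    vals = mem.values[whats, whens, cells]
    df = pd.DataFrame(
        {
            "what": whats,
            "when": whens,
            "cell": cells,
            "x": cells % width,
            "y": cells // width,
            "value": [repr(float(v)) for v in vals],
        }
    )
    df.to_csv(path, index=False)


def load_memory(
    path,
    n_what: Optional[int] = None,
    n_when: Optional[int] = None,
    n_where: Optional[int] = None,
) -> EpisodicMemory:
    """Read a memory dump written by :func:`save_memory`.

    Shape is inferred from the maximum indices present unless given
    explicitly (needed for nonzero-only dumps whose extremal indices may
    be absent).
    """
    df = pd.read_csv(path)
    expected = ["what", "when", "cell", "x", "y", "value"]
    if list(df.columns) != expected:
        raise ValueError(f"malformed memory dump: expected columns {expected}, got {list(df.columns)}")
    if n_what is None:
        n_what = int(df["what"].max()) + 1 if len(df) else 1
    if n_when is None:
        n_when = int(df["when"].max()) + 1 if len(df) else 1
    if n_where is None:
        n_where = int(df["cell"].max()) + 1 if len(df) else 1
    width = None
    nz = df[df["y"] > 0]
    if len(nz):
        # cell = y*width + x  =>  width recoverable from any row with y > 0
        width = int((nz["cell"].iloc[0] - nz["x"].iloc[0]) / nz["y"].iloc[0])
    mem = make_memory(n_what, n_when, n_where, width=width)
    mem.values[df["what"].to_numpy(), df["when"].to_numpy(), df["cell"].to_numpy()] = df[
        "value"
    ].to_numpy(dtype=float)
    return mem
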