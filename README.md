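# cuttlesim

An agent-based model of episodic-like memory. The core is a dense
three-dimensional value store indexed by **what** (object kind), **when**
(hour of day) and **where** (grid cell), learned with the delta rule
`v ← v + α(r − v)` and read out through partial queries; actions are
sampled by softmax over queried values. Two grid-world experiments
exercise the memory:

- **Two-phase foraging (`elm`)** — an 8×8 world with a crab (reward 1) and
  a shrimp (reward 4) at fixed cells. In phase 1 both are available every
  hour; in phase 2 the shrimp appears only at the last of the three hours.
  The agent learns to take the crab at short delays and wait for the
  shrimp at the long delay.
- **Predator–prey (`pp`)** — a 12×12 world split into nine 4×4 regions,
  with shrimp (region 6, hours 2–5), crabs (region 8, all day) and a
  predator (left half, hours 1–3, penalty −8). Two query modes produce
  different behavior from the same memory: *what*-queries (per-object
  value totals, with a hide action valued by remembered danger) yield
  risk-averse hunting, while *where*-queries (per-region signed totals)
  yield opportunistic, riskier crab hunting.

The same persistent memory can be queried at any hour index, exposing the
expected-value landscape forward or backward in time (`landscape`).

## Layout

| module | contents |
|---|---|
| `cuttlesim.memory_core` | the 3-D value store, delta rule, softmax, queries, CSV dumps |
| `cuttlesim.gridworld` | Chebyshev geometry, movement, regions, object placement |
| `cuttlesim.scenario_elm` | the two-phase foraging experiment |
| `cuttlesim.scenario_predprey` | the predator–prey experiment (what/where modes) |
| `cuttlesim.reporting` / `cuttlesim.cli` | configs, boxplot summaries, landscape export, CLI |

## Command line

```sh
# two-phase foraging: 100 runs x 100 days, phase 2 after day 50
cuttlesim elm --runs 100 --days 100 --phase2-day 50 --seed 0 --out out/elm

# predator-prey, either query mode
cuttlesim pp --mode what  --runs 100 --days 200 --seed 0 --out out/what
cuttlesim pp --mode where --runs 100 --days 200 --seed 0 --out out/where

# summary tables from a run directory
cuttlesim report --in out/elm  --figure 4
cuttlesim report --in out/what --figure 5

# per-hour expected-value landscapes from a memory dump
cuttlesim elm --runs 1 --days 100 --phase2-day 50 --seed 0 --out out/one --dump-memories
cuttlesim landscape --memory out/one/elm_memory_run000.csv --out out/land
```

Outputs are tidy CSV files (one row per run/day/hour) plus a
`manifest.yaml` that pins the config and per-run seeds; a repeated
invocation with the same manifest reproduces every record byte-for-byte.
Scenario parameters can also be given as a flat YAML file (`--config`);
unknown keys are rejected and an empty file yields the reference defaults.

## Reproducibility

Each run uses its own `numpy` generator seeded with `base_seed + run index`,
so runs are order-independent. Softmax is computed with max-subtraction,
ties in value maxima break to the smallest flat cell index, and the flat
cell index is `y * width + x` (0-based, y downward).

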