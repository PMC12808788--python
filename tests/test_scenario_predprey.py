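from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cuttlesim.gridworld import (
    AgentState,
    Cell,
    GridSpec,
    distance,
    region_cells,
    region_of,
)
from cuttlesim.memory_core import make_memory, softmax_probs
from cuttlesim.scenario_predprey import (
    CRAB,
    PREDATOR,
    SHRIMP,
    WHAT_ACTIONS,
    WHERE_ACTIONS,
    PredPreyConfig,
    actions_per_hour,
    hide_value,
    outcome_means,
    pp_place_objects,
    predator_step,
    run_pp,
    run_pp_hour,
    select_action_what,
    what_action_values,
    where_action_values,
)

GRID = GridSpec(12, 12)


def fresh_mem():
    return make_memory(3, 6, 144, width=12)


@pytest.fixture
def small_config():
    return PredPreyConfig(days=30, n_runs=3, base_seed=11)


class TestPlacement:
    def test_hour_0_crab_only(self):
        p = pp_place_objects(0, PredPreyConfig(), np.random.default_rng(0))
        assert p["shrimp"] is None and p["predator"] is None
        assert region_of(p["crab"]) == 8

    def test_hour_2_all_present(self):
        p = pp_place_objects(2, PredPreyConfig(), np.random.default_rng(0))
        assert region_of(p["shrimp"]) == 6
        assert region_of(p["crab"]) == 8
        assert p["predator"].x < 6

    def test_hour_4_predator_free(self):
        p = pp_place_objects(4, PredPreyConfig(), np.random.default_rng(0))
        assert p["shrimp"] is not None and p["crab"] is not None
        assert p["predator"] is None

    def test_schedule_full_day(self):
        cfg = PredPreyConfig()
        rng = np.random.default_rng(1)
        present = {
            h: {k: v is not None for k, v in pp_place_objects(h, cfg, rng).items()}
            for h in range(6)
        }
        assert [present[h]["shrimp"] for h in range(6)] == [False, False, True, True, True, True]
        assert all(present[h]["crab"] for h in range(6))
        assert [present[h]["predator"] for h in range(6)] == [False, True, True, True, False, False]


class TestActionValues:
    def test_fresh_memory_what_values(self):
        vals = what_action_values(fresh_mem(), 0, PredPreyConfig().params)
        assert vals == [0.0, 0.0, 0.0, 0.5]

    def test_hide_value_sign_convention(self):
        mem = fresh_mem()
        mem.values[PREDATOR, 2, 10] = -4.0
        mem.values[PREDATOR, 2, 11] = -2.0
        assert hide_value(mem, 2) == 6.0
        vals = what_action_values(mem, 2, PredPreyConfig().params)
        assert vals[2] == 6.0

    def test_fresh_memory_where_values(self):
        vals = where_action_values(fresh_mem(), 0, PredPreyConfig().params)
        assert vals == [0.0] * 9 + [0.5]
        with_hide = where_action_values(fresh_mem(), 0, PredPreyConfig().params, include_hide=True)
        assert with_hide == [0.0] * 9 + [0.5, 0.0]

    def test_region_value_signed_sum_oracle(self):
        mem = fresh_mem()
        cells = region_cells(6)
        c0, c1 = GRID.cell_index(cells[0]), GRID.cell_index(cells[1])
        mem.values[CRAB, 3, c0] = 1.0
        mem.values[PREDATOR, 3, c1] = -8.0
        vals = where_action_values(mem, 3, PredPreyConfig().params)
        # loop-sum oracle over objects and cells
        expected = sum(
            mem.values[obj, 3, GRID.cell_index(c)]
            for obj in (CRAB, SHRIMP, PREDATOR)
            for c in cells
        )
        assert vals[6] == expected == -7.0

    def test_what_choice_distribution(self):
        mem = fresh_mem()
        mem.values[PREDATOR, 1, 0] = -6.0
        params = PredPreyConfig().params
        p_expected = softmax_probs([0.0, 0.0, 6.0, 0.5], 1.0)
        rng = np.random.default_rng(0)
        n = 20_000
        counts = {a: 0 for a in WHAT_ACTIONS}
        for _ in range(n):
            counts[select_action_what(mem, 1, params, rng)] += 1
        freqs = np.array([counts[a] / n for a in WHAT_ACTIONS])
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert np.all(np.abs(freqs - p_expected) <= 3 * se + 1e-9)


class TestPredatorStep:
    def _pred(self, pos):
        return AgentState(Cell(*pos), vision_radius=4, role="predator")

    def test_hidden_prey_means_random_step(self):
        cuttle = AgentState(Cell(5, 5), vision_radius=2, hidden=True)
        pred = self._pred((6, 6))
        rng = np.random.default_rng(0)
        seen = {predator_step(pred, cuttle, GRID, rng) for _ in range(200)}
        assert len(seen) == 8  # all 8 neighbors show up: not locked onto the prey

    def test_visible_prey_in_range_is_chased(self):
        cuttle = AgentState(Cell(5, 5), vision_radius=2)
        pred = self._pred((8, 8))
        nxt = predator_step(pred, cuttle, GRID, np.random.default_rng(0))
        assert distance(nxt, cuttle.position) == distance(pred.position, cuttle.position) - 1

    def test_visible_prey_out_of_range_random(self):
        cuttle = AgentState(Cell(0, 0), vision_radius=2)
        pred = self._pred((5, 5))
        rng = np.random.default_rng(0)
        steps = {predator_step(pred, cuttle, GRID, rng) for _ in range(200)}
        assert len(steps) == 8


class TestRunPpHour:
    def test_hide_is_inert(self):
        """A hiding agent is never caught and never learns."""
        config = PredPreyConfig()
        mem = fresh_mem()
        mem.values[PREDATOR, 2, 0] = -100.0  # makes hide overwhelmingly likely
        before = mem.values.copy()
        for seed in range(30):
            rec = run_pp_hour(mem, 0, 0, 2, config, np.random.default_rng(seed))
            assert rec.action == "hide"
            assert rec.outcome == "none"
        np.testing.assert_array_equal(mem.values, before)

    def test_hunt_crab_trace(self):
        """Forced crab hunt at hour 0: reach region 8 and usually eat."""
        config = PredPreyConfig()
        outcomes = []
        for seed in range(30):
            mem = fresh_mem()
            decoy = GRID.cell_index(Cell(9, 9))
            mem.values[CRAB, 0, decoy] = 100.0
            rec = run_pp_hour(mem, 0, 0, 0, config, np.random.default_rng(seed))
            assert rec.action == "hunt_crab"
            outcomes.append(rec.outcome)
            if rec.outcome == "ate_crab":
                # first success writes alpha * reward = 0.1 at the crab's cell
                nz = np.nonzero(mem.values[CRAB, 0, :])[0]
                written = [c for c in nz if c != decoy]
                if written:
                    assert len(written) == 1
                    assert mem.values[CRAB, 0, written[0]] == pytest.approx(0.1)
                else:
                    # the crab happened to sit on the decoy cell itself
                    assert mem.values[CRAB, 0, decoy] == pytest.approx(100.0 + 0.1 * (1.0 - 100.0))
        assert outcomes.count("ate_crab") >= 25  # found within the budget w.h.p.

    def test_capture_writes_signed_penalty(self):
        config = replace(PredPreyConfig(), predator_hours=(0, 5))
        captured = 0
        for seed in range(60):
            mem = fresh_mem()
            rec = run_pp_hour(mem, 0, 0, 0, config, np.random.default_rng(seed))
            if rec.outcome == "eaten":
                captured += 1
                nz = np.nonzero(mem.values[PREDATOR, 0, :])[0]
                assert len(nz) == 1
                assert mem.values[PREDATOR, 0, nz[0]] == pytest.approx(-0.8)
        assert captured > 0

    def test_one_event_max(self, small_config):
        records, _ = run_pp(small_config)
        assert set(records["outcome"]) <= {"ate_crab", "ate_shrimp", "eaten", "none"}

    def test_predator_extinction_decays_danger(self):
        config = PredPreyConfig()
        mem = fresh_mem()
        start = GRID.cell_index(Cell(6, 0))
        mem.values[PREDATOR, 0, start] = -2.0
        # force a hunt toward region 8: path starts at (6,0), leaving the
        # remembered danger cell inside vision on the first step
        mem.values[CRAB, 0, GRID.cell_index(Cell(9, 9))] = 100.0
        run_pp_hour(mem, 0, 0, 0, config, np.random.default_rng(0))
        assert mem.values[PREDATOR, 0, start] == pytest.approx(-1.8)

    def test_predator_extinction_off(self):
        config = replace(PredPreyConfig(), predator_extinction=False)
        mem = fresh_mem()
        start = GRID.cell_index(Cell(6, 0))
        mem.values[PREDATOR, 0, start] = -2.0
        mem.values[CRAB, 0, GRID.cell_index(Cell(9, 9))] = 100.0
        run_pp_hour(mem, 0, 0, 0, config, np.random.default_rng(0))
        assert mem.values[PREDATOR, 0, start] == -2.0


class TestRunPp:
    def test_record_count(self, small_config):
        records, memories = run_pp(small_config)
        assert len(records) == small_config.n_runs * small_config.days * 6
        assert len(memories) == small_config.n_runs

    def test_determinism(self, small_config):
        rec1, mem1 = run_pp(small_config)
        rec2, mem2 = run_pp(small_config)
        pd.testing.assert_frame_equal(rec1, rec2)
        for a, b in zip(mem1, mem2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_eaten_only_during_predator_hours(self, small_config):
        records, _ = run_pp(small_config)
        eaten = records[records["outcome"] == "eaten"]
        assert eaten["hour"].isin([1, 2, 3]).all()

    def test_memory_sign_structure_and_bounds(self, small_config):
        for mode in ("what", "where"):
            _, memories = run_pp(replace(small_config, query_mode=mode))
            for mem in memories:
                assert np.all(mem.values[CRAB] >= 0)
                assert np.all(mem.values[SHRIMP] >= 0)
                assert np.all(mem.values[PREDATOR] <= 0)
                assert mem.values.min() >= -8.0
                assert mem.values.max() <= 4.0

    def test_mode_field_and_action_sets(self, small_config):
        rec_what, _ = run_pp(small_config)
        assert (rec_what["mode"] == "what").all()
        assert set(rec_what["action"]) <= set(WHAT_ACTIONS)
        rec_where, _ = run_pp(replace(small_config, query_mode="where"))
        assert (rec_where["mode"] == "where").all()
        assert set(rec_where["action"]) <= set(WHERE_ACTIONS)
        assert "hide" not in set(rec_where["action"])  # where_hide off by default

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            PredPreyConfig(query_mode="why")


class TestOutcomeMeans:
    def _records(self, counts_by_run):
        """counts_by_run: per-run number of ate_crab events on day 0."""
        rows = []
        for run, k in enumerate(counts_by_run):
            for hour in range(6):
                rows.append(
                    {"run": run, "day": 0, "hour": hour, "mode": "what",
                     "action": "roam", "outcome": "ate_crab" if hour < k else "none"}
                )
        return pd.DataFrame(rows)

    def test_constant_counts_zero_se(self):
        out = outcome_means(self._records([2, 2, 2, 2]))
        row = out[(out["day"] == 0) & (out["event"] == "ate_crab")].iloc[0]
        assert row["mean"] == 2.0
        assert row["se"] == 0.0

    def test_mean_and_se(self):
        out = outcome_means(self._records([1, 3]))
        row = out[(out["day"] == 0) & (out["event"] == "ate_crab")].iloc[0]
        assert row["mean"] == 2.0
        assert row["se"] == pytest.approx(np.std([1, 3], ddof=1) / np.sqrt(2))

    def test_daily_totals_bounded_by_hours(self, small_config):
        records, _ = run_pp(small_config)
        out = outcome_means(records)
        totals = out.groupby("day")["mean"].sum()
        assert (totals <= 6.0 + 1e-12).all()


class TestActionsPerHour:
    def test_all_roam_counts_equal_window(self):
        rows = [
            {"run": r, "day": d, "hour": h, "mode": "what", "action": "roam", "outcome": "none"}
            for r in range(2) for d in range(40) for h in range(6)
        ]
        out = actions_per_hour(pd.DataFrame(rows), "first-20")
        roam = out[out["action"] == "roam"]
        assert (roam["mean"] == 20.0).all()
        assert (roam["sd"] == 0.0).all()

    def test_counts_sum_to_window_length(self, small_config):
        records, _ = run_pp(small_config)
        for window in ("first-20", "last-20"):
            out = actions_per_hour(records, window)
            sums = out.groupby("hour")["mean"].sum()
            assert np.allclose(sums, 20.0)

    def test_reproducible(self, small_config):
        records, _ = run_pp(small_config)
        pd.testing.assert_frame_equal(
            actions_per_hour(records, "last-20"), actions_per_hour(records, "last-20")
        )

    def test_bad_window_rejected(self, small_config):
        records, _ = run_pp(small_config)
        with pytest.raises(ValueError):
            actions_per_hour(records, "middle-20")
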