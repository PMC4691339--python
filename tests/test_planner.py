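"""Planner tests: feasibility, scheduling vs brute force, value floors,
redundancy discounting, expected-value ranking and the time allocator
against exhaustive enumeration."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from curationkit.errors import DomainError
from curationkit.metrics import ValueScale, ValuedItemSet, display_percent, overhead_value_weighted
from curationkit.planner import (
    CurationProject,
    Item,
    allocate_time,
    apply_value_floor,
    curate,
    expected_value_rank,
    feasibility,
    mark_redundant,
    rank_and_schedule,
)
from conftest import small_project


def project_of(values, times=None, t_max=10.0, scale=None, **item_kwargs):
    scale = scale or ValueScale(0.0, 1.0)
    times = times or [1.0] * len(values)
    items = tuple(
        Item(id=f"i{k}", est_value=v, est_time=t, **item_kwargs)
        for k, (v, t) in enumerate(zip(values, times))
    )
    return CurationProject("p", items, t_max=t_max, scale=scale)


class TestFeasibility:
    def test_speed_based_slack(self):
        p = replace(project_of([0.5] * 15), speed=2.0)
        f = feasibility(p)
        assert f.sufficient and f.slack == pytest.approx(5.0) and f.basis == "items"

    def test_boundary_is_sufficient(self):
        p = replace(project_of([0.5] * 20), speed=2.0)
        assert feasibility(p).sufficient

    def test_insufficient(self):
        p = replace(project_of([0.5] * 100, t_max=1.0), speed=1.0)
        f = feasibility(p)
        assert not f.sufficient and f.slack == pytest.approx(-99.0)

    def test_time_based_when_no_speed(self):
        p = project_of([0.5, 0.5], times=[3.0, 4.0], t_max=10.0)
        f = feasibility(p)
        assert f.sufficient and f.slack == pytest.approx(3.0) and f.basis == "time"


class TestRankAndSchedule:
    def test_highest_value_first(self):
        p = project_of([0.3, 0.1, 0.2], t_max=2.0)
        s = rank_and_schedule(p)
        assert s.curated == ("i0", "i2")
        assert s.metrics["est_value_sum"] == pytest.approx(0.5)

    def test_everything_fits(self):
        p = project_of([0.3, 0.1, 0.2], t_max=100.0)
        assert len(rank_and_schedule(p).curated) == 3

    def test_nothing_fits(self):
        p = project_of([0.5], times=[5.0], t_max=1.0)
        s = rank_and_schedule(p)
        assert s.curated == () and s.leftover == ("i0",)

    def test_skips_oversized_item_instead_of_stopping(self):
        # best item does not fit; the next two do
        p = project_of([0.9, 0.5, 0.4], times=[5.0, 1.0, 1.0], t_max=2.0)
        s = rank_and_schedule(p)
        assert s.curated == ("i1", "i2")

    def test_ties_prefer_shorter_then_id(self):
        p = project_of([0.5, 0.5, 0.5], times=[2.0, 1.0, 1.0], t_max=10.0)
        assert rank_and_schedule(p).curated == ("i1", "i2", "i0")

    def test_optimal_value_with_uniform_times(self):
        """Greedy value ranking with unit times maximizes the curated value
        sum; brute force over all feasible subsets confirms it."""
        rng = np.random.default_rng(40)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            values = rng.uniform(0, 1, n).tolist()
            budget = float(rng.integers(1, n + 1))
            p = project_of(values, t_max=budget)
            s = rank_and_schedule(p)
            best = 0.0
            for r in range(len(values) + 1):
                for combo in itertools.combinations(range(n), r):
                    if len(combo) <= budget:
                        best = max(best, sum(values[i] for i in combo))
            assert s.metrics["est_value_sum"] == pytest.approx(best)

    def test_budget_never_exceeded(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            p = project_of(
                rng.uniform(0, 1, n).tolist(),
                times=rng.uniform(0.1, 3.0, n).tolist(),
                t_max=float(rng.uniform(0.5, 10)),
            )
            s = rank_and_schedule(p)
            assert s.total_time <= p.t_max + 1e-12
            assert set(s.curated) | set(s.leftover) == {it.id for it in p.items}
            assert not set(s.curated) & set(s.leftover)


class TestValueFloor:
    def test_floor_at_minimum_changes_nothing(self):
        p = project_of([0.2, 0.6, 0.9])
        assert apply_value_floor(p, 0.0).n == 3

    def test_floor_above_scale_rejected(self):
        p = project_of([0.2, 0.6, 0.9])
        with pytest.raises(DomainError):
            apply_value_floor(p, 1.1)

    def test_floor_removes_low_value_items(self):
        p = project_of([0.2, 0.6, 0.9])
        filtered = apply_value_floor(p, 0.5)
        assert [it.id for it in filtered.items] == ["i1", "i2"]

    def test_commutes_with_scheduling(self):
        """Floor-then-schedule equals schedule-then-drop when every curated
        item clears the floor anyway."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            p = project_of(rng.uniform(0, 1, n).tolist(), t_max=float(n // 2))
            floor = float(rng.uniform(0, 0.5))
            try:
                floored_first = rank_and_schedule(apply_value_floor(p, floor))
            except DomainError:
                continue  # floor removed everything
            sched = rank_and_schedule(p)
            by_id = {it.id: it for it in p.items}
            curated_vals = [by_id[i].est_value for i in sched.curated]
            if all(v >= floor for v in curated_vals):
                kept = tuple(i for i in sched.curated if by_id[i].est_value >= floor)
                assert floored_first.curated == kept


class TestMarkRedundant:
    def test_disjoint_keys_unchanged(self):
        p = project_of([0.5, 0.6])
        assert mark_redundant(p, {"other"}) == p

    def test_in_project_duplicate_devalued(self):
        items = (
            Item(id="a", est_value=0.8, est_time=1.0, duplicate_key="k"),
            Item(id="b", est_value=0.7, est_time=1.0, duplicate_key="k"),
        )
        p = CurationProject("p", items, t_max=5.0, scale=ValueScale(0.0, 1.0))
        marked = mark_redundant(p)
        assert marked.items[0].est_value == 0.8  # first occurrence kept
        assert marked.items[1].est_value == 0.0 and marked.items[1].redundant

    def test_prior_key_devalues_unique_item(self):
        p = project_of([0.9])
        marked = mark_redundant(p, {"i0"})
        assert marked.items[0].est_value == 0.0

    def test_idempotent(self):
        items = tuple(
            Item(id=f"x{k}", est_value=0.5, est_time=1.0, duplicate_key="same")
            for k in range(4)
        )
        p = CurationProject("p", items, t_max=5.0, scale=ValueScale(0.0, 1.0))
        once = mark_redundant(p, {"z"})
        assert mark_redundant(once, {"z"}) == once


class TestExpectedValueRank:
    def test_certain_items_rank_by_value(self):
        items = [
            Item(id=f"i{k}", est_value=v, est_time=1.0, p_tp=1.0)
            for k, v in enumerate([0.2, 0.9, 0.5])
        ]
        ranked = expected_value_rank(items, ValueScale(0.0, 1.0))
        assert [it.id for it in ranked] == ["i1", "i2", "i0"]

    def test_probability_discounts_value(self):
        risky = Item(id="risky", est_value=1.0, est_time=1.0, p_tp=0.5)
        safe = Item(id="safe", est_value=0.6, est_time=1.0, p_tp=1.0)
        ranked = expected_value_rank([risky, safe], ValueScale(0.0, 1.0))
        assert ranked[0].id == "safe"  # 0.6 > 0.5

    def test_hopeless_items_tie_stably(self):
        items = [
            Item(id=f"i{k}", est_value=v, est_time=1.0, p_tp=0.0)
            for k, v in enumerate([0.3, 0.9, 0.1])
        ]
        ranked = expected_value_rank(items, ValueScale(0.0, 1.0))
        assert [it.id for it in ranked] == ["i0", "i1", "i2"]

    def test_missing_probability_names_items(self):
        items = [Item(id="ok", est_value=0.5, est_time=1.0, p_tp=0.5),
                 Item(id="nope", est_value=0.5, est_time=1.0)]
        with pytest.raises(DomainError, match="nope"):
            expected_value_rank(items, ValueScale(0.0, 1.0))


class TestAllocateTime:
    def test_single_project_gets_everything(self):
        rng = np.random.default_rng(43)
        p = small_project(rng, "solo", 6)
        plan = allocate_time([p], t_max_total=4.0, quantum=1.0)
        assert plan.budgets == {"solo": 4.0}

    def test_symmetric_split_among_optima(self):
        rng = np.random.default_rng(44)
        vals = rng.uniform(0.2, 1.0, 6).tolist()
        a = project_of(vals, t_max=6.0)
        b = CurationProject("q", tuple(replace(it, id=f"q{it.id}") for it in a.items),
                            t_max=6.0, scale=a.scale)
        plan = allocate_time([a, b], t_max_total=6.0, quantum=1.0)
        sym = sum(
            overhead_value_weighted(
                ValuedItemSet(values=tuple(sorted(vals, reverse=True)[:3])), a.scale
            )
            for _ in range(2)
        )
        assert plan.objective <= sym + 1e-12

    def test_budget_conserved_exactly(self):
        rng = np.random.default_rng(45)
        for method in ("exhaustive", "greedy"):
            projects = [small_project(rng, f"p{j}", int(rng.integers(2, 8))) for j in range(3)]
            plan = allocate_time(projects, t_max_total=9.0, quantum=1.0, method=method)
            assert sum(plan.budgets.values()) == pytest.approx(9.0, abs=1e-12)

    def test_greedy_matches_exhaustive_on_small_instances(self):
        """Greedy + pairwise exchange reaches the enumerated optimum on
        instances small enough to enumerate."""
        rng = np.random.default_rng(46)
        for trial in range(15):
            k = int(rng.integers(2, 4))
            projects = [small_project(rng, f"p{j}", int(rng.integers(2, 7))) for j in range(k)]
            quanta = int(rng.integers(3, 13))
            ex = allocate_time(projects, float(quanta), 1.0, method="exhaustive")
            gr = allocate_time(projects, float(quanta), 1.0, method="greedy")
            assert gr.objective == pytest.approx(ex.objective, abs=1e-9)

    def test_beats_or_matches_equal_split(self):
        rng = np.random.default_rng(47)
        for _ in range(10):
            projects = [small_project(rng, f"p{j}", int(rng.integers(2, 9))) for j in range(3)]
            plan = allocate_time(projects, 6.0, 1.0)
            from curationkit.planner import _project_overhead
            equal = sum(_project_overhead(p, 2.0, "value") for p in projects)
            assert plan.objective <= equal + 1e-12

    def test_starved_project_pays_worst_case(self):
        """Starving a project costs its worst single-item overhead (here 9),
        so the optimizer funds it rather than dumping all budget elsewhere."""
        scale = ValueScale(0.0, 1.0)
        mixed = CurationProject(
            "mixed",
            (Item(id="m0", est_value=0.9, est_time=1.0),
             Item(id="m1", est_value=0.1, est_time=1.0)),
            t_max=2.0, scale=scale,
        )
        rich = CurationProject(
            "rich", (Item(id="r0", est_value=1.0, est_time=1.0),), t_max=1.0, scale=scale
        )
        plan = allocate_time([mixed, rich], 2.0, 1.0)
        assert plan.budgets == {"mixed": 1.0, "rich": 1.0}
        assert plan.objective == pytest.approx(0.1 / 0.9)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(48)
        p = small_project(rng, "p", 3)
        with pytest.raises(DomainError):
            allocate_time([], 4.0, 1.0)
        with pytest.raises(DomainError):
            allocate_time([p], 4.0, 8.0)
        with pytest.raises(DomainError):
            allocate_time([p], 4.0, 3.0)  # does not divide evenly


class TestCurate:
    def test_all_tp_schedule_has_zero_overhead(self):
        p = project_of([0.9, 0.8], gold_label="TP", true_value=1.0)
        s = rank_and_schedule(p)
        result = curate(p, s)
        assert result["overhead_simple"] == 0.0

    def test_usecase_counts_reproduce_printed_overheads(self):
        """11 TPs at 2 time units and 7 FPs at 1: the filtered-set
        time-weighted overhead renders as 19%, the equal-time first
        approximation as 39%."""
        items = tuple(
            Item(id=f"tp{k}", est_value=1.0, est_time=2.0, gold_label="TP", true_value=1.0)
            for k in range(11)
        ) + tuple(
            Item(id=f"fp{k}", est_value=0.0, est_time=1.0, gold_label="FP", true_value=0.0)
            for k in range(7)
        )
        p = CurationProject("il32-il10", items, t_max=29.0, scale=ValueScale(0.0, 1.0))
        s = rank_and_schedule(p)
        assert len(s.curated) == 18
        result = curate(p, s)
        assert display_percent(result["overhead_time_weighted_filtered"]) == 19
        assert result["precision"] == pytest.approx(11 / 18)

    def test_realized_precision_definition(self):
        p = project_of([0.9, 0.8, 0.7], t_max=3.0)
        items = tuple(
            replace(it, gold_label="TP" if k < 2 else "FP") for k, it in enumerate(p.items)
        )
        p = replace(p, items=items)
        result = curate(p, rank_and_schedule(p))
        assert result["precision"] == pytest.approx(2 / 3)

    def test_missing_ground_truth_reports_requirements(self):
        p = project_of([0.9, 0.8])
        with pytest.raises(DomainError, match="gold labels or true values"):
            curate(p, rank_and_schedule(p))

    def test_estimation_error_reported(self):
        items = (
            Item(id="a", est_value=0.8, est_time=1.0, true_value=1.0, gold_label="TP"),
            Item(id="b", est_value=0.4, est_time=1.0, true_value=0.0, gold_label="FP"),
        )
        p = CurationProject("p", items, t_max=5.0, scale=ValueScale(0.0, 1.0))
        result = curate(p, rank_and_schedule(p))
        assert result["value_estimation_mae"] == pytest.approx(0.3)
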