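"""Planning curation work under fixed, insufficient resources.

A curation project holds ``n`` candidate items, a time budget ``T_max`` and
an average curation speed ``v`` (items per unit time).  Resources are
*sufficient* when ``v * T_max >= n``; otherwise not everything can be
curated and the work must be triaged.  The planner implements the standard
devices for that:

* **value-ranked scheduling** — curate items in descending order of
  estimated value until time runs out, which maximizes the value created
  without needing to estimate ``v`` beforehand;
* **value floors** — drop items below a minimum acceptable value
  ``w_floor`` so no budget is spent on near-worthless items;
* **redundancy discounting** — an item already curated (in this project or
  a previous one) is revalued to ``w_min``, the value of a false positive;
* **expected-value ranking** — when TP status is uncertain, rank by
  ``p * w + (1 - p) * w_min``, the expectation with FPs valued at the floor;
* **multi-project allocation** — split a global budget across competing
  projects so the summed overheads are minimized.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, NamedTuple, Sequence

from .errors import CurationError, DomainError, InfiniteOverheadError, UndefinedMetricError
from .metrics import (
    ConfusionCounts,
    TimeModel,
    ValueScale,
    ValuedItemSet,
    overhead_probability_adjusted,
    overhead_simple,
    overhead_time_weighted,
    overhead_value_weighted,
    overhead_value_time_weighted,
    precision,
)

__all__ = [
    "Item",
    "CurationProject",
    "Schedule",
    "AllocationPlan",
    "Feasibility",
    "feasibility",
    "rank_and_schedule",
    "apply_value_floor",
    "mark_redundant",
    "expected_value_rank",
    "allocate_time",
    "curate",
]

#: finite stand-in for an unbounded overhead inside the allocator's
#: objective, so starving a project is never mistaken for solving it
WORST_CASE_OVERHEAD = 1e9


@dataclass(frozen=True)
class Item:
    """One curable unit: a document, an interaction, an evidence record."""

    id: str
    est_value: float
    est_time: float
    duplicate_key: str | None = None
    true_value: float | None = None
    p_tp: float | None = None
    gold_label: Literal["TP", "FP"] | None = None
    redundant: bool = False

    def __post_init__(self) -> None:
        if self.est_time <= 0:
            raise DomainError(f"item {self.id}: est_time must be > 0, got {self.est_time}")
        if self.p_tp is not None and not 0 <= self.p_tp <= 1:
            raise DomainError(f"item {self.id}: p_tp must be in [0, 1], got {self.p_tp}")
        if self.gold_label is not None and self.gold_label not in ("TP", "FP"):
            raise DomainError(f"item {self.id}: gold_label must be 'TP' or 'FP'")
        if self.duplicate_key is None:
            object.__setattr__(self, "duplicate_key", self.id)


@dataclass(frozen=True)
class CurationProject:
    """An item set plus the resources available to curate it."""

    name: str
    items: tuple[Item, ...]
    t_max: float
    scale: ValueScale
    speed: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise DomainError(f"project {self.name}: items must be non-empty")
        if self.t_max <= 0:
            raise DomainError(f"project {self.name}: t_max must be > 0, got {self.t_max}")
        if self.speed is not None and self.speed <= 0:
            raise DomainError(f"project {self.name}: speed must be > 0")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"project {self.name}: duplicate item ids {dupes}")

    @property
    def n(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class Schedule:
    """The outcome of scheduling: who gets curated, in what order."""

    curated: tuple[str, ...]
    leftover: tuple[str, ...]
    total_time: float
    metrics: dict


class Feasibility(NamedTuple):
    sufficient: bool
    slack: float
    basis: Literal["items", "time"]


def feasibility(project: CurationProject) -> Feasibility:
    """Are the resources sufficient to curate everything?

    With a known speed the criterion is ``v * T_max >= n`` and the slack is
    in items; otherwise per-item time estimates are summed and the slack is
    in time units.  The boundary counts as sufficient.
    """
    if project.speed is not None:
        slack = project.speed * project.t_max - project.n
        return Feasibility(sufficient=slack >= 0, slack=slack, basis="items")
    slack = project.t_max - sum(it.est_time for it in project.items)
    return Feasibility(sufficient=slack >= 0, slack=slack, basis="time")


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------


def _rank_key(it: Item) -> tuple:
    # descending value; ties -> shorter first (more items per budget), then id
    return (-it.est_value, it.est_time, it.id)


def rank_and_schedule(project: CurationProject) -> Schedule:
    """Curate in descending order of estimated value until T_max.

    An item that does not fit the remaining budget is skipped and the next
    one tried, rather than stopping outright.  Realized metrics are
    attached when ground truth (gold labels / true values) is available.
    """
    ordered = sorted(project.items, key=_rank_key)
    curated: list[Item] = []
    leftover: list[Item] = []
    remaining = project.t_max
    for it in ordered:
        if it.est_time <= remaining:
            curated.append(it)
            remaining -= it.est_time
        else:
            leftover.append(it)
    total = project.t_max - remaining
    metrics: dict = {
        "n_curated": len(curated),
        "est_value_sum": sum(it.est_value for it in curated),
    }
    if curated:
        metrics.update(_realized_metrics(curated, project.scale, total))
    return Schedule(
        curated=tuple(it.id for it in curated),
        leftover=tuple(it.id for it in leftover),
        total_time=total,
        metrics=metrics,
    )


def _realized_metrics(curated: Sequence[Item], scale: ValueScale, total_time: float) -> dict:
    out: dict = {}
    labels = [it.gold_label for it in curated]
    if all(l is not None for l in labels):
        tp = sum(1 for l in labels if l == "TP")
        fp = len(labels) - tp
        counts = ConfusionCounts(tp=tp, fp=fp)
        out["tp"] = tp
        out["fp"] = fp
        out["precision"] = precision(counts)
        try:
            out["overhead_simple"] = overhead_simple(counts)
        except InfiniteOverheadError:
            out["overhead_infinite"] = True
        tp_times = [it.est_time for it in curated if it.gold_label == "TP"]
        fp_times = [it.est_time for it in curated if it.gold_label == "FP"]
        if tp_times:
            tm = TimeModel(
                t_tp=sum(tp_times) / len(tp_times),
                t_fp=sum(fp_times) / len(fp_times) if fp_times else 0.0,
            )
            out["overhead_time_weighted"] = overhead_time_weighted(counts, tm, "tp")
            out["overhead_time_weighted_filtered"] = overhead_time_weighted(counts, tm, "filtered")
            if total_time > 0:
                out["v_tp"] = tp / total_time
    truths = [it.true_value for it in curated]
    if all(w is not None for w in truths):
        out["true_value_sum"] = sum(truths)
        vis = ValuedItemSet(values=tuple(truths), times=tuple(it.est_time for it in curated))
        try:
            out["overhead_value_weighted"] = overhead_value_weighted(vis, scale)
            out["overhead_value_time_weighted"] = overhead_value_time_weighted(vis, scale)
        except InfiniteOverheadError:
            out["overhead_infinite"] = True
        out["value_estimation_mae"] = sum(
            abs(it.est_value - it.true_value) for it in curated
        ) / len(curated)
    return out


def apply_value_floor(project: CurationProject, w_floor: float) -> CurationProject:
    """Drop items whose estimated value is below the floor."""
    if not project.scale.w_min <= w_floor <= project.scale.w_max:
        raise DomainError(
            f"value floor {w_floor} outside scale "
            f"[{project.scale.w_min}, {project.scale.w_max}]"
        )
    kept = tuple(it for it in project.items if it.est_value >= w_floor)
    if not kept:
        raise DomainError(
            f"project {project.name}: floor {w_floor} removes every item"
        )
    return replace(project, items=kept)


def mark_redundant(
    project: CurationProject, prior_keys: Iterable[str] = ()
) -> CurationProject:
    """Revalue redundant items to w_min, the value of a false positive.

    An item is redundant if its ``duplicate_key`` was curated in a prior
    project (``prior_keys``) or repeats a key already seen within this
    project (the first occurrence is kept).  Idempotent.
    """
    prior = set(prior_keys)
    seen: set[str] = set()
    items: list[Item] = []
    for it in project.items:
        dup = it.duplicate_key in prior or it.duplicate_key in seen
        seen.add(it.duplicate_key)
        if dup and not it.redundant:
            items.append(replace(it, est_value=project.scale.w_min, redundant=True))
        else:
            items.append(it)
    return replace(project, items=tuple(items))


def expected_value_rank(items: Sequence[Item], scale: ValueScale) -> list[Item]:
    """Order by expected value p * w + (1 - p) * w_min, descending.

    FPs are valued at the scale floor, so an item's expectation blends its
    estimated value with the floor by its TP probability.  Stable for ties.
    """
    missing = [it.id for it in items if it.p_tp is None]
    if missing:
        raise DomainError(f"expected-value ranking requires p_tp; missing for: {missing}")

    def ev(it: Item) -> float:
        return it.p_tp * it.est_value + (1.0 - it.p_tp) * scale.w_min

    return sorted(items, key=lambda it: -ev(it))


# ---------------------------------------------------------------------------
# multi-project time allocation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AllocationPlan:
    """Per-project budgets summing to the global T_max, with overheads."""

    budgets: dict
    overheads: dict
    objective: float
    quantum: float
    method: str

    def __post_init__(self) -> None:
        for name, b in self.budgets.items():
            if b < 0:
                raise DomainError(f"negative budget for project {name}")


OverheadKind = Literal["value", "probability", "simple"]


def _project_overhead(
    project: CurationProject, budget: float, kind: OverheadKind
) -> float:
    """Overhead of what rank_and_schedule would curate under ``budget``.

    An empty schedule contributes the overhead of the project's single
    least valuable item (the worst single-item outcome), so the optimizer
    cannot "solve" a project by starving it.
    """
    if budget <= 0:
        curated: list[Item] = []
    else:
        sched = rank_and_schedule(replace(project, t_max=budget))
        by_id = {it.id: it for it in project.items}
        curated = [by_id[i] for i in sched.curated]
    if not curated:
        worst = min(project.items, key=lambda it: it.est_value)
        curated = [worst]
    try:
        if kind == "value":
            vis = ValuedItemSet(values=tuple(it.est_value for it in curated))
            return overhead_value_weighted(vis, project.scale)
        if kind == "probability":
            missing = [it.id for it in curated if it.p_tp is None]
            if missing:
                raise DomainError(f"probability overhead requires p_tp; missing: {missing}")
            vis = ValuedItemSet(
                values=tuple(it.est_value for it in curated),
                times=tuple(it.est_time for it in curated),
                probs=tuple(it.p_tp for it in curated),
            )
            return overhead_probability_adjusted(vis, project.scale)
        if kind == "simple":
            labels = [it.gold_label for it in curated]
            if any(l is None for l in labels):
                raise DomainError("simple overhead requires gold labels on all items")
            tp = sum(1 for l in labels if l == "TP")
            return overhead_simple(ConfusionCounts(tp=tp, fp=len(labels) - tp))
        raise DomainError(f"unknown overhead kind {kind!r}")
    except InfiniteOverheadError:
        return WORST_CASE_OVERHEAD


def allocate_time(
    projects: Sequence[CurationProject],
    t_max_total: float,
    quantum: float,
    kind: OverheadKind = "value",
    method: Literal["auto", "exhaustive", "greedy"] = "auto",
    exhaustive_limit: int = 10_000,
) -> AllocationPlan:
    """Split a global time budget across projects to minimize summed overhead.

    Time is discretized into quanta.  When the composition space (ways to
    split Q quanta over k projects) is small the optimum is found by
    exhaustive enumeration; otherwise quanta are assigned greedily by
    marginal improvement and polished by pairwise exchange.  Budgets always
    sum exactly to ``t_max_total``.
    """
    if not projects:
        raise DomainError("allocate_time requires at least one project")
    if t_max_total <= 0:
        raise DomainError(f"t_max_total must be > 0, got {t_max_total}")
    if quantum <= 0 or quantum > t_max_total:
        raise DomainError(
            f"quantum must be in (0, t_max_total]; got {quantum} with total {t_max_total}"
        )
    n_quanta = round(t_max_total / quantum)
    if abs(n_quanta * quantum - t_max_total) > 1e-9 * t_max_total:
        raise DomainError(
            f"quantum {quantum} does not evenly divide t_max_total {t_max_total}"
        )
    if n_quanta > 100_000:
        raise DomainError(f"{n_quanta} quanta exceed the 1e5 limit; use a coarser quantum")

    names = [p.name for p in projects]
    if len(set(names)) != len(names):
        raise DomainError(f"project names must be unique: {names}")

    cache: dict[tuple[int, int], float] = {}

    def obj(j: int, q: int) -> float:
        key = (j, q)
        if key not in cache:
            cache[key] = _project_overhead(projects[j], q * quantum, kind)
        return cache[key]

    k = len(projects)
    n_states = math.comb(n_quanta + k - 1, k - 1)
    if method == "auto":
        method = "exhaustive" if n_states <= exhaustive_limit else "greedy"

    if method == "exhaustive":
        best: tuple[float, tuple[int, ...]] | None = None
        for cuts in itertools.combinations(range(n_quanta + k - 1), k - 1):
            alloc = _cuts_to_alloc(cuts, n_quanta, k)
            total = sum(obj(j, q) for j, q in enumerate(alloc))
            if best is None or total < best[0]:
                best = (total, alloc)
        objective, alloc = best
    else:
        alloc_list = [0] * k
        for _ in range(n_quanta):
            gains = [obj(j, alloc_list[j]) - obj(j, alloc_list[j] + 1) for j in range(k)]
            j_best = max(range(k), key=lambda j: gains[j])
            alloc_list[j_best] += 1
        # pairwise exchange: move any number of quanta between two projects
        # while doing so lowers the summed overhead
        improved = True
        guard = 0
        while improved and guard < 10 * n_quanta * k:
            improved = False
            guard += 1
            best_delta, best_move = -1e-12, None
            for j in range(k):
                for l in range(k):
                    if l == j:
                        continue
                    for t in range(1, alloc_list[j] + 1):
                        delta = (
                            obj(j, alloc_list[j] - t)
                            + obj(l, alloc_list[l] + t)
                            - obj(j, alloc_list[j])
                            - obj(l, alloc_list[l])
                        )
                        if delta < best_delta:
                            best_delta, best_move = delta, (j, l, t)
            if best_move is not None:
                j, l, t = best_move
                alloc_list[j] -= t
                alloc_list[l] += t
                improved = True
        alloc = tuple(alloc_list)
        objective = sum(obj(j, q) for j, q in enumerate(alloc))

    budgets = {names[j]: alloc[j] * quantum for j in range(k)}
    overheads = {names[j]: obj(j, alloc[j]) for j in range(k)}
    return AllocationPlan(
        budgets=budgets,
        overheads=overheads,
        objective=objective,
        quantum=quantum,
        method=method,
    )


def _cuts_to_alloc(cuts: tuple[int, ...], n_quanta: int, k: int) -> tuple[int, ...]:
    # stars-and-bars: cut positions among n_quanta + k - 1 slots
    prev = -1
    alloc = []
    for c in cuts:
        alloc.append(c - prev - 1)
        prev = c
    alloc.append(n_quanta + k - 1 - prev - 1)
    return tuple(alloc)


# ---------------------------------------------------------------------------
# retrospective evaluation
# ---------------------------------------------------------------------------


def curate(project: CurationProject, schedule: Schedule) -> dict:
    """Evaluate a schedule against ground truth.

    Recomputes precision, the overhead variants, value created and the TP
    production rate on the realized (gold-labelled) outcomes, and reports
    the mean absolute error of the value estimates.  Items' ``est_time`` is
    taken as the realized curation time.
    """
    by_id = {it.id: it for it in project.items}
    unknown = [i for i in schedule.curated if i not in by_id]
    if unknown:
        raise DomainError(f"schedule names items not in project: {unknown}")
    curated = [by_id[i] for i in schedule.curated]
    if not curated:
        raise DomainError("cannot evaluate an empty schedule")
    has_labels = all(it.gold_label is not None for it in curated)
    has_truth = all(it.true_value is not None for it in curated)
    if not (has_labels or has_truth):
        missing = [it.id for it in curated if it.gold_label is None and it.true_value is None]
        raise DomainError(
            "evaluation requires gold labels or true values on every curated "
            f"item; missing for: {missing[:10]}"
        )
    return _realized_metrics(curated, project.scale, schedule.total_time)
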