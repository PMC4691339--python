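"""Filtering-strategy toolboxes in precision-recall space.

A curation team rarely keeps a single document filter.  The "multiple
strategies" approach maintains a toolbox of filters with different
precision-recall trade-offs — a high-precision filter for scarce budgets, a
high-recall one for exhaustive projects — and picks per project.  Two
questions follow:

* is a *new* strategy worth adding?  It is not if some existing strategy
  weakly dominates it, i.e. it falls inside the **area covered** (AC): the
  region of the unit square weakly dominated by the toolbox, whose area is
  the union of the origin-anchored rectangles ``[0, recall] x [0,
  precision]`` of the frontier points (adjustable curves contribute the
  region under their curve);
* which strategy suits *this* project's budget?  Feasibility means the
  expected curation time of the filter's output fits in T_max after paying
  the filter's own application cost.

Adjustable strategies trace a monotone precision-recall curve: raising
recall grows the output set, adding both TPs and FPs, so precision falls
and overhead rises monotonically along the curve.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .errors import CurationError, DomainError, RangeError
from .metrics import TimeModel, overhead_from_precision

__all__ = [
    "StrategyPoint",
    "AdjustableStrategy",
    "Toolbox",
    "dominates",
    "pareto_frontier",
    "area_covered",
    "is_inferior",
    "operating_point",
    "expected_output_size",
    "OutputSize",
    "select_strategy",
    "StrategyOption",
    "SelectionResult",
    "NoFeasibleStrategyError",
]


@dataclass(frozen=True)
class StrategyPoint:
    """A fixed (recall, precision) operating point with an application cost."""

    name: str
    precision: float
    recall: float
    application_cost: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.precision <= 1:
            raise DomainError(f"{self.name}: precision must be in (0, 1], got {self.precision}")
        if not 0 <= self.recall <= 1:
            raise DomainError(f"{self.name}: recall must be in [0, 1], got {self.recall}")
        if self.application_cost < 0:
            raise DomainError(f"{self.name}: application_cost must be >= 0")

    @property
    def overhead(self) -> float:
        return overhead_from_precision(self.precision)


@dataclass(frozen=True)
class AdjustableStrategy:
    """A tunable filter tracing a monotone precision-recall curve.

    ``curve`` is an ordered list of (recall, precision) knots with recall
    strictly increasing and precision non-increasing; operating points
    between knots are linearly interpolated.
    """

    name: str
    curve: tuple[tuple[float, float], ...]
    application_cost: float = 0.0

    def __post_init__(self) -> None:
        curve = tuple((float(r), float(p)) for r, p in self.curve)
        object.__setattr__(self, "curve", curve)
        if len(curve) < 2:
            raise DomainError(f"{self.name}: an adjustable curve needs at least 2 knots")
        for i, (r, p) in enumerate(curve):
            if not 0 <= r <= 1:
                raise DomainError(f"{self.name}: knot {i} recall {r} outside [0, 1]")
            if not 0 < p <= 1:
                raise DomainError(f"{self.name}: knot {i} precision {p} outside (0, 1]")
        recalls = [r for r, _ in curve]
        precisions = [p for _, p in curve]
        if any(b <= a for a, b in zip(recalls, recalls[1:])):
            raise DomainError(f"{self.name}: knot recalls must be strictly increasing")
        if any(b > a for a, b in zip(precisions, precisions[1:])):
            raise DomainError(
                f"{self.name}: precisions must be non-increasing along the curve"
            )
        if self.application_cost < 0:
            raise DomainError(f"{self.name}: application_cost must be >= 0")

    @property
    def recall_range(self) -> tuple[float, float]:
        return self.curve[0][0], self.curve[-1][0]

    def precision_at(self, recall: float) -> float:
        lo, hi = self.recall_range
        if not lo <= recall <= hi:
            raise RangeError(
                f"{self.name}: recall {recall} outside achievable range [{lo}, {hi}]"
            )
        recalls = [r for r, _ in self.curve]
        i = bisect_right(recalls, recall) - 1
        if i == len(self.curve) - 1:
            return self.curve[-1][1]
        (r0, p0), (r1, p1) = self.curve[i], self.curve[i + 1]
        t = (recall - r0) / (r1 - r0)
        return p0 + t * (p1 - p0)

    def knot_points(self) -> list[StrategyPoint]:
        return [
            StrategyPoint(f"{self.name}@R={r:g}", p, r, self.application_cost)
            for r, p in self.curve
        ]


@dataclass(frozen=True)
class Toolbox:
    """A named collection of fixed and adjustable filtering strategies."""

    fixed: tuple[StrategyPoint, ...] = ()
    adjustable: tuple[AdjustableStrategy, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "adjustable", tuple(self.adjustable))
        names = [s.name for s in self.fixed] + [s.name for s in self.adjustable]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DomainError(f"strategy names must be unique; duplicated: {dupes}")

    def __len__(self) -> int:
        return len(self.fixed) + len(self.adjustable)

    def all_points(self) -> list[StrategyPoint]:
        """Fixed points plus every adjustable strategy's knot points."""
        pts = list(self.fixed)
        for s in self.adjustable:
            pts.extend(s.knot_points())
        return pts


# ---------------------------------------------------------------------------
# dominance and the Pareto frontier
# ---------------------------------------------------------------------------


def dominates(a: StrategyPoint, b: StrategyPoint) -> bool:
    """True iff ``a`` is at least as good as ``b`` on both axes and strictly
    better on at least one; equal points do not dominate each other."""
    return (
        a.precision >= b.precision
        and a.recall >= b.recall
        and (a.precision > b.precision or a.recall > b.recall)
    )


def pareto_frontier(tb: Toolbox) -> list[StrategyPoint]:
    """The maximal (non-dominated) operating points, sorted by recall.

    Adjustable strategies contribute their knot points.  Exact duplicates
    are collapsed to a single representative.
    """
    points = tb.all_points()
    if not points:
        raise DomainError("cannot take the frontier of an empty toolbox")
    frontier: list[StrategyPoint] = []
    seen: set[tuple[float, float]] = set()
    for p in points:
        if any(dominates(q, p) for q in points):
            continue
        if (p.recall, p.precision) in seen:
            continue
        seen.add((p.recall, p.precision))
        frontier.append(p)
    frontier.sort(key=lambda s: (s.recall, s.precision))
    return frontier


# ---------------------------------------------------------------------------
# area covered
# ---------------------------------------------------------------------------
#
# The covered region is { (R, P) : some achievable operating point (r, p)
# has r >= R and p >= P }.  Its upper boundary as a function of recall is
# the pointwise max of one "profile" per strategy:
#   fixed (r_i, p_i)      ->  p_i on [0, r_i]
#   adjustable curve      ->  p(r_lo) on [0, r_lo], then the curve itself
# Each profile is a set of linear segments, so the boundary is the upper
# envelope of segments and the area is integrated exactly, piece by piece.

class _Segment(NamedTuple):
    x0: float
    x1: float
    y0: float
    y1: float

    def value_at(self, x: float) -> float:
        if self.x1 == self.x0:
            return max(self.y0, self.y1)
        t = (x - self.x0) / (self.x1 - self.x0)
        return self.y0 + t * (self.y1 - self.y0)


def _coverage_segments(tb: Toolbox) -> list[_Segment]:
    segs: list[_Segment] = []
    for p in tb.fixed:
        segs.append(_Segment(0.0, p.recall, p.precision, p.precision))
    for s in tb.adjustable:
        r_lo, _ = s.recall_range
        p_lo = s.curve[0][1]
        if r_lo > 0:
            segs.append(_Segment(0.0, r_lo, p_lo, p_lo))
        for (r0, p0), (r1, p1) in zip(s.curve, s.curve[1:]):
            segs.append(_Segment(r0, r1, p0, p1))
    return segs


def _envelope_at(segs: Sequence[_Segment], x: float) -> float:
    best = 0.0
    for s in segs:
        if s.x0 <= x <= s.x1:
            best = max(best, s.value_at(x))
    return best


def area_covered(tb: Toolbox) -> float:
    """Area of the region of the precision-recall unit square weakly
    dominated by the toolbox (union of origin-anchored rectangles of the
    fixed points, plus the region under each adjustable curve).

    An empty toolbox covers nothing (area 0).
    """
    segs = _coverage_segments(tb)
    if not segs:
        return 0.0
    # breakpoints: segment endpoints plus pairwise intersections, so that
    # the upper envelope is realised by a single segment between neighbours
    xs = {0.0, 1.0}
    for s in segs:
        xs.add(s.x0)
        xs.add(s.x1)
    for i, a in enumerate(segs):
        for b in segs[i + 1 :]:
            lo, hi = max(a.x0, b.x0), min(a.x1, b.x1)
            if lo >= hi:
                continue
            # solve a(x) = b(x) on the overlap
            da = (a.y1 - a.y0) / (a.x1 - a.x0) if a.x1 > a.x0 else 0.0
            db = (b.y1 - b.y0) / (b.x1 - b.x0) if b.x1 > b.x0 else 0.0
            ca = a.y0 - da * a.x0
            cb = b.y0 - db * b.x0
            if da == db:
                continue
            x = (cb - ca) / (da - db)
            if lo < x < hi:
                xs.add(x)
    grid = sorted(x for x in xs if 0.0 <= x <= 1.0)
    area = 0.0
    for x0, x1 in zip(grid, grid[1:]):
        if x1 <= x0:
            continue
        mid = 0.5 * (x0 + x1)
        top = None
        best_mid = 0.0
        for s in segs:
            if s.x0 <= mid <= s.x1:
                v = s.value_at(mid)
                if v > best_mid:
                    best_mid = v
                    top = s
        if top is not None:
            area += 0.5 * (top.value_at(x0) + top.value_at(x1)) * (x1 - x0)
    return area


def is_inferior(candidate: StrategyPoint, tb: Toolbox) -> bool:
    """True iff the candidate falls inside the area covered by the toolbox,
    i.e. some achievable operating point weakly dominates it.  An exact
    duplicate of an existing point is inferior (it adds no capability)."""
    segs = _coverage_segments(tb)
    if not segs:
        return False
    return _envelope_at(segs, candidate.recall) >= candidate.precision


# ---------------------------------------------------------------------------
# operating points and output sizes
# ---------------------------------------------------------------------------


class OutputSize(NamedTuple):
    """Expected composition of a filter's output on a project."""

    expected_tps: float
    expected_m: float


def expected_output_size(s: StrategyPoint, n: int, base_rate: float) -> OutputSize:
    """Expected output of applying strategy ``s`` to ``n`` items of which a
    fraction ``base_rate`` are valuable: TPs = n * base_rate * recall and
    m = TPs / precision."""
    if not 0 < base_rate <= 1:
        raise DomainError(f"base_rate must be in (0, 1], got {base_rate}")
    if n < 0:
        raise DomainError(f"n must be non-negative, got {n}")
    tps = n * base_rate * s.recall
    m = tps / s.precision
    if m > n:
        raise DomainError(
            f"inconsistent inputs: recall {s.recall} and precision {s.precision} "
            f"at base rate {base_rate} imply m = {m:.1f} > n = {n}"
        )
    return OutputSize(expected_tps=tps, expected_m=m)


def operating_point(
    s: AdjustableStrategy,
    *,
    target_recall: float | None = None,
    target_precision: float | None = None,
    target_output_size: float | None = None,
    n: int | None = None,
    base_rate: float | None = None,
) -> StrategyPoint:
    """Tune an adjustable strategy to a target recall, precision or expected
    output size (the latter needs the project context ``n`` and ``base_rate``).

    Linear interpolation between knots; targets outside the achievable
    range raise a :class:`RangeError` listing the bounds.
    """
    given = [t is not None for t in (target_recall, target_precision, target_output_size)]
    if sum(given) != 1:
        raise DomainError("specify exactly one of target_recall / target_precision / target_output_size")

    if target_recall is not None:
        r = target_recall
    elif target_precision is not None:
        p_hi = s.curve[0][1]  # precision is non-increasing in recall
        p_lo = s.curve[-1][1]
        if not p_lo <= target_precision <= p_hi:
            raise RangeError(
                f"{s.name}: precision {target_precision} outside achievable "
                f"range [{p_lo}, {p_hi}]"
            )
        r = _invert_monotone(
            lambda x: -s.precision_at(x), -target_precision, *s.recall_range
        )
    else:
        if n is None or base_rate is None:
            raise DomainError("target_output_size requires n and base_rate context")

        def m_of(r_: float) -> float:
            p_ = s.precision_at(r_)
            return n * base_rate * r_ / p_

        lo, hi = s.recall_range
        m_lo, m_hi = m_of(lo), m_of(hi)
        if not m_lo <= target_output_size <= m_hi:
            raise RangeError(
                f"{s.name}: output size {target_output_size} outside achievable "
                f"range [{m_lo:.2f}, {m_hi:.2f}]"
            )
        r = _invert_monotone(m_of, target_output_size, lo, hi)

    p = s.precision_at(r)  # raises RangeError if r is out of range
    return StrategyPoint(f"{s.name}@R={r:.6g}", p, r, s.application_cost)


def _invert_monotone(f, target: float, lo: float, hi: float, tol: float = 1e-12) -> float:
    """Find x in [lo, hi] with f(x) = target for non-decreasing f (bisection)."""
    if f(lo) >= target:
        return lo
    if f(hi) <= target:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < tol:
            break
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# strategy selection under a budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyOption:
    """One candidate operating point with its feasibility verdict."""

    point: StrategyPoint
    feasible: bool
    expected_m: float
    expected_tps: float
    overhead: float
    expected_time: float
    note: str = ""


@dataclass(frozen=True)
class SelectionResult:
    chosen: StrategyPoint
    options: tuple[StrategyOption, ...]


class NoFeasibleStrategyError(CurationError):
    """No strategy's expected workload fits the budget; carries the report."""

    def __init__(self, options: Sequence[StrategyOption], t_max: float):
        self.options = tuple(options)
        self.t_max = t_max
        achievable = [o.expected_time for o in options if o.expected_time == o.expected_time]
        smallest = min(achievable) if achievable else float("nan")
        super().__init__(
            f"no feasible strategy: smallest achievable expected time "
            f"{smallest:.3g} exceeds budget t_max = {t_max:.3g}"
        )


def _expected_time(m: float, tps: float, tm: TimeModel) -> float:
    """Expected curation time of m items of which ``tps`` are TPs."""
    if tm.t_bar is not None:
        return m * tm.t_bar
    return tps * tm.t_tp + (m - tps) * tm.t_fp


def select_strategy(
    tb: Toolbox,
    n: int,
    base_rate: float,
    tm: TimeModel,
    t_max: float,
) -> SelectionResult:
    """Pick the strategy maximizing expected curated TPs within the budget.

    Each strategy's application cost is charged against ``t_max`` before
    its output's expected curation time is checked for feasibility.
    Adjustable strategies contribute their best feasible operating point
    (expected workload is monotone in recall, so the feasible frontier is
    found by bisection).  Ties break toward lower overhead, then smaller
    output, then name.
    """
    if len(tb) == 0:
        raise DomainError("cannot select from an empty toolbox")

    options: list[StrategyOption] = []

    def record(pt: StrategyPoint, note: str = "") -> None:
        try:
            size = expected_output_size(pt, n, base_rate)
        except DomainError as exc:
            options.append(
                StrategyOption(pt, False, float("nan"), float("nan"),
                               pt.overhead, float("nan"), note=str(exc))
            )
            return
        time = _expected_time(size.expected_m, size.expected_tps, tm) + pt.application_cost
        options.append(
            StrategyOption(
                pt,
                feasible=time <= t_max,
                expected_m=size.expected_m,
                expected_tps=size.expected_tps,
                overhead=pt.overhead,
                expected_time=time,
                note=note,
            )
        )

    for pt in tb.fixed:
        record(pt)

    for s in tb.adjustable:
        budget = t_max - s.application_cost
        lo, hi = s.recall_range

        def time_at(r: float, s=s) -> float:
            pt = StrategyPoint("_", s.precision_at(r), r)
            tps = n * base_rate * r
            m = tps / pt.precision
            return _expected_time(m, tps, tm)

        if budget < 0 or time_at(lo) > budget:
            record(operating_point(s, target_recall=lo), note="even minimum recall exceeds budget")
            continue
        if time_at(hi) <= budget:
            r_best = hi
        else:
            r_best = _invert_monotone(time_at, budget, lo, hi)
            if time_at(r_best) > budget:  # land on the feasible side
                r_best = max(lo, r_best - 1e-9)
        record(operating_point(s, target_recall=r_best), note="best feasible operating point")

    feasible = [o for o in options if o.feasible]
    if not feasible:
        raise NoFeasibleStrategyError(options, t_max)
    chosen = min(
        feasible,
        key=lambda o: (-o.expected_tps, o.overhead, o.expected_m, o.point.name),
    )
    return SelectionResult(chosen=chosen.point, options=tuple(options))


# ---------------------------------------------------------------------------
# JSON interface
# ---------------------------------------------------------------------------


def toolbox_from_dict(data: dict) -> Toolbox:
    """Build a toolbox from the JSON structure
    ``{"fixed": [{"name", "precision", "recall", "cost"}],
       "adjustable": [{"name", "curve": [[recall, precision], ...], "cost"}]}``.

    Validation errors name the offending entry and field.
    """
    from .errors import InputFormatError

    if not isinstance(data, dict):
        raise InputFormatError(f"toolbox JSON must be an object, got {type(data).__name__}")
    fixed = []
    for i, entry in enumerate(data.get("fixed", [])):
        for key in ("name", "precision", "recall"):
            if key not in entry:
                raise InputFormatError(f"fixed[{i}]: missing required field '{key}'")
        try:
            fixed.append(
                StrategyPoint(
                    name=str(entry["name"]),
                    precision=float(entry["precision"]),
                    recall=float(entry["recall"]),
                    application_cost=float(entry.get("cost", 0.0)),
                )
            )
        except (DomainError, ValueError, TypeError) as exc:
            raise InputFormatError(f"fixed[{i}]: {exc}") from exc
    adjustable = []
    for i, entry in enumerate(data.get("adjustable", [])):
        for key in ("name", "curve"):
            if key not in entry:
                raise InputFormatError(f"adjustable[{i}]: missing required field '{key}'")
        try:
            curve = tuple((float(r), float(p)) for r, p in entry["curve"])
            adjustable.append(
                AdjustableStrategy(
                    name=str(entry["name"]),
                    curve=curve,
                    application_cost=float(entry.get("cost", 0.0)),
                )
            )
        except (DomainError, ValueError, TypeError) as exc:
            raise InputFormatError(f"adjustable[{i}]: {exc}") from exc
    try:
        return Toolbox(fixed=tuple(fixed), adjustable=tuple(adjustable))
    except DomainError as exc:
        raise InputFormatError(str(exc)) from exc
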