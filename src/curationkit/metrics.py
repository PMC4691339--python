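"""Closed-form efficiency metrics for resource-limited curation.

The central quantity is *overhead*, the wasted curation effort relative to
the productive effort.  In its simplest, binary-valued form it is the ratio
of false positives to true positives in the curated set::

    O = FP / TP          and equivalently          precision = 1 / (1 + O)

Overhead generalises in three directions, all implemented here:

* **time weighting** — FPs and TPs need not take equally long to curate,
  so each class is weighted by its mean curation time;
* **value weighting** — items carry graded values on a scale
  ``[w_min, w_max]``; overhead becomes the value left uncreated relative to
  the value created, and reduces exactly to FP/TP for binary values;
* **probability adjustment** — before curation, item values and TP status
  are only estimates; a per-item TP probability folds the risk of curating
  a worthless item into the expected overhead.

Alongside these live the familiar retrieval metrics (precision, recall,
F_beta) and the productivity rate ``v_TP``, the number of TPs produced per
unit of curation time.  All quantities are plain fractions; percentage
rendering is a presentation concern (see :func:`display_percent`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

from .errors import DomainError, InfiniteOverheadError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "TimeModel",
    "ValueScale",
    "ValuedItemSet",
    "precision",
    "recall",
    "f_beta",
    "overhead_simple",
    "overhead_from_precision",
    "precision_from_overhead",
    "overhead_time_weighted",
    "tp_production_rate",
    "fp_cost_for_target_tps",
    "FPCost",
    "overhead_value_weighted",
    "overhead_value_time_weighted",
    "overhead_probability_adjusted",
    "display_percent",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN tallies for one applied filtering strategy.

    ``fn`` and ``tn`` are optional because a filtering strategy's output set
    reveals only its TPs and FPs; the misses require knowing the full
    candidate set.
    """

    tp: int
    fp: int
    fn: int | None = None
    tn: int | None = None

    def __post_init__(self) -> None:
        for field in ("tp", "fp", "fn", "tn"):
            v = getattr(self, field)
            if v is None:
                continue
            if v < 0 or v != int(v):
                raise DomainError(f"{field} must be a non-negative integer, got {v!r}")

    @property
    def filtered_size(self) -> int:
        """Size m of the curated set x^f."""
        return self.tp + self.fp


@dataclass(frozen=True)
class TimeModel:
    """Mean curation times per class.

    t_tp
        Mean time to curate a true positive (store, annotate).
    t_fp
        Mean time to dismiss a false positive (read, reject).
    t_bar
        Overall mean curation time T-bar across all items; the average
        curation speed is its inverse, v = 1/T-bar.
    """

    t_tp: float
    t_fp: float = 0.0
    t_bar: float | None = None

    def __post_init__(self) -> None:
        if self.t_tp <= 0:
            raise DomainError(f"t_tp must be > 0, got {self.t_tp}")
        if self.t_fp < 0:
            raise DomainError(f"t_fp must be >= 0, got {self.t_fp}")
        if self.t_bar is not None and self.t_bar <= 0:
            raise DomainError(f"t_bar must be > 0, got {self.t_bar}")

    @property
    def speed(self) -> float:
        """Average curation speed v = 1/T-bar (items per time unit)."""
        if self.t_bar is None:
            raise UndefinedMetricError("speed", "t_bar not set on this TimeModel")
        return 1.0 / self.t_bar


@dataclass(frozen=True)
class ValueScale:
    """Bounds [w_min, w_max] of per-item value; FPs sit at w_min."""

    w_min: float
    w_max: float

    def __post_init__(self) -> None:
        if not self.w_max > self.w_min:
            raise DomainError(
                f"value scale requires w_max > w_min, got [{self.w_min}, {self.w_max}]"
            )

    @property
    def span(self) -> float:
        return self.w_max - self.w_min


@dataclass(frozen=True)
class ValuedItemSet:
    """Per-item values w_i, optional times T(w_i) and TP probabilities p(x_i)."""

    values: tuple[float, ...]
    times: tuple[float, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise DomainError("ValuedItemSet requires at least one item")
        for name in ("times", "probs"):
            seq = getattr(self, name)
            if seq is None:
                continue
            seq = tuple(seq)
            object.__setattr__(self, name, seq)
            if len(seq) != len(self.values):
                raise DomainError(
                    f"{name} has length {len(seq)} but values has {len(self.values)}"
                )
        if self.times is not None and any(t <= 0 for t in self.times):
            raise DomainError("all per-item times must be > 0")
        if self.probs is not None and any(not 0 <= p <= 1 for p in self.probs):
            raise DomainError("all TP probabilities must lie in [0, 1]")

    def check_scale(self, scale: ValueScale) -> None:
        for w in self.values:
            if not scale.w_min <= w <= scale.w_max:
                raise DomainError(
                    f"item value {w} outside scale [{scale.w_min}, {scale.w_max}]"
                )


# ---------------------------------------------------------------------------
# retrieval metrics
# ---------------------------------------------------------------------------


def precision(counts: ConfusionCounts) -> float:
    """Density of TPs in the curated set: TP / (TP + FP)."""
    denom = counts.tp + counts.fp
    if denom == 0:
        raise UndefinedMetricError("precision", "tp + fp = 0 (empty curated set)")
    return counts.tp / denom


def recall(counts: ConfusionCounts) -> float:
    """Fraction of valuable items captured: TP / (TP + FN)."""
    if counts.fn is None:
        raise UndefinedMetricError("recall", "fn is not known for these counts")
    denom = counts.tp + counts.fn
    if denom == 0:
        raise UndefinedMetricError("recall", "tp + fn = 0 (no valuable items exist)")
    return counts.tp / denom


def f_beta(p: float, r: float, beta: float = 1.0) -> float:
    """F_beta = (beta^2 + 1) P R / (beta^2 P + R).

    beta < 1 favours precision, beta > 1 favours recall; beta = 1 is the
    harmonic mean.  Returns 0 when the denominator vanishes (p = r = 0),
    the common convention.
    """
    if not 0 <= p <= 1:
        raise DomainError(f"precision must lie in [0, 1], got {p}")
    if not 0 <= r <= 1:
        raise DomainError(f"recall must lie in [0, 1], got {r}")
    if beta < 0:
        raise DomainError(f"beta must be non-negative, got {beta}")
    b2 = beta * beta
    denom = b2 * p + r
    if denom == 0:
        return 0.0
    return (b2 + 1.0) * p * r / denom


# ---------------------------------------------------------------------------
# overhead family
# ---------------------------------------------------------------------------


def overhead_simple(counts: ConfusionCounts) -> float:
    """Overhead in its simplest form: O = FP / TP."""
    if counts.tp == 0:
        if counts.fp == 0:
            raise UndefinedMetricError("overhead", "tp = fp = 0 (nothing curated)")
        raise InfiniteOverheadError(reason=f"fp = {counts.fp} with tp = 0")
    return counts.fp / counts.tp


def overhead_from_precision(p: float) -> float:
    """Invert precision = 1/(1+O): O = (1 - P) / P."""
    if not 0 <= p <= 1:
        raise DomainError(f"precision must lie in [0, 1], got {p}")
    if p == 0:
        raise InfiniteOverheadError(reason="precision = 0")
    return (1.0 - p) / p


def precision_from_overhead(o: float) -> float:
    """Precision = 1 / (1 + O)."""
    if o < 0:
        raise DomainError(f"overhead must be non-negative, got {o}")
    return 1.0 / (1.0 + o)


def overhead_time_weighted(
    counts: ConfusionCounts,
    tm: TimeModel,
    denominator: Literal["tp", "filtered"] = "tp",
) -> float:
    """Overhead weighted by per-class mean curation times.

    The definitional form (``denominator="tp"``) is::

        O = (FP * T_fp) / (TP * T_tp)

    The ``"filtered"`` convention divides by the whole curated set's TP-time
    instead, ``(TP + FP) * T_tp`` — the "first approximation" used when a
    quick workload estimate over the filtered set is wanted.  With equal
    per-class times the two reduce to FP/TP and FP/(TP+FP) respectively.
    """
    if denominator not in ("tp", "filtered"):
        raise DomainError(f"denominator must be 'tp' or 'filtered', got {denominator!r}")
    if denominator == "tp":
        if counts.tp == 0:
            if counts.fp == 0:
                raise UndefinedMetricError("overhead", "tp = fp = 0 (nothing curated)")
            raise InfiniteOverheadError(reason=f"fp = {counts.fp} with tp = 0")
        return (counts.fp * tm.t_fp) / (counts.tp * tm.t_tp)
    if counts.filtered_size == 0:
        raise UndefinedMetricError("overhead", "tp + fp = 0 (nothing curated)")
    return (counts.fp * tm.t_fp) / (counts.filtered_size * tm.t_tp)


def tp_production_rate(tm: TimeModel, o: float) -> float:
    """Productivity v_TP = 1 / (T_tp * (1 + O)), TPs per unit time.

    With uniform curation times this equals v * precision.
    """
    if o < 0:
        raise DomainError(f"overhead must be non-negative, got {o}")
    return 1.0 / (tm.t_tp * (1.0 + o))


class FPCost(NamedTuple):
    """FPs a strategy co-produces with a target TP count."""

    exact: float
    rounded: int


def fp_cost_for_target_tps(p: float, n_tp: int) -> FPCost:
    """FPs produced alongside ``n_tp`` TPs at precision ``p``: n_tp (1-P)/P."""
    if not 0 <= p <= 1:
        raise DomainError(f"precision must lie in [0, 1], got {p}")
    if n_tp < 0:
        raise DomainError(f"n_tp must be non-negative, got {n_tp}")
    if p == 0:
        raise InfiniteOverheadError("fp_cost", "precision = 0")
    exact = n_tp * (1.0 - p) / p
    return FPCost(exact=exact, rounded=_round_half_away(exact))


# ---------------------------------------------------------------------------
# value-weighted overhead
# ---------------------------------------------------------------------------


def overhead_value_weighted(items: ValuedItemSet, scale: ValueScale) -> float:
    """Value-weighted overhead on a graded scale:

        O = sum_i (w_max - w_i) / sum_i (w_i - w_min)

    The numerator is value left uncreated relative to curating only maximal
    items; the denominator is value actually created.  Binary values on
    [0, 1] recover FP/TP exactly.
    """
    items.check_scale(scale)
    num = sum(scale.w_max - w for w in items.values)
    den = sum(w - scale.w_min for w in items.values)
    if den == 0:
        raise InfiniteOverheadError(reason="all items at w_min (no value created)")
    return num / den


def overhead_value_time_weighted(items: ValuedItemSet, scale: ValueScale) -> float:
    """Value-weighted overhead with per-item curation times:

        O = sum_i (w_max - w_i) T(w_i) / sum_i (w_i - w_min) T(w_i)
    """
    items.check_scale(scale)
    if items.times is None:
        raise UndefinedMetricError("overhead_value_time_weighted", "per-item times missing")
    num = sum((scale.w_max - w) * t for w, t in zip(items.values, items.times))
    den = sum((w - scale.w_min) * t for w, t in zip(items.values, items.times))
    if den == 0:
        raise InfiniteOverheadError(reason="all items at w_min (no value created)")
    return num / den


def overhead_probability_adjusted(items: ValuedItemSet, scale: ValueScale) -> float:
    """Expected overhead when TP status is uncertain.

    Each item is a TP with probability p_i; with probability 1 - p_i it is
    worth only w_min (the FP value), so its full potential value span is
    wasted::

        O = [ sum (w_max - w_i) T_i p_i + sum (w_max - w_min) T_i (1 - p_i) ]
            / sum (w_i - w_min) T_i p_i

    With all p_i = 1 this reduces to the value-and-time-weighted overhead.
    """
    items.check_scale(scale)
    if items.probs is None:
        raise UndefinedMetricError("overhead_probability_adjusted", "TP probabilities missing")
    times = items.times if items.times is not None else tuple(1.0 for _ in items.values)
    num = sum(
        (scale.w_max - w) * t * p + scale.span * t * (1.0 - p)
        for w, t, p in zip(items.values, times, items.probs)
    )
    den = sum(
        (w - scale.w_min) * t * p for w, t, p in zip(items.values, times, items.probs)
    )
    if den == 0:
        raise InfiniteOverheadError(
            reason="no expected value created (all p = 0 or all values at w_min)"
        )
    return num / den


# ---------------------------------------------------------------------------
# presentation
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def display_percent(fraction: float) -> int:
    """Render a fraction as a whole percentage, rounding half away from zero."""
    return _round_half_away(fraction * 100.0)
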