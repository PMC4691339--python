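"""Shared fixtures: the abstract-triage use-case counts and random
toolbox/project generators used by the oracle cross-checks."""

from __future__ import annotations

import numpy as np
import pytest

from curationkit.metrics import ConfusionCounts, TimeModel, ValueScale
from curationkit.planner import CurationProject, Item
from curationkit.toolbox import AdjustableStrategy, StrategyPoint, Toolbox


@pytest.fixture
def usecase_counts() -> ConfusionCounts:
    """The IL32/IL10 sentence co-occurrence triage: 18 abstracts filtered,
    11 genuinely relate the proteins, 7 do not."""
    return ConfusionCounts(tp=11, fp=7)


@pytest.fixture
def usecase_times() -> TimeModel:
    """Curating a TP (store + annotate) takes twice as long as dismissing an FP."""
    return TimeModel(t_tp=2.0, t_fp=1.0)


@pytest.fixture
def unit_scale() -> ValueScale:
    return ValueScale(0.0, 1.0)


def random_toolbox(rng: np.random.Generator, max_fixed: int = 8,
                   with_adjustable: bool = False) -> Toolbox:
    """Draw a valid toolbox with 1..max_fixed fixed points and optionally
    one monotone adjustable curve."""
    n = int(rng.integers(1, max_fixed + 1))
    fixed = tuple(
        StrategyPoint(
            name=f"f{i}",
            precision=float(rng.uniform(0.05, 1.0)),
            recall=float(rng.uniform(0.0, 1.0)),
        )
        for i in range(n)
    )
    adjustable = ()
    if with_adjustable:
        k = int(rng.integers(2, 6))
        recalls = np.sort(rng.uniform(0.05, 1.0, size=k))
        while len(np.unique(recalls)) < k:
            recalls = np.sort(rng.uniform(0.05, 1.0, size=k))
        precisions = np.sort(rng.uniform(0.1, 1.0, size=k))[::-1]
        adjustable = (
            AdjustableStrategy("adj", tuple(zip(recalls.tolist(), precisions.tolist()))),
        )
    return Toolbox(fixed=fixed, adjustable=adjustable)


def grid_area_oracle(tb: Toolbox, res: int = 1000) -> float:
    """Independent area-covered oracle: fraction of an res x res grid of
    cell centers that some strategy weakly dominates.  Uses direct
    membership tests (step functions and np.interp), not the package's
    segment-envelope sweep."""
    rs = (np.arange(res) + 0.5) / res
    env = np.zeros(res)
    for pt in tb.fixed:
        env = np.maximum(env, np.where(rs <= pt.recall, pt.precision, 0.0))
    for s in tb.adjustable:
        knot_r = [r for r, _ in s.curve]
        knot_p = [p for _, p in s.curve]
        vals = np.zeros(res)
        vals[rs < knot_r[0]] = knot_p[0]
        inside = (rs >= knot_r[0]) & (rs <= knot_r[-1])
        vals[inside] = np.interp(rs[inside], knot_r, knot_p)
        env = np.maximum(env, vals)
    ps = (np.arange(res) + 0.5) / res
    return float(np.sum(ps[None, :] <= env[:, None])) / (res * res)


def small_project(rng: np.random.Generator, name: str, n_items: int,
                  scale: ValueScale | None = None) -> CurationProject:
    """A small unit-time project with random estimated values, for
    allocation and scheduling oracles."""
    scale = scale or ValueScale(0.0, 1.0)
    items = tuple(
        Item(
            id=f"{name}-i{k}",
            est_value=float(rng.uniform(scale.w_min, scale.w_max)),
            est_time=1.0,
        )
        for k in range(n_items)
    )
    return CurationProject(name=name, items=items, t_max=float(n_items), scale=scale)
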