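"""File formats and report rendering.

Item tables travel as TSV with a required header; projects, toolboxes,
simulation configs and reports are JSON.  Reports carry metrics twice: a
``metrics`` block with full-precision fractions and a ``display`` block
with whole-percent renderings (rounded half away from zero, so 0.389
prints as 39%), plus provenance (package version, seed, timestamp).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .errors import DomainError, InputFormatError
from .metrics import ValueScale, display_percent
from .planner import CurationProject, Item

__all__ = [
    "read_items",
    "write_items",
    "load_project",
    "make_report",
    "write_report",
    "ITEM_COLUMNS",
]

ITEM_COLUMNS = ("id", "duplicate_key", "true_value", "est_value", "p_tp", "est_time", "gold_label")
_REQUIRED = ("id", "est_value", "est_time")


def read_items(path: str | Path) -> list[Item]:
    """Read an item table TSV, validating row by row.

    Required columns: ``id``, ``est_value``, ``est_time``.  Optional:
    ``duplicate_key``, ``true_value``, ``p_tp``, ``gold_label``.  Errors
    name the offending row (1-based, excluding the header) and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", float_precision="round_trip",
            dtype={"id": str, "duplicate_key": str, "gold_label": str},
        )
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"{path}: cannot parse item table: {exc}") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in ITEM_COLUMNS]
    if unknown:
        raise InputFormatError(f"{path}: unknown columns {unknown}")

    items: list[Item] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        rec = row._asdict()

        def get(col: str):
            v = rec.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        item_id = get("id")
        if not item_id:
            raise InputFormatError(f"{path}: row {row_no}, column id: empty identifier")
        if item_id in seen:
            raise InputFormatError(f"{path}: row {row_no}, column id: duplicate id {item_id!r}")
        seen.add(item_id)
        kwargs = {"id": item_id}
        for col, cast in (
            ("est_value", float),
            ("est_time", float),
            ("true_value", float),
            ("p_tp", float),
            ("duplicate_key", str),
            ("gold_label", str),
        ):
            v = get(col)
            if v is None:
                if col in _REQUIRED:
                    raise InputFormatError(f"{path}: row {row_no}, column {col}: missing value")
                continue
            try:
                kwargs[col] = cast(v)
            except (TypeError, ValueError) as exc:
                raise InputFormatError(
                    f"{path}: row {row_no}, column {col}: invalid value {v!r}"
                ) from exc
        try:
            items.append(Item(**kwargs))
        except DomainError as exc:
            # attribute domain errors to the column the constraint is about
            col = "p_tp" if "p_tp" in str(exc) else (
                "gold_label" if "gold_label" in str(exc) else "est_time"
            )
            raise InputFormatError(f"{path}: row {row_no}, column {col}: {exc}") from exc
    if not items:
        raise InputFormatError(f"{path}: item table contains no rows")
    return items


def write_items(items: Sequence[Item], path: str | Path) -> None:
    """Write items as TSV; the round trip through :func:`read_items` is lossless."""
    rows = []
    for it in items:
        rows.append(
            {
                "id": it.id,
                "duplicate_key": it.duplicate_key,
                "true_value": it.true_value,
                "est_value": it.est_value,
                "p_tp": it.p_tp,
                "est_time": it.est_time,
                "gold_label": it.gold_label,
            }
        )
    # %.17g keeps the round trip bit-exact for doubles
    pd.DataFrame(rows, columns=list(ITEM_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def load_project(path: str | Path) -> CurationProject:
    """Load a project JSON: ``{"name", "t_max", "speed"?, "scale": {"w_min",
    "w_max"}, "items": "<table.tsv>"}``; the item-table path is resolved
    relative to the JSON file."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputFormatError(f"{path}: cannot read project JSON: {exc}") from exc
    for key in ("name", "t_max", "scale", "items"):
        if key not in data:
            raise InputFormatError(f"{path}: missing required field '{key}'")
    scale_raw = data["scale"]
    for key in ("w_min", "w_max"):
        if key not in scale_raw:
            raise InputFormatError(f"{path}: scale: missing field '{key}'")
    try:
        scale = ValueScale(float(scale_raw["w_min"]), float(scale_raw["w_max"]))
    except DomainError as exc:
        raise InputFormatError(f"{path}: scale: {exc}") from exc
    items = read_items(path.parent / data["items"])
    try:
        return CurationProject(
            name=str(data["name"]),
            items=tuple(items),
            t_max=float(data["t_max"]),
            scale=scale,
            speed=float(data["speed"]) if data.get("speed") is not None else None,
        )
    except (DomainError, ValueError, TypeError) as exc:
        raise InputFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def make_report(
    inputs: dict,
    metrics: dict,
    decisions: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a report: full-precision ``metrics``, whole-percent
    ``display`` strings for every fractional metric, and provenance."""
    display = {}
    for key, value in metrics.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            continue
        if key.startswith(("precision", "recall", "overhead", "f_", "v_tp")) or key.endswith(
            ("_fraction", "_rate")
        ):
            if math.isfinite(value):
                display[key] = f"{display_percent(value)}%"
    return {
        "inputs": inputs,
        "metrics": metrics,
        "display": display,
        "decisions": decisions or {},
        "provenance": {
            "package": "curationkit",
            "version": __version__,
            "seed": seed,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        },
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (set, tuple)):
        return list(obj)
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)
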