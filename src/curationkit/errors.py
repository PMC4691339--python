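"""Error types shared across the toolkit.

Overhead is the ratio of wasted to productive curation effort.  When a
curated set contains no true positives the ratio has no finite value; we
signal that explicitly instead of letting ``inf`` propagate through
downstream arithmetic, so that optimizers can substitute a worst-case
penalty deliberately.
"""

from __future__ import annotations


class CurationError(Exception):
    """Base class for all toolkit errors."""


class UndefinedMetricError(CurationError, ValueError):
    """A metric has no defined value on the given inputs (e.g. empty set)."""

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        super().__init__(f"{metric} is undefined: {reason}")


class InfiniteOverheadError(CurationError, ArithmeticError):
    """Overhead is unbounded: effort was spent but no value was produced."""

    def __init__(self, metric: str = "overhead", reason: str = "no true positives"):
        self.metric = metric
        super().__init__(f"{metric} is infinite: {reason}")


class DomainError(CurationError, ValueError):
    """An argument lies outside the metric's mathematical domain."""


class RangeError(CurationError, ValueError):
    """A requested operating point lies outside the achievable range."""


class InputFormatError(CurationError, ValueError):
    """A file or config failed validation; message carries row/field detail."""
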