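"""Univariate time-series container.

The data model uses 1-based ordinal time indices ``t = 1..T`` matching the
standard notation y_1..y_T for an evenly spaced series.  Even spacing is a
modelling assumption, not a checked property: the container stores no
timestamps beyond ordinal position, and optional labels are carried along
purely for display and export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["TimeSeries", "validate_series"]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, evenly spaced, complete numeric series.

    Parameters
    ----------
    values : ndarray of float
        Observations y_1..y_T in time order.  Must be finite.
    labels : tuple of str, optional
        Per-observation labels (e.g. ISO dates), same length as ``values``.
    """

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != arr.size:
                raise ValueError(
                    f"labels length {len(labels)} != values length {arr.size}"
                )

    @property
    def T(self) -> int:
        """Number of observations."""
        return int(self.values.size)

    def __len__(self) -> int:
        return self.T

    def value_at(self, t: int) -> float:
        """Return y_t for a 1-based ordinal index ``t``."""
        if not 1 <= t <= self.T:
            raise IndexError(f"t={t} outside 1..{self.T}")
        return float(self.values[t - 1])

    def window(self, start: int, stop: int) -> np.ndarray:
        """Values y_start..y_stop inclusive (1-based)."""
        if not (1 <= start <= stop <= self.T):
            raise IndexError(f"window {start}..{stop} outside 1..{self.T}")
        return self.values[start - 1 : stop]


def validate_series(raw: Iterable) -> TimeSeries:
    """Validate raw input into a :class:`TimeSeries`.

    Accepts a sequence of numbers or of ``{label, value}``-style mappings
    (any mapping with a numeric ``value`` entry and one other entry taken
    as the label).  Order of appearance defines time order.

    Raises
    ------
    ValueError
        If the input is empty, contains a non-numeric entry, or contains a
        non-finite value; the error names the offending 0-based index.
    """
    items = list(raw)
    if not items:
        raise ValueError("empty series")

    labels: list[str] | None = None
    values = np.empty(len(items), dtype=float)
    for i, item in enumerate(items):
        if isinstance(item, dict):
            if "value" not in item:
                raise ValueError(f"record at index {i} has no 'value' field")
            val = item["value"]
            label_keys = [k for k in item if k != "value"]
            if labels is None:
                labels = []
            labels.append(str(item[label_keys[0]]) if label_keys else str(i))
        else:
            val = item
        try:
            values[i] = float(val)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric value at index {i}: {val!r}") from None
        if not np.isfinite(values[i]):
            raise ValueError(f"non-finite value at index {i}: {val!r}")

    return TimeSeries(values=values, labels=tuple(labels) if labels else None)
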