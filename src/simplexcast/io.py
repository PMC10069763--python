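"""Reading time series and writing forecast exports.

Accepted inputs: two-column CSV (label, value) with an optional header
auto-detected by a non-numeric first row, single-column CSV of values, a
JSON array of numbers, or a JSON array of {label, value} records.  Order
of appearance defines time order.

Exports: the point-forecast series (step, forecast) and the per-neighbor
parallel series (one column per enabled neighbor, named by its time
index).  Floats are written with 17 significant digits so round-trips are
lossless.
"""

from __future__ import annotations

import csv
import io as _io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .forecast import PointForecast
from .neighbors import NeighborSet
from .series import TimeSeries, validate_series

__all__ = [
    "ExportBundle",
    "read_series",
    "write_point_forecast",
    "write_neighbor_series",
    "write_density_grids",
]

_FLOAT_FMT = "{:.17g}"


@dataclass(frozen=True)
class ExportBundle:
    """Results of one forecast run packaged for export.

    ``neighbor_series`` maps each *enabled* neighbor's time index t_i to
    its future vector of length tp.
    """

    origin_t: int
    point: PointForecast | None = None
    neighbor_series: Mapping[int, np.ndarray] | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def from_run(
        cls,
        ns: NeighborSet,
        pf: PointForecast | None = None,
        metadata: Mapping[str, object] | None = None,
    ) -> "ExportBundle":
        return cls(
            origin_t=ns.query.t,
            point=pf,
            neighbor_series={nb.t_i: nb.z_i.copy() for nb in ns.enabled_neighbors},
            metadata=dict(metadata or {}),
        )


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def _read_text(path_or_text: str | os.PathLike) -> str:
    if isinstance(path_or_text, os.PathLike) or (
        isinstance(path_or_text, str)
        and "\n" not in path_or_text
        and os.path.exists(path_or_text)
    ):
        return Path(path_or_text).read_text(encoding="utf-8")
    return str(path_or_text)


def read_series(path_or_text: str | os.PathLike, format: str = "csv") -> TimeSeries:
    """Read a :class:`TimeSeries` from a file path or raw text.

    Parameters
    ----------
    path_or_text : str or path
        Path to a file, or the file content itself.
    format : {"csv", "json"}
    """
    text = _read_text(path_or_text)
    if format == "csv":
        return _read_csv(text)
    if format == "json":
        return _read_json(text)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def _read_csv(text: str) -> TimeSeries:
    rows = [row for row in csv.reader(_io.StringIO(text))]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError("empty file")
    width = len(rows[0])
    if width > 2:
        raise ValueError(f"expected 1 or 2 columns, found {width} in row 1")

    start = 0
    first_value_cell = rows[0][-1].strip()
    if not _is_number(first_value_cell):
        start = 1  # header row
        if len(rows) == 1:
            raise ValueError("file contains only a header row")

    labels: list[str] | None = [] if width == 2 else None
    values = []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) != width:
            raise ValueError(f"row {i}: expected {width} columns, found {len(row)}")
        cell = row[-1].strip()
        if not cell:
            raise ValueError(f"row {i}: blank value cell")
        if not _is_number(cell):
            raise ValueError(f"row {i}: non-numeric value {cell!r}")
        values.append(float(cell))
        if labels is not None:
            labels.append(row[0].strip())
    ts = validate_series(values)
    return TimeSeries(values=ts.values, labels=tuple(labels) if labels else None)


def _read_json(text: str) -> TimeSeries:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"invalid JSON: {exc}") from None
    if not isinstance(data, list):
        raise ValueError("JSON input must be an array")
    return validate_series(data)


def write_series(ts: TimeSeries, path: str | os.PathLike) -> None:
    """Write a series as (label, value) CSV, or single-column if unlabeled."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if ts.labels is not None:
            writer.writerow(["label", "value"])
            for lab, val in zip(ts.labels, ts.values):
                writer.writerow([lab, _FLOAT_FMT.format(val)])
        else:
            for val in ts.values:
                writer.writerow([_FLOAT_FMT.format(val)])


def write_point_forecast(
    pf: PointForecast,
    labels: list[str] | None = None,
    path: str | os.PathLike = "point_forecast.csv",
) -> None:
    """Write point forecasts as CSV with columns (step, forecast)."""
    if pf.tp == 0:
        raise ValueError("empty forecast")
    if labels is not None and len(labels) != pf.tp:
        raise ValueError("labels length must equal the forecast horizon")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["step", "forecast"] + (["label"] if labels else [])
        writer.writerow(header)
        for r, val in enumerate(pf.values, start=1):
            row = [r, _FLOAT_FMT.format(val)]
            if labels:
                row.append(labels[r - 1])
            writer.writerow(row)


def read_point_forecast(path: str | os.PathLike, origin_t: int = 0) -> PointForecast:
    """Read back a point-forecast CSV written by :func:`write_point_forecast`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    values = [float(row[1]) for row in rows[1:]]
    return PointForecast(origin_t=origin_t, values=np.asarray(values))


def write_neighbor_series(bundle: ExportBundle, path: str | os.PathLike) -> None:
    """Write the enabled neighbors' futures as parallel series.

    Wide CSV: a "step" column plus one column per enabled neighbor, named
    by the neighbor's time index; tp data rows.
    """
    if not bundle.neighbor_series:
        raise ValueError("all neighbors disabled: nothing to export")
    t_is = sorted(bundle.neighbor_series)
    tp = len(next(iter(bundle.neighbor_series.values())))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step"] + [str(t) for t in t_is])
        for r in range(tp):
            writer.writerow(
                [r + 1]
                + [_FLOAT_FMT.format(bundle.neighbor_series[t][r]) for t in t_is]
            )


def write_density_grids(grids, path: str | os.PathLike) -> None:
    """Write shaded-area densities as long CSV (step, v, density, opacity)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "v", "density", "opacity"])
        for dg in grids:
            for v, k, o in zip(dg.grid_v, dg.density_K, dg.opacity):
                writer.writerow(
                    [dg.step_r, _FLOAT_FMT.format(v), _FLOAT_FMT.format(k), _FLOAT_FMT.format(o)]
                )
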