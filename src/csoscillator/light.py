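"""Photic time-series container and CSV input/output.

A :class:`LightSeries` is a possibly-irregularly sampled record of light
exposure, tagged with its unit: photopic illuminance (``lux``), circadian
light (``cla``), or circadian stimulus (``cs``).  Times are decimal hours
since the simulation origin, defined as midnight of the first recorded day,
so ``t % 24`` is local clock time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default simulation origin used when writing series that were generated
#: synthetically (no wall-clock provenance).
DEFAULT_ORIGIN = pd.Timestamp("2000-01-03 00:00:00")  # a Monday


class Unit(str, Enum):
    """Photic input unit."""

    LUX = "lux"
    CLA = "cla"
    CS = "cs"


@dataclass
class LightSeries:
    """Unit-tagged light-exposure time series.

    Parameters
    ----------
    times : ndarray
        Sample times in decimal hours since the origin (midnight of the
        first recorded day).  Sorted ascending; out-of-order input is
        sorted with a warning.
    values : ndarray
        Nonnegative light values in ``unit``.  Small negative sensor
        readings are clamped to zero with a warning.
    unit : Unit
        Unit of ``values``.
    subject_id : str, optional
    origin : pandas.Timestamp, optional
        Wall-clock time corresponding to ``times == 0``.
    """

    times: np.ndarray
    values: np.ndarray
    unit: Unit
    subject_id: str | None = None
    origin: pd.Timestamp = field(default=DEFAULT_ORIGIN)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.unit = Unit(self.unit)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D and equal length")
        if self.times.size and not np.all(np.isfinite(self.times)):
            raise ValidationError("non-finite timestamps")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            logger.warning("light series timestamps out of order; sorting")
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.values = self.values[order]
        if self.values.size and np.any(self.values < 0):
            logger.warning(
                "clamping %d negative light value(s) to 0", int((self.values < 0).sum())
            )
            self.values = np.maximum(self.values, 0.0)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Span in hours from first to last sample."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    @property
    def clock_times(self) -> np.ndarray:
        """Sample times folded to local clock hours in [0, 24)."""
        return np.mod(self.times, 24.0)

    def with_values(self, values: np.ndarray, unit: Unit | None = None) -> "LightSeries":
        """Copy of the series with replaced values (and optionally unit)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else Unit(unit))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id or "",
                "timestamp": self.origin + pd.to_timedelta(np.round(self.times * 3600.0), unit="s"),
                "value": self.values,
                "unit": self.unit.value,
            }
        )


def read_light_csv(path: str | Path, cs_ceiling: float = 0.7) -> LightSeries:
    """Read a single-subject light series from CSV.

    Expected header: ``subject_id,timestamp,value,unit`` with ISO-8601
    timestamps and unit one of ``lux``/``cla``/``cs``.  Storage intervals of
    30–180 s and irregular gaps are accepted as-is; gap policy is applied at
    integration time, not here.

    Raises
    ------
    ValidationError
        On unknown unit tokens, malformed rows (reported with line
        numbers), mixed units, or CS values exceeding ``cs_ceiling``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "unit": str})
    required = {"subject_id", "timestamp", "value", "unit"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = ts.isna() | vals.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"{path}: malformed rows at lines {lines[:20]}")

    units = set(df["unit"].str.strip().str.lower())
    unknown = units - {u.value for u in Unit}
    if unknown:
        raise ValidationError(f"{path}: unknown unit token(s) {sorted(unknown)}")
    if len(units) != 1:
        raise ValidationError(f"{path}: mixed units {sorted(units)}")
    unit = Unit(units.pop())

    if unit is Unit.CS and (vals > cs_ceiling + 1e-12).any():
        raise ValidationError(
            f"{path}: CS values exceed the asymptote {cs_ceiling}"
        )

    ts = ts.dt.tz_localize(None) if ts.dt.tz is not None else ts
    origin = ts.min().normalize()
    times = (ts - origin).dt.total_seconds().to_numpy() / 3600.0
    sid = df["subject_id"].iloc[0] if len(df) else None
    return LightSeries(times=times, values=vals.to_numpy(float), unit=unit,
                       subject_id=sid, origin=origin)


def write_light_csv(series: LightSeries, path: str | Path) -> None:
    """Write a series as CSV; round-trips timestamps to 1 s, values to 1e-6."""
    df = series.to_frame()
    df["value"] = df["value"].round(6)
    df.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
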