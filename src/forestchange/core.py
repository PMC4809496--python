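"""Shared containers and vocabulary for the forest-change pipeline.

Time is represented as decimal years throughout the package
(``year + day_of_year / 365.25``), so the annual harmonic of the
season-trend model is simply ``sin(2*pi*t + delta)``.  Trend intercepts
are reported at the baseline origin 1999.0, the start of the assembled
satellite record.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

#: Reflectance input bands, in sensor order.
REFLECTANCE_BANDS: tuple[str, ...] = ("B", "G", "R", "NIR", "SWIR1", "SWIR2")

#: Derived spectral indices, in the order they are tabulated.
DERIVED_BANDS: tuple[str, ...] = (
    "NDVI", "NDMI", "NBR", "NBR2", "TCB", "TCG", "TCW", "TCA",
)

#: Canonical band order (reflectance bands first, then indices).  Used for
#: metric-vector layout and deterministic tie-breaking in importance ranking.
ALL_BANDS: tuple[str, ...] = REFLECTANCE_BANDS + DERIVED_BANDS

#: Change classes predicted by the model.
CHANGE_CLASSES: tuple[str, ...] = ("DEF", "DEG", "NOCH")

#: All labels a location can carry (NONFOREST is excluded from modelling).
ALL_LABELS: tuple[str, ...] = CHANGE_CLASSES + ("NONFOREST",)

#: Origin (decimal years) for trend intercepts.
BASELINE_YEAR: float = 1999.0

#: The six spectral-temporal metrics derived per band.
METRIC_NAMES: tuple[str, ...] = (
    "rlm_intercept", "rlm_slope", "gamma1", "gamma2", "beta1", "beta2",
)


class InsufficientDataError(ValueError):
    """A series is too short for the requested fit."""


class SeasonalUnidentifiableError(ValueError):
    """The observation window is too short to identify an annual cycle."""


def decimal_year(date: _dt.date) -> float:
    """Convert a calendar date to decimal years (year + doy/365.25)."""
    doy = date.timetuple().tm_yday
    return date.year + doy / 365.25


def from_decimal_year(t: float) -> _dt.date:
    """Approximate inverse of :func:`decimal_year` (nearest day)."""
    year = int(np.floor(t))
    doy = int(round((t - year) * 365.25))
    doy = min(max(doy, 1), 365 + int(_is_leap(year)))
    return _dt.date(year, 1, 1) + _dt.timedelta(days=doy - 1)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


@dataclass(frozen=True)
class IrregularTimeSeries:
    """Ordered (time, value) observations for one pixel and one band.

    Parameters
    ----------
    times
        Decimal years, strictly increasing.
    values
        Surface reflectance or index values; no NaN/inf stored.
    band
        Band name from :data:`ALL_BANDS`.
    """

    times: np.ndarray
    values: np.ndarray
    band: str = "NDVI"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise ValueError("times and values must be 1-D and equal length")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Observation window length in years (0 for empty series)."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0


@dataclass
class SceneStack:
    """Dated multi-band raster cube with per-date validity masks.

    ``bands`` maps band name to a float array of shape
    ``(n_dates, n_rows, n_cols)``; ``valid_mask`` is boolean with the same
    shape semantics and is shared across bands (one gap pattern per date).
    Invalid observations are stored as NaN.
    """

    dates: np.ndarray
    bands: dict[str, np.ndarray]
    valid_mask: np.ndarray
    sensors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype=float)
        if self.dates.ndim != 1:
            raise ValueError("dates must be 1-D")
        if np.any(np.diff(self.dates) < 0):
            raise ValueError("dates must be sorted ascending")
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        shape = (self.n_dates, *self.shape)
        if self.valid_mask.shape != shape:
            raise ValueError("valid_mask shape mismatch")
        for name, grid in self.bands.items():
            if grid.shape != shape:
                raise ValueError(f"band {name!r} shape mismatch")
        if not self.sensors:
            self.sensors = ["SYN"] * self.n_dates

    @property
    def n_dates(self) -> int:
        return int(self.dates.size)

    @property
    def shape(self) -> tuple[int, int]:
        grid = next(iter(self.bands.values()))
        return grid.shape[1], grid.shape[2]
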