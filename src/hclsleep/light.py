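"""Reading, cleaning, transforming and synthesizing light time series.

The model is driven by minute-resolution environmental light (lux).  This
module provides the :class:`LightSeries` container with a piecewise-linear
interpolation contract, zero-value imputation during reported wake, smooth
two-level synthetic day/evening profiles, and light interventions
(e.g. evening light reduction, morning light enhancement).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import SECONDS_PER_DAY, SECONDS_PER_HOUR

logger = logging.getLogger(__name__)


class LightFormatError(ValueError):
    """Raised when an input light CSV is malformed."""


class LightValidationError(ValueError):
    """Raised when light values violate the LightSeries invariants."""


@dataclass
class LightSeries:
    """Timestamped minute-resolution lux values for one participant.

    Parameters
    ----------
    participant_id : str
        Opaque label.
    times : pandas.DatetimeIndex
        Strictly increasing timestamps at nominal 1-min spacing (gaps are
        allowed and preserved; no silent filling).
    lux : numpy.ndarray
        Non-negative light intensity per sample.
    source : str
        One of ``{"wrist", "shoulder", "synthetic"}``.
    """

    participant_id: str
    times: pd.DatetimeIndex
    lux: np.ndarray
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.lux = np.asarray(self.lux, dtype=float)
        if len(self.times) != len(self.lux):
            raise LightValidationError("times and lux must have equal length")
        if len(self.times) >= 2 and not self.times.is_monotonic_increasing:
            raise LightValidationError("timestamps must be strictly increasing")
        if len(self.times) >= 2 and self.times.has_duplicates:
            raise LightValidationError("timestamps must be strictly increasing")
        if np.any(self.lux < 0):
            bad = int(np.flatnonzero(self.lux < 0)[0])
            raise LightValidationError(f"negative lux at sample {bad}")
        if self.source not in ("wrist", "shoulder", "synthetic"):
            raise LightValidationError(f"unknown source {self.source!r}")

    # -- basic geometry ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.lux)

    @property
    def start(self) -> pd.Timestamp:
        return self.times[0]

    @property
    def duration_seconds(self) -> float:
        return (self.times[-1] - self.times[0]).total_seconds()

    @property
    def n_whole_days(self) -> int:
        """Number of complete days covered (used to truncate simulation
        passes to an integer number of days)."""
        return int(self.duration_seconds // SECONDS_PER_DAY)

    @property
    def t0_clock_hours(self) -> float:
        """Clock time of the first sample in decimal hours."""
        t = self.times[0]
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    def seconds_from_start(self) -> np.ndarray:
        return (self.times - self.times[0]).total_seconds().to_numpy()

    def clock_hours(self) -> np.ndarray:
        """Clock time of each sample in decimal hours [0, 24)."""
        return (self.t0_clock_hours
                + self.seconds_from_start() / SECONDS_PER_HOUR) % 24.0

    def copy_with(self, lux: np.ndarray) -> "LightSeries":
        return LightSeries(self.participant_id, self.times.copy(),
                           np.asarray(lux, dtype=float), self.source)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"timestamp": self.times, "lux": self.lux}).to_csv(
            path, index=False)

    def iter_days(self, anchor_hour: float = 0.0,
                  min_coverage: float = 0.8):
        """Yield (day_start, LightSeries) for each sufficiently covered day.

        Days run from ``anchor_hour`` to ``anchor_hour`` + 24 h (midnight to
        midnight by default).  A day with less than ``min_coverage`` of its
        nominal 1440 samples is excluded and logged.
        """
        start = self.times[0].normalize() + pd.Timedelta(hours=anchor_hour)
        if start > self.times[0]:
            start -= pd.Timedelta(days=1)
        day = start
        while day < self.times[-1]:
            sel = (self.times >= day) & (self.times < day + pd.Timedelta(days=1))
            n = int(sel.sum())
            if n >= min_coverage * 1440:
                yield day, LightSeries(self.participant_id, self.times[sel],
                                       self.lux[sel], self.source)
            elif n > 0:
                logger.info("excluding day %s with %d/1440 samples", day, n)
            day += pd.Timedelta(days=1)


def read_light_csv(path: str | Path, participant_id: str,
                   source: str = "wrist") -> LightSeries:
    """Read a ``timestamp,lux`` CSV into a validated :class:`LightSeries`.

    Malformed rows (unparseable timestamp or lux) are rejected with their
    row numbers reported; negative lux raises a validation error naming the
    offending row.  Gaps in the record are preserved.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "timestamp" not in cols or "lux" not in cols:
        raise LightFormatError(
            f"{path}: expected columns 'timestamp' and 'lux', "
            f"found {list(df.columns)}")
    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce",
                        format="ISO8601")
    lux = pd.to_numeric(df[cols["lux"]], errors="coerce")
    bad = df.index[ts.isna() | lux.isna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # header is row 1
        raise LightFormatError(f"{path}: malformed rows at lines {rows}")
    neg = df.index[lux < 0]
    if len(neg):
        raise LightValidationError(
            f"{path}: negative lux at line {neg[0] + 2}")
    return LightSeries(participant_id, pd.DatetimeIndex(ts), lux.to_numpy(),
                       source=source)


def interpolate_lux(series: LightSeries, t: pd.Timestamp) -> float:
    """Piecewise-linear lux at timestamp ``t``; exact at samples.

    Raises if ``t`` lies outside the recorded range (no extrapolation).
    """
    t = pd.Timestamp(t)
    if t < series.times[0] or t > series.times[-1]:
        raise ValueError(f"timestamp {t} outside recorded range "
                         f"[{series.times[0]}, {series.times[-1]}]")
    ts = series.seconds_from_start()
    return float(np.interp((t - series.times[0]).total_seconds(), ts,
                           series.lux))


def impute_wake_zeros(series: LightSeries,
                      wake_mask: Sequence[bool]) -> LightSeries:
    """Replace zero lux recorded during reported wake by a clock-time median.

    Each sample with ``lux == 0`` and ``wake_mask`` true is replaced by the
    median of all raw samples (across all available days) whose clock time
    lies within +-30 min (inclusive) of the sample's clock time.  Zeros
    during sleep and non-zero values are untouched.  If the pooled window
    median is itself 0 the value is left at 0 and logged.
    """
    wake_mask = np.asarray(wake_mask, dtype=bool)
    if wake_mask.shape != series.lux.shape:
        raise ValueError("wake_mask must align with the light samples")
    clock = series.clock_hours()
    raw = series.lux
    out = raw.copy()
    targets = np.flatnonzero((raw == 0) & wake_mask)
    for i in targets:
        # circular clock-time distance, inclusive half-hour window
        d = np.abs(clock - clock[i])
        d = np.minimum(d, 24.0 - d)
        window = raw[d <= 0.5 + 1e-12]
        med = float(np.median(window))
        if med == 0.0:
            logger.info("imputation window at clock %.2f h has zero median; "
                        "value left at 0", clock[i])
        else:
            out[i] = med
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# Synthetic two-level light availability profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LightProfileSpec:
    """Smooth two-level 24-h periodic light availability profile.

    ``day_level`` lux between ``dawn_time`` and ``dusk_time`` (clock hours),
    ``evening_level`` lux at all other times, with logistic transitions of
    half-width ``transition_width`` minutes.  This represents round-the-clock
    access to electric light with brighter light during daylight hours; the
    day length approximates the natural photoperiod around the equinoxes.
    """

    dawn_time: float = 6.0
    dusk_time: float = 18.0
    day_level: float = 1000.0
    evening_level: float = 40.0
    transition_width: float = 30.0

    def __post_init__(self) -> None:
        if not (self.day_level >= self.evening_level >= 0):
            raise ValueError("require day_level >= evening_level >= 0")
        if not self.dawn_time < self.dusk_time:
            raise ValueError("dawn must precede dusk")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")

    def lux_at(self, clock_hours: float | np.ndarray):
        return synthetic_profile(self, clock_hours)


def synthetic_profile(spec: LightProfileSpec,
                      clock_hours: float | np.ndarray):
    """Evaluate the smooth two-level profile at clock time(s) in hours.

    The profile is 24-h periodic, equals ``day_level`` at midday and
    ``evening_level`` at midnight, and is monotone across each transition.
    """
    t = np.asarray(clock_hours, dtype=float) % 24.0
    w = spec.transition_width / 60.0 / 2.0  # logistic scale, hours
    up = 1.0 / (1.0 + np.exp(-(t - spec.dawn_time) / w))
    down = 1.0 / (1.0 + np.exp((t - spec.dusk_time) / w))
    frac = up * down
    out = spec.evening_level + (spec.day_level - spec.evening_level) * frac
    if np.isscalar(clock_hours):
        return float(out)
    return out


def profile_to_series(spec: LightProfileSpec, n_days: int,
                      participant_id: str = "synthetic",
                      start: str | pd.Timestamp = "2024-03-18") -> LightSeries:
    """Sample a profile at 1-min resolution into a LightSeries of n_days."""
    times = pd.date_range(pd.Timestamp(start), periods=n_days * 1440 + 1,
                          freq="1min")
    clock = (times.hour + times.minute / 60.0).to_numpy()
    return LightSeries(participant_id, times, synthetic_profile(spec, clock),
                       source="synthetic")


# ---------------------------------------------------------------------------
# Interventions
# ---------------------------------------------------------------------------

INTERVENTION_KINDS = ("evening_reduction", "morning_enhancement", "custom")


@dataclass(frozen=True)
class Intervention:
    """Set available light to a fixed level inside a daily clock window.

    ``evening_reduction`` sets 18:00-06:00 to 4 lux; ``morning_enhancement``
    sets 09:30-10:00 to 1000 lux.  Windows may wrap midnight.  All samples
    outside the window keep their original recorded values.
    """

    kind: str = "custom"
    window_start: float = 0.0
    window_end: float = 0.0
    set_level: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in INTERVENTION_KINDS:
            raise ValueError(f"unknown intervention kind {self.kind!r}")
        if self.set_level < 0:
            raise ValueError("set_level must be non-negative")

    @classmethod
    def evening_reduction(cls) -> "Intervention":
        return cls("evening_reduction", 18.0, 6.0, 4.0)

    @classmethod
    def morning_enhancement(cls) -> "Intervention":
        return cls("morning_enhancement", 9.5, 10.0, 1000.0)

    def resolved(self) -> "Intervention":
        if self.kind == "evening_reduction" and self.window_start == self.window_end == 0:
            return Intervention.evening_reduction()
        if self.kind == "morning_enhancement" and self.window_start == self.window_end == 0:
            return Intervention.morning_enhancement()
        return self


def apply_intervention(series: LightSeries, iv: Intervention) -> LightSeries:
    """Apply a light intervention; returns a new LightSeries.

    Samples whose clock time lies in [window_start, window_end) — a window
    that may wrap midnight — are set to ``set_level``; all other values are
    left at their original recorded values.  Idempotent.
    """
    iv = iv.resolved()
    if series.duration_seconds < SECONDS_PER_DAY:
        raise ValueError("intervention requires at least one day of light")
    a, b = iv.window_start % 24.0, iv.window_end % 24.0
    if a == b:
        raise ValueError("empty intervention window")
    clock = series.clock_hours()
    if a < b:
        mask = (clock >= a) & (clock < b)
    else:  # wraps midnight
        mask = (clock >= a) | (clock < b)
    if not mask.any():
        logger.warning("intervention window overlaps no samples; no-op")
        return series.copy_with(series.lux)
    out = series.lux.copy()
    out[mask] = iv.set_level
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# Fast scalar light drivers for the ODE integrator
# ---------------------------------------------------------------------------

class LightFunction:
    """Callable light drive I(t) for the integrator.

    Maps time in seconds since the driver's own origin (clock time
    ``t0_clock_hours``) to lux.  Exposes ``duration_seconds`` where finite.
    """

    t0_clock_hours: float = 0.0
    duration_seconds: float = math.inf

    def __call__(self, t_seconds: float) -> float:  # pragma: no cover
        raise NotImplementedError


class ProfileLight(LightFunction):
    """Periodic synthetic profile driver; origin at midnight."""

    def __init__(self, spec: LightProfileSpec):
        self.spec = spec
        self.t0_clock_hours = 0.0
        # precompute a 1-min lookup table for speed; profile is smooth
        grid = np.arange(0.0, 24.0, 1.0 / 60.0)
        self._grid = grid
        self._vals = synthetic_profile(spec, grid)

    def __call__(self, t_seconds: float) -> float:
        h = (t_seconds / SECONDS_PER_HOUR) % 24.0
        i = h * 60.0
        i0 = int(i)
        frac = i - i0
        i1 = (i0 + 1) % len(self._vals)
        return self._vals[i0] * (1.0 - frac) + self._vals[i1] * frac


class SeriesLight(LightFunction):
    """Linearly interpolated recorded light; origin at the first sample.

    When chained simulation passes run past the end of the truncated
    record, time wraps modulo the integer-day duration.
    """

    def __init__(self, series: LightSeries):
        self._t = series.seconds_from_start()
        self._lux = series.lux
        self.t0_clock_hours = series.t0_clock_hours
        n_days = series.n_whole_days
        self.duration_seconds = max(n_days, 1) * SECONDS_PER_DAY

    def __call__(self, t_seconds: float) -> float:
        t = t_seconds % self.duration_seconds
        return float(np.interp(t, self._t, self._lux))


def as_light_function(light) -> LightFunction:
    """Coerce a LightSeries or LightProfileSpec to a LightFunction."""
    if isinstance(light, LightFunction):
        return light
    if isinstance(light, LightProfileSpec):
        return ProfileLight(light)
    if isinstance(light, LightSeries):
        return SeriesLight(light)
    raise TypeError(f"cannot interpret {type(light).__name__} as light input")
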