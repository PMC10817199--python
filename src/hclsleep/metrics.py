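"""Daily light-exposure metrics.

Five standard metrics per complete day of data — hours of bright light
(> 500 lux), mean lux, geometric mean (10 to the power of the mean of
log10(lux + 1)), and the clock times at which half the cumulative daily lux
and half the cumulative daily log10(lux + 1) are reached — plus a
model-based metric of the *biological effect* of light.

The biological-effect metric feeds one day of light into the free-running
light-circadian model (no sleep gating) from a fixed reference state — the
pacemaker state at midnight of an entrained 'average person' with mid-sleep
04:30 and sleep duration 8.22 h — and integrates for 24 h.  If the clock
covers more than one full cycle the light pattern has a net speeding-up
effect (positive minutes); less than one cycle, a net slowing-down effect
(negative minutes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import defaults
from .light import LightSeries, SeriesLight, as_light_function
from .pacemaker import cycles_completed, light_circadian_rhs
from .params import SECONDS_PER_DAY, SECONDS_PER_HOUR, ModelParams

logger = logging.getLogger(__name__)

BRIGHT_LUX = 500.0


@dataclass(frozen=True)
class ReferenceState:
    """Pacemaker state (x, y, n) at midnight for the entrained reference
    person (mid-sleep 04:30, sleep duration 8.22 h, default light profile)."""

    x0: float
    y0: float
    n0: float

    def __post_init__(self):
        if not 0.0 <= self.n0 <= 1.0:
            raise ValueError("photoreceptor fraction n0 must lie in [0, 1]")


def default_reference_state() -> ReferenceState:
    return ReferenceState(*defaults.reference_state())


@dataclass
class DailyLightMetrics:
    hours_bright: float
    mean_lux: float
    geometric_mean: float
    t_half_lux: float
    t_half_loglux: float
    bio_effect: float = math.nan

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("hours_bright", "mean_lux", "geometric_mean",
                 "t_half_lux", "t_half_loglux", "bio_effect")}


def _half_time(hours: np.ndarray, values: np.ndarray) -> float:
    """Clock time at which the piecewise-linear cumulative curve of
    ``values`` reaches half its day total (continuous time)."""
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (values[1:] + values[:-1]) * np.diff(hours))])
    total = cum[-1]
    if total <= 0:
        return math.nan
    return float(np.interp(total / 2.0, cum, hours))


def standard_daily_metrics(day: LightSeries) -> DailyLightMetrics:
    """The five standard light metrics for one day of data.

    ``hours_bright`` counts samples above 500 lux; logs are base 10; the
    half-light times are computed on the piecewise-linear cumulative curve
    over the day window.
    """
    if len(day) == 0:
        raise ValueError("empty day of light data")
    lux = day.lux
    secs = day.seconds_from_start()
    hours = day.t0_clock_hours + secs / SECONDS_PER_HOUR
    dt_hours = float(np.median(np.diff(secs))) / SECONDS_PER_HOUR if len(secs) > 1 else 1 / 60
    loglux = np.log10(lux + 1.0)
    return DailyLightMetrics(
        hours_bright=float(np.sum(lux > BRIGHT_LUX) * dt_hours),
        mean_lux=float(lux.mean()),
        geometric_mean=float(10.0 ** loglux.mean()),
        t_half_lux=_half_time(hours, lux) % 24.0,
        t_half_loglux=_half_time(hours, loglux) % 24.0,
    )


def cycles_to_minutes(cycles: float) -> float:
    """Convert the fraction of a circadian cycle covered in 24 h to the
    signed biological-effect metric in minutes.

    One full cycle maps to 0; e.g. completing 98.13% of a cycle means the
    clock is 26.9 min slow over the day, recorded as -27 after rounding.
    """
    return (cycles - 1.0) * 24.0 * 60.0


def biological_effect(day, ref: ReferenceState | None = None,
                      params: ModelParams | None = None,
                      rtol: float = 1e-7, atol: float = 1e-9) -> float:
    """Biological effect of one day of light on the circadian clock, minutes.

    Integrates the light-circadian system (S = 0 throughout: the metric
    evaluates the light pattern itself, not its interaction with sleep) for
    24 h from the reference state, counts the unwrapped pacemaker phase
    advance, and converts (cycles - 1) to minutes.
    """
    params = params or ModelParams()
    ref = ref or default_reference_state()
    lf = as_light_function(day)
    if isinstance(day, LightSeries):
        if day.duration_seconds < SECONDS_PER_DAY - 61:
            raise ValueError("biological_effect requires a full 24 h of light")
    rhs = light_circadian_rhs(params, lf)
    ts = np.linspace(0.0, SECONDS_PER_DAY, 24 * 60 + 1)
    sol = solve_ivp(rhs, (0.0, SECONDS_PER_DAY), [ref.x0, ref.y0, ref.n0],
                    method="LSODA", rtol=rtol, atol=atol, t_eval=ts,
                    max_step=600.0)
    if not sol.success:
        raise RuntimeError(f"light-circadian integration failed: {sol.message}")
    return cycles_to_minutes(cycles_completed(sol.y[0], sol.y[1]))


def daily_metrics_table(series: LightSeries,
                        ref: ReferenceState | None = None,
                        params: ModelParams | None = None,
                        anchor_hour: float = 0.0,
                        with_bio_effect: bool = True,
                        min_coverage: float = 0.8) -> pd.DataFrame:
    """One row of light metrics per sufficiently covered day.

    The biological-effect metric uses the same fixed reference state for
    every day and every participant, so values are comparable across both.
    """
    rows = []
    for day_start, day in series.iter_days(anchor_hour=anchor_hour,
                                           min_coverage=min_coverage):
        m = standard_daily_metrics(day)
        if with_bio_effect and len(day) >= 1380:
            try:
                m.bio_effect = biological_effect(day, ref=ref, params=params)
            except ValueError as exc:
                logger.info("bio_effect skipped for %s: %s", day_start, exc)
        rows.append({"day": day_start, **m.to_dict()})
    if not rows:
        raise ValueError("no day with sufficient coverage")
    return pd.DataFrame(rows)


def compute_reference_state(params: ModelParams | None = None,
                            mid_sleep: float = 28.5,
                            duration: float = 8.22) -> ReferenceState:
    """Compute the reference pacemaker state at midnight.

    Entrains the full HCL model on the default synthetic profile with
    (mu, tauc) adjusted so that the converged mean mid-sleep is 04:30 and
    the mean duration 8.22 h, then reads (x, y, n) at midnight of the final
    converged day.  The shipped default in :mod:`hclsleep.defaults` caches
    the result for the default parameters.
    """
    from .calibration import default_profile
    from .fitting import FitTargets, fit_mu_tauc
    params = params or ModelParams()
    fit = fit_mu_tauc(default_profile(), FitTargets(duration, mid_sleep),
                      params0=params, keep_sim=True)
    if not fit.converged or fit.sim is None or not fit.sim.entrained:
        raise RuntimeError("reference person failed to entrain at the "
                           "requested mid-sleep and duration")
    sim = fit.sim
    # last midnight in the converged pass
    midnights = sim.t[np.isclose(sim.t % 24.0, 0.0, atol=1e-6)]
    t_mid = midnights[-1]
    x0 = float(np.interp(t_mid, sim.t, sim.x))
    y0 = float(np.interp(t_mid, sim.t, sim.y))
    n0 = float(np.interp(t_mid, sim.t, sim.n))
    return ReferenceState(x0, y0, min(max(n0, 0.0), 1.0))
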