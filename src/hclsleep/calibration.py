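"""Calibration of the default wake-propensity waveform C(t).

The circadian modulation of the switching thresholds is a quadratic form
C(x, y) in the pacemaker variables.  Its coefficients are obtained by
least-squares fitting a circadian wake-propensity template to the entrained
pacemaker cycle:

1. The free-running (S = 0, no sleep gating) light-circadian system is
   entrained to the default two-level light profile, giving the pacemaker
   cycle (x(t), y(t)) against clock time.
2. A template waveform — an asymmetric (time-warped) cosine with its
   maximum in the late evening, its minimum in the second half of the night
   and peak-to-peak amplitude 2 — is fitted by the quadratic form over that
   cycle.
3. The template phase is then calibrated so that the full HCL model with
   default parameters and the default profile settles to a mean mid-sleep
   time of 03:16, the value the default parameter set is defined to
   reproduce for people aged ~65 y.

The resulting coefficients are frozen in :mod:`hclsleep.defaults`.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .light import LightProfileSpec, ProfileLight
from .pacemaker import fit_wake_propensity_coeffs, light_circadian_rhs
from .params import (SECONDS_PER_DAY, SECONDS_PER_HOUR, ModelParams,
                     WakePropensityCoeffs)

#: Mean mid-sleep time the default model is calibrated to, noon-anchored
#: hours (03:16).
DEFAULT_MID_SLEEP_TARGET = 24.0 + 3.0 + 16.0 / 60.0

#: Template extrema: maximum ~1.5 h before a habitual ~23:15 sleep onset,
#: minimum in the second half of the night.
TEMPLATE_MAX_CLOCK = 21.75
TEMPLATE_MIN_CLOCK = 28.5  # 04:30


def default_profile(evening_level: float | None = None,
                    day_level: float | None = None) -> LightProfileSpec:
    """The default synthetic light availability profile."""
    from .defaults import (DEFAULT_DAWN, DEFAULT_DAY_LUX, DEFAULT_DUSK,
                           DEFAULT_EVENING_LUX)
    return LightProfileSpec(
        dawn_time=DEFAULT_DAWN, dusk_time=DEFAULT_DUSK,
        day_level=DEFAULT_DAY_LUX if day_level is None else day_level,
        evening_level=(DEFAULT_EVENING_LUX if evening_level is None
                       else evening_level))


def wake_propensity_template(clock_hours, max_clock: float = TEMPLATE_MAX_CLOCK,
                             min_clock: float = TEMPLATE_MIN_CLOCK):
    """Asymmetric circadian wake-propensity template.

    A cosine warped in phase so that its maximum (+1) falls at
    ``max_clock`` and its minimum (-1) at ``min_clock``; rising over the
    long day branch and falling over the short night branch, matching the
    observed shape of the circadian drive for wakefulness (rising through
    the day, collapsing across the night).
    """
    h = np.asarray(clock_hours, dtype=float)
    fall_len = (min_clock - max_clock) % 24.0
    rise_len = 24.0 - fall_len
    since_max = (h - max_clock) % 24.0
    theta = np.where(
        since_max < fall_len,
        np.pi * since_max / fall_len,
        np.pi + np.pi * (since_max - fall_len) / rise_len,
    )
    out = np.cos(theta)
    return float(out) if np.isscalar(clock_hours) else out


def entrained_pacemaker_cycle(params: ModelParams,
                              profile: LightProfileSpec,
                              settle_days: int = 30,
                              n_samples: int = 1440,
                              ) -> tuple[np.ndarray, np.ndarray,
                                         np.ndarray, np.ndarray]:
    """Entrain the free-running (S = 0) light-circadian system and return
    one day of the cycle.

    Returns ``(clock_hours, x, y, n)`` sampled over the final 24 h; also
    used to obtain the reference pacemaker state at midnight.
    """
    lf = ProfileLight(profile)
    rhs = light_circadian_rhs(params, lf)
    t_end = settle_days * SECONDS_PER_DAY
    sol = solve_ivp(rhs, (0.0, t_end), [1.0, 0.0, 0.1], method="LSODA",
                    rtol=1e-8, atol=1e-8, max_step=600.0)
    s_last = sol.y[:, -1]
    ts = np.linspace(0.0, SECONDS_PER_DAY, n_samples, endpoint=False)
    sol2 = solve_ivp(rhs, (0.0, SECONDS_PER_DAY), s_last, method="LSODA",
                     rtol=1e-8, atol=1e-8, t_eval=ts, max_step=600.0)
    clock = ts / SECONDS_PER_HOUR % 24.0
    return clock, sol2.y[0], sol2.y[1], sol2.y[2]


def fit_template_coeffs(params: ModelParams, profile: LightProfileSpec,
                        phase_shift_hours: float = 0.0,
                        ) -> tuple[WakePropensityCoeffs, float]:
    """Fit the quadratic form to the (possibly phase-shifted) template over
    the entrained pacemaker cycle."""
    clock, x, y, _ = entrained_pacemaker_cycle(params, profile)
    target = wake_propensity_template(clock - phase_shift_hours)
    return fit_wake_propensity_coeffs(target, x, y)


def calibrate_defaults(params: ModelParams | None = None,
                       profile: LightProfileSpec | None = None,
                       mid_sleep_target: float = DEFAULT_MID_SLEEP_TARGET,
                       shift_bracket: tuple[float, float] = (-7.0, -4.0),
                       tol_minutes: float = 0.5,
                       n_rounds: int = 4,
                       ) -> tuple[WakePropensityCoeffs, float]:
    """Calibrate the default wake-propensity coefficients.

    Alternates two steps until self-consistent:

    1. root-find the template phase shift so that the full model, with the
       current amplitude scaling, settles to the target mean mid-sleep time
       (03:16) under the default profile;
    2. rescale and recentre the quadratic form so that C over the
       converged entrained cycle has peak-to-peak amplitude exactly 2 and
       zero mean.

    Returns the frozen coefficients and the final phase shift (hours).
    """
    from .pacemaker import wake_propensity_xy
    from .simulate import circular_diff_hours, simulate_to_convergence
    params = params or ModelParams()
    profile = profile or default_profile()

    scale, center = 1.0, 0.0
    raw_cache: dict[float, WakePropensityCoeffs] = {}

    def coeffs_at(delta: float) -> WakePropensityCoeffs:
        if delta not in raw_cache:
            raw_cache[delta] = fit_template_coeffs(params, profile, delta)[0]
        c = raw_cache[delta]
        return WakePropensityCoeffs(
            c20=scale * c.c20 - center, a21=scale * c.a21,
            a22=scale * c.a22, b21=scale * c.b21, b22=scale * c.b22,
            b23=scale * c.b23)

    def run(delta: float):
        sim = simulate_to_convergence(params, profile, coeffs=coeffs_at(delta))
        if not sim.episodes:
            raise RuntimeError("default model produced no sleep episodes "
                               "during calibration")
        return sim

    def mid_err(delta: float) -> float:
        return circular_diff_hours(run(delta).mean_mid_sleep,
                                   mid_sleep_target)

    delta = shift_bracket[0]
    for _ in range(n_rounds):
        lo, hi = shift_bracket
        e_lo, e_hi = mid_err(lo), mid_err(hi)
        if e_lo * e_hi > 0:
            raise RuntimeError(
                f"calibration bracket does not straddle the target "
                f"mid-sleep: err({lo})={e_lo:.3f} h, err({hi})={e_hi:.3f} h")
        delta = float(brentq(mid_err, lo, hi, xtol=tol_minutes / 60.0 / 6.0))
        # measure C over the converged entrained cycle and renormalize
        sim = run(delta)
        sel = sim.t > sim.t[-1] - 24.0
        C = wake_propensity_xy(sim.x[sel], sim.y[sel], coeffs_at(delta))
        pp, mean = float(np.ptp(C)), float(C.mean())
        if abs(pp - 2.0) < 0.02 and abs(mean) < 0.02:
            break
        r = 2.0 / pp
        scale *= r
        center = r * (center + mean)
    return coeffs_at(delta), delta
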