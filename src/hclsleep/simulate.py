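"""Hybrid simulation of the HCL model: the sleep homeostat switching at
circadian-modulated thresholds, coupled to the light-forced pacemaker.

The continuous state is (H, x, y, n); the discrete state is the sleep
indicator S.  Switching from wake to sleep occurs when H reaches the upper
threshold H+ = H0bar + Delta/2 + ca*C(x, y) from below, and from sleep to
wake when H reaches H- = H0bar - Delta/2 + ca*C(x, y) from above.  Sleep
gates light (eyes closed), so sleep timing feeds back on circadian phase.

Integration uses a stiff-capable solver (LSODA) with event location at the
threshold crossings; default relative/absolute tolerances are 1e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .defaults import default_coeffs
from .light import LightFunction, as_light_function
from .pacemaker import unforced_limit_cycle, wake_propensity_xy
from .params import (KAPPA, SECONDS_PER_DAY, SECONDS_PER_HOUR, ModelParams,
                     WakePropensityCoeffs)

__all__ = [
    "SleepEpisode", "SimResult", "thresholds", "simulate",
    "simulate_to_convergence", "episode_metrics", "circadian_minimum_times",
    "rise_fall_ratio", "parameter_sweep", "entrainment_edge",
    "default_initial_state", "simulate_fixed_schedule",
]


def thresholds(C: float, params: ModelParams) -> tuple[float, float]:
    """Upper and lower switching thresholds at wake-propensity value C."""
    base = params.H0bar + params.ca * C
    return base + 0.5 * params.Delta, base - 0.5 * params.Delta


def noon_anchored(clock_hours):
    """Map clock hours into the noon-anchored window [12, 36).

    Night-time clock values (before noon) gain 24 h so that means and SDs of
    sleep times spanning midnight are computed without wrap artefacts.
    """
    c = np.asarray(clock_hours, dtype=float) % 24.0
    out = np.where(c < 12.0, c + 24.0, c)
    return float(out) if np.isscalar(clock_hours) else out


def circular_diff_hours(a: float, b: float) -> float:
    """Signed shortest-arc difference a - b between clock hours."""
    return (a - b + 12.0) % 24.0 - 12.0


@dataclass(frozen=True)
class SleepEpisode:
    """One sleep episode on the absolute time axis (hours since midnight of
    the simulation's first day; values beyond 24 simply continue counting)."""

    onset: float
    offset: float

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("episode offset must follow onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def mid(self) -> float:
        return 0.5 * (self.onset + self.offset)

    @property
    def mid_sleep(self) -> float:
        """Mid-sleep clock time in the noon-anchored window [12, 36)."""
        return noon_anchored(self.mid % 24.0)


@dataclass
class SimResult:
    """Trajectory, sleep episodes and summary statistics of one simulation.

    Times in ``t`` are absolute hours (same axis as the episodes); the
    trajectory columns are H, x, y, n, C and S sampled on a regular grid.
    """

    t: np.ndarray
    H: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n: np.ndarray
    C: np.ndarray
    S: np.ndarray
    episodes: list[SleepEpisode]
    t0_clock: float
    params: ModelParams
    coeffs: WakePropensityCoeffs
    final_state: tuple[float, float, float, float]  # (H, x, y, n)
    final_S: int
    passes: int = 1
    entrained: bool | None = None
    #: (t_abs_hours, H, x, y, n, new_S) at each located threshold crossing
    switch_states: list[tuple] = field(default_factory=list)

    mean_duration: float = math.nan
    sd_duration: float = math.nan
    mean_mid_sleep: float = math.nan
    sd_mid_sleep: float = math.nan

    def __post_init__(self):
        if self.episodes:
            m = episode_metrics(self.episodes)
            self.mean_duration = m["mean_duration"]
            self.sd_duration = m["sd_duration"]
            self.mean_mid_sleep = m["mean_mid_sleep"]
            self.sd_mid_sleep = m["sd_mid_sleep"]

    @property
    def circadian_minima(self) -> list[float]:
        return circadian_minimum_times(self)

    def to_dict(self) -> dict:
        return {
            "episodes": [{"onset": e.onset, "offset": e.offset,
                          "duration": e.duration,
                          "mid_sleep": e.mid_sleep} for e in self.episodes],
            "mean_duration": self.mean_duration,
            "sd_duration": self.sd_duration,
            "mean_mid_sleep": self.mean_mid_sleep,
            "sd_mid_sleep": self.sd_mid_sleep,
            "entrained": self.entrained,
            "passes": self.passes,
            "params": self.params.to_dict(),
            "coeffs": self.coeffs.to_dict(),
        }


def episode_metrics(episodes: list[SleepEpisode]) -> dict:
    """Clock-time means and SDs of onset, offset, mid-sleep and duration.

    Clock statistics are computed in the noon-anchored window [12, 36) so
    that times either side of midnight average correctly.
    """
    if not episodes:
        raise ValueError("episode_metrics requires at least one episode")
    onset = noon_anchored([e.onset % 24.0 for e in episodes])
    offset = noon_anchored([e.offset % 24.0 for e in episodes])
    mid = np.array([e.mid_sleep for e in episodes])
    dur = np.array([e.duration for e in episodes])
    return {
        "mean_onset": float(onset.mean()), "sd_onset": float(onset.std()),
        "mean_offset": float(offset.mean()), "sd_offset": float(offset.std()),
        "mean_mid_sleep": float(mid.mean()), "sd_mid_sleep": float(mid.std()),
        "mean_duration": float(dur.mean()), "sd_duration": float(dur.std()),
        "n_episodes": len(episodes),
    }


# ---------------------------------------------------------------------------
# Default initial conditions
# ---------------------------------------------------------------------------

_INIT_CACHE: dict = {}


def default_initial_state(params: ModelParams,
                          coeffs: WakePropensityCoeffs | None = None,
                          ) -> tuple[float, float, float, float]:
    """Default initial state (H, x, y, n) for simulations starting at
    midnight.

    H starts at the threshold mean level H0bar and n at 0 (dark-adapted).
    (x, y) is placed on the unforced limit cycle at the phase where the
    wake-propensity rhythm crosses its mean going downward — the cycle's
    subjective midnight, between the evening maximum and the late-night
    minimum of C.  Transients are removed downstream by repeated passes.
    """
    coeffs = coeffs or default_coeffs()
    key = (params.tauc, params.f, params.gamma, coeffs.as_tuple())
    if key not in _INIT_CACHE:
        cx, cy = unforced_limit_cycle(params, n_samples=720)
        C = wake_propensity_xy(cx, cy, coeffs)
        dev = C - C.mean()
        down = np.flatnonzero((dev[:-1] > 0) & (dev[1:] <= 0))
        i = int(down[0]) if len(down) else 0
        _INIT_CACHE[key] = (float(cx[i]), float(cy[i]))
    x0, y0 = _INIT_CACHE[key]
    return (params.H0bar, x0, y0, 0.0)


# ---------------------------------------------------------------------------
# Core hybrid integrator
# ---------------------------------------------------------------------------

def simulate(params: ModelParams, light, n_days: int | None = None,
             coeffs: WakePropensityCoeffs | None = None,
             init: tuple[float, float, float, float] | None = None,
             init_S: int = 0,
             rtol: float = 1e-4, atol: float = 1e-4,
             traj_dt: float = 60.0, max_step: float = 1800.0) -> SimResult:
    """Integrate the HCL model for ``n_days`` under the given light input.

    ``light`` may be a LightSeries, a LightProfileSpec or a LightFunction.
    The wake->sleep and sleep->wake switches are located by the solver's
    event detection; light is gated off during sleep.  The returned
    trajectory is sampled every ``traj_dt`` seconds.
    """
    coeffs = coeffs or default_coeffs()
    lf = as_light_function(light)
    if n_days is None:
        if not math.isfinite(lf.duration_seconds):
            raise ValueError("n_days is required for periodic profile input")
        n_days = int(lf.duration_seconds // SECONDS_PER_DAY)
    if n_days < 1:
        raise ValueError("light must cover at least one full day")
    t_end = n_days * SECONDS_PER_DAY

    mu, chi = params.mu, params.chi
    G, p_exp, kshape, b = params.G, params.p, params.k, params.b
    gamma, alpha0, beta, I0 = params.gamma, params.alpha0, params.beta, params.I0
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2
    c20, a21, a22, b21, b22, b23 = coeffs.as_tuple()
    H0bar, Delta, ca = params.H0bar, params.Delta, params.ca
    hi_off = H0bar + 0.5 * Delta
    lo_off = H0bar - 0.5 * Delta

    def _C(x, y):
        return c20 + a21 * x + a22 * y + b21 * x * x + b22 * x * y + b23 * y * y

    def rhs_wake(t, s):
        H, x, y, n = s
        I = lf(t)
        a = alpha0 * (I / I0) ** p_exp if I > 0 else 0.0
        Bhat = G * 60.0 * a * (1.0 - n)  # drive on the per-minute scale
        B = (1.0 - b * x) * (1.0 - b * y) * Bhat
        return ((mu - H) / chi,
                (gamma * (x - 4.0 * x ** 3 / 3.0) - y * (omega0_sq + kshape * B)) / KAPPA,
                (x + B) / KAPPA,
                a * (1.0 - n) - beta * n)

    def rhs_sleep(t, s):
        H, x, y, n = s
        return (-H / chi,
                (gamma * (x - 4.0 * x ** 3 / 3.0) - y * omega0_sq) / KAPPA,
                x / KAPPA,
                -beta * n)

    def ev_to_sleep(t, s):
        return s[0] - (hi_off + ca * _C(s[1], s[2]))
    ev_to_sleep.terminal = True
    ev_to_sleep.direction = 1.0

    def ev_to_wake(t, s):
        return s[0] - (lo_off + ca * _C(s[1], s[2]))
    ev_to_wake.terminal = True
    ev_to_wake.direction = -1.0

    if init is None:
        init = default_initial_state(params, coeffs)
    state = np.asarray(init, dtype=float)
    S = int(init_S)
    # if the initial H already lies beyond the active threshold, switch
    if S == 0 and ev_to_sleep(0.0, state) > 0:
        S = 1
    elif S == 1 and ev_to_wake(0.0, state) < 0:
        S = 0

    grid = np.arange(0.0, t_end + 0.5 * traj_dt, traj_dt)
    Hs = np.empty_like(grid)
    xs = np.empty_like(grid)
    ys = np.empty_like(grid)
    ns = np.empty_like(grid)
    Ss = np.zeros_like(grid, dtype=int)
    gi = 0  # next grid index to fill

    t = 0.0
    onsets: list[float] = []
    offsets: list[float] = []
    switch_states: list[tuple] = []
    if S == 1:
        onsets.append(0.0)  # simulation starts mid-sleep
    max_segments = 10 * n_days + 20
    for _ in range(max_segments):
        if t >= t_end:
            break
        rhs = rhs_sleep if S == 1 else rhs_wake
        ev = ev_to_wake if S == 1 else ev_to_sleep
        sol = solve_ivp(rhs, (t, t_end), state, method="LSODA",
                        rtol=rtol, atol=atol, events=ev, max_step=max_step,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t / 3600:.2f} h: "
                               f"{sol.message}")
        seg_end = sol.t[-1]
        while gi < len(grid) and grid[gi] <= seg_end + 1e-9:
            v = sol.sol(min(grid[gi], seg_end))
            Hs[gi], xs[gi], ys[gi], ns[gi] = v
            Ss[gi] = S
            gi += 1
        state = sol.y[:, -1]
        if np.abs(state[1]) > 10.0 or state[0] > 1e3:
            raise RuntimeError("state blow-up during integration")
        t = seg_end
        if sol.t_events[0].size:  # threshold crossing located
            t = float(sol.t_events[0][0])
            state = sol.y_events[0][0].copy()
            if S == 0:
                onsets.append(t)
                S = 1
            else:
                offsets.append(t)
                S = 0
            switch_states.append((lf.t0_clock_hours + t / SECONDS_PER_HOUR,
                                  *(float(v) for v in state), S))
    else:
        raise RuntimeError("event alternation failed to terminate")

    # clamp n into [0,1] against solver tolerance excursions
    np.clip(ns, 0.0, 1.0, out=ns)
    t0_clock = lf.t0_clock_hours
    episodes = []
    for on, off in zip(onsets, offsets):
        if on == 0.0:
            continue  # episode already in progress at t=0; onset unknown
        episodes.append(SleepEpisode(t0_clock + on / SECONDS_PER_HOUR,
                                     t0_clock + off / SECONDS_PER_HOUR))
    t_abs = t0_clock + grid / SECONDS_PER_HOUR
    C_traj = wake_propensity_xy(xs, ys, coeffs)
    return SimResult(t=t_abs, H=Hs, x=xs, y=ys, n=ns, C=C_traj, S=Ss,
                     episodes=episodes, t0_clock=t0_clock, params=params,
                     coeffs=coeffs,
                     final_state=tuple(float(v) for v in state),
                     final_S=S, switch_states=switch_states)


# ---------------------------------------------------------------------------
# Convergence over repeated passes of the light record
# ---------------------------------------------------------------------------

def simulate_to_convergence(params: ModelParams, light,
                            coeffs: WakePropensityCoeffs | None = None,
                            init: tuple | None = None, init_S: int = 0,
                            tol_minutes: float = 1.0, max_passes: int = 50,
                            pass_days: int | None = None,
                            entrain_window_days: int = 7,
                            drift_tol_minutes: float = 5.0,
                            **sim_kwargs) -> SimResult:
    """Integrate repeated passes of the light record until the mean sleep
    duration and mean mid-sleep time converge.

    The light record is truncated to an integer number of days; the final
    state of each pass seeds the next, so circadian phase carries over.
    Convergence requires successive-pass changes in both mean duration and
    mean mid-sleep below ``tol_minutes``.  The result is flagged
    ``entrained`` when converged and the mid-sleep drift over the final
    ``entrain_window_days`` stays below ``drift_tol_minutes`` per day;
    non-convergence is a reported state, not an exception.
    """
    coeffs = coeffs or default_coeffs()
    lf = as_light_function(light)
    if pass_days is None:
        pass_days = (int(lf.duration_seconds // SECONDS_PER_DAY)
                     if math.isfinite(lf.duration_seconds) else 7)
    if pass_days < 1:
        raise ValueError("light must cover at least one full day")

    state, S = init, init_S
    prev_dur = prev_mid = None
    converged = False
    recent: list[list[SleepEpisode]] = []  # episodes of recent passes
    sim = None
    n_pass = 0
    for n_pass in range(1, max_passes + 1):
        sim = simulate(params, lf, n_days=pass_days, coeffs=coeffs,
                       init=state, init_S=S, **sim_kwargs)
        state, S = sim.final_state, sim.final_S
        recent.append(sim.episodes)
        if len(recent) * pass_days > 2 * max(entrain_window_days, pass_days):
            recent.pop(0)
        if sim.episodes:
            dur, mid = sim.mean_duration, sim.mean_mid_sleep
            if prev_dur is not None:
                d_dur = abs(dur - prev_dur)
                d_mid = abs(circular_diff_hours(mid, prev_mid))
                if max(d_dur, d_mid) < tol_minutes / 60.0:
                    converged = True
                    break
            prev_dur, prev_mid = dur, mid

    # entrainment: systematic mid-sleep drift over the final window, as the
    # slope of mid-sleep clock deviation against day number (robust to
    # night-to-night jitter induced by non-periodic light)
    entrained = False
    if converged and sim is not None and sim.episodes:
        mids = []
        for k, eps in enumerate(reversed(recent)):
            off = -k * pass_days * 24.0
            mids.extend(e.mid + off for e in eps)
        mids = np.sort(np.asarray(mids))
        window = mids[mids > mids[-1] - entrain_window_days * 24.0 - 1.0]
        if len(window) >= 3:
            day_no = np.round((window - window[0]) / 24.0)
            dev = window - 24.0 * day_no
            gaps_ok = bool(np.all(np.diff(day_no) <= 2.0)
                           and np.ptp(dev) < 6.0)
            slope = float(np.polyfit(day_no, dev, 1)[0])
            entrained = gaps_ok and abs(slope) < drift_tol_minutes / 60.0
        else:
            entrained = len(window) >= 1
    sim = sim if sim is not None else simulate(
        params, lf, n_days=pass_days, coeffs=coeffs, init=init, init_S=init_S,
        **sim_kwargs)
    sim.passes = n_pass
    sim.entrained = entrained
    return sim


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def circadian_minimum_times(sim: SimResult) -> list[float]:
    """Per 24-h window, the absolute time (hours) at which C is minimal."""
    out = []
    start = sim.t[0]
    while start < sim.t[-1] - 1.0:
        sel = (sim.t >= start) & (sim.t < start + 24.0)
        if sel.sum() > 2:
            i = np.argmin(sim.C[sel])
            out.append(float(sim.t[sel][i]))
        start += 24.0
    return out


def rise_fall_ratio(sim: SimResult) -> float:
    """Ratio of the mean rate of rise of sleep pressure during wake to the
    mean rate of fall during sleep.

    On an entrained periodic solution the net change of H over a period is
    zero, so this ratio equals (sleep duration)/(wake duration).
    """
    if sim.entrained is False:
        raise ValueError("rise/fall ratio requires an entrained solution")
    eps = sim.episodes
    if len(eps) < 2:
        raise ValueError("need at least two episodes")
    H_at = lambda t: float(np.interp(t, sim.t, sim.H))
    # full cycles from onset_1 to onset_m contain sleeps 1..m-1 and the
    # wake intervals between consecutive episodes
    rise_dH = rise_T = fall_dH = fall_T = 0.0
    for e in eps[:-1]:
        fall_dH += H_at(e.onset) - H_at(e.offset)
        fall_T += e.duration
    for a, b in zip(eps[:-1], eps[1:]):
        rise_dH += H_at(b.onset) - H_at(a.offset)
        rise_T += b.onset - a.offset
    if fall_T <= 0 or rise_T <= 0:
        raise ValueError("degenerate episode structure")
    return (rise_dH / rise_T) / abs(fall_dH / fall_T)


def simulate_fixed_schedule(params: ModelParams, sleep_onset_clock: float,
                            sleep_offset_clock: float, n_days: int = 3,
                            traj_dt: float = 60.0) -> SimResult:
    """Integrate the homeostat under a prescribed daily sleep schedule.

    The exponential homeostat is advanced analytically between the imposed
    switch times, starting from its periodic fixed point, so the returned
    trajectory is the exact entrained solution for that schedule.  The
    pacemaker variables are irrelevant here and set to zero (``ca`` plays no
    role because switching is imposed, not threshold-driven).
    """
    mu, chi_h = params.mu, params.chi / SECONDS_PER_HOUR
    on, off = sleep_onset_clock % 24.0, sleep_offset_clock % 24.0
    T_sleep = (off - on) % 24.0
    T_wake = 24.0 - T_sleep
    if T_sleep <= 0 or T_wake <= 0:
        raise ValueError("schedule must include both sleep and wake")
    # periodic fixed point: H after wake (at onset) and after sleep (offset)
    ew, es = math.exp(-T_wake / chi_h), math.exp(-T_sleep / chi_h)
    H_on = (mu * (1.0 - ew)) / (1.0 - ew * es)
    H_off = H_on * es
    ts = np.arange(0.0, n_days * 24.0 + traj_dt / SECONDS_PER_HOUR / 2,
                   traj_dt / SECONDS_PER_HOUR)
    H = np.empty_like(ts)
    S = np.zeros_like(ts, dtype=int)
    episodes = []
    for d in range(n_days + 1):
        episodes.append(SleepEpisode(d * 24.0 + on,
                                     d * 24.0 + on + T_sleep))
    episodes = [e for e in episodes if e.offset <= n_days * 24.0]
    for i, t in enumerate(ts):
        since_on = (t - on) % 24.0
        if since_on < T_sleep:  # asleep
            H[i] = H_on * math.exp(-since_on / chi_h)
            S[i] = 1
        else:
            tw = since_on - T_sleep
            H[i] = mu + (H_off - mu) * math.exp(-tw / chi_h)
    zero = np.zeros_like(ts)
    return SimResult(t=ts, H=H, x=zero, y=zero, n=zero, C=zero, S=S,
                     episodes=episodes, t0_clock=0.0, params=params,
                     coeffs=WakePropensityCoeffs(),
                     final_state=(float(H[-1]), 0.0, 0.0, 0.0),
                     final_S=int(S[-1]), entrained=True)


# ---------------------------------------------------------------------------
# Sweeps and entrainment boundary
# ---------------------------------------------------------------------------

def parameter_sweep(param_name: str, values, light,
                    params0: ModelParams | None = None,
                    coeffs: WakePropensityCoeffs | None = None,
                    warm_start: bool = True, **conv_kwargs) -> pd.DataFrame:
    """One converged simulation per parameter value.

    Returns a DataFrame with mean duration, mean mid-sleep, the mean clock
    time of the circadian minimum, and the entrained flag; non-entrained
    values are where the sensitivity curves 'stop'.  Consecutive runs are
    warm-started from the previous converged state to track the entrained
    branch efficiently.
    """
    params0 = params0 or ModelParams()
    coeffs = coeffs or default_coeffs()
    rows = []
    state, S = None, 0
    for v in values:
        params = params0.replace(**{param_name: v})
        sim = simulate_to_convergence(params, light, coeffs=coeffs,
                                      init=state, init_S=S, **conv_kwargs)
        if warm_start and sim.entrained:
            state, S = sim.final_state, sim.final_S
        minima = sim.circadian_minima
        min_clock = (noon_anchored(np.asarray(minima) % 24.0).mean()
                     if minima else math.nan)
        rows.append({param_name: v,
                     "mean_duration": sim.mean_duration,
                     "mean_mid_sleep": sim.mean_mid_sleep,
                     "circadian_min": float(min_clock),
                     "entrained": bool(sim.entrained),
                     "passes": sim.passes})
    return pd.DataFrame(rows)


def entrainment_edge(param_name: str, bracket: tuple[float, float], light,
                     params0: ModelParams | None = None,
                     coeffs: WakePropensityCoeffs | None = None,
                     xtol: float = 0.005, **conv_kwargs) -> float:
    """Bisect the entrainment boundary of a parameter.

    Requires entrainment at ``bracket[0]`` and loss of entrainment at
    ``bracket[1]``; returns the boundary to within ``xtol`` of the
    parameter's unit.
    """
    params0 = params0 or ModelParams()
    coeffs = coeffs or default_coeffs()

    def entrained_at(v, init=None, S=0):
        params = params0.replace(**{param_name: v})
        sim = simulate_to_convergence(params, light, coeffs=coeffs,
                                      init=init, init_S=S, **conv_kwargs)
        return bool(sim.entrained), sim

    lo, hi = bracket
    ok_lo, sim_lo = entrained_at(lo)
    ok_hi, _ = entrained_at(hi)
    if not ok_lo or ok_hi:
        raise ValueError(
            f"invalid bracket: entrained({lo})={ok_lo}, "
            f"entrained({hi})={ok_hi}; need entrained at the low end only")
    state, S = sim_lo.final_state, sim_lo.final_S
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        ok, sim = entrained_at(mid, init=state, S=S)
        if ok:
            lo = mid
            state, S = sim.final_state, sim.final_S
        else:
            hi = mid
    return 0.5 * (lo + hi)
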