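"""Photoreceptor dynamics, the light-forced van der Pol pacemaker, and the
circadian wake-propensity waveform C(t).

The pacemaker is a van der Pol oscillator in its weakly nonlinear regime:

    kappa dx/dt = gamma (x - 4x^3/3) - y ((24/(f tauc))^2 + k B)
    kappa dy/dt = x + B

driven by light through a saturating photoreceptor pool (fraction ``n``):

    dn/dt = alpha0 (Itilde/I0)^p (1 - n) - beta n
    Bhat  = G alpha0 (Itilde/I0)^p (1 - n),   Itilde = (1 - S) I

with the drive modulated by circadian position, B = (1-bx)(1-by) Bhat.
In the absence of light the oscillation has period ``tauc`` hours, enforced
by the correction factor ``f``.

Phase convention: the unwrapped polar angle atan2(y, x), which increases by
2*pi per cycle (the unforced flow rotates counterclockwise in the (x, y)
plane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import KAPPA, SECONDS_PER_HOUR, ModelParams, WakePropensityCoeffs


@dataclass
class PacemakerState:
    """Pacemaker state: auxiliary variable x, activity y, photoreceptor
    fraction n in [0, 1]."""

    x: float
    y: float
    n: float = 0.0


def photic_drive(I: float, S: int, n: float,
                 params: ModelParams) -> tuple[float, float]:
    """Photoreceptor kinetics and light drive.

    Returns ``(dn_dt, Bhat)`` for available light ``I`` (lux), sleep
    indicator ``S`` (1 = asleep: eyes closed, so the retina sees no light)
    and activated fraction ``n``.

    ``dn_dt`` is in per-second units.  ``Bhat`` is the dimensionless drive
    of the pacemaker equations (which are the hour-based Kronauer equations
    rescaled by kappa seconds): it uses the photoreceptor activation rate
    expressed per minute, G * (60*alpha0) * (I/I0)^p * (1-n), the scale on
    which the gain G is defined.
    """
    Itilde = (1 - S) * I
    a = params.alpha0 * (Itilde / params.I0) ** params.p if Itilde > 0 else 0.0
    dn_dt = a * (1.0 - n) - params.beta * n
    Bhat = params.G * 60.0 * a * (1.0 - n)
    return dn_dt, Bhat


def pacemaker_rhs(state: PacemakerState, Bhat: float,
                  params: ModelParams) -> tuple[float, float]:
    """Right-hand sides (dx/dt, dy/dt) in per-second units.

    The raw drive ``Bhat`` is modulated by the circadian sensitivity factor
    (1 - b x)(1 - b y) before acting on the oscillator.
    """
    x, y = state.x, state.y
    B = (1.0 - params.b * x) * (1.0 - params.b * y) * Bhat
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2
    dx_dt = (params.gamma * (x - 4.0 * x ** 3 / 3.0)
             - y * (omega0_sq + params.k * B)) / KAPPA
    dy_dt = (x + B) / KAPPA
    return dx_dt, dy_dt


def wake_propensity(state: PacemakerState | tuple,
                    coeffs: WakePropensityCoeffs) -> float:
    """Evaluate the quadratic wake-propensity form at a pacemaker state."""
    if isinstance(state, PacemakerState):
        x, y = state.x, state.y
    else:
        x, y = state[0], state[1]
    c20, a21, a22, b21, b22, b23 = coeffs.as_tuple()
    return c20 + a21 * x + a22 * y + b21 * x * x + b22 * x * y + b23 * y * y


def wake_propensity_xy(x: np.ndarray, y: np.ndarray,
                       coeffs: WakePropensityCoeffs) -> np.ndarray:
    """Vectorized evaluation of C over arrays of x and y."""
    c20, a21, a22, b21, b22, b23 = coeffs.as_tuple()
    return c20 + a21 * x + a22 * y + b21 * x * x + b22 * x * y + b23 * y * y


# ---------------------------------------------------------------------------
# Unforced period and the correction factor f
# ---------------------------------------------------------------------------

def _unforced_rhs(t, s, gamma, omega0_sq):
    x, y = s
    return ((gamma * (x - 4.0 * x ** 3 / 3.0) - y * omega0_sq) / KAPPA,
            x / KAPPA)


def unforced_period(params: ModelParams, n_transient: int = 20,
                    n_average: int = 10) -> float:
    """Limit-cycle period of the unforced pacemaker, in hours.

    Integrates the dark (B = 0) oscillator from (x, y) = (1, 0), discards
    the first ``n_transient`` cycles and averages the following
    ``n_average`` intervals between successive upward zero crossings of x.
    The limit cycle is strongly attracting for the default stiffness, so
    this converges well within the transient window.
    """
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2

    def cross(t, s, *args):
        return s[0]
    cross.direction = 1.0

    t_max = (n_transient + n_average + 3) * params.tauc * SECONDS_PER_HOUR
    sol = solve_ivp(_unforced_rhs, (0.0, t_max), [1.0, 0.0],
                    args=(params.gamma, omega0_sq), method="DOP853",
                    rtol=1e-11, atol=1e-11, events=cross, dense_output=False)
    crossings = sol.t_events[0]
    if len(crossings) < n_transient + n_average + 1:
        raise RuntimeError("pacemaker did not settle onto a periodic orbit")
    kept = crossings[n_transient:n_transient + n_average + 1]
    periods = np.diff(kept)
    if np.ptp(periods) > 10.0:  # seconds; cycle not yet periodic
        raise RuntimeError("unforced oscillation has not converged to a "
                           "limit cycle (period spread %.1f s)" % np.ptp(periods))
    return float(np.mean(periods)) / SECONDS_PER_HOUR


def calibrate_f(tauc: float, gamma: float, tol_seconds: float = 1.0,
                params: ModelParams | None = None) -> float:
    """Root-find the correction factor f so the unforced period equals tauc.

    The weak van der Pol nonlinearity lengthens the period of the underlying
    linear oscillator, so f is slightly below 1; in the gamma -> 0 limit the
    oscillator is linear with period f*tauc exactly and f = 1.
    """
    if gamma == 0:
        return 1.0
    base = params or ModelParams()

    def err(f):
        p = base.replace(tauc=tauc, gamma=gamma, f=f)
        return unforced_period(p) - tauc

    # period is close to linear in f with slope ~tauc hours per unit f
    xtol = tol_seconds / SECONDS_PER_HOUR / tauc
    lo, hi = 0.95, 1.0
    if err(lo) * err(hi) > 0:
        raise RuntimeError("failed to bracket the period correction factor")
    return float(brentq(err, lo, hi, xtol=min(xtol, 1e-6)))


def unforced_limit_cycle(params: ModelParams,
                         n_samples: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Sample one period of the unforced limit cycle.

    Returns ``(x, y)`` arrays of length ``n_samples`` starting at the upward
    zero crossing of x, equally spaced in time over one period.
    """
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2

    def cross(t, s, *args):
        return s[0]
    cross.direction = 1.0

    # settle transients, find a crossing, then sample one period
    t_settle = 25 * params.tauc * SECONDS_PER_HOUR
    sol = solve_ivp(_unforced_rhs, (0.0, t_settle), [1.0, 0.0],
                    args=(params.gamma, omega0_sq), method="DOP853",
                    rtol=1e-10, atol=1e-10, events=cross)
    t0 = sol.t_events[0][-1]
    s0 = sol.y_events[0][-1]
    period = unforced_period(params) * SECONDS_PER_HOUR
    ts = np.linspace(0.0, period, n_samples, endpoint=False)
    sol2 = solve_ivp(_unforced_rhs, (0.0, period), s0,
                     args=(params.gamma, omega0_sq), method="DOP853",
                     rtol=1e-10, atol=1e-10, t_eval=ts)
    return sol2.y[0], sol2.y[1]


def light_circadian_rhs(params: ModelParams, light_fun):
    """RHS factory for the free-running (S = 0) light-circadian subsystem.

    Returns ``rhs(t, (x, y, n))`` with t in seconds; ``light_fun`` maps
    seconds to lux.  Used for entraining the pacemaker without sleep gating
    and for the biological-effect-of-light metric.
    """
    G, p_exp, kshape, b = params.G, params.p, params.k, params.b
    gamma, alpha0, beta, I0 = (params.gamma, params.alpha0, params.beta,
                               params.I0)
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2

    def rhs(t, s):
        x, y, n = s
        I = light_fun(t)
        a = alpha0 * (I / I0) ** p_exp if I > 0 else 0.0
        Bhat = G * 60.0 * a * (1.0 - n)
        B = (1.0 - b * x) * (1.0 - b * y) * Bhat
        return ((gamma * (x - 4.0 * x ** 3 / 3.0)
                 - y * (omega0_sq + kshape * B)) / KAPPA,
                (x + B) / KAPPA,
                a * (1.0 - n) - beta * n)

    return rhs


# ---------------------------------------------------------------------------
# Phase utilities
# ---------------------------------------------------------------------------

def unwrapped_phase(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unwrapped pacemaker phase atan2(y, x) in radians.

    Increases by 2*pi per completed circadian cycle; requires sampling dense
    enough that consecutive samples advance by less than pi.
    """
    return np.unwrap(np.arctan2(y, x))


def cycles_completed(x: np.ndarray, y: np.ndarray) -> float:
    """Number of circadian cycles covered by a sampled (x, y) trajectory."""
    phase = unwrapped_phase(x, y)
    return float((phase[-1] - phase[0]) / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# Fitting the wake-propensity quadratic form
# ---------------------------------------------------------------------------

def fit_wake_propensity_coeffs(waveform: np.ndarray, cycle_x: np.ndarray,
                               cycle_y: np.ndarray,
                               degree: int = 2,
                               ) -> tuple[WakePropensityCoeffs, float]:
    """Least-squares fit of the quadratic form to a wake-propensity waveform.

    Parameters
    ----------
    waveform : array
        Target circadian wake-propensity values sampled at phases matched to
        the cycle samples.  The target is z-scored and rescaled to
        peak-to-peak amplitude 2 before fitting, matching the convention
        that C(t) has amplitude ~2 on the entrained cycle.
    cycle_x, cycle_y : array
        Samples of the pacemaker limit cycle at the matching phases.
    degree : int
        1 fits only the linear terms (constant + x + y); 2 (default) fits
        the full quadratic form.

    Returns
    -------
    (coeffs, residual) where residual is the RMS misfit after scaling.
    """
    w = np.asarray(waveform, dtype=float)
    x = np.asarray(cycle_x, dtype=float)
    y = np.asarray(cycle_y, dtype=float)
    if not (len(w) == len(x) == len(y)):
        raise ValueError("waveform and cycle must be sampled at matched phases")
    # z-score, then normalize to peak-to-peak 2
    w = w - w.mean()
    sd = w.std()
    if sd == 0:
        raise ValueError("constant waveform cannot be fitted")
    w = w / sd
    w = w * (2.0 / np.ptp(w))
    cols = [np.ones_like(x), x, y]
    if degree >= 2:
        cols += [x * x, x * y, y * y]
    A = np.column_stack(cols)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design; cycle samples do "
                                    "not span the quadratic monomials")
    beta, res, *_ = np.linalg.lstsq(A, w, rcond=None)
    fitted = A @ beta
    rms = float(np.sqrt(np.mean((fitted - w) ** 2)))
    full = np.zeros(6)
    full[:len(beta)] = beta
    return WakePropensityCoeffs(*full), rms
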