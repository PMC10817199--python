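"""Photoreceptor dynamics, the van der Pol pacemaker, the unforced period
and the wake-propensity quadratic form."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hclsleep import (KAPPA, ModelParams, WakePropensityCoeffs, calibrate_f,
                      default_coeffs, fit_wake_propensity_coeffs,
                      pacemaker_rhs, photic_drive, unforced_limit_cycle,
                      unforced_period, wake_propensity)
from hclsleep.pacemaker import (PacemakerState, light_circadian_rhs,
                                wake_propensity_xy)


@pytest.fixture(scope="module")
def params():
    return ModelParams()


# -- photic drive -----------------------------------------------------------

def test_dark_decay(params):
    dn, Bhat = photic_drive(0.0, 0, 0.5, params)
    assert dn == pytest.approx(-params.beta * 0.5)
    assert Bhat == 0.0


def test_sleep_gates_light(params):
    """Eyes closed during sleep: bright light with S=1 equals darkness."""
    dark = photic_drive(0.0, 0, 0.5, params)
    gated = photic_drive(10000.0, 1, 0.5, params)
    assert gated == dark


def test_photoreceptor_steady_state(params):
    """dn/dt vanishes at n* = a/(a+beta), a = alpha0 (I/I0)^p (oracle from
    setting the kinetics to zero and solving)."""
    I = 750.0
    a = params.alpha0 * (I / params.I0) ** params.p
    n_star = a / (a + params.beta)
    dn, _ = photic_drive(I, 0, n_star, params)
    assert dn == pytest.approx(0.0, abs=1e-15)


def test_drive_compression_slope_is_p(params):
    """For constant light, the drive scales as I^p: log-log slope 0.6."""
    I = np.logspace(1, 4, 40)  # 10..10000 lux
    B = np.array([photic_drive(i, 0, 0.0, params)[1] for i in I])
    slope = np.polyfit(np.log10(I), np.log10(B), 1)[0]
    assert slope == pytest.approx(params.p, abs=0.01)


# -- pacemaker right-hand side ---------------------------------------------

def test_rhs_at_origin_unit_sensitivity(params):
    q = 0.37
    dx, dy = pacemaker_rhs(PacemakerState(0.0, 0.0), q, params)
    assert dy == pytest.approx(q / KAPPA)
    assert dx == pytest.approx(0.0)


def test_rhs_dark_substitution(params):
    dx, dy = pacemaker_rhs(PacemakerState(0.5, 0.0), 0.0, params)
    assert dx == pytest.approx(params.gamma * (0.5 - 4 * 0.125 / 3) / KAPPA)
    assert dy == pytest.approx(0.5 / KAPPA)


def test_sensitivity_null_at_x_equals_inverse_b(params):
    """At x = 1/b the modulation factor kills the drive entirely."""
    x = 1.0 / params.b
    dx0, dy0 = pacemaker_rhs(PacemakerState(x, 0.2), 0.0, params)
    dx1, dy1 = pacemaker_rhs(PacemakerState(x, 0.2), 5.0, params)
    assert (dx0, dy0) == (dx1, dy1)


def test_n_forward_invariance(params):
    """n stays in [0, 1] under strong alternating light."""
    def lf(t):
        return 10000.0 if (t // 3600) % 2 == 0 else 0.0
    rhs = light_circadian_rhs(params, lf)
    sol = solve_ivp(rhs, (0.0, 3 * 86400.0), [1.0, 0.0, 0.0],
                    method="LSODA", rtol=1e-6, atol=1e-8, max_step=600.0)
    assert sol.y[2].min() >= -1e-6
    assert sol.y[2].max() <= 1.0 + 1e-6


# -- unforced period and f --------------------------------------------------

def test_unforced_period_defaults(params):
    assert unforced_period(params) == pytest.approx(24.2, abs=1e-3)


def test_period_monotone_in_tauc(params):
    p_lo = unforced_period(params.replace(tauc=24.1))
    p_hi = unforced_period(params.replace(tauc=24.3))
    assert p_lo < p_hi


def test_calibrate_f_gamma_zero_limit():
    """gamma -> 0 gives a linear oscillator with period f*tauc exactly."""
    assert calibrate_f(24.2, 0.0) == 1.0
    p = ModelParams().replace(f=1.0, gamma=1e-6)
    assert unforced_period(p) == pytest.approx(24.2, abs=1e-4)


def test_calibrate_f_round_trip(params):
    f = calibrate_f(24.2, params.gamma)
    per = unforced_period(params.replace(f=f))
    assert abs(per - 24.2) * 3600.0 < 1.0  # within one second


def test_limit_cycle_attracts_distinct_initial_conditions(params):
    """Trajectories from distinct starts converge to the same cycle."""
    omega0_sq = (24.0 / (params.f * params.tauc)) ** 2

    def rhs(t, s):
        x, y = s
        return ((params.gamma * (x - 4 * x ** 3 / 3) - y * omega0_sq) / KAPPA,
                x / KAPPA)

    t_end = 50 * 24.2 * 3600.0
    amps = []
    for s0 in ([0.1, 0.0], [2.0, 1.5]):
        # integrate the transient first, then measure one cycle's amplitude
        pre = solve_ivp(rhs, (0.0, t_end - 25 * 3600), s0, method="DOP853",
                        rtol=1e-10, atol=1e-10)
        sol = solve_ivp(rhs, (0.0, 25 * 3600.0), pre.y[:, -1],
                        method="DOP853", rtol=1e-10, atol=1e-10,
                        t_eval=np.linspace(0, 25 * 3600.0, 2000))
        amps.append(np.ptp(sol.y[0]))
    assert abs(amps[0] - amps[1]) < 1e-3


# -- wake propensity --------------------------------------------------------

def test_wake_propensity_terms():
    assert wake_propensity(PacemakerState(0.7, -0.2),
                           WakePropensityCoeffs(c20=1.0)) == 1.0
    assert wake_propensity(PacemakerState(0.3, 0.9),
                           WakePropensityCoeffs(a21=1.0)) == pytest.approx(0.3)
    mixed = WakePropensityCoeffs(0.5, 1.0, -1.0, 0.25, 0.5, -0.25)
    x, y = 0.4, -0.8
    assert wake_propensity(PacemakerState(x, y), mixed) == pytest.approx(
        0.5 + x - y + 0.25 * x * x + 0.5 * x * y - 0.25 * y * y)


def test_fit_recovers_exact_quadratic(params):
    """A waveform generated from known coefficients (already centred and
    peak-to-peak 2 on the cycle) is recovered to numerical precision."""
    cx, cy = unforced_limit_cycle(params, n_samples=480)
    raw = WakePropensityCoeffs(0.0, 0.6, -0.4, 0.3, 0.2, -0.1)
    w = wake_propensity_xy(cx, cy, raw)
    w0 = w - w.mean()
    w0 *= 2.0 / np.ptp(w0)
    # normalized target still lies in the quadratic span
    target_coeffs, rms = fit_wake_propensity_coeffs(w0, cx, cy)
    assert rms < 1e-6
    fitted = wake_propensity_xy(cx, cy, target_coeffs)
    assert np.allclose(fitted, w0, atol=1e-6)


def test_quadratic_fit_beats_linear(params):
    from hclsleep.calibration import wake_propensity_template
    cx, cy = unforced_limit_cycle(params, n_samples=480)
    phase = np.linspace(0.0, 24.0, 480, endpoint=False)
    target = wake_propensity_template(phase)
    _, rms_quad = fit_wake_propensity_coeffs(target, cx, cy, degree=2)
    _, rms_lin = fit_wake_propensity_coeffs(target, cx, cy, degree=1)
    assert rms_quad <= rms_lin


def test_fit_rank_deficient_design():
    x = np.zeros(100)
    y = np.zeros(100)
    with pytest.raises(np.linalg.LinAlgError):
        fit_wake_propensity_coeffs(np.sin(np.linspace(0, 6, 100)), x, y)


def test_default_coeffs_waveform_geometry(default_sim):
    """On the default entrained cycle, C peaks during the evening wake
    period before sleep onset and bottoms out in the second half of the
    night (the shape that makes the thresholds produce realistic sleep)."""
    sim = default_sim
    sel = sim.t > sim.t[-1] - 24.0
    t = sim.t[sel]
    C = sim.C[sel]
    t_max = t[np.argmax(C)] % 24.0
    t_min = t[np.argmin(C)] % 24.0
    last = sim.episodes[-1]
    onset, offset = last.onset % 24.0, last.offset % 24.0
    assert 14.0 < t_max < onset          # evening wake, before onset
    mid_night = (last.onset + last.offset) / 2.0 % 24.0
    assert mid_night < t_min < offset    # second half of the night
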