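"""Hybrid simulator: thresholds, event-located switching, the closed-form
homeostat oracle, episode statistics, gating, sweeps and entrainment."""

import math

import numpy as np
import pytest

from hclsleep import (LightProfileSpec, ModelParams, circadian_minimum_times,
                      episode_metrics, entrainment_edge, parameter_sweep,
                      profile_to_series, rise_fall_ratio, simulate,
                      simulate_fixed_schedule, simulate_to_convergence,
                      thresholds)
from hclsleep.calibration import default_profile
from hclsleep.simulate import SleepEpisode, noon_anchored


@pytest.fixture(scope="module")
def params():
    return ModelParams()


# -- thresholds -------------------------------------------------------------

def test_threshold_values(params):
    hi, lo = thresholds(0.0, params)
    assert (hi, lo) == (13.5, 12.5)
    hi1, lo1 = thresholds(1.0, params)
    assert hi1 == pytest.approx(13.5 + 1.72)
    assert lo1 == pytest.approx(12.5 + 1.72)
    assert hi1 - lo1 == pytest.approx(params.Delta)
    hi0, lo0 = thresholds(5.0, params.replace(ca=0.0))
    assert (hi0, lo0) == (13.5, 12.5)  # ca = 0: constant thresholds


# -- closed-form oracle -----------------------------------------------------

def test_constant_light_zero_amplitude_matches_closed_form(params):
    """With ca = 0 and constant light the homeostat bounces between fixed
    thresholds; first-passage times of the exponential relaxation give
    wake = chi ln((mu-H-)/(mu-H+)) and sleep = chi ln(H+/H-)."""
    p = params.replace(ca=0.0)
    light = LightProfileSpec(day_level=100.0, evening_level=100.0)
    sim = simulate(p, light, n_days=6)
    chi_h = p.chi / 3600.0
    wake_cf = chi_h * math.log((p.mu - 12.5) / (p.mu - 13.5))
    sleep_cf = chi_h * math.log(13.5 / 12.5)
    sleeps = [e.duration for e in sim.episodes[-3:]]
    wakes = [b.onset - a.offset
             for a, b in zip(sim.episodes[-4:-1], sim.episodes[-3:])]
    for s in sleeps:
        assert abs(s - sleep_cf) * 3600.0 < 10.0
    for w in wakes:
        assert abs(w - wake_cf) * 3600.0 < 10.0


def test_switch_instants_sit_on_the_thresholds(default_sim):
    """At every located switch the homeostat equals the active threshold."""
    from hclsleep.pacemaker import wake_propensity_xy
    sim = default_sim
    assert len(sim.switch_states) >= 2
    for t_abs, H, x, y, n, new_S in sim.switch_states:
        C = wake_propensity_xy(np.array([x]), np.array([y]), sim.coeffs)[0]
        hi, lo = thresholds(C, sim.params)
        target = hi if new_S == 1 else lo
        assert abs(H - target) < 1e-6


def test_determinism_bit_exact(params):
    light = default_profile()
    a = simulate(params, light, n_days=3)
    b = simulate(params, light, n_days=3)
    assert np.array_equal(a.H, b.H)
    assert np.array_equal(a.x, b.x)
    assert a.episodes == b.episodes
    c1 = simulate_to_convergence(params, light)
    c2 = simulate_to_convergence(params, light)
    assert c1.mean_mid_sleep == c2.mean_mid_sleep
    assert c1.mean_duration == c2.mean_duration


def test_sleep_gates_light_input(params):
    """Changing available light during model-sleep changes nothing."""
    base = profile_to_series(default_profile(), 4)
    sim = simulate(params, base, n_days=4)
    lux = base.lux.copy()
    t_abs = base.t0_clock_hours + base.seconds_from_start() / 3600.0
    asleep = np.zeros(len(base), dtype=bool)
    for e in sim.episodes:
        asleep |= (t_abs > e.onset + 0.02) & (t_abs < e.offset - 0.02)
    lux[asleep] *= 2.0
    sim2 = simulate(params, base.copy_with(lux), n_days=4)
    # identical up to solver accuracy: the integrator's trial steps
    # overshoot each switching instant before the root is located, and the
    # O(rtol) event-time perturbations propagate through later segments
    assert len(sim.episodes) == len(sim2.episodes)
    for a, b in zip(sim.episodes, sim2.episodes):
        assert abs(a.onset - b.onset) * 3600.0 < 10.0
        assert abs(a.offset - b.offset) * 3600.0 < 10.0


# -- episode metrics --------------------------------------------------------

def test_episode_metrics_and_wrap():
    e = SleepEpisode(23.0, 31.0)  # 23:00 -> 07:00
    assert e.duration == 8.0
    assert e.mid_sleep == 27.0    # 03:00 noon-anchored
    m = episode_metrics([SleepEpisode(23.0 + 50 / 60, 30.0),
                         SleepEpisode(24.0 + 10 / 60, 31.0)])
    assert m["mean_onset"] == pytest.approx(24.0)  # 00:00, not 12:00
    m2 = episode_metrics([SleepEpisode(23.0, 31.0), SleepEpisode(47.0, 55.0)])
    assert m2["sd_duration"] == 0.0
    assert m2["sd_mid_sleep"] == 0.0
    with pytest.raises(ValueError):
        episode_metrics([])


def test_noon_anchored_mapping():
    assert noon_anchored(3.0) == 27.0
    assert noon_anchored(13.0) == 13.0
    assert noon_anchored(12.0) == 12.0


# -- rise/fall ratio --------------------------------------------------------

def test_rise_fall_ratio_imposed_schedules(params):
    """Over a periodic solution net sleep-pressure change is zero, so the
    rise/fall rate ratio equals sleep/wake duration: 1/2 for 8 h/16 h."""
    sim = simulate_fixed_schedule(params, 23.0, 7.0, n_days=4)
    assert rise_fall_ratio(sim) == pytest.approx(0.5, abs=1e-9)
    sim12 = simulate_fixed_schedule(params, 22.0, 10.0, n_days=4)
    assert rise_fall_ratio(sim12) == pytest.approx(1.0, abs=1e-9)


def test_rise_fall_equals_duration_ratio_on_entrained_solution(default_sim):
    sim = default_sim
    r = rise_fall_ratio(sim)
    eps = sim.episodes
    sleep_T = np.mean([e.duration for e in eps[:-1]])
    wake_T = np.mean([b.onset - a.offset for a, b in zip(eps[:-1], eps[1:])])
    assert r == pytest.approx(sleep_T / wake_T, abs=1e-3)


def test_rise_fall_requires_entrainment(params):
    sim = simulate_fixed_schedule(params, 23.0, 7.0, n_days=4)
    sim.entrained = False
    with pytest.raises(ValueError):
        rise_fall_ratio(sim)


# -- circadian minimum ------------------------------------------------------

def test_circadian_minimum_in_second_half_of_night(default_sim):
    sim = default_sim
    minima = circadian_minimum_times(sim)
    assert minima
    last = sim.episodes[-1]
    m = [t for t in minima if last.onset <= t <= last.offset]
    assert m, "circadian minimum should fall within the sleep episode"
    assert m[0] > (last.onset + last.offset) / 2.0


def test_circadian_minimum_of_pure_cosine(params):
    """With a cosine C the minimum is at the known phase analytically."""
    sim = simulate_fixed_schedule(params, 23.0, 7.0, n_days=2)
    t = sim.t
    sim.C = np.cos(2 * np.pi * (t - 4.6) / 24.0 + np.pi)  # minimum at 4.6 h
    for m in circadian_minimum_times(sim):
        assert (m % 24.0) == pytest.approx(4.6, abs=0.02)


# -- convergence and entrainment -------------------------------------------

def test_periodic_profile_entrains(default_sim):
    assert default_sim.entrained is True
    assert default_sim.passes < 50


def test_long_tauc_fails_to_entrain(params):
    sim = simulate_to_convergence(params.replace(tauc=24.5),
                                  default_profile(), max_passes=12)
    assert sim.entrained is False


def test_sweep_mu_monotone_duration(params):
    sw = parameter_sweep("mu", [17.0, 17.87, 18.8], default_profile())
    d = sw["mean_duration"].to_numpy()
    assert d[0] < d[1] < d[2]


def test_sweep_tauc_timing_but_not_duration(params):
    """Mid-sleep shifts later with tauc while duration barely moves."""
    sw = parameter_sweep("tauc", [24.0, 24.1, 24.2],
                         default_profile(evening_level=10.0))
    mid = sw["mean_mid_sleep"].to_numpy()
    assert mid[0] < mid[1] < mid[2]
    assert np.ptp(sw["mean_duration"].to_numpy()) < 5.0 / 60.0


def test_entrainment_edge_degenerate_bracket(params):
    with pytest.raises(ValueError, match="bracket"):
        entrainment_edge("tauc", (24.0, 24.05),
                         default_profile(evening_level=10.0))
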