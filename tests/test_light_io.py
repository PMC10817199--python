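"""Light series reading, interpolation, imputation, synthetic profiles and
interventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hclsleep import (Intervention, LightProfileSpec, apply_intervention,
                      impute_wake_zeros, interpolate_lux, profile_to_series,
                      read_light_csv, synthetic_profile)
from hclsleep.light import LightFormatError, LightValidationError

from conftest import make_series


# -- reading ----------------------------------------------------------------

def test_read_light_csv_identity(tmp_path):
    p = tmp_path / "l.csv"
    p.write_text("timestamp,lux\n"
                 "2024-03-18T00:00:00,0\n"
                 "2024-03-18T00:01:00,10\n"
                 "2024-03-18T00:02:00,20\n")
    s = read_light_csv(p, "p1")
    assert len(s) == 3
    assert list(s.lux) == [0.0, 10.0, 20.0]
    assert s.participant_id == "p1"


def test_read_light_csv_errors(tmp_path):
    neg = tmp_path / "neg.csv"
    neg.write_text("timestamp,lux\n2024-03-18T00:00:00,5\n"
                   "2024-03-18T00:01:00,-5\n")
    with pytest.raises(LightValidationError, match="line 3"):
        read_light_csv(neg, "p")
    bad = tmp_path / "bad.csv"
    bad.write_text("time,lux\n2024-03-18T00:00:00,5\n")
    with pytest.raises(LightFormatError, match="timestamp"):
        read_light_csv(bad, "p")
    mal = tmp_path / "mal.csv"
    mal.write_text("timestamp,lux\n2024-03-18T00:00:00,5\nnot-a-time,6\n")
    with pytest.raises(LightFormatError, match="lines 3"):
        read_light_csv(mal, "p")


def test_read_preserves_gaps(tmp_path):
    p = tmp_path / "gap.csv"
    p.write_text("timestamp,lux\n"
                 "2024-03-18T00:00:00,1\n"
                 "2024-03-18T00:01:00,2\n"
                 "2024-03-18T00:11:00,3\n")
    s = read_light_csv(p, "p")
    assert len(s) == 3  # the 10-min gap is kept, not filled
    assert (s.times[2] - s.times[1]).total_seconds() == 600


# -- interpolation ----------------------------------------------------------

def test_interpolation_contract():
    s = make_series([37.0, 100.0, 200.0])
    assert interpolate_lux(s, s.times[0]) == 37.0
    midpoint = s.times[1] + pd.Timedelta(seconds=30)
    assert interpolate_lux(s, midpoint) == pytest.approx(150.0)
    const = make_series([40.0] * 5)
    assert interpolate_lux(
        const, const.times[0] + pd.Timedelta(seconds=137)) == 40.0
    with pytest.raises(ValueError, match="outside"):
        interpolate_lux(s, s.times[-1] + pd.Timedelta(minutes=1))


# -- imputation -------------------------------------------------------------

def test_impute_single_day_window_median():
    # zero at 10:00 during wake; window holds 50/100/150 among zeros
    lux = np.zeros(24 * 60)
    lux[9 * 60 + 35] = 50.0
    lux[10 * 60 + 5] = 100.0
    lux[10 * 60 + 25] = 150.0
    wake = np.ones_like(lux, dtype=bool)
    s = make_series(lux)
    out = impute_wake_zeros(s, wake)
    # the zero at exactly 10:00 sees {0...,50,100,150}: median over the
    # whole +-30 min window of raw values
    window = lux[(9 * 60 + 30):(10 * 60 + 31)]
    assert out.lux[10 * 60] == np.median(window)


def test_impute_only_wake_zeros():
    lux = np.full(24 * 60, 80.0)
    lux[3 * 60] = 0.0   # 03:00, asleep
    lux[15 * 60] = 0.0  # 15:00, awake
    wake = np.ones_like(lux, dtype=bool)
    wake[(0 * 60):(7 * 60)] = False
    out = impute_wake_zeros(make_series(lux), wake)
    assert out.lux[3 * 60] == 0.0      # sleep zero untouched
    assert out.lux[15 * 60] == 80.0    # wake zero imputed
    # non-zero values untouched everywhere
    nz = lux > 0
    assert np.array_equal(out.lux[nz], lux[nz])


def test_impute_pools_window_across_days():
    # two-day series; zero at 10:00 on day 1; oracle = brute-force median
    # over every sample (both days) within +-30 min of clock 10:00
    rng = np.random.default_rng(7)
    lux = rng.uniform(10.0, 200.0, 2 * 24 * 60).round(1)
    i_zero = 10 * 60
    lux[i_zero] = 0.0
    s = make_series(lux)
    clock_min = np.arange(len(lux)) % (24 * 60)
    d = np.abs(clock_min - 10 * 60)
    d = np.minimum(d, 24 * 60 - d)
    expected = np.median(lux[d <= 30])
    out = impute_wake_zeros(s, np.ones_like(lux, dtype=bool))
    assert out.lux[i_zero] == pytest.approx(expected)


def test_impute_never_decreases_and_zero_median_stays():
    lux = np.zeros(24 * 60)  # an all-zero record: window medians are 0
    out = impute_wake_zeros(make_series(lux), np.ones_like(lux, dtype=bool))
    assert np.array_equal(out.lux, lux)


# -- synthetic profile ------------------------------------------------------

def test_profile_plateaus_and_monotone_dawn():
    spec = LightProfileSpec(dawn_time=6.0, dusk_time=18.0,
                            day_level=1000.0, evening_level=40.0)
    assert synthetic_profile(spec, 12.0) == pytest.approx(1000.0, abs=0.1)
    assert synthetic_profile(spec, 0.0) == pytest.approx(40.0, abs=0.1)
    assert synthetic_profile(spec, 5.5) < synthetic_profile(spec, 6.5)


@settings(deadline=None, max_examples=50)
@given(t=st.floats(0.0, 48.0))
def test_profile_periodic_and_bounded(t):
    spec = LightProfileSpec()
    v = synthetic_profile(spec, t)
    assert spec.evening_level <= v <= spec.day_level
    assert v == pytest.approx(synthetic_profile(spec, t + 24.0), rel=1e-12)


def test_profile_spec_validation():
    with pytest.raises(ValueError):
        LightProfileSpec(day_level=10.0, evening_level=40.0)
    with pytest.raises(ValueError):
        LightProfileSpec(dawn_time=19.0, dusk_time=18.0)


# -- interventions ----------------------------------------------------------

def test_evening_reduction_window():
    s = profile_to_series(LightProfileSpec(day_level=100.0,
                                           evening_level=100.0), 1)
    out = apply_intervention(s, Intervention.evening_reduction())
    clock = out.clock_hours()
    inside = (clock >= 18.0) | (clock < 6.0)
    assert np.all(out.lux[inside] == 4.0)
    assert np.all(out.lux[~inside] == 100.0)


def test_morning_enhancement_window():
    s = profile_to_series(LightProfileSpec(day_level=100.0,
                                           evening_level=100.0), 1)
    out = apply_intervention(s, Intervention.morning_enhancement())
    clock = out.clock_hours()
    inside = (clock >= 9.5) & (clock < 10.0)
    assert np.all(out.lux[inside] == 1000.0)
    assert np.all(out.lux[~inside] == 100.0)


def test_intervention_idempotent_and_noop():
    s = profile_to_series(LightProfileSpec(), 1)
    iv = Intervention.evening_reduction()
    once = apply_intervention(s, iv)
    twice = apply_intervention(once, iv)
    assert np.array_equal(once.lux, twice.lux)
    with pytest.raises(ValueError, match="empty"):
        apply_intervention(s, Intervention("custom", 3.0, 3.0, 10.0))
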