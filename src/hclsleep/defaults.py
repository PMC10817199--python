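"""Shipped default calibration artefacts.

The numeric values in this module are produced by
:mod:`hclsleep.calibration` (see ``calibrate_defaults`` and
``compute_reference_state``) and frozen here so that ordinary use of the
package does not re-run the calibration:

* ``DEFAULT_COEFFS`` — coefficients of the quadratic wake-propensity form
  C(x, y), fitted to an asymmetric circadian wake-propensity template
  (maximum in the late evening, minimum in the second half of the night,
  peak-to-peak amplitude 2) on the entrained pacemaker cycle, with the
  template phase calibrated so that the default model under the default
  two-level light profile has a mean mid-sleep time of 03:16.
* ``DEFAULT_PROFILE_*`` — the default synthetic light availability profile:
  1000 lux between dawn 06:00 and dusk 18:00, 40 lux otherwise, 30-min
  transitions.
* ``REFERENCE_STATE`` — pacemaker state (x, y, n) at midnight for the
  entrained 'average person' (mid-sleep 04:30, sleep duration 8.22 h) used
  as the fixed initial condition of the biological-effect-of-light metric.

Override either by passing explicit objects to the library calls or via the
CLI configuration file.
"""

from __future__ import annotations

from .params import WakePropensityCoeffs

# produced by hclsleep.calibration.calibrate_defaults()
# (template phase shift -4.7748 h; C normalized to peak-to-peak 2 and zero
# mean over the converged entrained cycle of the default model)
_DEFAULT_COEFFS = WakePropensityCoeffs(
    c20=1.6161065906735679,
    a21=-0.718591883625455,
    a22=0.7217797267156708,
    b21=-1.1751990447929361,
    b22=-0.21504322433885487,
    b23=-1.6388475328843883,
)

# produced by hclsleep.metrics.compute_reference_state()
_REFERENCE_STATE = (-0.8465097165620054,   # x at midnight
                    -0.6140901256766211,   # y at midnight
                    0.31706430147770054)   # n at midnight

DEFAULT_DAY_LUX = 2000.0
DEFAULT_EVENING_LUX = 40.0
DEFAULT_DAWN = 6.0
DEFAULT_DUSK = 18.0


def default_coeffs() -> WakePropensityCoeffs:
    """The shipped default wake-propensity coefficients."""
    return _DEFAULT_COEFFS


def reference_state() -> tuple[float, float, float]:
    """Pacemaker state (x, y, n) at midnight of the reference person."""
    return _REFERENCE_STATE
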