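"""Model parameters for the Homeostatic-Circadian-Light (HCL) sleep model.

The model couples an exponential sleep homeostat (pressure ``H`` relaxing
towards an upper asymptote ``mu`` during wake and towards zero during sleep,
time constant ``chi``) to a light-forced van der Pol circadian pacemaker
(variables ``x``, ``y``) via circadian modulation of the wake->sleep and
sleep->wake switching thresholds.  Light acts through a saturating pool of
activated photoreceptors (fraction ``n``).

All rate constants are expressed in seconds; the intrinsic circadian period
``tauc`` is in hours and converted at the point of use.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Time-scale constant of the pacemaker equations, 24*3600/(2*pi) seconds.
#: One radian of pacemaker phase corresponds to kappa seconds at the nominal
#: 24 h angular velocity.
KAPPA = 24.0 * 3600.0 / (2.0 * math.pi)

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ModelParams:
    """The 14 HCL parameters with their default values.

    Attributes
    ----------
    mu : float
        Upper asymptote of homeostatic sleep pressure (dimensionless).
        Controls the rate of rise of sleep pressure during wake.
    chi : float
        Time constant for the rise and decay of sleep pressure, seconds.
    H0bar : float
        Mean level of the switching thresholds (dimensionless).
    Delta : float
        Separation between the upper and lower thresholds (dimensionless).
    ca : float
        Circadian amplitude: the thresholds move by ``ca * C(t)`` where the
        wake-propensity rhythm C has peak-to-peak amplitude ~2.
    tauc : float
        Intrinsic circadian period of the pacemaker, hours.
    f : float
        Correction factor so that the unforced van der Pol oscillator has
        period exactly ``tauc`` (the nonlinearity lengthens the period of
        the underlying linear oscillator slightly).
    G : float
        Gain of the photic drive on the pacemaker.
    p : float
        Light-sensitivity exponent; the drive scales as ``(I/I0)**p`` with
        p < 1, compressing the response to bright light.
    k : float
        Shape factor setting the relative effect of light on x and y.
    b : float
        Sensitivity-modulation factor: the drive is scaled by
        ``(1 - b*x)(1 - b*y)`` so light efficacy depends on circadian phase.
    gamma : float
        Stiffness of the van der Pol oscillator.
    alpha0 : float
        Photoreceptor activation rate scale, per second.
    beta : float
        Photoreceptor decay rate, per second.
    I0 : float
        Light intensity scaling, lux.
    """

    mu: float = 17.87
    chi: float = 45.0 * SECONDS_PER_HOUR
    H0bar: float = 13.0
    Delta: float = 1.0
    ca: float = 1.72
    tauc: float = 24.2
    f: float = 0.99669
    G: float = 19.9
    p: float = 0.6
    k: float = 0.55
    b: float = 0.4
    gamma: float = 0.23
    alpha0: float = 0.16 / 60.0
    beta: float = 0.013 / 60.0
    I0: float = 9500.0

    @property
    def kappa(self) -> float:
        """Derived time-scale constant 24*3600/(2*pi) seconds."""
        return KAPPA

    def __post_init__(self) -> None:
        for name in ("mu", "chi", "Delta", "tauc", "f", "G", "p", "k", "b",
                     "alpha0", "beta", "I0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.H0bar <= 0 or self.ca < 0:
            raise ValueError("H0bar must be positive and ca non-negative")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given parameters replaced."""
        return dataclasses.replace(self, **changes)

    @property
    def physiological(self) -> bool:
        """Whether spontaneous sleep onset is possible at every circadian
        phase, i.e. ``mu > ca + H0bar + Delta/2``."""
        return self.mu > self.ca + self.H0bar + 0.5 * self.Delta

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


#: Names a user may sweep or fit.
PARAMETER_NAMES = (
    "mu", "chi", "H0bar", "Delta", "ca",
    "tauc", "f", "G", "p", "k", "b", "gamma", "alpha0", "beta", "I0",
)


@dataclass(frozen=True)
class WakePropensityCoeffs:
    """Coefficients of the quadratic form for the circadian wake-propensity
    rhythm ``C = c20 + a21*x + a22*y + b21*x^2 + b22*x*y + b23*y^2``.

    On the entrained limit cycle the resulting waveform has peak-to-peak
    amplitude ~2, a maximum shortly before habitual sleep onset and a
    minimum in the second half of the night.
    """

    c20: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    b21: float = 0.0
    b22: float = 0.0
    b23: float = 0.0

    def as_tuple(self) -> tuple[float, ...]:
        return (self.c20, self.a21, self.a22, self.b21, self.b22, self.b23)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WakePropensityCoeffs":
        return cls(**d)
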