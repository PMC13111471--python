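"""Lumped joint description and gait-derived cyclic loading.

The joint is reduced to a zero-dimensional cavity: a synovial volume, an
injected HA volume and (optionally) a lumped capsular compliance.  Gait
is represented as a strain-controlled oscillation of the fluid film at
the step frequency; axial load enters through a body-weight multiple
that scales the shear-strain amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .exceptions import ParameterError, ResolutionError


class JointType(str, Enum):
    KNEE = "knee"
    HIP = "hip"
    SHOULDER = "shoulder"


#: Mean synovial cavity volumes (mL) by joint.
SYNOVIAL_VOLUME_RANGE = {
    JointType.KNEE: (5.0, 8.0),
    JointType.HIP: (3.0, 6.0),
    JointType.SHOULDER: (2.0, 4.0),
}

#: Admissible injected volume (mL) irrespective of joint.
INJECTED_VOLUME_RANGE = (1.0, 4.0)

#: Gait frequency band (Hz), i.e. 30–120 steps/min.
FREQUENCY_RANGE = (0.5, 2.0)

#: Axial load band as multiples of body weight during gait.
LOAD_MULTIPLE_RANGE = (1.0, 3.0)

#: Shear-strain amplitude per unit body-weight multiple (see module docs).
STRAIN_PER_LOAD_MULTIPLE = 0.25


@dataclass(frozen=True)
class JointSpec:
    """Lumped description of one articular cavity.

    ``capsule_compliance`` (mL/kPa) is accepted for forward compatibility
    with a pressure extension but is not used by the default lumped model.
    """

    joint_type: JointType
    synovial_volume: float  # mL
    injected_volume: float  # mL
    body_weight: float = 70.0  # kg
    capsule_compliance: Optional[float] = None  # mL/kPa, currently unused

    def __post_init__(self) -> None:
        try:
            jt = JointType(self.joint_type)
        except ValueError:
            raise ParameterError(f"unknown joint type: {self.joint_type!r}") from None
        object.__setattr__(self, "joint_type", jt)
        lo, hi = SYNOVIAL_VOLUME_RANGE[jt]
        if not (lo <= self.synovial_volume <= hi):
            raise ParameterError(
                f"{jt.value}: synovial volume {self.synovial_volume} mL outside [{lo}, {hi}]"
            )
        lo, hi = INJECTED_VOLUME_RANGE
        if not (lo <= self.injected_volume <= hi):
            raise ParameterError(
                f"injected volume {self.injected_volume} mL outside [{lo}, {hi}]"
            )
        if self.body_weight <= 0.0:
            raise ParameterError("body_weight must be > 0")


@dataclass(frozen=True)
class GaitLoading:
    """Strain-controlled cyclic loading waveform.

    The strain amplitude defaults to ``STRAIN_PER_LOAD_MULTIPLE *
    peak_load_multiple`` (0.5 at 2x body weight), which keeps the peak
    shear rates of ordinary gait well inside the 0.1–100 1/s band over
    which the shear-thinning law is parameterised.
    """

    frequency: float  # Hz
    peak_load_multiple: float = 2.0  # x body weight
    strain_amplitude: Optional[float] = None
    n_cycles: int = 100
    dt: Optional[float] = None  # s
    waveform: str = "sine"

    def __post_init__(self) -> None:
        lo, hi = FREQUENCY_RANGE
        if not (lo <= self.frequency <= hi):
            raise ParameterError(f"frequency {self.frequency} Hz outside [{lo}, {hi}]")
        lo, hi = LOAD_MULTIPLE_RANGE
        if not (lo <= self.peak_load_multiple <= hi):
            raise ParameterError(
                f"peak_load_multiple {self.peak_load_multiple} outside [{lo}, {hi}]"
            )
        if self.strain_amplitude is None:
            object.__setattr__(
                self, "strain_amplitude", STRAIN_PER_LOAD_MULTIPLE * self.peak_load_multiple
            )
        elif self.strain_amplitude < 0.0:
            raise ParameterError("strain_amplitude must be >= 0")
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.dt is None:
            object.__setattr__(self, "dt", 1e-3 / self.frequency)
        if self.dt <= 0.0 or self.dt > 1.0 / (100.0 * self.frequency):
            raise ResolutionError(
                f"dt={self.dt} too coarse: need dt <= 1/(100*frequency) = "
                f"{1.0 / (100.0 * self.frequency):.6g} s"
            )
        if self.waveform not in ("sine", "haversine"):
            raise ParameterError(f"unknown waveform {self.waveform!r}")

    @property
    def angular_frequency(self) -> float:
        """omega = 2 pi f, rad/s."""
        return 2.0 * np.pi * self.frequency


def steps_to_frequency(steps_per_min: float) -> float:
    """Convert a cadence in steps/min to a loading frequency in Hz.

    One loading cycle per step: 30–120 steps/min maps onto 0.5–2.0 Hz.
    """
    if steps_per_min <= 0.0:
        raise ParameterError(f"steps_per_min must be > 0, got {steps_per_min}")
    return steps_per_min / 60.0


def gait_waveform(loading: GaitLoading) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the strain and strain-rate series for the loading programme.

    Returns
    -------
    (t, strain, strain_rate):
        Time base covering ``n_cycles`` full periods at step ``dt``
        (``round(n_cycles/(f*dt)) + 1`` samples, endpoint included),
        with gamma(0) = 0 and max |gamma_dot| = gamma_0 * 2 pi f for the
        default sine waveform.  The strain rate is analytic, not a finite
        difference.
    """
    f = loading.frequency
    g0 = loading.strain_amplitude
    n_samples = int(round(loading.n_cycles / (f * loading.dt))) + 1
    t = np.arange(n_samples) * loading.dt
    w = 2.0 * np.pi * f
    if loading.waveform == "sine":
        strain = g0 * np.sin(w * t)
        strain_rate = g0 * w * np.cos(w * t)
    else:  # haversine: unidirectional compression pulse train
        strain = 0.5 * g0 * (1.0 - np.cos(w * t))
        strain_rate = 0.5 * g0 * w * np.sin(w * t)
    return t, strain, strain_rate


@dataclass(frozen=True)
class InjectionAdmissibility:
    """Outcome of the volume-tolerance check for one joint."""

    admissible: bool
    borderline: bool
    efflux_fraction: float


#: Fraction of injected HA lost to capsular efflux in the borderline band.
BORDERLINE_EFFLUX = 0.25
#: Fraction lost under frank capsular overdistension.
OVERDISTENSION_EFFLUX = 0.5


def injection_admissibility(
    joint: JointSpec,
    borderline_efflux: float = BORDERLINE_EFFLUX,
    overdistension_efflux: float = OVERDISTENSION_EFFLUX,
) -> InjectionAdmissibility:
    """Classify the injected volume against joint-specific tolerance.

    The knee tolerates the full 1–4 mL dosing range without efflux.  The
    smaller, more pressurised hip and shoulder cavities tolerate at most
    2 mL; 2–3 mL is borderline (partial pressure-driven efflux) and
    >= 3 mL causes capsular overdistension with substantial efflux.  The
    efflux fractions themselves are configurable model constants.
    """
    v = joint.injected_volume
    if joint.joint_type is JointType.KNEE:
        return InjectionAdmissibility(admissible=True, borderline=False, efflux_fraction=0.0)
    if v <= 2.0:
        return InjectionAdmissibility(admissible=True, borderline=False, efflux_fraction=0.0)
    if v < 3.0:
        return InjectionAdmissibility(
            admissible=False, borderline=True, efflux_fraction=borderline_efflux
        )
    return InjectionAdmissibility(
        admissible=False, borderline=False, efflux_fraction=overdistension_efflux
    )
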