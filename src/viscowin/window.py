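"""The optimal viscoelastic window and patient/joint alignment rules.

A formulation is *in window* when its reference-condition rheology
(37 °C, 10 1/s) falls inside the optimal band for damping, coverage and
retention:

* storage modulus G' in [120, 220] Pa,
* dynamic viscosity eta in [50, 120] Pa·s,
* loss tangent tan δ in [0.4, 0.6].

*Alignment* additionally conditions on the patient and the target joint:
advanced radiographic disease (KL III–IV) demands a more concentrated
(>= 20 mg/mL) and stiffer (G' > 160 Pa) product to offset elevated
synovial turnover, and the small rotational joints (hip, shoulder)
demand low injection volumes (<= 2 mL), high elasticity (G' > 180 Pa)
and moderate viscosity (60–100 Pa·s).  Window boundaries are closed
intervals; the patient/joint modifiers use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hasim import KLGrade
from .loading import JointSpec, JointType
from .rheology import FormulationRheology


@dataclass(frozen=True)
class WindowBounds:
    """Closed intervals defining the optimal viscoelastic window."""

    g_prime_lo: float = 120.0
    g_prime_hi: float = 220.0
    eta_lo: float = 50.0
    eta_hi: float = 120.0
    tan_delta_lo: float = 0.4
    tan_delta_hi: float = 0.6

    def __post_init__(self) -> None:
        for lo, hi, label in (
            (self.g_prime_lo, self.g_prime_hi, "g_prime"),
            (self.eta_lo, self.eta_hi, "eta"),
            (self.tan_delta_lo, self.tan_delta_hi, "tan_delta"),
        ):
            if not lo < hi:
                raise ValueError(f"{label}: require lo < hi, got ({lo}, {hi})")


DEFAULT_BOUNDS = WindowBounds()


def in_window(formulation: FormulationRheology, bounds: WindowBounds = DEFAULT_BOUNDS) -> bool:
    """True iff G', eta and tan δ all lie within their closed intervals."""
    return (
        bounds.g_prime_lo <= formulation.g_prime <= bounds.g_prime_hi
        and bounds.eta_lo <= formulation.eta_ref <= bounds.eta_hi
        and bounds.tan_delta_lo <= formulation.tan_delta <= bounds.tan_delta_hi
    )


# Patient/joint alignment modifiers (strict inequalities).
KL_MIN_CONCENTRATION = 20.0  # mg/mL, required in KL III-IV
KL_MIN_G_PRIME = 160.0  # Pa, required (exclusive) in KL III-IV
SMALL_JOINT_MAX_VOLUME = 2.0  # mL
SMALL_JOINT_MIN_G_PRIME = 180.0  # Pa, exclusive
SMALL_JOINT_ETA_RANGE = (60.0, 100.0)  # Pa·s, inclusive


def alignment_label(
    formulation: FormulationRheology,
    kl_grade,
    joint: JointSpec,
    bounds: WindowBounds = DEFAULT_BOUNDS,
) -> bool:
    """Whether the formulation is aligned with this patient and joint.

    Aligned means in-window *and* compatible with the disease-severity
    modifier (KL III–IV requires concentration >= 20 mg/mL and
    G' > 160 Pa) *and* with the joint modifier (hip/shoulder require
    injected volume <= 2 mL, G' > 180 Pa and eta in [60, 100] Pa·s).
    Alignment is therefore always a subset of the in-window set.
    """
    kl = KLGrade.parse(kl_grade)
    if not in_window(formulation, bounds):
        return False
    if kl >= KLGrade.III and not (
        formulation.concentration >= KL_MIN_CONCENTRATION
        and formulation.g_prime > KL_MIN_G_PRIME
    ):
        return False
    if joint.joint_type is not JointType.KNEE:
        eta_lo, eta_hi = SMALL_JOINT_ETA_RANGE
        if not (
            joint.injected_volume <= SMALL_JOINT_MAX_VOLUME
            and formulation.g_prime > SMALL_JOINT_MIN_G_PRIME
            and eta_lo <= formulation.eta_ref <= eta_hi
        ):
            return False
    return True
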