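"""Constitutive rheology of hyaluronic-acid (HA) viscosupplements.

Synovial-fluid substitutes based on sodium hyaluronate behave as
shear-thinning viscoelastic liquids.  This module provides the two
constitutive ingredients used throughout the package:

* a Carreau–Yasuda law ``eta(gamma_dot)`` interpolating between the
  zero-shear plateau ``eta_zero`` and the infinite-shear plateau
  ``eta_inf``, which captures the progressive thinning of high
  molecular-weight HA under gait-induced shear, and
* a Kelvin–Voigt stress law ``sigma(t) = G' * gamma(t) +
  eta(|gamma_dot|) * gamma_dot(t)`` — a spring (storage modulus G')
  in parallel with a shear-rate-dependent dashpot.

All reference rheometry is taken at 37 °C and a shear rate of 10 1/s;
formulations carry their storage modulus G' (Pa), dynamic viscosity at
the reference shear rate (Pa·s) and loss tangent tan δ = G''/G'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import InfeasibleCalibrationError, ParameterError, ShapeError

#: Reference measurement conditions for tabulated rheology.
REF_TEMPERATURE_C = 37.0
REF_SHEAR_RATE = 10.0  # 1/s

#: Range of HA concentrations (mg/mL) covered by the model.
CONCENTRATION_RANGE = (10.0, 40.0)
#: Range of molecular weights (MDa) covered by the model.
MOL_WEIGHT_RANGE = (0.5, 3.0)


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Parameters of the Carreau–Yasuda shear-thinning law.

    eta(gamma_dot) = eta_inf + (eta_zero - eta_inf)
                     * [1 + (lam * gamma_dot)**a_exp]**((n_index - 1)/a_exp)

    Attributes
    ----------
    eta_zero:
        Zero-shear viscosity plateau, Pa·s.
    eta_inf:
        Infinite-shear viscosity plateau, Pa·s.
    lam:
        Characteristic relaxation time λ, s; sets the shear rate
        ``1/lam`` at which thinning begins.
    a_exp:
        Yasuda transition-width exponent (dimensionless, > 0).
    n_index:
        Power-law index n in (0, 1]; n = 1 recovers a Newtonian fluid.
    """

    eta_zero: float
    eta_inf: float = 0.0
    lam: float = 0.0
    a_exp: float = 2.0
    n_index: float = 0.5

    def __post_init__(self) -> None:
        if not (self.eta_zero >= self.eta_inf >= 0.0):
            raise ParameterError(
                f"require eta_zero >= eta_inf >= 0, got ({self.eta_zero}, {self.eta_inf})"
            )
        if self.lam < 0.0:
            raise ParameterError(f"lam must be >= 0, got {self.lam}")
        if self.a_exp <= 0.0:
            raise ParameterError(f"a_exp must be > 0, got {self.a_exp}")
        if not (0.0 < self.n_index <= 1.0):
            raise ParameterError(
                f"n_index must lie in (0, 1] (shear-thinning or Newtonian), got {self.n_index}"
            )


def carreau_yasuda_viscosity(cy: CarreauYasudaParams, shear_rate):
    """Evaluate the Carreau–Yasuda viscosity at the given shear rate(s).

    Parameters
    ----------
    cy:
        Model parameters (validated at construction).
    shear_rate:
        Non-negative shear rate, 1/s; scalar or array.

    Returns
    -------
    Viscosity in Pa·s, guaranteed to lie in ``[eta_inf, eta_zero]``.
    """
    rate = np.asarray(shear_rate, dtype=float)
    if np.any(rate < 0.0):
        raise ParameterError("shear_rate must be >= 0")
    expo = (cy.n_index - 1.0) / cy.a_exp
    eta = cy.eta_inf + (cy.eta_zero - cy.eta_inf) * (1.0 + (cy.lam * rate) ** cy.a_exp) ** expo
    if np.isscalar(shear_rate) or np.ndim(shear_rate) == 0:
        return float(eta)
    return eta


def calibrate_lambda(
    eta_zero: float,
    eta_inf: float,
    a_exp: float,
    n_index: float,
    eta_ref: float,
    ref_shear_rate: float = REF_SHEAR_RATE,
) -> float:
    """Solve for the relaxation time λ that pins ``eta(ref_shear_rate) == eta_ref``.

    The Carreau–Yasuda law is strictly decreasing in λ at fixed shear rate
    (for n < 1), so the 1-D problem has a unique root, obtained here by
    analytic inversion of the closed form.

    Raises
    ------
    InfeasibleCalibrationError
        If ``eta_ref`` does not lie strictly between the two plateaus, or
        if n = 1 (a Newtonian fluid cannot thin down to ``eta_ref``).
    """
    # validate the remaining parameters through the dataclass invariants
    CarreauYasudaParams(eta_zero=eta_zero, eta_inf=eta_inf, lam=0.0, a_exp=a_exp, n_index=n_index)
    if ref_shear_rate <= 0.0:
        raise ParameterError(f"ref_shear_rate must be > 0, got {ref_shear_rate}")
    if not (eta_inf < eta_ref < eta_zero):
        raise InfeasibleCalibrationError(
            f"eta_ref={eta_ref} must lie strictly between eta_inf={eta_inf} "
            f"and eta_zero={eta_zero}"
        )
    if n_index == 1.0:
        raise InfeasibleCalibrationError("n_index = 1 (Newtonian) cannot reach eta_ref < eta_zero")
    ratio = (eta_ref - eta_inf) / (eta_zero - eta_inf)  # in (0, 1)
    base = ratio ** (a_exp / (n_index - 1.0)) - 1.0  # (lam * rate)**a_exp
    return base ** (1.0 / a_exp) / ref_shear_rate


@dataclass(frozen=True)
class FormulationRheology:
    """Composition and 37 °C / 10 1/s rheometry of one HA product.

    Attributes
    ----------
    name:
        Product label.
    concentration:
        HA concentration, mg/mL (10–40).
    mol_weight:
        Mean molecular weight, MDa (0.5–3.0).
    crosslinked:
        Whether the polymer network is chemically cross-linked.
    g_prime:
        Storage modulus G', Pa.
    eta_ref:
        Dynamic viscosity at the reference shear rate of 10 1/s, Pa·s.
    tan_delta:
        Loss tangent tan δ = G''/G' (measured independently; see
        :func:`loss_modulus`).
    cy:
        Optional calibrated Carreau–Yasuda parameters; attach with
        :meth:`calibrated` when absent.
    """

    name: str
    concentration: float
    mol_weight: float
    crosslinked: bool
    g_prime: float
    eta_ref: float
    tan_delta: float
    cy: Optional[CarreauYasudaParams] = None

    def __post_init__(self) -> None:
        lo, hi = CONCENTRATION_RANGE
        if not (lo <= self.concentration <= hi):
            raise ParameterError(
                f"{self.name}: concentration {self.concentration} mg/mL outside [{lo}, {hi}]"
            )
        lo, hi = MOL_WEIGHT_RANGE
        if not (lo <= self.mol_weight <= hi):
            raise ParameterError(
                f"{self.name}: molecular weight {self.mol_weight} MDa outside [{lo}, {hi}]"
            )
        if self.g_prime <= 0.0:
            raise ParameterError(f"{self.name}: g_prime must be > 0")
        if self.eta_ref <= 0.0:
            raise ParameterError(f"{self.name}: eta_ref must be > 0")
        if self.tan_delta <= 0.0:
            raise ParameterError(f"{self.name}: tan_delta must be > 0")

    @property
    def g_double_prime(self) -> float:
        """Loss modulus G'' = tan δ · G', Pa."""
        return loss_modulus(self.g_prime, self.tan_delta)

    def calibrated(
        self,
        eta_zero: Optional[float] = None,
        eta_inf: float = 0.0,
        a_exp: float = 2.0,
        n_index: float = 0.5,
        ref_shear_rate: float = REF_SHEAR_RATE,
    ) -> "FormulationRheology":
        """Return a copy with a Carreau–Yasuda fit pinned to ``eta_ref``.

        Only one rheometric point is tabulated per product, so the thinning
        profile is under-determined: the default shape (a = 2, n = 0.5,
        eta_inf = 0, eta_zero = 2 * eta_ref) is a physically typical HA
        thinning profile, and λ is always solved so that the law reproduces
        the tabulated viscosity at the reference shear rate exactly.
        All parameters may be overridden.
        """
        if eta_zero is None:
            eta_zero = 2.0 * self.eta_ref
        lam = calibrate_lambda(eta_zero, eta_inf, a_exp, n_index, self.eta_ref, ref_shear_rate)
        cy = CarreauYasudaParams(
            eta_zero=eta_zero, eta_inf=eta_inf, lam=lam, a_exp=a_exp, n_index=n_index
        )
        return replace(self, cy=cy)


def loss_modulus(g_prime: float, tan_delta: float) -> float:
    """Loss modulus G'' = tan δ · G' (Pa)."""
    if g_prime <= 0.0:
        raise ParameterError(f"g_prime must be > 0, got {g_prime}")
    if tan_delta < 0.0:
        raise ParameterError(f"tan_delta must be >= 0, got {tan_delta}")
    return tan_delta * g_prime


def viscoelastic_stress(g_prime: float, cy: CarreauYasudaParams, strain, strain_rate):
    """Kelvin–Voigt stress with shear-rate-dependent viscosity.

    sigma(t) = G' * gamma(t) + eta(|gamma_dot(t)|) * gamma_dot(t)

    The viscosity is evaluated at the absolute shear rate so that the
    dashpot is direction-independent; the resulting stress is odd under
    simultaneous sign reversal of strain and strain rate.

    Parameters
    ----------
    g_prime:
        Storage modulus, Pa.
    cy:
        Shear-thinning law for the dashpot.
    strain, strain_rate:
        Same-length series sharing one time base (dimensionless, 1/s).
    """
    if g_prime < 0.0:
        raise ParameterError(f"g_prime must be >= 0, got {g_prime}")
    gamma = np.asarray(strain, dtype=float)
    gamma_dot = np.asarray(strain_rate, dtype=float)
    if gamma.shape != gamma_dot.shape:
        raise ShapeError(
            f"strain and strain_rate shapes differ: {gamma.shape} vs {gamma_dot.shape}"
        )
    eta = carreau_yasuda_viscosity(cy, np.abs(gamma_dot))
    return g_prime * gamma + eta * gamma_dot


def energy_per_cycle_closed_form(
    strain_amplitude: float, eta: float, angular_frequency: float
) -> float:
    """Dissipated energy density per cycle for a constant-viscosity dashpot.

    For sinusoidal strain gamma_0 * sin(omega t) and constant viscosity the
    stress–strain loop is an ellipse of area W = pi * gamma_0**2 * eta * omega
    (J/m^3 per cycle).  Serves as the analytic oracle for the time-stepping
    simulator; with an oscillatory loss modulus G'' the same identity reads
    W = pi * gamma_0**2 * G''.
    """
    if strain_amplitude < 0.0 or eta < 0.0 or angular_frequency < 0.0:
        raise ParameterError("all arguments must be >= 0")
    return math.pi * strain_amplitude**2 * eta * angular_frequency
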