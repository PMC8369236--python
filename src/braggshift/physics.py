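"""Range-energy, stopping-power, momentum and curvature primitives.

All quantities use cm, MeV and Tesla internally.  The range-energy relation
is the Bragg-Kleeman power law R = alpha * E^p, whose fit constants for
protons in water (alpha ~ 2.43e-3 cm/MeV^p, p ~ 1.75) reproduce tabulated
CSDA ranges to a few percent over the therapeutic window.  The stopping
power is the derivative form S(E) = E^(1-p) / (alpha * p), so that range
and stopping power are analytically consistent: int_0^E dE'/S(E') = alpha E^p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StoppingModel",
    "PhysicsConstants",
    "CONSTANTS",
    "WATER",
    "range_from_energy",
    "energy_from_range",
    "stopping_power",
    "momentum",
    "curvature",
]


@dataclass(frozen=True)
class PhysicsConstants:
    """Unit-conversion constants, kept in one place.

    rigidity_constant converts momentum to curvature: a particle of momentum
    pc [GeV] and unit charge in a field B [T] has curvature
    0.29979 * B / pc per metre.  fwhm_factor is 2*sqrt(2*ln 2), the
    FWHM/sigma ratio of a Gaussian.
    """

    rigidity_constant: float = 0.29979  # GeV per (T * m)
    fwhm_factor: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


CONSTANTS = PhysicsConstants()


@dataclass(frozen=True)
class StoppingModel:
    """Bragg-Kleeman stopping model for protons in water.

    Parameters
    ----------
    alpha : range coefficient, cm * MeV^(-p).
    p : range exponent, dimensionless (between 1 and 2).
    rest_energy : proton rest energy m*c^2, MeV.
    charge_number : charge in elementary charges (1 for protons).
    cutoff_energy : transport stop energy, MeV; below it the residual
        energy is deposited locally.
    """

    alpha: float = 2.43e-3
    p: float = 1.75
    rest_energy: float = 938.272
    charge_number: int = 1
    cutoff_energy: float = 0.1

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 1.0 < self.p < 2.0:
            raise ValueError(f"p must lie in (1, 2), got {self.p}")
        if not self.rest_energy > 0:
            raise ValueError("rest_energy must be positive")
        if self.charge_number < 1:
            raise ValueError("charge_number must be >= 1")
        if self.cutoff_energy < 0:
            raise ValueError("cutoff_energy must be non-negative")


#: Default water model.
WATER = StoppingModel()


def range_from_energy(energy, model: StoppingModel = WATER):
    """CSDA range in water [cm] for kinetic energy [MeV]: R = alpha * E^p."""
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < 0):
        raise ValueError("energy must be non-negative")
    out = model.alpha * energy**model.p
    return float(out) if out.ndim == 0 else out


def energy_from_range(range_cm, model: StoppingModel = WATER):
    """Kinetic energy [MeV] whose CSDA range is ``range_cm``: (R/alpha)^(1/p)."""
    range_cm = np.asarray(range_cm, dtype=float)
    if np.any(range_cm < 0):
        raise ValueError("range must be non-negative")
    out = (range_cm / model.alpha) ** (1.0 / model.p)
    return float(out) if out.ndim == 0 else out


def stopping_power(energy, model: StoppingModel = WATER):
    """Stopping power S(E) = E^(1-p) / (alpha * p) in MeV/cm.

    This is -dE/dz implied by the range law, so quadrature of 1/S
    reproduces ``range_from_energy`` exactly.
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy <= 0):
        raise ValueError("energy must be positive for stopping power")
    out = energy ** (1.0 - model.p) / (model.alpha * model.p)
    return float(out) if out.ndim == 0 else out


def momentum(energy, relativistic: bool = True, model: StoppingModel = WATER):
    """Momentum pc [MeV] at kinetic energy E.

    Relativistic: pc = sqrt(E^2 + 2 mc^2 E).  Non-relativistic:
    pc = sqrt(2 mc^2 E) (the sqrt(2mE) factor of the analytic shift model).
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < 0):
        raise ValueError("energy must be non-negative")
    mc2 = model.rest_energy
    if relativistic:
        out = np.sqrt(energy**2 + 2.0 * mc2 * energy)
    else:
        out = np.sqrt(2.0 * mc2 * energy)
    return float(out) if out.ndim == 0 else out


def curvature(
    energy,
    field_tesla: float,
    relativistic: bool = True,
    model: StoppingModel = WATER,
    constants: PhysicsConstants = CONSTANTS,
):
    """Track curvature kappa [1/cm] of a proton of kinetic energy E in field B.

    kappa = 0.29979 * q * B / pc[GeV], converted to 1/cm.  Zero field gives
    zero curvature (straight track); zero energy with nonzero field is a
    domain error (infinite curvature).
    """
    if field_tesla < 0:
        raise ValueError("field must be non-negative")
    energy = np.asarray(energy, dtype=float)
    if field_tesla == 0:
        out = np.zeros_like(energy)
        return float(out) if out.ndim == 0 else out
    if np.any(energy <= 0):
        raise ValueError("curvature diverges at zero energy in a nonzero field")
    pc_gev = np.asarray(momentum(energy, relativistic=relativistic, model=model)) / 1000.0
    out = constants.rigidity_constant * model.charge_number * field_tesla / pc_gev / 100.0
    return float(out) if out.ndim == 0 else out
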