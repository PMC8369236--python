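"""Closed-form model of Bragg-peak position shifts in a uniform magnetic field.

A proton pencil beam entering water perpendicular to a uniform field B is
deflected by the Lorentz force.  In the continuous slowing-down
approximation the residual range at arc length s is R - s, so the local
curvature kappa(E(s)) can be integrated in closed form under the
Bragg-Kleeman range law R = alpha * E^p.  Two small-angle integrals give

* the lateral Bragg-peak shift

      WD = (2p/(4p-1)) * kappa0 * alpha^2 * E0^((4p-1)/2)

  where kappa0 = C*q*B/sqrt(2 mc^2) collects the curvature prefactor at
  unit sqrt(energy); at p = 1.75 the coefficient is 7/12 and the energy
  power is exactly 3;

* the penetration-depth retraction (path curvature shortens the depth
  reached at end of range)

      dDD = kappa0^2 * alpha^3 * E0^(3p-1) * 2p^2 / ((4p-1)(3p-1)).

A first-order relativistic momentum expansion multiplies WD by
(1 - (3/8) * E0 / (2 mc^2)).  Both forward maps invert algebraically,
which is how a required shift selects the incident energy at a given
field strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .physics import CONSTANTS, WATER, PhysicsConstants, StoppingModel, range_from_energy

__all__ = [
    "ShiftPrediction",
    "lateral_shift",
    "depth_retraction",
    "energy_for_lateral_shift",
    "energy_for_depth_retraction",
    "deflection_angle",
    "relativistic_correction",
    "prediction_table",
    "predictions_to_frame",
]


@dataclass(frozen=True)
class ShiftPrediction:
    """Predicted Bragg-peak displacement for one (energy, field) pair.

    wd is the lateral shift [cm] perpendicular to the field and to the
    incident axis; ddd the depth retraction [cm] along the incident axis;
    angle_def the deflection angle [deg] of the peak position seen from
    the entry point.
    """

    energy: float
    field: float
    wd: float
    ddd: float
    angle_def: float
    relativistic: bool


def _kappa0(field_tesla: float, model: StoppingModel, constants: PhysicsConstants) -> float:
    """Curvature prefactor kappa0 [cm^-1 MeV^(1/2)]: kappa(E) = kappa0 / sqrt(E)."""
    # 0.29979 GeV/(T m) -> 2.9979 MeV/(T cm) working in MeV and cm
    c_mev_cm = constants.rigidity_constant * 1000.0 / 100.0
    return c_mev_cm * model.charge_number * field_tesla / math.sqrt(2.0 * model.rest_energy)


def relativistic_correction(energy, model: StoppingModel = WATER):
    """First-order momentum correction factor (1 - (3/8) E / (2 mc^2)); < 1."""
    energy = np.asarray(energy, dtype=float)
    out = 1.0 - 0.375 * energy / (2.0 * model.rest_energy)
    return float(out) if out.ndim == 0 else out


def lateral_shift(
    energy,
    field_tesla: float,
    relativistic: bool = False,
    model: StoppingModel = WATER,
    constants: PhysicsConstants = CONSTANTS,
):
    """Lateral Bragg-peak shift WD [cm] at incident energy E0 [MeV], field B [T].

    Non-relativistic closed form (exactly invertible); with
    ``relativistic=True`` the first-order correction factor is applied.
    """
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < 0):
        raise ValueError("energy must be non-negative")
    if field_tesla < 0:
        raise ValueError("field must be non-negative")
    p = model.p
    coef = (2.0 * p / (4.0 * p - 1.0)) * _kappa0(field_tesla, model, constants) * model.alpha**2
    out = coef * energy ** ((4.0 * p - 1.0) / 2.0)
    if relativistic:
        out = out * relativistic_correction(energy, model)
    return float(out) if out.ndim == 0 else out


def _ddd_prefactor(field_tesla: float, model: StoppingModel, constants: PhysicsConstants) -> float:
    p = model.p
    k0 = _kappa0(field_tesla, model, constants)
    return k0**2 * model.alpha**3 * 2.0 * p**2 / ((4.0 * p - 1.0) * (3.0 * p - 1.0))


def depth_retraction(
    energy,
    field_tesla: float,
    model: StoppingModel = WATER,
    constants: PhysicsConstants = CONSTANTS,
):
    """Depth retraction dDD [cm] of the Bragg peak; scales exactly as B^2."""
    energy = np.asarray(energy, dtype=float)
    if np.any(energy < 0):
        raise ValueError("energy must be non-negative")
    if field_tesla < 0:
        raise ValueError("field must be non-negative")
    out = _ddd_prefactor(field_tesla, model, constants) * energy ** (3.0 * model.p - 1.0)
    return float(out) if out.ndim == 0 else out


def energy_for_lateral_shift(
    wd_cm: float,
    field_tesla: float,
    model: StoppingModel = WATER,
    constants: PhysicsConstants = CONSTANTS,
) -> float:
    """Incident energy [MeV] whose non-relativistic lateral shift equals wd_cm.

    Exact algebraic inverse of :func:`lateral_shift`; at p = 1.75 this is
    the cube-root inversion used to select beam energy for a required
    lateral displacement.
    """
    if wd_cm < 0:
        raise ValueError("wd must be non-negative")
    if wd_cm == 0:
        return 0.0
    if field_tesla <= 0:
        raise ValueError("no energy produces a lateral shift at zero field")
    p = model.p
    coef = (2.0 * p / (4.0 * p - 1.0)) * _kappa0(field_tesla, model, constants) * model.alpha**2
    return float((wd_cm / coef) ** (2.0 / (4.0 * p - 1.0)))


def energy_for_depth_retraction(
    ddd_cm: float,
    field_tesla: float,
    model: StoppingModel = WATER,
    constants: PhysicsConstants = CONSTANTS,
) -> float:
    """Incident energy [MeV] whose depth retraction equals ddd_cm (exact inverse)."""
    if ddd_cm < 0:
        raise ValueError("ddd must be non-negative")
    if ddd_cm == 0:
        return 0.0
    if field_tesla <= 0:
        raise ValueError("no energy produces a depth retraction at zero field")
    pref = _ddd_prefactor(field_tesla, model, constants)
    return float((ddd_cm / pref) ** (1.0 / (3.0 * model.p - 1.0)))


def deflection_angle(
    wd_cm: float,
    ddd_cm: float,
    energy: float,
    model: StoppingModel = WATER,
) -> float:
    """Deflection angle [deg] of the peak position from the incident axis.

    The adjacent side is the retracted depth R(E0) - dDD, the opposite the
    lateral shift WD.
    """
    if wd_cm < 0 or ddd_cm < 0:
        raise ValueError("shifts must be non-negative")
    if energy <= 0:
        raise ValueError("energy must be positive")
    depth = range_from_energy(energy, model) - ddd_cm
    if depth <= 0:
        raise ValueError("depth retraction exceeds the proton range")
    return math.degrees(math.atan2(wd_cm, depth))


def predict(
    energy: float,
    field_tesla: float,
    relativistic: bool = False,
    model: StoppingModel = WATER,
) -> ShiftPrediction:
    """Full prediction (WD, dDD, deflection angle) for one (energy, field)."""
    wd = lateral_shift(energy, field_tesla, relativistic=relativistic, model=model)
    ddd = depth_retraction(energy, field_tesla, model=model)
    angle = deflection_angle(wd, ddd, energy, model=model) if energy > 0 else 0.0
    return ShiftPrediction(
        energy=float(energy),
        field=float(field_tesla),
        wd=float(wd),
        ddd=float(ddd),
        angle_def=float(angle),
        relativistic=relativistic,
    )


def prediction_table(
    energies: Sequence[float],
    fields: Sequence[float],
    relativistic: bool = False,
    model: StoppingModel = WATER,
) -> list[ShiftPrediction]:
    """Cartesian product of predictions, energy-major ordering."""
    energies = list(energies)
    fields = list(fields)
    if not energies or not fields:
        raise ValueError("energies and fields must be non-empty")
    return [
        predict(e, b, relativistic=relativistic, model=model)
        for e in energies
        for b in fields
    ]


def predictions_to_frame(predictions: Iterable[ShiftPrediction]) -> pd.DataFrame:
    """Tabulate predictions with the CSV column names used by the CLI."""
    rows = [
        {
            "energy_mev": pr.energy,
            "field_t": pr.field,
            "wd_cm": pr.wd,
            "ddd_cm": pr.ddd,
            "angle_deg": pr.angle_def,
            "relativistic": pr.relativistic,
        }
        for pr in predictions
    ]
    return pd.DataFrame(rows)
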