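"""TIMS mobility physics: voltage calibration and CCS conversion.

Converts between TIMS elution voltage, inverse reduced mobility (1/K0,
Vs cm^-2) and collision cross section (Angstrom^2) in nitrogen. The
CCS conversion uses the Mason-Schamp relation for reduced mobility, so
no pressure input is needed: the gas number density is fixed at the
273.15 K / 1 atm Loschmidt value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CalibrantPoint",
    "CalibrationModel",
    "DEFAULT_CONSTANTS",
    "fit_voltage_calibration",
    "ccs_from_inverse_mobility",
    "inverse_mobility_from_ccs",
]

#: 1 unified atomic mass unit in kg (CODATA 2018).
DALTON_KG = 1.66053906660e-27


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the CCS conversion.

    The drift-gas temperature of a TIMS tunnel is not controlled by the
    instrument; 305 K is the conventional assumption and is configurable.
    ``gas_mass`` defaults to molecular nitrogen.
    """

    elementary_charge: float = 1.602176634e-19  # C
    boltzmann: float = 1.380649e-23  # J K^-1
    loschmidt: float = 2.686780111e25  # m^-3 (273.15 K, 1 atm)
    gas_mass: float = 28.013406  # Da
    temperature: float = 305.0  # K

    def __post_init__(self) -> None:
        for name in (
            "elementary_charge",
            "boltzmann",
            "loschmidt",
            "gas_mass",
            "temperature",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"PhysicalConstants.{name} must be > 0")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class CalibrantPoint:
    """One calibrant ion: m/z, reference 1/K0 and its TIMS elution voltage."""

    mz: float
    ref_inv_k0: float
    elution_voltage: float

    def __post_init__(self) -> None:
        if self.ref_inv_k0 <= 0:
            raise ValueError("ref_inv_k0 must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from elution voltage to 1/K0 (Vs cm^-2)."""

    intercept: float
    slope: float
    n_points: int
    max_abs_residual: float
    residuals: tuple = field(default=(), repr=False)

    def predict(self, voltage):
        return self.intercept + self.slope * np.asarray(voltage, dtype=float)


def fit_voltage_calibration(points: Sequence[CalibrantPoint]) -> CalibrationModel:
    """Ordinary least-squares fit of 1/K0 on elution voltage.

    Requires at least three calibrant ions with distinct voltages.
    Residuals are always reported on the returned model.
    """
    if len(points) < 3:
        raise ValueError(
            f"voltage calibration needs >= 3 calibrant points, got {len(points)}"
        )
    v = np.array([p.elution_voltage for p in points], dtype=float)
    y = np.array([p.ref_inv_k0 for p in points], dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("singular calibration fit: all elution voltages equal")
    slope, intercept = np.polyfit(v, y, 1)
    resid = y - (intercept + slope * v)
    return CalibrationModel(
        intercept=float(intercept),
        slope=float(slope),
        n_points=len(points),
        max_abs_residual=float(np.max(np.abs(resid))),
        residuals=tuple(resid.tolist()),
    )


def _mobility_coefficient(charge, mz, constants: PhysicalConstants):
    """CCS (m^2) per unit 1/K0 (SI, Vs m^-2)."""
    charge = np.asarray(charge, dtype=float)
    mz = np.asarray(mz, dtype=float)
    if np.any(charge < 1):
        raise ValueError("charge must be >= 1")
    if np.any(mz <= 0):
        raise ValueError("mz must be > 0")
    ion_mass = charge * mz * DALTON_KG  # no electron-mass correction
    gas_mass = constants.gas_mass * DALTON_KG
    mu = ion_mass * gas_mass / (ion_mass + gas_mass)
    return (
        3.0
        * charge
        * constants.elementary_charge
        / (16.0 * constants.loschmidt)
        * np.sqrt(2.0 * np.pi / (mu * constants.boltzmann * constants.temperature))
    )


def ccs_from_inverse_mobility(
    inv_k0, charge, mz, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Convert 1/K0 (Vs cm^-2) to CCS (Angstrom^2) via Mason-Schamp.

    Accepts scalars or array-likes (broadcast together). The reduced mass
    uses ion mass = charge * mz.
    """
    inv_k0 = np.asarray(inv_k0, dtype=float)
    if np.any(inv_k0 <= 0):
        raise ValueError("inv_k0 must be > 0")
    coef = _mobility_coefficient(charge, mz, constants)
    ccs_m2 = coef * inv_k0 * 1.0e4  # Vs cm^-2 -> Vs m^-2
    out = ccs_m2 * 1.0e20  # m^2 -> A^2
    return float(out) if out.ndim == 0 else out


def inverse_mobility_from_ccs(
    ccs, charge, mz, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Exact algebraic inverse of :func:`ccs_from_inverse_mobility`."""
    ccs = np.asarray(ccs, dtype=float)
    if np.any(ccs <= 0):
        raise ValueError("ccs must be > 0")
    coef = _mobility_coefficient(charge, mz, constants)
    inv_k0 = ccs * 1.0e-20 / coef / 1.0e4
    return float(inv_k0) if inv_k0.ndim == 0 else inv_k0
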