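"""Deterministic forward model for small-particle static light scattering.

All quantities live in a single unit system: lengths in cm, concentrations
in g/mL, molar masses in g/mol, the Rayleigh ratio in 1/cm, dn/dc in mL/g
and the second virial coefficient A2 in mL·mol/g². Conversions to and from
other unit systems happen only at I/O boundaries.

The forward model is the dilute-solution, small-particle approximation of
Rayleigh scattering: the excess Rayleigh ratio of a solution of particles
of weight-average molar mass ``Mw`` at concentration ``c`` is

    R(c) = K* · Mw · c · (1 − 2·A2·Mw·c)

with the optical ("material") constant

    K* = 4·π²·n0²·(dn/dc)² / (N_A·λ⁴)

and the refractive-index difference between solution and solvent

    Δn(c) = c · dn/dc.

For scatterers much smaller than the wavelength the angular form factor
P(r_g, θ) is indistinguishable from 1; it is provided for completeness but
defaults to 1 downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

AVOGADRO = 6.022e23  # 1/mol

__all__ = [
    "AVOGADRO",
    "PhysicalConstants",
    "ForwardInputs",
    "material_constant",
    "angular_factor",
    "true_delta_n",
    "true_rayleigh",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed instrument/material constants of one experiment.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength of the incident light, in cm.
    solvent_index : float
        Refractive index of the solvent (dimensionless, ≥ 1).
    monomer_mass : float
        Molar mass of the protein monomer, g/mol.
    avogadro : float
        Avogadro's number, 1/mol.
    """

    wavelength: float = 657e-7
    solvent_index: float = 1.33
    monomer_mass: float = 14307.0
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")
        if self.solvent_index < 1:
            raise ValueError(f"solvent_index must be >= 1, got {self.solvent_index}")
        if not self.monomer_mass > 0:
            raise ValueError(f"monomer_mass must be positive, got {self.monomer_mass}")


@dataclass(frozen=True)
class ForwardInputs:
    """State of one (condition, level) cell fed to the forward model."""

    concentration: float  # g/mL
    dn_dc: float  # mL/g
    A2: float  # mL·mol/g²
    Mw: float  # g/mol
    radius_of_gyration: float = 0.0  # cm
    angle: float = 90.0  # degrees

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")
        if not self.Mw > 0:
            raise ValueError("Mw must be positive")


def material_constant(dn_dc, constants: PhysicalConstants = PhysicalConstants()):
    """Optical constant K* = 4π²·n0²·(dn/dc)²/(N_A·λ⁴).

    Quadratic in dn/dc and in n0; scales as λ⁻⁴. Units: mL²·mol·cm⁻²·g⁻²
    (so that K*·Mw·c has units 1/cm when c is in g/mL).
    """
    lam = constants.wavelength
    if not lam > 0:
        raise ValueError(f"wavelength must be positive, got {lam}")
    n0 = constants.solvent_index
    return (
        4.0
        * math.pi**2
        * n0**2
        * np.asarray(dn_dc) ** 2
        / (constants.avogadro * lam**4)
    )


def angular_factor(r_g, theta_deg=90.0, wavelength=657e-7):
    """Small-particle angular form factor P(r_g, θ).

    Uses the Guinier-type expansion P⁻¹ ≈ 1 + (16π²/3λ²)·r_g²·sin²(θ/2);
    P = 1 exactly when r_g = 0 or θ = 0. For globular proteins
    (r_g ~ 10⁻⁷ cm) at visible wavelengths P differs from 1 by < 10⁻³,
    which is why the likelihood fixes P = 1.
    """
    if not wavelength > 0:
        raise ValueError("wavelength must be positive")
    theta = np.deg2rad(theta_deg)
    p_inv = 1.0 + (16.0 * math.pi**2 / (3.0 * wavelength**2)) * np.asarray(
        r_g
    ) ** 2 * np.sin(theta / 2.0) ** 2
    return 1.0 / p_inv


def true_delta_n(c, dn_dc):
    """Refractive-index difference of the solution vs. the solvent: c·(dn/dc)."""
    return np.asarray(c) * dn_dc


def true_rayleigh(c, Mw, A2, Kstar):
    """Noise-free excess Rayleigh ratio R = K*·Mw·c·(1 − 2·A2·Mw·c).

    Linear in c at the origin with slope K*·Mw; the quadratic correction
    carries the pairwise-interaction (second virial) term. For A2 > 0 the
    curve crosses zero at c = 1/(2·A2·Mw).
    """
    c = np.asarray(c)
    return Kstar * Mw * c * (1.0 - 2.0 * A2 * Mw * c)
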