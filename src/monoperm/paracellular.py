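"""Paracellular pore-pathway resistance.

Diffusion through water-filled tight-junction pores between cells,
hindered by size sieving (Renkin hindrance in a cylindrical pore) and
by the electric field of negatively charged pore-lining residues acting
on charged microspecies.  A small secondary pore population without
sieving or field effects carries very large solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .descriptors import (
    ANGSTROM_TO_CM,
    K_BOLTZMANN_CGS,
    ModelParameters,
    SpeciationProfile,
)


@dataclass(frozen=True)
class ParacellularInputs:
    """Inputs of the paracellular submodel for one chemical."""

    mw: float
    d_aq_37: float
    speciation: SpeciationProfile


def hydrodynamic_radius(mw: float, d_aq_37: float, params: ModelParameters) -> float:
    """Hydrodynamic solute radius, angstrom.

    Stokes-Einstein radius from the aqueous diffusion coefficient with
    the Sutherland small-molecule correction ``0.92 + 21.8/MW``, using
    the *dynamic* viscosity of water at 37 C.  Evaluated in CGS and
    converted to angstrom.
    """
    eta_poise = params.eta * 10.0  # N s/m^2 -> g/(cm s)
    r_cm = (
        (0.92 + 21.8 / mw)
        * K_BOLTZMANN_CGS * params.temperature
        / (6.0 * math.pi * eta_poise * d_aq_37)
    )
    return r_cm / ANGSTROM_TO_CM


def renkin_sieving(r_hydr: float, r_pore: float) -> float:
    """Renkin hindrance factor F(rho) for a cylinder pore, rho = r_hydr/r_pore.

    ``F(0) = 1`` (point solute), decreasing to ``F(1) = 0``; solutes at
    least as large as the pore are fully excluded (clamped to 0 rather
    than evaluating the polynomial outside its physical domain).
    """
    rho = r_hydr / r_pore
    if rho >= 1.0:
        return 0.0
    return (1.0 - rho) ** 2 * (
        1.0 - 2.104 * rho + 2.09 * rho**3 - 0.95 * rho**5
    )


def _field_weight(valence: int, x: float) -> float:
    """Hindrance/acceleration of a charged species in the pore field.

    ``x = kappa * |delta_phi|``; positive valences are accelerated into
    the negatively charged pore (weight > 1), negative ones repelled
    (weight < 1); divalent species feel twice the potential.  The weight
    tends to 1 as the field vanishes.
    """
    z = abs(valence) * x
    if z == 0.0:
        return 1.0
    # expm1 keeps the z -> 0 limit accurate (weight -> 1 +- z/2)
    if valence > 0:
        return z / -math.expm1(-z)
    return z / math.expm1(z)


def efield_factor(speciation: SpeciationProfile, delta_phi: float, kappa: float) -> float:
    """Speciation-weighted electric-field factor E of the pore pathway.

    Neutral species and zwitterions (zero net charge) are unaffected
    (weight 1); cations and anions get the single-valence Goldman-type
    weights, dications and dianions the double-valence ones.
    """
    x = kappa * abs(delta_phi)
    return (
        speciation.f_neutral
        + speciation.f_zwitterion
        + speciation.f_cation * _field_weight(+1, x)
        + speciation.f_anion * _field_weight(-1, x)
        + speciation.f_dication * _field_weight(+2, x)
        + speciation.f_dianion * _field_weight(-2, x)
    )


def paracellular_resistance(inputs: ParacellularInputs, params: ModelParameters) -> float:
    """Paracellular resistance, s/cm.

    ``P_para = (eps/delta) * D_aq * F * E + (eps/delta2) * D_aq``; the
    secondary pore term has neither sieving nor field weighting.
    Returns ``inf`` when both terms vanish (closed pores).
    """
    r_hydr = hydrodynamic_radius(inputs.mw, inputs.d_aq_37, params)
    f_sieve = renkin_sieving(r_hydr, params.r_pore)
    e_field = efield_factor(inputs.speciation, params.delta_phi, params.kappa)
    p_para = (
        params.eps_over_delta * inputs.d_aq_37 * f_sieve * e_field
        + params.eps_over_delta2 * inputs.d_aq_37
    )
    if p_para <= 0.0:
        return math.inf
    return 1.0 / p_para
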