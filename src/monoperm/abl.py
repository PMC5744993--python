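"""Aqueous boundary layer resistances.

Three stagnant-water barriers are serial in every permeation pathway:
the unstirred water layer (UWL) adjacent to the monolayer, the crowded
cytosolic water, and the water-filled pores of the supporting filter.
Speciation is irrelevant here — neutral and ionic species diffuse
through water at the same rate — so each resistance depends only on the
aqueous diffusion coefficient and layer geometry.
"""

from __future__ import annotations

from .descriptors import ModelParameters, effective_rpm


def uwl_resistance(stirring_rpm: float | None, params: ModelParameters) -> float:
    """Combined apical+basal UWL resistance, s/cm.

    The UWL thickness shrinks with agitation; its permeability follows
    the hydrodynamic power law ``P_UWL = chi_uwl * nu**alpha`` with the
    stirring speed ``nu`` in rpm.  Unreported or sub-default speeds are
    replaced by the 150 rpm floor, below which stirring differences are
    not experimentally resolvable.  Apical and basal layers are modelled
    as one lumped resistance.
    """
    nu = effective_rpm(stirring_rpm, params.default_rpm)
    return 1.0 / (params.chi_uwl * nu ** params.alpha)


def cytosol_resistance(d_aq_37: float, params: ModelParameters) -> float:
    """Cytosol resistance, s/cm.

    The cytosol is treated as a watery compartment of thickness
    ``h_cytosol`` (cell diameter, 15 um) in which macromolecular
    crowding slows diffusion to ``cytosol_d_factor`` (default 1/4) of
    the pure-water value.
    """
    return params.h_cytosol / (params.cytosol_d_factor * d_aq_37)


def filter_resistance(d_aq_37: float, params: ModelParameters) -> float:
    """Supporting-filter resistance, s/cm.

    Stagnant water column of length ``h_filter`` restricted to the pore
    area fraction ``eps_filter`` of the polycarbonate filter.
    """
    return params.h_filter / (params.eps_filter * d_aq_37)
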