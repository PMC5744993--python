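"""Lateral along-membrane permeation pathway.

A solute may sorb into the apical membrane, diffuse laterally within
the membrane plane around the cell, and desorb on the basolateral side.
Partitioning is governed by the whole-membrane liposome-water
coefficient K_lipw (polar solutes sorb into the headgroup region), the
path length is a quarter circumference of the (spherical) cell, and a
geometric annulus factor phi accounts for the tiny cross-section the
membrane offers relative to the cell body.
"""

from __future__ import annotations

import math

from .descriptors import ANGSTROM_TO_CM, ModelParameters


def phi_factor(h_cytosol: float, h_membrane: float) -> float:
    """Space-restriction factor of lateral diffusion (dimensionless).

    Ratio of the cell's cross-section to the annular membrane
    cross-section: ``r^2 / ((r + h_m)^2 - r^2)`` with ``r`` half the
    cell diameter.  Both arguments in cm.  About 682 for a 15-um cell
    with a 55-angstrom membrane.
    """
    r = 0.5 * h_cytosol
    return r**2 / ((r + h_membrane) ** 2 - r**2)


def lateral_path_length(h_cytosol: float) -> float:
    """Lateral diffusion path length, cm: a quarter circumference,
    ``0.5 * pi * h_cytosol`` (about 24 um for a 15-um cell)."""
    return 0.5 * math.pi * h_cytosol


def lateral_resistance(
    log_klipw: float,
    d_lateral: float,
    f_neutral: float,
    params: ModelParameters,
) -> float:
    """Lateral pathway resistance, s/cm.

    ``R = h_lateral * phi / (f_neutral * K_lipw * D_lateral)``; only the
    non-zwitterionic neutral fraction is assumed to permeate laterally.
    Infinite when the pathway is disabled or no neutral species exists.
    """
    if not params.lateral_enabled or f_neutral == 0.0:
        return math.inf
    h_lat = lateral_path_length(params.h_cytosol)
    phi = phi_factor(params.h_cytosol, params.h_membrane * ANGSTROM_TO_CM)
    return (h_lat * phi) / (f_neutral * 10.0 ** log_klipw * d_lateral)
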