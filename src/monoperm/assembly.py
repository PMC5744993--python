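"""Resistance-network assembly, P_app, and route classification.

Three parallel pathways connect the apical and basolateral
compartments — paracellular, lateral and cytosolic (transcellular) —
each a series of resistances; the lumped UWL and the filter are serial
in every pathway.  The apparent permeability is the parallel sum of the
three pathway conductances, ``P_app = 1/R_para + 1/R_lat + 1/R_cyt``.

Infinite resistances are carried explicitly (``math.inf``), so closed
pathways (e.g. fully ionized chemicals with no transmembrane route)
drop out of the sum exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import abl, lateral, membrane, paracellular
from .descriptors import (
    AssayConditions,
    ChemicalDescriptors,
    ModelParameters,
    ResistanceBreakdown,
    SpeciationProfile,
    ValidationError,
    clamp_speciation,
)

ROUTES = ("paracellular", "cytosolic", "lateral")
BARRIERS = ("UWL", "membranes", "cytosol", "filter")


@dataclass(frozen=True)
class RouteClassification:
    """Dominant (lowest-resistance) pathway for one chemical; when the
    cytosolic route dominates, also its largest serial barrier."""

    dominant_route: str
    cytosolic_main_barrier: str  # "n/a" unless dominant_route == "cytosolic"


def compute_breakdown(
    chem: ChemicalDescriptors,
    speciation: SpeciationProfile,
    conditions: AssayConditions,
    params: ModelParameters | None = None,
) -> ResistanceBreakdown:
    """Run the full forward model for one chemical.

    Applies the fully-ionized speciation cutoff, evaluates every serial
    resistance, assembles the three pathway totals and P_app.
    """
    if params is None:
        params = ModelParameters()
    spec = clamp_speciation(speciation, params.ionized_cutoff)

    r_uwl = abl.uwl_resistance(conditions.stirring_rpm, params)
    r_cyt = abl.cytosol_resistance(chem.d_aq_37, params)
    r_fil = abl.filter_resistance(chem.d_aq_37, params)

    pm = membrane.intrinsic_membrane_permeability(chem.log_khexw, chem.d_hex, params)
    r_mb = membrane.basal_membrane_resistance(pm, spec.f_neutral, spec.f_zwitterion)
    r_ma = membrane.apical_membrane_resistance(pm, spec.f_neutral, spec.f_zwitterion, params)

    r_par = paracellular.paracellular_resistance(
        paracellular.ParacellularInputs(mw=chem.mw, d_aq_37=chem.d_aq_37, speciation=spec),
        params,
    )
    r_lat = lateral.lateral_resistance(chem.log_klipw, chem.d_lateral, spec.f_neutral, params)

    return pathway_totals(
        r_uwl=r_uwl, r_filter=r_fil, r_cytosol=r_cyt,
        r_m_apical=r_ma, r_m_basal=r_mb, r_para=r_par, r_lateral=r_lat,
    )


def pathway_totals(
    *,
    r_uwl: float,
    r_filter: float,
    r_cytosol: float,
    r_m_apical: float,
    r_m_basal: float,
    r_para: float,
    r_lateral: float,
) -> ResistanceBreakdown:
    """Assemble the serial components into the three pathway totals and
    the resulting P_app.  ``r_uwl`` is the lumped apical+basal term."""
    r_para_total = r_uwl + r_para + r_filter
    r_lateral_total = r_uwl + r_lateral + r_filter
    r_cytosol_total = r_uwl + r_m_apical + r_cytosol + r_m_basal + r_filter
    bd = ResistanceBreakdown(
        r_uwl=r_uwl, r_filter=r_filter, r_cytosol=r_cytosol,
        r_m_apical=r_m_apical, r_m_basal=r_m_basal,
        r_para=r_para, r_lateral=r_lateral,
        r_para_total=r_para_total,
        r_lateral_total=r_lateral_total,
        r_cytosol_total=r_cytosol_total,
        p_app=_parallel_papp(r_para_total, r_lateral_total, r_cytosol_total),
    )
    return bd


def _parallel_papp(*totals: float) -> float:
    if all(math.isinf(r) for r in totals):
        raise ValidationError("no transport path: all pathway resistances are infinite")
    return sum(0.0 if math.isinf(r) else 1.0 / r for r in totals)


def total_papp(breakdown: ResistanceBreakdown) -> float:
    """Apparent permeability, cm/s: parallel sum of the three pathway
    conductances (``1/inf`` counts as 0)."""
    return _parallel_papp(
        breakdown.r_para_total, breakdown.r_lateral_total, breakdown.r_cytosol_total
    )


# deterministic tie-break: cytosolic first, then paracellular, then lateral
_TIE_ORDER = ("cytosolic", "paracellular", "lateral")


def classify_routes(breakdown: ResistanceBreakdown) -> RouteClassification:
    """Dominant route = pathway with the smallest total resistance
    (ties broken cytosolic > paracellular > lateral); for a dominant
    cytosolic route the main barrier is the largest of UWL, the two
    membranes combined, cytosol and filter."""
    totals = {
        "cytosolic": breakdown.r_cytosol_total,
        "paracellular": breakdown.r_para_total,
        "lateral": breakdown.r_lateral_total,
    }
    dominant = min(_TIE_ORDER, key=lambda k: totals[k])
    barrier = "n/a"
    if dominant == "cytosolic":
        contributions = {
            "UWL": breakdown.r_uwl,
            "membranes": breakdown.r_m_apical + breakdown.r_m_basal,
            "cytosol": breakdown.r_cytosol,
            "filter": breakdown.r_filter,
        }
        barrier = max(BARRIERS, key=lambda k: contributions[k])
    return RouteClassification(dominant_route=dominant, cytosolic_main_barrier=barrier)


def predict_table(df: pd.DataFrame, params: ModelParameters | None = None) -> pd.DataFrame:
    """Run the forward model over a descriptor table.

    Returns one row per chemical with every serial resistance, the three
    pathway totals, ``p_app``, ``log_papp`` and the route classification.
    """
    from .descriptors import iter_table_inputs  # local import avoids cycle at module load

    if params is None:
        params = ModelParameters()
    rows = []
    for chem, spec, cond in iter_table_inputs(df, params):
        bd = compute_breakdown(chem, spec, cond, params)
        cls = classify_routes(bd)
        rec = {"name": chem.name, **bd.as_dict()}
        rec["log_papp"] = math.log10(bd.p_app)
        rec["dominant_route"] = cls.dominant_route
        rec["cytosolic_main_barrier"] = cls.cytosolic_main_barrier
        rec["paracellular_only"] = math.isinf(bd.r_cytosol_total) and math.isinf(
            bd.r_lateral_total
        )
        rows.append(rec)
    return pd.DataFrame(rows)
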