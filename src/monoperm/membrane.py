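"""Transmembrane (solubility-diffusion) resistances.

The rate-limiting barrier of a phospholipid bilayer is its alkane-like
interior, modelled as a 15-angstrom hexadecane slab: the intrinsic
permeability of the neutral species is ``P_m = K_hexw * D_hex / h``.
This is the black-lipid-membrane (BLM) submodel; the monolayer's basal
membrane uses it directly, the apical membrane additionally gains the
24-fold microvilli surface amplification.

Per the pH partition hypothesis only the (non-zwitterionic) neutral
fraction crosses; fully ionized chemicals have infinite transmembrane
resistance.  Zwitterions, although net-neutral, permeate bilayers about
as poorly as alkali ions, so a zwitterion-dominated chemical is also
assigned infinite membrane resistance.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .descriptors import ANGSTROM_TO_CM, ModelParameters, ValidationError


def intrinsic_membrane_permeability(
    log_khexw: float, d_hex: float, params: ModelParameters
) -> float:
    """Neutral-species intrinsic membrane permeability P_m, cm/s.

    Homogeneous solubility-diffusion across the hexadecane-like inner
    slab of thickness ``h_hexlike``.
    """
    h_cm = params.h_hexlike * ANGSTROM_TO_CM
    return 10.0 ** log_khexw * d_hex / h_cm


def log10_membrane_permeability(
    log_khexw: float, d_hex: float, params: ModelParameters
) -> float:
    """log10 P_m; exactly ``log_khexw + log10(d_hex) - log10(h)``."""
    return log_khexw + math.log10(d_hex) - math.log10(params.h_hexlike * ANGSTROM_TO_CM)


def _speciation_blocks_membrane(f_neutral: float, f_zwitterion: float) -> bool:
    # zwitterion-dominated chemicals: P_m negligibly small
    return f_neutral == 0.0 or f_zwitterion > f_neutral


def basal_membrane_resistance(pm: float, f_neutral: float, f_zwitterion: float = 0.0) -> float:
    """Basal membrane resistance ``1/(f_neutral * P_m)``, s/cm.

    Infinite when no neutral species exists or when the zwitterion is
    the dominant net-neutral form.
    """
    if _speciation_blocks_membrane(f_neutral, f_zwitterion):
        return math.inf
    return 1.0 / (f_neutral * pm)


def apical_membrane_resistance(
    pm: float, f_neutral: float, f_zwitterion: float = 0.0,
    params: ModelParameters | None = None,
) -> float:
    """Apical membrane resistance, s/cm: the basal value divided by the
    microvilli surface-amplification factor (default 24)."""
    factor = params.microvilli_factor if params is not None else 24.0
    return basal_membrane_resistance(pm, f_neutral, f_zwitterion) / factor


# --- BLM dataset IO ---------------------------------------------------------

BLM_COLUMNS = ["name", "mw", "log_khexw", "d_hex", "log_pm_exp"]


def read_blm_table(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a BLM validation table (columns: name, mw, log_khexw, d_hex,
    log_pm_exp) from delimited text."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in BLM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"BLM table missing column(s): {', '.join(missing)}")
    return df
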