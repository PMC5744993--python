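"""Domain types, unit conventions and input validation.

Everything downstream works in CGS units (cm, s, g) with temperature in
kelvin and electric potentials in millivolt.  Parameters that are
conventionally quoted in angstrom or micrometre (pore radius, membrane
thicknesses, cytosol height) are stored in their conventional unit and
converted to cm at the point of use; the conversion constants live here.

All logarithms are base 10.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

# --- unit conversions -------------------------------------------------------

ANGSTROM_TO_CM = 1e-8
MICRON_TO_CM = 1e-4

#: Boltzmann constant, erg/K (CGS)
K_BOLTZMANN_CGS = 1.380649e-16
#: elementary charge, C — used for the electric-field constant kappa
ELEMENTARY_CHARGE = 1.602176634e-19
#: Boltzmann constant, J/K (SI) — used for kappa
K_BOLTZMANN_SI = 1.380649e-23


class ValidationError(ValueError):
    """Raised when a model input violates its documented invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


# --- chemical descriptors ---------------------------------------------------

#: sanity ceiling for any molecular diffusion coefficient, cm^2/s
_D_MAX = 1e-3


@dataclass(frozen=True)
class ChemicalDescriptors:
    """Per-chemical physicochemical inputs of the resistance network.

    Attributes
    ----------
    name : str
        Chemical identifier.
    mw : float
        Molecular weight, g/mol.
    log_khexw : float
        log10 hexadecane-water partition coefficient of the neutral
        species (surrogate for the alkane-like membrane interior).
    log_klipw : float
        log10 liposome-water partition coefficient of the neutral
        species (whole-membrane partitioning; drives the lateral route).
    d_aq_37 : float
        Aqueous diffusion coefficient at 37 C, cm^2/s.
    d_hex : float
        Diffusion coefficient in hexadecane, cm^2/s.
    d_lateral : float
        Lateral membrane diffusion coefficient, cm^2/s.
    """

    name: str
    mw: float
    log_khexw: float
    log_klipw: float
    d_aq_37: float
    d_hex: float
    d_lateral: float

    def __post_init__(self) -> None:
        validate_descriptors(self)


def validate_descriptors(d: ChemicalDescriptors) -> ChemicalDescriptors:
    """Check descriptor invariants; return ``d`` unchanged if they hold.

    Raises :class:`ValidationError` naming the offending field otherwise.
    """
    _require(d.mw > 0, f"{d.name!r}: mw must be > 0, got {d.mw}")
    for fld in ("d_aq_37", "d_hex", "d_lateral"):
        v = getattr(d, fld)
        _require(v > 0, f"{d.name!r}: {fld} must be > 0, got {v}")
        _require(v < _D_MAX, f"{d.name!r}: {fld}={v} exceeds sanity bound {_D_MAX} cm^2/s")
    for fld in ("log_khexw", "log_klipw"):
        v = getattr(d, fld)
        _require(math.isfinite(v), f"{d.name!r}: {fld} must be finite, got {v}")
    return d


# --- speciation -------------------------------------------------------------

_SPECIES_FIELDS = (
    "f_neutral",
    "f_cation",
    "f_anion",
    "f_dication",
    "f_dianion",
    "f_zwitterion",
)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SpeciationProfile:
    """Fractions of the six microspecies classes at pH 7.4.

    Fractions must lie in [0, 1] and sum to one.  Charge classes are
    neutral, mono-/di-valent cation, mono-/di-valent anion, and the
    net-neutral zwitterion.
    """

    f_neutral: float = 0.0
    f_cation: float = 0.0
    f_anion: float = 0.0
    f_dication: float = 0.0
    f_dianion: float = 0.0
    f_zwitterion: float = 0.0

    def __post_init__(self) -> None:
        total = 0.0
        for fld in _SPECIES_FIELDS:
            v = getattr(self, fld)
            _require(0.0 <= v <= 1.0, f"{fld} must be in [0,1], got {v}")
            total += v
        _require(total > 0.0, "all-zero speciation profile")
        _require(abs(total - 1.0) <= _SUM_TOL, f"species fractions must sum to 1, got {total!r}")

    def as_dict(self) -> dict[str, float]:
        return {fld: getattr(self, fld) for fld in _SPECIES_FIELDS}

    @property
    def charged_fraction(self) -> float:
        return self.f_cation + self.f_anion + self.f_dication + self.f_dianion


def clamp_speciation(raw: SpeciationProfile, cutoff: float = 1e-4) -> SpeciationProfile:
    """Apply the fully-ionized cutoff to a speciation profile.

    A chemical whose neutral fraction falls below ``cutoff`` (default
    0.01%) is treated as fully ionized: its residual neutral mass is
    redistributed proportionally over the nonzero charged (and
    zwitterionic) fractions so the profile still sums to one.  Profiles
    at or above the cutoff pass through unchanged.  Idempotent.
    """
    if raw.f_neutral >= cutoff or raw.f_neutral == 0.0:
        return raw
    rest = 1.0 - raw.f_neutral
    _require(rest > 0.0, "cannot clamp: profile is entirely neutral below cutoff")
    scale = 1.0 / rest
    vals = {fld: getattr(raw, fld) * scale for fld in _SPECIES_FIELDS}
    vals["f_neutral"] = 0.0
    # renormalise exactly to kill float drift
    total = sum(vals.values())
    vals = {k: v / total for k, v in vals.items()}
    return SpeciationProfile(**vals)


# --- assay conditions -------------------------------------------------------

@dataclass(frozen=True)
class AssayConditions:
    """Experimental conditions of a monolayer permeability assay.

    ``stirring_rpm=None`` means unreported; the hydrodynamic model then
    falls back to the 150 rpm default (reported speeds below 150 rpm are
    raised to 150 as well, since milder stirring is experimentally
    indistinguishable).
    """

    stirring_rpm: float | None = None
    cell_line: str = "combined"
    ph: float = 7.4
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.stirring_rpm is not None:
            _require(self.stirring_rpm >= 0, f"stirring_rpm must be >= 0, got {self.stirring_rpm}")
        _require(self.cell_line in {"Caco-2", "MDCK", "combined"},
                 f"cell_line must be Caco-2, MDCK or combined, got {self.cell_line!r}")


def effective_rpm(stirring_rpm: float | None, default_rpm: float = 150.0) -> float:
    """Effective stirring speed: reported value, floored at the default."""
    if stirring_rpm is None:
        return default_rpm
    return max(stirring_rpm, default_rpm)


# --- model parameters -------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Geometric and physical constants of the monolayer model.

    Defaults are the published parametrisation of the Caco-2/MDCK
    monolayer at 37 C and pH 7.4.  Units are noted per field; angstrom
    and mV values are converted internally where needed.
    """

    #: UWL hydrodynamic constant, cm/s
    chi_uwl: float = 2e-6
    #: UWL stirring exponent (dimensionless)
    alpha: float = 0.6
    #: default / floor stirring speed, rpm
    default_rpm: float = 150.0
    #: primary paracellular porosity over path length, 1/cm
    eps_over_delta: float = 0.78
    #: secondary (unsieved) pore population porosity over path length, 1/cm
    eps_over_delta2: float = 0.05
    #: magnitude of the paracellular potential drop, mV
    delta_phi: float = 30.0
    #: paracellular pore radius, angstrom
    r_pore: float = 12.9
    #: dynamic viscosity of water at 37 C, N s/m^2
    eta: float = 0.6913e-3
    #: cytosol path length, cm (15 um)
    h_cytosol: float = 15e-4
    #: cytosolic diffusivity retardation relative to pure water
    cytosol_d_factor: float = 0.25
    #: filter thickness (pore length), cm (10 um)
    h_filter: float = 10e-4
    #: filter porosity (translucent filter)
    eps_filter: float = 0.13
    #: full membrane height, angstrom
    h_membrane: float = 55.0
    #: hexadecane-like inner barrier thickness, angstrom
    h_hexlike: float = 15.0
    #: apical surface amplification by microvilli
    microvilli_factor: float = 24.0
    #: absolute temperature, K
    temperature: float = 310.0
    #: electric-field constant kappa = F/(N_A k_B T), 1/mV
    kappa: float = 0.037414
    #: neutral-fraction threshold below which a chemical is fully ionized
    ionized_cutoff: float = 1e-4
    #: whether the lateral pathway contributes at all
    lateral_enabled: bool = True
    #: fallback lateral diffusion coefficient when none is supplied, cm^2/s
    default_d_lateral: float = 1e-8

    def __post_init__(self) -> None:
        positive = (
            "chi_uwl", "eps_over_delta", "eps_over_delta2", "delta_phi",
            "r_pore", "eta", "h_cytosol", "cytosol_d_factor", "h_filter",
            "h_membrane", "h_hexlike", "microvilli_factor", "temperature",
            "kappa", "default_rpm", "default_d_lateral",
        )
        for fld in positive:
            _require(getattr(self, fld) > 0, f"{fld} must be > 0")
        _require(0 < self.eps_filter <= 1, f"eps_filter must be in (0,1], got {self.eps_filter}")
        _require(0 < self.alpha <= 1, f"alpha must be in (0,1], got {self.alpha}")
        _require(self.eps_over_delta > self.eps_over_delta2,
                 "primary pore ratio must exceed the secondary one")
        _require(0 < self.ionized_cutoff < 1, "ionized_cutoff must be in (0,1)")

    def replace(self, **kwargs: object) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)  # type: ignore[arg-type]


def derived_kappa(temperature: float = 310.0) -> float:
    """Electric-field constant kappa = F/(N_A k_B T) = e/(k_B T), in 1/mV."""
    return ELEMENTARY_CHARGE / (K_BOLTZMANN_SI * temperature) * 1e-3


def load_parameters(config: str | Path | dict | None = None) -> ModelParameters:
    """Build :class:`ModelParameters`, optionally overriding fields.

    ``config`` may be a mapping or a path to a YAML/JSON key-value file.
    Unknown keys raise :class:`ValidationError` naming the key.
    """
    if config is None:
        return ModelParameters()
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError(f"config must be a mapping, got {type(config).__name__}")
    known = {f.name for f in dataclasses.fields(ModelParameters)}
    for key in config:
        if key not in known:
            raise ValidationError(f"unknown model parameter {key!r}")
    return ModelParameters(**config)


# --- resistance breakdown ---------------------------------------------------

@dataclass(frozen=True)
class ResistanceBreakdown:
    """Every serial resistance (s/cm) and the three pathway totals for
    one chemical, plus the resulting apparent permeability (cm/s).

    ``r_uwl`` is the lumped apical+basal unstirred-water-layer term; it
    (and ``r_filter``) appears serially in all three pathways.
    Resistances may be ``math.inf`` when a pathway is closed (e.g. no
    neutral species for the transmembrane routes).
    """

    r_uwl: float
    r_filter: float
    r_cytosol: float
    r_m_apical: float
    r_m_basal: float
    r_para: float
    r_lateral: float
    r_para_total: float
    r_lateral_total: float
    r_cytosol_total: float
    p_app: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


# --- descriptor table IO ----------------------------------------------------

DESCRIPTOR_COLUMNS = [
    "name", "mw", "log_khexw", "log_klipw", "d_aq_37", "d_hex", "d_lateral",
]
SPECIATION_COLUMNS = list(_SPECIES_FIELDS)
OPTIONAL_COLUMNS = ["stirring_rpm", "cell_line"]


def read_descriptor_table(path: str | Path, *, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited descriptor table (CSV/TSV inferred by default).

    Required columns: name, mw, log_khexw, log_klipw, d_aq_37, d_hex,
    the six species-fraction columns; optional: d_lateral, stirring_rpm,
    cell_line.  Missing required columns raise :class:`ValidationError`
    naming them.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    required = [c for c in DESCRIPTOR_COLUMNS if c != "d_lateral"] + SPECIATION_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"descriptor table missing column(s): {', '.join(missing)}")
    return df


def row_to_inputs(
    row: pd.Series | dict, params: ModelParameters
) -> tuple[ChemicalDescriptors, SpeciationProfile, AssayConditions]:
    """Convert one descriptor-table row into validated model inputs."""
    get = row.get if hasattr(row, "get") else row.__getitem__
    d_lat = get("d_lateral", None)
    if d_lat is None or (isinstance(d_lat, float) and math.isnan(d_lat)):
        d_lat = params.default_d_lateral
    chem = ChemicalDescriptors(
        name=str(get("name")),
        mw=float(get("mw")),
        log_khexw=float(get("log_khexw")),
        log_klipw=float(get("log_klipw")),
        d_aq_37=float(get("d_aq_37")),
        d_hex=float(get("d_hex")),
        d_lateral=float(d_lat),
    )
    spec = SpeciationProfile(**{f: float(get(f, 0.0) or 0.0) for f in _SPECIES_FIELDS})
    rpm = get("stirring_rpm", None)
    if rpm is not None and isinstance(rpm, float) and math.isnan(rpm):
        rpm = None
    cell = get("cell_line", "combined")
    if not isinstance(cell, str):
        cell = "combined"
    cond = AssayConditions(
        stirring_rpm=None if rpm is None else float(rpm),
        cell_line=cell,
    )
    return chem, spec, cond


def iter_table_inputs(
    df: pd.DataFrame, params: ModelParameters
) -> Iterable[tuple[ChemicalDescriptors, SpeciationProfile, AssayConditions]]:
    for _, row in df.iterrows():
        yield row_to_inputs(row, params)
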