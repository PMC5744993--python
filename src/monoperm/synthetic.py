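"""Synthetic descriptor tables and pseudo-experimental datasets.

The generator emulates the statistical structure of a curated
monolayer-permeability compilation so that every pipeline stage is
testable without external data: molecular weights of drug-like solutes,
hexadecane- and liposome-water partition coefficients spanning the
hydrophile-lipophile range, diffusion coefficients scaled with size,
speciation profiles drawn from the six-species simplex including its
pure-ion and pure-zwitterion corners, and a mix of stirred/unstirred
assay conditions.

It is deliberately not a chemical-space sampler: descriptors are drawn
independently (no covariance between lipophilicity and size, no real
structures), which is enough to exercise every model branch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assembly import predict_table
from .descriptors import (
    ModelParameters,
    SPECIATION_COLUMNS,
    ValidationError,
)
from .evaluation import ExperimentalRecord

#: corner-case rows always injected first so that route-classification
#: branches (paracellular-only, zwitterion block, UWL- vs membrane-limited
#: cytosolic transport) are exercised by any generated table
_CORNERS = [
    # (suffix, speciation dict, log_khexw, log_klipw)
    ("pure_cation", {"f_cation": 1.0}, -2.0, 2.0),
    ("pure_zwitterion", {"f_zwitterion": 1.0}, -2.0, 2.0),
    ("neutral_lipophile", {"f_neutral": 1.0}, 2.0, 4.5),
    ("neutral_hydrophile", {"f_neutral": 1.0}, -6.5, 0.5),
]


def _sample_speciation(rng: np.random.Generator) -> dict[str, float]:
    kind = rng.random()
    if kind < 0.35:
        return {"f_neutral": 1.0}
    if kind < 0.45:  # pure single ion
        fld = rng.choice(["f_cation", "f_anion", "f_dication", "f_dianion"])
        return {str(fld): 1.0}
    if kind < 0.5:
        return {"f_zwitterion": 1.0}
    # mixed ionizable: Dirichlet over a random subset including neutral
    n_extra = int(rng.integers(1, 4))
    extras = rng.choice(SPECIATION_COLUMNS[1:], size=n_extra, replace=False)
    fields = ["f_neutral", *map(str, extras)]
    weights = rng.dirichlet(np.ones(len(fields)))
    return dict(zip(fields, weights.tolist()))


def generate_chemicals(n: int, seed: int) -> pd.DataFrame:
    """Deterministic synthetic descriptor table of ``n`` chemicals.

    MW ~ U[50, 800]; log K_hexw ~ U[-8, 4]; log K_lipw ~ U[-1, 6];
    D_aq(37 C) follows an MW^-0.45 power law around 7e-6 cm^2/s with
    lognormal scatter, D_hex is 0.3-1x D_aq (hexadecane is ~4x more
    viscous than water), and D_lateral scatters around 1e-8 cm^2/s.
    The four corner-case chemicals are always included first.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for i in range(n):
        corner = _CORNERS[i] if i < len(_CORNERS) else None
        mw = float(rng.uniform(50.0, 800.0))
        d_aq = 7e-6 * (mw / 300.0) ** -0.45 * float(rng.lognormal(0.0, 0.1))
        d_hex = d_aq * float(rng.uniform(0.3, 1.0))
        d_lat = 1e-8 * float(rng.lognormal(0.0, 0.2))
        if corner is not None:
            suffix, spec, log_khexw, log_klipw = corner
            name = f"chem_{i:04d}_{suffix}"
        else:
            spec = _sample_speciation(rng)
            log_khexw = float(rng.uniform(-8.0, 4.0))
            log_klipw = float(rng.uniform(-1.0, 6.0))
            name = f"chem_{i:04d}"
        row = {
            "name": name,
            "mw": mw,
            "log_khexw": log_khexw,
            "log_klipw": log_klipw,
            "d_aq_37": d_aq,
            "d_hex": d_hex,
            "d_lateral": d_lat,
            **{c: 0.0 for c in SPECIATION_COLUMNS},
            "stirring_rpm": float(rng.choice([150.0, 150.0, 600.0])),
            "cell_line": str(rng.choice(["Caco-2", "MDCK"])),
        }
        row.update(spec)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_pseudo_experiment(
    table: pd.DataFrame,
    noise_sd: float,
    seed: int,
    params: ModelParameters | None = None,
) -> list[ExperimentalRecord]:
    """Forward-model P_app for every chemical in ``table`` and emit
    experimental records with Gaussian noise of ``noise_sd`` log units.

    With ``noise_sd=0`` the evaluation pipeline recovers the model
    exactly (RMSE 0, R^2 1).  Records whose noisy value would leave the
    sane log P_app range are clipped to it.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    preds = predict_table(table, params)
    records = []
    for (_, row), (_, trow) in zip(preds.iterrows(), table.iterrows()):
        log_obs = row["log_papp"] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        log_obs = float(np.clip(log_obs, -8.99, -2.01))
        records.append(
            ExperimentalRecord(
                name=row["name"],
                log_papp_exp=log_obs,
                cell_line=str(trow.get("cell_line", "combined")),
                efflux_ratio=None,
                stirring_rpm=float(trow["stirring_rpm"]) if "stirring_rpm" in trow else None,
                source="synthetic",
            )
        )
    return records
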