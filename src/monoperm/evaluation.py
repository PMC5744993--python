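"""Dataset curation, prediction-vs-experiment metrics, and the BLM
validation protocol.

Curation of literature monolayer data follows three rules: measurements
with efflux ratio >= 2 indicate active transport and are dropped;
replicate measurements (within a source, including both transport
directions) are averaged as arithmetic means of linear-scale P_app and
then pooled across sources and cell lines; entries measured at reported
stirring speeds of 150 rpm or more are kept as separate modelling
conditions, while milder or unreported stirring pools at the 150 rpm
default.

The BLM protocol evaluates the intrinsic-membrane submodel alone
against black-lipid-membrane permeabilities of neutral species, after
excluding molecules below 50 g/mol whose permeation is governed by
polymer-like membrane behaviour the liquid-hydrocarbon model does not
capture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import ModelParameters, ValidationError
from .membrane import log10_membrane_permeability

#: records below this molecular weight are excluded from BLM validation
BLM_MW_CUTOFF = 50.0


@dataclass(frozen=True)
class ExperimentalRecord:
    """One literature P_app measurement (log10 cm/s) with its assay
    metadata."""

    name: str
    log_papp_exp: float
    cell_line: str = "combined"
    efflux_ratio: float | None = None
    stirring_rpm: float | None = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        if not (-9.0 < self.log_papp_exp < -2.0):
            raise ValidationError(
                f"{self.name!r}: log_papp_exp={self.log_papp_exp} outside the sane range (-9, -2)"
            )


@dataclass(frozen=True)
class EvaluationReport:
    """Prediction-vs-experiment summary: RMSE and R^2 of log10 values
    plus the per-chemical comparison."""

    n: int
    rmse: float
    r2: float
    per_chemical: list[tuple] = field(default_factory=list)


def curate_records(
    records: list[ExperimentalRecord],
    *,
    efflux_cutoff: float = 2.0,
    default_rpm: float = 150.0,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> list[ExperimentalRecord]:
    """Apply the curation rules; returns one record per (chemical,
    effective stirring speed).  Idempotent.

    ``exclude`` optionally drops named chemicals (e.g. ones whose
    predicted speciation is known to be unreliable).
    """
    kept = [
        r for r in records
        if r.name not in exclude
        and (r.efflux_ratio is None or r.efflux_ratio < efflux_cutoff)
    ]
    if not kept:
        return []

    df = pd.DataFrame(
        {
            "name": [r.name for r in kept],
            "papp": [10.0 ** r.log_papp_exp for r in kept],
            "cell_line": [r.cell_line for r in kept],
            "source": [r.source for r in kept],
            "eff_rpm": [
                default_rpm if r.stirring_rpm is None else max(r.stirring_rpm, default_rpm)
                for r in kept
            ],
        }
    )
    # within-source replicate averaging, then pooling across sources/cell lines
    within = df.groupby(["name", "eff_rpm", "cell_line", "source"], as_index=False)["papp"].mean()
    pooled = within.groupby(["name", "eff_rpm"], as_index=False).agg(
        papp=("papp", "mean"), cell_line=("cell_line", lambda s: s.iloc[0] if s.nunique() == 1 else "combined")
    )
    out = [
        ExperimentalRecord(
            name=row["name"],
            log_papp_exp=math.log10(row["papp"]),
            cell_line=row["cell_line"],
            efflux_ratio=None,
            stirring_rpm=row["eff_rpm"],
            source="curated",
        )
        for _, row in pooled.iterrows()
    ]
    out.sort(key=lambda r: (r.name, r.stirring_rpm))
    return out


def fit_metrics(
    pred, exp, *, r2_kind: str = "pearson"
) -> tuple[float, float]:
    """RMSE and R^2 of two equal-length log10 vectors.

    ``r2_kind='pearson'`` (default) is the squared Pearson correlation;
    ``'cod'`` is the coefficient of determination
    ``1 - SS_res/SS_tot`` relative to the experimental mean.
    """
    p = np.asarray(pred, dtype=float)
    e = np.asarray(exp, dtype=float)
    if p.shape != e.shape:
        raise ValidationError("pred and exp must have equal length")
    if p.size < 2:
        raise ValidationError("need at least 2 points for R^2")
    rmse = float(np.sqrt(np.mean((p - e) ** 2)))
    if r2_kind == "pearson":
        sp, se = p.std(), e.std()
        if sp == 0.0 or se == 0.0:
            r2 = 1.0 if rmse == 0.0 else 0.0
        else:
            r2 = float(np.corrcoef(p, e)[0, 1] ** 2)
    elif r2_kind == "cod":
        ss_tot = float(np.sum((e - e.mean()) ** 2))
        ss_res = float(np.sum((p - e) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0.0 else 0.0)
    else:
        raise ValidationError(f"unknown r2_kind {r2_kind!r}")
    return rmse, r2


def evaluate_predictions(
    predictions: pd.DataFrame,
    records: list[ExperimentalRecord],
    *,
    r2_kind: str = "pearson",
) -> EvaluationReport:
    """Join model predictions (from ``assembly.predict_table``) with
    curated experimental records on chemical name and summarise the fit."""
    pred_map = dict(zip(predictions["name"], predictions["log_papp"]))
    route_map = dict(zip(predictions["name"], predictions.get("dominant_route", [""] * len(predictions))))
    per = [
        (r.name, pred_map[r.name], r.log_papp_exp, route_map.get(r.name, ""))
        for r in records
        if r.name in pred_map
    ]
    if not per:
        raise ValidationError("no overlap between predictions and experimental records")
    rmse, r2 = fit_metrics([p[1] for p in per], [p[2] for p in per], r2_kind=r2_kind)
    return EvaluationReport(n=len(per), rmse=rmse, r2=r2, per_chemical=per)


def blm_evaluate(
    records: pd.DataFrame,
    params: ModelParameters | None = None,
    *,
    mw_cutoff: float = BLM_MW_CUTOFF,
    r2_kind: str = "pearson",
) -> EvaluationReport:
    """Validate the intrinsic-membrane submodel against a BLM table.

    Drops molecules with ``mw < mw_cutoff``, predicts
    ``log10 P_m = log_khexw + log10(D_hex) - log10(h_hexlike)`` and
    returns the fit metrics over the remaining values.
    """
    if params is None:
        params = ModelParameters()
    kept = records[records["mw"] >= mw_cutoff]
    if kept.empty:
        raise ValidationError("BLM table empty after molecular-weight filter")
    preds = [
        log10_membrane_permeability(row["log_khexw"], row["d_hex"], params)
        for _, row in kept.iterrows()
    ]
    obs = kept["log_pm_exp"].to_numpy(dtype=float)
    rmse, r2 = fit_metrics(preds, obs, r2_kind=r2_kind)
    per = list(zip(kept["name"], preds, obs, ["membrane"] * len(preds)))
    return EvaluationReport(n=len(per), rmse=rmse, r2=r2, per_chemical=per)
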