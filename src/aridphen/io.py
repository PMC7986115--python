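"""CSV / YAML / JSON / PNG input-output for the pipeline's tabular formats."""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .types import (
    PotWeightSeries,
    SegmentedFit,
    TruthParams,
    VPDStep,
    VPDStepLog,
    WeightRecord,
)

__all__ = [
    "write_pot_weight_csv",
    "read_pot_weight_csv",
    "write_vpd_log_csv",
    "read_vpd_log_csv",
    "write_fit_results_csv",
    "load_scenario",
    "dump_truth_json",
    "save_image",
    "load_image",
]

POT_WEIGHT_COLUMNS = [
    "plant_id",
    "species",
    "accession",
    "watering",
    "timestamp",
    "weight_g",
    "rewatered",
]


def write_pot_weight_csv(series_list: list[PotWeightSeries], path) -> None:
    rows = [
        {
            "plant_id": s.plant_id,
            "species": s.species,
            "accession": s.accession,
            "watering": s.watering,
            "timestamp": r.timestamp.isoformat(),
            "weight_g": r.weight,
            "rewatered": r.rewatered,
        }
        for s in series_list
        for r in s.records
    ]
    pd.DataFrame(rows, columns=POT_WEIGHT_COLUMNS).to_csv(path, index=False)


def read_pot_weight_csv(path) -> list[PotWeightSeries]:
    df = pd.read_csv(path)
    out = []
    for plant_id, grp in df.groupby("plant_id", sort=False):
        first = grp.iloc[0]
        records = [
            WeightRecord(
                dt.datetime.fromisoformat(row.timestamp),
                float(row.weight_g),
                bool(row.rewatered),
            )
            for row in grp.itertuples()
        ]
        out.append(
            PotWeightSeries(
                plant_id=str(plant_id),
                species=str(first["species"]),
                accession=str(first["accession"]),
                watering=str(first["watering"]),
                records=sorted(records, key=lambda r: r.timestamp),
            )
        )
    return out


def write_vpd_log_csv(logs: list[VPDStepLog], path) -> None:
    rows = [
        {
            "plant_id": log.plant_id,
            "leaf_area_m2": log.leaf_area,
            "target_vpd_kpa": s.target_vpd,
            "start": s.start.isoformat(),
            "end": s.end.isoformat(),
            "mean_temperature_c": s.mean_temperature,
            "mean_rh_pct": s.mean_rh,
            "start_weight_g": s.start_weight,
            "end_weight_g": s.end_weight,
        }
        for log in logs
        for s in log.steps
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vpd_log_csv(path) -> list[VPDStepLog]:
    df = pd.read_csv(path)
    out = []
    for plant_id, grp in df.groupby("plant_id", sort=False):
        steps = [
            VPDStep(
                float(row.target_vpd_kpa),
                dt.datetime.fromisoformat(row.start),
                dt.datetime.fromisoformat(row.end),
                float(row.mean_temperature_c),
                float(row.mean_rh_pct),
                float(row.start_weight_g),
                float(row.end_weight_g),
            )
            for row in grp.itertuples()
        ]
        out.append(
            VPDStepLog(
                plant_id=str(plant_id),
                leaf_area=float(grp.iloc[0]["leaf_area_m2"]),
                steps=steps,
            )
        )
    return out


def write_fit_results_csv(fits: dict[str, SegmentedFit], path) -> None:
    rows = []
    for label, f in fits.items():
        ci = f.x0_ci or (np.nan, np.nan)
        rows.append(
            {
                "label": label,
                "intercept1": f.intercept1,
                "slope1": f.slope1,
                "x0": f.x0,
                "slope2": f.slope2,
                "r2": f.r2,
                "n": f.n,
                "residual_sd": f.residual_sd,
                "x0_pinned": f.x0_pinned,
                "x0_ci_low": ci[0],
                "x0_ci_high": ci[1],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_scenario(path) -> tuple[TruthParams, dict]:
    """Load a YAML scenario config: TruthParams keys plus any extra scenario
    settings (n_days, watering, levels, ...), returned as a second dict."""
    with open(path) as fh:
        cfg = dict(yaml.safe_load(fh) or {})
    truth_keys = TruthParams.__dataclass_fields__.keys()
    truth = TruthParams(**{k: cfg.pop(k) for k in list(cfg) if k in truth_keys})
    return truth, cfg


def dump_truth_json(truth: TruthParams, path, extra: dict | None = None) -> None:
    payload = asdict(truth)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def save_image(image: np.ndarray, path) -> None:
    Image.fromarray(image, mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
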