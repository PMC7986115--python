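"""Gravimetric water-use accounting and soil-water normalization.

Turns morning/evening pot-weight series into:

* daytime and nighttime water use (WU_day, WU_night), corrected by mean
  soil-only pot evaporation, with well-watered refills reconstructed as
  refill-to-target;
* total transpirable soil water (TTSW) and the per-date fraction of
  transpirable soil water, FTSW = (WTn - WTf) / TTSW, where WTn is the pot
  weight on a given date and WTf the endpoint weight at which a stressed
  plant transpires ~10% of the controls;
* post-stress recovery, 100 x WU on recovery day 6 / mean pre-stress WU.
"""

from __future__ import annotations

import datetime as dt
import logging
from statistics import mean

import numpy as np

from .types import FTSWSeries, PotWeightSeries, WaterUseRecord

__all__ = [
    "partition_water_use",
    "compute_ttsw",
    "find_endpoint",
    "compute_ftsw",
    "recovery_percent",
    "mean_daily_water_use",
]

logger = logging.getLogger(__name__)


def _split_records(series: PotWeightSeries):
    """Index records by date: morning (< 12:00) and evening (>= 12:00)."""
    mornings: dict[dt.date, tuple[float, bool]] = {}
    evenings: dict[dt.date, tuple[float, bool]] = {}
    for rec in series.records:
        slot = mornings if rec.timestamp.hour < 12 else evenings
        slot[rec.timestamp.date()] = (rec.weight, rec.rewatered)
    return mornings, evenings


def partition_water_use(
    series: PotWeightSeries,
    soil_mean_day: float,
    soil_mean_night: float,
    target_weight: float | None = None,
) -> list[WaterUseRecord]:
    """Partition pot weight loss into soil-corrected day/night water use.

    For each date with a morning record, a same-date evening record, and a
    next-morning record:

    * WU_day  = (morning weight - evening weight)      - soil_mean_day
    * WU_night = (evening start - next-morning weight) - soil_mean_night

    where the evening *start* weight of the night window is ``target_weight``
    when the evening record is flagged ``rewatered`` (refill-to-target: the
    recorded evening weight is pre-refill, and water added = target -
    recorded weight). Dates missing a paired record are skipped with a
    warning.
    """
    series.validate()
    if target_weight is None and any(r.rewatered for r in series.records):
        raise ValueError("target_weight is required for series with rewatering")
    mornings, evenings = _split_records(series)
    out: list[WaterUseRecord] = []
    for date in sorted(mornings):
        nxt = date + dt.timedelta(days=1)
        if date not in evenings or nxt not in mornings:
            if date != max(mornings):  # the final morning closes the series
                logger.warning(
                    "%s: missing paired record for %s; date skipped",
                    series.plant_id,
                    date,
                )
            continue
        w_morning = mornings[date][0]
        w_evening, rewatered = evenings[date]
        night_start = target_weight if rewatered else w_evening
        out.append(
            WaterUseRecord(
                plant_id=series.plant_id,
                date=date,
                wu_day=(w_morning - w_evening) - soil_mean_day,
                wu_night=(night_start - mornings[nxt][0]) - soil_mean_night,
            )
        )
    return out


def compute_ttsw(weight_at_full_awc: float, endpoint_weight: float) -> float:
    """Total transpirable soil water (g): pot weight at 100% available water
    content minus the drydown endpoint weight."""
    diff = weight_at_full_awc - endpoint_weight
    if diff <= 0:
        raise ValueError(
            "weight at full AWC must exceed the endpoint weight "
            f"({weight_at_full_awc} g vs {endpoint_weight} g)"
        )
    return diff


def find_endpoint(
    ws_series: PotWeightSeries,
    control_wu: float,
    threshold_fraction: float = 0.10,
    soil_mean_day: float = 0.0,
    soil_mean_night: float = 0.0,
) -> tuple[dt.date, float]:
    """First date a stressed plant's daily water use falls to the control
    threshold; its morning weight is the endpoint weight WTf.

    ``control_wu`` is the reference daily WU of well-watered plants (see
    :func:`mean_daily_water_use`); the endpoint is the first date with
    soil-corrected WU_day + WU_night <= threshold_fraction * control_wu.
    """
    if control_wu <= 0:
        raise ValueError("control_wu must be positive (degenerate control)")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    records = partition_water_use(ws_series, soil_mean_day, soil_mean_night)
    mornings, _ = _split_records(ws_series)
    for rec in records:
        if rec.wu_day + rec.wu_night <= threshold_fraction * control_wu:
            return rec.date, mornings[rec.date][0]
    raise ValueError(
        f"{ws_series.plant_id}: daily WU never fell to "
        f"{threshold_fraction:.0%} of the control (stress run too short)"
    )


def compute_ftsw(series: PotWeightSeries, wtf: float, ttsw: float) -> FTSWSeries:
    """Per-date FTSW = (WTn - WTf) / TTSW from morning weights.

    Values are clipped to [0, 1] for downstream fitting; raw (unclipped)
    values are retained for QC, since weighing noise can push them
    marginally outside the unit interval.
    """
    if ttsw <= 0:
        raise ValueError("ttsw must be positive")
    mornings, _ = _split_records(series)
    raw = [(date, (w - wtf) / ttsw) for date, (w, _) in sorted(mornings.items())]
    entries = [(date, float(np.clip(v, 0.0, 1.0))) for date, v in raw]
    return FTSWSeries(plant_id=series.plant_id, entries=entries, raw=raw)


def recovery_percent(
    post_wu: list[float], pre_stress_wu: list[float], mode: str = "day6"
) -> float:
    """Post-stress water-use recovery as a percentage of pre-stress use.

    ``mode="day6"`` (default) takes the literal day-6 value of the recovery
    window: 100 x post_wu[5] / mean(pre_stress_wu). ``mode="mean"`` uses the
    mean over the whole recovery window instead.
    """
    if not pre_stress_wu:
        raise ValueError("pre_stress_wu must be non-empty")
    pre = mean(pre_stress_wu)
    if pre <= 0:
        raise ValueError("pre-stress mean water use must be positive")
    if mode == "day6":
        if len(post_wu) < 6:
            raise ValueError("day-6 recovery needs at least 6 post-stress values")
        post = post_wu[5]
    elif mode == "mean":
        if not post_wu:
            raise ValueError("post_wu must be non-empty")
        post = mean(post_wu)
    else:
        raise ValueError(f"unknown recovery mode {mode!r}")
    return 100.0 * post / pre


def mean_daily_water_use(records: list[WaterUseRecord]) -> float:
    """Mean daily (day + night) water use over a set of records; used as the
    well-watered control reference for endpoint detection."""
    if not records:
        raise ValueError("no water-use records")
    return float(np.mean([r.wu_day + r.wu_night for r in records]))
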