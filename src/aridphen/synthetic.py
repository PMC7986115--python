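"""Synthetic-data generators with recorded ground truth.

Emulates the three data streams of a pot-based drydown phenotyping
experiment so that every downstream estimator can be tested against known
truth:

* gravimetric pot-weight logs with morning/evening weighings, well-watered
  (WW) refills to a target weight, additive soil evaporation, and a
  two-phase (plateau, then decline below a breakpoint) transpiration
  response to the fraction of transpirable soil water (FTSW);
* chamber VPD-step logs in which per-step mass loss follows a segmented
  transpiration-rate response to vapour pressure deficit;
* procedural side-view RGB plant images with an exact foreground pixel
  count and bottom-up senescence recolouring.

The drydown simulator depletes the transpirable pool (TTSW) with
plant-attributed water loss only; soil evaporation draws on a separate
surface store that still shows up in pot weight. Integrated plant water
loss over a complete drydown therefore equals TTSW exactly in the
noiseless limit, which downstream TTSW estimators are tested against.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as draw_line

from .response import predict_segmented, saturation_vapour_pressure
from .types import (
    VALID_ANGLES,
    WATERING_LABELS,
    PlantImageSet,
    PlantView,
    PotWeightSeries,
    ResponseDataset,
    TruthParams,
    VPDStep,
    VPDStepLog,
    WeightRecord,
)

__all__ = [
    "simulate_tr_response",
    "noise_sd_from_range",
    "simulate_drydown",
    "simulate_soil_pot",
    "simulate_vpd_steps",
    "render_plant_image",
    "render_image_set",
]

#: Record times fixed inside the platform's weighing windows:
#: evening ~19:30-21:00 and morning ~4:30-6:00.
EVENING_TIME = dt.time(20, 0)
MORNING_TIME = dt.time(5, 0)

#: WW refill target pot weight (g); ~2500 ml available water content.
DEFAULT_TARGET_WEIGHT = 3750.0

#: Fraction of daily plant water loss spent in the 14 h photoperiod; the
#: remainder is nighttime transpiration (day:night WU ratios of roughly
#: 7:1 are typical for these species).
DEFAULT_DAY_FRACTION = 0.875


def _rng(truth: TruthParams, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(truth.seed)


def noise_sd_from_range(
    truth: TruthParams, x_range: tuple[float, float], fraction: float = 0.10
) -> float:
    """Noise SD as a fraction of the noiseless response range over
    ``x_range`` (the range is attained at an endpoint or the breakpoint)."""
    xs = [x_range[0], x_range[1]]
    if x_range[0] < truth.x0 < x_range[1]:
        xs.append(truth.x0)
    ys = predict_segmented(truth, np.array(xs))
    return fraction * float(np.ptp(ys))


def simulate_tr_response(
    truth: TruthParams,
    n_points: int = 30,
    x_range: tuple[float, float] = (1.0, 3.5),
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
    kind: str = "vpd",
) -> ResponseDataset:
    """Segmented response observations on an evenly spaced design.

    The fixed design emulates controlled chamber steps (or binned FTSW
    levels); Gaussian noise with SD ``noise_sd`` (default ``truth.noise_sd``)
    is added to the response.
    """
    rng = _rng(truth, rng)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    x = np.linspace(x_range[0], x_range[1], n_points)
    y = predict_segmented(truth, x)
    if sd > 0:
        y = y + rng.normal(0.0, sd, size=n_points)
    return ResponseDataset(x, y, kind=kind)


def simulate_drydown(
    truth: TruthParams,
    n_days: int,
    watering: str,
    plant_id: str = "plant-1",
    species: str = "synthetic",
    accession: str = "synthetic",
    start_date: dt.date = dt.date(2020, 5, 4),
    target_weight: float = DEFAULT_TARGET_WEIGHT,
    day_fraction: float = DEFAULT_DAY_FRACTION,
    rng: np.random.Generator | None = None,
) -> PotWeightSeries:
    """Simulate a morning/evening pot-weight series over a drydown.

    Daily plant water loss is the two-segment response evaluated at the
    morning FTSW, plus Gaussian noise (``truth.noise_sd``), split between
    the daytime and nighttime windows by ``day_fraction``; soil evaporation
    (``truth.soil_evap_day``/``_night``) is added to the weight loss of each
    period. WS pots deplete freely (loss is capped at the remaining
    transpirable water); WW pots are refilled to ``target_weight`` at each
    evening record (flagged ``rewatered``). The returned series carries a
    ``truth`` dict with per-day plant-attributed day/night losses and
    morning FTSW for recovery testing.
    """
    if watering not in WATERING_LABELS:
        raise ValueError(f"watering must be one of {WATERING_LABELS}, got {watering!r}")
    if n_days < 3:
        raise ValueError("n_days must be >= 3")
    if not 0 < day_fraction < 1:
        raise ValueError("day_fraction must be in (0, 1)")
    rng = _rng(truth, rng)

    endpoint_weight = target_weight - truth.ttsw  # pot weight at FTSW = 0
    if endpoint_weight <= 0:
        raise ValueError("ttsw exceeds target pot weight")

    pool = truth.ttsw  # remaining transpirable water (g)
    evap = 0.0  # cumulative soil evaporation since last refill (g)
    records: list[WeightRecord] = []
    truth_log: dict = {
        "dates": [],
        "wu_day": [],
        "wu_night": [],
        "ftsw_morning": [],
        "target_weight": target_weight,
        "day_fraction": day_fraction,
    }

    def weight() -> float:
        return endpoint_weight + pool - evap

    records.append(
        WeightRecord(dt.datetime.combine(start_date, MORNING_TIME), weight(), False)
    )
    for d in range(n_days):
        date = start_date + dt.timedelta(days=d)
        ftsw = pool / truth.ttsw
        daily = predict_segmented(truth, ftsw)
        if truth.noise_sd > 0:
            daily += rng.normal(0.0, truth.noise_sd)
        daily = max(daily, 0.0)

        wu_day = min(day_fraction * daily, pool)
        pool -= wu_day
        evap += truth.soil_evap_day
        rewatered = watering == "WW"
        records.append(
            WeightRecord(dt.datetime.combine(date, EVENING_TIME), weight(), rewatered)
        )
        if rewatered:
            pool, evap = truth.ttsw, 0.0

        wu_night = min((1.0 - day_fraction) * daily, pool)
        pool -= wu_night
        evap += truth.soil_evap_night
        records.append(
            WeightRecord(
                dt.datetime.combine(date + dt.timedelta(days=1), MORNING_TIME),
                weight(),
                False,
            )
        )
        truth_log["dates"].append(date)
        truth_log["wu_day"].append(wu_day)
        truth_log["wu_night"].append(wu_night)
        truth_log["ftsw_morning"].append(ftsw)

    series = PotWeightSeries(
        plant_id=plant_id,
        species=species,
        accession=accession,
        watering=watering,
        records=records,
        truth=truth_log,
    )
    series.validate()
    return series


def simulate_soil_pot(
    truth: TruthParams,
    n_days: int,
    pot_id: str = "soil-1",
    start_date: dt.date = dt.date(2020, 5, 4),
    target_weight: float = DEFAULT_TARGET_WEIGHT,
    rng: np.random.Generator | None = None,
) -> PotWeightSeries:
    """Plant-free pot losing only soil evaporation (plus weighing noise at
    one tenth of ``truth.noise_sd``); used to estimate the soil-only
    correction terms."""
    rng = _rng(truth, rng)
    w = target_weight
    jitter = 0.1 * truth.noise_sd
    records = [
        WeightRecord(dt.datetime.combine(start_date, MORNING_TIME), w, False)
    ]
    for d in range(n_days):
        date = start_date + dt.timedelta(days=d)
        w -= truth.soil_evap_day
        records.append(
            WeightRecord(
                dt.datetime.combine(date, EVENING_TIME),
                w + (rng.normal(0, jitter) if jitter > 0 else 0.0),
                False,
            )
        )
        w -= truth.soil_evap_night
        records.append(
            WeightRecord(
                dt.datetime.combine(date + dt.timedelta(days=1), MORNING_TIME),
                w + (rng.normal(0, jitter) if jitter > 0 else 0.0),
                False,
            )
        )
    return PotWeightSeries(pot_id, "none", "soil-only", "WS", records)


def simulate_vpd_steps(
    truth: TruthParams,
    levels: list[float],
    duration_min: float = 60.0,
    equilibration_min: float = 30.0,
    leaf_area: float = 0.05,
    chamber_temperature: float = 30.0,
    start_weight: float = 3000.0,
    plant_id: str = "plant-1",
    start: dt.datetime = dt.datetime(2020, 3, 10, 9, 0),
    rng: np.random.Generator | None = None,
) -> VPDStepLog:
    """Simulate a sequential VPD-step chamber run.

    Each target level is applied for ``duration_min`` after an
    equilibration gap; per-step mass loss is TR(level) x leaf area x
    duration (TR from the segmented response, in mg m^-2 s^-1, plus
    Gaussian noise of ``truth.noise_sd``). The emitted mean temperature/RH
    pair reproduces the target level exactly under the Tetens formulation,
    so VPD recomputed from the log round-trips.
    """
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(v <= 0 for v in levels):
        raise ValueError("all VPD levels must be positive")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(truth, rng)

    es = saturation_vapour_pressure(chamber_temperature)
    steps: list[VPDStep] = []
    w = start_weight
    t = start
    for level in levels:
        if level >= es:
            raise ValueError(
                f"VPD {level} kPa unreachable at {chamber_temperature} C "
                f"(es = {es:.2f} kPa); raise chamber_temperature"
            )
        rh = 100.0 * (1.0 - level / es)
        t0 = t + dt.timedelta(minutes=equilibration_min)
        t1 = t0 + dt.timedelta(minutes=duration_min)
        tr = predict_segmented(truth, level)
        if truth.noise_sd > 0:
            tr += rng.normal(0.0, truth.noise_sd)
        loss_g = tr * leaf_area * duration_min * 60.0 / 1000.0
        steps.append(VPDStep(level, t0, t1, chamber_temperature, rh, w, w - loss_g))
        w -= loss_g
        t = t1
    log = VPDStepLog(plant_id=plant_id, leaf_area=leaf_area, steps=steps)
    log.validate()
    return log


# ---------------------------------------------------------------------------
# Procedural plant rendering
# ---------------------------------------------------------------------------

#: Neutral grey background; fails both foreground classifiers.
_BACKGROUND = (112, 112, 112)
#: Healthy tissue base colour (green-dominant).
_GREEN = (45, 175, 60)
#: Senescent tissue base colour (yellow/red-dominant, G < R).
_SENESCENT = (190, 150, 45)


def _plant_skeleton(
    shape: tuple[int, int], angle: int, rng: np.random.Generator
) -> np.ndarray:
    """Stem plus leaf midribs as a connected boolean line drawing."""
    h, w = shape
    skel = np.zeros(shape, dtype=bool)
    base_r, base_c = h - 1, w // 2
    top_r = int(0.12 * h)
    rr, cc = draw_line(base_r, base_c, top_r, base_c)
    skel[rr, cc] = True

    n_leaves = 6
    az = np.deg2rad(angle)
    for i in range(n_leaves):
        attach_r = int(top_r + (base_r - top_r) * (0.15 + 0.75 * i / n_leaves))
        side = -1 if i % 2 == 0 else 1
        # Apparent leaf length varies with view angle (foreshortening) and a
        # seeded per-leaf jitter.
        length = 0.42 * w * (0.55 + 0.45 * abs(np.cos(az + i))) * rng.uniform(0.8, 1.2)
        elev = rng.uniform(0.25, 0.8)  # leaves point upward
        tip_r = int(np.clip(attach_r - elev * length, 0, h - 1))
        tip_c = int(np.clip(base_c + side * length, 0, w - 1))
        rr, cc = draw_line(attach_r, base_c, tip_r, tip_c)
        skel[rr, cc] = True
    return skel


def render_plant_image(
    area_pixels: int,
    senescent_fraction: float,
    angle: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = (200, 200),
) -> tuple[np.ndarray, dict]:
    """Render a procedural side-view plant with an exact foreground count.

    A stem-plus-leaves skeleton is thickened by keeping exactly
    ``area_pixels`` pixels nearest the skeleton (Euclidean distance, ties
    broken by row then column), so the foreground count is exact by
    construction. The lowest ``senescent_fraction`` of foreground pixels by
    image height is recoloured from green-dominant to yellow/red-dominant
    tissue.

    Returns the HxWx3 uint8 raster and a truth dict with ``green_pixels``,
    ``senescent_pixels`` and ``area_pixels``.
    """
    if area_pixels < 0:
        raise ValueError("area_pixels must be >= 0")
    if not 0.0 <= senescent_fraction <= 1.0:
        raise ValueError("senescent_fraction must be in [0, 1]")
    h, w = shape
    if area_pixels >= h * w:
        raise ValueError("area_pixels must be smaller than the raster size")
    if angle not in VALID_ANGLES:
        raise ValueError(f"angle must be one of {VALID_ANGLES}")

    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = _BACKGROUND
    truth = {"area_pixels": area_pixels, "green_pixels": 0, "senescent_pixels": 0}
    if area_pixels == 0:
        return img, truth

    skel = _plant_skeleton(shape, angle, rng)
    dist = distance_transform_edt(~skel)
    rows, cols = np.indices(shape)
    order = np.lexsort((cols.ravel(), rows.ravel(), dist.ravel()))
    selected = order[:area_pixels]

    sel_rows = selected // w
    sel_cols = selected % w
    n_sen = int(round(senescent_fraction * area_pixels))
    # bottom-up: largest row indices senesce first
    bottom_first = np.lexsort((sel_cols, -sel_rows))
    sen_idx = selected[bottom_first[:n_sen]]
    green_idx = selected[bottom_first[n_sen:]]

    flat = img.reshape(-1, 3)
    if green_idx.size:
        jitter = rng.integers(-12, 13, size=(green_idx.size, 3))
        flat[green_idx] = np.clip(np.array(_GREEN) + jitter, 0, 255)
    if sen_idx.size:
        jitter = rng.integers(-10, 11, size=(sen_idx.size, 3))
        flat[sen_idx] = np.clip(np.array(_SENESCENT) + jitter, 0, 255)

    truth["green_pixels"] = int(green_idx.size)
    truth["senescent_pixels"] = int(n_sen)
    return img, truth


def render_image_set(
    plant_id: str,
    day: int,
    view_areas: dict[int, int],
    senescent_fraction: float,
    seed: int = 0,
    shape: tuple[int, int] = (200, 200),
) -> PlantImageSet:
    """Render one plant's multi-angle views for one day.

    ``view_areas`` maps side-view angle -> target foreground pixel count
    (the platform lists seven angles, 0-90 deg in 15 deg steps; any subset
    is accepted).
    """
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = ss.generate_state(len(view_areas))
    views, truth_green = [], []
    for (ang, area), s in zip(sorted(view_areas.items()), child_seeds):
        img, truth = render_plant_image(
            area, senescent_fraction, angle=ang, seed=int(s), shape=shape
        )
        views.append(PlantView(ang, img))
        truth_green.append(truth["green_pixels"])
    image_set = PlantImageSet(
        plant_id=plant_id,
        day=day,
        views=views,
        truth_green_pixels=truth_green,
        truth_senescent_fraction=senescent_fraction,
    )
    image_set.validate()
    return image_set
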