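"""Core data containers shared across the drought-phenomics pipeline.

The containers mirror the experimental objects of a pot-based drydown study:
timestamped pot-weight series, chamber VPD-step logs, multi-angle RGB image
sets, and the parameter sets of the continuous two-segment response model
(water use vs. fraction of transpirable soil water, or transpiration rate
vs. vapour pressure deficit).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: Allowed watering arms: well-watered controls and water-stressed plants.
WATERING_LABELS = ("WW", "WS")

#: Side-view camera angles supported by the imaging platform emulation.
VALID_ANGLES = (0, 15, 30, 45, 60, 75, 90)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generator parameters for one synthetic scenario.

    The four leading fields parameterise the continuous two-segment response
    (segment 1 below the breakpoint, segment 2 at/above it); the remaining
    fields control the gravimetric, growth and senescence structure of the
    simulated experiment.

    Parameters
    ----------
    intercept1
        Y value of segment 1 at X = 0 (g day^-1 for FTSW curves,
        mg m^-2 s^-1 for VPD curves).
    slope1
        Slope of segment 1 (X < x0), response units per X unit.
    x0
        Breakpoint: FTSW fraction (unitless) or VPD (kPa).
    slope2
        Slope of segment 2 (X >= x0).
    noise_sd
        Additive Gaussian noise SD on the response, same units as Y.
    ttsw
        Total transpirable soil water per pot (g).
    soil_evap_day, soil_evap_night
        Soil-only evaporation per daytime/nighttime period (g).
    pla_slope_ww, pla_slope_ws
        Linear projected-leaf-area growth rates (pixels per day).
    senescence_onset_ftsw
        FTSW below which basal senescence starts to accumulate.
    seed
        Default RNG seed for scenarios built from these parameters.
    """

    intercept1: float
    slope1: float
    x0: float
    slope2: float
    noise_sd: float = 0.0
    ttsw: float = 2500.0
    soil_evap_day: float = 6.0
    soil_evap_night: float = 2.0
    pla_slope_ww: float = 1500.0
    pla_slope_ws: float = 700.0
    senescence_onset_ftsw: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ttsw > 0:
            raise ValueError(f"ttsw must be positive, got {self.ttsw}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.x0 > 0:
            raise ValueError(f"x0 must be positive, got {self.x0}")
        if self.pla_slope_ww < 0 or self.pla_slope_ws < 0:
            raise ValueError("projected-leaf-area growth slopes must be >= 0")


class WeightRecord(NamedTuple):
    """One pot weighing: timestamp, weight in g, and whether the pot was
    re-watered (refilled to target) immediately after this reading."""

    timestamp: dt.datetime
    weight: float
    rewatered: bool


@dataclass
class PotWeightSeries:
    """Raw gravimetric record for one plant (or soil-only pot)."""

    plant_id: str
    species: str
    accession: str
    watering: str
    records: list[WeightRecord]
    #: generator-side ground truth (per-day plant water loss, FTSW, ...);
    #: absent for real data.
    truth: dict | None = None

    def validate(self) -> None:
        if self.watering not in WATERING_LABELS:
            raise ValueError(f"watering must be one of {WATERING_LABELS}")
        times = [r.timestamp for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.plant_id}: timestamps not strictly increasing")
        if any(r.weight <= 0 for r in self.records):
            raise ValueError(f"{self.plant_id}: non-positive pot weight")
        if self.watering == "WS" and any(r.rewatered for r in self.records):
            raise ValueError(f"{self.plant_id}: WS plant has rewatering events")


class VPDStep(NamedTuple):
    """One chamber VPD step: target level, time window, mean air conditions
    and bracketing pot weights."""

    target_vpd: float
    start: dt.datetime
    end: dt.datetime
    mean_temperature: float
    mean_rh: float
    start_weight: float
    end_weight: float


@dataclass
class VPDStepLog:
    """Chamber log for one plant across sequential VPD steps."""

    plant_id: str
    leaf_area: float  # m^2, one-sided
    steps: list[VPDStep]

    def validate(self) -> None:
        if not self.leaf_area > 0:
            raise ValueError("leaf_area must be positive")
        for s in self.steps:
            if s.end <= s.start:
                raise ValueError("step end must be after start")
            if not 0 < s.mean_rh <= 100:
                raise ValueError("RH must be in (0, 100]")


class PlantView(NamedTuple):
    angle: int
    image: np.ndarray  # HxWx3 uint8


@dataclass
class PlantImageSet:
    """Multi-angle side-view RGB frames for one plant on one day (DAT)."""

    plant_id: str
    day: int
    views: list[PlantView]
    truth_green_pixels: list[int] | None = None
    truth_senescent_fraction: float | None = None

    def validate(self) -> None:
        if any(v.angle not in VALID_ANGLES for v in self.views):
            raise ValueError(f"view angles must be drawn from {VALID_ANGLES}")
        shapes = {v.image.shape for v in self.views}
        if len(shapes) > 1:
            raise ValueError("all views must share one resolution")
        if self.truth_green_pixels is not None and any(
            g < 0 for g in self.truth_green_pixels
        ):
            raise ValueError("truth_green_pixels must be >= 0")


@dataclass(frozen=True)
class SegmentedFit:
    """Least-squares estimate of the continuous two-segment response model.

    ``x0`` is the breakpoint (called WU_bp for water-use-vs-FTSW curves and
    TR_bp for transpiration-vs-VPD curves). Continuity at ``x0`` holds by
    construction: segment 2 starts at Y1(x0).
    """

    intercept1: float
    slope1: float
    x0: float
    slope2: float
    r2: float
    n: int
    residual_sd: float
    x0_pinned: bool = False
    x0_ci: tuple[float, float] | None = None


@dataclass
class ResponseDataset:
    """Paired response observations for segmented fitting.

    ``kind`` is ``"ftsw"`` (x = FTSW fraction, y = WU g day^-1) or ``"vpd"``
    (x = VPD kPa, y = TR mg m^-2 s^-1).
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "vpd"
    label: str | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")


@dataclass(frozen=True)
class WaterUseRecord:
    """Soil-corrected day/night water use for one plant on one date."""

    plant_id: str
    date: dt.date
    wu_day: float
    wu_night: float
    soil_corrected: bool = True


@dataclass
class FTSWSeries:
    """Per-date fraction of transpirable soil water for one plant.

    ``entries`` hold values clipped to [0, 1] for downstream fitting;
    ``raw`` retains the unclipped values for QC.
    """

    plant_id: str
    entries: list[tuple[dt.date, float]]
    raw: list[tuple[dt.date, float]] = field(default_factory=list)


@dataclass(frozen=True)
class RecoveryMetric:
    plant_id: str
    period: str  # "day" | "night"
    recovery_pct: float


@dataclass
class SegmentationMask:
    """Binary plant/background mask aligned to its source image."""

    mask: np.ndarray  # bool, HxW

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class PLARecord:
    """Projected leaf area (max green pixels over side views) plus the
    green:red ratio per area decile of the best view, ordered bottom-to-top."""

    plant_id: str
    day: int
    pla: int
    best_view_angle: int
    decile_green_red: tuple[float, ...]


@dataclass(frozen=True)
class SenescenceRecord:
    plant_id: str
    day: int
    senescence_pct: float


@dataclass(frozen=True)
class LeafMeasurement:
    """One leaf's length and width (cm) with the grass-leaf shape factor."""

    leaf_id: str
    length: float
    width: float
    k: float = 0.858

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError("leaf dimensions must be >= 0")
        if not 0 < self.k <= 1:
            raise ValueError("shape factor k must be in (0, 1]")


@dataclass
class ScenarioResult:
    """Bundle of ground truth, estimates and per-parameter errors for one
    seeded synthetic scenario."""

    truth: TruthParams
    estimates: dict
    errors: dict
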