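"""RGB plant segmentation, projected leaf area and senescence scoring.

Side-view plant pixels are classified by colour indices on 8-bit channels:

* green (healthy) tissue: excess-green 2G - R - B > tau (default 20) and
  G > R;
* senescent (yellow/red) tissue: warm dominance R + G - 2B > tau_warm
  (default 120) — admitted into the plant foreground but not into the
  green count.

Projected leaf area (PLA) is the green-pixel count of the side view with
the greatest area. Senescence is scored from the green:red channel ratio
computed per area decile by height (ten bins of equal pixel count ordered
from the bottom of the image upward) and expressed in stressed plants as a
percentage relative to the well-watered control.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import linregress
from skimage.morphology import remove_small_objects

from .types import PlantImageSet, PLARecord, SegmentationMask

__all__ = [
    "green_mask",
    "segment_plant",
    "projected_leaf_area",
    "green_red_deciles",
    "senescence_percent",
    "validate_pla",
]

DEFAULT_GREEN_TAU = 20.0
DEFAULT_WARM_TAU = 120.0


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {image.shape}")
    return image.astype(np.int32)


def green_mask(image: np.ndarray, tau: float = DEFAULT_GREEN_TAU) -> np.ndarray:
    """Healthy-tissue classifier: 2G - R - B > tau and G > R."""
    rgb = _check_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return (2 * g - r - b > tau) & (g > r)


def segment_plant(
    image: np.ndarray,
    tau: float = DEFAULT_GREEN_TAU,
    warm_tau: float = DEFAULT_WARM_TAU,
    min_size: int = 0,
) -> SegmentationMask:
    """Plant-vs-background segmentation.

    Foreground is green tissue OR warm (yellow/red) senescent tissue.
    ``min_size`` > 1 removes connected specks below that pixel area
    (useful on photographic input; leave 0 for exact counts on clean
    procedural renders).
    """
    rgb = _check_rgb(image)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    fg = green_mask(image, tau) | (r + g - 2 * b > warm_tau)
    if min_size > 1:
        fg = remove_small_objects(fg, min_size=min_size)
    return SegmentationMask(mask=fg)


def projected_leaf_area(
    image_set: PlantImageSet,
    tau: float = DEFAULT_GREEN_TAU,
    warm_tau: float = DEFAULT_WARM_TAU,
    min_size: int = 0,
) -> PLARecord:
    """Projected leaf area: the green-pixel count of the best side view.

    The view with the most green pixels defines PLA (ties go to the first
    view in angle order); the green:red deciles are computed on that view's
    full plant foreground (green plus senescent tissue).
    """
    image_set.validate()
    if not image_set.views:
        raise ValueError("image set has no views")
    counts = [int(green_mask(v.image, tau).sum()) for v in image_set.views]
    best = int(np.argmax(counts))
    best_view = image_set.views[best]
    fg = segment_plant(best_view.image, tau, warm_tau, min_size)
    deciles = green_red_deciles(best_view.image, fg.mask)
    return PLARecord(
        plant_id=image_set.plant_id,
        day=image_set.day,
        pla=counts[best],
        best_view_angle=best_view.angle,
        decile_green_red=tuple(deciles),
    )


def green_red_deciles(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Green:red channel ratio per area decile by height.

    Foreground pixels are ordered from the bottom of the image upward
    (row 0 is the top, so largest row indices first; ties broken by column)
    and split into ten bins of equal pixel count (sizes differ by at most
    one). The ratio per bin is mean(G) / mean(R) over that bin's pixels.
    """
    rgb = _check_rgb(image)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rgb.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    rows, cols = np.nonzero(mask)
    if rows.size < 10:
        raise ValueError(f"mask has {rows.size} pixels; need >= 10 for deciles")
    order = np.lexsort((cols, -rows))  # bottom of the plant first
    g = rgb[..., 1][rows[order], cols[order]].astype(float)
    r = rgb[..., 0][rows[order], cols[order]].astype(float)
    ratios = []
    for g_bin, r_bin in zip(np.array_split(g, 10), np.array_split(r, 10)):
        mean_r = r_bin.mean()
        ratios.append(g_bin.mean() / mean_r if mean_r > 0 else np.inf)
    return np.array(ratios)


def senescence_percent(ws_deciles, ww_deciles) -> float:
    """Senescence of a stressed plant as % of its well-watered reference.

    The per-plant summary green:red value is the mean over the ten height
    deciles; senescence = 100 x (1 - GR_WS / GR_WW), floored at zero.
    0% means the stressed plant is as green as the control; values
    approach 100% as the canopy yellows completely.
    """
    gr_ws = float(np.mean(ws_deciles))
    gr_ww = float(np.mean(ww_deciles))
    if gr_ww <= 0:
        raise ValueError("well-watered reference green:red ratio must be positive")
    return max(0.0, 100.0 * (1.0 - gr_ws / gr_ww))


def validate_pla(
    pla_records: list[PLARecord],
    destructive: list[tuple[str, float]],
) -> tuple[float, float, float]:
    """Regress destructively measured leaf area (cm^2) on image-based PLA.

    Pairs records by plant id and fits ordinary least squares
    destructive_area = slope * pla_pixels + intercept; returns
    (slope, intercept, r^2). Requires at least three pairs.
    """
    by_plant = {rec.plant_id: rec.pla for rec in pla_records}
    pairs = [(by_plant[p], area) for p, area in destructive if p in by_plant]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(y) == 0:  # constant destructive areas: zero explainable variance
        return 0.0, float(y[0]), 0.0
    res = linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
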