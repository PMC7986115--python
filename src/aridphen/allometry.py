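"""Non-destructive leaf-area estimation from leaf dimensions.

Grass (Poaceae) leaf blades are close to elongated ellipses, so one-sided
leaf area is estimated as length x width x k with the shape factor
k = 0.858. Per-plant area is the sum over leaves, converted to m^2 for
normalising whole-plant transpiration rates.
"""

from __future__ import annotations

from typing import Iterable

from .types import LeafMeasurement

__all__ = ["POACEAE_SHAPE_FACTOR", "leaf_area", "plant_leaf_area"]

#: Shape factor converting length x width to one-sided area for grass leaves.
POACEAE_SHAPE_FACTOR = 0.858

#: cm^2 per m^2.
_CM2_PER_M2 = 1e4


def leaf_area(m: LeafMeasurement) -> float:
    """One-sided area of a single leaf in cm^2: width * length * k."""
    return m.width * m.length * m.k


def plant_leaf_area(measurements: Iterable[LeafMeasurement]) -> float:
    """Total one-sided leaf area of a plant in m^2.

    Sums per-leaf areas (cm^2) over the measurement list and converts to m^2.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("need at least one leaf measurement")
    return sum(leaf_area(m) for m in measurements) / _CM2_PER_M2
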