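"""Five-way land classification: degrading/improving x remote/accessible.

Agricultural land is *degrading* (DAL) where the 1981-2000 NPP change is
strictly negative and *improving* (IAL) where it is non-negative (exact
zeros count as improving). A cell has *market access* when its travel
time to the nearest market city is strictly below the threshold (5 hours
by default); otherwise it is *remote*, including unreachable cells at
+inf. Cells outside the agricultural extent, or with missing data in any
required layer, are EXCLUDED.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .grids import AlignmentError, GridLayer, LayerStack, analysis_mask

__all__ = [
    "LandClass",
    "LandClassGrid",
    "classify_trend",
    "classify_remoteness",
    "classify_land",
]

DEFAULT_THRESHOLD_HOURS = 5.0


class LandClass(IntEnum):
    """Integer label codes used when the grid is serialized."""

    EXCLUDED = 0
    DAL_ACC = 1
    DAL_REM = 2
    IAL_ACC = 3
    IAL_REM = 4


@dataclass
class LandClassGrid:
    """Per-cell land-class labels plus the remoteness threshold that produced them."""

    labels: np.ndarray  # integer array of LandClass codes
    threshold_hours: float = DEFAULT_THRESHOLD_HOURS
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def count(self, cls: LandClass) -> int:
        return int((self.labels == cls).sum())

    def mask(self, *classes: LandClass) -> np.ndarray:
        return np.isin(self.labels, [int(c) for c in classes])

    @property
    def dal_mask(self) -> np.ndarray:
        return self.mask(LandClass.DAL_ACC, LandClass.DAL_REM)

    @property
    def ial_mask(self) -> np.ndarray:
        return self.mask(LandClass.IAL_ACC, LandClass.IAL_REM)

    def to_layer(self) -> GridLayer:
        return GridLayer(
            self.labels.astype(float), kind="zone", cell_size=self.cell_size,
            origin=self.origin, nodata=-1.0,
        )


def classify_trend(npp_trend: GridLayer) -> tuple[np.ndarray, np.ndarray]:
    """Split cells into (degrading, improving) by the sign of the NPP change.

    Degrading means strictly negative change; zero change is improving.
    Nodata cells appear in neither mask.
    """
    valid = npp_trend.valid_mask()
    degrading = valid & (npp_trend.values < 0)
    improving = valid & (npp_trend.values >= 0)
    return degrading, improving


def classify_remoteness(
    travel_time: GridLayer, threshold_hours: float = DEFAULT_THRESHOLD_HOURS
) -> tuple[np.ndarray, np.ndarray]:
    """Split cells into (remote, accessible) at the travel-time threshold.

    Access is strictly less than the threshold; a cell at exactly the
    threshold, or unreachable (+inf), is remote.
    """
    if threshold_hours <= 0:
        raise ValueError("threshold_hours must be positive")
    valid = travel_time.valid_mask()
    accessible = valid & (travel_time.values < threshold_hours)
    remote = valid & ~(travel_time.values < threshold_hours)
    return remote, accessible


def classify_land(
    stack: LayerStack, threshold_hours: float = DEFAULT_THRESHOLD_HOURS
) -> LandClassGrid:
    """Cross the trend and remoteness classifications over agricultural cells."""
    ref = stack.npp_trend
    for name, layer in stack.layers().items():
        if not layer.same_geometry(ref):
            raise AlignmentError(f"layer {name} is not aligned with the stack reference")
    usable = analysis_mask(stack) & (stack.agri_mask.values == 1)
    degrading, improving = classify_trend(stack.npp_trend)
    remote, accessible = classify_remoteness(stack.travel_time, threshold_hours)

    labels = np.full(ref.shape, int(LandClass.EXCLUDED), dtype=np.int8)
    labels[usable & degrading & accessible] = int(LandClass.DAL_ACC)
    labels[usable & degrading & remote] = int(LandClass.DAL_REM)
    labels[usable & improving & accessible] = int(LandClass.IAL_ACC)
    labels[usable & improving & remote] = int(LandClass.IAL_REM)
    return LandClassGrid(
        labels, threshold_hours=threshold_hours, cell_size=ref.cell_size, origin=ref.origin
    )
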