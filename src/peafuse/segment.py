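"""Soil/background removal via SAVI thresholds.

Two rules are provided, matching common practice for the two image scales:
an absolute SAVI cut for fine UAS imagery, and a lower-tail percentile cut
of the within-ROI SAVI histogram for satellite-scale and pan-sharpened
imagery (dropping the darkest 15% or 25% of pixels to eliminate spectrally
mixed ones). Whether a stated "15%" is a histogram percentile or an absolute
SAVI value of 0.15 is ambiguous in the field; both rules are exposed and the
percentile reading is the default for satellite-scale products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ParameterError
from .raster import Scene

log = logging.getLogger(__name__)

#: canonical soil-adjustment factor (Huete's SAVI)
SAVI_L = 0.5

#: default absolute SAVI threshold for fine UAS imagery (configurable)
DEFAULT_UAS_SAVI_THRESHOLD = 0.3

#: default histogram percentiles per product class
SATELLITE_PERCENTILE = 15.0
PANSHARPENED_PERCENTILE = 25.0


@dataclass
class VegetationMask:
    """Binary vegetation mask aligned to its source scene, with provenance."""

    values: np.ndarray
    rule: str
    threshold: float | None = None
    percentile: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ParameterError("mask grid must be 2-D")

    @property
    def n_kept(self) -> int:
        return int(self.values.sum())

    @property
    def empty(self) -> bool:
        return self.n_kept == 0


def compute_savi(scene: Scene, L: float = SAVI_L) -> np.ndarray:
    """SAVI = (1 + L)(NIR − R)/(NIR + R + L), NaN-propagating."""
    nir = scene.band("nir")
    red = scene.band("red")
    denom = nir + red + L
    with np.errstate(invalid="ignore", divide="ignore"):
        savi = (1.0 + L) * (nir - red) / denom
    savi = np.where(denom == 0, np.nan, savi)
    return savi


def mask_by_value(savi: np.ndarray, threshold: float = DEFAULT_UAS_SAVI_THRESHOLD) -> VegetationMask:
    """Keep pixels with SAVI strictly above an absolute threshold."""
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    with np.errstate(invalid="ignore"):
        kept = savi > threshold
    mask = VegetationMask(values=kept, rule="value", threshold=float(threshold))
    if mask.empty:
        log.warning("value rule at %.4g kept no pixels", threshold)
    return mask


def mask_by_percentile(
    savi: np.ndarray, percentile: float, roi: np.ndarray | None = None
) -> VegetationMask:
    """Keep pixels whose SAVI exceeds the within-ROI percentile.

    ``roi`` is an optional boolean grid restricting both the histogram and
    the kept pixels (e.g. the union of plot footprints). The percentile uses
    linear interpolation for determinism across implementations.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ParameterError(f"percentile {percentile} outside [0, 100]")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != savi.shape:
            raise GeometryError("ROI grid shape does not match the SAVI grid")
        pool = savi[roi]
    else:
        pool = savi.ravel()
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise GeometryError("empty ROI: no finite SAVI values to threshold")
    cut = float(np.percentile(pool, percentile, method="linear"))
    with np.errstate(invalid="ignore"):
        kept = savi > cut
    if percentile == 0.0:
        # the darkest pixel itself survives a zero cut
        kept = np.isfinite(savi) & (savi >= cut)
    if roi is not None:
        kept &= roi
    mask = VegetationMask(values=kept, rule="percentile", threshold=cut, percentile=float(percentile))
    if mask.empty:
        log.warning("percentile rule at %.4g kept no pixels", percentile)
    return mask
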