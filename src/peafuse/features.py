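"""Vegetation indices, GLCM texture statistics, and feature-table assembly.

The VI registry is data-driven: each index is one entry naming the bands it
needs and an arithmetic formula over reflectances, so alternative formula
variants can be swapped in without touching code. The registry holds the 11
indices used for plot-level spectral features; nine of them need only the
five UAS bands ("common" VIs), while NDRE2 and NDVI2 additionally require
the satellite-only yellow and NIR2 bands.

Texture features are the four Haralick statistics contrast (CO), homogeneity
(HO), correlation (CR), and energy (EN, the angular second moment Σp²)
computed from symmetric, normalized grey-level co-occurrence matrices on the
rectangular plot window, averaged over the four standard offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix, graycoprops

from .errors import BandError, ContractError, DataError, PipelineError
from .raster import PlotMap, Scene, polygon_pixel_indices
from .segment import VegetationMask

log = logging.getLogger(__name__)

BandGrids = Mapping[str, np.ndarray]


@dataclass(frozen=True)
class VIDefinition:
    name: str
    bands: tuple[str, ...]
    formula: Callable[[BandGrids], np.ndarray]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def _tvi(b: BandGrids) -> np.ndarray:
    nd = _safe_div(b["nir"] - b["red"], b["nir"] + b["red"])
    with np.errstate(invalid="ignore"):
        return np.sqrt(0.5 + nd)


VI_REGISTRY: dict[str, VIDefinition] = {
    "NDVI": VIDefinition("NDVI", ("nir", "red"),
                         lambda b: _safe_div(b["nir"] - b["red"], b["nir"] + b["red"])),
    "GNDVI": VIDefinition("GNDVI", ("nir", "green"),
                          lambda b: _safe_div(b["nir"] - b["green"], b["nir"] + b["green"])),
    "NDREI": VIDefinition("NDREI", ("nir", "red_edge"),
                          lambda b: _safe_div(b["nir"] - b["red_edge"], b["nir"] + b["red_edge"])),
    "SAVI": VIDefinition("SAVI", ("nir", "red"),
                         lambda b: _safe_div(1.5 * (b["nir"] - b["red"]), b["nir"] + b["red"] + 0.5)),
    "ARVI": VIDefinition("ARVI", ("nir", "red", "blue"),
                         lambda b: _safe_div(b["nir"] - (2 * b["red"] - b["blue"]),
                                             b["nir"] + (2 * b["red"] - b["blue"]))),
    "TVI": VIDefinition("TVI", ("nir", "red"), _tvi),
    "IPVI": VIDefinition("IPVI", ("nir", "red"),
                         lambda b: _safe_div(b["nir"], b["nir"] + b["red"])),
    "RDVI": VIDefinition("RDVI", ("nir", "red"),
                         lambda b: _safe_div(b["nir"] - b["red"],
                                             np.sqrt(np.clip(b["nir"] + b["red"], 0, None)))),
    "EVI2": VIDefinition("EVI2", ("nir", "red"),
                         lambda b: _safe_div(2.5 * (b["nir"] - b["red"]),
                                             b["nir"] + 2.4 * b["red"] + 1.0)),
    "NDRE2": VIDefinition("NDRE2", ("nir", "yellow"),
                          lambda b: _safe_div(b["nir"] - b["yellow"], b["nir"] + b["yellow"])),
    "NDVI2": VIDefinition("NDVI2", ("nir2", "red"),
                          lambda b: _safe_div(b["nir2"] - b["red"], b["nir2"] + b["red"])),
}

#: the nine indices computable from both sensors' band sets
COMMON_VIS: tuple[str, ...] = (
    "NDVI", "GNDVI", "NDREI", "SAVI", "ARVI", "TVI", "IPVI", "RDVI", "EVI2"
)

TEXTURE_STATS: tuple[str, ...] = ("CO", "HO", "CR", "EN")
_PROP_FOR_STAT = {"CO": "contrast", "HO": "homogeneity", "CR": "correlation", "EN": "ASM"}


def available_vis(scene: Scene) -> list[str]:
    """Registry indices computable from this scene's band set, in registry order."""
    names = set(scene.band_names)
    return [k for k, vi in VI_REGISTRY.items() if set(vi.bands) <= names]


def compute_vi(scene: Scene, name: str) -> np.ndarray:
    """Per-pixel index grid; NaN where undefined (zero denominators, nodata)."""
    try:
        vi = VI_REGISTRY[name]
    except KeyError:
        raise BandError(f"unknown vegetation index {name!r}") from None
    missing = [b for b in vi.bands if b not in scene.band_names]
    if missing:
        raise BandError(f"{name} requires bands {missing} absent from {scene.band_names}")
    grids = {b: scene.band(b) for b in vi.bands}
    return vi.formula(grids)


# ---------------------------------------------------------------------------
# Plot-level spectral features
# ---------------------------------------------------------------------------

def plot_spectral_features(
    scene: Scene,
    plots: PlotMap,
    mask: VegetationMask | np.ndarray | None = None,
    vis: Sequence[str] | None = None,
    source: str = "UAS",
    timepoint: str = "TP1",
) -> pd.DataFrame:
    """Median per-plot value of each VI over vegetation pixels.

    Columns are named ``<VI>_<source>_<timepoint>``, rows indexed by plot_id.
    Plots whose masked pixel set is empty get NaN and a logged warning; if
    every plot is empty a :class:`PipelineError` is raised.
    """
    vis = list(vis) if vis is not None else available_vis(scene)
    mask_grid = mask.values if isinstance(mask, VegetationMask) else mask
    grids = {name: compute_vi(scene, name) for name in vis}
    index = [r.plot_id for r in plots]
    out = pd.DataFrame(index=pd.Index(index, name="plot_id"),
                       columns=[f"{v}_{source}_{timepoint}" for v in vis], dtype=float)
    n_empty = 0
    for rec in plots:
        rows, cols = polygon_pixel_indices(scene, rec.polygon)
        if mask_grid is not None and rows.size:
            keep = mask_grid[rows, cols].astype(bool)
            rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            n_empty += 1
            log.warning("plot %s: no vegetation pixels, features set to NaN", rec.plot_id)
            continue
        for name in vis:
            vals = grids[name][rows, cols]
            vals = vals[np.isfinite(vals)]
            out.loc[rec.plot_id, f"{name}_{source}_{timepoint}"] = (
                float(np.median(vals)) if vals.size else np.nan
            )
    if n_empty == len(plots):
        raise PipelineError("every plot produced an empty vegetation pixel set")
    return out


# ---------------------------------------------------------------------------
# GLCM texture features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMParams:
    """Grey-level co-occurrence setup: 32 levels, distance 1, four angles."""

    levels: int = 32
    distances: tuple[int, ...] = (1,)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    normed: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ContractError("GLCM needs at least 2 grey levels")
        if not self.distances or not self.angles_deg:
            raise ContractError("GLCM needs at least one offset")


def glcm_features(window: np.ndarray, params: GLCMParams = GLCMParams()) -> dict[str, float]:
    """Haralick CO/HO/CR/EN for one plot window of band reflectances.

    The window is quantized to ``params.levels`` bins over its own min–max
    range (making the statistics invariant to affine rescaling), accumulated
    into symmetric normalized co-occurrence matrices for every offset, and
    the four statistics are averaged over offsets. A constant window returns
    the degenerate values (CO, HO, CR, EN) = (0, 1, 0, 1); correlation is
    undefined there and fixed at 0.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or min(window.shape) < 2:
        raise ContractError(f"GLCM window must be at least 2×2, got {window.shape}")
    finite = np.isfinite(window)
    if not finite.any():
        raise DataError("GLCM window has no finite values")
    lo = np.nanmin(window)
    hi = np.nanmax(window)
    if hi == lo:
        return {"CO": 0.0, "HO": 1.0, "CR": 0.0, "EN": 1.0}
    q = np.floor((window - lo) / (hi - lo) * params.levels).astype(np.int64)
    np.clip(q, 0, params.levels - 1, out=q)
    q[~finite] = 0  # non-finite pixels fall into the darkest bin
    angles = np.deg2rad(params.angles_deg)
    P = graycomatrix(
        q.astype(np.uint8),
        distances=list(params.distances),
        angles=list(angles),
        levels=params.levels,
        symmetric=params.symmetric,
        normed=params.normed,
    )
    out = {}
    for stat in TEXTURE_STATS:
        vals = graycoprops(P, _PROP_FOR_STAT[stat])
        out[stat] = float(np.mean(vals))
    return out


def plot_texture_features(
    scene: Scene,
    plots: PlotMap,
    params: GLCMParams = GLCMParams(),
    source: str = "UAS",
    timepoint: str = "TP1",
) -> pd.DataFrame:
    """Per-plot GLCM statistics for every spectral band.

    Texture is computed on the full rectangular window spanned by the plot
    polygon (co-occurrence needs spatial contiguity, so the vegetation mask
    is deliberately not applied). Columns: ``<band>-<stat>_<source>_<tp>``.
    """
    index = [r.plot_id for r in plots]
    cols = [f"{b}-{s}_{source}_{timepoint}" for b in scene.band_names for s in TEXTURE_STATS]
    out = pd.DataFrame(index=pd.Index(index, name="plot_id"), columns=cols, dtype=float)
    xs, ys = scene.pixel_centers()
    for rec in plots:
        xmin, ymin, xmax, ymax = rec.polygon.bounds
        c0 = int(np.searchsorted(xs, xmin, side="left"))
        c1 = int(np.searchsorted(xs, xmax, side="right"))
        r0 = int(np.searchsorted(ys, ymin, side="left"))
        r1 = int(np.searchsorted(ys, ymax, side="right"))
        if (r1 - r0) < 2 or (c1 - c0) < 2:
            raise ContractError(f"plot {rec.plot_id} window smaller than 2×2 pixels")
        for bname in scene.band_names:
            stats = glcm_features(scene.band(bname)[r0:r1, c0:c1], params)
            for s, v in stats.items():
                out.loc[rec.plot_id, f"{bname}-{s}_{source}_{timepoint}"] = v
    return out


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

def attach_metadata(features: pd.DataFrame, plots: PlotMap) -> pd.DataFrame:
    """Prefix entry/replicate/yield metadata columns onto a feature table."""
    meta = plots.to_dataframe()
    joined = meta.join(features, how="left")
    return joined


def build_scenario(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Column-wise concatenation of feature tables over an identical plot set.

    Raises on duplicate column names and on plot-set mismatch — a silent
    intersection would quietly change the modeling population.
    """
    if not tables:
        raise ContractError("no tables to combine")
    base = tables[0].index
    for t in tables[1:]:
        if not base.equals(t.index) and (len(base) != len(t.index) or set(base) != set(t.index)):
            raise ContractError("plot sets differ between feature tables")
    aligned = [t.reindex(base) for t in tables]
    names = [c for t in aligned for c in t.columns]
    dupes = {c for c in names if names.count(c) > 1}
    if dupes:
        raise ContractError(f"duplicate feature columns: {sorted(dupes)}")
    return pd.concat(aligned, axis=1)
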