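"""Scene/plot data model, GeoTIFF & GeoJSON I/O, resampling, zonal extraction.

World convention
----------------
All coordinates live in a local planar frame in metres. ``origin`` is the world
coordinate of the *top-left corner* of pixel (0, 0); x grows with columns and y
grows with rows (image-style, downward). A pixel occupies the half-open square
``[x, x + gsd) × [y, y + gsd)`` and its center sits at ``(x + gsd/2, y + gsd/2)``.
Plot polygons are expressed in the same frame, so no CRS machinery is needed;
GeoTIFF output still records the affine transform via the standard
ModelPixelScale/ModelTiepoint tags.

Nodata is carried as NaN in float grids, never as 0 reflectance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, mapping, shape

from .errors import (
    AlignmentError,
    FormatError,
    GeometryError,
    MetadataError,
    ResolutionError,
)

log = logging.getLogger(__name__)

# GeoTIFF tag codes for the affine georeferencing of an axis-aligned raster.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass(frozen=True)
class Band:
    """One spectral band: a short lowercase name and its center wavelength."""

    name: str
    center_nm: float


@dataclass
class Scene:
    """A georeferenced reflectance stack of shape (height, width, n_bands)."""

    values: np.ndarray
    bands: tuple[Band, ...]
    gsd_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise FormatError(f"scene grid must be H×W×B, got ndim={self.values.ndim}")
        if not self.bands:
            raise FormatError("scene must declare at least one band")
        if self.values.shape[2] != len(self.bands):
            raise FormatError(
                f"{self.values.shape[2]} band planes vs {len(self.bands)} descriptors"
            )
        if not self.gsd_m > 0:
            raise FormatError("gsd_m must be positive")
        self.bands = tuple(self.bands)
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate band names: {names}")

    # -- basic geometry -----------------------------------------------------
    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the pixel-area footprint."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.width * self.gsd_m, y0 + self.height * self.gsd_m)

    def band(self, name: str) -> np.ndarray:
        """2-D view of one band plane, resolved by name."""
        from .errors import BandError

        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise BandError(
                f"band {name!r} not in scene bands {self.band_names}"
            ) from None
        return self.values[:, :, idx]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World x (per column) and y (per row) coordinates of pixel centers."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.width) + 0.5) * self.gsd_m
        ys = y0 + (np.arange(self.height) + 0.5) * self.gsd_m
        return xs, ys

    def with_values(self, values: np.ndarray, bands: Sequence[Band] | None = None) -> "Scene":
        return Scene(
            values=values,
            bands=tuple(bands) if bands is not None else self.bands,
            gsd_m=self.gsd_m,
            origin=self.origin,
        )


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    entry_id: str
    replicate: int
    polygon: Polygon
    yield_kg_ha: float | None = None


@dataclass
class PlotMap:
    """Plot polygons with entry/replicate labels and optional yields."""

    records: list[PlotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.plot_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise GeometryError("plot_id values must be unique")
        for r in self.records:
            if not r.polygon.is_valid:
                raise GeometryError(f"invalid polygon for plot {r.plot_id}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        boxes = np.array([r.polygon.bounds for r in self.records])
        return (
            float(boxes[:, 0].min()),
            float(boxes[:, 1].min()),
            float(boxes[:, 2].max()),
            float(boxes[:, 3].max()),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "plot_id": [r.plot_id for r in self.records],
                "entry_id": [r.entry_id for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "yield_kg_ha": [r.yield_kg_ha for r in self.records],
            }
        ).set_index("plot_id")

    # -- GeoJSON ------------------------------------------------------------
    def to_geojson(self, path) -> None:
        features = []
        for r in self.records:
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(r.polygon),
                    "properties": {
                        "plot_id": r.plot_id,
                        "entry_id": r.entry_id,
                        "replicate": r.replicate,
                        "yield_kg_ha": r.yield_kg_ha,
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "PlotMap":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise FormatError("expected a GeoJSON FeatureCollection")
        records = []
        for feat in doc["features"]:
            props = feat["properties"]
            records.append(
                PlotRecord(
                    plot_id=str(props["plot_id"]),
                    entry_id=str(props["entry_id"]),
                    replicate=int(props["replicate"]),
                    polygon=shape(feat["geometry"]),
                    yield_kg_ha=props.get("yield_kg_ha"),
                )
            )
        return cls(records=records)


@dataclass
class PixelSet:
    """Per-band pixel values extracted for one plot.

    ``values`` has shape (n_pixels, n_bands); ``rows``/``cols`` index back
    into the source grid. An empty extraction is kept, flagged via ``empty``.
    """

    plot_id: str
    band_names: tuple[str, ...]
    values: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    @property
    def empty(self) -> bool:
        return self.values.shape[0] == 0

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile; grids stored float32, band-interleaved-by-plane)
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, path) -> None:
    """Write a scene as a multi-band float32 GeoTIFF.

    Band names, wavelengths, GSD and origin go into a JSON ImageDescription;
    the affine transform is additionally recorded in the standard GeoTIFF
    ModelPixelScale / ModelTiepoint tags.
    """
    import tifffile

    meta = {
        "peafuse": 1,
        "gsd_m": scene.gsd_m,
        "origin": list(scene.origin),
        "bands": [{"name": b.name, "center_nm": b.center_nm} for b in scene.bands],
    }
    x0, y0 = scene.origin
    data = np.moveaxis(scene.values.astype(np.float32), 2, 0)  # (B, H, W)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (scene.gsd_m, scene.gsd_m, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        ],
    )


def read_scene(path, expect_bands: int | None = None) -> Scene:
    """Read a scene written by :func:`write_scene`.

    Raises :class:`MetadataError` when georeferencing is absent and
    :class:`FormatError` when ``expect_bands`` disagrees with the file.
    """
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        desc = page.description
    try:
        meta = json.loads(desc)
        if "gsd_m" not in meta:
            raise KeyError("gsd_m")
    except (json.JSONDecodeError, TypeError, KeyError) as exc:
        raise MetadataError(f"{path}: missing peafuse georeferencing metadata") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    values = np.moveaxis(data, 0, 2).astype(np.float64)
    bands = tuple(Band(b["name"], float(b["center_nm"])) for b in meta["bands"])
    if expect_bands is not None and len(bands) != expect_bands:
        raise FormatError(f"{path}: expected {expect_bands} bands, found {len(bands)}")
    return Scene(
        values=values,
        bands=bands,
        gsd_m=float(meta["gsd_m"]),
        origin=tuple(meta["origin"]),
    )


def write_mask(mask_values: np.ndarray, gsd_m: float, origin, path) -> None:
    """Write a 0/1 vegetation mask as single-band uint8 GeoTIFF."""
    import tifffile

    meta = {"peafuse": 1, "gsd_m": gsd_m, "origin": list(origin), "mask": True}
    tifffile.imwrite(
        path,
        np.asarray(mask_values, dtype=np.uint8),
        photometric="minisblack",
        description=json.dumps(meta),
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentReport:
    overlap: bool
    gsd_ratio: float
    integral_ratio: bool
    offset_coarse_px: tuple[float, float]
    aligned: bool


def check_alignment(a: Scene, b: Scene, tolerance_px: float = 0.5) -> AlignmentReport:
    """Verify the co-registration contract between two scenes.

    Reports extent overlap, whether the GSD ratio is integral, and the origin
    offset in units of the coarser pixel. ``aligned`` is True when the ratio
    is integral and the sub-pixel offset stays within ``tolerance_px``.
    Disjoint extents raise :class:`AlignmentError`.
    """
    ax0, ay0, ax1, ay1 = a.extent
    bx0, by0, bx1, by1 = b.extent
    overlap = (ax0 < bx1 and bx0 < ax1) and (ay0 < by1 and by0 < ay1)
    if not overlap:
        raise AlignmentError("scene extents are disjoint")
    coarse = max(a.gsd_m, b.gsd_m)
    fine = min(a.gsd_m, b.gsd_m)
    ratio = coarse / fine
    integral = abs(ratio - round(ratio)) < 1e-9
    dx = (b.origin[0] - a.origin[0]) / coarse
    dy = (b.origin[1] - a.origin[1]) / coarse
    # positive fractional remainder of the origin offset, in coarse pixels
    fx = dx % 1.0
    fy = dy % 1.0
    fx = 0.0 if fx > 1.0 - 1e-9 else fx  # guard float wrap-around
    fy = 0.0 if fy > 1.0 - 1e-9 else fy
    aligned = integral and fx <= tolerance_px and fy <= tolerance_px
    if not aligned:
        log.warning(
            "misaligned scenes: ratio=%.6f offset=(%.3f, %.3f) coarse px", ratio, fx, fy
        )
    return AlignmentReport(
        overlap=True,
        gsd_ratio=ratio,
        integral_ratio=integral,
        offset_coarse_px=(fx, fy),
        aligned=aligned,
    )


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_UPSAMPLE_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def upsample(scene: Scene, ratio: int, method: str = "nearest") -> Scene:
    """Increase pixel counts by ``ratio`` per axis, preserving world extent."""
    ratio = _check_ratio(ratio)
    if method not in _UPSAMPLE_ORDER:
        raise ResolutionError(f"unknown upsampling method {method!r}")
    if ratio == 1:
        return scene.with_values(scene.values.copy())
    if method == "nearest":
        out = np.repeat(np.repeat(scene.values, ratio, axis=0), ratio, axis=1)
    else:
        order = _UPSAMPLE_ORDER[method]
        planes = [
            ndimage.zoom(
                scene.values[:, :, k], ratio, order=order, mode="nearest", grid_mode=True
            )
            for k in range(scene.n_bands)
        ]
        out = np.stack(planes, axis=2)
    return Scene(out, scene.bands, scene.gsd_m / ratio, scene.origin)


def degrade(scene: Scene, ratio: int) -> Scene:
    """Block-mean aggregation over ratio × ratio windows (NaN-ignoring)."""
    ratio = _check_ratio(ratio)
    if ratio == 1:
        return scene.with_values(scene.values.copy())
    h, w = scene.height, scene.width
    if h % ratio or w % ratio:
        raise ResolutionError(
            f"grid {h}×{w} not divisible by degradation ratio {ratio}"
        )
    v = scene.values.reshape(h // ratio, ratio, w // ratio, ratio, scene.n_bands)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(v, axis=(1, 3))
        # constant blocks reduce to their value bit-exactly (round-trip contract)
        lo = np.nanmin(v, axis=(1, 3))
        hi = np.nanmax(v, axis=(1, 3))
    out = np.where(lo == hi, lo, out)
    return Scene(out, scene.bands, scene.gsd_m * ratio, scene.origin)


def _check_ratio(ratio) -> int:
    if not float(ratio).is_integer() or ratio < 1:
        raise ResolutionError(f"resampling ratio must be a positive integer, got {ratio}")
    return int(ratio)


# ---------------------------------------------------------------------------
# Zonal extraction
# ---------------------------------------------------------------------------

def polygon_pixel_indices(scene: Scene, polygon: Polygon) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers fall inside ``polygon``."""
    xs, ys = scene.pixel_centers()
    xmin, ymin, xmax, ymax = polygon.bounds
    c0 = int(np.searchsorted(xs, xmin, side="left"))
    c1 = int(np.searchsorted(xs, xmax, side="right"))
    r0 = int(np.searchsorted(ys, ymin, side="left"))
    r1 = int(np.searchsorted(ys, ymax, side="right"))
    if c0 >= c1 or r0 >= r1:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(polygon, xs[cc.ravel()], ys[rr.ravel()])
    return rr.ravel()[inside], cc.ravel()[inside]


def extract_plot_pixels(
    scene: Scene,
    plots: PlotMap,
    mask: np.ndarray | None = None,
    buffer_m: float = 0.0,
) -> dict[str, PixelSet]:
    """Pixel-center-in-polygon extraction for every plot.

    ``mask`` (a boolean vegetation mask aligned to the scene) is intersected
    when given. ``buffer_m`` > 0 shrinks each polygon inward before the test.
    Empty extractions are kept and flagged, never dropped silently. A polygon
    wholly outside the scene raises :class:`GeometryError`.
    """
    if mask is not None and mask.shape != (scene.height, scene.width):
        raise GeometryError(
            f"mask shape {mask.shape} does not match scene {scene.height}×{scene.width}"
        )
    ex0, ey0, ex1, ey1 = scene.extent
    scene_box = shapely.box(ex0, ey0, ex1, ey1)
    out: dict[str, PixelSet] = {}
    for rec in plots:
        poly = rec.polygon
        if buffer_m > 0:
            poly = poly.buffer(-buffer_m)
            if poly.is_empty:
                out[rec.plot_id] = _empty_pixelset(rec.plot_id, scene)
                log.warning("plot %s vanished under buffer %.3g m", rec.plot_id, buffer_m)
                continue
        if not scene_box.intersects(poly):
            raise GeometryError(f"plot {rec.plot_id} lies outside the scene extent")
        rows, cols = polygon_pixel_indices(scene, poly)
        if mask is not None and rows.size:
            keep = mask[rows, cols].astype(bool)
            rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            out[rec.plot_id] = _empty_pixelset(rec.plot_id, scene)
            log.warning("plot %s: empty pixel set", rec.plot_id)
            continue
        out[rec.plot_id] = PixelSet(
            plot_id=rec.plot_id,
            band_names=scene.band_names,
            values=scene.values[rows, cols, :],
            rows=rows,
            cols=cols,
        )
    return out


def _empty_pixelset(plot_id: str, scene: Scene) -> PixelSet:
    return PixelSet(
        plot_id=plot_id,
        band_names=scene.band_names,
        values=np.empty((0, scene.n_bands)),
        rows=np.empty(0, dtype=int),
        cols=np.empty(0, dtype=int),
    )


def rasterize_polygons(scene: Scene, polygons: Iterable[Polygon]) -> np.ndarray:
    """Boolean grid marking pixels whose centers fall in any polygon."""
    grid = np.zeros((scene.height, scene.width), dtype=bool)
    for poly in polygons:
        rows, cols = polygon_pixel_indices(scene, poly)
        grid[rows, cols] = True
    return grid
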