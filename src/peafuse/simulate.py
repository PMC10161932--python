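"""Synthetic multi-scale trial scenes with known yield → reflectance structure.

The generator stands in for imagery that is not publicly deposited: it lays
out a randomized-complete-block pea trial (6.1 × 1.5 m plots with 6 seed rows
and 0.75 m alleys), draws plot yields from a site-calibrated normal model,
and renders co-registered reflectance stacks in which canopy reflectance is
monotonically linked to plot yield. Coarser sensors (satellite-scale,
HD-like) are derived from the fine scene by block averaging plus spectral
mixing, so every downstream stage — segmentation, features, pan-sharpening,
modeling — can be exercised against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box

from .errors import ContractError, GeometryError, InvalidDesignError, ResolutionError
from .raster import Band, PlotMap, PlotRecord, Scene, degrade, polygon_pixel_indices

# ---------------------------------------------------------------------------
# Band sets (center wavelengths in nm)
# ---------------------------------------------------------------------------

UAS_BANDS: tuple[Band, ...] = (
    Band("blue", 475.0),
    Band("green", 560.0),
    Band("red", 668.0),
    Band("red_edge", 717.0),
    Band("nir", 842.0),
)

SATELLITE_BANDS: tuple[Band, ...] = (
    Band("blue", 480.0),
    Band("green", 545.0),
    Band("yellow", 605.0),
    Band("red", 660.0),
    Band("red_edge", 725.0),
    Band("nir", 832.0),
    Band("nir2", 950.0),
)

HD_BANDS: tuple[Band, ...] = (
    Band("blue", 480.0),
    Band("green", 545.0),
    Band("red", 660.0),
    Band("nir", 832.0),
)


@dataclass(frozen=True)
class TrialDesign:
    """Randomized-complete-block layout of a plot trial.

    Plots are ``plot_width_m`` wide (x) and ``plot_length_m`` long (y) with a
    ``plot_gap_m`` alley on all sides. Each replicate block is a grid of
    ``block_columns`` plots per row; blocks are stacked vertically.
    ``extra_check_plots`` appends additional replicates of the first few
    entries (check varieties) in a trailing partial block.
    """

    n_entries: int
    n_replicates: int
    plot_length_m: float = 6.1
    plot_width_m: float = 1.5
    plot_gap_m: float = 0.75
    rows_per_plot: int = 6
    block_columns: int | None = None
    extra_check_plots: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 1 or self.n_replicates < 1:
            raise InvalidDesignError("entry and replicate counts must be positive")
        if min(self.plot_length_m, self.plot_width_m, self.plot_gap_m) <= 0:
            raise InvalidDesignError("plot dimensions and gap must be positive")
        if self.rows_per_plot < 1:
            raise InvalidDesignError("rows_per_plot must be positive")
        if self.extra_check_plots < 0:
            raise InvalidDesignError("extra_check_plots must be >= 0")

    @property
    def columns(self) -> int:
        if self.block_columns is not None:
            if self.block_columns < 1:
                raise InvalidDesignError("block_columns must be positive")
            return self.block_columns
        return max(1, math.ceil(math.sqrt(self.n_entries)))

    @property
    def n_plots(self) -> int:
        return self.n_entries * self.n_replicates + self.extra_check_plots


@dataclass(frozen=True)
class YieldModel:
    """Normal yield model: plot yield = mean + entry effect + residual.

    The two variance components should satisfy
    ``sd_kg_ha² ≈ entry_effect_sd² + residual_sd²``; generated yields are
    truncated to stay positive (redrawn residuals).
    """

    mean_kg_ha: float
    sd_kg_ha: float
    entry_effect_sd: float
    residual_sd: float

    def __post_init__(self) -> None:
        if min(self.sd_kg_ha, self.entry_effect_sd, self.residual_sd) < 0:
            raise InvalidDesignError("standard deviations must be >= 0")

    @classmethod
    def from_total_sd(
        cls, mean_kg_ha: float, sd_kg_ha: float, entry_variance_share: float = 0.8
    ) -> "YieldModel":
        """Split a trial-level SD into entry/residual components.

        The default 80% entry share emulates the high between-line
        repeatability typical of advanced yield trials.
        """
        ev = sd_kg_ha * math.sqrt(entry_variance_share)
        rv = sd_kg_ha * math.sqrt(1.0 - entry_variance_share)
        return cls(mean_kg_ha, sd_kg_ha, ev, rv)


@dataclass(frozen=True)
class SitePreset:
    name: str
    design: TrialDesign
    yield_model: YieldModel
    n_usable_plots: int
    n_excluded: int


# Site 1: advanced yield trial — 65 entries × 3 reps plus 9 extra check plots,
# one outlier excluded → 203 usable plots; yields 1938 ± 498 kg/ha.
# Site 2: variety testing trial — 33 entries × 4 reps, one excluded → 131
# usable plots; yields 4514 ± 783 kg/ha.
SITE_PRESETS: dict[str, SitePreset] = {
    "site1": SitePreset(
        name="site1",
        design=TrialDesign(n_entries=65, n_replicates=3, extra_check_plots=9),
        yield_model=YieldModel.from_total_sd(1938.0, 498.0),
        n_usable_plots=203,
        n_excluded=1,
    ),
    "site2": SitePreset(
        name="site2",
        design=TrialDesign(n_entries=33, n_replicates=4, extra_check_plots=0),
        yield_model=YieldModel.from_total_sd(4514.0, 783.0),
        n_usable_plots=131,
        n_excluded=1,
    ),
}


@dataclass(frozen=True)
class ReflectanceLink:
    """How plot yield maps to per-band canopy reflectance.

    ``yield_slope`` is the reflectance change per yield z-score (positive for
    NIR-type bands, negative for visible bands). ``cover_fraction`` gives the
    canopy fractional cover at each time point (vegetative < pod development
    by default). ``structure`` selects how cover is realised within a plot:

    * ``"uniform"`` — every within-plot pixel is the cover-weighted mixture
      of canopy and soil (no sub-plot spatial structure);
    * ``"rows"`` — canopy is concentrated in ``rows_per_plot`` stripes whose
      width scales with cover, leaving bare alleys between seed rows. This is
      the mode that gives pan-sharpening something to recover.

    All generated reflectances are clipped to [0, 1].
    """

    soil_spectrum: dict[str, float]
    canopy_base_spectrum: dict[str, float]
    yield_slope: dict[str, float]
    pixel_noise_sd: float = 0.01
    cover_fraction: dict[str, float] = field(
        default_factory=lambda: {"TP1": 0.55, "TP2": 0.9}
    )
    structure: str = "uniform"

    def __post_init__(self) -> None:
        if self.pixel_noise_sd < 0:
            raise ContractError("pixel_noise_sd must be >= 0")
        for tp, cf in self.cover_fraction.items():
            if not 0.0 <= cf <= 1.0:
                raise ContractError(f"cover_fraction[{tp!r}]={cf} outside [0, 1]")
        if self.structure not in ("uniform", "rows"):
            raise ContractError(f"unknown structure {self.structure!r}")


# Flat-soil line rising into the NIR; canopy is a classic vegetation curve
# (low red, red-edge shoulder, high NIR). Only the monotone yield link — not
# absolute reflectance — matters downstream.
_DEFAULT_SOIL = {
    "blue": 0.15, "green": 0.15, "yellow": 0.15, "red": 0.15,
    "red_edge": 0.20, "nir": 0.25, "nir2": 0.25,
}
_DEFAULT_CANOPY = {
    "blue": 0.04, "green": 0.08, "yellow": 0.07, "red": 0.05,
    "red_edge": 0.28, "nir": 0.48, "nir2": 0.45,
}
_DEFAULT_SLOPE = {
    "blue": -0.004, "green": -0.008, "yellow": -0.008, "red": -0.012,
    "red_edge": 0.02, "nir": 0.045, "nir2": 0.04,
}


def default_link(**overrides) -> ReflectanceLink:
    """The package's stated-world yield→reflectance link."""
    params = dict(
        soil_spectrum=dict(_DEFAULT_SOIL),
        canopy_base_spectrum=dict(_DEFAULT_CANOPY),
        yield_slope=dict(_DEFAULT_SLOPE),
    )
    params.update(overrides)
    return ReflectanceLink(**params)


def severed_link(**overrides) -> ReflectanceLink:
    """Same link with the yield signal removed (all slopes zero)."""
    params = dict(
        soil_spectrum=dict(_DEFAULT_SOIL),
        canopy_base_spectrum=dict(_DEFAULT_CANOPY),
        yield_slope={k: 0.0 for k in _DEFAULT_SLOPE},
    )
    params.update(overrides)
    return ReflectanceLink(**params)


@dataclass(frozen=True)
class SceneSpec:
    """Sensor geometry for rendering: GSD, band set, world origin, margin."""

    gsd_m: float
    bands: tuple[Band, ...] = UAS_BANDS
    origin: tuple[float, float] = (0.0, 0.0)
    margin_m: float = 1.5

    def __post_init__(self) -> None:
        if self.gsd_m <= 0:
            raise ContractError("gsd_m must be positive")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ContractError("band names must be unique")


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def generate_trial(
    design: TrialDesign,
    yield_model: YieldModel,
    seed: int,
    n_exclude: int = 0,
) -> PlotMap:
    """Lay out the trial and draw plot yields; deterministic given ``seed``.

    Entry assignment is an independent random permutation within each
    replicate block. ``n_exclude`` removes that many plots at random after
    generation (field outliers / missing harvests).
    """
    rng = np.random.default_rng(seed)
    n_e, n_r = design.n_entries, design.n_replicates
    cols = design.columns
    pw, pl, gap = design.plot_width_m, design.plot_length_m, design.plot_gap_m
    rows_per_block = math.ceil(n_e / cols)
    block_h = rows_per_block * (pl + gap)

    entry_ids = [f"E{i + 1:03d}" for i in range(n_e)]
    entry_effects = rng.normal(0.0, yield_model.entry_effect_sd, size=n_e)
    effects = dict(zip(entry_ids, entry_effects))

    records: list[PlotRecord] = []

    def add_plot(entry: str, rep: int, slot: int, y_base: float) -> None:
        r, c = divmod(slot, cols)
        x0 = gap + c * (pw + gap)
        y0 = y_base + gap + r * (pl + gap)
        poly = box(x0, y0, x0 + pw, y0 + pl)
        # redraw the residual until the yield is positive (truncation)
        while True:
            y = yield_model.mean_kg_ha + effects[entry] + rng.normal(0.0, yield_model.residual_sd)
            if y > 0:
                break
        records.append(
            PlotRecord(
                plot_id=f"P{len(records) + 1:04d}",
                entry_id=entry,
                replicate=rep,
                polygon=poly,
                yield_kg_ha=float(y),
            )
        )

    for rep in range(1, n_r + 1):
        order = rng.permutation(n_e)
        y_base = (rep - 1) * block_h
        for slot, entry_idx in enumerate(order):
            add_plot(entry_ids[entry_idx], rep, slot, y_base)

    if design.extra_check_plots:
        n_checks = max(1, math.ceil(design.extra_check_plots / 3))
        y_base = n_r * block_h
        for k in range(design.extra_check_plots):
            add_plot(entry_ids[k % n_checks], n_r + 1 + k // n_checks, k % cols, y_base)

    if n_exclude:
        if n_exclude >= len(records):
            raise InvalidDesignError("cannot exclude every plot")
        drop = set(rng.choice(len(records), size=n_exclude, replace=False).tolist())
        records = [r for i, r in enumerate(records) if i not in drop]

    return PlotMap(records=records)


def simulate_site(site: str, seed: int) -> PlotMap:
    """Generate a preset trial (``site1``/``site2``) with its exclusions."""
    try:
        preset = SITE_PRESETS[site]
    except KeyError:
        raise InvalidDesignError(
            f"unknown site preset {site!r}; choose from {sorted(SITE_PRESETS)}"
        ) from None
    return generate_trial(
        preset.design, preset.yield_model, seed=seed, n_exclude=preset.n_excluded
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_scene(
    plots: PlotMap,
    link: ReflectanceLink,
    spec: SceneSpec,
    timepoint: str = "TP1",
    seed: int = 0,
) -> Scene:
    """Rasterize the trial into a multispectral reflectance stack.

    Inter-plot pixels carry the soil spectrum plus noise; within-plot pixels
    mix canopy and soil according to the time point's fractional cover (see
    :class:`ReflectanceLink.structure`). The canopy spectrum of a plot is
    ``base + slope × yield z-score`` with the z-score taken over the plots at
    hand. Reproducible for a given seed; values clipped to [0, 1].
    """
    if timepoint not in link.cover_fraction:
        raise ContractError(f"no cover_fraction for time point {timepoint!r}")
    cf = link.cover_fraction[timepoint]
    band_names = [b.name for b in spec.bands]
    for table, what in (
        (link.soil_spectrum, "soil_spectrum"),
        (link.canopy_base_spectrum, "canopy_base_spectrum"),
        (link.yield_slope, "yield_slope"),
    ):
        missing = [n for n in band_names if n not in table]
        if missing:
            raise ContractError(f"{what} missing bands {missing}")

    xmin, ymin, xmax, ymax = plots.bounds
    m = spec.margin_m
    x0 = xmin - m
    y0 = ymin - m
    width = int(math.ceil((xmax + m - x0) / spec.gsd_m))
    height = int(math.ceil((ymax + m - y0) / spec.gsd_m))
    if width <= 0 or height <= 0:
        raise GeometryError("degenerate scene extent")

    min_span = min(
        min(r.polygon.bounds[2] - r.polygon.bounds[0] for r in plots),
        min(r.polygon.bounds[3] - r.polygon.bounds[1] for r in plots),
    )
    if min_span / spec.gsd_m < 4:
        raise GeometryError(
            f"GSD {spec.gsd_m} m too coarse: plots span < 4 pixels per axis"
        )

    rng = np.random.default_rng(seed)
    soil = np.array([link.soil_spectrum[n] for n in band_names])
    base = np.array([link.canopy_base_spectrum[n] for n in band_names])
    slope = np.array([link.yield_slope[n] for n in band_names])

    yields = np.array([r.yield_kg_ha for r in plots], dtype=float)
    mu, sd = yields.mean(), yields.std()
    z = (yields - mu) / sd if sd > 0 else np.zeros_like(yields)

    grid = np.empty((height, width, len(band_names)))
    grid[:] = soil

    scene = Scene(grid, tuple(spec.bands), spec.gsd_m, (x0, y0))
    xs, _ = scene.pixel_centers()

    for rec, zi in zip(plots, z):
        rows, cols = polygon_pixel_indices(scene, rec.polygon)
        if rows.size == 0:
            raise GeometryError(f"plot {rec.plot_id} rasterized to zero pixels")
        canopy = np.clip(base + slope * zi, 0.0, 1.0)
        if link.structure == "uniform":
            grid[rows, cols, :] = cf * canopy + (1.0 - cf) * soil
        else:  # seed-row stripes along the plot length
            px0, _, px1, _ = rec.polygon.bounds
            n_rows = max(1, _plot_rows(rec))
            spacing = (px1 - px0) / n_rows
            centers = px0 + (np.arange(n_rows) + 0.5) * spacing
            half = 0.5 * cf * spacing
            xc = xs[cols]
            in_row = np.min(np.abs(xc[:, None] - centers[None, :]), axis=1) <= half
            grid[rows[in_row], cols[in_row], :] = canopy
            # pixels between rows keep the soil background

    if link.pixel_noise_sd > 0:
        grid += rng.normal(0.0, link.pixel_noise_sd, size=grid.shape)
    np.clip(grid, 0.0, 1.0, out=grid)
    return scene


def _plot_rows(rec: PlotRecord) -> int:
    # seed rows per plot; fixed at the design default (6) for rendered rows
    return 6


# ---------------------------------------------------------------------------
# Sensor degradation
# ---------------------------------------------------------------------------

def default_band_map(src: tuple[Band, ...], dst: tuple[Band, ...]) -> np.ndarray:
    """Row-stochastic spectral mixing matrix mapping src bands to dst bands.

    Exact name matches are passed through; ``yellow`` is synthesized as the
    mean of green and red; ``nir2`` borrows the NIR band.
    """
    src_names = [b.name for b in src]
    W = np.zeros((len(dst), len(src)))
    for i, b in enumerate(dst):
        if b.name in src_names:
            W[i, src_names.index(b.name)] = 1.0
        elif b.name == "yellow" and "green" in src_names and "red" in src_names:
            W[i, src_names.index("green")] = 0.5
            W[i, src_names.index("red")] = 0.5
        elif b.name == "nir2" and "nir" in src_names:
            W[i, src_names.index("nir")] = 1.0
        else:
            raise ContractError(f"cannot synthesize band {b.name!r} from {src_names}")
    return W


def degrade_to_sensor(
    fine: Scene,
    target: SceneSpec,
    band_map: np.ndarray | None = None,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> Scene:
    """Derive a coarser sensor's view: block mean, then spectral mixing.

    The target GSD must be an integer multiple of the fine GSD; the fine grid
    is cropped to a whole number of blocks (origin preserved). ``band_map``
    rows must sum to 1 (defaults to :func:`default_band_map`).
    """
    ratio_f = target.gsd_m / fine.gsd_m
    if abs(ratio_f - round(ratio_f)) > 1e-9:
        raise ResolutionError(
            f"target GSD {target.gsd_m} not an integer multiple of {fine.gsd_m}"
        )
    ratio = int(round(ratio_f))
    if band_map is None:
        band_map = default_band_map(fine.bands, target.bands)
    band_map = np.asarray(band_map, dtype=float)
    if band_map.shape != (len(target.bands), fine.n_bands):
        raise ContractError(
            f"band_map shape {band_map.shape} != ({len(target.bands)}, {fine.n_bands})"
        )
    if not np.allclose(band_map.sum(axis=1), 1.0, atol=1e-9):
        raise ContractError("band_map rows must sum to 1")

    h = (fine.height // ratio) * ratio
    w = (fine.width // ratio) * ratio
    cropped = Scene(fine.values[:h, :w, :], fine.bands, fine.gsd_m, fine.origin)
    coarse = degrade(cropped, ratio)
    mixed = np.einsum("hwb,kb->hwk", coarse.values, band_map)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mixed = np.clip(mixed + rng.normal(0.0, noise_sd, size=mixed.shape), 0.0, 1.0)
    return Scene(mixed, tuple(target.bands), coarse.gsd_m, coarse.origin)
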