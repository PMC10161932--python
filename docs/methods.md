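# Methods

`peafuse` re-creates, end to end, a multi-scale remote-sensing workflow for
plot-level seed-yield estimation in field pea breeding trials: synthetic
trial imagery → soil removal → plot-level spectral/texture features →
optional satellite pan-sharpening with UAS imagery → an entry-holdout
random-forest protocol → a stability-aware feature-importance statistic.
This note documents the models, the defaults and why they were chosen, and
what the synthetic world does and does not establish.

## The synthetic trial world

Real trial imagery of this kind (commercial high-resolution satellite plus
UAS orthomosaics over breeding plots) is rarely redistributable, so every
stage is exercised against a generator whose statistical structure matches
what the analysis assumes.

**Trial layout.** A randomized complete block design of 6.1 m × 1.5 m plots
with six seed rows and 0.75 m alleys. Entry order is an independent random
permutation within each replicate block. Two site presets reproduce the
trial dimensions the pipeline is calibrated for:

| preset | entries × reps | extra check plots | excluded | usable plots | yield (kg/ha) |
|---|---|---|---|---|---|
| `site1` (advanced yield trial) | 65 × 3 | 9 | 1 | 203 | 1938 ± 498 |
| `site2` (variety testing trial) | 33 × 4 | 0 | 1 | 131 | 4514 ± 783 |

The extra check plots emulate check varieties grown with additional
replicates; exclusions emulate outlier plots removed before analysis.

**Yield model.** Plot yield = trial mean + entry effect + residual, with
`entry_effect_sd² + residual_sd² = sd²` and redrawn residuals enforcing
positivity. The default 80 % entry share of variance reflects the high
between-line repeatability typical of advanced yield trials; nothing
downstream is sensitive to the exact split because features track total
plot yield, not the entry effect alone.

**Reflectance link.** Soil is a flat visible line (0.15) rising into the
NIR (0.25); canopy is a classic vegetation curve (low red, red-edge
shoulder, high NIR). The canopy spectrum of a plot shifts by
`yield_slope × yield z-score` per band — positive in the NIR/red-edge,
negative in the visible — which is the monotone yield → vegetation-index
signal the whole analysis exploits. Fractional canopy cover is
time-point-dependent (defaults 0.55 at TP1, 0.90 at TP2: vegetative → pod
development). Two within-plot structures are available:

* `uniform` — each within-plot pixel is the cover-weighted canopy/soil
  mixture. No sub-plot spatial structure; appropriate for exact-value
  oracles.
* `rows` — canopy concentrated in six row stripes whose width scales with
  cover, bare alleys between. This puts real sub-pixel structure under a
  coarse sensor, which is what gives pan-sharpening something to recover.

Pixel noise is i.i.d. Gaussian per pixel and band (default SD 0.01
reflectance). Within-plot spatial autocorrelation of reflectance is *not*
modelled — a documented simplification; consequences: plot medians over
many pixels are less noisy than in real imagery, and texture features carry
less information than they might in the field.

**Sensor chain.** The fine (UAS-like, 5-band) scene is the only rendered
product; satellite-scale (7-band) and HD-like (4-band) companions are
derived by exact block-mean aggregation followed by row-stochastic spectral
mixing (yellow ≈ mean of green and red; NIR2 borrows NIR). This guarantees
perfect co-registration and reflectance conservation, so fusion tests
isolate algorithmic behaviour from registration error. No radiative
transfer, BRDF, atmosphere, shadow, or lodging is simulated.

## Segmentation

SAVI = (1 + L)(NIR − R)/(NIR + R + L) with the canonical L = 0.5. Fine
imagery uses an absolute SAVI cut (default 0.3, configurable — the value a
practitioner would set by inspecting the SAVI histogram). Satellite-scale
and pan-sharpened products use a lower-tail percentile cut of the
within-ROI SAVI histogram (drop the darkest 15 % for original/HD satellite
products, 25 % for pan-sharpened ones) to discard spectrally mixed pixels.
Whether a stated "15 %" means a percentile or an absolute SAVI of 0.15 is
genuinely ambiguous in practice; both rules are implemented, with the
percentile reading the default because it is the only scale-free choice.
The percentile is computed once per scene over the trial ROI (union of plot
footprints), not per plot — a per-plot cut would delete a fixed fraction of
every plot and destroy the cover signal. Linear-interpolation percentiles
keep the cut deterministic across implementations.

## Features

Eleven vegetation indices in a data-driven registry (canonical literature
forms; any variant can be swapped in as a registry entry):
NDVI, GNDVI, NDREI, SAVI (L = 0.5), ARVI, TVI = √(0.5 + NDVI), IPVI, RDVI,
EVI2, and the satellite-only NDRE2 = (N − Y)/(N + Y) and
NDVI2 = (NIR2 − R)/(NIR2 + R). Nine are computable from both sensors
("common" VIs); multi-source fusion scenarios use exactly those nine from
each source, giving the 18- and 36-column fusion tables.

Plot spectral features are the **median of per-pixel VI values** over
vegetation pixels (compute-then-aggregate, not VI-of-median-reflectance);
even counts take the mean of the two middle values.

Texture features are Haralick contrast, homogeneity, correlation, and
energy from grey-level co-occurrence matrices: 32 levels quantized over the
plot window's own min–max (hence invariant to affine band rescaling),
distance 1, angles {0°, 45°, 90°, 135°}, symmetric, normalized, averaged
over angles — standard defaults where none are otherwise fixed. Energy is
the angular second moment Σp² (the MATLAB `graycoprops` convention).
Texture is computed on the full rectangular plot window without the
vegetation mask because co-occurrence needs spatial contiguity; a constant
window returns (CO, HO, CR, EN) = (0, 1, 0, 1), with correlation fixed at 0
where its variance-normalized definition is undefined.

## Pan-sharpening

The panchromatic band is simulated as the unweighted per-pixel mean of the
five fine-scale bands. Both fusions histogram-match the pan band to the
target component by linear mean–variance matching (full CDF matching
available behind a flag).

* **Generalized IHS** (component substitution): I = mean of *all* MS bands
  (not visible-only), P′ = matched pan, fused_k = MS_k + (P′ − I). Adds the
  same detail to every band, so per-pixel band differences are preserved
  exactly.
* **AWLP** (multi-resolution): the matched pan is decomposed by the
  undecimated à-trous transform (separable B3-spline kernel [1,4,6,4,1]/16,
  kernel dilated 2ʲ per level, mirror boundary; default levels
  ⌈log₂ (GSD ratio)⌉) and the summed detail planes are injected
  proportionally to each band's share of the luminance:
  fused_k = MS_k + (MS_k / max(L, 1e−6)) ΣD_j. Band *ratios* are preserved
  wherever L is bounded away from zero — the mechanism behind AWLP's lower
  spectral-angle distortion.

MS grids are upsampled to the pan grid by nearest-neighbour (pixel
replication) before injection. This choice makes block-mean degradation an
exact inverse of the upsampling, so the reduced-resolution (Wald) check
isolates what the injection itself does to the spectra: AWLP then returns
the original spectra exactly (SAM ≈ 0) while IHS's additive shift does
not. Interpolated upsampling (bilinear/bicubic) is available but mixes
interpolation error into both methods' scores. Negative fused reflectances
are clipped to 0 with a logged count.

**Quality metrics** (fused degraded back to the MS GSD, scored against the
original): per-band Pearson CC, SSIM (11 × 11 Gaussian window, σ = 1.5,
K1 = 0.01, K2 = 0.03, dynamic range = per-band reference max − min; the
window shrinks on very small grids), PSNR with peak = per-band reference
max (+∞ sentinel on identity), ERGAS = 100 (h/l) √(mean_b RMSE_b²/μ_b²),
and SAM reported in degrees.

## Modeling protocol

One run: (1) split plots by *entry* — every replicate of a held-out entry
is in the test set; ⌈0.8 E⌉ entries train (a plot-level splitter exists but
entry holdout is the default because it gives the stabler estimate of
generalization to unseen genotypes); (2) drop highly correlated features on
the training side only: while any pair has |r| ≥ 0.99, remove the member of
the worst pair with the larger mean absolute correlation (ties remove the
later column) — greedy, deterministic, idempotent; (3) tune the random
forest's variables-per-split over 5 integers evenly spaced in [1, p] by
3-fold cross-validation repeated 15 times, minimum mean RMSE, ties to the
smaller value; (4) refit with 500 trees on all training rows, unscaled
features, otherwise default hyperparameters; (5) report R² and RMSE on
train and test, where R² is the squared Pearson correlation of predictions
vs observations (the caret convention; the 1 − SSres/SStot variant is
behind a flag); (6) record out-of-bag permutation importance: per tree,
100 (MSE_permuted − MSE_baseline)/MSE_baseline on that tree's out-of-bag
rows, averaged over trees (the raw-percentage convention; permuting a
constant column gives exactly 0). An ensemble repeats this over n seeds
(default 10, seeds base + i) and reports mean ± SD per metric.

One numerical economy: the cross-validation models used *only to rank the
five grid values* are grown with 100 trees (configurable); the selected
value is refit with the full 500. RMSE rankings over so coarse a grid are
stable well below 100 trees, and the change keeps a 10-run ensemble near
40 s on one CPU instead of several minutes. The final models everywhere
use 500 trees.

Plots with missing features (empty vegetation mask) or missing yield are
dropped with a logged warning before modeling, mirroring field practice of
excluding unharvestable plots.

## Adjusted rank

Per feature, across the n runs of an ensemble: R1 ranks the *minimum*
%IncMSE across runs (descending — a large worst-case importance is best),
R2 ranks the coefficient of variation of %IncMSE (ascending — stability is
best), R3 ranks the selection frequency after the correlation filter
(descending). Ties get average ranks (keeps the denominator well defined
and reproducible). Then

    R_A = 1 − (R1 + R2 + R3) / (max R1 + max R2 + max R3),

normalized to percent of the best feature (best = 100). Only features
selected in more than one run are rankable (a single observation has no
CV); maxima are taken over those eligible features — the only set that has
ranks. Ineligible features are reported with their occurrence and blank
ranks. Features whose mean %IncMSE is ≤ 0 carry no real importance signal;
their CV is set to +∞ so they take the worst R2 ranks (logged). The
statistic is invariant to positive rescaling of all importances. With a
single eligible feature the statistic is degenerate (the feature is both
best and worst, R_A = 0) and normalization is reported as an error; the
experiment orchestrator degrades to an occurrences-only table there.

## What a green test establishes — and what it does not

The synthetic world has perfectly co-registered scenes, i.i.d. pixel noise,
a deterministic monotone yield → reflectance link, and no atmosphere,
shadows, lodging, or registration error. Green pipeline tests therefore
establish *internal correctness* (each stage computes what it claims, the
protocol recovers a signal it should recover, and refuses one that is not
there) and *directional behaviour* (combined time points beat single time
points when each is a partial view; pan-sharpened satellite features beat
original-resolution ones when sub-plot row structure carries the signal;
AWLP's spectral fidelity beats IHS's under the Wald check). They do not
establish field-accuracy numbers: absolute R²/RMSE on real trials depends
on canopy, weather, and sensor effects the generator deliberately omits.

## Numerical choices and degenerate inputs

- Reflectance grids are float64 internally, float32 on disk (GeoTIFF);
  nodata is NaN, never 0.
- Zonal extraction is strict pixel-center-in-polygon; plot edges coinciding
  with pixel centers exclude that row/column. An optional inward buffer
  (`buffer_m`, default 0) guards against neighbour contamination.
- Block-mean degradation returns constant blocks bit-exactly, making
  degrade ∘ upsample(nearest) an exact identity.
- Alignment checks report the positive fractional origin offset in coarse
  pixels; pairs beyond 0.5 coarse pixel (configurable) are refused.
- Zero-denominator VI pixels are NaN and excluded from medians; an
  all-empty plot set is a pipeline error, a single empty plot a warning.
- Tuning-grid ties take the smaller variables-per-split; correlation-filter
  ties drop the later column; rank ties average.
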