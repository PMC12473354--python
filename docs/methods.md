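# Methods

## Harmonic summary of an NDVI time series

Each pixel's series y(t) (ordinal days t, typically ~22 observations at a
~27-day mean interval over about one and a half annual cycles) is reduced in
two stages. First an ordinary-least-squares line m·t + b absorbs slow drift
(calibration differences, background brightening). The residuals are then
fitted with a single sinusoid plus bias, a₀ + a₁·cos x + b₁·sin x, under one
of two time encodings:

- **annual_radian** — x = τ = 2π·DOY/365.25, wrapped to [0, 2π). The phase
  Φ = atan2(b₁, a₁) is then a calendar angle (peak timing in the year).
- **ordinal_day** — x = t in raw days, an implicit period of 2π days. The
  phase is only a relative offset, not calendar-interpretable, but it tends
  to decorrelate neighbouring fields more strongly because the fit is free
  to absorb sub-annual management signals.

The model is linear in (a₀, a₁, b₁). A Levenberg–Marquardt route is exposed
per series (unweighted, unbounded, standard tolerances) and is tested to
agree with the closed-form normal-equation solution to 1e-8; whole-scene
fitting therefore uses the vectorised closed form — one batched 3×3 solve
per pixel — which is orders of magnitude faster for an identical result.
Amplitude is A = √(a₁²+b₁²) ≥ 0; the convention A = 0 ⇒ Φ = 0 handles the
degenerate case. The a₀ bias is retained in the fit but unused downstream.
The third descriptor is the empirical mean of the pixel's valid NDVI values
(not a model parameter).

**Missing data.** A pixel invalid on a date is simply excluded from that
date's series; there is no interpolation or resampling. Pixels with fewer
than `min_valid_obs = 8` valid dates (of ~22) are flagged unfittable and
rendered as nodata; 8 leaves one observation of headroom over the 2·(2+3)
parameters of the two fitting stages and was fixed a priori.

**Known estimator bias.** Detrending a finite, irregularly sampled cosine
is not neutral: over ~1.55 annual cycles the OLS line absorbs part of the
sinusoid, biasing the recovered amplitude by up to ~7% and the phase by up
to ~0.04 rad, deterministically and depending on the true phase. This is a
property of the sequential detrend-then-fit procedure itself (a joint
[1, t, cos, sin] fit would be unbiased) and is kept because the sequential
order *is* the method; tests assert recovery within this envelope, and the
test-suite documents where the bias binds.

**Coefficient cache.** `fit_stack` can persist all coefficient grids in a
single `.npz` archive keyed by a SHA-256 content hash of (values, mask,
dates, grid, encoding, threshold); a stale or unreadable cache is ignored
with a warning and the fit redone. Reloads are bit-identical.

## Recolouring

Channels are normalised with scene-wide ("AOI-width") scalers so contrast
is consistent across tiles: A′ = A/max A (max over fittable pixels),
V′ = (mean+1)/2, ϕ′ = Φ+π ∈ [0, 2π) (wrap at exactly 2π maps to 0).

- **HSV**: H = ϕ′/2π, S = A′, V = V′ — hue encodes timing, vividness the
  seasonal range, brightness the mean greenness.
- **HWB**: H = ϕ′/2π, W = V′, B = 1 − A′. The directions are: brightness
  proportional to amplitude, whiteness from the NDVI mean; W = V′ and
  B = 1 − A′ is the simplest assignment satisfying both and is the
  configurable default. Conversion follows the standard HWB rule
  (achromatic grey W/(W+B) when W+B ≥ 1, else via HSV).
- **LCH(ab)**: L = 100·V′, h = ϕ′, C = s·100·A′. A single global scale
  s ∈ (0, 1] is found by geometric search (factor 0.95 from 1.0) until at
  most 0.1% of valid pixels fall outside the sRGB gamut; the residue is
  clipped. A global rather than per-pixel scale is used so the relative
  chroma relationships between parcels are preserved; hue and lightness are
  untouched by construction. LAB↔XYZ↔sRGB uses D65 and the IEC 61966-2-1
  companding, with the conversion matrix derived exactly from the sRGB
  primary chromaticities so the neutral axis maps to exact grey.

Unfittable pixels render black in every space.

## Segmentation

Composites are processed in 512 px tiles with 35% overlap (stride 333 px);
edge tiles are clipped, not padded. Any callable `(window_rgb, cfg) ->
MaskSet` can serve as the mask-proposal backend; the `BackendConfig`
surface mirrors a zero-shot segmenter's automatic mask generator
(points_per_side = 32, pred_iou_thresh = 0.75, stability_score_thresh =
0.80, crop_n_layers = 2, crop_overlap_ratio = 0.35). The built-in backend
quantizes each channel into 12 equal-width bins and emits 4-connected
components of identical bin triples with ≥ 4 px; it ignores pure-black
(nodata) pixels, emits score 1.0, and is fully deterministic. 12 bins and
4 px were chosen so the smallest meaningful region (≈ 30 m² at 3 m pixels)
aligns with the downstream area filter.

Per-tile masks are merged with greedy non-maximum suppression: descending
score, ties by larger pixel area then lower index; a mask is dropped iff
its IoU with an already-kept mask exceeds 0.70 (the deduplication logic of
the original tiling wrapper is unpublished; this contract is a documented
stand-in, and 0.70 is configurable). Surviving masks are vectorised to
exact pixel-edge polygons — holes preserved, no morphology, no smoothing —
then filtered: area < 30 m² removed (strict), and predictions kept only if
their best IoU against ground truth exceeds 0.50 (strict), mirroring the
evaluation protocol's preselection. `preselect_iou: null` disables the
preselection for symmetric-evaluation use cases.

## Evaluation

Matching is ground-truth anchored: iterating ground-truth parcels in input
order, each takes the unused prediction with the highest IoU from a spatial
index, registered iff IoU ≥ 0.50 (note the deliberate asymmetry with the
strict > 0.50 of preselection — both thresholds are implemented exactly as
specified). TP/FP/FN feed P, R, F1; pixel metrics rasterize both sets as
binary masks at native resolution (overlaps burn the union; TN is never
counted). Strata use [0, 5000), [5000, 20000], (20000, ∞) m²; the placement
of the 20000 m² boundary in the middle stratum is a documented choice, and
the bounds are configurable. Per-stratum false positives attribute each
unmatched prediction to the stratum of its largest-intersection parcel.

Fragmentation associates every retained prediction to the ground-truth
parcel of largest intersection; the stratum ratio is associated predictions
per ground-truth parcel (2 dp). Classification errors per prediction S with
best-overlap parcel O: OC = 1 − |S∩O|/|O|, UC = 1 − |S∩O|/|S|,
TC = √((OC²+UC²)/2); global values are means weighted by prediction area.
GUC aggregates UC (a printed formula elsewhere repeats OC inside the GUC
sum; that is treated as a typographical slip — the UC definition and the
surrounding narrative are unambiguous). Predictions intersecting no ground
truth are excluded from the weighted sums and counted.

Seam analysis marks pixels within 16 px (Euclidean) of any interior tile
boundary line as the seam zone, its complement as interior, and reports
pixel metrics and their interior-minus-seam deltas separately; a
single-tile scene is flagged undefined.

Per-parcel scores for the statistics are the matched pair's vector IoU and
its Dice coefficient 2|S∩O|/(|S|+|O|) (the vector-space limit of pairwise
pixel F1), with unmatched parcels scored 0 so the repeated-measures design
stays balanced across all six variants.

## Statistical testing

The Friedman statistic uses within-row average ranks with the standard tie
correction and a χ²(k−1) reference; fully tied data yield Q = 0, p = 1.
Pairwise comparisons use the Wilcoxon signed-rank test: zero differences
dropped (Wilcoxon's original rule — documented because zero-inflation from
jointly-unmatched parcels is expected), average-rank ties, exact two-sided
p by dynamic programming over the signed-rank null distribution for
effective n ≤ 25, and a normal approximation with tie and continuity
correction above. Family-wise error is controlled by Holm's step-down
adjustment. Effect sizes are Hodges–Lehmann pseudo-medians of the paired
differences (median of Walsh averages) with confidence intervals from
signed-rank distribution quantiles (exact to n = 200, normal beyond);
n < 6 cannot reach 95% coverage and is flagged unreliable.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the *structure* that matters to the method: a
mosaic of elongated strip parcels produced by recursive guillotine splits
(defaults tuned once, with recorded seeds, to a median parcel area of
~0.69 ha with ~83% under 1 ha on a 5×5 km extent), a class mix of 80%
field / 10% forest / 5% water / 5% urban by area, ~22 acquisitions at a
~27-day mean interval with jitter, and per-parcel seasonal cycles
y(t) = mean + trend·(t−t̄) + amp·cos(τ(t) − τ*) + ε with i.i.d. Gaussian ε,
clipped to [−1, 1]. Field parameters keep mean ± amplitude inside [−1, 1]
so clipping never distorts the sinusoid. Forests render high-mean /
low-amplitude, water and urban flat and low.

The **easy preset** used by the end-to-end quality bar draws field
phenology from a discrete menu whose hue, saturation and value land at the
centres of the built-in backend's quantization bins, and assigns menu
combinations so that *touching* parcels never share one — the generator-side
realisation of "phases well separated". This makes the end-to-end test a
test of the pipeline (fitting, recolouring, tiling, NMS, polygonization,
matching) rather than of bin-edge dithering.

Deliberately not modelled: spatial noise autocorrelation, cloud gaps,
misregistration, within-parcel heterogeneity, double cropping, and sensor
radiometry. Passing tests on synthetic scenes therefore demonstrate the
correctness and internal consistency of the pipeline, not field performance
on real imagery, where boundary contrast is weaker and the error modes
(over-segmentation, fragmentation) are stronger.

## Numerical and design choices

- Rasterization burns a pixel iff its centre lies inside the polygon
  (pixel-centre rule, fixed for all metrics); 0-based indices, half-open
  windows, row 0 = north; polygon coordinates in metres.
- Polygonization is exact over pixel edges (run-length rectangles merged
  per 4-connected component); a component that self-touches only at a pixel
  corner cannot be one simple polygon and yields multiple parts.
- NDVI with NIR+RED = 0 marks the pixel invalid instead of raising.
- Multiband scenes need explicit 1-based NIR/RED band indices (sensor band
  layout is configuration, e.g. 8 and 6 for an 8-band cubesat sensor).
- Problem sizes in the test-suite and acceptance script (200–512 px scenes,
  2000 null simulations, 1000-triple colour oracles) were chosen as the
  smallest sizes at which the checked properties are stable across seeds.
- GeoTIFF IO is implemented over tifffile with standard georeferencing tags
  (pixel scale, tiepoint, EPSG geokey); vector IO is GeoJSON. Reprojection,
  cloud masking and atmospheric correction are out of scope.

## Known limitations

- The sequential detrend→harmonic estimator's amplitude bias (above) means
  amplitude-derived channels are compressed by up to ~7% for unluckily
  phased parcels; with 22 dates and noise σ = 0.05 about 85–90% of
  field pixels recover amplitude within 10% (≈ 99% recover phase within
  0.15 rad).
- The built-in backend is a deterministic stand-in: it shares the proposal
  *contract* of a zero-shot segmenter but none of its learned behaviour, so
  absolute metric levels on synthetic scenes do not transfer to real
  imagery.
- Ordinal-day phases are sensitive to the acquisition-date vector; two
  scenes with different date sets are not comparable in that encoding.
- Shapefile input is not supported (GeoJSON only).
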