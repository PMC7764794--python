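# Methods

## Scope and data model

The toolkit evaluates single-frame point clouds from an RGB-D camera
observing a fruit-tree row from a static station. A cloud carries
Cartesian coordinates in metres in the sensor-origin frame, optional
8-bit RGB, and optional NIR intensity in raw digital numbers (DN,
16-bit). Because the colour and depth imagers have different fields of
view, some points legitimately lack colour; a per-point `has_rgb` mask
records this, and such points are excluded from colour statistics only —
they still count for geometry and NIR. Coordinates stay in metres
internally; accuracy and repeatability are reported in millimetres,
the scale on which these sensors are evaluated.

## Geometric metrics

**Density.** Each point's neighbour count `Nᵢ` is the number of *other*
points within Euclidean distance ≤ R (boundary inclusive, self
excluded), and the cloud density is the mean of `3Nᵢ/(4πR³)`. No edge
correction is applied: boundary points genuinely see fewer neighbours,
and the estimator is used comparatively (same R across captures), not as
an absolute density. The default `R = 0.05 m` resolves foliage-scale
structure at 1–3 m range; densities are only comparable at equal R, so
reports record the radius. Neighbour search uses a k-d tree
(`scipy.spatial.cKDTree`); correctness is defined by exhaustive
all-pairs search and the tests assert exact agreement.

**Accuracy.** `accuracy_metrics` consumes operator-style repeated
measurements of a known length (mm) — in practice distances between two
picked points, provided here by `point_pair_distance` and the synthetic
striped rod. `Ac` is the mean absolute error, `RMSE` the quadratic
mean; `RMSE ≥ Ac` always.

**Repeatability.** Replicate captures of a static scene are compared by
nearest-neighbour cloud-to-cloud distances for the ordered pairs 1→2,
1→3, 2→3, pooled with the normaliser `2·P₁ + P₂` — the number of pooled
distances, since replicate 1 is the source of two of the three
collections. The statistic is therefore order-sensitive; this exact
form is kept because it is how the three-replicate protocol is defined,
and the sigma uses the same population-style denominator. A clearly
separated symmetric variant (`precision_metrics_symmetric`, mean over
all ordered pairs) exists for designs with ≠ 3 replicates and is never
used by the standard pipeline. Ties in nearest-neighbour identity are
irrelevant: only the distance enters the metric.

**Penetrability.** Depths along the chosen axis are taken relative to
the canopy front — by default the cloud's own minimum depth coordinate,
or an explicit `origin` (use a shared one for clouds registered into a
common frame; `compare_stations` exposes this as `shared_depth_origin`,
off by default because unregistered sensor-frame captures must each use
their own front). Sections are half-open `[a, a+w)` bins of width
0.1 m by default; the profile reports percentages (always summing to
100), and the mean/sd of the raw relative depths rather than bin
centres — raw depths lose nothing and avoid a bin-width artefact.

**Trend fits.** Metric-vs-illuminance trends use ordinary least
squares with `R² = 1 − SS_res/SS_tot`. A constant response is reported
as slope 0 and R² = 0 (no variance to explain) instead of a NaN
correlation.

## Spectral metrics

RGB is normalised to [0, 1] and converted with the standard hexcone
RGB→HSV transform; per-channel arithmetic means are reported as
percentages. Hue is averaged arithmetically on [0, 1] — canopy hues
cluster far from the red wrap-around, where the arithmetic and circular
means coincide for practical purposes — with a circular option for
scenes that straddle the wrap; achromatic pixels contribute H = 0.

NIR returns from the active emitter fall off with the square of the
range, so the corrected intensity `NIRc = NIR·r²` (DN·m²) is used
whenever captures from different distances are compared; it is constant
for a surface of fixed albedo regardless of stand-off. `scale_nir`
divides intensities by a display factor (default 15 000, the magnitude
of foliage NIRc with this sensor class) for 0–1 plotting. Histograms
are equal-width, normalised to sum to 1, and accept shared bin ranges
so two clouds can be overlaid on one axis.

## Synthetic scene generator

The generator exists so the full metric stack is testable without field
data. It emulates, per capture:

- a pinhole ray per pixel of a 512×424 raster spanning a 70°×60° FOV
  (tangent-spaced, z = optical axis);
- a canopy wall centred on the row axis: a shell of depth 1.5 m (the
  width of a mature fruit-tree row) populated by ~150 disc-shaped
  leaf/fruit blobs at uniform depths, front-most blob wins per ray,
  uncovered rays pass to the back of the shell; 1 cm Gaussian surface
  roughness;
- per-pixel Bernoulli dropout with a piecewise-linear probability in
  illuminance (≈1 % in the dark, ≈3 % at 2000 lx, 40 % at 16 000 lx,
  90 % at full sun) — the observed *phenomenon* of sunlight flooding an
  active emitter, with no radiometric mechanism claimed;
- NIR = albedo / r², with a mean albedo of 6500 DN·m² (foliage scale)
  under 25 % lognormal speckle, rounded to integer DN;
- a foliage RGB palette with shading noise, a low-light exposure
  roll-off below ~50 lx, and colour missing from border raster rows
  (smaller colour FOV);
- replicate captures: independent dropout draws plus 5 mm Gaussian
  coordinate jitter, seeds derived as `seed + replicate index`.

All randomness comes from `numpy.random.default_rng`; the canopy layout
is drawn from the scene seed alone while capture noise uses a
per-capture seed, so one scene can be re-captured from another distance
or as a replicate against identical geometry. Fixed seeds reproduce
clouds bit-identically.

Emergent behaviours match the field phenomenology qualitatively: closer
stations see higher density and *shallower* mean penetration (foreground
blobs subtend more angle and occlude the interior); raw NIR means from
1.5 m vs 2.5 m differ by roughly the squared distance ratio — exactly so
in the near-planar-canopy limit — while mean NIRc agrees to well under
2 %. What the generator does **not** model: multipath/flying-pixel ToF
artefacts, wind-induced motion, auto-exposure dynamics beyond the
low-light roll-off, radiative transfer or leaf-angle distributions, and
any calibrated dropout-vs-lux curve for a specific device. Passing
tests therefore demonstrate the correctness of the metrics and the
internal consistency of the mechanisms, not a radiometric model of any
particular sensor.

## Evaluation pipeline

Observations are grouped into five illumination classes with half-open
ranges at breaks 0, 250, 1000, 4000, 16 000, 64 000 lx; a lux value on a
break belongs to the upper class. Class summaries are plain means per
(station, class), with untested cells absent rather than zero-filled.
Station comparisons report each metric at both stations plus the
absolute percent difference with the farther (first) station as
denominator, rounded to one decimal; both inputs are stored so every
difference is recomputable. The statistical machinery beyond this
(ANOVA, post-hoc tests) is deliberately out of scope — the class-summary
CSV is designed for consumption by general statistics software.

`run_experiment` consumes a YAML manifest (observations as replicate
file lists or synthetic configs, plus analysis parameters) and emits
`observations.csv`, `class_summary.csv` and `comparison.json`; outputs
are a pure function of the manifest and its seed, and each observation
is logged with its parameters.

## Problem sizes and numerical notes

The test suite and the reproduction script run synthetic scenes at the
full 512×424 raster where the pixel count itself is the claim, and at
half or quarter raster elsewhere — the metrics are resolution-covariant
quantities (means, percentages), so reduced rasters change sampling
noise, not behaviour; replicate-repeatability envelopes are stated for
the raster they were measured at, since the nearest-neighbour floor
scales with pixel spacing. Exact-equality tests against brute-force
oracles avoid distance ties at the sphere boundary by using random
coordinates. PLY stores coordinates as float32 (the format's
convention); CSV round-trips float64 exactly via `%.17g`.
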