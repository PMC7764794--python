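# canopyqa

Quality assessment of RGB-D point clouds of fruit-tree canopies.

Low-cost RGB-D cameras (time-of-flight depth plus a colour imager) are
increasingly used to characterise orchard canopies for precision
agriculture — canopy volume, porosity, fruit detection. Their depth
channel degrades under bright sunlight and their colour channel under
dusk-level light, so before trusting a survey one has to know *how much*
a given sensor degrades with ambient illuminance and stand-off distance.
`canopyqa` implements the metrics such an evaluation needs, for anyone
assessing a depth camera for field work:

- **Resolution / density** — point count `P` and mean volumetric density

  ```
  δ = (1/P) Σᵢ 3·Nᵢ / (4πR³)        [points m⁻³]
  ```

  where `Nᵢ` is the number of neighbours within a sphere of radius `R`
  around point `i`.

- **Accuracy** — repeated measurements `Dⱼ` of a known reference length
  `D` (a striped ranging rod: 500 mm stripe spacing, 25 mm diameter)
  summarised as `Ac = mean |Dⱼ − D|` and `RMSE = sqrt(mean (Dⱼ − D)²)`,
  in mm.

- **Repeatability** — for three replicate captures of a static scene,
  nearest-neighbour cloud-to-cloud distances `d(k→t)` pooled over the
  pairs 1→2, 1→3, 2→3:

  ```
  Pr = [Σ d(1→2) + Σ d(1→3) + Σ d(2→3)] / (2·P₁ + P₂)     [mm]
  ```

  with σ the standard deviation of the pooled distances about `Pr`.

- **Penetrability** — the distribution of points in 0.1 m depth sections
  into the canopy, with the mean and sd of depth relative to the canopy
  front.

- **Spectral metrics** — mean hue/saturation/value of the coloured
  points (%), mean raw NIR intensity (DN), and the range-corrected

  ```
  NIRc,ᵢ = NIRᵢ · (xᵢ² + yᵢ² + zᵢ²)        [DN·m²]
  ```

  which cancels inverse-square attenuation and tracks target
  reflectance independently of distance.

A **synthetic orchard generator** renders canopy captures with the
statistical structure of real field data — a 512×424 pinhole raster with
70°×60° FOV, illuminance-driven pixel dropout, inverse-square NIR
returns, leaf-blob occlusion — so every metric is exercisable without a
field dataset. A manifest-driven pipeline (`run_experiment`) and a thin
CLI (`canopyqa evaluate|simulate|compare|precision`) sit on top.

## Worked example

`examples/distance_comparison.py` renders one synthetic canopy from
2.5 m and from 1.5 m and compares the captures (percent difference uses
the 2.5 m value as denominator):

```
       point_cloud_density:     56809.38 vs    185154.07  ->  225.9 %
  penetrability_mean_depth:         1.05 vs         0.87  ->   17.5 %
                  mean_hue:        26.33 vs        24.54  ->    6.8 %
           mean_saturation:        53.38 vs        54.50  ->    2.1 %
           mean_brightness:        33.78 vs        37.66  ->   11.5 %
                  mean_nir:       786.27 vs      2473.11  ->  214.5 %
                 mean_nirc:      6709.25 vs      6709.25  ->    0.0 %
```

Moving closer triples the density (same rays, smaller footprint) but
*reduces* mean penetration depth (foreground foliage shadows more of the
interior). Raw NIR inflates by roughly the squared distance ratio,
while the range-corrected NIRc mean is distance-invariant — the point of
the correction. The other scripts in `examples/` walk through accuracy
against the ranging rod, replicate repeatability, and an illuminance
sweep with trend fits and illumination-class summaries.

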