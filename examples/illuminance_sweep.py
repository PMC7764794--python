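"""Point-count and density trends across an illuminance sweep.

Active depth sensors lose pixels as ambient sunlight floods the
emitter. This sweep generates one station across rising lux, fits the
linear trend of point count vs illuminance, and groups repeatability by
the five standard illumination classes (breaks at 0, 250, 1000, 4000,
16000, 64000 lx).
"""

import canopyqa as cq

lux_levels = [100, 500, 2000, 8000, 20000, 40000, 60000]
counts, observations = [], []
for k, lux in enumerate(lux_levels):
    cfg = cq.SyntheticSceneConfig(seed=100 + k, illuminance=lux,
                                  raster=(128, 106))
    reps = cq.generate_replicates(cfg)
    counts.append(reps.replicates[0].n_points)
    observations.append((reps.meta, cq.precision_metrics(reps)))
    print(f"{lux:>6} lx: {counts[-1]:>6} points "
          f"(class {cq.classify_illuminance(lux).class_id})")

slope, intercept, r2 = cq.trend_fit(lux_levels, counts)
print(f"\npoints vs lux: slope = {slope:.3f} points/lx, R^2 = {r2:.3f}")
print("The negative slope quantifies sunlight-driven pixel dropout.")

print("\nmean precision error per illumination class:")
print(cq.class_summary(observations).to_string(index=False))
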