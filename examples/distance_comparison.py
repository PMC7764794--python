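"""Comparing one canopy captured from 2.5 m and from 1.5 m.

The same synthetic scene (same seed = same canopy) is rendered from two
station distances and compared metric by metric: density, penetrability,
HSV means, and raw vs range-corrected NIR. The percent difference uses
the 2.5 m value as denominator.
"""

import canopyqa as cq

def capture(distance):
    return cq.generate_scene(cq.SyntheticSceneConfig(
        seed=7, sensor_distance=distance, raster=(256, 212), illuminance=2000
    ))

far, near = capture(2.5), capture(1.5)
report = cq.compare_stations(far, near, "2.5m", "1.5m", depth_axis="z")
for row in report.rows:
    print(f"{row['metric']:>26}: {row['value_a']:12.2f} vs "
          f"{row['value_b']:12.2f}  -> {row['pct_difference']:6.1f} %")
print()
print("Raw NIR digital numbers inflate close up (inverse-square return),")
print("while the range-corrected mean NIRc — NIR times squared range —")
print("agrees across distances: it tracks target reflectance, not range.")
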