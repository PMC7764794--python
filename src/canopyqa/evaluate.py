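"""Experiment orchestration: metric tables, illumination classes and
station comparisons.

The evaluation protocol groups observations into five illumination
classes with breaks at 0, 250, 1000, 4000, 16000 and 64000 lx and
summarises repeatability per (station, class).  Station pairs at
different stand-off distances are compared metric by metric with an
absolute percent difference whose denominator is the *farther* (first)
station's value.

:func:`run_experiment` drives everything from a plain YAML manifest and
writes CSV/JSON reports that are a pure function of the manifest plus
its seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cloud import (
    ObservationMeta,
    PointCloud,
    ReplicateSet,
    ValidationError,
)
from . import geometry, spectral
from .io import read_point_cloud
from .synthetic import SyntheticSceneConfig, generate_replicates

logger = logging.getLogger("canopyqa")

#: Illumination class breaks in lux; five half-open classes [lo, hi).
ILLUMINATION_BREAKS: Tuple[float, ...] = (0, 250, 1000, 4000, 16000, 64000)


@dataclass(frozen=True)
class IlluminationClass:
    """One of the five standard illumination levels."""

    class_id: int
    lux_range: Tuple[float, float]  # half-open [lo, hi)


ILLUMINATION_CLASSES: Tuple[IlluminationClass, ...] = tuple(
    IlluminationClass(i + 1, (ILLUMINATION_BREAKS[i], ILLUMINATION_BREAKS[i + 1]))
    for i in range(len(ILLUMINATION_BREAKS) - 1)
)


def classify_illuminance(lux: float) -> IlluminationClass:
    """Map an illuminance to its class; classes are half-open [lo, hi)."""
    if not 0 <= lux < ILLUMINATION_BREAKS[-1]:
        raise ValidationError(
            f"illuminance {lux} lx outside [0, {ILLUMINATION_BREAKS[-1]}) lx"
        )
    for cls in ILLUMINATION_CLASSES:
        if cls.lux_range[0] <= lux < cls.lux_range[1]:
            return cls
    raise AssertionError("classes partition the range")  # unreachable


def percent_difference(value_a: float, value_b: float) -> float:
    """Absolute percent difference of ``value_b`` relative to ``value_a``.

    ``value_a`` is the reference (by convention the value measured from
    the farther station); the result is ``100 * |b - a| / a`` rounded to
    one decimal for reporting.
    """
    if value_a == 0:
        raise ValidationError("reference value must be non-zero")
    return round(100.0 * abs(value_b - value_a) / abs(value_a), 1)


@dataclass
class ComparisonReport:
    """Metric-by-metric comparison of two stations.

    Each row stores both station values and their percent difference
    (denominator: station A), so every difference is recomputable from
    the stored values.  The density radius used is recorded because
    density values are only comparable at equal R.
    """

    station_a: str
    station_b: str
    rows: List[Dict[str, float]]
    density_radius: float
    denominator: str = "station_a"

    def to_dict(self) -> dict:
        return asdict(self)


def compare_stations(
    cloud_a: PointCloud,
    cloud_b: PointCloud,
    station_a: str = "A",
    station_b: str = "B",
    density_radius: float = geometry.DEFAULT_DENSITY_RADIUS,
    depth_axis: Union[str, int] = "z",
    n_bins: int = 50,
    shared_depth_origin: bool = False,
) -> ComparisonReport:
    """Compare two captures of one scene taken from different distances.

    Computes density, penetrability mean depth, HSV means, and mean
    NIR / NIRc for each cloud, with percent differences relative to
    station A.  Channels missing from either cloud are skipped.

    Penetrability uses each cloud's own canopy front as depth origin by
    default, which is right for clouds still in their sensor frames;
    set ``shared_depth_origin`` for clouds registered into one frame, to
    measure both from the union's front.
    """
    rows: List[Dict[str, float]] = []

    def add(metric: str, va: float, vb: float) -> None:
        rows.append(
            {
                "metric": metric,
                "value_a": va,
                "value_b": vb,
                "pct_difference": percent_difference(va, vb),
            }
        )

    da = geometry.point_density(cloud_a, density_radius).mean_density
    db = geometry.point_density(cloud_b, density_radius).mean_density
    add("point_cloud_density", da, db)

    origin = None
    if shared_depth_origin:
        axis = (
            geometry._AXES[depth_axis]
            if isinstance(depth_axis, str)
            else depth_axis
        )
        origin = float(
            min(cloud_a.coords[:, axis].min(), cloud_b.coords[:, axis].min())
        )
    pa = geometry.penetrability_profile(cloud_a, depth_axis, origin=origin)
    pb = geometry.penetrability_profile(cloud_b, depth_axis, origin=origin)
    add("penetrability_mean_depth", pa.mean_depth, pb.mean_depth)

    both_rgb = cloud_a.rgb is not None and cloud_b.rgb is not None
    if both_rgb:
        ha, sa, va = spectral.hsv_summary(cloud_a)
        hb, sb, vb = spectral.hsv_summary(cloud_b)
        add("mean_hue", ha, hb)
        add("mean_saturation", sa, sb)
        add("mean_brightness", va, vb)

    if cloud_a.nir is not None and cloud_b.nir is not None:
        sa_ = spectral.nir_summary(cloud_a, n_bins=n_bins)
        sb_ = spectral.nir_summary(cloud_b, n_bins=n_bins)
        add("mean_nir", sa_.mean_nir, sb_.mean_nir)
        add("mean_nirc", sa_.mean_nirc, sb_.mean_nirc)

    return ComparisonReport(
        station_a=station_a,
        station_b=station_b,
        rows=rows,
        density_radius=density_radius,
    )


def class_summary(
    observations: Sequence[Tuple[ObservationMeta, "geometry.PrecisionResult"]]
) -> pd.DataFrame:
    """Mean precision error and standard deviation per (station, class).

    Returns a tidy frame with columns ``station``, ``class_id``,
    ``lux_range``, ``n``, ``mean_pr_mm``, ``mean_sigma_mm``.  A station
    never observed in a class simply has no row (absent, not zero).
    """
    records = []
    for meta, prec in observations:
        cls = classify_illuminance(meta.illuminance)
        records.append(
            {
                "station": meta.station_id,
                "class_id": cls.class_id,
                "lux_range": f"{cls.lux_range[0]:g} to {cls.lux_range[1]:g}",
                "pr_mm": prec.precision_error,
                "sigma_mm": prec.std_dev,
            }
        )
    df = pd.DataFrame.from_records(records)
    grouped = (
        df.groupby(["station", "class_id", "lux_range"], as_index=False)
        .agg(n=("pr_mm", "size"), mean_pr_mm=("pr_mm", "mean"),
             mean_sigma_mm=("sigma_mm", "mean"))
        .sort_values(["station", "class_id"], ignore_index=True)
    )
    return grouped


# ------------------------------------------------------------ manifest

def run_experiment(
    manifest: Union[str, Path, dict], out_dir: Union[str, Path]
) -> Dict[str, Path]:
    """Run a full evaluation from a manifest and write report files.

    The manifest (YAML mapping or path to one) lists observations —
    each either a set of replicate cloud files or a synthetic scene
    config — plus global analysis parameters::

        seed: 1
        density_radius: 0.05
        depth_axis: z
        histogram_bins: 50
        observations:
          - station: K2S1
            distance: 2.5        # m from row axis
            illuminance: 12000   # lx
            replicates: 3
            # either file paths ...
            clouds: [r1.ply, r2.ply, r3.ply]
            # ... or synthetic-scene overrides (any SyntheticSceneConfig field)
            scene: {n_blobs: 120}
        comparison: {station_a: K2S1, station_b: K2S2}

    Writes ``observations.csv`` (one row per observation with P, density,
    Pr, sigma and spectral means), ``class_summary.csv`` and, when a
    comparison is requested, ``comparison.json``.  Outputs are a pure
    function of the manifest content and its seed.
    """
    if isinstance(manifest, (str, Path)):
        with open(manifest, "r", encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "observations" not in manifest:
        raise ValidationError("manifest must be a mapping with 'observations'")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(manifest.get("seed", 0))
    radius = float(manifest.get("density_radius", geometry.DEFAULT_DENSITY_RADIUS))
    depth_axis = manifest.get("depth_axis", "z")
    n_bins = int(manifest.get("histogram_bins", 50))

    rows = []
    precision_obs = []
    first_replicates: Dict[str, PointCloud] = {}
    for k, obs in enumerate(manifest["observations"]):
        station = str(obs.get("station", f"station{k}"))
        meta = ObservationMeta(
            station_id=station,
            illuminance=float(obs.get("illuminance", 0.0)),
            distance_to_row_axis=float(obs.get("distance", 2.5)),
            timestamp=str(obs.get("timestamp", "")),
        )
        reps = _load_observation(obs, meta, seed + k)
        logger.info(
            "observation %s: station=%s lux=%g distance=%g replicates=%d "
            "radius=%g axis=%s",
            k, station, meta.illuminance, meta.distance_to_row_axis,
            len(reps), radius, depth_axis,
        )
        lead = reps.replicates[0]
        dens = geometry.point_density(lead, radius)
        row = {
            "station": station,
            "illuminance_lx": meta.illuminance,
            "distance_m": meta.distance_to_row_axis,
            "n_points": lead.n_points,
            "density_pts_m3": dens.mean_density,
            "density_radius_m": radius,
        }
        if len(reps) == 3:
            prec = geometry.precision_metrics(reps)
            row["pr_mm"] = prec.precision_error
            row["sigma_mm"] = prec.std_dev
            precision_obs.append((meta, prec))
        summ = spectral.spectral_summary(lead, n_bins=n_bins)
        for name in ("mean_h", "mean_s", "mean_v", "mean_nir", "mean_nirc"):
            value = getattr(summ, name)
            if value is not None:
                row[name] = value
        rows.append(row)
        first_replicates.setdefault(station, lead)

    outputs: Dict[str, Path] = {}
    obs_path = out_dir / "observations.csv"
    pd.DataFrame(rows).to_csv(obs_path, index=False)
    outputs["observations"] = obs_path

    if precision_obs:
        cls_path = out_dir / "class_summary.csv"
        class_summary(precision_obs).to_csv(cls_path, index=False)
        outputs["class_summary"] = cls_path

    cmp_spec = manifest.get("comparison")
    if cmp_spec:
        a, b = str(cmp_spec["station_a"]), str(cmp_spec["station_b"])
        for name in (a, b):
            if name not in first_replicates:
                raise ValidationError(f"comparison station {name!r} not observed")
        report = compare_stations(
            first_replicates[a],
            first_replicates[b],
            station_a=a,
            station_b=b,
            density_radius=radius,
            depth_axis=depth_axis,
            n_bins=n_bins,
        )
        cmp_path = out_dir / "comparison.json"
        with open(cmp_path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["comparison"] = cmp_path
    return outputs


def _load_observation(
    obs: dict, meta: ObservationMeta, seed: int
) -> ReplicateSet:
    n_reps = int(obs.get("replicates", 3))
    if "clouds" in obs:
        clouds = []
        for path in obs["clouds"]:
            try:
                clouds.append(read_point_cloud(path))
            except FileNotFoundError:
                raise ValidationError(
                    f"observation {meta.station_id!r}: cloud file {path!r} missing"
                ) from None
        if len(clouds) != n_reps:
            raise ValidationError(
                f"observation {meta.station_id!r}: expected {n_reps} replicates, "
                f"got {len(clouds)} cloud files"
            )
        return ReplicateSet(replicates=clouds, meta=meta)
    overrides = dict(obs.get("scene", {}))
    overrides.setdefault("sensor_distance", meta.distance_to_row_axis)
    overrides.setdefault("illuminance", meta.illuminance)
    overrides.setdefault("seed", seed)
    config = SyntheticSceneConfig(**overrides)
    return generate_replicates(config, n=n_reps)
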