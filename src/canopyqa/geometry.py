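"""Geometric quality metrics for depth-camera point clouds.

Four evaluation parameters, each a standard quantity in sensor
assessments of tree-row scans:

* **Resolution / density** — the number of points and the mean
  volumetric density, estimated by counting, for every point, the
  neighbours inside a sphere of radius ``R`` and averaging
  ``3*Ni / (4*pi*R^3)`` over the cloud.
* **Accuracy** — mean absolute error and RMSE of repeated measurements
  of a reference length (a striped ranging rod) against its true value.
* **Repeatability (precision)** — nearest-neighbour cloud-to-cloud
  distances between replicate captures of a static scene, summarised as
  a precision error Pr and its standard deviation.
* **Penetrability** — the depth distribution of points into the canopy
  along the row-perpendicular axis, binned in fixed sections.

Nearest-neighbour queries use a k-d tree; correctness is defined by
exhaustive search and the test suite verifies the equivalence.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .cloud import (
    AccuracyResult,
    DensityResult,
    PenetrabilityProfile,
    PointCloud,
    PrecisionResult,
    ReplicateSet,
    ValidationError,
)

_AXES = {"x": 0, "y": 1, "z": 2}

#: Default neighbourhood radius for density estimation, metres.
DEFAULT_DENSITY_RADIUS = 0.05


def neighbor_counts(cloud: PointCloud, radius: float) -> np.ndarray:
    """Number of neighbouring points within ``radius`` of each point.

    The sphere boundary is inclusive (distance <= radius) and the query
    point itself is not counted as its own neighbour.
    """
    if radius <= 0:
        raise ValidationError("radius must be positive")
    if cloud.n_points == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(cloud.coords)
    counts = tree.query_ball_point(
        cloud.coords, r=radius, return_length=True
    )
    return np.asarray(counts, dtype=np.int64) - 1  # remove self-count


def point_density(
    cloud: PointCloud, radius: float = DEFAULT_DENSITY_RADIUS
) -> DensityResult:
    """Mean volumetric point density (points per cubic metre).

    Each point contributes ``3*Ni / (4*pi*R^3)`` where ``Ni`` is its
    neighbour count inside radius ``R``; the cloud density is the mean
    contribution.  No edge correction is applied: points near the cloud
    boundary legitimately report fewer neighbours.
    """
    if cloud.n_points == 0:
        raise ValidationError("cannot compute density of an empty cloud")
    counts = neighbor_counts(cloud, radius)
    densities = 3.0 * counts / (4.0 * np.pi * radius**3)
    return DensityResult(
        radius=radius,
        neighbor_counts=counts,
        mean_density=float(densities.mean()),
    )


def accuracy_metrics(
    measurements: Sequence[float], reference: float
) -> AccuracyResult:
    """Accuracy (mean |error|) and RMSE of distance measurements, mm.

    ``measurements`` are repeated estimates of the same physical length
    ``reference`` (both in millimetres, as ranging-rod lengths are
    specified).
    """
    m = np.asarray(measurements, dtype=float)
    if m.size == 0:
        raise ValidationError("at least one measurement is required")
    if reference <= 0:
        raise ValidationError("reference length must be positive")
    err = m - reference
    return AccuracyResult(
        reference=float(reference),
        measurements=m,
        accuracy=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
    )


def cloud_to_cloud_distances(
    source: PointCloud, target: PointCloud
) -> np.ndarray:
    """Distance from every source point to its nearest target point (m)."""
    if source.n_points == 0 or target.n_points == 0:
        raise ValidationError("both clouds must be non-empty")
    tree = cKDTree(target.coords)
    d, _ = tree.query(source.coords, k=1)
    return np.asarray(d, dtype=float)


def precision_metrics(replicates: Union[ReplicateSet, Sequence[PointCloud]]) -> PrecisionResult:
    """Repeatability of three replicate captures of a static scene.

    Nearest-neighbour distances are gathered for the ordered replicate
    pairs 1→2, 1→3 and 2→3 and pooled with the normalisation
    ``2*P1 + P2`` (P1, P2 = point counts of replicates 1 and 2 — the
    total number of pooled distances, since pairs 1→2 and 1→3 both use
    replicate 1 as the source).  The precision error Pr is the pooled
    mean; sigma is the population-style standard deviation about Pr
    under the same normalisation.  Both are returned in millimetres.

    Replicate order is significant.  For a symmetric statistic over any
    number of replicates, see :func:`precision_metrics_symmetric`.
    """
    reps = list(replicates.replicates if isinstance(replicates, ReplicateSet) else replicates)
    if len(reps) != 3:
        raise ValidationError(
            "precision_metrics requires exactly 3 replicates "
            "(use precision_metrics_symmetric for other counts)"
        )
    for k, rep in enumerate(reps):
        if rep.n_points == 0:
            raise ValidationError(f"replicate {k + 1} is empty")
    d12 = cloud_to_cloud_distances(reps[0], reps[1])
    d13 = cloud_to_cloud_distances(reps[0], reps[2])
    d23 = cloud_to_cloud_distances(reps[1], reps[2])
    denom = 2 * reps[0].n_points + reps[1].n_points
    pr = (d12.sum() + d13.sum() + d23.sum()) / denom
    sq = ((d12 - pr) ** 2).sum() + ((d13 - pr) ** 2).sum() + ((d23 - pr) ** 2).sum()
    sigma = np.sqrt(sq / denom)
    return PrecisionResult(
        precision_error=float(pr * 1000.0),
        std_dev=float(sigma * 1000.0),
        pair_distances=(d12, d13, d23),
    )


def precision_metrics_symmetric(
    replicates: Union[ReplicateSet, Sequence[PointCloud]]
) -> PrecisionResult:
    """Symmetric repeatability variant for two or more replicates.

    Pools nearest-neighbour distances over *all* ordered replicate pairs
    and normalises by the pooled count, so the result is invariant to
    replicate ordering.  This is not the three-replicate statistic used
    in the standard evaluation protocol; it is provided for designs with
    a different replicate count.
    """
    reps = list(replicates.replicates if isinstance(replicates, ReplicateSet) else replicates)
    if len(reps) < 2:
        raise ValidationError("at least 2 replicates are required")
    pools = []
    for k in range(len(reps)):
        for t in range(len(reps)):
            if k != t:
                pools.append(cloud_to_cloud_distances(reps[k], reps[t]))
    pooled = np.concatenate(pools)
    pr = pooled.mean()
    sigma = pooled.std()
    return PrecisionResult(
        precision_error=float(pr * 1000.0),
        std_dev=float(sigma * 1000.0),
        pair_distances=tuple(pools),
    )


def penetrability_profile(
    cloud: PointCloud,
    depth_axis: Union[str, int] = "y",
    bin_width: float = 0.1,
    origin: Optional[float] = None,
) -> PenetrabilityProfile:
    """Point distribution in depth along the canopy depth axis.

    Depth values are taken relative to the canopy front: ``origin`` if
    given, else the cloud's minimum depth coordinate.  Bins are
    half-open ``[a, a + w)`` sections of width ``bin_width`` starting at
    the front; the profile reports the percentage of points per section
    plus the mean and standard deviation of the relative depths.  Pass a
    shared ``origin`` when comparing two clouds on one axis.
    """
    if cloud.n_points == 0:
        raise ValidationError("cannot profile an empty cloud")
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    axis = _AXES[depth_axis] if isinstance(depth_axis, str) else int(depth_axis)
    depth = cloud.coords[:, axis]
    front = float(depth.min()) if origin is None else float(origin)
    rel = depth - front
    if rel.min() < 0:
        raise ValidationError("origin must not exceed the minimum depth")
    idx = np.floor(rel / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = front + bin_width * np.arange(n_bins + 1)
    return PenetrabilityProfile(
        bin_edges=edges,
        percentages=100.0 * counts / cloud.n_points,
        mean_depth=float(rel.mean()),
        std_depth=float(rel.std()),
    )


def trend_fit(
    x: Sequence[float], y: Sequence[float]
) -> Tuple[float, float, float]:
    """Ordinary least-squares line y = s*x + b with R².

    Used for metric-vs-illuminance trends (e.g. point count against
    lux).  A constant response is reported as slope 0 with R² = 0 (no
    variance explained).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValidationError("x values must not all be equal")
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0, float(y.mean()), 0.0
    ss_res = ((y - (slope * x + intercept)) ** 2).sum()
    return float(slope), float(intercept), float(1.0 - ss_res / ss_tot)
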