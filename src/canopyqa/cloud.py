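"""Domain types for RGB-D canopy point clouds.

The unit of analysis throughout the package is a :class:`PointCloud`:
per-point Cartesian coordinates in metres in the sensor-origin frame,
with optional 8-bit RGB colour and optional NIR intensity in raw digital
numbers (DN).  The colour and depth imagers of the modelled sensor have
different fields of view, so some geometric points legitimately carry no
colour; a boolean ``has_rgb`` mask records which points do.

Distances handed to the user-facing accuracy/precision metrics are in
millimetres, matching how depth-camera evaluations are normally tabled;
coordinates stay in metres internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Pixel count of the modelled depth raster (512 x 424).
MAX_RASTER_POINTS = 512 * 424


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class PointCloud:
    """A 3D point cloud with optional colour and NIR channels.

    Parameters
    ----------
    coords
        ``(n, 3)`` float array, metres, sensor-origin frame.
    rgb
        Optional ``(n, 3)`` uint8 array of 8-bit colour values.
    nir
        Optional ``(n,)`` array of non-negative NIR intensities (DN,
        16-bit range).
    has_rgb
        Optional ``(n,)`` boolean mask; ``False`` marks points that fall
        outside the colour camera's field of view.  Defaults to all
        ``True`` when ``rgb`` is present.
    """

    coords: np.ndarray
    rgb: Optional[np.ndarray] = None
    nir: Optional[np.ndarray] = None
    has_rgb: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"coords must have shape (n, 3), got {self.coords.shape}"
            )
        bad = ~np.isfinite(self.coords)
        if bad.any():
            idx = int(np.flatnonzero(bad.any(axis=1))[0])
            raise ValidationError(f"non-finite coordinate at point index {idx}")
        n = self.n_points
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.shape != (n, 3):
                raise ValidationError(
                    f"rgb must have shape ({n}, 3), got {self.rgb.shape}"
                )
            if self.rgb.min(initial=0) < 0 or self.rgb.max(initial=0) > 255:
                raise ValidationError("rgb values must lie in [0, 255]")
            self.rgb = self.rgb.astype(np.uint8)
            if self.has_rgb is None:
                self.has_rgb = np.ones(n, dtype=bool)
        if self.has_rgb is not None:
            self.has_rgb = np.asarray(self.has_rgb, dtype=bool)
            if self.has_rgb.shape != (n,):
                raise ValidationError(f"has_rgb must have shape ({n},)")
            if self.rgb is None and self.has_rgb.any():
                raise ValidationError("has_rgb set without an rgb channel")
        if self.nir is not None:
            self.nir = np.asarray(self.nir)
            if self.nir.shape != (n,):
                raise ValidationError(
                    f"nir must have shape ({n},), got {self.nir.shape}"
                )
            if self.nir.min(initial=0) < 0 or self.nir.max(initial=0) > 65535:
                raise ValidationError("nir values must lie in [0, 65535]")
            self.nir = self.nir.astype(np.uint16)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return a new cloud with the points where ``mask`` is true,
        all channels carried along."""
        return PointCloud(
            coords=self.coords[mask],
            rgb=self.rgb[mask] if self.rgb is not None else None,
            nir=self.nir[mask] if self.nir is not None else None,
            has_rgb=self.has_rgb[mask] if self.has_rgb is not None else None,
        )


@dataclass
class ObservationMeta:
    """Metadata for one observation (a station at one moment)."""

    station_id: str
    illuminance: float  # lx
    distance_to_row_axis: float  # m
    timestamp: str = ""
    wind_speed: float = 0.0  # m/s, informational

    def __post_init__(self) -> None:
        if self.illuminance < 0:
            raise ValidationError("illuminance must be non-negative")
        if self.distance_to_row_axis <= 0:
            raise ValidationError("distance_to_row_axis must be positive")
        if self.wind_speed < 0:
            raise ValidationError("wind_speed must be non-negative")


@dataclass
class ReplicateSet:
    """Ordered replicate captures of one static scene.

    Order matters: the repeatability statistic pairs replicates by
    position (1 vs 2, 1 vs 3, 2 vs 3).
    """

    replicates: Sequence[PointCloud]
    meta: Optional[ObservationMeta] = None

    def __post_init__(self) -> None:
        self.replicates = list(self.replicates)
        if len(self.replicates) < 2:
            raise ValidationError("a ReplicateSet needs at least 2 replicates")

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class DensityResult:
    """Neighbour counts and mean volumetric density at radius R."""

    radius: float  # m
    neighbor_counts: np.ndarray  # per point
    mean_density: float  # points / m^3


@dataclass
class AccuracyResult:
    """Mean absolute error (accuracy) and RMSE of repeated distance
    measurements against a known reference length, in mm."""

    reference: float  # mm
    measurements: np.ndarray  # mm
    accuracy: float  # mm
    rmse: float  # mm


@dataclass
class PrecisionResult:
    """Repeatability of replicate captures: mean (Pr) and spread (sigma)
    of cloud-to-cloud nearest-neighbour distances, in mm."""

    precision_error: float  # mm
    std_dev: float  # mm
    pair_distances: tuple  # the d(1->2), d(1->3), d(2->3) collections, m


@dataclass
class PenetrabilityProfile:
    """Depth-bin occupancy along the canopy depth axis."""

    bin_edges: np.ndarray  # m, uniform width
    percentages: np.ndarray  # % per bin, sums to 100
    mean_depth: float  # m, relative to canopy front
    std_depth: float  # m


@dataclass
class SpectralSummary:
    """Per-cloud colour and NIR summary statistics.

    HSV means are percentages in [0, 100]; NIR is in raw DN and NIRc in
    DN·m² (NIR scaled by squared sensor range).  Histograms are
    normalised to sum to 1.
    """

    mean_h: Optional[float] = None
    mean_s: Optional[float] = None
    mean_v: Optional[float] = None
    mean_nir: Optional[float] = None
    mean_nirc: Optional[float] = None
    nir_histogram: Optional[np.ndarray] = None
    nirc_histogram: Optional[np.ndarray] = None
    nir_bin_edges: Optional[np.ndarray] = None
    nirc_bin_edges: Optional[np.ndarray] = None


def crop_box(cloud: PointCloud, bounds: Sequence[Sequence[float]]) -> PointCloud:
    """Crop a cloud to a closed axis-aligned box.

    ``bounds`` is ``((xmin, xmax), (ymin, ymax), (zmin, zmax))``; points
    with ``min <= c <= max`` on every axis are kept, all channels
    preserved, input untouched.
    """
    b = np.asarray(bounds, dtype=float)
    if b.shape != (3, 2):
        raise ValidationError("bounds must be three (min, max) pairs")
    if (b[:, 0] > b[:, 1]).any():
        raise ValidationError("each axis must satisfy min <= max")
    mask = np.all((cloud.coords >= b[:, 0]) & (cloud.coords <= b[:, 1]), axis=1)
    return cloud.select(mask)


def point_pair_distance(cloud: PointCloud, i: int, j: int) -> float:
    """Euclidean distance between two picked points, in millimetres.

    This is the programmatic counterpart of measuring a reference target
    (e.g. a striped ranging rod) by picking two points in a viewer.
    """
    n = cloud.n_points
    for idx in (i, j):
        if not (-n <= idx < n):
            raise ValidationError(f"point index {idx} out of range for {n} points")
    return float(np.linalg.norm(cloud.coords[i] - cloud.coords[j]) * 1000.0)
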