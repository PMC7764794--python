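"""Synthetic orchard scenes for exercising the quality metrics.

The generator emulates the statistical structure of RGB-D captures of a
fruit-tree row taken from a static station in an alleyway:

* a perspective depth sensor with a 512 x 424 raster and a 70 x 60
  degree field of view, casting one ray per pixel through a pinhole;
* a leafy canopy wall centred on the row axis — a front plane plus
  randomly placed leaf/fruit blobs at varying depths, so rays stop at
  different penetrations and the depth profile is non-trivial;
* illuminance-dependent point dropout: ambient sunlight floods the
  active emitter, so pixels fail to range with a probability that rises
  with lux (negligible below ~2000 lx);
* inverse-square NIR return: each surface element has an albedo in
  DN·m² and the sensor records ``albedo / range²`` digital numbers, so
  range correction recovers the albedo;
* foliage-palette RGB with a phenomenological low-light exposure
  roll-off, and a colour field of view slightly smaller vertically than
  the depth raster (border points carry no RGB);
* millimetre-scale coordinate jitter between replicate captures of the
  same static scene.

All randomness flows from ``numpy.random.default_rng`` seeded from the
scene config, so a fixed seed reproduces clouds bit-identically.  The
canopy (blob layout) is drawn from ``seed`` alone; capture noise
(dropout, NIR speckle, jitter) is drawn from a per-capture seed, so the
same scene can be re-captured — from another distance or as a replicate
— against an unchanged canopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .cloud import PointCloud, ObservationMeta, ReplicateSet, ValidationError

#: lux -> per-pixel ranging-failure probability, piecewise linear.
#: Dropout is negligible up to ~2000 lx and grows towards full sun.
DEFAULT_DROPOUT_KNOTS: Tuple[Tuple[float, float], ...] = (
    (0.0, 0.01),
    (2000.0, 0.03),
    (16000.0, 0.40),
    (64000.0, 0.90),
)

#: Foliage / branch / inner-canopy RGB palette (8-bit).
DEFAULT_PALETTE: Tuple[Tuple[int, int, int], ...] = (
    (76, 132, 56),   # sunlit leaf
    (52, 98, 40),    # shaded leaf
    (96, 72, 48),    # branch / trunk
    (34, 60, 30),    # canopy interior
)


@dataclass
class SyntheticSceneConfig:
    """Parameters of one synthetic capture station.

    Distances in metres, illuminance in lux, albedo in DN·m².  The
    canopy wall is centred on the row axis: its front face sits at
    ``sensor_distance - canopy_depth / 2`` from the sensor.
    """

    sensor_distance: float = 2.5
    illuminance: float = 1000.0
    fov: Tuple[float, float] = (70.0, 60.0)
    raster: Tuple[int, int] = (512, 424)
    canopy_depth: float = 1.5      # occupied shell thickness along the view axis
    canopy_extent: Tuple[float, float] = (6.0, 4.0)  # wall width x height
    n_blobs: int = 150
    blob_radius: Tuple[float, float] = (0.05, 0.30)
    depth_jitter: float = 0.01     # sd of per-pixel surface roughness, m
    dropout_knots: Tuple[Tuple[float, float], ...] = DEFAULT_DROPOUT_KNOTS
    nir_albedo: float = 6500.0     # mean foliage albedo, DN·m²
    albedo_noise_sd: float = 0.25  # lognormal sigma of per-pixel albedo
    rgb_palette: Tuple[Tuple[int, int, int], ...] = DEFAULT_PALETTE
    rgb_fov_fraction: float = 0.92  # vertical fraction of raster with colour
    replicate_jitter: float = 0.005  # sd of between-replicate coordinate noise, m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_distance <= 0:
            raise ValidationError("sensor_distance must be positive")
        if self.illuminance < 0:
            raise ValidationError("illuminance must be non-negative")
        if not (0 < self.fov[0] < 180 and 0 < self.fov[1] < 180):
            raise ValidationError("fov angles must lie in (0, 180) degrees")
        if self.raster[0] < 1 or self.raster[1] < 1:
            raise ValidationError("raster dimensions must be positive")
        if self.canopy_depth <= 0:
            raise ValidationError("canopy_depth must be positive")
        for _, p in self.dropout_knots:
            if not 0.0 <= p <= 1.0:
                raise ValidationError("dropout probabilities must lie in [0, 1]")
        if not 0.0 <= self.rgb_fov_fraction <= 1.0:
            raise ValidationError("rgb_fov_fraction must lie in [0, 1]")


def dropout_probability(config: SyntheticSceneConfig, illuminance: float) -> float:
    """Per-pixel ranging-failure probability at a given illuminance."""
    knots = np.asarray(config.dropout_knots, dtype=float)
    return float(np.interp(illuminance, knots[:, 0], knots[:, 1]))


def generate_scene(
    config: SyntheticSceneConfig, capture_seed: Optional[int] = None
) -> PointCloud:
    """Render one capture of the configured scene as a point cloud.

    One ray per raster pixel is cast through the pinhole; the first
    intersection with the canopy depth field gives the point, retained
    with probability ``1 - dropout(illuminance)``.  The sensor frame has
    z along the optical axis (range), x right, y up; the optical axis is
    perpendicular to the row, so z doubles as the canopy depth axis.

    ``capture_seed`` controls capture noise only (dropout, NIR speckle,
    exposure jitter); the canopy itself always comes from
    ``config.seed``, so two captures of one scene share their geometry.
    """
    cols, rows = config.raster
    canopy_rng = np.random.default_rng(config.seed)
    cap_seed = config.seed if capture_seed is None else capture_seed
    capture_rng = np.random.default_rng(cap_seed)

    blobs = _draw_canopy_blobs(config, canopy_rng)

    # Pinhole ray grid in tangent space (z = 1 plane).
    half_u = np.tan(np.deg2rad(config.fov[0]) / 2.0)
    half_v = np.tan(np.deg2rad(config.fov[1]) / 2.0)
    u = half_u * np.linspace(-1.0, 1.0, cols)
    v = half_v * np.linspace(-1.0, 1.0, rows)
    uu, vv = np.meshgrid(u, v)           # (rows, cols)
    uu, vv = uu.ravel(), vv.ravel()
    row_index = np.repeat(np.arange(rows), cols)

    # Lateral position where each ray crosses the canopy front plane.
    z_front = config.sensor_distance - config.canopy_depth / 2.0
    if z_front <= 0:
        raise ValidationError("sensor sits inside the canopy shell")
    lx = uu * z_front
    ly = vv * z_front

    half_w = config.canopy_extent[0] / 2.0
    half_h = config.canopy_extent[1] / 2.0
    hits = (np.abs(lx) <= half_w) & (np.abs(ly) <= half_h)

    # Depth-field evaluation: front-most blob covering the ray, else the
    # far side of the shell (the ray slips through to the back).
    penetration = np.full(uu.shape, config.canopy_depth)
    surface = np.full(uu.shape, -1, dtype=np.int64)  # blob id, -1 = interior
    for b, (bx, by, bdepth, brad) in enumerate(blobs):
        covered = (lx - bx) ** 2 + (ly - by) ** 2 <= brad**2
        nearer = covered & (bdepth < penetration)
        penetration[nearer] = bdepth
        surface[nearer] = b

    penetration = penetration + capture_rng.normal(
        0.0, config.depth_jitter, uu.shape
    )
    penetration = np.clip(penetration, 0.0, None)

    # Illuminance-driven dropout: one uniform draw per pixel compared to
    # the failure probability, so a fixed capture seed gives point sets
    # that shrink monotonically as illuminance rises.
    p_drop = dropout_probability(config, config.illuminance)
    retained = capture_rng.uniform(size=uu.shape) >= p_drop
    keep = hits & retained

    z = z_front + penetration[keep]
    coords = np.column_stack((uu[keep] * z, vv[keep] * z, z))

    rgb, has_rgb = _render_rgb(
        config, surface[keep], row_index[keep], rows, capture_rng
    )
    nir = _render_nir(config, coords, capture_rng)
    return PointCloud(coords=coords, rgb=rgb, nir=nir, has_rgb=has_rgb)


def generate_replicates(
    config: SyntheticSceneConfig, n: int = 3
) -> ReplicateSet:
    """Replicate captures of one static scene.

    Each replicate re-draws dropout and sensor noise independently
    (capture seeds ``config.seed + 1 … config.seed + n``) and adds
    zero-mean Gaussian coordinate jitter of sd ``replicate_jitter``,
    emulating ranging noise between otherwise identical captures.
    """
    if n < 2:
        raise ValidationError("at least 2 replicates are required")
    reps = []
    for k in range(1, n + 1):
        cloud = generate_scene(config, capture_seed=config.seed + k)
        if config.replicate_jitter > 0:
            jrng = np.random.default_rng(config.seed + k)
            coords = cloud.coords + jrng.normal(
                0.0, config.replicate_jitter, cloud.coords.shape
            )
            cloud = PointCloud(
                coords=coords, rgb=cloud.rgb, nir=cloud.nir, has_rgb=cloud.has_rgb
            )
        reps.append(cloud)
    meta = ObservationMeta(
        station_id="synthetic",
        illuminance=config.illuminance,
        distance_to_row_axis=config.sensor_distance,
    )
    return ReplicateSet(replicates=reps, meta=meta)


def generate_ranging_rod(
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    length: float = 1.0,
    diameter: float = 0.025,
    stripe: float = 0.5,
    axial_spacing: float = 0.005,
    points_per_ring: int = 32,
) -> PointCloud:
    """Dense point cloud of a striped reference rod (vertical cylinder).

    The rod models the physical accuracy target: stripe boundaries a
    known axial distance apart (default 0.5 m) on a cylinder of known
    diameter (default 25 mm).  Points are laid out ring by ring along
    the axis — ring ``r`` occupies indices ``[r * points_per_ring,
    (r+1) * points_per_ring)`` and sits at height ``r * axial_spacing``
    — so stripe-boundary or diametrically opposite points can be picked
    by index for :func:`~canopyqa.cloud.point_pair_distance`.
    Stripes alternate red/white every ``stripe`` metres.
    """
    if length <= 0 or diameter <= 0 or stripe <= 0 or axial_spacing <= 0:
        raise ValidationError("rod dimensions must be positive")
    if points_per_ring < 2 or points_per_ring % 2:
        raise ValidationError("points_per_ring must be even and >= 2")
    origin = np.asarray(origin, dtype=float)
    n_rings = int(round(length / axial_spacing)) + 1
    heights = axial_spacing * np.arange(n_rings)
    angles = 2.0 * np.pi * np.arange(points_per_ring) / points_per_ring
    r = diameter / 2.0
    ring_x = r * np.cos(angles)
    ring_z = r * np.sin(angles)
    coords = np.column_stack(
        (
            np.tile(ring_x, n_rings),
            np.repeat(heights, points_per_ring),
            np.tile(ring_z, n_rings),
        )
    ) + origin
    stripe_id = np.repeat((heights / stripe).astype(np.int64), points_per_ring)
    rgb = np.where(
        (stripe_id % 2 == 0)[:, None],
        np.array([[200, 30, 30]], dtype=np.uint8),
        np.array([[235, 235, 235]], dtype=np.uint8),
    ).astype(np.uint8)
    return PointCloud(coords=coords, rgb=rgb)


# -------------------------------------------------------------- helpers

def _draw_canopy_blobs(
    config: SyntheticSceneConfig, rng: np.random.Generator
) -> np.ndarray:
    """Leaf/fruit blobs: lateral centre, surface depth and radius, drawn
    in the row frame so the canopy is shared across capture distances."""
    half_w = config.canopy_extent[0] / 2.0
    half_h = config.canopy_extent[1] / 2.0
    bx = rng.uniform(-half_w, half_w, config.n_blobs)
    by = rng.uniform(-half_h, half_h, config.n_blobs)
    bdepth = rng.uniform(0.0, config.canopy_depth, config.n_blobs)
    brad = rng.uniform(*config.blob_radius, config.n_blobs)
    return np.column_stack((bx, by, bdepth, brad))


def _render_rgb(
    config: SyntheticSceneConfig,
    surface: np.ndarray,
    row_index: np.ndarray,
    n_rows: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    palette = np.asarray(config.rgb_palette, dtype=float)
    n = surface.shape[0]
    # Blob surfaces draw from the leaf/branch entries, interior points
    # from the last (darkest) palette entry.
    choice = rng.integers(0, max(len(palette) - 1, 1), n)
    choice[surface < 0] = len(palette) - 1
    rgb = palette[choice]
    rgb = rgb * (1.0 + rng.normal(0.0, 0.08, (n, 1)))  # per-point shading
    # Phenomenological auto-exposure roll-off: colour darkens below ~50 lx.
    exposure = min(1.0, np.sqrt(config.illuminance / 50.0))
    rgb = np.clip(rgb * exposure, 0, 255).astype(np.uint8)
    # Colour camera covers a slightly smaller vertical FOV than the
    # depth raster: border rows lack RGB.
    margin = (1.0 - config.rgb_fov_fraction) / 2.0
    lo, hi = margin * n_rows, (1.0 - margin) * n_rows
    has_rgb = (row_index >= lo) & (row_index < hi)
    return rgb, has_rgb


def _render_nir(
    config: SyntheticSceneConfig,
    coords: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    sq_range = (coords**2).sum(axis=1)
    albedo = config.nir_albedo * rng.lognormal(
        0.0, config.albedo_noise_sd, coords.shape[0]
    )
    nir = albedo / np.maximum(sq_range, 1e-12)
    return np.clip(np.round(nir), 0, 65535).astype(np.uint16)
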