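"""Depth coordinates, laminar ROIs and thickness measurement for cartilage.

The cartilage sits between two ordered polylines in millimetre coordinates:
the articular surface and the subchondral bone interface.  Every mask pixel
gets a normalized depth d = dist_surface / (dist_surface + dist_bone), 0 at
the surface and 1 at the bone.  Laminar ROIs take the superficial third
(d <= 1/3) and the deep third (d >= 2/3) with a half-pixel partial-volume
guard against the interfaces; segment thickness is measured by casting the
inward surface normal at fixed arc-length fractions {0.25, 0.5, 0.75} of the
segment's surface polyline and intersecting it with the bone interface, the
mean of the three samples being the reported thickness.

All geometry is computed in millimetres with a pixel-centre convention
(pixel (row, col) sits at (col * pixel_size, row * pixel_size)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "CartilageROI",
    "DepthField",
    "ThicknessMeasurement",
    "compute_depth",
    "extract_layer",
    "measure_thickness",
    "roi_mean",
    "split_segments_by_angle",
]

THICKNESS_FRACTIONS = (0.25, 0.5, 0.75)
LAYERS = ("superficial", "deep", "full")


@dataclass
class CartilageROI:
    """A labeled pixel set: compartment x segment x layer.

    ``pixels`` is an (n, 2) integer array of (row, col) indices.
    """

    compartment: str
    segment: str
    layer: str
    pixels: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0

    def as_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if not self.empty:
            m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class DepthField:
    """Normalized depth plus the raw interface distances (mm) per pixel."""

    depth: np.ndarray
    dist_surface_mm: np.ndarray
    dist_bone_mm: np.ndarray


@dataclass
class ThicknessMeasurement:
    """Three normal-cast thickness samples and their mean for one segment."""

    segment: str
    samples_mm: tuple[float, float, float]
    mean_mm: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.samples_mm):
            raise ValueError("thickness samples must be positive")
        expected = float(np.mean(self.samples_mm))
        if abs(expected - self.mean_mm) > 1e-9:
            raise ValueError("mean_mm is not the mean of samples_mm")


def _point_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min Euclidean distance from each point to a polyline, vectorized.

    points: (n, 2); polyline: (m, 2) ordered vertices.
    """
    a = polyline[:-1]
    ab = polyline[1:] - a
    ab2 = np.maximum(np.einsum("sd,sd->s", ab, ab), 1e-30)
    ap = points[:, None, :] - a[None, :, :]  # (n, m-1, 2)
    t = np.clip(np.einsum("nsd,sd->ns", ap, ab) / ab2, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def compute_depth(
    mask: np.ndarray,
    articular_surface: np.ndarray,
    bone_interface: np.ndarray,
    pixel_size_mm: float,
) -> DepthField:
    """Normalized depth in [0, 1] for every mask pixel.

    Distances are Euclidean point-to-polyline in mm; d = 0 on the articular
    surface, d = 1 on the bone interface; NaN outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float) * pixel_size_mm
    depth = np.full(mask.shape, np.nan)
    ds_map = np.full(mask.shape, np.nan)
    db_map = np.full(mask.shape, np.nan)
    if rows.size == 0:
        return DepthField(depth, ds_map, db_map)
    ds = _point_polyline_distance(pts, np.asarray(articular_surface, dtype=float))
    db = _point_polyline_distance(pts, np.asarray(bone_interface, dtype=float))
    total = ds + db
    bad = total <= 0
    if np.any(bad):
        r, c = rows[bad][0], cols[bad][0]
        raise ValueError(
            f"degenerate geometry: pixel ({r}, {c}) lies on both interfaces"
        )
    depth[rows, cols] = ds / total
    ds_map[rows, cols] = ds
    db_map[rows, cols] = db
    return DepthField(depth, ds_map, db_map)


def extract_layer(
    mask: np.ndarray,
    depth: DepthField,
    layer: str,
    pixel_size_mm: float,
    guard_px: float = 0.5,
    layer_fraction: float = 1.0 / 3.0,
    compartment: str = "",
    segment: str = "",
) -> CartilageROI:
    """Extract a laminar ROI from a depth field.

    superficial: d <= layer_fraction; deep: d >= 1 - layer_fraction; full:
    all mask pixels.  Pixels whose centre lies within ``guard_px *
    pixel_size_mm`` of either interface are excluded from the laminar ROIs
    (partial-volume guard) but kept in the full ROI.  An empty laminar ROI
    (very thin cartilage) is returned empty with a warning rather than
    failing.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    mask = np.asarray(mask, dtype=bool)
    if layer == "full":
        sel = mask
    else:
        guard_mm = guard_px * pixel_size_mm
        clear = (depth.dist_surface_mm >= guard_mm) & (
            depth.dist_bone_mm >= guard_mm
        )
        with np.errstate(invalid="ignore"):
            if layer == "superficial":
                band = depth.depth <= layer_fraction
            else:
                band = depth.depth >= 1.0 - layer_fraction
        sel = mask & band & clear
        if not sel.any():
            warnings.warn(
                f"{layer} layer of {compartment or '?'}/{segment or '?'} is "
                f"empty after the {guard_px:.2f}-pixel guard (cartilage too "
                "thin)",
                stacklevel=2,
            )
    pixels = np.argwhere(sel)
    return CartilageROI(compartment, segment, layer, pixels, mask.shape)


def measure_thickness(
    segment_surface: np.ndarray,
    bone_interface: np.ndarray,
    segment: str = "",
    fractions: tuple[float, ...] = THICKNESS_FRACTIONS,
    max_cast_mm: float = 20.0,
) -> ThicknessMeasurement:
    """Normal-cast thickness at fixed arc-length fractions of a segment.

    At each fraction of the segment's articular-surface polyline the local
    inward normal is cast and the distance to its first intersection with
    the bone interface recorded (sub-pixel, in mm).  Raises if a normal
    fails to hit the bone interface.
    """
    surf = np.asarray(segment_surface, dtype=float)
    if surf.shape[0] < 2:
        raise ValueError("segment surface polyline needs at least 2 points")
    bone = LineString(np.asarray(bone_interface, dtype=float))
    seglen = np.linalg.norm(np.diff(surf, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    if arc[-1] <= 0:
        raise ValueError("degenerate segment surface polyline")

    samples = []
    for frac in fractions:
        s = frac * arc[-1]
        i = min(int(np.searchsorted(arc, s, side="right")) - 1, len(seglen) - 1)
        t = (s - arc[i]) / seglen[i]
        p = surf[i] + t * (surf[i + 1] - surf[i])
        tangent = (surf[i + 1] - surf[i]) / seglen[i]
        normal = np.array([-tangent[1], tangent[0]])
        hit = None
        for direction in (normal, -normal):
            ray = LineString([p, p + direction * max_cast_mm])
            inter = ray.intersection(bone)
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            coords = np.vstack([np.asarray(g.coords) for g in geoms])
            d = float(np.min(np.hypot(coords[:, 0] - p[0], coords[:, 1] - p[1])))
            if hit is None or d < hit:
                hit = d
        if hit is None or hit <= 0:
            raise ValueError(
                f"surface normal at arc fraction {frac} does not intersect "
                "the bone interface; geometry inconsistent"
            )
        samples.append(float(hit))
    samples = tuple(samples)
    return ThicknessMeasurement(segment, samples, float(np.mean(samples)))


def roi_mean(map_2d: np.ndarray, roi: CartilageROI) -> tuple[float, float, int]:
    """Mean, SD and pixel count of a map over an ROI (finite pixels only).

    An empty ROI yields (nan, nan, 0) so the caller can flag the missing
    value instead of crashing.
    """
    if roi.empty:
        return (float("nan"), float("nan"), 0)
    vals = np.asarray(map_2d, dtype=float)[roi.pixels[:, 0], roi.pixels[:, 1]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return (float("nan"), float("nan"), 0)
    return (float(vals.mean()), float(vals.std(ddof=0)), int(vals.size))


def split_segments_by_angle(
    mask: np.ndarray,
    center_mm: tuple[float, float],
    boundary_angle_deg: float,
    pixel_size_mm: float,
) -> np.ndarray:
    """Label an external cartilage mask into WB/NWB by polar angle.

    Pixels at angle below the boundary (measured anticlockwise from +x at
    the given centre) are labeled WB (1), the rest NWB (2); background 0.
    Provided for real-data masks where no ground-truth labels exist.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    theta = np.degrees(
        np.arctan2(rows * pixel_size_mm - center_mm[1],
                   cols * pixel_size_mm - center_mm[0])
    )
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[rows, cols] = np.where(theta < boundary_angle_deg, 1, 2)
    return labels
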