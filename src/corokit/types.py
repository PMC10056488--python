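"""Core data containers shared across the toolkit.

Conventions (used everywhere, see docs/methods.md):

* Polar OCT frames are arrays of shape ``(n_alines, n_depth)``: row index is
  the A-line, column index is depth from the catheter center.  The A-line
  angle is ``theta = 2*pi*row/n_alines`` with ``theta = 0`` at the image top
  and counter-clockwise orientation in the cartesian view.
* All physical distances are millimetres, areas mm^2, angles degrees.
* Cartesian mapping of a polar point at radius ``R`` (px) and angle
  ``theta``:  ``x = -R*spacing*sin(theta)``, ``y = R*spacing*cos(theta)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PolarFrame",
    "RadialContour",
    "GuidewireMask",
    "StrutPoint",
    "Centerline3D",
    "Volume3D",
    "LabelVolume",
    "CrossSectionSeries",
    "RegressionReport",
    "polar_to_xy",
    "xy_to_polar",
    "contour_polygon",
    "radial_dice",
    "contour_hausdorff_mm",
]

# label codes for CT-like multi-class volumes
LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_WALL = 2
LABEL_CP = 3
LABEL_NCP = 4
LABEL_STENT = 5


@dataclass
class PolarFrame:
    """One OCT frame in (A-line x depth) coordinates.

    ``intensities`` is a ``(n_alines, n_depth)`` float array normalized to
    [0, 1]; ``radial_spacing`` is mm per depth pixel; ``catheter_offset`` is
    the first valid depth sample (pixels occupied by the catheter are
    excluded from analysis).
    """

    intensities: np.ndarray
    radial_spacing: float
    frame_index: int = 0
    catheter_offset: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("PolarFrame intensities must be 2D (alines x depth)")
        if self.n_alines < 8:
            raise ValueError("PolarFrame requires at least 8 A-lines")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("PolarFrame intensities must be finite")
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError("PolarFrame intensities must lie in [0, 1]")
        if self.radial_spacing <= 0:
            raise ValueError("radial_spacing must be positive")

    @property
    def n_alines(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_depth(self) -> int:
        return self.intensities.shape[1]

    @property
    def angles(self) -> np.ndarray:
        """A-line angles in radians, one per row."""
        return 2.0 * np.pi * np.arange(self.n_alines) / self.n_alines


@dataclass
class RadialContour:
    """Closed vessel border sampled as one radius (px) per A-line."""

    radii: np.ndarray
    kind: str = "lumen"  # "lumen" | "adventitia"
    excluded_alines: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii.ndim != 1:
            raise ValueError("radii must be a 1D per-A-line array")
        if np.any(~np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise ValueError("contour radii must be finite and positive")

    @property
    def n_alines(self) -> int:
        return self.radii.size

    def polygon(self, radial_spacing: float) -> np.ndarray:
        """Cartesian polygon (N, 2) in mm, counter-clockwise, open."""
        return contour_polygon(self.radii, radial_spacing)

    def area_mm2(self, radial_spacing: float) -> float:
        """Area enclosed by the contour (polar sector integration)."""
        r = self.radii * radial_spacing
        return float(0.5 * np.sum(r**2) * (2.0 * np.pi / self.n_alines))


@dataclass
class GuidewireMask:
    """Per-A-line guidewire occlusion flags plus the wire tip location."""

    occluded: np.ndarray
    tip: Optional[tuple] = None  # (aline, depth) of the wire reflection

    def __post_init__(self) -> None:
        self.occluded = np.asarray(self.occluded, dtype=bool)

    @property
    def empty(self) -> bool:
        return not bool(self.occluded.any())

    @property
    def alines(self) -> np.ndarray:
        return np.flatnonzero(self.occluded)


@dataclass
class StrutPoint:
    """One detected stent strut on one frame."""

    frame_index: int
    aline_index: int
    depth_px: float
    xy_mm: tuple
    cluster_id: int = -1
    kind: str = "metal"  # "metal" | "bvs"
    malapposition_mm: float = float("nan")


@dataclass
class Centerline3D:
    """Ordered 3D path with arclength and per-point orthonormal frames."""

    points: np.ndarray           # (N, 3) mm
    arclength: np.ndarray        # (N,) cumulative mm, strictly increasing
    tangents: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    binormals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.points.shape[0] != self.arclength.size:
            raise ValueError("points/arclength length mismatch")
        if self.points.shape[0] > 1 and np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def length(self) -> float:
        return float(self.arclength[-1] - self.arclength[0])

    def has_frames(self) -> bool:
        return self.tangents is not None and self.normals is not None


@dataclass
class Volume3D:
    """CT-like scalar grid (HU) with voxel spacing and origin in mm.

    Voxel ``(i, j, k)`` is centred at ``origin + (i, j, k) * spacing``.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Volume3D expects a 3D grid")
        sp = np.atleast_1d(np.asarray(self.spacing, dtype=float))
        if sp.size == 1:
            sp = np.repeat(sp, 3)
        self.spacing = tuple(sp[:3])
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume intensities must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelVolume:
    """Multi-class segmentation on the same grid as its source volume.

    Codes: 0 background, 1 lumen, 2 wall, 3 calcified plaque, 4 non-calcified
    plaque, 5 stent.
    """

    labels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume expects a 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class CrossSectionSeries:
    """Per-station cross-section areas/diameters along a vessel."""

    stations_mm: np.ndarray
    areas_mm2: np.ndarray
    diameters_mm: np.ndarray
    source: str = "frames"  # "model" | "frames"

    def __post_init__(self) -> None:
        self.stations_mm = np.asarray(self.stations_mm, dtype=float)
        self.areas_mm2 = np.asarray(self.areas_mm2, dtype=float)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        if np.any(np.diff(self.stations_mm) < 0):
            raise ValueError("stations must be sorted")
        if np.any(self.areas_mm2 <= 0):
            raise ValueError("areas must be positive")


@dataclass
class RegressionReport:
    """Agreement stats between two paired series (model vs frames)."""

    r_squared: float
    rss: float
    bias: float
    loa_low: float
    loa_high: float

    def as_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "rss": self.rss,
            "bland_altman": {
                "bias": self.bias,
                "loa_low": self.loa_low,
                "loa_high": self.loa_high,
            },
        }


# ---------------------------------------------------------------------------
# polar <-> cartesian helpers

def polar_to_xy(radii_px: np.ndarray, radial_spacing: float,
                angles: Optional[np.ndarray] = None) -> np.ndarray:
    """Map per-A-line radii (px) to cartesian mm points (CCW, start at top)."""
    radii_px = np.asarray(radii_px, dtype=float)
    if angles is None:
        angles = 2.0 * np.pi * np.arange(radii_px.size) / radii_px.size
    r = radii_px * radial_spacing
    return np.column_stack([-r * np.sin(angles), r * np.cos(angles)])


def xy_to_polar(xy_mm: np.ndarray, radial_spacing: float) -> tuple:
    """Inverse of :func:`polar_to_xy`: returns (angles rad in [0, 2pi), radii px)."""
    xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
    r = np.hypot(xy[:, 0], xy[:, 1]) / radial_spacing
    theta = np.mod(np.arctan2(-xy[:, 0], xy[:, 1]), 2.0 * np.pi)
    return theta, r


def contour_polygon(radii_px: np.ndarray, radial_spacing: float) -> np.ndarray:
    """Closed-border polygon (open representation: first point not repeated)."""
    return polar_to_xy(radii_px, radial_spacing)


def radial_dice(radii_a: np.ndarray, radii_b: np.ndarray) -> float:
    """Dice overlap of two star-shaped contours on the same angular grid.

    Sector-exact for borders sampled one radius per A-line:
    area of the intersection sector at angle i is ``0.5*min(ra, rb)^2*dtheta``.
    """
    ra = np.asarray(radii_a, dtype=float)
    rb = np.asarray(radii_b, dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("contours must share the angular grid")
    inter = np.minimum(ra, rb) ** 2
    return float(2.0 * inter.sum() / (np.sum(ra**2) + np.sum(rb**2)))


def contour_hausdorff_mm(radii_a: np.ndarray, radii_b: np.ndarray,
                         radial_spacing: float) -> float:
    """Symmetric Hausdorff distance (mm) between two sampled borders."""
    from scipy.spatial.distance import directed_hausdorff

    pa = polar_to_xy(radii_a, radial_spacing)
    pb = polar_to_xy(radii_b, radial_spacing)
    return float(max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0]))
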