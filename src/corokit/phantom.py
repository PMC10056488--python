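"""Synthetic OCT pullbacks and CT-like coronary volumes with exact truth.

The OCT generator emulates the appearance cues the segmentation pipeline
relies on: a dark lumen interior, a bright intima ridge at the true lumen
radius, a speckled tissue band, a dark media ring whose outer edge is the
true adventitia radius, a guidewire reflection with a full-depth shadow, and
stent struts (metallic blooms with full-depth shadows, or bright-rimmed dark
BVS boxes at the lumen).  Speckle is multiplicative exponential noise on a
piecewise-constant radial template, smoothed to a ~1 px grain.

The CT generator rasterizes a parametric tube (line or helix) into labelled
voxels (lumen / wall / calcified / non-calcified plaque / stent), emits HU
intensities per class, then optionally blurs and adds Gaussian noise.

Both generators are deterministic given their seed and return the exact
ground truth on the same grid/frame convention as the images, so every other
module is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import fusion3d
from .types import (LABEL_BACKGROUND, LABEL_CP, LABEL_LUMEN, LABEL_NCP,
                    LABEL_STENT, LABEL_WALL, Centerline3D, LabelVolume,
                    PolarFrame, RadialContour, Volume3D, polar_to_xy)

__all__ = [
    "StrutSpec",
    "OCTPhantomSpec",
    "CTPhantomSpec",
    "PhantomTruth",
    "synth_oct_pullback",
    "synth_ct_volume",
]


@dataclass
class StrutSpec:
    """One stent strut to draw: frame, azimuth, optional radius override."""

    frame: int
    angle_deg: float
    depth_mm: Optional[float] = None   # radius from catheter; None = on lumen
    kind: str = "metal"                # "metal" | "bvs"
    malapposed_mm: float = 0.0         # + pulls the strut into the lumen


@dataclass
class OCTPhantomSpec:
    """Parameters of a synthetic OCT pullback.

    ``lumen_radius_mm`` may be a constant or a callable ``frame -> mm``
    (mean radius).  ``eccentricity`` is the minor/major axis ratio of an
    elliptical lumen (1 = circular).  ``noise_seed`` is mandatory.
    """

    n_frames: int = 10
    n_alines: int = 360
    n_depth: int = 500
    radial_spacing: float = 0.01          # mm per depth px
    lumen_radius_mm: Union[float, Callable[[int], float]] = 1.5
    eccentricity: float = 1.0
    wall_thickness_mm: float = 0.7
    media_ring_mm: float = 0.31           # thickness of the dark media ring
    guidewire_angle_deg: Optional[float] = None
    guidewire_width_deg: float = 12.0
    catheter_offset_px: int = 20
    struts: List[StrutSpec] = field(default_factory=list)
    noise_seed: Optional[int] = None
    speckle: bool = True
    frame_spacing_mm: float = 0.2         # pullback step between frames

    # template intensities (piecewise-constant radial profile)
    i_lumen: float = 0.05
    i_ridge: float = 0.95
    i_tissue: float = 0.60
    i_media: float = 0.12
    i_beyond: float = 0.32
    ridge_px: int = 3

    def lumen_radius(self, frame: int) -> float:
        if callable(self.lumen_radius_mm):
            return float(self.lumen_radius_mm(frame))
        return float(self.lumen_radius_mm)

    def validate(self) -> None:
        if self.noise_seed is None:
            raise ValueError("noise_seed is mandatory")
        if not (0 < self.eccentricity <= 1):
            raise ValueError("eccentricity must be in (0, 1]")
        if self.guidewire_angle_deg is not None and not (
                0 <= self.guidewire_angle_deg < 360):
            raise ValueError("guidewire angle must be in [0, 360)")
        depth_mm = self.n_depth * self.radial_spacing
        for f in range(self.n_frames):
            if self.lumen_radius(f) + self.wall_thickness_mm >= depth_mm:
                raise ValueError("lumen radius + wall thickness exceeds imaged depth")
        for st in self.struts:
            if not (0 <= st.angle_deg < 360):
                raise ValueError("strut angles must be in [0, 360)")
            if not (0 <= st.frame < self.n_frames):
                raise ValueError("strut frame outside pullback")
            r = st.depth_mm if st.depth_mm is not None else (
                self.lumen_radius(st.frame) - st.malapposed_mm)
            if r / self.radial_spacing + 5 >= self.n_depth or r <= 0:
                raise ValueError("strut placed outside imaged depth")


@dataclass
class CTPhantomSpec:
    """Parameters of a CT-like labelled tube volume.

    Class intensities must satisfy background < NCP < wall < lumen < CP <=
    stent (HU), and the curve must keep at least ``lumen + wall`` clearance
    from the lateral grid boundary.  ``seed`` is mandatory.
    """

    shape: tuple = (64, 64, 160)
    spacing_mm: float = 0.25
    curve: str = "line"                   # "line" | "helix"
    helix_radius_mm: float = 8.0
    helix_pitch_mm: float = 20.0
    lumen_radius_mm: float = 1.5
    wall_thickness_mm: float = 1.0
    hu: dict = field(default_factory=lambda: {
        "background": -50.0, "ncp": 30.0, "wall": 60.0,
        "lumen": 350.0, "cp": 900.0, "stent": 1200.0})
    cp_inclusions: List[tuple] = field(default_factory=list)   # (s_mm, angle_deg, size_mm)
    ncp_inclusions: List[tuple] = field(default_factory=list)
    stent_extent_mm: Optional[tuple] = None                    # (s0, s1)
    blur_sigma_mm: float = 0.0
    noise_sd_hu: float = 0.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        h = self.hu
        order = [h["background"], h["ncp"], h["wall"], h["lumen"], h["cp"]]
        if not all(a < b for a, b in zip(order, order[1:])) or h["cp"] > h["stent"]:
            raise ValueError(
                "class intensities must be ordered background < NCP < wall < lumen < CP <= stent")
        if self.curve not in ("line", "helix"):
            raise ValueError("curve must be 'line' or 'helix'")
        if self.shape[2] < 2:
            raise ValueError("degenerate curve (zero length)")
        clearance = self.lumen_radius_mm + self.wall_thickness_mm
        half_x = (self.shape[0] - 1) / 2 * self.spacing_mm
        half_y = (self.shape[1] - 1) / 2 * self.spacing_mm
        reach = self.helix_radius_mm if self.curve == "helix" else 0.0
        if reach + clearance > min(half_x, half_y):
            raise ValueError("curve comes closer than lumen+wall to the grid boundary")


@dataclass
class PhantomTruth:
    """Exact ground truth emitted alongside phantom images."""

    lumen_contours: Optional[List[RadialContour]] = None
    adventitia_contours: Optional[List[RadialContour]] = None
    struts: Optional[List[dict]] = None
    guidewire_sector: Optional[tuple] = None      # (start_deg, end_deg)
    labels: Optional[LabelVolume] = None
    centerline: Optional[Centerline3D] = None
    stent_extent_mm: Optional[tuple] = None


# ---------------------------------------------------------------------------
# OCT pullback

def _ellipse_radii(mean_r_px: float, ecc: float, angles: np.ndarray) -> np.ndarray:
    """Polar radii of an ellipse with semi-axes (a, ecc*a) centred at origin."""
    a = mean_r_px
    b = ecc * a
    return a * b / np.sqrt((b * np.cos(angles)) ** 2 + (a * np.sin(angles)) ** 2)


def _smooth_speckle(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """Unit-mean multiplicative exponential speckle with ~1 px grain."""
    raw = rng.exponential(1.0, size=shape)
    sm = ndimage.gaussian_filter(raw, sigma=1.0, mode=("wrap", "nearest"))
    return sm / sm.mean()


def synth_oct_pullback(spec: OCTPhantomSpec) -> tuple:
    """Generate a synthetic polar OCT pullback plus its ground truth.

    Returns ``(frames, truth)`` where frames is a list of
    :class:`~corokit.types.PolarFrame` and truth carries the exact per-frame
    lumen/adventitia radii, strut records and guidewire sector.
    """
    spec.validate()
    rng = np.random.default_rng(spec.noise_seed)
    angles = 2.0 * np.pi * np.arange(spec.n_alines) / spec.n_alines
    depth = np.arange(spec.n_depth)
    sp = spec.radial_spacing
    ring_px = spec.media_ring_mm / sp
    wall_px = spec.wall_thickness_mm / sp

    frames: List[PolarFrame] = []
    lumen_truth: List[RadialContour] = []
    adv_truth: List[RadialContour] = []
    strut_truth: List[dict] = []
    gw_sector = None
    if spec.guidewire_angle_deg is not None:
        half = spec.guidewire_width_deg / 2
        gw_sector = (np.mod(spec.guidewire_angle_deg - half, 360.0),
                     np.mod(spec.guidewire_angle_deg + half, 360.0))

    for f in range(spec.n_frames):
        r_lum = _ellipse_radii(spec.lumen_radius(f) / sp, spec.eccentricity, angles)
        r_adv = r_lum + wall_px

        # piecewise-constant radial template, broadcast over (aline, depth)
        d = depth[None, :]
        rl = r_lum[:, None]
        ra = r_adv[:, None]
        tmpl = np.full((spec.n_alines, spec.n_depth), spec.i_beyond)
        tmpl = np.where(d < ra, spec.i_media, tmpl)
        tmpl = np.where(d < ra - ring_px, spec.i_tissue, tmpl)
        tmpl = np.where(d < rl + spec.ridge_px, spec.i_ridge, tmpl)
        tmpl = np.where(d < rl, spec.i_lumen, tmpl)
        tmpl[:, :spec.catheter_offset_px] = 0.0

        blooms = []  # (aline_center, depth_px) drawn after speckle
        for st in spec.struts:
            if st.frame != f:
                continue
            a_c = int(round(st.angle_deg / 360.0 * spec.n_alines)) % spec.n_alines
            if st.depth_mm is not None:
                r_st = st.depth_mm / sp
            else:
                r_st = r_lum[a_c] - st.malapposed_mm / sp
            r_i = int(round(r_st))
            rec = {"frame": f, "aline": a_c, "depth_px": float(r_st),
                   "angle_deg": st.angle_deg, "kind": st.kind,
                   "malapposed_mm": st.malapposed_mm,
                   "xy_mm": tuple(polar_to_xy(np.array([r_st]), sp,
                                              np.array([angles[a_c]]))[0])}
            strut_truth.append(rec)
            rows = (np.arange(a_c - 2, a_c + 3)) % spec.n_alines
            if st.kind == "metal":
                cols = np.arange(min(r_i + 4, spec.n_depth), spec.n_depth)
                tmpl[rows[:, None], cols[None, :]] *= 0.05
                blooms.append((a_c, r_i))
            else:  # BVS: bright-rimmed dark box near the lumen
                core_rows = np.arange(a_c - 1, a_c + 2) % spec.n_alines
                rim_rows = np.arange(a_c - 2, a_c + 3) % spec.n_alines
                tmpl[rim_rows[:, None],
                     np.clip(np.arange(r_i - 2, r_i + 7), 0, spec.n_depth - 1)] = 0.9
                tmpl[core_rows[:, None],
                     np.clip(np.arange(r_i, r_i + 5), 0, spec.n_depth - 1)] = 0.06

        if gw_sector is not None:
            half = spec.guidewire_width_deg / 2
            ddeg = np.abs(np.mod(np.degrees(angles) - spec.guidewire_angle_deg
                                 + 180.0, 360.0) - 180.0)
            gw_rows = ddeg <= half
            tip = spec.catheter_offset_px + 6
            tmpl[gw_rows, tip + 6:] *= 0.02
            tmpl[np.ix_(gw_rows, np.arange(tip - 3, tip + 4))] = 0.95

        img = tmpl * _smooth_speckle(rng, tmpl.shape) if spec.speckle else tmpl.copy()

        for a_c, r_i in blooms:  # saturated metallic blooms
            rr, dd = np.ogrid[:spec.n_alines, :spec.n_depth]
            da = np.minimum(np.abs(rr - a_c), spec.n_alines - np.abs(rr - a_c))
            disc = da**2 + (dd - r_i) ** 2 <= 3**2
            img[disc] = np.maximum(img[disc], 0.97)

        img[:, :spec.catheter_offset_px] = 0.0
        np.clip(img, 0.0, 1.0, out=img)
        frames.append(PolarFrame(intensities=img, radial_spacing=sp,
                                 frame_index=f,
                                 catheter_offset=spec.catheter_offset_px))
        lumen_truth.append(RadialContour(radii=r_lum, kind="lumen"))
        adv_truth.append(RadialContour(radii=r_adv, kind="adventitia"))

    truth = PhantomTruth(lumen_contours=lumen_truth,
                         adventitia_contours=adv_truth,
                         struts=strut_truth, guidewire_sector=gw_sector)
    return frames, truth


# ---------------------------------------------------------------------------
# CT volume

def _curve_points(spec: CTPhantomSpec, step_mm: float) -> np.ndarray:
    nz = spec.shape[2]
    cx = (spec.shape[0] - 1) / 2 * spec.spacing_mm
    cy = (spec.shape[1] - 1) / 2 * spec.spacing_mm
    z = np.arange(0.0, (nz - 1) * spec.spacing_mm + 1e-9, step_mm)
    if spec.curve == "line":
        x = np.full_like(z, cx)
        y = np.full_like(z, cy)
    else:
        phase = 2.0 * np.pi * z / spec.helix_pitch_mm
        x = cx + spec.helix_radius_mm * np.cos(phase)
        y = cy + spec.helix_radius_mm * np.sin(phase)
    return np.column_stack([x, y, z])


def synth_ct_volume(spec: CTPhantomSpec) -> tuple:
    """Rasterize the parametric tube into labels, then emit HU intensities.

    Returns ``(Volume3D, PhantomTruth)``; the truth holds the
    :class:`~corokit.types.LabelVolume`, the true centerline and the stent
    extent.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sp = spec.spacing_mm
    curve = _curve_points(spec, step_mm=sp / 4.0)
    cl = fusion3d.build_frames(curve, step=sp / 2.0)

    idx = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    xyz = idx * sp
    tree = cKDTree(cl.points)
    dist, nearest = tree.query(xyz, workers=-1)
    s_near = cl.arclength[nearest]

    r = spec.lumen_radius_mm
    w = spec.wall_thickness_mm
    labels = np.full(spec.shape, LABEL_BACKGROUND, dtype=np.uint8).ravel()
    labels[dist <= r + w] = LABEL_WALL
    labels[dist <= r] = LABEL_LUMEN

    for inclusions, code in ((spec.cp_inclusions, LABEL_CP),
                             (spec.ncp_inclusions, LABEL_NCP)):
        for (s0, ang_deg, size) in inclusions:
            i0 = int(np.argmin(np.abs(cl.arclength - s0)))
            a = np.radians(ang_deg)
            center = (cl.points[i0] + (r + w / 2)
                      * (np.cos(a) * cl.normals[i0] + np.sin(a) * cl.binormals[i0]))
            d_inc = np.linalg.norm(xyz - center, axis=1)
            sel = (d_inc <= size / 2) & (labels == LABEL_WALL)
            labels[sel] = code

    if spec.stent_extent_mm is not None:
        s0, s1 = spec.stent_extent_mm
        shell = (np.abs(dist - r) <= sp / 2 + 1e-9) & (s_near >= s0) & (s_near <= s1)
        labels[shell] = LABEL_STENT

    labels = labels.reshape(spec.shape)
    lut = np.empty(6, dtype=float)
    lut[LABEL_BACKGROUND] = spec.hu["background"]
    lut[LABEL_LUMEN] = spec.hu["lumen"]
    lut[LABEL_WALL] = spec.hu["wall"]
    lut[LABEL_CP] = spec.hu["cp"]
    lut[LABEL_NCP] = spec.hu["ncp"]
    lut[LABEL_STENT] = spec.hu["stent"]
    intens = lut[labels]
    if spec.blur_sigma_mm > 0:
        intens = ndimage.gaussian_filter(intens, sigma=spec.blur_sigma_mm / sp)
    if spec.noise_sd_hu > 0:
        intens = intens + rng.normal(0.0, spec.noise_sd_hu, size=intens.shape)

    vol = Volume3D(values=intens, spacing=(sp, sp, sp))
    truth = PhantomTruth(labels=LabelVolume(labels=labels, spacing=(sp, sp, sp)),
                         centerline=cl, stent_extent_mm=spec.stent_extent_mm)
    return vol, truth
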