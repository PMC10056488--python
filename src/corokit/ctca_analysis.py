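"""CTCA-style coronary segmentation.

The chain mirrors how contrast CT of a stented coronary is analysed:

1. multiscale Frangi vesselness enhances bright tubular structures;
2. a minimum-cost path through ``1/(eps + vesselness)`` between two user
   seeds extracts the centerline;
3. the user annotates a few voxels per tissue class; sigmoidal membership
   ("weight") functions of HU are calibrated on those seeds — a band
   (product of a rising and a falling sigmoid) for the lumen, a falling
   sigmoid for the outer wall, a rising one for calcified plaque (CP);
4. a 3D level set initialized as a thin tube around the centerline evolves
   with speed ``(2*w(I) - 1) - kappa*curvature`` to segment the lumen, then
   the outer wall; CP components are thresholded within the wall and
   non-calcified plaque (NCP) is what remains of the wall-weighted tissue;
5. the stent is localized from a sigmoid adapted to the mean luminal
   intensity, scored on a perilumenal shell per 0.5 mm centerline station.

Labels compose with precedence stent > CP > lumen > NCP > wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import graph
from skimage.filters import frangi

from .types import (LABEL_BACKGROUND, LABEL_CP, LABEL_LUMEN, LABEL_NCP,
                    LABEL_STENT, LABEL_WALL, Centerline3D, LabelVolume,
                    Volume3D)

__all__ = [
    "SigmoidWeight",
    "SeedAnnotation",
    "vesselness_preprocess",
    "extract_centerline",
    "calibrate_weights",
    "levelset_segment",
    "detect_stent_ctca",
]


def _sigmoid(x: np.ndarray, midpoint: float, slope: float, rising: bool) -> np.ndarray:
    z = slope * (np.asarray(x, dtype=float) - midpoint)
    if not rising:
        z = -z
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class SigmoidWeight:
    """HU membership function for one tissue class; output in [0, 1]."""

    klass: str                 # "lumen" | "wall" | "cp" | "stent"
    form: str                  # "rising" | "falling" | "band"
    midpoints: Tuple[float, ...]
    slopes: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.form == "band":
            if len(self.midpoints) != 2 or self.midpoints[0] >= self.midpoints[1]:
                raise ValueError("band form requires midpoint_low < midpoint_high")
        elif len(self.midpoints) != 1:
            raise ValueError("rising/falling forms take one midpoint")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        if self.form == "rising":
            return _sigmoid(hu, self.midpoints[0], self.slopes[0], rising=True)
        if self.form == "falling":
            return _sigmoid(hu, self.midpoints[0], self.slopes[0], rising=False)
        return (_sigmoid(hu, self.midpoints[0], self.slopes[0], rising=True)
                * _sigmoid(hu, self.midpoints[1], self.slopes[-1], rising=False))


@dataclass
class SeedAnnotation:
    """User-annotated voxel indices per tissue class (>= 5 voxels each)."""

    lumen: np.ndarray
    wall: np.ndarray
    cp: np.ndarray
    ncp: Optional[np.ndarray] = None
    stent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        sets = []
        for name in ("lumen", "wall", "cp", "ncp", "stent"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.atleast_2d(np.asarray(arr, dtype=int))
            setattr(self, name, arr)
            if arr.shape[1] != 3:
                raise ValueError(f"{name} seeds must be (N, 3) voxel indices")
            if arr.shape[0] < 5:
                raise ValueError(f"{name} needs at least 5 seed voxels")
            sets.append(set(map(tuple, arr)))
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("seed classes must be disjoint")


# ---------------------------------------------------------------------------
# vesselness + centerline

def vesselness_preprocess(vol: Volume3D, scales_mm: Sequence[float]) -> Volume3D:
    """Multiscale Frangi vesselness (bright tubes), rescaled to [0, 1].

    Scales are the vessel radii (mm) to enhance; the Gaussian width is
    matched as ``sigma = scale / sqrt(2)``, where the second-derivative
    response to a ridge of that radius peaks.  The response is the voxelwise
    maximum over scales; scales finer than the voxel spacing are skipped with
    a warning.  Hessian-based, hence invariant under a volume-wide intensity
    offset.
    """
    if len(scales_mm) == 0:
        raise ValueError("need at least one scale")
    spacing = float(np.mean(vol.spacing))
    sigmas = []
    for s in scales_mm:
        if s < spacing:
            warnings.warn(f"scale {s} mm below voxel spacing; skipped")
            continue
        sigmas.append(s / spacing / np.sqrt(2.0))
    if not sigmas:
        raise ValueError("all scales below voxel spacing")
    resp = frangi(vol.values, sigmas=sigmas, black_ridges=False)
    m = float(resp.max())
    if m > 0:
        resp = resp / m
    return Volume3D(values=resp, spacing=vol.spacing, origin=vol.origin)


def _recenter_path(path: np.ndarray, v: np.ndarray, radius: int = 5,
                   iterations: int = 4) -> np.ndarray:
    """Pull path points onto the local vesselness ridge.

    A minimum-cost path cuts corners or drifts wherever the response
    plateaus across the lumen; replacing each point by the response-weighted
    centroid of its neighborhood recenters it on the vessel axis.  The
    neighborhood radius must reach the plateau edges, i.e. be on the order
    of the lumen radius in voxels.
    """
    offs = np.array([(i, j, k)
                     for i in range(-radius, radius + 1)
                     for j in range(-radius, radius + 1)
                     for k in range(-radius, radius + 1)
                     if i * i + j * j + k * k <= radius * radius])
    shape = np.asarray(v.shape)
    out = path.astype(float)
    for _ in range(iterations):
        new = out.copy()
        for i, p in enumerate(out):
            nb = np.clip(np.round(p).astype(int) + offs, 0, shape - 1)
            w = v[tuple(nb.T)]
            ws = w.sum()
            if ws > 0:
                new[i] = (nb * w[:, None]).sum(axis=0) / ws
        out = new
    return out


def extract_centerline(vesselness: Volume3D, start: tuple, end: tuple,
                       epsilon: float = 1e-3,
                       smooth_window: int = 5) -> Centerline3D:
    """Minimum-cost path through the vesselness field between two seeds.

    Cost ``1/(eps + vesselness)`` over a 26-connected grid with metric edge
    lengths; the voxel path is recentered on the vesselness ridge, smoothed
    with a moving average (window 5) and converted to mm.
    """
    v = vesselness.values
    start = tuple(int(c) for c in start)
    end = tuple(int(c) for c in end)
    for p in (start, end):
        if any(c < 0 or c >= s for c, s in zip(p, v.shape)):
            raise ValueError("seed outside grid")
        if v[p] <= 0:
            raise ValueError("no vessel response at seed")
    if start == end:
        pt = vesselness.voxel_to_mm(np.asarray([start], dtype=float))
        return Centerline3D(points=pt, arclength=np.array([0.0]))

    cost = 1.0 / (epsilon + v)
    mcp = graph.MCP_Geometric(cost, fully_connected=True)
    costs, _ = mcp.find_costs([start], [end])
    if not np.isfinite(costs[end]):
        raise ValueError("no finite-cost path between seeds")
    path = np.asarray(mcp.traceback(end), dtype=float)
    path = _recenter_path(path, v)

    if smooth_window > 1 and len(path) > smooth_window:
        k = smooth_window
        pad = k // 2
        padded = np.vstack([np.repeat(path[:1], pad, axis=0), path,
                            np.repeat(path[-1:], pad, axis=0)])
        kernel = np.ones(k) / k
        path = np.column_stack([np.convolve(padded[:, i], kernel, mode="valid")
                                for i in range(3)])
    pts = vesselness.voxel_to_mm(path)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    pts = pts[keep]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return Centerline3D(points=pts, arclength=s)


# ---------------------------------------------------------------------------
# weight calibration

MIN_BAND_WIDTH_HU = 20.0   # floor for degenerate (noiseless) seed spreads
MIN_SLOPE_DENOM_HU = 5.0


def calibrate_weights(vol: Volume3D, seeds: SeedAnnotation) -> Dict[str, SigmoidWeight]:
    """Fit the lumen/wall/CP sigmoidal weight functions from seed voxels.

    Lumen: band between the 5th and 95th percentile of lumen-seed HU with
    slope ``4 / IQR``; wall: falling sigmoid midway between the wall-seed
    mean and the lumen 5th percentile; CP: rising sigmoid midway between the
    lumen 95th percentile and the CP-seed mean.  Raises when the seed means
    are not ordered wall < lumen < CP.
    """
    def hu_at(idx: np.ndarray) -> np.ndarray:
        return vol.values[tuple(idx.T)]

    lum = hu_at(seeds.lumen)
    wal = hu_at(seeds.wall)
    cp = hu_at(seeds.cp)
    if not (wal.mean() < lum.mean() < cp.mean()):
        raise ValueError("calibration inconsistent: seed means not ordered wall < lumen < CP")

    p5, p95 = np.percentile(lum, [5, 95])
    iqr = np.percentile(lum, 75) - np.percentile(lum, 25)
    slope = 4.0 / max(iqr, MIN_SLOPE_DENOM_HU)
    if p95 - p5 < MIN_BAND_WIDTH_HU:
        mid = 0.5 * (p5 + p95)
        p5, p95 = mid - MIN_BAND_WIDTH_HU / 2, mid + MIN_BAND_WIDTH_HU / 2
    lumen_w = SigmoidWeight("lumen", "band", (float(p5), float(p95)), (slope, slope))

    wall_mid = 0.5 * (wal.mean() + p5)
    wall_slope = 8.0 / max(p5 - wal.mean(), MIN_SLOPE_DENOM_HU)
    wall_w = SigmoidWeight("wall", "falling", (float(wall_mid),), (wall_slope,))

    cp_mid = 0.5 * (p95 + cp.mean())
    cp_slope = 8.0 / max(cp.mean() - p95, MIN_SLOPE_DENOM_HU)
    cp_w = SigmoidWeight("cp", "rising", (float(cp_mid),), (cp_slope,))
    return {"lumen": lumen_w, "wall": wall_w, "cp": cp_w}


# ---------------------------------------------------------------------------
# level set

def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance in voxels, negative inside ``mask``."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def _curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature of the level sets of phi (central differences)."""
    gx, gy, gz = np.gradient(phi)
    norm = np.sqrt(gx**2 + gy**2 + gz**2) + 1e-12
    nx, ny, nz = gx / norm, gy / norm, gz / norm
    k = (np.gradient(nx, axis=0) + np.gradient(ny, axis=1)
         + np.gradient(nz, axis=2))
    return np.clip(k, -1.0, 1.0)


def _evolve(phi: np.ndarray, speed: np.ndarray, kappa: float = 0.2,
            dt: float = 0.4, max_iter: int = 500, reinit_every: int = 50,
            conv_tol: float = 1e-3, conv_window: int = 10) -> tuple:
    """First-order upwind level-set evolution of ``phi`` under a static speed.

    ``speed > 0`` inflates the region ``{phi < 0}``.  Convergence: relative
    labelled-volume change below ``conv_tol`` over ``conv_window``
    iterations.  Returns ``(phi, converged)``.
    """
    vols: List[float] = []
    converged = False
    for it in range(max_iter):
        F = speed - kappa * _curvature(phi)

        dmx = phi - np.roll(phi, 1, axis=0)
        dpx = np.roll(phi, -1, axis=0) - phi
        dmy = phi - np.roll(phi, 1, axis=1)
        dpy = np.roll(phi, -1, axis=1) - phi
        dmz = phi - np.roll(phi, 1, axis=2)
        dpz = np.roll(phi, -1, axis=2) - phi
        grad_plus = np.sqrt(np.maximum(dmx, 0)**2 + np.minimum(dpx, 0)**2
                            + np.maximum(dmy, 0)**2 + np.minimum(dpy, 0)**2
                            + np.maximum(dmz, 0)**2 + np.minimum(dpz, 0)**2)
        grad_minus = np.sqrt(np.minimum(dmx, 0)**2 + np.maximum(dpx, 0)**2
                             + np.minimum(dmy, 0)**2 + np.maximum(dpy, 0)**2
                             + np.minimum(dmz, 0)**2 + np.maximum(dpz, 0)**2)
        phi = phi - dt * (np.maximum(F, 0) * grad_plus
                          + np.minimum(F, 0) * grad_minus)

        if (it + 1) % reinit_every == 0:
            phi = _signed_distance(phi < 0)

        vols.append(float(np.count_nonzero(phi < 0)))
        if len(vols) > conv_window:
            recent = vols[-conv_window - 1:]
            ref = max(recent[0], 1.0)
            if max(abs(v - recent[0]) for v in recent[1:]) / ref < conv_tol:
                converged = True
                break
    return phi, converged


def _tube_mask(shape: tuple, cl: Centerline3D, spacing: float,
               radius_vox: float = 1.0) -> np.ndarray:
    """Rasterize a thin tube around the centerline (voxel-space radius)."""
    seed = np.zeros(shape, dtype=bool)
    vox = np.round(cl.points / spacing).astype(int)
    vox = vox[np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)]
    if len(vox) == 0:
        raise ValueError("centerline outside the volume")
    seed[tuple(vox.T)] = True
    dist = ndimage.distance_transform_edt(~seed)
    return dist <= radius_vox


def levelset_segment(vol: Volume3D, weights: Dict[str, SigmoidWeight],
                     cl: Centerline3D, kappa: float = 0.2, dt: float = 0.4,
                     max_iter: int = 500) -> LabelVolume:
    """Level-set segmentation of lumen, outer wall, CP and NCP.

    The lumen front starts as a 1-voxel tube around the centerline and
    evolves under ``(2*w_lumen(I) - 1) - kappa*curvature``; the outer-wall
    front restarts from the lumen result with the wall weight (combined with
    the lumen weight so the interior keeps a positive force).  CP = connected
    components of ``w_cp > 0.5`` inside the wall; NCP = remaining
    wall-weighted tissue between lumen and outer wall.  A non-convergent
    evolution returns the best labels with a warning.
    """
    spacing = float(np.mean(vol.spacing))
    I = vol.values

    w_lum = weights["lumen"](I)
    phi = _signed_distance(_tube_mask(I.shape, cl, spacing))
    phi, ok1 = _evolve(phi, 2.0 * w_lum - 1.0, kappa, dt, max_iter)
    lumen = phi < 0

    # the outer-wall surface encloses lumen, wall tissue and plaque: keep a
    # positive force on all three so inclusions do not punch holes in the front
    w_wall = np.maximum.reduce([weights["wall"](I), w_lum, weights["cp"](I)])
    phi2 = _signed_distance(lumen)
    phi2, ok2 = _evolve(phi2, 2.0 * w_wall - 1.0, kappa, dt, max_iter)
    outer = (phi2 < 0) | lumen
    if not (ok1 and ok2):
        warnings.warn("level set did not converge within max_iter; returning best labels")

    # stent first: blooming metal on the perilumenal shell would otherwise
    # masquerade as calcium (precedence stent > CP > lumen > NCP > wall)
    stent = np.zeros(I.shape, dtype=bool)
    try:
        det = detect_stent_ctca(vol, lumen, cl)
        if len(det["stent_voxels"]):
            stent[tuple(det["stent_voxels"].T)] = True
    except ValueError:
        pass  # empty lumen; nothing to relabel

    wall_band = outer & ~lumen
    cp = (weights["cp"](I) > 0.5) & wall_band & ~stent
    ncp = wall_band & ~cp & ~stent & (weights["wall"](I) > 0.5)

    labels = np.full(I.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[wall_band] = LABEL_WALL
    labels[ncp] = LABEL_NCP
    labels[lumen] = LABEL_LUMEN
    labels[cp] = LABEL_CP
    labels[stent] = LABEL_STENT
    return LabelVolume(labels=labels, spacing=vol.spacing, origin=vol.origin)


# ---------------------------------------------------------------------------
# stent localization

def detect_stent_ctca(vol: Volume3D, lumen_mask: np.ndarray, cl: Centerline3D,
                      station_mm: float = 0.5, run_threshold: float = 0.1,
                      sigma_floor_hu: float = 10.0) -> dict:
    """Locate the stented arclength interval from perilumenal brightness.

    A rising sigmoid with midpoint ``mu + 3*sigma`` of the luminal HU scores
    voxels of the perilumenal shell (morphological gradient of the lumen
    mask, dilated by one voxel).  Stations of ``station_mm`` along the
    centerline whose bright-shell fraction exceeds ``run_threshold`` form
    the stent extent (longest contiguous run).  An empty extent is valid.
    """
    I = vol.values
    if not lumen_mask.any():
        raise ValueError("empty lumen mask")
    mu = float(I[lumen_mask].mean())
    sigma = float(I[lumen_mask].std())
    weight = SigmoidWeight("stent", "rising", (mu + 3.0 * sigma,),
                           (4.0 / max(sigma, sigma_floor_hu),))

    grad = ndimage.binary_dilation(lumen_mask) & ~ndimage.binary_erosion(lumen_mask)
    shell = ndimage.binary_dilation(grad)

    spacing = np.asarray(vol.spacing)
    idx = np.argwhere(shell)
    xyz = idx * spacing + np.asarray(vol.origin)
    tree = cKDTree(cl.points)
    _, nearest = tree.query(xyz, workers=-1)
    s_vox = cl.arclength[nearest]

    n_st = int(np.floor(cl.arclength[-1] / station_mm)) + 1
    station_of = np.minimum((s_vox / station_mm).astype(int), n_st - 1)
    bright = weight(I[tuple(idx.T)]) > 0.5
    scores = np.zeros(n_st)
    for k in range(n_st):
        sel = station_of == k
        if sel.any():
            scores[k] = float(bright[sel].mean())

    hot = scores > run_threshold
    best_run = None
    i = 0
    while i < n_st:
        if hot[i]:
            j = i
            while j < n_st and hot[j]:
                j += 1
            if best_run is None or (j - i) > (best_run[1] - best_run[0] + 1):
                best_run = (i, j - 1)
            i = j
        else:
            i += 1

    if best_run is None:
        return {"extent_mm": None, "stations": scores,
                "stent_voxels": np.empty((0, 3), int), "weight": weight}
    s0, s1 = best_run
    in_run = (station_of >= s0) & (station_of <= s1)
    stent_vox = idx[in_run & bright]
    return {"extent_mm": (s0 * station_mm, (s1 + 1) * station_mm),
            "stations": scores, "stent_voxels": stent_vox, "weight": weight}
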