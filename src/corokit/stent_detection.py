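"""Stent strut detection on OCT frames.

Metallic struts bloom brightly and cast full-depth shadows: per A-line the
detector keeps pixels above a high intensity percentile and accepts the
brightest one as a candidate when the brightness profile drops steeply
behind it (slope criterion) and the remaining depth is shadowed for long
enough (shadow-length criterion).  Candidates are condensed with DBSCAN —
one cluster per physical strut — and each cluster is reduced to its
intensity-weighted centroid.

BVS (bioresorbable) struts are bright-rimmed dark boxes at the lumen.  They
are found on the scan-converted grayscale frame by a fixed morphological
rule chain: binarize at 0.15, close with a one-pixel disk, fill holes,
subtract the thresholded image, then keep 8-connected components with area
in [10, 40] px, second-moments aspect ratio < 5 and centroid inside a
10-pixel band around the lumen border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk
from sklearn.cluster import DBSCAN

from .types import GuidewireMask, PolarFrame, RadialContour, StrutPoint, polar_to_xy

__all__ = [
    "StrutDetectorParams",
    "detect_metal_candidates",
    "cluster_struts",
    "detect_bvs_struts",
    "detect_struts_frame",
]


@dataclass
class StrutDetectorParams:
    """Tunables of the strut detectors (BVS values are fixed by the rule chain)."""

    percentile: float = 99.5          # intensity percentile for candidate pixels
    min_shadow_len: int = 150         # px of shadow behind the strut
    max_slope: float = 0.05           # required drop (intensity/px) behind peak
    shadow_gap: int = 10              # px skipped between peak and shadow window
    shadow_level_frac: float = 0.2    # shadow level = frac * beyond-lumen median
    dbscan_eps_mm: float = 0.15
    dbscan_min_pts: int = 1
    bvs_threshold: float = 0.15
    bvs_area_range: Tuple[int, int] = (10, 40)
    bvs_max_aspect: float = 5.0
    bvs_band_width: int = 10

    def validate(self) -> None:
        if not (50.0 < self.percentile < 100.0):
            raise ValueError("percentile must be in (50, 100)")


# ---------------------------------------------------------------------------
# metallic struts

def detect_metal_candidates(frame: PolarFrame, lumen: RadialContour,
                            params: Optional[StrutDetectorParams] = None,
                            mask: Optional[GuidewireMask] = None) -> List[tuple]:
    """Per-A-line metallic strut candidates ``(aline, depth_px, intensity)``.

    An A-line yields a candidate iff its brightest above-percentile pixel is
    followed by a steep drop and a sufficiently long, sufficiently dark
    shadow reaching toward the image edge.  Guidewire-masked A-lines are
    skipped.  An empty list is a valid outcome.
    """
    params = params or StrutDetectorParams()
    params.validate()
    I = frame.intensities
    n, nd = frame.n_alines, frame.n_depth
    thr = np.percentile(I, params.percentile)
    # shadow level referenced to the typical beyond-lumen tissue brightness
    cols = np.arange(nd)[None, :]
    beyond = I[cols >= lumen.radii[:, None]]
    shadow_level = params.shadow_level_frac * float(np.median(beyond))

    out: List[tuple] = []
    for a in range(n):
        if mask is not None and mask.occluded[a]:
            continue
        row = I[a]
        cand = np.flatnonzero((row >= thr)
                              & (np.arange(nd) >= frame.catheter_offset + 5))
        if cand.size == 0:
            continue
        p = int(cand[np.argmax(row[cand])])
        # slope of the brightness profile behind the peak
        w = np.arange(1, 6)
        w = w[p + w < nd]
        if w.size == 0:
            continue
        slope = np.max((row[p] - row[p + w]) / w)
        if slope < params.max_slope:
            continue
        tail = row[min(p + params.shadow_gap, nd):]
        if tail.size < params.min_shadow_len:
            continue
        if float(tail.mean()) >= shadow_level:
            continue
        out.append((a, p, float(row[p])))
    return out


def cluster_struts(candidates: Sequence[tuple], frame: PolarFrame,
                   params: Optional[StrutDetectorParams] = None) -> List[StrutPoint]:
    """Cluster per-A-line candidates into one :class:`StrutPoint` each.

    Candidates are mapped to cartesian mm, grouped with DBSCAN
    (``eps = dbscan_eps_mm``, ``min_pts``) and reduced to intensity-weighted
    centroids; DBSCAN noise points are dropped.  The result is invariant to
    the input order up to relabeling.
    """
    params = params or StrutDetectorParams()
    if len(candidates) == 0:
        return []
    cands = sorted(candidates)  # order-independent clustering input
    alines = np.array([c[0] for c in cands])
    depths = np.array([float(c[1]) for c in cands])
    weights = np.array([float(c[2]) for c in cands])
    angles = 2.0 * np.pi * alines / frame.n_alines
    xy = polar_to_xy(depths, frame.radial_spacing, angles)

    labels = DBSCAN(eps=params.dbscan_eps_mm,
                    min_samples=params.dbscan_min_pts).fit_predict(xy)
    points: List[StrutPoint] = []
    for cid in sorted(set(labels)):
        if cid == -1:
            continue
        sel = labels == cid
        wsum = weights[sel].sum()
        cx, cy = (xy[sel] * weights[sel, None]).sum(axis=0) / wsum
        # representative polar position: weighted circular mean
        ang = np.arctan2(np.sum(weights[sel] * np.sin(angles[sel])),
                         np.sum(weights[sel] * np.cos(angles[sel])))
        aline = int(round(np.mod(ang, 2 * np.pi) / (2 * np.pi) * frame.n_alines)) \
            % frame.n_alines
        depth = float(np.sum(weights[sel] * depths[sel]) / wsum)
        points.append(StrutPoint(frame_index=frame.frame_index,
                                 aline_index=aline, depth_px=depth,
                                 xy_mm=(float(cx), float(cy)),
                                 cluster_id=int(cid), kind="metal"))
    return points


# ---------------------------------------------------------------------------
# BVS struts

def detect_bvs_struts(image: np.ndarray, lumen_polygon_px: np.ndarray,
                      params: Optional[StrutDetectorParams] = None,
                      frame_index: int = 0,
                      pixel_spacing_mm: float = 1.0,
                      center_px: Optional[Tuple[float, float]] = None
                      ) -> List[StrutPoint]:
    """Apply the BVS morphological rule chain to a cartesian grayscale frame.

    ``image`` is min-max normalized per frame before the 0.15 cut.
    ``lumen_polygon_px`` is the lumen border polygon in (row, col) pixels of
    the same image.  Survivors become BVS :class:`StrutPoint`s whose
    ``xy_mm`` is relative to ``center_px`` (defaults to the image center).
    """
    params = params or StrutDetectorParams()
    img = np.asarray(image, dtype=float)
    rng_ = img.max() - img.min()
    norm = (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)

    bw = norm > params.bvs_threshold
    closed = closing(bw, disk(1))
    filled = ndimage.binary_fill_holes(closed)
    diff = filled & ~bw

    lab = cc_label(diff, connectivity=2)
    border = Polygon(np.asarray(lumen_polygon_px, dtype=float)).exterior
    lo, hi = params.bvs_area_range
    if center_px is None:
        center_px = ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)

    out: List[StrutPoint] = []
    for i, region in enumerate(regionprops(lab)):
        if not (lo <= region.area <= hi):
            continue
        minor = region.axis_minor_length
        aspect = region.axis_major_length / minor if minor > 0 else np.inf
        if aspect >= params.bvs_max_aspect:
            continue
        cr, cc_ = region.centroid
        if border.distance(Point(cr, cc_)) > params.bvs_band_width:
            continue
        x_mm = (cc_ - center_px[1]) * pixel_spacing_mm
        y_mm = (center_px[0] - cr) * pixel_spacing_mm
        theta = np.mod(np.arctan2(-x_mm, y_mm), 2 * np.pi)
        out.append(StrutPoint(frame_index=frame_index,
                              aline_index=int(theta / (2 * np.pi) * 360) % 360,
                              depth_px=float(np.hypot(cr - center_px[0],
                                                      cc_ - center_px[1])),
                              xy_mm=(float(x_mm), float(y_mm)),
                              cluster_id=len(out), kind="bvs"))
    return out


def detect_struts_frame(frame: PolarFrame, lumen: RadialContour,
                        params: Optional[StrutDetectorParams] = None,
                        mask: Optional[GuidewireMask] = None) -> List[StrutPoint]:
    """Metal candidate detection + DBSCAN clustering for one frame."""
    cands = detect_metal_candidates(frame, lumen, params, mask)
    return cluster_struts(cands, frame, params)
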