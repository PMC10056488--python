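"""Quantitative vessel and stent metrics from contours, masks and struts.

Vessel side: lumen/wall area and perimeter, minimum/maximum diameter, plaque
burden (EEM-based: ``100*(A_wall - A_lumen)/A_wall``) and per-class plaque
area/arc angle.  Stent side: stent cross-sectional area from the strut
polygon, min/max stent diameter, per-strut malapposition distance against
the lumen border, percent unapposed struts, restenosis burden and a
frame-gap fracture heuristic.

All metrics are invariant under rigid motions of the frame; distances are
mm, areas mm^2, angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from shapely.geometry import Point, Polygon

from .types import StrutPoint

__all__ = [
    "FrameMetrics",
    "StentMetrics",
    "contour_metrics",
    "plaque_burden",
    "plaque_class_metrics",
    "stent_metrics",
]


@dataclass
class FrameMetrics:
    """Per-frame vessel evaluation outputs."""

    lumen_area_mm2: float
    lumen_perimeter_mm: float
    wall_area_mm2: float
    wall_perimeter_mm: float
    plaque_burden_pct: float
    plaque_class_areas_mm2: Dict[str, float] = field(default_factory=dict)
    plaque_class_angles_deg: Dict[str, float] = field(default_factory=dict)


@dataclass
class StentMetrics:
    """Per-frame stent evaluation outputs plus pullback-level flags."""

    stent_csa_mm2: List[Optional[float]]
    min_diameter_mm: List[Optional[float]]
    max_diameter_mm: List[Optional[float]]
    malapposition_mm: List[List[float]]
    pct_unapposed: float
    restenosis_burden_pct: List[Optional[float]]
    fracture_gaps: List[Tuple[int, int]]


def _as_polygon(poly: np.ndarray) -> Polygon:
    p = Polygon(np.asarray(poly, dtype=float))
    if not p.is_valid:
        raise ValueError("self-intersecting polygon")
    return p


def _min_width(hull_pts: np.ndarray) -> float:
    """Rotating-calipers minimum width of a convex polygon."""
    n = len(hull_pts)
    best = np.inf
    for i in range(n):
        a, b = hull_pts[i], hull_pts[(i + 1) % n]
        e = b - a
        ln = np.hypot(*e)
        if ln < 1e-15:
            continue
        nrm = np.array([-e[1], e[0]]) / ln
        widths = (hull_pts - a) @ nrm
        best = min(best, float(widths.max() - widths.min()))
    return best


def contour_metrics(poly: np.ndarray) -> Tuple[float, float, float, float]:
    """(area, perimeter, min diameter, max diameter) of a simple polygon.

    Shoelace area; polyline perimeter; max diameter is the largest pairwise
    hull-vertex distance; min diameter the rotating-calipers width.
    """
    p = _as_polygon(poly)
    area = float(p.area)
    perimeter = float(p.exterior.length)
    hull = np.asarray(p.convex_hull.exterior.coords)[:-1]
    d = np.linalg.norm(hull[:, None, :] - hull[None, :, :], axis=-1)
    return area, perimeter, _min_width(hull), float(d.max())


def plaque_burden(lumen: np.ndarray, wall: np.ndarray) -> float:
    """Percent of the outer-wall cross-section not occupied by lumen."""
    pl = _as_polygon(lumen)
    pw = _as_polygon(wall)
    if not pw.buffer(1e-9).contains(pl):
        raise ValueError("lumen not inside wall")
    return float(100.0 * (pw.area - pl.area) / pw.area)


def plaque_class_metrics(class_mask: np.ndarray, lumen_center_px: Tuple[float, float],
                         pixel_spacing_mm: float,
                         class_names: Optional[Dict[int, str]] = None,
                         n_angle_bins: int = 360) -> Dict[str, Tuple[float, float]]:
    """Per-class plaque area (mm^2) and arc angle (degrees).

    ``class_mask`` holds integer labels on a cartesian grid (0 = none).  The
    angle is the measure of the union of angular sectors containing the
    class, seen from the lumen center.
    """
    mask = np.asarray(class_mask)
    px_area = pixel_spacing_mm**2
    out: Dict[str, Tuple[float, float]] = {}
    cy, cx = lumen_center_px
    for code in np.unique(mask):
        if code == 0:
            continue
        name = (class_names or {}).get(int(code), str(int(code)))
        rr, cc = np.nonzero(mask == code)
        area = float(rr.size * px_area)
        x = cc - cx
        y = cy - rr
        theta = np.mod(np.arctan2(-x, y), 2 * np.pi)
        bins = np.unique((theta / (2 * np.pi) * n_angle_bins).astype(int))
        angle = float(bins.size * 360.0 / n_angle_bins)
        out[name] = (area, angle)
    return out


def _strut_polygon(struts: Sequence[StrutPoint], lumen_centroid: np.ndarray) -> np.ndarray:
    """Stent polygon: struts ordered by azimuth about the lumen centroid."""
    pts = np.asarray([s.xy_mm for s in struts], dtype=float)
    rel = pts - lumen_centroid
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
    return pts[order]


def stent_metrics(struts_by_frame: Dict[int, List[StrutPoint]],
                  lumen_polys: Dict[int, np.ndarray],
                  strut_thickness_mm: float = 0.1,
                  malappose_threshold_mm: float = 0.1,
                  gap_frames: int = 3,
                  stented_extent: Optional[Tuple[int, int]] = None) -> StentMetrics:
    """Stent evaluation over a pullback.

    Per frame (>= 3 struts; fewer are skipped with a ``None`` entry): the
    stent polygon is the struts ordered by azimuth about the lumen centroid;
    its area is the stent CSA.  Malapposition per strut is the signed
    distance from the strut's abluminal edge (center pushed
    ``strut_thickness_mm`` toward the wall) to the lumen border — positive
    when the edge still floats inside the lumen cavity, i.e. away from the
    wall; a strut is unapposed iff that distance exceeds the threshold.
    Restenosis burden is ``100*(CSA - lumen area)/CSA`` clipped at 0.
    Fracture: any run of >= ``gap_frames`` consecutive strut-free frames
    strictly inside the stented extent.
    """
    frames = sorted(set(struts_by_frame) | set(lumen_polys))
    csa: List[Optional[float]] = []
    dmin: List[Optional[float]] = []
    dmax: List[Optional[float]] = []
    rest: List[Optional[float]] = []
    malapp: List[List[float]] = []
    n_total = 0
    n_unapposed = 0

    for f in frames:
        struts = struts_by_frame.get(f, [])
        poly = lumen_polys.get(f)
        frame_mal: List[float] = []
        if poly is not None and struts:
            lum = _as_polygon(poly)
            centroid = np.asarray(lum.centroid.coords[0])
            for s in struts:
                p = np.asarray(s.xy_mm, dtype=float)
                v = p - centroid
                nv = np.linalg.norm(v)
                outward = v / nv if nv > 0 else np.array([1.0, 0.0])
                edge = p + strut_thickness_mm * outward
                d = lum.exterior.distance(Point(edge))
                signed = d if lum.contains(Point(edge)) else -d
                s.malapposition_mm = float(signed)
                frame_mal.append(float(signed))
                n_total += 1
                if signed > malappose_threshold_mm:
                    n_unapposed += 1
        malapp.append(frame_mal)

        if len(struts) >= 3:
            spoly = _strut_polygon(
                struts, np.asarray(_as_polygon(poly).centroid.coords[0])
                if poly is not None else np.zeros(2))
            area, _, mn, mx = contour_metrics(spoly)
            csa.append(area)
            dmin.append(mn)
            dmax.append(mx)
            if poly is not None:
                la = _as_polygon(poly).area
                rest.append(float(np.clip(100.0 * (area - la) / area, 0.0, None)))
            else:
                rest.append(None)
        else:
            csa.append(None)
            dmin.append(None)
            dmax.append(None)
            rest.append(None)

    # fracture: strut-free runs strictly inside the stented extent
    fractures: List[Tuple[int, int]] = []
    if stented_extent is not None:
        f0, f1 = stented_extent
        run_start = None
        for f in range(f0, f1 + 1):
            empty = len(struts_by_frame.get(f, [])) == 0
            if empty and f0 < f:
                if run_start is None:
                    run_start = f
            if (not empty or f == f1) and run_start is not None:
                run_end = f - 1 if not empty else f
                if run_end < f1 and run_end - run_start + 1 >= gap_frames:
                    fractures.append((run_start, run_end))
                run_start = None

    pct = 100.0 * n_unapposed / n_total if n_total else 0.0
    return StentMetrics(stent_csa_mm2=csa, min_diameter_mm=dmin,
                        max_diameter_mm=dmax, malapposition_mm=malapp,
                        pct_unapposed=pct, restenosis_burden_pct=rest,
                        fracture_gaps=fractures)
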