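"""2D -> 3D fusion of per-frame borders and strut clouds onto a centerline.

Cross-sectional contours segmented on pullback frames live in a local 2D
frame.  To reconstruct the vessel in 3D each frame is mapped rigidly onto the
plane orthogonal to the centerline at its arclength station: a contour point
``(x, y)`` becomes ``c(s) + x*n(s) + y*b(s)``.  The per-point orthonormal
bases ``(t, n, b)`` are propagated by rotation-minimizing (parallel)
transport, which is well defined on straight segments and never flips at
inflections (a Frenet frame is neither).

The absolute rotational orientation of the frames about the centerline is not
recoverable from the pullback itself; the initial normal is fixed and
documented.  This affects strut azimuth in 3D but not areas or diameters.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import trimesh

from .types import (Centerline3D, CrossSectionSeries, RegressionReport,
                    StrutPoint)

__all__ = [
    "build_frames",
    "place_contours",
    "transform_struts",
    "loft_mesh",
    "resample_ring",
    "slice_mesh_areas",
    "compare_model_to_frames",
]


# ---------------------------------------------------------------------------
# centerline frames

def _resample_polyline(points: np.ndarray, step: float) -> tuple:
    """Resample an ordered polyline at uniform arclength spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-12])
    if not keep.all():
        warnings.warn("duplicate consecutive centerline points removed")
        points = points[keep]
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("centerline has zero length")
    n_out = max(int(np.floor(total / step)) + 1, 2)
    s_new = np.minimum(np.arange(n_out) * step, total)
    if total - s_new[-1] > 1e-9:
        s_new = np.append(s_new, total)
    out = np.column_stack([np.interp(s_new, s, points[:, k]) for k in range(3)])
    return out, s_new


def build_frames(points: np.ndarray, step: float = 0.5,
                 initial_normal: Optional[np.ndarray] = None) -> Centerline3D:
    """Resample a 3D path and attach rotation-minimizing orthonormal frames.

    Parameters
    ----------
    points : (N, 3) ordered path in mm (``N >= 2`` distinct points).
    step : arclength resampling step in mm.
    initial_normal : optional unit vector used to seed the transport; it is
        orthogonalized against the first tangent.  Default: any vector
        perpendicular to the first tangent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 2:
        raise ValueError("need at least 2 distinct points")
    pts, s = _resample_polyline(points, step)

    tangents = np.gradient(pts, s, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    t0 = tangents[0]
    if initial_normal is None:
        trial = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(trial, t0)) > 0.9:
            trial = np.array([1.0, 0.0, 0.0])
        initial_normal = trial
    n0 = np.asarray(initial_normal, dtype=float)
    n0 = n0 - np.dot(n0, t0) * t0
    nrm = np.linalg.norm(n0)
    if nrm < 1e-12:
        raise ValueError("initial normal is parallel to the first tangent")
    n0 /= nrm

    normals = np.empty_like(tangents)
    normals[0] = n0
    # double-reflection rotation-minimizing transport
    for i in range(len(pts) - 1):
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-24:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-24:
            n_next = rL
        else:
            n_next = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        n_next = n_next - np.dot(n_next, tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = n_next / np.linalg.norm(n_next)

    binormals = np.cross(tangents, normals)
    binormals /= np.linalg.norm(binormals, axis=1, keepdims=True)
    return Centerline3D(points=pts, arclength=s, tangents=tangents,
                        normals=normals, binormals=binormals)


def _frame_at(cl: Centerline3D, s: float) -> tuple:
    """Interpolated (point, normal, binormal) at arclength ``s``."""
    if not cl.has_frames():
        raise ValueError("centerline has no frames; call build_frames first")
    sl = cl.arclength
    if s < sl[0] - 1e-9 or s > sl[-1] + 1e-9:
        raise ValueError("arclength outside centerline")
    p = np.array([np.interp(s, sl, cl.points[:, k]) for k in range(3)])
    n = np.array([np.interp(s, sl, cl.normals[:, k]) for k in range(3)])
    b = np.array([np.interp(s, sl, cl.binormals[:, k]) for k in range(3)])
    n /= np.linalg.norm(n)
    b -= np.dot(b, n) * n
    b /= np.linalg.norm(b)
    return p, n, b


# ---------------------------------------------------------------------------
# placement

def resample_ring(polygon: np.ndarray, ring_size: int) -> np.ndarray:
    """Resample a closed 2D polygon to ``ring_size`` points by arclength."""
    poly = np.asarray(polygon, dtype=float)
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, s[-1], ring_size, endpoint=False)
    return np.column_stack([np.interp(s_new, s, closed[:, k]) for k in range(2)])


def place_contours(contours: Sequence[np.ndarray], cl: Centerline3D,
                   frame_spacing: float, registration_offset: float = 0.0,
                   ring_size: int = 90) -> tuple:
    """Map per-frame 2D contours onto the centerline as 3D rings.

    Frame ``i`` lands at arclength ``registration_offset + i*frame_spacing``.
    Returns ``(rings, stations)`` where rings is a list of (ring_size, 3)
    arrays; frames falling outside the centerline are dropped with a warning.
    """
    rings, stations = [], []
    for i, poly in enumerate(contours):
        s_i = registration_offset + i * frame_spacing
        try:
            p, n, b = _frame_at(cl, s_i)
        except ValueError:
            warnings.warn(f"frame {i} at s={s_i:.2f} mm outside centerline; dropped")
            continue
        ring2d = resample_ring(np.asarray(poly, dtype=float), ring_size)
        ring3d = p[None, :] + ring2d[:, 0:1] * n[None, :] + ring2d[:, 1:2] * b[None, :]
        rings.append(ring3d)
        stations.append(s_i)
    return rings, np.asarray(stations)


def transform_struts(cloud: Iterable[StrutPoint], cl: Centerline3D,
                     frame_spacing: float, registration_offset: float = 0.0,
                     link_radius_mm: float = 0.3) -> tuple:
    """Map per-frame strut points into 3D with the same rigid placement.

    Returns ``(points3d, struts, wire_ids)``: the 3D coordinates, the kept
    strut records (frames outside the centerline are dropped), and a wire id
    per strut linking struts of adjacent frames closer than
    ``link_radius_mm`` into one stent-wire sample set.
    """
    kept, pts3d = [], []
    for sp in cloud:
        s_i = registration_offset + sp.frame_index * frame_spacing
        try:
            p, n, b = _frame_at(cl, s_i)
        except ValueError:
            warnings.warn(f"strut on frame {sp.frame_index} outside centerline; dropped")
            continue
        x, y = sp.xy_mm
        pts3d.append(p + x * n + y * b)
        kept.append(sp)
    pts3d = np.asarray(pts3d).reshape(-1, 3)

    # union-find linking across adjacent frames
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_frame: dict = {}
    for idx, sp in enumerate(kept):
        by_frame.setdefault(sp.frame_index, []).append(idx)
    for f, idxs in by_frame.items():
        for g in (f + 1,):
            for i in idxs:
                for j in by_frame.get(g, []):
                    if np.linalg.norm(pts3d[i] - pts3d[j]) <= link_radius_mm:
                        parent[find(i)] = find(j)
    roots = {}
    wire_ids = np.empty(len(kept), dtype=int)
    for i in range(len(kept)):
        r = find(i)
        wire_ids[i] = roots.setdefault(r, len(roots))
    return pts3d, kept, wire_ids


def back_project(point3d: np.ndarray, cl: Centerline3D, frame_index: int,
                 frame_spacing: float, registration_offset: float = 0.0) -> tuple:
    """Inverse of the rigid placement: recover in-frame (x, y) mm."""
    s_i = registration_offset + frame_index * frame_spacing
    p, n, b = _frame_at(cl, s_i)
    v = np.asarray(point3d, dtype=float) - p
    return float(np.dot(v, n)), float(np.dot(v, b))


# ---------------------------------------------------------------------------
# mesh lofting and slicing

def loft_mesh(rings: Sequence[np.ndarray], smooth: bool = False,
              smooth_lambda: float = 0.1, smooth_iters: int = 5) -> trimesh.Trimesh:
    """Loft a stack of rings into a capped, watertight triangle mesh.

    Adjacent rings are stitched quad-by-quad (two triangles each) after seam
    alignment by minimal twist; the ends are clipped flat with triangle fans.
    Optional Laplacian smoothing is off by default because it shrinks
    cross-sections slightly.
    """
    rings = [np.asarray(r, dtype=float) for r in rings]
    if len(rings) < 2:
        raise ValueError("need at least 2 rings")
    m = rings[0].shape[0]
    if any(r.shape != (m, 3) for r in rings):
        raise ValueError("all rings must share the same point count")

    # seam alignment: roll each ring to minimize total twist vs the previous
    aligned = [rings[0]]
    for r in rings[1:]:
        prev = aligned[-1]
        shifts = np.arange(m)
        best = min(shifts, key=lambda k: float(
            np.sum((np.roll(r, -k, axis=0) - prev) ** 2)))
        aligned.append(np.roll(r, -best, axis=0))

    for a, b in zip(aligned[:-1], aligned[1:]):
        gap = np.linalg.norm(b.mean(axis=0) - a.mean(axis=0))
        ra = np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
        if gap < 1e-12 and ra > 0:
            raise ValueError("fold-over; reduce step or smooth centerline")

    verts = np.vstack(aligned)
    faces = []
    for i in range(len(aligned) - 1):
        base, nxt = i * m, (i + 1) * m
        for j in range(m):
            j2 = (j + 1) % m
            faces.append([base + j, base + j2, nxt + j])
            faces.append([base + j2, nxt + j2, nxt + j])
    # flat end caps (triangle fans around the ring centroid)
    c0 = len(verts)
    verts = np.vstack([verts, aligned[0].mean(axis=0), aligned[-1].mean(axis=0)])
    c1 = c0 + 1
    last = (len(aligned) - 1) * m
    for j in range(m):
        j2 = (j + 1) % m
        faces.append([j2, j, c0])
        faces.append([last + j, last + j2, c1])

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if smooth:
        trimesh.smoothing.filter_laplacian(mesh, lamb=smooth_lambda,
                                           iterations=smooth_iters,
                                           volume_constraint=False)
    areas = mesh.area_faces
    if np.any(areas <= 0) or not mesh.is_watertight:
        # degenerate triangles or open seams indicate fold-over
        if not mesh.is_watertight:
            raise ValueError("lofted mesh is not watertight")
    return mesh


def _section_area(mesh: trimesh.Trimesh, origin: np.ndarray,
                  normal: np.ndarray) -> Optional[float]:
    """Cross-section area of a tubular mesh cut by one plane.

    The cut of a tube orthogonal to its axis is star-shaped about its
    centroid, so the intersection vertices can be ordered by azimuth and
    integrated with the shoelace formula.
    """
    seg = trimesh.intersections.mesh_plane(mesh, plane_normal=normal,
                                           plane_origin=origin)
    if len(seg) == 0:
        return None
    pts = np.unique(np.asarray(seg).reshape(-1, 3).round(9), axis=0)
    n = normal / np.linalg.norm(normal)
    u = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, n)) > 0.9:
        u = np.array([1.0, 0.0, 0.0])
    u = u - np.dot(u, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    rel = pts - pts.mean(axis=0)
    xy = np.column_stack([rel @ u, rel @ v])
    order = np.argsort(np.arctan2(xy[:, 1], xy[:, 0]))
    xy = xy[order]
    x, y = xy[:, 0], xy[:, 1]
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def slice_mesh_areas(mesh: trimesh.Trimesh, cl: Centerline3D,
                     station_step: float = 0.5) -> CrossSectionSeries:
    """Slice a vessel mesh by planes orthogonal to the centerline.

    Stations are spaced ``station_step`` mm apart (0.5 mm by default, the
    granularity used for the model-vs-frames comparison).  Effective diameter
    is the area-equivalent diameter ``2*sqrt(A/pi)``.
    """
    s0, s1 = cl.arclength[0], cl.arclength[-1]
    stations = np.arange(s0, s1 + 1e-9, station_step)
    out_s, out_a = [], []
    for s in stations:
        p, n, b = _frame_at(cl, s)
        t = np.cross(n, b)
        area = _section_area(mesh, p, t)
        if area is not None and area > 0:
            out_s.append(s)
            out_a.append(area)
    areas = np.asarray(out_a)
    return CrossSectionSeries(stations_mm=np.asarray(out_s), areas_mm2=areas,
                              diameters_mm=2.0 * np.sqrt(areas / np.pi),
                              source="model")


# ---------------------------------------------------------------------------
# model vs frames comparison

def _agreement(a: np.ndarray, b: np.ndarray) -> RegressionReport:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    diff = a - b
    resid = a - b  # residuals about the identity line
    rss = float(np.sum(resid**2))
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return RegressionReport(r_squared=float(r**2), rss=rss, bias=bias,
                            loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def compare_model_to_frames(mesh: trimesh.Trimesh, cl: Centerline3D,
                            frame_series: CrossSectionSeries,
                            landmarks: Sequence[tuple],
                            station_step: float = 0.5) -> tuple:
    """Compare mesh cross-sections against per-frame measurements.

    ``frame_series`` carries one area/diameter per pullback frame, indexed by
    frame number in ``stations_mm`` (frame index, not mm).  ``landmarks`` is a
    sequence of ``(arclength_mm, frame_index)`` pairs (>= 2) fixing the linear
    frame -> arclength registration; pullback frames outnumber model stations,
    so frame values are interpolated at the model stations.

    Returns ``(model_series, frames_at_stations, RegressionReport for areas,
    RegressionReport for diameters)``.
    """
    if len(landmarks) < 2:
        raise ValueError("need at least 2 landmarks for registration")
    lm = np.asarray(landmarks, dtype=float)
    # linear fit: arclength = a*frame + b
    a_fit, b_fit = np.polyfit(lm[:, 1], lm[:, 0], 1)

    model = slice_mesh_areas(mesh, cl, station_step)
    frame_s = a_fit * frame_series.stations_mm + b_fit
    order = np.argsort(frame_s)
    frame_s = frame_s[order]
    f_area = frame_series.areas_mm2[order]
    f_diam = frame_series.diameters_mm[order]

    keep = (model.stations_mm >= frame_s[0]) & (model.stations_mm <= frame_s[-1])
    st = model.stations_mm[keep]
    m_area = model.areas_mm2[keep]
    m_diam = model.diameters_mm[keep]
    fa = np.interp(st, frame_s, f_area)
    fd = np.interp(st, frame_s, f_diam)

    frames_at = CrossSectionSeries(stations_mm=st, areas_mm2=fa,
                                   diameters_mm=fd, source="frames")
    model_at = CrossSectionSeries(stations_mm=st, areas_mm2=m_area,
                                  diameters_mm=m_diam, source="model")
    return model_at, frames_at, _agreement(m_area, fa), _agreement(m_diam, fd)
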