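"""3D fusion: frame transport, rigid placement, lofting, slicing, comparison."""

import numpy as np
import pytest

from corokit import fusion3d as f3
from corokit.types import CrossSectionSeries, StrutPoint


def circle_polygon(r, n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestBuildFrames:
    def test_straight_line_normals_identical(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 10.0]]), step=0.5)
        assert np.allclose(cl.normals, cl.normals[0])

    def test_planar_circle_normals_stay_in_plane(self):
        t = np.linspace(0, 2 * np.pi, 400)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)])
        # seed with an in-plane (radial) normal
        cl = f3.build_frames(pts, step=0.2, initial_normal=np.array([1.0, 0, 0]))
        assert np.abs(cl.normals[:, 2]).max() < 1e-6
        dots = np.sum(cl.normals[:-1] * cl.normals[1:], axis=1)
        rot = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert rot.max() < 30.0  # no flips over the full revolution

    def test_orthonormal_frames(self):
        t = np.linspace(0, 4 * np.pi, 300)
        pts = np.column_stack([3 * np.cos(t), 3 * np.sin(t), 2 * t])
        cl = f3.build_frames(pts, step=0.3)
        for v, w in [(cl.tangents, cl.normals), (cl.tangents, cl.binormals),
                     (cl.normals, cl.binormals)]:
            assert np.abs(np.sum(v * w, axis=1)).max() < 1e-9
        assert np.allclose(np.linalg.norm(cl.normals, axis=1), 1.0)

    def test_resampled_spacing(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 7.03]]), step=0.5)
        d = np.diff(cl.arclength)
        assert np.allclose(d[:-1], 0.5, atol=1e-6)

    def test_duplicate_points_removed_with_warning(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 5.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            cl = f3.build_frames(pts, step=0.5)
        assert cl.length == pytest.approx(5.0)


class TestPlacement:
    def test_circles_on_straight_line(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 10.0]]), step=0.25)
        poly = circle_polygon(1.5)
        rings, st = f3.place_contours([poly] * 3, cl, frame_spacing=1.0,
                                      registration_offset=2.0)
        assert np.allclose(st, [2.0, 3.0, 4.0])
        for ring, s in zip(rings, st):
            assert np.allclose(ring[:, 2], s, atol=1e-9)
            radii = np.linalg.norm(ring[:, :2], axis=1)
            assert np.allclose(radii, 1.5, atol=1e-9)

    def test_ring_area_preserved_by_isometry(self):
        t = np.linspace(0, np.pi, 100)
        curved = np.column_stack([5 * np.cos(t), 5 * np.sin(t), t])
        cl = f3.build_frames(curved, step=0.2)
        poly = circle_polygon(2.0, 180)
        rings, _ = f3.place_contours([poly], cl, frame_spacing=0.5,
                                     registration_offset=1.0, ring_size=180)
        ring = rings[0]
        c = ring.mean(axis=0)
        # area via the cross-product sum (planar ring)
        v = ring - c
        area = 0.5 * np.linalg.norm(np.sum(np.cross(v, np.roll(v, -1, axis=0)),
                                           axis=0))
        x, y = poly[:, 0], poly[:, 1]
        poly_area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area == pytest.approx(poly_area, rel=1e-6)

    def test_centered_contour_centroids_on_centerline(self):
        t = np.linspace(0, np.pi, 200)
        curved = np.column_stack([8 * np.cos(t), 8 * np.sin(t), 2 * t])
        cl = f3.build_frames(curved, step=0.1)
        poly = circle_polygon(1.0, 720)
        rings, st = f3.place_contours([poly] * 5, cl, frame_spacing=1.0,
                                      registration_offset=3.0)
        for ring, s in zip(rings, st):
            i = np.argmin(np.abs(cl.arclength - s))
            assert np.linalg.norm(ring.mean(axis=0) - cl.points[i]) < 1e-6

    def test_out_of_range_frame_dropped(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 2.0]]), step=0.25)
        with pytest.warns(UserWarning, match="dropped"):
            rings, st = f3.place_contours([circle_polygon(1.0)] * 5, cl,
                                          frame_spacing=1.0)
        assert len(rings) == 3  # s = 0, 1, 2 fit; 3 and 4 dropped


class TestStruts:
    @staticmethod
    def _cloud(n_frames=4, r=1.6, n=8):
        pts = []
        for f in range(n_frames):
            for k in range(n):
                th = 2 * np.pi * k / n
                pts.append(StrutPoint(frame_index=f, aline_index=int(th * 180 / np.pi),
                                      depth_px=100.0,
                                      xy_mm=(r * np.cos(th), r * np.sin(th)),
                                      cluster_id=k))
        return pts

    def test_cylinder_radius_preserved(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 10.0]]), step=0.25)
        cloud = self._cloud()
        pts3d, kept, wires = f3.transform_struts(cloud, cl, frame_spacing=0.2)
        radii = np.linalg.norm(pts3d[:, :2], axis=1)
        assert np.allclose(radii, 1.6, atol=1e-12)
        # struts aligned across adjacent frames (0.2 mm < 0.3 mm link radius)
        # merge into 8 stent wires
        assert len(set(wires)) == 8

    def test_back_projection_roundtrip(self):
        t = np.linspace(0, np.pi, 200)
        curved = np.column_stack([8 * np.cos(t), 8 * np.sin(t), 2 * t])
        cl = f3.build_frames(curved, step=0.1)
        cloud = self._cloud(n_frames=3)
        pts3d, kept, _ = f3.transform_struts(cloud, cl, frame_spacing=1.0,
                                             registration_offset=2.0)
        for p3, sp in zip(pts3d, kept):
            x, y = f3.back_project(p3, cl, sp.frame_index, 1.0, 2.0)
            assert abs(x - sp.xy_mm[0]) < 1e-9
            assert abs(y - sp.xy_mm[1]) < 1e-9

    def test_helix_in_frame_distances_preserved(self):
        t = np.linspace(0, 4 * np.pi, 400)
        helix = np.column_stack([6 * np.cos(t), 6 * np.sin(t), 3 * t])
        cl = f3.build_frames(helix, step=0.2)
        cloud = self._cloud(n_frames=1)
        pts3d, kept, _ = f3.transform_struts(cloud, cl, frame_spacing=1.0,
                                             registration_offset=5.0)
        xy = np.array([s.xy_mm for s in kept])
        d2 = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        d3 = np.linalg.norm(pts3d[:, None] - pts3d[None, :], axis=-1)
        assert np.allclose(d2, d3, atol=1e-9)


class TestLoft:
    def test_cylinder_lateral_area(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 5.0]]), step=0.25)
        poly = circle_polygon(2.0, 360)
        rings, _ = f3.place_contours([poly, poly], cl, frame_spacing=1.0,
                                     ring_size=360)
        mesh = f3.loft_mesh(rings)
        ngon_area = 0.5 * 360 * 4.0 * np.sin(2 * np.pi / 360)
        lateral = mesh.area - 2 * ngon_area
        assert abs(lateral - 2 * np.pi * 2.0 * 1.0) / (2 * np.pi * 2.0) < 0.005

    def test_watertight_euler(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 5.0]]), step=0.25)
        rings, _ = f3.place_contours([circle_polygon(1.0)] * 4, cl,
                                     frame_spacing=1.0)
        mesh = f3.loft_mesh(rings)
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_smoothing_shrinks_below_one_percent(self):
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, 10.0]]), step=0.25)
        rings, _ = f3.place_contours([circle_polygon(2.0)] * 11, cl,
                                     frame_spacing=1.0)
        plain = f3.loft_mesh(rings)
        smooth = f3.loft_mesh(rings, smooth=True)
        # slice strictly inside the tube, away from the clipped ends
        slicer = f3.build_frames(np.array([[0, 0, 2.0], [0, 0, 8.0]]), step=0.25)
        s0 = f3.slice_mesh_areas(plain, slicer)
        s1 = f3.slice_mesh_areas(smooth, slicer)
        common = np.intersect1d(s0.stations_mm, s1.stations_mm)
        a0 = s0.areas_mm2[np.isin(s0.stations_mm, common)]
        a1 = s1.areas_mm2[np.isin(s1.stations_mm, common)]
        shrink = (a0 - a1) / a0
        assert np.all(shrink < 0.01)
        assert np.all(shrink > -0.005)

    def test_too_few_rings_rejected(self):
        with pytest.raises(ValueError):
            f3.loft_mesh([circle_polygon(1.0)])


class TestCompare:
    def _mesh_and_cl(self, areas_prof):
        n = len(areas_prof)
        cl = f3.build_frames(np.array([[0, 0, 0], [0, 0, (n - 1) * 0.2]]),
                             step=0.1)
        polys = [circle_polygon(np.sqrt(a / np.pi)) for a in areas_prof]
        rings, _ = f3.place_contours(polys, cl, frame_spacing=0.2)
        return f3.loft_mesh(rings), cl

    def test_self_comparison_identity(self):
        areas = 4.0 + 2.0 * np.sin(np.linspace(0, np.pi, 40))
        mesh, cl = self._mesh_and_cl(areas)
        series = CrossSectionSeries(np.arange(40, dtype=float), areas,
                                    2 * np.sqrt(areas / np.pi), "frames")
        landmarks = [(0.0, 0), (39 * 0.2, 39)]
        _, _, rep_a, rep_d = f3.compare_model_to_frames(mesh, cl, series,
                                                        landmarks)
        assert rep_a.r_squared >= 0.99
        assert abs(rep_a.bias) < 0.05

    def test_cylinder_station_areas(self):
        mesh, cl = self._mesh_and_cl(np.full(26, 4 * np.pi))
        out = f3.slice_mesh_areas(mesh, cl, 0.5)
        assert np.all(np.abs(out.areas_mm2 - 4 * np.pi) / (4 * np.pi) < 0.005)

    def test_fewer_than_two_landmarks_rejected(self):
        mesh, cl = self._mesh_and_cl(np.full(10, 4.0))
        series = CrossSectionSeries(np.arange(10, dtype=float), np.full(10, 4.0),
                                    np.full(10, 2.0), "frames")
        with pytest.raises(ValueError, match="landmark"):
            f3.compare_model_to_frames(mesh, cl, series, [(0.0, 0)])
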