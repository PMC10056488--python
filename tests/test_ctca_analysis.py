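"""CTCA chain: vesselness, centerline, weight calibration, level set, stent."""

import numpy as np
import pytest
from scipy import ndimage

from corokit import ctca_analysis as ca
from corokit.phantom import CTPhantomSpec, synth_ct_volume
from corokit.types import Volume3D


@pytest.fixture(scope="module")
def tube():
    """Plain noiseless straight tube, 48x48x80 voxels at 0.25 mm."""
    spec = CTPhantomSpec(shape=(48, 48, 80), spacing_mm=0.25, seed=3)
    vol, truth = synth_ct_volume(spec)
    return spec, vol, truth


@pytest.fixture(scope="module")
def tube_vesselness(tube):
    _, vol, _ = tube
    return ca.vesselness_preprocess(vol, [1.0, 1.5, 2.0])


def _seeds_from_truth(truth, rng_seed=0, n=30):
    lab = truth.labels.labels
    rng = np.random.default_rng(rng_seed)

    def pick(code):
        idx = np.argwhere(lab == code)
        return idx[rng.choice(len(idx), min(n, len(idx)), replace=False)]

    return pick


class TestVesselness:
    def test_constant_volume_zero_response(self):
        vol = Volume3D(values=np.full((20, 20, 20), 100.0), spacing=(1, 1, 1))
        out = ca.vesselness_preprocess(vol, [1.5])
        assert np.allclose(out.values, 0.0)

    def test_tube_response_concentrated_on_axis(self):
        """Bare bright cylinder r = 1.5 mm: centerline response dominates the
        response two radii off-axis by more than 5x."""
        sp = 0.25
        ii, jj = np.mgrid[0:48, 0:48]
        d = np.hypot(ii - 23.5, jj - 23.5) * sp
        vals = np.where(d <= 1.5, 300.0, 0.0)[:, :, None] * np.ones(80)
        vol = Volume3D(values=vals, spacing=(sp, sp, sp))
        v = ca.vesselness_preprocess(vol, [1.0, 1.5, 2.0]).values
        on_axis = v[23, 23, 30:50].mean()
        off = v[35, 23, 30:50].mean()  # 2r = 3 mm = 12 voxels off-axis
        assert on_axis > 5 * off

    def test_offset_invariance(self, tube, tube_vesselness):
        _, vol, _ = tube
        shifted = Volume3D(values=vol.values + 100.0, spacing=vol.spacing)
        out = ca.vesselness_preprocess(shifted, [1.0, 1.5, 2.0])
        denom = max(tube_vesselness.values.max(), 1e-12)
        assert np.max(np.abs(out.values - tube_vesselness.values)) / denom <= 0.01

    def test_sub_voxel_scale_skipped(self, tube):
        _, vol, _ = tube
        with pytest.warns(UserWarning, match="skipped"):
            out = ca.vesselness_preprocess(vol, [0.1, 1.5])
        assert out.values.max() > 0


class TestCenterline:
    def test_straight_tube_deviation_below_one_voxel(self, tube, tube_vesselness):
        spec, _, truth = tube
        c = int((spec.shape[0] - 1) // 2)
        cl = ca.extract_centerline(tube_vesselness, (c, c, 3), (c, c, 76))
        axis_mm = (np.asarray(spec.shape[:2]) - 1) / 2.0 * spec.spacing_mm
        dev = np.abs(cl.points[:, :2] - axis_mm).max()
        assert dev <= spec.spacing_mm

    def test_start_equals_end_single_point(self, tube_vesselness):
        cl = ca.extract_centerline(tube_vesselness, (23, 23, 40), (23, 23, 40))
        assert cl.n_points == 1

    def test_helix_arclength_within_3pct(self):
        spec = CTPhantomSpec(shape=(56, 56, 80), spacing_mm=0.5, curve="helix",
                             helix_radius_mm=10.0, helix_pitch_mm=20.0, seed=4)
        vol, truth = synth_ct_volume(spec)
        ves = ca.vesselness_preprocess(vol, [1.0, 1.5, 2.0])
        p0 = np.round(truth.centerline.points[4] / spec.spacing_mm).astype(int)
        p1 = np.round(truth.centerline.points[-5] / spec.spacing_mm).astype(int)
        cl = ca.extract_centerline(ves, tuple(p0), tuple(p1))
        dz = abs(truth.centerline.points[-5][2] - truth.centerline.points[4][2])
        analytic = dz * np.sqrt(1 + (2 * np.pi * 10.0 / 20.0) ** 2)
        assert abs(cl.length - analytic) / analytic <= 0.03


class TestWeights:
    def test_sigmoid_half_at_midpoint(self):
        w = ca.SigmoidWeight("wall", "falling", (200.0,), (0.05,))
        assert w(np.array([200.0]))[0] == pytest.approx(0.5)
        r = ca.SigmoidWeight("cp", "rising", (500.0,), (0.05,))
        assert r(np.array([500.0]))[0] == pytest.approx(0.5)

    def test_noiseless_phantom_seeds(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        # add synthetic CP HU population by reusing wall voxels at 800 HU
        vol2 = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        cp_idx = pick(2)[:10]
        vol2.values[tuple(cp_idx.T)] = 800.0
        seeds = ca.SeedAnnotation(lumen=pick(1), wall=pick(2)[10:], cp=cp_idx)
        w = ca.calibrate_weights(vol2, seeds)
        assert w["lumen"](np.array([350.0]))[0] >= 0.9
        assert w["lumen"](np.array([60.0]))[0] <= 0.1
        assert w["lumen"](np.array([800.0]))[0] <= 0.1
        # each weight >= 0.5 on >= 90% of its own seeds
        for name, idx in (("lumen", seeds.lumen), ("wall", seeds.wall),
                          ("cp", seeds.cp)):
            vals = w[name](vol2.values[tuple(idx.T)])
            assert (vals >= 0.5 - 1e-9).mean() >= 0.9

    def test_seed_permutation_invariance(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        lum, wal = pick(1), pick(2)
        cp = pick(0)[:10]
        vol2 = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        vol2.values[tuple(cp.T)] = 900.0
        a = ca.calibrate_weights(vol2, ca.SeedAnnotation(lumen=lum, wall=wal, cp=cp))
        rng = np.random.default_rng(2)
        b = ca.calibrate_weights(vol2, ca.SeedAnnotation(
            lumen=lum[rng.permutation(len(lum))],
            wall=wal[rng.permutation(len(wal))],
            cp=cp[rng.permutation(len(cp))]))
        assert a["lumen"].midpoints == b["lumen"].midpoints
        assert a["wall"].midpoints == b["wall"].midpoints

    def test_unordered_class_means_rejected(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        with pytest.raises(ValueError, match="calibration inconsistent"):
            # CP seeds drawn from background (-50 HU) break the ordering
            ca.calibrate_weights(vol, ca.SeedAnnotation(
                lumen=pick(1), wall=pick(2), cp=pick(0)))


class TestLevelSet:
    def test_noiseless_tube_lumen_dice(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        vol2 = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        cp_idx = pick(2)[:10]
        vol2.values[tuple(cp_idx.T)] = 900.0
        seeds = ca.SeedAnnotation(lumen=pick(1), wall=pick(2)[10:], cp=cp_idx)
        w = ca.calibrate_weights(vol2, seeds)
        seg = ca.levelset_segment(vol2, w, truth.centerline)
        a = seg.labels == 1
        b = truth.labels.labels == 1
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95

    def test_zero_speed_front_never_inflates(self, tube):
        """Under w = 0.5 everywhere the only force is curvature, which can
        shrink but never inflate: the evolved region must stay inside the
        one-voxel dilation of the initial tube."""
        _, vol, truth = tube
        const = ca.SigmoidWeight("lumen", "rising", (0.0,), (0.0,))
        w = {"lumen": const, "wall": const, "cp": const}
        spacing = float(np.mean(vol.spacing))
        init = ca._tube_mask(vol.values.shape, truth.centerline, spacing)
        phi, _ = ca._evolve(np.asarray(ca._signed_distance(init)),
                            np.zeros(vol.values.shape), max_iter=100)
        final = phi < 0
        allowed = ndimage.binary_dilation(init, iterations=1)
        assert not np.any(final & ~allowed)

    def test_rerun_identical(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        vol2 = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        cp_idx = pick(2)[:10]
        vol2.values[tuple(cp_idx.T)] = 900.0
        seeds = ca.SeedAnnotation(lumen=pick(1), wall=pick(2)[10:], cp=cp_idx)
        w = ca.calibrate_weights(vol2, seeds)
        a = ca.levelset_segment(vol2, w, truth.centerline)
        b = ca.levelset_segment(vol2, w, truth.centerline)
        assert np.array_equal(a.labels, b.labels)

    def test_label_precedence_no_lumen_cp_overlap(self, tube):
        _, vol, truth = tube
        pick = _seeds_from_truth(truth)
        vol2 = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        cp_idx = pick(2)[:10]
        vol2.values[tuple(cp_idx.T)] = 900.0
        seeds = ca.SeedAnnotation(lumen=pick(1), wall=pick(2)[10:], cp=cp_idx)
        seg = ca.levelset_segment(vol2, ca.calibrate_weights(vol2, seeds),
                                  truth.centerline)
        assert not np.any((seg.labels == 1) & (seg.labels == 3))


@pytest.fixture(scope="module")
def stented():
    spec = CTPhantomSpec(shape=(48, 48, 120), spacing_mm=0.25, seed=6,
                         stent_extent_mm=(10.0, 22.0))
    vol, truth = synth_ct_volume(spec)
    return spec, vol, truth


class TestStentDetection:
    def test_extent_within_two_stations(self, stented):
        spec, vol, truth = stented
        lumen = truth.labels.labels == 1
        out = ca.detect_stent_ctca(vol, lumen, truth.centerline)
        assert out["extent_mm"] is not None
        (s0, s1), (t0, t1) = out["extent_mm"], truth.stent_extent_mm
        assert abs(s0 - t0) <= 1.0 and abs(s1 - t1) <= 1.0  # 2 stations = 1 mm

    def test_no_stent_empty_extent(self, tube):
        _, vol, truth = tube
        lumen = truth.labels.labels == 1
        out = ca.detect_stent_ctca(vol, lumen, truth.centerline)
        assert out["extent_mm"] is None

    def test_contrast_doubling_leaves_extent(self, stented):
        spec, vol, truth = stented
        boosted = Volume3D(values=vol.values.copy(), spacing=vol.spacing)
        stent_mask = truth.labels.labels == 5
        boosted.values[stent_mask] *= 2.0
        lumen = truth.labels.labels == 1
        a = ca.detect_stent_ctca(vol, lumen, truth.centerline)
        b = ca.detect_stent_ctca(boosted, lumen, truth.centerline)
        assert a["extent_mm"] == b["extent_mm"]
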