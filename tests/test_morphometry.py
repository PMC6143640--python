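import numpy as np
import pytest

from fibrequant import morphometry as mo
from fibrequant import phantoms as ph
from fibrequant.core import Mask3D


def _disc(r, pad=7):
    n = int(2 * r + 2 * pad)
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


class TestResample:
    def test_axis_aligned_bypasses_interpolation(self):
        rng = np.random.default_rng(0)
        vol, _ = ph.make_cylinder_phantom([12.0], axis=(0, 1, 0), spacing=50,
                                          shape=(32, 32, 32))
        stack, px = mo.resample_perpendicular(vol, (0, 1, 0))
        assert px == vol.voxel_size
        for k in (0, 15, 31):
            assert np.array_equal(stack[k], vol.data[:, k, :])

    def test_tilted_cylinder_circular_sections(self):
        d = np.array([0.0, 2.0, 1.0])
        d /= np.linalg.norm(d)
        vol, _ = ph.make_cylinder_phantom([16.0], axis=tuple(d), spacing=50,
                                          shape=(64, 64, 64))
        stack, px = mo.resample_perpendicular(vol, tuple(d))
        mids = [s for s in stack if (s > 125).sum() > 50]
        mid = mids[len(mids) // 2] > 125
        secs = mo.detect_sections(mid, px)
        assert len(secs) >= 1
        sec = max(secs, key=lambda s: s.area)
        assert sec.equivalent_diameter == pytest.approx(16.0, rel=0.05)
        assert sec.roundness > 0.9

    def test_volume_preserved(self):
        d = np.array([1.0, 3.0, 0.5])
        d /= np.linalg.norm(d)
        vol, _ = ph.make_cylinder_phantom([14.0], axis=tuple(d), spacing=50,
                                          shape=(48, 48, 48))
        fg = (vol.data > 125).sum()
        stack, _ = mo.resample_perpendicular(vol, tuple(d))
        fg_res = (stack > 125).sum()
        assert fg_res == pytest.approx(fg, rel=0.05)

    def test_non_unit_direction_errors(self):
        vol, _ = ph.make_cylinder_phantom([12.0], axis=(0, 1, 0), spacing=50,
                                          shape=(32, 32, 32))
        with pytest.raises(ValueError, match="unit"):
            mo.resample_perpendicular(vol, (0, 2, 0))


class TestDetectSections:
    def test_disc_metrics(self):
        secs = mo.detect_sections(_disc(10), pixel_size=1.0)
        assert len(secs) == 1
        s = secs[0]
        assert s.equivalent_diameter == pytest.approx(20.0, rel=0.03)
        assert s.roundness >= 0.95
        assert s.perimeter == pytest.approx(2 * np.pi * 10, rel=0.03)

    def test_square_roundness_approaches_pi_over_4(self):
        a = 80
        sq = np.zeros((a + 12, a + 12), dtype=bool)
        sq[6:6 + a, 6:6 + a] = True
        s = mo.detect_sections(sq, pixel_size=1.0)[0]
        assert s.roundness == pytest.approx(np.pi / 4, abs=0.05)

    def test_two_discs_two_sections_with_centroids(self):
        img = np.zeros((60, 90), dtype=bool)
        yy, xx = np.mgrid[:60, :90]
        img |= (yy - 25) ** 2 + (xx - 25) ** 2 <= 8**2
        img |= (yy - 35) ** 2 + (xx - 65) ** 2 <= 8**2
        secs = mo.detect_sections(img, pixel_size=2.0)
        assert len(secs) == 2
        cents = sorted(s.centroid for s in secs)
        assert cents[0] == pytest.approx((50.0, 50.0), abs=1.0)
        assert cents[1] == pytest.approx((70.0, 130.0), abs=1.0)

    def test_min_area_filter(self):
        img = np.zeros((20, 20), dtype=bool)
        img[5, 5] = True  # 1 px: below the floor
        img[10:14, 10:14] = True
        secs = mo.detect_sections(img, pixel_size=1.0, min_area_px=9)
        assert len(secs) == 1

    def test_equivalent_diameter_formula_exact(self):
        s = mo.detect_sections(_disc(12), pixel_size=3.0)[0]
        assert s.equivalent_diameter == pytest.approx(
            np.sqrt(4 * s.area / np.pi), rel=1e-12
        )

    def test_roundness_monotone_approach(self):
        xis = []
        for r in (5, 10, 20, 40):
            xis.append(mo.detect_sections(_disc(r), 1.0)[0].roundness)
        assert all(x <= 1.0 + 1e-9 for x in xis)
        assert all(xis[i] <= xis[i + 1] + 1e-9 for i in range(len(xis) - 1))

    def test_perimeter_error_below_3pct_for_d15(self):
        for r in (7.5, 10, 20, 40):
            s = mo.detect_sections(_disc(r), 1.0)[0]
            assert abs(s.perimeter - 2 * np.pi * r) / (2 * np.pi * r) < 0.03

    def test_invariance_under_rotation(self):
        img = _disc(9) | np.roll(_disc(9), 15, axis=1)
        secs0 = mo.detect_sections(img, 1.0)
        secs1 = mo.detect_sections(np.rot90(img), 1.0)
        d0 = sorted(s.equivalent_diameter for s in secs0)
        d1 = sorted(s.equivalent_diameter for s in secs1)
        assert d0 == pytest.approx(d1, rel=1e-9)


def _stacks_from_cylinders(diameters, spacing, shape=(64, 48, 64), axis=(0, 1, 0)):
    vol, _ = ph.make_cylinder_phantom(diameters, axis=axis, spacing=spacing,
                                      shape=shape)
    stack, px = mo.resample_perpendicular(vol, np.array(axis, dtype=float))
    return [
        mo.detect_sections(sl > 125, px, slice_index=k)
        for k, sl in enumerate(stack)
    ], px


class TestTracking:
    def test_parallel_cylinders_one_track_each(self):
        stacks, px = _stacks_from_cylinders([10.0, 10.0], spacing=24.0)
        tracks = mo.link_tracks(stacks, max_jump=2.0, slice_spacing=px)
        long_tracks = [t for t in tracks if len(t.slice_indices) > 5]
        assert len(long_tracks) == 2
        kept, discarded = mo.misalignment_filter(long_tracks, (1, 0, 0), 30.0)
        assert len(kept) == 2 and not discarded

    def test_tilted_cylinder_discarded(self):
        d = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)  # 45 deg off e_y
        vol, _ = ph.make_cylinder_phantom([10.0], axis=tuple(d), spacing=50,
                                          shape=(64, 64, 64))
        stack, px = mo.resample_perpendicular(vol, (0.0, 1.0, 0.0))
        stacks = [mo.detect_sections(sl > 125, px, slice_index=k)
                  for k, sl in enumerate(stack)]
        tracks = mo.link_tracks(stacks, max_jump=3.0, slice_spacing=px)
        long_tracks = [t for t in tracks if len(t.slice_indices) > 5]
        assert long_tracks
        kept, discarded = mo.misalignment_filter(long_tracks, (1, 0, 0), 30.0)
        assert discarded and not kept
        assert "misaligned" in discarded[0].discard_reason

    def test_zero_jump_gives_singletons(self):
        stacks, px = _stacks_from_cylinders([10.0], spacing=50.0)
        tracks = mo.link_tracks(stacks, max_jump=0.0, slice_spacing=px)
        assert all(len(t.slice_indices) == 1 for t in tracks)

    def test_needs_two_slices(self):
        with pytest.raises(ValueError):
            mo.link_tracks([[]], max_jump=1.0, slice_spacing=1.0)


class TestDensityAndStats:
    def test_ten_cylinders_exact_density(self):
        # 10 sections per slice in a 0.1 mm^2 slice -> 100 per mm^2
        secs = mo.detect_sections(_disc(10), 1.0)
        stacks = [[secs[0]] * 10 for _ in range(5)]
        out = mo.density_and_stats(stacks, slice_area_mm2=0.1)
        assert out["density_per_mm2"] == pytest.approx(100.0, abs=1e-12)

    def test_equal_discs_peak_equals_median(self):
        s = mo.detect_sections(_disc(10), 1.0)[0]
        out = mo.density_and_stats([[s] * 6], slice_area_mm2=1.0)
        assert out["d_e_peak_um"] == pytest.approx(out["d_e_median_um"], rel=1e-9)
        assert out["d_e_median_um"] == pytest.approx(s.equivalent_diameter)

    def test_mixture_mode_is_majority_diameter(self):
        small = mo.detect_sections(_disc(6), 1.0)[0]
        large = mo.detect_sections(_disc(14), 1.0)[0]
        out = mo.density_and_stats([[small] * 30 + [large] * 10], 1.0)
        assert out["d_e_peak_um"] == pytest.approx(small.equivalent_diameter,
                                                   rel=0.15)

    def test_slice_order_reversal_invariance(self):
        stacks, _ = _stacks_from_cylinders([10.0, 14.0], spacing=26.0)
        a = mo.density_and_stats(stacks, 0.5)
        b = mo.density_and_stats(stacks[::-1], 0.5)
        for key in ("density_per_mm2", "d_e_peak_um", "d_e_median_um"):
            assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mo.density_and_stats([[]], 1.0)


class TestSingleFibreProfile:
    def test_straight_cylinder_constant_profile(self):
        vol, _ = ph.make_cylinder_phantom([20.0], axis=(0, 1, 0), spacing=50,
                                          shape=(48, 72, 48))
        mask = Mask3D(data=vol.data > 125, voxel_size=1.0)
        prof = mo.single_fibre_profile(mask)
        assert len(prof) >= 5
        assert np.all(np.abs(prof["d_e_um"] / 20.0 - 1) < 0.05)
        assert np.all(prof["roundness"] >= 0.9)

    def test_cone_monotone_diameter(self):
        ny = 60
        data = np.zeros((48, ny, 48), dtype=bool)
        yy, xx = np.mgrid[:48, :48]
        for j in range(ny):
            r = 5 + 7 * j / (ny - 1)
            data[:, j, :] |= (yy - 24) ** 2 + (xx - 24) ** 2 <= r**2
        mask = Mask3D(data=data, voxel_size=1.0)
        t = np.linspace(4, ny - 5, 40)
        centreline = np.stack([np.full_like(t, 24.0), t,
                               np.full_like(t, 24.0)], axis=1)
        prof = mo.single_fibre_profile(mask, centreline=centreline)
        d = prof["d_e_um"].to_numpy()
        # monotone growth up to measurement jitter
        assert np.polyfit(np.arange(len(d)), d, 1)[0] > 0
        assert (np.diff(d) > -0.5).all()

    def test_wavy_tube_flat_profile(self):
        # centred quasi-sinusoidal tube of constant radius, built voxel by
        # voxel against the analytic centreline distance
        ny, r0, amp, lam = 96, 5.0, 5.0, 48.0
        t = np.arange(0, ny, 0.25)
        centreline = np.stack(
            [24.0 + amp * np.sin(2 * np.pi * t / lam), t,
             np.full_like(t, 24.0)], axis=1,
        )
        xx, yy, zz = np.mgrid[:48, :ny, :48].astype(float)
        pts = np.stack([xx, yy, zz], axis=-1)
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(centreline).query(pts.reshape(-1, 3))
        data = (dist <= r0).reshape(48, ny, 48)
        mask = Mask3D(data=data, voxel_size=1.0)
        prof = mo.single_fibre_profile(mask, centreline=centreline[::8])
        d = prof["d_e_um"].to_numpy()
        assert np.all(np.abs(d / (2 * r0) - 1) < 0.10)

    def test_branching_skeleton_errors(self):
        data = np.zeros((40, 40, 40), dtype=bool)
        data[18:23, 5:35, 18:23] = True       # main bar along y
        data[18:23, 18:23, 5:35] = True       # crossing bar along z
        mask = Mask3D(data=data, voxel_size=1.0)
        with pytest.raises(ValueError, match="branch"):
            mo.single_fibre_profile(mask)
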