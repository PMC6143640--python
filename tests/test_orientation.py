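import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibrequant import orientation as ori
from fibrequant import phantoms as ph
from fibrequant import volio
from fibrequant.core import Mask3D, Volume3D

from conftest import char_poly_eigenvalues


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestGradient:
    def test_linear_ramp(self):
        x = np.arange(16, dtype=float)
        data = np.broadcast_to(3.0 * x[:, None, None], (16, 16, 16)).copy()
        vol = Volume3D(data=data, voxel_size=2.0)
        g = ori.grey_gradient(vol)
        interior = g[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior[..., 0], 1.5)  # 3 per 2 µm
        assert np.allclose(interior[..., 1:], 0.0)

    def test_constant_volume_zero_gradient(self):
        vol = Volume3D(data=np.full((8, 8, 8), 5.0), voxel_size=1.0)
        assert np.allclose(ori.grey_gradient(vol), 0.0)

    def test_sine_max_derivative(self):
        L = 32
        x = np.arange(L, dtype=float)
        data = np.broadcast_to(np.sin(2 * np.pi * x / L)[:, None, None],
                               (L, 8, 8)).copy()
        vol = Volume3D(data=data, voxel_size=1.0)
        g = ori.grey_gradient(vol)[..., 0]
        analytic = 2 * np.pi / L
        # centred differences attenuate by sinc(2/L) and the sample grid may
        # miss the exact crest: allow a few percent of discretisation error
        assert abs(g.max() - analytic) < 0.05 * analytic

    def test_too_small_grid_errors(self):
        vol = Volume3D(data=np.zeros((2, 8, 8)), voxel_size=1.0)
        with pytest.raises(ValueError):
            ori.grey_gradient(vol)


class TestStructureTensor:
    def test_cylinder_minor_eigenvector_on_axis(self, cylinder_phantom):
        vol, _ = cylinder_phantom
        mask = volio.threshold_volume(vol, "otsu")
        S = ori.structure_tensor_field(ori.grey_gradient(vol), 9)
        # interior voxel on the cylinder axis
        sel = S[24, 24, 24]
        w, v = np.linalg.eigh(sel)
        minor = v[:, 0]
        ang = np.degrees(np.arccos(abs(minor @ [0, 1, 0])))
        assert ang < 3.0

    def test_zero_gradient_zero_tensor(self):
        g = np.zeros((8, 8, 8, 3))
        S = ori.structure_tensor_field(g, 3)
        assert np.allclose(S, 0.0)

    def test_symmetric_psd(self, rng):
        g = rng.normal(size=(12, 12, 12, 3))
        S = ori.structure_tensor_field(g, 5)
        assert np.allclose(S, np.swapaxes(S, -1, -2))
        w = np.linalg.eigvalsh(S.reshape(-1, 3, 3))
        assert w.min() > -1e-9

    def test_isotropic_noise_ratio_grows_with_window(self):
        ratios = {}
        for w in (5, 15):
            acc = []
            for seed in range(3):
                r = np.random.default_rng(seed)
                vol = Volume3D(data=r.normal(100, 20, (40, 40, 40)), voxel_size=1.0)
                S = ori.structure_tensor_field(ori.grey_gradient(vol), w)
                core = S[12:-12, 12:-12, 12:-12].reshape(-1, 3, 3)
                ev = np.linalg.eigvalsh(core)
                acc.append(float((ev[:, 0] / ev[:, 2]).mean()))
            ratios[w] = np.mean(acc)
        assert ratios[15] > ratios[5] > 0.4
        assert ratios[15] > 0.75  # approaching 1 in expectation

    def test_even_window_errors(self):
        with pytest.raises(ValueError):
            ori.structure_tensor_field(np.zeros((8, 8, 8, 3)), 4)

    def test_window_larger_than_grid_errors(self):
        with pytest.raises(ValueError):
            ori.structure_tensor_field(np.zeros((8, 8, 8, 3)), 9)


class TestAngles:
    @pytest.mark.parametrize("p,expected", [
        ((0, 1, 0), (90.0, 90.0)),
        ((1, 0, 0), (90.0, 0.0)),
        ((-1, 0, 0), (90.0, 0.0)),
        ((0, 0, 1), (0.0, 0.0)),
        ((0, 0, -1), (0.0, 0.0)),
    ])
    def test_reference_directions(self, p, expected):
        th, phi = ori.angles_from_vector(np.array(p, dtype=float))
        assert (th, phi) == pytest.approx(expected)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            ori.angles_from_vector(np.zeros(3))

    @settings(max_examples=80, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_reconstruction_roundtrip(self, seed):
        p = _unit(np.random.default_rng(seed).normal(size=3))
        th, phi = ori.angles_from_vector(p)
        assert 0.0 <= th <= 180.0
        assert 0.0 <= phi < 180.0
        q = ori.vector_from_angles(th, phi)
        assert min(np.linalg.norm(q - p), np.linalg.norm(q + p)) < 1e-9

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_antipodal_identity(self, seed):
        p = _unit(np.random.default_rng(seed).normal(size=3))
        assert ori.angles_from_vector(p) == pytest.approx(
            ori.angles_from_vector(-p)
        )

    def test_canonicalise_idempotent(self, rng):
        p = rng.normal(size=(100, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        c1 = ori.canonicalise(p)
        assert np.array_equal(ori.canonicalise(c1), c1)
        assert np.all(c1[:, 1] >= 0)


class TestOrientationTensor:
    def test_delta_field(self):
        p = np.tile([0.0, 1.0, 0.0], (50, 1))
        a = ori.orientation_tensor(p)
        assert np.allclose(a.matrix, np.diag([0, 1, 0]), atol=1e-12)

    def test_three_axes_give_isotropy(self):
        p = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        a = ori.orientation_tensor(p)
        assert np.allclose(a.matrix, np.eye(3) / 3, atol=1e-12)

    def test_watson_matches_brute_force_sum(self):
        rng = np.random.default_rng(8)
        p = ph.sample_watson_axes(np.array([0, 1, 0.0]), 5.0, 10_000, rng)
        a = ori.orientation_tensor(p)
        # independent brute-force summation oracle
        acc = np.zeros((3, 3))
        for v in p:
            acc += np.outer(v, v)
        oracle = acc / len(p)
        assert np.allclose(a.matrix, oracle, atol=1e-12)
        assert abs(a.matrix[0, 0] - a.matrix[2, 2]) < 0.02

    def test_antipodal_invariance(self, rng):
        p = rng.normal(size=(500, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        a1 = ori.orientation_tensor(p)
        a2 = ori.orientation_tensor(-p)
        assert np.allclose(a1.matrix, a2.matrix, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ori.orientation_tensor(np.empty((0, 3)))

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_eigh_matches_characteristic_polynomial(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(3, 3))
        a = m @ m.T
        a /= np.trace(a)
        ours = np.sort(np.linalg.eigvalsh(a))
        oracle = char_poly_eigenvalues(a)
        assert np.allclose(ours, oracle, atol=1e-8)


class TestOrientationTensor2D:
    def test_delta_in_plane(self):
        p = np.tile([0.0, 1.0, 0.0], (20, 1))
        a = ori.orientation_tensor_2d(p, "xy")
        assert np.allclose(a.matrix, [[0, 0], [0, 1]], atol=1e-12)

    def test_isotropic_in_plane(self):
        ang = np.linspace(0, np.pi, 721)[:-1]
        p = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        a = ori.orientation_tensor_2d(p, "xy")
        assert np.allclose(a.matrix, np.eye(2) / 2, atol=1e-3)

    def test_trace_one_after_projection(self, rng):
        p = rng.normal(size=(300, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        a = ori.orientation_tensor_2d(p, "xz")
        assert np.trace(a.matrix) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_projections_error(self):
        p = np.tile([0.0, 0.0, 1.0], (5, 1))
        with pytest.raises(ValueError):
            ori.orientation_tensor_2d(p, "xy")


class TestOrientationField:
    def test_cylinder_axis_recovery(self, cylinder_phantom):
        vol, _ = cylinder_phantom
        mask = volio.threshold_volume(vol, "otsu")
        dist = volio.euclidean_distance_map(mask)
        S = ori.structure_tensor_field(ori.grey_gradient(vol), 9)
        f = ori.orientation_field(S, mask, dist, min_depth=1.0,
                                  min_coherence=0.2, window=9)
        p = f.valid_vectors()
        ang = np.degrees(np.arccos(np.clip(np.abs(p @ [0, 1, 0.0]), 0, 1)))
        assert np.mean(ang <= 3.0) >= 0.95

    def test_impossible_coherence_gives_empty_field(self, cylinder_phantom):
        vol, _ = cylinder_phantom
        mask = volio.threshold_volume(vol, "otsu")
        S = ori.structure_tensor_field(ori.grey_gradient(vol), 9)
        f = ori.orientation_field(S, mask, min_coherence=1.01, window=9)
        assert f.n_valid == 0

    def test_flip_x_maps_phi_to_supplement(self, fibre_phantom_small):
        vol, _ = fibre_phantom_small
        mask = volio.threshold_volume(vol, "otsu")
        S = ori.structure_tensor_field(ori.grey_gradient(vol), 9)
        f = ori.orientation_field(S, mask, min_coherence=0.2, window=9)

        flipped = vol.with_data(vol.data[::-1].copy())
        mask_f = volio.threshold_volume(flipped, "otsu")
        S_f = ori.structure_tensor_field(ori.grey_gradient(flipped), 9)
        f_f = ori.orientation_field(S_f, mask_f, min_coherence=0.2, window=9)

        both = f.valid & f_f.valid[::-1]
        phi_a = f.phi[both]
        phi_b = f_f.phi[::-1][both]
        expected = (180.0 - phi_a) % 180.0
        # away from the 0/180 wrap the identity is tight
        core = (phi_a > 5) & (phi_a < 175)
        assert np.quantile(np.abs(phi_b - expected)[core], 0.95) < 1.0

    def test_degenerate_tensor_marked_invalid(self):
        S = np.zeros((5, 5, 5, 3, 3))
        S[...] = np.eye(3)  # mu1 == mu2 == mu3
        mask = np.ones((5, 5, 5), dtype=bool)
        f = ori.orientation_field(S, mask, min_coherence=0.0, window=3)
        assert f.n_valid == 0


class TestODF:
    def _field_from_vectors(self, p):
        n = len(p)
        th, phi = ori.angles_from_vector(p)
        valid = np.ones((n, 1, 1), dtype=bool)
        return ori.OrientationField(
            vectors=p.reshape(n, 1, 1, 3), theta=th.reshape(n, 1, 1),
            phi=phi.reshape(n, 1, 1), coherence=np.ones((n, 1, 1)),
            valid=valid, window=0,
        )

    def test_delta_single_peak(self):
        p = np.tile([0.0, 1.0, 0.0], (400, 1))
        f = self._field_from_vectors(p)
        hist = ori.odf_histogram(f, bin_width=3.0)
        peaks = ori.find_odf_peaks(hist)
        assert len(peaks) == 1
        th, phi, _ = peaks[0]
        assert abs(th - 90.0) <= 3.0 and abs(phi - 90.0) <= 3.0

    def test_two_clusters_two_peaks(self, rng):
        a = ori.vector_from_angles(90.0, 60.0)
        b = ori.vector_from_angles(90.0, 120.0)
        p = np.concatenate([
            a + rng.normal(0, 0.03, (500, 3)),
            b + rng.normal(0, 0.03, (500, 3)),
        ])
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        f = self._field_from_vectors(p)
        hist = ori.odf_histogram(f, bin_width=3.0)
        peaks = ori.find_odf_peaks(hist)
        assert len(peaks) == 2
        phis = sorted(round(pk[1]) for pk in peaks)
        assert abs(phis[0] - 60) <= 4 and abs(phis[1] - 120) <= 4

    def test_frequencies_sum_to_one(self, rng):
        p = rng.normal(size=(300, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        f = self._field_from_vectors(p)
        hist = ori.odf_histogram(f, bin_width=5.0)
        assert hist.frequencies.sum() == pytest.approx(1.0)
        assert hist.counts.sum() == 300

    def test_bad_bin_width_errors(self):
        p = np.tile([0.0, 1.0, 0.0], (10, 1))
        f = self._field_from_vectors(p)
        with pytest.raises(ValueError):
            ori.odf_histogram(f, bin_width=7.0)


class TestAngleSummary:
    def _field(self, th, phi):
        n = len(th)
        return ori.OrientationField(
            vectors=np.zeros((n, 1, 1, 3)), theta=np.asarray(th).reshape(n, 1, 1),
            phi=np.asarray(phi).reshape(n, 1, 1), coherence=np.ones((n, 1, 1)),
            valid=np.ones((n, 1, 1), dtype=bool), window=0,
        )

    def test_delta(self):
        f = self._field([82.0] * 10, [82.0] * 10)
        s = ori.angle_summary(f)
        assert s["theta_mean"] == pytest.approx(82.0)
        assert s["theta_sd"] == pytest.approx(0.0)
        assert s["phi_mean"] == pytest.approx(82.0)

    def test_uniform_band_moments(self):
        th = np.linspace(80, 100, 20001)
        f = self._field(th, np.full_like(th, 90.0))
        s = ori.angle_summary(f)
        assert s["theta_mean"] == pytest.approx(90.0, abs=1e-6)
        assert s["theta_sd"] == pytest.approx(20 / np.sqrt(12), rel=1e-3)

    def test_sd_invariant_under_phi_shift(self, rng):
        phi = rng.uniform(40, 60, 500)
        th = rng.uniform(70, 110, 500)
        s1 = ori.angle_summary(self._field(th, phi))
        s2 = ori.angle_summary(self._field(th, phi + 20.0))
        assert s1["phi_sd"] == pytest.approx(s2["phi_sd"], abs=1e-9)
        assert s2["phi_mean"] == pytest.approx(s1["phi_mean"] + 20.0, abs=1e-9)

    def test_needs_two_voxels(self):
        with pytest.raises(ValueError):
            ori.angle_summary(self._field([10.0], [10.0]))


class TestEquivariance:
    def test_rotation_equivariance_90deg(self, fibre_phantom_small):
        vol, gt = fibre_phantom_small

        def recover(v):
            mask = volio.threshold_volume(v, "otsu")
            dist = volio.euclidean_distance_map(mask)
            S = ori.structure_tensor_field(ori.grey_gradient(v), 9)
            f = ori.orientation_field(S, mask, dist, min_depth=1.0,
                                      min_coherence=0.2, window=9)
            return ori.orientation_tensor(f).matrix

        a = recover(vol)
        # rotate 90 degrees about e_z: x -> y, y -> -x
        rot = vol.with_data(np.rot90(vol.data, k=1, axes=(0, 1)).copy())
        a_rot = recover(rot)
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        assert np.allclose(a_rot, R @ a @ R.T, atol=0.03)
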