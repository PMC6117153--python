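import dataclasses
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import random_directions, random_psd_tensor
from pvsdwi import AcquisitionParams, PhantomSpec, simulate
from pvsdwi import phantom as ph
from pvsdwi.estimation import (
    RankDeficientError,
    build_bmatrix,
    dstar_volume,
    eig_sorted,
    estimate_dstar,
    fit_tensor,
    fit_tensor_volume,
    fractional_anisotropy,
    mean_diffusivity,
    smooth_edge_preserving,
    tensor_ellipsoids,
    threshold_mask,
)
from pvsdwi.signal_model import ParameterError, axisymmetric_tensor, dwi_signal


class TestEstimateDstar:
    def test_no_attenuation(self):
        assert estimate_dstar(50.0, 50.0, 107) == 0.0

    def test_forward_inverse_worked_example(self):
        assert estimate_dstar(0.4988, 1.0, 107) == pytest.approx(0.0065, rel=1e-3)

    def test_monotone_in_signal(self):
        assert estimate_dstar(0.3, 1.0, 107) > estimate_dstar(0.5, 1.0, 107)

    def test_negative_permitted(self):
        assert estimate_dstar(1.2, 1.0, 107) < 0

    def test_nonpositive_signal_flagged(self):
        assert math.isnan(estimate_dstar(0.0, 1.0, 107))
        assert math.isnan(estimate_dstar(-1.0, 1.0, 107))

    def test_zero_b_rejected(self):
        with pytest.raises(ParameterError):
            estimate_dstar(0.5, 1.0, 0)


class TestDstarVolume:
    def test_recovers_adc_noiseless(self, noiseless_phantom, default_params):
        vol, gt = noiseless_phantom
        maps, valid = dstar_volume(vol)
        g = default_params.direction_array[0]
        mask = gt.label_map == ph.PVS
        adc = np.einsum("i,vij,j->v", g, gt.tensor_map[mask], g)
        got = maps[..., 0, 0][mask]
        assert valid[..., 0, 0][mask].all()
        assert np.allclose(got, adc, rtol=1e-9)

    def test_invalid_flagged_on_zero_background(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        _, valid = dstar_volume(vol)
        assert not valid[gt.label_map == 0].any()


class TestFitTensor:
    def test_noiseless_recovery_icosahedral(self, rng, default_params):
        D = random_psd_tensor(rng)
        g = default_params.direction_array
        b = np.full(len(g), 107.0)
        bmat = build_bmatrix(b, g)
        signals = np.array([dwi_signal(1.0, bi, gi, D) for bi, gi in zip(b, g)])
        D_hat = fit_tensor(signals, 1.0, bmat)
        assert np.allclose(D_hat, D, rtol=1e-10, atol=1e-16)

    def test_isotropic_signals_give_isotropic_tensor(self, rng):
        d = 0.0042
        g = random_directions(rng, 6)
        bmat = build_bmatrix(np.full(6, 100.0), g)
        signals = np.full(6, math.exp(-100.0 * d))
        D_hat = fit_tensor(signals, 1.0, bmat)
        assert np.allclose(D_hat, d * np.eye(3), atol=1e-12)

    def test_five_directions_rejected(self, rng):
        g = random_directions(rng, 6)[:5]
        bmat = build_bmatrix(np.full(5, 100.0), g)
        with pytest.raises(RankDeficientError, match="6"):
            fit_tensor(np.full(5, 0.5), 1.0, bmat)

    def test_coplanar_directions_rejected(self):
        ang = np.linspace(0, np.pi, 6, endpoint=False)
        g = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
        bmat = build_bmatrix(np.full(6, 100.0), g)
        with pytest.raises(RankDeficientError, match="rank"):
            fit_tensor(np.full(6, 0.5), 1.0, bmat)

    def test_nonpositive_signal_rejected(self, rng):
        g = random_directions(rng, 6)
        bmat = build_bmatrix(np.full(6, 100.0), g)
        with pytest.raises(ParameterError):
            fit_tensor(np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.0]), 1.0, bmat)

    def test_external_bmatrix_accepted(self, rng):
        # a full 3x3 b-matrix with off-axis (cross-term) contributions
        D = random_psd_tensor(rng)
        g = random_directions(rng, 8)
        bmat = build_bmatrix(rng.uniform(80, 120, 8), g)
        bmat = bmat + 1.0 * np.eye(3)  # imaging-gradient-like isotropic term
        signals = np.exp(-np.einsum("nij,ij->n", bmat, D))
        D_hat = fit_tensor(signals, 1.0, bmat)
        assert np.allclose(D_hat, D, rtol=1e-8, atol=1e-14)


class TestEigSorted:
    def test_identity(self):
        w, v = eig_sorted(np.eye(3))
        assert np.allclose(w, 1.0)
        assert np.allclose(v @ v.T, np.eye(3), atol=1e-12)

    def test_diagonal(self):
        w, v = eig_sorted(np.diag([3.0, 2.0, 1.0]))
        assert np.allclose(w, [3, 2, 1])
        assert np.allclose(np.abs(v), np.eye(3), atol=1e-12)

    def test_rotated_diagonal(self):
        R = Rotation.from_euler("xyz", [0.3, -0.5, 1.1]).as_matrix()
        D = R @ np.diag([3.0, 2.0, 1.0]) @ R.T
        w, v = eig_sorted(D)
        assert np.allclose(w, [3, 2, 1], atol=1e-12)
        for k in range(3):
            assert np.abs(v[:, k] @ R[:, k]) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_and_handedness(self, rng):
        for _ in range(20):
            D = random_psd_tensor(rng)
            w, v = eig_sorted(D)
            assert w[0] >= w[1] >= w[2]
            assert np.linalg.det(v) == pytest.approx(1.0, abs=1e-10)
            for k in range(2):
                first = v[np.flatnonzero(np.abs(v[:, k]) > 1e-12)[0], k]
                assert first >= 0


class TestScalarMetrics:
    def test_fa_isotropic(self):
        assert fractional_anisotropy(2e-3, 2e-3, 2e-3) == 0.0

    def test_fa_stick(self):
        assert fractional_anisotropy(2e-3, 0.0, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_fa_hand_computed(self):
        assert fractional_anisotropy(2e-3, 1e-3, 1e-3) == pytest.approx(0.408, abs=5e-4)

    def test_fa_all_zero_flagged(self):
        assert math.isnan(fractional_anisotropy(0.0, 0.0, 0.0))

    def test_fa_negative_rejected(self):
        with pytest.raises(ParameterError):
            fractional_anisotropy(1e-3, -1e-3, 1e-3)

    def test_md_examples(self):
        assert mean_diffusivity(5e-3, 5e-3, 5e-3) == 5e-3
        assert mean_diffusivity(2e-3, 1e-3, 1e-3) == pytest.approx(4e-3 / 3, rel=1e-12)

    def test_md_rotation_invariant(self, rng):
        D = random_psd_tensor(rng)
        R = Rotation.random(rng=np.random.default_rng(0)).as_matrix()
        w1 = np.linalg.eigvalsh(D)
        w2 = np.linalg.eigvalsh(R @ D @ R.T)
        assert mean_diffusivity(*w1) == pytest.approx(mean_diffusivity(*w2), rel=1e-12)


class TestThresholdMask:
    def test_noiseless_phantom_mask_is_exactly_fluid(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        mask = threshold_mask(vol.b0[..., 0])
        assert np.array_equal(mask, np.isin(gt.label_map, ph.FLUID_LABELS))

    def test_all_zero_image_empty_with_warning(self):
        with pytest.warns(UserWarning):
            mask = threshold_mask(np.zeros((8, 8)))
        assert not mask.any()

    def test_fixed_zero_threshold_full_mask(self):
        img = np.full((4, 4), 3.0)
        img[0, 0] = 5.0  # non-constant
        assert threshold_mask(img, method="fixed", value=0.0).all()

    def test_otsu_keeps_fluid_drops_background_and_blood(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        mask = threshold_mask(vol.b0[..., 0], method="otsu")
        fluid = np.isin(gt.label_map, ph.FLUID_LABELS)
        assert mask[fluid].all()
        assert not mask[gt.label_map == 0].any()
        assert not mask[gt.label_map == ph.BLOOD].any()

    def test_negative_image_rejected(self):
        with pytest.raises(ParameterError):
            threshold_mask(-np.ones((4, 4)))


class TestSmoothing:
    def test_radius_zero_identity(self, rng):
        img = rng.normal(size=(16, 16))
        assert np.array_equal(smooth_edge_preserving(img, 0), img)

    def test_constant_unchanged(self):
        img = np.full((16, 16), 7.0)
        assert np.allclose(smooth_edge_preserving(img, 1), img)

    def test_outlier_replaced(self):
        img = np.full((9, 9), 2.0)
        img[4, 4] = 100.0
        out = smooth_edge_preserving(img, 1)
        assert out[4, 4] == 2.0

    def test_masked_region_untouched(self):
        img = np.full((9, 9), 2.0)
        img[4, 4] = 100.0
        mask = np.zeros((9, 9), dtype=bool)
        out = smooth_edge_preserving(img, 1, mask)
        assert out[4, 4] == 100.0  # outside mask: passthrough


class TestFitTensorVolume:
    def test_noiseless_phantom_exact(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        mask = threshold_mask(vol.b0[..., 0])[..., None]
        res = fit_tensor_volume(vol, mask=mask)
        pvs = (gt.label_map == ph.PVS)[..., None] & res.valid_mask
        assert np.allclose(res.fa_map[pvs], 0.44, atol=1e-9)
        assert np.allclose(res.md_map[pvs], 0.0042, rtol=1e-9)
        assert np.allclose(res.residual[pvs], 0.0, atol=1e-10)

    def test_eigenvalues_sorted_and_md_consistent(self, noisy_phantom):
        vol, _ = noisy_phantom
        res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
        ev = res.eigenvalues[res.valid_mask]
        assert np.all(ev[:, 0] >= ev[:, 1]) and np.all(ev[:, 1] >= ev[:, 2])
        assert np.allclose(res.md_map[res.valid_mask], ev.mean(axis=1), rtol=1e-12)
        fa = res.fa_map[res.valid_mask]
        assert np.all((fa >= 0) & (fa <= 1))

    def test_tensor_at_roundtrip(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
        i, j = map(int, np.argwhere(gt.label_map == ph.SUBARACHNOID)[0])
        assert np.allclose(res.tensor_at(i, j, 0), gt.tensor_map[i, j], rtol=1e-8)

    def test_monte_carlo_recovery_smoke(self, default_spec, default_params):
        # desk-scale version of the recovery experiment (full run in acceptance)
        sigma = ph.sigma_for_snr(default_spec, default_params, 50.0)
        fas, mds = [], []
        for seed in range(5):
            spec = dataclasses.replace(default_spec, noise_sigma=sigma, seed=seed)
            vol, gt = simulate(spec, default_params)
            res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
            m = (gt.label_map == ph.PVS)[..., None] & res.valid_mask
            fas.append(np.nanmean(res.fa_map[m]))
            mds.append(np.nanmean(res.md_map[m]))
        assert abs(np.mean(fas) - 0.44) < 0.07
        assert abs(np.mean(mds) - 0.0042) / 0.0042 < 0.10


class TestRotationEquivariance:
    def test_quarter_turn_in_plane(self, default_spec, default_params):
        """Rotating geometry and directions 90 deg in-plane leaves FA/MD maps
        unchanged after inverse rotation."""
        from pvsdwi.phantom import GroundTruth, render_dwi

        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        gt = ph.build_geometry(default_spec)

        def rot_map(m):  # (i', j') = (N-1-j, i)
            return np.rot90(m, 1, axes=(0, 1))

        tens_rot = rot_map(np.einsum("ab,xybc,dc->xyad", R, gt.tensor_map, R))
        gt_rot = GroundTruth(
            rot_map(gt.label_map), tens_rot, rot_map(gt.tangent_map @ R.T)
        )
        dirs = default_params.direction_array
        params_rot = dataclasses.replace(
            default_params, directions=tuple(map(tuple, dirs @ R.T))
        )
        vol = render_dwi(gt, default_params, default_spec)
        vol_rot = render_dwi(gt_rot, params_rot, default_spec)

        res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
        res_rot = fit_tensor_volume(
            vol_rot, mask=threshold_mask(vol_rot.b0[..., 0])[..., None]
        )
        fa_back = np.rot90(res_rot.fa_map[..., 0], -1, axes=(0, 1))
        md_back = np.rot90(res_rot.md_map[..., 0], -1, axes=(0, 1))
        ok = np.isfinite(res.fa_map[..., 0])
        assert np.array_equal(ok, np.isfinite(fa_back))
        assert np.allclose(res.fa_map[..., 0][ok], fa_back[ok], atol=1e-6)
        assert np.allclose(res.md_map[..., 0][ok], md_back[ok], rtol=1e-6)


class TestEllipsoids:
    def test_isotropic_voxel_is_sphere(self, rng):
        g = random_directions(rng, 6)
        d = 0.005
        from pvsdwi.phantom import DWIVolume

        data = np.concatenate(
            [np.ones((2, 2, 1, 1)), np.full((2, 2, 1, 6), math.exp(-100 * d))], axis=-1
        )
        vol = DWIVolume(
            data, np.r_[0.0, np.full(6, 100.0)], np.vstack([np.zeros(3), g]), (1, 1, 1)
        )
        res = fit_tensor_volume(vol)
        df = tensor_ellipsoids(res)
        ax = df[["semi_axis_1", "semi_axis_2", "semi_axis_3"]].to_numpy()
        assert np.allclose(ax, d, rtol=1e-8)

    def test_pvs_long_axis_parallel_to_tangent(self, noiseless_phantom):
        vol, gt = noiseless_phantom
        res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
        df = tensor_ellipsoids(res)
        pvs_idx = {tuple(v) for v in np.argwhere(gt.label_map == ph.PVS)}
        sub = df[[(r.i0, r.i1) in pvs_idx for r in df.itertuples()]]
        assert len(sub) > 100
        for row in sub.head(50).itertuples():
            Rm = Rotation.from_quat([row.qx, row.qy, row.qz, row.qw]).as_matrix()
            v1 = Rm[:, 0]
            t = gt.tangent_map[row.i0, row.i1]
            assert abs(v1 @ t) == pytest.approx(1.0, abs=1e-6)

    def test_semi_axis_ratio_preserves_eigenvalue_ratio(self, noiseless_phantom):
        vol, _ = noiseless_phantom
        res = fit_tensor_volume(vol, mask=threshold_mask(vol.b0[..., 0])[..., None])
        df = tensor_ellipsoids(res)
        row = df.iloc[0]
        t = tuple(int(row[f"i{k}"]) for k in range(3))
        ev = res.eigenvalues[t]
        assert row.semi_axis_1 / row.semi_axis_3 == pytest.approx(ev[0] / ev[2], rel=1e-9)
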