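import numpy as np
import pytest

from ktjoint.nlgrappa import (
    KernelGeometry,
    apply_kernel,
    build_features,
    calibrate,
    _features_from_grid,
    _source_grid,
)
from ktjoint.sampling import make_sampling_plan


def _exact_model_data(rng, L=2, n_pe=48, n_kx=40, n_frames=3, R=2, geom=None, scale=0.2):
    """k-space where every missing line is an exact truncated second-order
    polynomial of the lattice lines, with a known coefficient set."""
    geom = geom or KernelGeometry(n_coils=L, orf=R, b1=0, b2=1, h1=-1, h2=1)
    w_true = {
        r: scale
        * (
            rng.standard_normal((geom.n_features, L))
            + 1j * rng.standard_normal((geom.n_features, L))
        )
        for r in geom.offsets
    }
    ksp = np.zeros((n_frames, L, n_pe, n_kx), complex)
    lattice = np.arange(0, n_pe, R)
    for t in range(n_frames):
        ksp[t][:, lattice, :] = rng.standard_normal(
            (L, len(lattice), n_kx)
        ) + 1j * rng.standard_normal((L, len(lattice), n_kx))
        for ky in range(n_pe):
            if ky % R == 0:
                continue
            r = ky % R
            feats = _features_from_grid(_source_grid(ksp[t], ky - r, geom))
            ksp[t][:, ky, :] = (feats @ w_true[r]).T
    return ksp, geom, w_true, lattice


class TestGeometry:
    @pytest.mark.parametrize(
        "L,b1,b2,h1,h2,expected",
        [
            (1, 0, 0, -1, 1, 1 + 3 + 3 + 2 + 1),  # L=1, B=1, H=3 -> 10
            (4, -1, 2, -2, 2, 1 + 80 + 80 + 64 + 48),  # L=4, B=4, H=5 -> 273
        ],
    )
    def test_feature_count(self, L, b1, b2, h1, h2, expected):
        geom = KernelGeometry(n_coils=L, orf=2, b1=b1, b2=b2, h1=h1, h2=h2)
        assert geom.n_features == expected

    def test_linear_mode_feature_count(self):
        geom = KernelGeometry(n_coils=3, orf=2, second_order=False)
        assert geom.n_features == 1 + 3 * 4 * 5

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            KernelGeometry(n_coils=2, orf=0)
        with pytest.raises(ValueError):
            KernelGeometry(n_coils=2, orf=2, h1=2, h2=-2)


class TestBuildFeatures:
    def test_zero_sources_constant_only(self):
        geom = KernelGeometry(n_coils=1, orf=2, b1=0, b2=0, h1=-1, h2=1)
        ksp = np.zeros((1, 8, 6), complex)
        f = build_features(ksp, 2, 3, geom)
        assert f[0] == 1
        assert np.all(f[1:] == 0)

    def test_feature_order_first_block(self, rng):
        # with a single source sample set to s, the first-order feature holds
        # s, the square group holds s^2
        geom = KernelGeometry(n_coils=1, orf=2, b1=0, b2=0, h1=0, h2=0)
        ksp = np.zeros((1, 8, 6), complex)
        s = 1.5 - 0.5j
        ksp[0, 2, 3] = s
        f = build_features(ksp, 2, 3, geom)
        assert f.shape == (3,)  # 1 + 1 + 1 (H=1: no products)
        assert f[1] == s and f[2] == pytest.approx(s * s)

    def test_strict_edge_mode_raises(self):
        geom = KernelGeometry(n_coils=1, orf=2, b1=-1, b2=1, edge_mode="strict")
        ksp = np.ones((1, 8, 6), complex)
        with pytest.raises(IndexError):
            build_features(ksp, 0, 2, geom)  # b=-1 row is out of bounds


class TestCalibrateApply:
    def test_exact_model_round_trip(self, rng):
        """Noiseless exact-second-order data: calibration + application fill
        the missing lines to machine precision."""
        ksp, geom, w_true, lattice = _exact_model_data(rng)
        n_frames, L, n_pe, n_kx = ksp.shape
        plan = make_sampling_plan(
            n_pe=n_pe, n_fe=n_kx, n_frames=n_frames, r1=geom.orf, r2=1,
            n_acs=20, seed=0,
        )
        kern = calibrate(ksp, geom, np.flatnonzero(plan.acs_mask), reg_rel=0.0)
        assert kern.calib_residual_rel < 1e-10
        uniform_kt = np.transpose(ksp, (1, 0, 2, 3)).copy()
        lat_mask = np.zeros((n_frames, n_pe), bool)
        lat_mask[:, lattice] = True
        stage1 = np.where(
            (lat_mask | plan.acs_mask[None, :])[None, :, :, None], uniform_kt, 0
        )
        full = apply_kernel(stage1, kern, plan, acquired_kt=uniform_kt)
        miss = ~(lat_mask | plan.acs_mask[None, :])
        err = np.linalg.norm((full - uniform_kt)[:, miss]) / np.linalg.norm(
            uniform_kt[:, miss]
        )
        assert err < 1e-8

    def test_duplicated_equations_leave_solution_unchanged(self, rng):
        ksp, geom, _, _ = _exact_model_data(rng)
        acs = np.arange(14, 34)
        k1 = calibrate(ksp, geom, acs, reg_rel=1e-8)
        k2 = calibrate(np.concatenate([ksp, ksp]), geom, acs, reg_rel=1e-8)
        for r in geom.offsets:
            np.testing.assert_allclose(k1.weights[r], k2.weights[r], rtol=1e-8)

    def test_recalibration_after_global_scaling(self, rng):
        # scaling all data by complex c changes second-order terms, but
        # recalibration restores an (almost) exact fit
        ksp, geom, _, _ = _exact_model_data(rng)
        acs = np.arange(14, 34)
        kern = calibrate(2.3j * ksp, geom, acs, reg_rel=0.0)
        assert kern.calib_residual_rel < 1e-8

    def test_underdetermined_needs_regularization(self, rng):
        ksp, geom, _, _ = _exact_model_data(rng, n_frames=1, n_kx=8)
        acs = np.arange(22, 27)  # tiny ACS: fewer equations than features
        with pytest.raises(ValueError, match="reg"):
            calibrate(ksp[:, :, :, :], geom, acs, reg_rel=0.0)

    def test_orf_one_is_identity(self, rng):
        plan = make_sampling_plan(
            n_pe=16, n_fe=8, n_frames=2, r1=1, r2=1, n_acs=4, seed=0
        )
        geom = KernelGeometry(n_coils=2, orf=1)
        kern_like = type("K", (), {"geometry": geom, "weights": {}})()
        data = rng.standard_normal((2, 2, 16, 8)).astype(complex)
        out = apply_kernel(data, kern_like, plan)
        np.testing.assert_array_equal(out, data)

    def test_acquired_locations_bit_identical(self, rng):
        ksp, geom, _, lattice = _exact_model_data(rng)
        n_frames, L, n_pe, n_kx = ksp.shape
        plan = make_sampling_plan(
            n_pe=n_pe, n_fe=n_kx, n_frames=n_frames, r1=geom.orf, r2=1,
            n_acs=20, seed=0,
        )
        kern = calibrate(ksp, geom, np.flatnonzero(plan.acs_mask), reg_rel=0.0)
        uniform_kt = np.transpose(ksp, (1, 0, 2, 3)).copy()
        lat_mask = np.zeros((n_frames, n_pe), bool)
        lat_mask[:, lattice] = True
        stage1 = np.where(
            (lat_mask | plan.acs_mask[None, :])[None, :, :, None], uniform_kt, 0
        )
        full = apply_kernel(stage1, kern, plan, acquired_kt=uniform_kt)
        keep = lat_mask | plan.acs_mask[None, :]
        np.testing.assert_array_equal(full[:, keep], uniform_kt[:, keep])

    def test_geometry_plan_mismatch_rejected(self, rng):
        plan = make_sampling_plan(
            n_pe=16, n_fe=8, n_frames=2, r1=2, r2=1, n_acs=6, seed=0
        )
        geom = KernelGeometry(n_coils=2, orf=4)
        kern = type("K", (), {"geometry": geom, "weights": {}})()
        with pytest.raises(ValueError):
            apply_kernel(np.zeros((2, 2, 16, 8), complex), kern, plan)

    def test_frame_permutation_equivariance(self, rng):
        ksp, geom, _, lattice = _exact_model_data(rng, n_frames=4)
        n_frames, L, n_pe, n_kx = ksp.shape
        plan = make_sampling_plan(
            n_pe=n_pe, n_fe=n_kx, n_frames=n_frames, r1=geom.orf, r2=1,
            n_acs=20, seed=0,
        )
        kern = calibrate(ksp, geom, np.flatnonzero(plan.acs_mask), reg_rel=0.0)
        uniform_kt = np.transpose(ksp, (1, 0, 2, 3)).copy()
        perm = np.array([2, 0, 3, 1])
        out = apply_kernel(uniform_kt, kern, plan, acquired_kt=uniform_kt)
        out_perm = apply_kernel(
            uniform_kt[:, perm], kern, plan, acquired_kt=uniform_kt[:, perm]
        )
        np.testing.assert_allclose(out[:, perm], out_perm, rtol=1e-12)


class TestLinearReduction:
    def test_matches_independent_linear_grappa(self, rng):
        """With second-order features disabled, calibration + application
        match an independently implemented (dense lstsq) linear GRAPPA."""
        L, n_pe, n_kx, n_frames, R = 2, 40, 24, 2, 2
        geom = KernelGeometry(
            n_coils=L, orf=R, b1=0, b2=1, h1=-1, h2=1, second_order=False
        )
        # smooth-ish random multi-coil k-space
        ksp = rng.standard_normal((n_frames, L, n_pe, n_kx)) + 1j * rng.standard_normal(
            (n_frames, L, n_pe, n_kx)
        )
        plan = make_sampling_plan(
            n_pe=n_pe, n_fe=n_kx, n_frames=n_frames, r1=R, r2=1, n_acs=16, seed=0
        )
        acs_lines = np.flatnonzero(plan.acs_mask)
        kern = calibrate(ksp, geom, acs_lines, reg_rel=0.0)

        # independent implementation: explicit source gathering + lstsq
        def lin_features(frame, base):
            rows = []
            for l in range(L):
                for b in range(geom.b1, geom.b2 + 1):
                    ky = base + b * R
                    for h in range(geom.h1, geom.h2 + 1):
                        col = np.zeros(n_kx, complex)
                        src = np.arange(n_kx) + h
                        ok = (src >= 0) & (src < n_kx)
                        if 0 <= ky < n_pe:
                            col[ok] = frame[l, ky, src[ok]]
                        rows.append(col)
            return np.vstack([np.ones(n_kx, complex)] + rows).T

        cols = np.arange(1, n_kx - 1)
        A_all, T_all = [], []
        lo, hi = acs_lines.min(), acs_lines.max()
        for t in range(n_frames):
            for base in range(lo, hi + 1):
                if base % R:
                    continue
                tgt = base + 1
                srcs = [base, base + R]
                if tgt not in set(acs_lines) or any(
                    s not in set(acs_lines) for s in srcs
                ):
                    continue
                A_all.append(lin_features(ksp[t], base)[cols])
                T_all.append(ksp[t, :, tgt][:, cols].T)
        A = np.concatenate(A_all)
        T = np.concatenate(T_all)
        w_ref, *_ = np.linalg.lstsq(A, T, rcond=None)
        # compare predictions on fresh lattice data
        test = rng.standard_normal((L, n_pe, n_kx)) + 1j * rng.standard_normal(
            (L, n_pe, n_kx)
        )
        base = 10
        pred_ref = lin_features(test, base) @ w_ref
        feats = build_features(test, base, np.arange(n_kx), geom)
        pred = feats @ kern.weights[1]
        np.testing.assert_allclose(pred, pred_ref, atol=1e-10 * np.abs(pred_ref).max())
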