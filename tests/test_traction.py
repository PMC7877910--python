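"""Forward elastic model, PIV displacement estimation, FTTC, RMS tractions."""

import numpy as np
import pytest

from cortopulse.traction import (
    DisplacementField,
    GelParams,
    TractionField,
    estimate_displacement,
    estimate_noise_floor,
    forward_displacement,
    fttc,
    generate_bead_images,
    rms_traction,
)

from conftest import dipole_traction_scene


def gauss_patch_field(n=128, h=0.5, sigma=0.75, amp=1000.0, gel=None):
    """Band-limited near-point tangential load along +x at the grid center."""
    gel = gel or GelParams()
    x = np.arange(n) * h
    X, Y = np.meshgrid(x, x)
    c = x[n // 2]
    tx = amp * np.exp(-((X - c) ** 2 + (Y - c) ** 2) / (2 * sigma**2))
    return TractionField((0.0, 0.0), h, tx, np.zeros_like(tx), gel=gel)


class TestForwardModel:
    def test_zero_traction_zero_displacement(self):
        tf = TractionField((0, 0), 1.0, np.zeros((16, 16)), np.zeros((16, 16)))
        d = forward_displacement(tf)
        assert np.allclose(d.fx, 0) and np.allclose(d.fy, 0)

    def test_point_force_matches_boussinesq_closed_form(self):
        """Along-axis surface displacement of a tangential point load.

        The FFT solution carries an arbitrary additive constant (zero-mean
        gauge), so displacements are compared as differences to a far
        reference point, against u(r) = (1 + nu) F / (pi E r).
        """
        gel = GelParams()
        h = 0.5
        tf = gauss_patch_field(h=h, gel=gel)
        disp = forward_displacement(tf, pad_factor=4.0)
        F = tf.fx.sum() * h * h
        E, nu = gel.youngs_modulus_pa, gel.poisson_ratio

        def u_cf(r):
            return (1 + nu) * F / (np.pi * E * r)

        ic = 64
        mref = 24
        offset = disp.fx[ic, ic + mref] - u_cf(mref * h)
        for m in range(3, 13):
            u_num = disp.fx[ic, ic + m] - offset
            assert abs(u_num - u_cf(m * h)) / u_cf(m * h) < 0.02

    def test_displacement_scales_inversely_with_youngs_modulus(self):
        tf1 = dipole_traction_scene(seed=1)
        tf2 = dipole_traction_scene(seed=1, gel=GelParams(youngs_modulus_pa=52000.0))
        d1, d2 = forward_displacement(tf1), forward_displacement(tf2)
        assert np.allclose(d1.fx, 2.0 * d2.fx, atol=1e-12)
        assert np.allclose(d1.fy, 2.0 * d2.fy, atol=1e-12)

    def test_superposition_linearity(self):
        a = dipole_traction_scene(seed=2)
        b = dipole_traction_scene(seed=3)
        ab = TractionField(a.origin_um, a.spacing_um, a.fx + b.fx, a.fy + b.fy, gel=a.gel)
        da, db, dab = (forward_displacement(t) for t in (a, b, ab))
        assert np.allclose(dab.fx, da.fx + db.fx, atol=1e-12)
        assert np.allclose(dab.fy, da.fy + db.fy, atol=1e-12)


class TestBeadImages:
    def test_zero_traction_identity(self):
        tf = TractionField((0, 0), 0.8, np.zeros((32, 32)), np.zeros((32, 32)))
        ref, stressed, gt = generate_bead_images(tf, seed=0)
        assert np.allclose(gt.fx, 0) and np.allclose(gt.fy, 0)
        assert np.array_equal(ref.data, stressed.data)

    def test_seed_determinism_and_spacing_check(self):
        tf = dipole_traction_scene(seed=4)
        a = generate_bead_images(tf, seed=5)
        b = generate_bead_images(tf, seed=5)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].data, b[1].data)
        with pytest.raises(ValueError, match="spacing"):
            generate_bead_images(tf, pixel_size_um=0.3)  # 0.8/0.3 not integral


class TestPIV:
    def test_identical_images_zero_field(self):
        rng = np.random.default_rng(0)
        img = rng.random((128, 128)) * 100
        d = estimate_displacement(img, img, window_px=32, pixel_size_um=1.0)
        assert np.allclose(d.fx, 0) and np.allclose(d.fy, 0)
        assert estimate_noise_floor(d) == 0.0

    def test_integer_shift_recovered_exactly(self):
        tf = dipole_traction_scene(seed=6)
        ref, _, _ = generate_bead_images(tf, bead_sigma_um=0.3, seed=7)
        img = ref.data[0]
        shifted = np.roll(np.roll(img, 3, axis=0), -2, axis=1)
        d = estimate_displacement(shifted, img, window_px=32, pixel_size_um=1.0)
        inner = d.valid.copy()
        inner[0, :] = inner[-1, :] = inner[:, 0] = inner[:, -1] = False
        assert inner.sum() > 100
        assert np.abs(d.fx[inner] - (-2.0)).max() < 1e-9
        assert np.abs(d.fy[inner] - 3.0).max() < 1e-9

    def test_bead_scene_subpixel_accuracy(self):
        """Vector-wise error vs forward-model ground truth <= 0.2 px RMS."""
        from scipy.interpolate import RegularGridInterpolator

        tf = dipole_traction_scene(seed=8, amp_pa=800.0)
        ref, stressed, gt = generate_bead_images(
            tf, bead_density_per_um2=0.08, bead_sigma_um=0.3, pixel_size_um=0.2, seed=9
        )
        d = estimate_displacement(stressed, ref, window_px=32)
        gx, gy = tf.node_coords_um()
        iu = RegularGridInterpolator((gy, gx), gt.fx)
        iv = RegularGridInterpolator((gy, gx), gt.fy)
        x, y = d.node_coords_um()
        X, Y = np.meshgrid(x, y)
        pts = np.column_stack([Y.ravel(), X.ravel()])
        ok = (
            (pts[:, 0] >= gy[0]) & (pts[:, 0] <= gy[-1])
            & (pts[:, 1] >= gx[0]) & (pts[:, 1] <= gx[-1])
        )
        err_u = (d.fx.ravel()[ok] - iu(pts[ok])) / 0.2
        err_v = (d.fy.ravel()[ok] - iv(pts[ok])) / 0.2
        rms_px = np.sqrt(np.mean(err_u**2 + err_v**2))
        assert rms_px <= 0.2

    def test_featureless_window_flagged_and_imputed(self):
        rng = np.random.default_rng(1)
        img = rng.random((96, 96))
        img[:40, :40] = 0.0  # featureless block
        d = estimate_displacement(img, img, window_px=32, overlap=0.0, pixel_size_um=1.0)
        assert not d.valid[0, 0]
        assert np.isfinite(d.fx).all()


class TestFTTC:
    def test_zero_displacement_zero_traction(self):
        d = DisplacementField((0, 0), 1.0, np.zeros((16, 16)), np.zeros((16, 16)))
        t = fttc(d, GelParams(), regularization_lambda=0.0)
        assert np.allclose(t.fx, 0) and np.allclose(t.fy, 0)

    def test_round_trip_recovers_traction_within_5_percent(self):
        gel = GelParams()
        errs = []
        for seed in range(3):
            tf = dipole_traction_scene(seed=seed, gel=gel)
            rec = fttc(forward_displacement(tf), gel, regularization_lambda=0.0)
            num = (rec.fx - tf.fx) ** 2 + (rec.fy - tf.fy) ** 2
            den = tf.fx**2 + tf.fy**2
            errs.append(np.sqrt(num.sum() / den.sum()))
        assert max(errs) < 0.05

    def test_traction_linear_in_youngs_modulus(self):
        tf = dipole_traction_scene(seed=1)
        d = forward_displacement(tf)
        t1 = fttc(d, GelParams(youngs_modulus_pa=26000.0), regularization_lambda=0.0)
        t2 = fttc(d, GelParams(youngs_modulus_pa=52000.0), regularization_lambda=0.0)
        assert np.allclose(t2.fx, 2.0 * t1.fx, atol=1e-9)

    def test_recovery_error_monotone_in_lambda(self):
        # periodic (unpadded) setting: the round trip at lambda = 0 is exact
        # and Tikhonov filter factors shrink monotonically with lambda
        gel = GelParams()
        tf = dipole_traction_scene(seed=2, gel=gel)
        d = forward_displacement(tf, pad_factor=1.0)
        errs = []
        for lam in (0.0, 1e-9, 1e-8, 1e-7, 1e-6):
            rec = fttc(d, gel, regularization_lambda=lam, pad_factor=1.0)
            errs.append(np.sqrt(np.sum((rec.fx - tf.fx) ** 2 + (rec.fy - tf.fy) ** 2)))
        assert errs[0] < 1e-6 * np.sqrt(np.sum(tf.fx**2))
        assert all(a <= b + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_force_balance_after_mean_subtraction(self):
        gel = GelParams()
        tf = dipole_traction_scene(seed=3, gel=gel)
        # over the full (periodic) transform domain the k=0 term is removed,
        # so the integrated traction vanishes identically
        rec = fttc(forward_displacement(tf, pad_factor=1.0), gel,
                   regularization_lambda=0.0, pad_factor=1.0)
        scale = np.abs(rec.fx).sum() + np.abs(rec.fy).sum()
        assert abs(rec.fx.sum()) / scale < 1e-9
        assert abs(rec.fy.sum()) / scale < 1e-9
        # with padding, the small imbalance left in the cropped view stays
        # below a percent of the total traction magnitude
        rec = fttc(forward_displacement(tf), gel, regularization_lambda=0.0)
        assert abs(rec.fx.sum()) / scale < 0.01

    def test_errors(self):
        d = DisplacementField((0, 0), 1.0, np.full((8, 8), np.nan), np.zeros((8, 8)))
        with pytest.raises(ValueError, match="NaN"):
            fttc(d, GelParams())
        with pytest.raises(ValueError):
            GelParams(youngs_modulus_pa=-1.0)
        with pytest.raises(ValueError):
            GelParams(poisson_ratio=0.7)


class TestRMS:
    def grid(self, mags):
        t = np.asarray(mags, dtype=float)
        return TractionField((0.0, 0.0), 1.0, t, np.zeros_like(t))

    def test_uniform_field(self):
        tf = self.grid(np.full((4, 4), 50.0))
        rms, flag = rms_traction(tf, [(-1, -1), (4, -1), (4, 4), (-1, 4)])
        assert rms == pytest.approx(50.0)
        assert not flag

    def test_hand_arithmetic_2x2(self):
        tf = self.grid([[30.0, 40.0], [0.0, 0.0]])
        rms, _ = rms_traction(tf, [(-1, -1), (2, -1), (2, 2), (-1, 2)])
        assert rms == pytest.approx(25.0)  # sqrt((900+1600)/4)

    def test_zero_field_flagged_below_floor(self):
        tf = self.grid(np.zeros((4, 4)))
        rms, flag = rms_traction(tf, [(-1, -1), (4, -1), (4, 4), (-1, 4)])
        assert rms == 0.0 and flag

    def test_below_floor_uses_displacement_noise_floor(self):
        gel = GelParams()
        tf = dipole_traction_scene(seed=5, gel=gel)
        d = forward_displacement(tf)
        d.noise_floor_um = 10.0  # everything below floor
        rec = fttc(d, gel, regularization_lambda=0.0)
        x, y = rec.node_coords_um()
        _, flag = rms_traction(rec, [(x[0], y[0]), (x[-1], y[0]), (x[-1], y[-1]), (x[0], y[-1])])
        assert flag

    def test_degenerate_polygon_raises(self):
        tf = self.grid(np.ones((4, 4)))
        with pytest.raises(ValueError, match="degenerate|intersect"):
            rms_traction(tf, [(0, 0), (1, 1), (2, 2)])

    def test_two_roi_ordering_and_mann_whitney(self):
        """Strong vs weak traction ROIs: RMS ordering preserved, groups separable."""
        from cortopulse.stats import mann_whitney_u

        gel = GelParams()
        strong, weak = [], []
        for seed in range(10):
            tf = dipole_traction_scene(seed=seed, gel=gel, amp_pa=800.0)
            rec = fttc(forward_displacement(tf), gel, regularization_lambda=0.0)
            x, y = rec.node_coords_um()
            roi = [(x[0], y[0]), (x[-1], y[0]), (x[-1], y[-1]), (x[0], y[-1])]
            strong.append(rms_traction(rec, roi)[0])
            tf10 = TractionField(tf.origin_um, tf.spacing_um, tf.fx / 10, tf.fy / 10, gel=gel)
            rec10 = fttc(forward_displacement(tf10), gel, regularization_lambda=0.0)
            weak.append(rms_traction(rec10, roi)[0])
        assert all(s > w for s, w in zip(strong, weak))
        _, p = mann_whitney_u(strong, weak)
        assert p < 0.001
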