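"""Regularized FTTC inversion and force/stress derivations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfmlab import (DisplacementField, RegularGrid, TractionField,
                    boussinesq_forward, fa_force, fa_stress, fttc_inverse,
                    select_lambda_discrepancy, select_lambda_lcurve,
                    stress_footprint, total_force)


@pytest.fixture(scope="module")
def dipole_displacement(gel, dipole_scene):
    """Periodic forward solution (pad 1) — exact counterpart of the inverse."""
    return boussinesq_forward(dipole_scene, gel, grid_spacing=0.25,
                              pad_factor=1.0)


def _gaussian_spot_field(peak=100.0, sigma=2.0, shape=(41, 41), spacing=0.5,
                         background=0.0):
    grid = RegularGrid(shape, spacing)
    X, Y = grid.meshgrid()
    cx = grid.x[-1] / 2
    amp = peak * np.exp(-(((X - cx) ** 2 + (Y - cx) ** 2) /
                          (2 * sigma ** 2))) + background
    return TractionField(grid, amp, np.zeros_like(amp))


class TestFttcInverse:
    def test_zero_displacement_zero_traction(self, gel):
        grid = RegularGrid((32, 32), 0.5)
        disp = DisplacementField(grid, np.zeros(grid.shape),
                                 np.zeros(grid.shape))
        tf = fttc_inverse(disp, gel, lam=0.01)
        assert np.all(tf.tx == 0) and np.all(tf.ty == 0)

    def test_forward_inverse_round_trip(self, gel, dipole_scene,
                                        dipole_displacement):
        """λ=0 inversion of the forward field recovers the scene < 1e-6."""
        with pytest.warns(UserWarning, match="amplifies"):
            tf = fttc_inverse(dipole_displacement, gel, lam=0.0,
                              pad_factor=1.0)
        tx, ty = dipole_scene.traction_map(tf.grid)
        err = np.sqrt(((tf.tx - tx) ** 2 + (tf.ty - ty) ** 2).sum() /
                      (tx ** 2 + ty ** 2).sum())
        assert err < 1e-6

    def test_regularization_attenuates_peak(self, gel, dipole_scene,
                                            dipole_displacement):
        true_peak = np.hypot(*dipole_scene.traction_map(
            dipole_displacement.grid)).max()
        tf = fttc_inverse(dipole_displacement, gel, lam=0.1, pad_factor=1.0)
        assert tf.magnitude().max() < true_peak

    def test_l2_norm_monotone_in_lambda(self, gel, dipole_displacement):
        """Tikhonov guarantee: ‖t_λ‖₂ is non-increasing in λ."""
        norms = []
        for lam in (1e-4, 1e-3, 1e-2, 0.1, 0.3, 1.0):
            tf = fttc_inverse(dipole_displacement, gel, lam=lam)
            norms.append(np.sqrt((tf.tx ** 2 + tf.ty ** 2).sum()))
        assert np.all(np.diff(norms) <= 1e-9 * norms[0])

    def test_linearity_in_displacement(self, gel, dipole_displacement):
        t1 = fttc_inverse(dipole_displacement, gel, lam=0.05)
        doubled = DisplacementField(dipole_displacement.grid,
                                    2 * dipole_displacement.ux,
                                    2 * dipole_displacement.uy)
        t2 = fttc_inverse(doubled, gel, lam=0.05)
        assert np.allclose(t2.tx, 2 * t1.tx, rtol=1e-10, atol=1e-9)

    def test_nan_displacement_rejected(self, gel):
        grid = RegularGrid((16, 16), 0.5)
        disp = DisplacementField(grid, np.zeros(grid.shape),
                                 np.zeros(grid.shape))
        disp.ux[3, 3] = np.nan  # corrupt a node marked valid
        with pytest.raises(ValueError, match="non-finite"):
            fttc_inverse(disp, gel, lam=0.01)

    def test_invalid_nodes_filled_before_transform(self, gel,
                                                   dipole_displacement):
        valid = np.ones(dipole_displacement.grid.shape, bool)
        valid[40:43, 40:43] = False
        holey = DisplacementField(dipole_displacement.grid,
                                  dipole_displacement.ux.copy(),
                                  dipole_displacement.uy.copy(), valid)
        tf = fttc_inverse(holey, gel, lam=0.01)
        ref = fttc_inverse(dipole_displacement, gel, lam=0.01)
        rel = np.abs(tf.tx - ref.tx).max() / np.abs(ref.tx).max()
        assert rel < 0.06

    def test_lambda_selectors_return_positive(self, gel,
                                              dipole_displacement):
        lam_l = select_lambda_lcurve(dipole_displacement, gel)
        lam_d = select_lambda_discrepancy(dipole_displacement, gel,
                                          noise_sd=0.005)
        assert lam_l > 0 and lam_d > 0


class TestTotalForce:
    def test_uniform_field_background_cancels(self):
        grid = RegularGrid((20, 20), 1.0)
        tf = TractionField(grid, np.full(grid.shape, 20.0),
                           np.zeros(grid.shape))
        mask = np.zeros(grid.shape, bool)
        mask[5:15, 5:15] = True
        bg = np.zeros(grid.shape, bool)
        bg[:3] = True
        fs = total_force(tf, mask, bg)
        assert fs.total_force == 0.0
        assert fs.background == pytest.approx(20.0)

    def test_unit_arithmetic_100pa_over_1um2(self):
        """100 Pa over one 1 µm² cell with zero background = 0.1 nN."""
        grid = RegularGrid((10, 10), 1.0)
        tx = np.zeros(grid.shape)
        tx[5, 5] = 100.0
        tf = TractionField(grid, tx, np.zeros(grid.shape))
        mask = np.zeros(grid.shape, bool)
        mask[5, 5] = True
        bg = np.zeros(grid.shape, bool)
        bg[0] = True
        assert total_force(tf, mask, bg).total_force == pytest.approx(0.1)

    @pytest.mark.parametrize("bad", ["empty_mask", "empty_bg", "overlap"])
    def test_degenerate_masks_rejected(self, bad):
        grid = RegularGrid((10, 10), 1.0)
        tf = TractionField(grid, np.ones(grid.shape), np.zeros(grid.shape))
        mask = np.zeros(grid.shape, bool)
        bg = np.zeros(grid.shape, bool)
        if bad != "empty_mask":
            mask[4:6, 4:6] = True
        if bad != "empty_bg":
            bg[0] = True
        if bad == "overlap":
            bg |= mask
        with pytest.raises(ValueError):
            total_force(tf, mask, bg)


class TestFaStress:
    def test_uniform_field_any_sigma(self):
        grid = RegularGrid((30, 30), 0.5)
        tf = TractionField(grid, np.full(grid.shape, 55.0),
                           np.zeros(grid.shape))
        for sigma in (0.5, 1.0, 3.0):
            res = fa_stress(tf, (7.0, 7.0), sigma)
            assert res.weighted_mean == pytest.approx(55.0)

    def test_delta_spot_recovered_as_sigma_shrinks(self):
        grid = RegularGrid((21, 21), 0.5)
        tx = np.zeros(grid.shape)
        tx[10, 10] = 500.0
        tf = TractionField(grid, tx, np.zeros(grid.shape))
        vals = [fa_stress(tf, (5.0, 5.0), s).weighted_mean
                for s in (2.0, 1.0, 0.3, 0.1)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(500.0, rel=1e-3)

    def test_gaussian_spot_closed_form_convolution(self):
        """σ_spot = 2σ_weight ⇒ weighted mean at centre = peak·σs²/(σs²+σw²)."""
        sig_spot, sig_w, peak = 2.0, 1.0, 300.0
        tf = _gaussian_spot_field(peak=peak, sigma=sig_spot, shape=(81, 81),
                                  spacing=0.25)
        c = tf.grid.x[-1] / 2
        res = fa_stress(tf, (c, c), sig_w)
        expected = peak * sig_spot ** 2 / (sig_spot ** 2 + sig_w ** 2)
        assert res.weighted_mean == pytest.approx(expected, rel=0.01)
        assert res.peak == pytest.approx(peak, rel=0.01)

    def test_boundary_kernel_warns(self):
        tf = _gaussian_spot_field()
        with pytest.warns(UserWarning, match="boundary"):
            fa_stress(tf, (0.5, 0.5), 2.0)


class TestFaForce:
    def test_printed_pairs_share_one_footprint(self):
        """60 Pa ↔ 1.8 nN implies 30 µm²; then 100 Pa ↔ 3 nN exactly."""
        area = 1.8 / (60.0 * 1e-3)
        assert area == pytest.approx(30.0)
        assert fa_force(60.0, area) == pytest.approx(1.8)
        assert fa_force(100.0, area) == pytest.approx(3.0)

    def test_tiny_stress_linearity(self):
        assert fa_force(1e-6, 1.0) == pytest.approx(1e-9)

    @given(st.floats(1e-3, 1e4), st.floats(1e-2, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_bilinear(self, peak, area):
        assert fa_force(peak, area) == pytest.approx(
            peak * area * 1e-3, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fa_force(0.0, 10.0)


class TestStressFootprint:
    def test_gaussian_spot_half_maximum_disc(self):
        """Area of the half-max disc of an isotropic Gaussian: π(σ√(2 ln 2))²."""
        sig = 2.0
        tf = _gaussian_spot_field(peak=200.0, sigma=sig, shape=(161, 161),
                                  spacing=0.125)
        c = tf.grid.x[-1] / 2
        area = stress_footprint(tf, (c, c), threshold_fraction=0.5,
                                max_domain_fraction=0.6)
        expected = np.pi * (sig * np.sqrt(2 * np.log(2))) ** 2
        assert area == pytest.approx(expected, rel=0.05)

    def test_uniform_field_rejected(self):
        grid = RegularGrid((20, 20), 1.0)
        tf = TractionField(grid, np.full(grid.shape, 50.0),
                           np.zeros(grid.shape))
        with pytest.raises(ValueError):
            stress_footprint(tf, (10.0, 10.0))

    def test_two_spots_only_own_component_counted(self):
        grid = RegularGrid((81, 81), 0.25)
        X, Y = grid.meshgrid()
        amp = 100.0 * np.exp(-((X - 5) ** 2 + (Y - 10) ** 2) / (2 * 1.0 ** 2)) \
            + 100.0 * np.exp(-((X - 15) ** 2 + (Y - 10) ** 2) / (2 * 1.0 ** 2))
        tf = TractionField(grid, amp, np.zeros(grid.shape))
        one = stress_footprint(tf, (5.0, 10.0))
        lone = _gaussian_spot_field(peak=100.0, sigma=1.0, shape=(81, 81),
                                    spacing=0.25)
        c = lone.grid.x[-1] / 2
        ref = stress_footprint(lone, (c, c))
        assert one == pytest.approx(ref, rel=0.1)
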