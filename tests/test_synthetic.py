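"""Generators: force balance, elastic forward model, bead/flow/FA rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from tfmlab import (DisplacementField, FASceneParams, FlowSceneParams,
                    GelSubstrate, RegularGrid, TractionFocus, TractionScene,
                    boussinesq_forward, make_cell_scene, render_bead_images,
                    synthesize_fa_tracks, synthesize_flow_movie)
from tfmlab._greens import boussinesq_kernel_realspace
from tfmlab.synthetic import _forward_spectral


class TestTractionScene:
    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_cell_scenes_are_force_balanced(self, seed):
        scene = make_cell_scene(seed=seed)
        assert scene.net_force_ratio() < 1e-10

    def test_scaling_sets_total_force(self):
        scene = make_cell_scene(total_force_nN=123.0, seed=2)
        assert scene.total_magnitude_force_nN() == pytest.approx(123.0)

    def test_focus_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="inside the domain"):
            TractionScene((TractionFocus((1.0, 15.0), 0.0, 100.0, (1.0, 1.0)),),
                          (30.0, 30.0))


class TestBoussinesqForward:
    def test_zero_traction_gives_zero_displacement(self, gel):
        scene = TractionScene((), (20.0, 20.0))
        disp = boussinesq_forward(scene, gel, grid_spacing=0.5)
        assert np.all(disp.ux == 0) and np.all(disp.uy == 0)

    def test_unbalanced_scene_rejected(self, gel):
        lone = TractionScene(
            (TractionFocus((15.0, 15.0), 0.0, 100.0, (1.0, 1.0)),),
            (30.0, 30.0))
        with pytest.raises(ValueError, match="not force balanced"):
            boussinesq_forward(lone, gel, grid_spacing=0.2)

    def test_underresolved_footprint_rejected(self, gel, dipole_scene):
        with pytest.raises(ValueError, match="under-resolves"):
            boussinesq_forward(dipole_scene, gel, grid_spacing=1.0)

    def test_dipole_displacement_antisymmetric(self, gel, dipole_scene):
        disp = boussinesq_forward(dipole_scene, gel, grid_spacing=0.25)
        # point antisymmetry about the dipole midpoint: u(-r) = -u(r)
        assert np.allclose(disp.ux, -disp.ux[::-1, ::-1], atol=1e-12)
        assert np.allclose(disp.uy, -disp.uy[::-1, ::-1], atol=1e-12)

    def test_linearity_in_peak_stress(self, gel, dipole_scene):
        d1 = boussinesq_forward(dipole_scene, gel, grid_spacing=0.25)
        d2 = boussinesq_forward(dipole_scene.scaled(2.0), gel,
                                grid_spacing=0.25)
        assert np.allclose(d2.ux, 2.0 * d1.ux)
        assert np.allclose(d2.uy, 2.0 * d1.uy)

    def test_displacement_decays_toward_edges(self, gel, dipole_scene):
        disp = boussinesq_forward(dipole_scene, gel, grid_spacing=0.25)
        mag = disp.magnitude()
        border = np.concatenate([mag[0], mag[-1], mag[:, 0], mag[:, -1]])
        assert border.max() < 0.1 * mag.max()

    def test_fourier_matches_realspace_convolution_oracle(self, gel):
        """Spectral forward vs direct Boussinesq convolution: < 1% rel L2.

        The oracle integrates the real-space half-space kernel directly,
        with sub-cell quadrature near the (integrable) singularity.
        """
        spacing, n = 0.25, 101
        grid = RegularGrid((n, n), spacing)
        X, Y = grid.meshgrid()
        sig = 1.2
        tx = 200.0 * (np.exp(-(((X - 9.0) / sig) ** 2 +
                               ((Y - 12.5) / sig) ** 2) / 2)
                      - np.exp(-(((X - 16.0) / sig) ** 2 +
                                 ((Y - 12.5) / sig) ** 2) / 2))
        ty = np.zeros_like(tx)
        ux_f, uy_f = _forward_spectral(tx, ty, gel, spacing, pad_factor=4.0)

        dA = spacing ** 2
        tgt = np.arange(12, n - 12, 6)
        sub = 15
        off = ((np.arange(sub) + 0.5) / sub - 0.5) * spacing
        ox, oy = np.meshgrid(off, off)
        near_px = 2
        ux_o = np.zeros((len(tgt), len(tgt)))
        uy_o = np.zeros_like(ux_o)
        for a, i in enumerate(tgt):
            for b, j in enumerate(tgt):
                dx, dy = X[i, j] - X, Y[i, j] - Y
                Kxx, Kxy, _ = boussinesq_kernel_realspace(dx, dy, gel)
                nearm = (np.abs(dx) <= near_px * spacing + 1e-9) & \
                        (np.abs(dy) <= near_px * spacing + 1e-9)
                Kxx[nearm] = Kxy[nearm] = 0.0
                ux_o[a, b] = (Kxx * tx).sum() * dA
                uy_o[a, b] = (Kxy * tx).sum() * dA
                for r, c in zip(*np.nonzero(nearm)):
                    kxx, kxy, _ = boussinesq_kernel_realspace(
                        dx[r, c] + ox, dy[r, c] + oy, gel)
                    ux_o[a, b] += kxx.mean() * tx[r, c] * dA
                    uy_o[a, b] += kxy.mean() * tx[r, c] * dA

        uxf = ux_f[np.ix_(tgt, tgt)]
        uyf = uy_f[np.ix_(tgt, tgt)]
        m = len(tgt) // 4
        sl = slice(m, len(tgt) - m)  # interior ~50% of the domain
        num = np.sqrt(((uxf[sl, sl] - ux_o[sl, sl]) ** 2 +
                       (uyf[sl, sl] - uy_o[sl, sl]) ** 2).sum())
        den = np.sqrt((ux_o[sl, sl] ** 2 + uy_o[sl, sl] ** 2).sum())
        assert num / den < 0.01


class TestRenderBeadImages:
    @staticmethod
    def _uniform_field(shift_um, shape=(101, 101), spacing=0.2):
        grid = RegularGrid(shape, spacing)
        return DisplacementField(grid,
                                 np.full(shape, shift_um),
                                 np.zeros(shape))

    def test_zero_displacement_identical_before_noise(self):
        disp = self._uniform_field(0.0)
        ref, strained = render_bead_images(disp, seed=1, noise_sd=0.0)
        assert np.array_equal(ref, strained)

    def test_integer_translation(self):
        disp = self._uniform_field(0.3)  # 3 px at 0.1 µm/px
        ref, strained = render_bead_images(disp, seed=1, noise_sd=0.0)
        assert np.allclose(strained[:, 3:], ref[:, :-3], atol=1e-8)

    def test_half_pixel_shift_moves_centroids(self):
        """Centroid-fit oracle: 0.5 px shift recovered within 0.02 px."""
        disp = self._uniform_field(0.05)
        ref, strained, pos = render_bead_images(
            disp, bead_density=0.3, seed=4, noise_sd=0.0,
            return_positions=True)
        shifts = []
        for x_um, y_um in pos:
            c, r = x_um / 0.1, y_um / 0.1
            ri, ci = int(round(r)), int(round(c))
            if not (6 <= ri < ref.shape[0] - 7 and 6 <= ci < ref.shape[1] - 7):
                continue
            # isolated beads only: centroid fitting assumes no overlap
            box = np.hypot(*(pos - [x_um, y_um]).T)
            if np.sort(box)[1] < 1.5:
                continue
            sl = np.s_[ri - 5:ri + 6, ci - 5:ci + 6]
            cols = np.arange(ci - 5, ci + 6)
            for img, acc in ((ref, 0.0), (strained, None)):
                w = img[sl]
                cx = (w * cols[None, :]).sum() / w.sum()
                if acc is None:
                    shifts.append(cx - cx_ref)
                else:
                    cx_ref = cx
        assert len(shifts) > 10
        assert abs(np.mean(shifts) - 0.5) < 0.02

    def test_seeded_determinism(self):
        disp = self._uniform_field(0.1)
        a = render_bead_images(disp, seed=7)
        b = render_bead_images(disp, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_large_displacement_warns(self):
        disp = self._uniform_field(1.0)  # ≫ half the mean bead spacing
        with pytest.warns(UserWarning, match="bead spacing"):
            render_bead_images(disp, bead_density=4.0, seed=1)


class TestFlowMovie:
    def test_zero_speed_frames_identical_before_noise(self):
        p = FlowSceneParams(speed=0.0, duration=2.0, fov=(10.0, 10.0),
                            snr=0.0, seed=3)
        stack = synthesize_flow_movie(p)
        assert np.allclose(stack[0], stack[-1], atol=1e-10)

    def test_interframe_shift_arithmetic(self):
        p = FlowSceneParams(speed=0.3, frame_interval=30.0)
        assert p.shift_per_frame_um == pytest.approx(0.15)

    def test_cumulative_shift_matches_whole_frame_correlation(self):
        """Frame 1 vs frame N cross-correlation peaks at (N−1)× the shift."""
        p = FlowSceneParams(duration=5.0, fov=(15.0, 15.0), snr=50.0, seed=9)
        stack = synthesize_flow_movie(p)
        N = stack.shape[0]
        a = stack[0] - stack[0].mean()
        b = stack[-1] - stack[-1].mean()
        corr = np.real(np.fft.ifft2(np.fft.fft2(a) *
                                    np.conj(np.fft.fft2(b))))
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        shift_px = [p - (n if p > n // 2 else 0)
                    for p, n in zip(peak, corr.shape)]
        expected = (N - 1) * p.shift_per_frame_um / p.pixel_size
        assert abs(-shift_px[1] - expected) <= 1.0  # integer-peak resolution
        assert shift_px[0] == 0

    def test_subresolution_speed_warns(self):
        with pytest.warns(UserWarning, match="tracking resolution"):
            synthesize_flow_movie(FlowSceneParams(
                speed=0.005, duration=1.0, fov=(5.0, 5.0), seed=0))

    def test_duration_must_tile_interval(self):
        with pytest.raises(ValueError, match="integer number"):
            FlowSceneParams(duration=0.7, frame_interval=30.0)


class TestFATracks:
    def test_linear_growth_arithmetic(self):
        """0.15 µm/min for 10 min from 1.0 µm ends at 2.5 µm, noise-free."""
        from tfmlab.synthetic import FATrackTruth
        tr = FATrackTruth(track_id=0, center=(5, 5), angle=0.0,
                          start_time=0.0, lifetime=40.0, elongation_rate=0.15,
                          loading_rate=25.0, disassembly_rate=0.1,
                          growth_duration=10.0, plateau_duration=20.0,
                          decay_duration=10.0, initial_length=1.0)
        assert tr.length_at(np.array([10.0]))[0] == pytest.approx(2.5)
        assert tr.length_at(np.array([20.0]))[0] == pytest.approx(2.5)

    def test_linear_loading_arithmetic(self):
        """25 Pa/min over 4 min of growth reaches 100 Pa from 0."""
        from tfmlab.synthetic import FATrackTruth
        tr = FATrackTruth(track_id=0, center=(5, 5), angle=0.0,
                          start_time=0.0, lifetime=12.0, elongation_rate=0.15,
                          loading_rate=25.0, disassembly_rate=0.1,
                          growth_duration=4.0, plateau_duration=4.0,
                          decay_duration=4.0, initial_length=1.0)
        assert tr.stress_at(np.array([4.0]))[0] == pytest.approx(100.0)

    def test_wild_type_lifetime_mean_within_2se(self):
        """n = 200 wild-type lifetimes average ~55 min (within 2 SE)."""
        params = FASceneParams(n_adhesions=200, seed=10)
        scene = synthesize_fa_tracks(params)
        lifetimes = np.array([t.lifetime for t in scene.tracks])
        se = lifetimes.std(ddof=1) / np.sqrt(len(lifetimes))
        assert abs(lifetimes.mean() - 55.0) < 2 * se + 1e-9

    def test_lifetimes_resampled_above_three_frames(self):
        params = FASceneParams(n_adhesions=50, lifetime_mean=2.0, seed=1)
        scene = synthesize_fa_tracks(params)
        assert min(t.lifetime for t in scene.tracks) >= \
            3 * params.frame_interval_min

    def test_scene_determinism(self):
        a = synthesize_fa_tracks(FASceneParams(n_adhesions=5, seed=3))
        b = synthesize_fa_tracks(FASceneParams(n_adhesions=5, seed=3))
        assert a.tracks == b.tracks
        assert np.array_equal(a.render_frame(10), b.render_frame(10))

    def test_rendered_length_matches_truth(self):
        """The rendered ellipse's major-axis FWHM is the ground-truth length."""
        from tfmlab.fa_dynamics import measure_length
        params = FASceneParams(n_adhesions=4, seed=6, length_noise_sd=0.0)
        scene = synthesize_fa_tracks(params)
        tr = scene.tracks[0]
        frames = scene.track_frames(tr)
        mid = frames[len(frames) // 2]
        img = scene.render_frame(int(mid))
        m = measure_length(img, tr.center, pixel_size=scene.pixel_size)
        truth = tr.length_at(np.array([mid * params.frame_interval_min]))[0]
        assert m is not None
        assert m.length == pytest.approx(truth, rel=0.12)
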