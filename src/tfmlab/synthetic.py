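"""Synthetic ground-truth scenes for every stage of the pipeline.

Four generators mirror the four kinds of raw data the analysis consumes:

* :func:`boussinesq_forward` — displacement of a linear-elastic half-space
  substrate under a prescribed, force-balanced set of traction foci;
* :func:`render_bead_images` — fiducial-bead image pairs (unstrained
  reference vs. strained) with a Gaussian point spread and shot-like noise;
* :func:`synthesize_flow_movie` — a speckled lamellar actin texture
  translating rigidly at a configured retrograde-flow speed;
* :func:`synthesize_fa_tracks` — focal adhesion tracks with prescribed
  elongation/loading/disassembly kinetics, rendered as elongating
  anisotropic Gaussians whose major-axis FWHM is the ground-truth length.

Presets encode the wild-type condition (0.3 µm/min lamellar flow,
0.15 µm/min elongation, 25 Pa/min loading, 55 min lifetime, ~250 nN total
force on a 2.8 kPa gel) and graded ROCK-inhibitor (Y-27632) conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from ._greens import greens_fourier
from .core import PA_UM2_TO_NN, DisplacementField, GelSubstrate, RegularGrid

__all__ = [
    "TractionFocus", "TractionScene", "FlowSceneParams", "FASceneParams",
    "FATrackTruth", "FAScene", "FA_PRESETS", "FLOW_PRESETS", "CONDITION_PRESETS",
    "boussinesq_forward", "render_bead_images", "synthesize_flow_movie",
    "synthesize_fa_tracks", "make_cell_scene",
]


# ---------------------------------------------------------------------------
# traction scenes and the forward substrate model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TractionFocus:
    """One elliptical traction focus (a focal adhesion's stress footprint).

    ``angle`` sets both the traction direction and the footprint major
    axis (adhesions pull along their long axis). ``semi_axes`` are the
    Gaussian σ along (major, minor) in µm; ``peak_stress`` in Pa.
    """

    center: tuple[float, float]      # (x, y) µm
    angle: float                     # rad
    peak_stress: float               # Pa
    semi_axes: tuple[float, float]   # (σ_major, σ_minor) µm

    @property
    def integrated_force_nN(self) -> float:
        """∫|t| dA = peak · 2π σa σb, in nN."""
        return self.peak_stress * 2.0 * np.pi * self.semi_axes[0] * \
            self.semi_axes[1] * PA_UM2_TO_NN

    @property
    def direction(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])


@dataclass(frozen=True)
class TractionScene:
    """A set of traction foci on a rectangular substrate domain.

    The vector sum of the integrated tractions must vanish (a cell exerts
    no net force on its substrate); :meth:`net_force_ratio` quantifies the
    residual and the forward solver rejects unbalanced scenes.
    """

    foci: tuple[TractionFocus, ...]
    domain_size: tuple[float, float]   # (width, height) µm
    seed: int = 0
    cell_radii: tuple[float, float] | None = None  # ellipse of the "cell"

    def __post_init__(self) -> None:
        w, h = self.domain_size
        for f in self.foci:
            # require the ±3σ footprint strictly inside the domain
            margin = 3.0 * max(f.semi_axes)
            x, y = f.center
            if not (margin < x < w - margin and margin < y < h - margin):
                raise ValueError(f"focus at {f.center} does not lie strictly "
                                 "inside the domain")

    def integrated_net_force(self) -> np.ndarray:
        """Vector sum of the integrated traction over all foci, nN."""
        out = np.zeros(2)
        for f in self.foci:
            out += f.integrated_force_nN * f.direction
        return out

    def total_magnitude_force_nN(self) -> float:
        """Σ over foci of ∫|t| dA — the summed-magnitude 'total force'."""
        return float(sum(f.integrated_force_nN for f in self.foci))

    def net_force_ratio(self) -> float:
        total = self.total_magnitude_force_nN()
        if total == 0:
            return 0.0
        return float(np.linalg.norm(self.integrated_net_force()) / total)

    def traction_map(self, grid: RegularGrid) -> tuple[np.ndarray, np.ndarray]:
        """Sample the scene's traction vectors (Pa) on a grid."""
        X, Y = grid.meshgrid()
        tx = np.zeros(grid.shape)
        ty = np.zeros(grid.shape)
        for f in self.foci:
            ca, sa = np.cos(f.angle), np.sin(f.angle)
            dx, dy = X - f.center[0], Y - f.center[1]
            xp = ca * dx + sa * dy          # along major axis
            yp = -sa * dx + ca * dy
            amp = f.peak_stress * np.exp(
                -0.5 * ((xp / f.semi_axes[0]) ** 2 + (yp / f.semi_axes[1]) ** 2))
            tx += amp * ca
            ty += amp * sa
        return tx, ty

    def scaled(self, factor: float) -> "TractionScene":
        return TractionScene(
            tuple(replace(f, peak_stress=f.peak_stress * factor)
                  for f in self.foci),
            self.domain_size, self.seed, self.cell_radii)


def make_cell_scene(total_force_nN: float = 250.0,
                    domain_size: tuple[float, float] = (60.0, 60.0),
                    n_foci: int = 32,
                    cell_radii: tuple[float, float] = (14.0, 10.0),
                    semi_axes: tuple[float, float] = (2.0, 1.0),
                    peak_cv: float = 0.25,
                    seed: int = 0) -> TractionScene:
    """Build a balanced cell-like scene of inward-pulling boundary foci.

    Foci sit on an elliptical "cell" outline at evenly spaced parametric
    angles and pull toward the cell centre. Balance is enforced exactly by
    generating foci in diametrically opposite pairs with equal integrated
    magnitude; peak stresses carry log-normal pair-to-pair variation. The
    whole scene is then rescaled so that the ground-truth summed-magnitude
    force Σ∫|t|dA equals ``total_force_nN``.
    """
    if n_foci % 2:
        raise ValueError("n_foci must be even (foci are balanced in pairs)")
    rng = np.random.default_rng(seed)
    cx, cy = domain_size[0] / 2.0, domain_size[1] / 2.0
    a, b = cell_radii
    half = n_foci // 2
    sig = np.sqrt(np.log(1.0 + peak_cv ** 2))
    foci: list[TractionFocus] = []
    for i in range(half):
        theta = 2.0 * np.pi * i / n_foci
        peak = float(np.exp(rng.normal(-0.5 * sig ** 2, sig)))  # mean 1
        for th in (theta, theta + np.pi):
            px = cx + a * np.cos(th)
            py = cy + b * np.sin(th)
            # pull toward the cell centre
            ang = np.arctan2(cy - py, cx - px)
            foci.append(TractionFocus((px, py), float(ang), peak, semi_axes))
    scene = TractionScene(tuple(foci), domain_size, seed, cell_radii)
    return scene.scaled(total_force_nN / scene.total_magnitude_force_nN())


def boussinesq_forward(scene: TractionScene, gel: GelSubstrate,
                       grid_spacing: float, pad_factor: float = 2.0,
                       balance_tol: float = 1e-8,
                       min_samples_per_semi_axis: int = 4) -> DisplacementField:
    """Displacement of the half-space surface under a traction scene.

    Computed spectrally: the traction map is sampled on a regular grid,
    zero-padded to ``pad_factor`` times its extent (to suppress the
    periodic images of the FFT), multiplied per wavevector by the
    half-space Green's tensor (see :mod:`tfmlab._greens`) and transformed
    back. The zero-frequency (rigid-body) component is set to zero.

    With the default padding, accuracy versus the true aperiodic solution
    is guaranteed on the interior ~50% of the domain; use ``pad_factor=1``
    for the exact periodic counterpart of the FTTC inverse.
    """
    if scene.net_force_ratio() > balance_tol:
        raise ValueError("scene is not force balanced: net/total = "
                         f"{scene.net_force_ratio():.2e}")
    min_axis = min(min(f.semi_axes) for f in scene.foci) if scene.foci else np.inf
    if scene.foci and min_axis / grid_spacing < min_samples_per_semi_axis:
        raise ValueError(
            f"grid spacing {grid_spacing} µm under-resolves the smallest "
            f"focus semi-axis {min_axis} µm "
            f"(need ≥ {min_samples_per_semi_axis} samples per semi-axis)")

    nx = int(round(scene.domain_size[0] / grid_spacing)) + 1
    ny = int(round(scene.domain_size[1] / grid_spacing)) + 1
    grid = RegularGrid((ny, nx), grid_spacing)
    tx, ty = scene.traction_map(grid)
    ux, uy = _forward_spectral(tx, ty, gel, grid_spacing, pad_factor)
    return DisplacementField(grid, ux, uy)


def _padded_shape(shape: tuple[int, int], pad_factor: float) -> tuple[int, int]:
    # pad_factor == 1 must keep the shape exactly: the FTTC inverse is the
    # per-wavevector inverse only when both transforms share one grid
    if pad_factor == 1.0:
        return shape
    return tuple(sfft.next_fast_len(int(np.ceil(n * pad_factor)))
                 for n in shape)


def _forward_spectral(tx: np.ndarray, ty: np.ndarray, gel: GelSubstrate,
                      spacing: float, pad_factor: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = tx.shape
    pny, pnx = _padded_shape((ny, nx), pad_factor)
    kx = 2.0 * np.pi * sfft.fftfreq(pnx, d=spacing)[None, :]
    ky = 2.0 * np.pi * sfft.fftfreq(pny, d=spacing)[:, None]
    Gxx, Gxy, Gyy = greens_fourier(kx, ky, gel)
    Tx = sfft.fft2(tx, s=(pny, pnx))
    Ty = sfft.fft2(ty, s=(pny, pnx))
    Ux = Gxx * Tx + Gxy * Ty
    Uy = Gxy * Tx + Gyy * Ty
    ux = sfft.ifft2(Ux).real[:ny, :nx]
    uy = sfft.ifft2(Uy).real[:ny, :nx]
    return ux, uy


# ---------------------------------------------------------------------------
# bead image rendering
# ---------------------------------------------------------------------------

def _render_gaussians(shape: tuple[int, int], rows: np.ndarray, cols: np.ndarray,
                      sigma_px: float, amplitude: float = 1.0) -> np.ndarray:
    """Accumulate unit-amplitude Gaussians at sub-pixel positions."""
    img = np.zeros(shape)
    half = max(2, int(np.ceil(4.0 * sigma_px)))
    ny, nx = shape
    for r, c in zip(rows, cols):
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        rlo, rhi = max(0, r0 - half), min(ny, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(nx, c0 + half + 1)
        if rlo >= rhi or clo >= chi:
            continue
        rr = np.arange(rlo, rhi)[:, None] - r
        cc = np.arange(clo, chi)[None, :] - c
        img[rlo:rhi, clo:chi] += amplitude * np.exp(
            -(rr ** 2 + cc ** 2) / (2.0 * sigma_px ** 2))
    return img


def render_bead_images(displacement: DisplacementField,
                       bead_density: float = 2.0,
                       psf_sigma: float = 0.15,
                       seed: int = 0,
                       pixel_size: float = 0.1,
                       noise_sd: float = 0.05,
                       return_positions: bool = False):
    """Render an (unstrained reference, strained) fiducial-bead image pair.

    Beads are laid down uniformly at ``bead_density`` beads/µm², rendered
    as Gaussians of σ ``psf_sigma`` µm. The reference image shows beads at
    rest; the strained image shows the same beads displaced by the field
    interpolated (bilinearly) at each bead position — i.e. the relaxed
    image a cell leaves behind after detachment versus the image with the
    cell attached. Both receive i.i.d. Gaussian noise of sd ``noise_sd``
    (bead peak amplitude is 1), drawn from the same seeded generator.

    Warns when the maximum displacement exceeds half the mean bead
    spacing, where window-matching correspondence starts to break.
    """
    if bead_density <= 0:
        raise ValueError("bead_density must be positive")
    rng = np.random.default_rng(seed)
    width, height = displacement.grid.extent
    n_beads = rng.poisson(bead_density * width * height)
    bx = rng.uniform(0.0, width, n_beads)
    by = rng.uniform(0.0, height, n_beads)

    interp_x = RegularGridInterpolator(
        (displacement.grid.y, displacement.grid.x), displacement.ux,
        bounds_error=False, fill_value=0.0)
    interp_y = RegularGridInterpolator(
        (displacement.grid.y, displacement.grid.x), displacement.uy,
        bounds_error=False, fill_value=0.0)
    pts = np.column_stack([by, bx])
    ux_b = interp_x(pts)
    uy_b = interp_y(pts)

    mean_spacing = 1.0 / np.sqrt(bead_density)
    max_disp = float(np.hypot(ux_b, uy_b).max()) if n_beads else 0.0
    if max_disp > 0.5 * mean_spacing:
        warnings.warn(
            f"max displacement {max_disp:.2f} µm exceeds half the mean bead "
            f"spacing {mean_spacing:.2f} µm; window matching may fail",
            stacklevel=2)

    shape = (int(round(height / pixel_size)) + 1,
             int(round(width / pixel_size)) + 1)
    sig_px = psf_sigma / pixel_size
    ref = _render_gaussians(shape, by / pixel_size, bx / pixel_size, sig_px)
    strained = _render_gaussians(shape, (by + uy_b) / pixel_size,
                                 (bx + ux_b) / pixel_size, sig_px)
    if noise_sd > 0:
        ref = ref + rng.normal(0.0, noise_sd, shape)
        strained = strained + rng.normal(0.0, noise_sd, shape)
    if return_positions:
        return ref, strained, np.column_stack([bx, by])
    return ref, strained


# ---------------------------------------------------------------------------
# lamellar actin flow movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowSceneParams:
    """Rigidly translating lamellar texture, the kinematics of retrograde flow.

    Defaults state the wild-type lamella: 0.3 µm/min flow imaged every
    30 s for 30 min. ``granularity`` is the Gaussian correlation length of
    the speckle texture (µm); ``snr`` the texture-sd to noise-sd ratio.
    """

    speed: float = 0.3                      # µm/min
    direction: tuple[float, float] = (1.0, 0.0)
    frame_interval: float = 30.0            # s
    duration: float = 30.0                  # min
    granularity: float = 0.25               # µm
    snr: float = 10.0
    fov: tuple[float, float] = (30.0, 30.0)  # µm
    pixel_size: float = 0.1                 # µm/px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0 or self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("speed must be >= 0; interval and duration > 0")
        n_int = self.duration * 60.0 / self.frame_interval
        if abs(n_int - round(n_int)) > 1e-9 or round(n_int) < 1:
            raise ValueError("duration must be an integer number >= 1 of "
                             "frame intervals")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 60.0 / self.frame_interval)) + 1

    @property
    def shift_per_frame_um(self) -> float:
        """Inter-frame translation in µm."""
        return self.speed * self.frame_interval / 60.0


def synthesize_flow_movie(params: FlowSceneParams) -> np.ndarray:
    """Render a (n_frames, H, W) stack of a translating speckle texture.

    The texture is a smoothed Gaussian random field (unit sd, baseline 2)
    shifted by the exact sub-pixel per-frame displacement with the Fourier
    shift theorem, so features persist for the whole movie; per-frame
    Gaussian noise of sd 1/snr emulates photon noise at the configured
    signal-to-noise ratio.
    """
    px = params.pixel_size
    shift_px = params.shift_per_frame_um / px
    if params.speed > 0 and shift_px < 0.05:
        warnings.warn(f"per-frame shift {shift_px:.3f} px is below the "
                      "0.05 px tracking resolution", stacklevel=2)
    rng = np.random.default_rng(params.seed)
    shape = (int(round(params.fov[1] / px)), int(round(params.fov[0] / px)))
    sigma_px = params.granularity / px
    base = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px,
                                   mode="wrap")
    base = (base - base.mean()) / base.std()

    d = np.asarray(params.direction, dtype=float)
    d = d / np.linalg.norm(d)
    F = sfft.fft2(base)
    ky = sfft.fftfreq(shape[0])[:, None]
    kx = sfft.fftfreq(shape[1])[None, :]
    frames = np.empty((params.n_frames,) + shape)
    for i in range(params.n_frames):
        # cumulative shift keeps the texture persistent across all frames
        sx = shift_px * d[0] * i
        sy = shift_px * d[1] * i
        phase = np.exp(-2j * np.pi * (kx * sx + ky * sy))
        frames[i] = sfft.ifft2(F * phase).real
    frames += 2.0
    if params.snr > 0:
        frames += rng.normal(0.0, 1.0 / params.snr, frames.shape)
    return frames


FLOW_PRESETS: dict[str, FlowSceneParams] = {
    "wild_type": FlowSceneParams(speed=0.3),
    "y27632_2uM": FlowSceneParams(speed=0.3),
    "y27632_5uM": FlowSceneParams(speed=0.3),
    # flow is essentially abrogated at full ROCK inhibition
    "y27632_10uM": FlowSceneParams(speed=0.05),
}


# ---------------------------------------------------------------------------
# focal adhesion track scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FASceneParams:
    """Kinetic parameters of a cohort of synthetic focal adhesions.

    Per-track rates and lifetimes are drawn from log-normal distributions
    with the given means and a common coefficient of variation ``cv``
    (positive support, unimodal peak — the shape the measured histograms
    suggest). ``length_noise_sd``/``stress_noise_sd`` are per-frame
    measurement-like jitters added to the returned traces.
    """

    elongation_rate_mean: float = 0.15     # µm/min
    loading_rate_mean: float = 25.0        # Pa/min
    lifetime_mean: float = 55.0            # min
    disassembly_rate_mean: float = 0.15    # µm/min
    cv: float = 0.3
    length_noise_sd: float = 0.05          # µm
    stress_noise_sd: float = 4.0           # Pa
    frame_interval: float = 30.0           # s
    n_adhesions: int = 100
    movie_duration: float = 150.0          # min
    start_span: float = 20.0               # min, appearance-time window
    initial_length: float = 0.5            # µm, nascent punctum
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("elongation_rate_mean", "loading_rate_mean",
                     "lifetime_mean", "disassembly_rate_mean",
                     "frame_interval", "movie_duration", "initial_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_adhesions < 1:
            raise ValueError("n_adhesions must be >= 1")

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval / 60.0

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_duration / self.frame_interval_min)) + 1


FA_PRESETS: dict[str, FASceneParams] = {
    "wild_type": FASceneParams(),
    # graded ROCK inhibition: loading collapses (7 → 5 → ~1 Pa/min) while the
    # elongation rate is tension-insensitive; lifetime drops by ~half and
    # disassembly speeds up
    "y27632_2uM": FASceneParams(loading_rate_mean=7.0, lifetime_mean=30.0,
                                disassembly_rate_mean=0.25),
    "y27632_5uM": FASceneParams(loading_rate_mean=5.0, lifetime_mean=25.0,
                                disassembly_rate_mean=0.25),
    "y27632_10uM": FASceneParams(elongation_rate_mean=0.03,
                                 loading_rate_mean=1.0, lifetime_mean=10.0,
                                 disassembly_rate_mean=0.1,
                                 movie_duration=60.0),
}

#: total traction force (nN) per condition, for building TFM scenes
CONDITION_PRESETS: dict[str, float] = {
    "wild_type": 250.0,
    "y27632_1uM": 125.0,
    "y27632_2uM": 90.0,
    "y27632_5uM": 60.0,
    "y27632_10uM": 25.0,
}


@dataclass(frozen=True)
class FATrackTruth:
    """Ground-truth kinetics of one synthetic adhesion."""

    track_id: int
    center: tuple[float, float]        # (x, y) µm in the rendered mosaic
    angle: float                       # major-axis orientation, rad
    start_time: float                  # min
    lifetime: float                    # min
    elongation_rate: float             # µm/min
    loading_rate: float                # Pa/min
    disassembly_rate: float            # µm/min
    growth_duration: float             # min
    plateau_duration: float            # min
    decay_duration: float              # min
    initial_length: float              # µm

    @property
    def end_time(self) -> float:
        return self.start_time + self.lifetime

    @property
    def peak_length(self) -> float:
        return self.initial_length + self.elongation_rate * self.growth_duration

    @property
    def peak_stress(self) -> float:
        return self.loading_rate * self.growth_duration

    def length_at(self, t: np.ndarray) -> np.ndarray:
        """Noise-free length (µm) at absolute movie times t (min); NaN when absent."""
        tau = np.asarray(t, dtype=float) - self.start_time
        L = np.full_like(tau, np.nan)
        alive = (tau >= 0) & (tau <= self.lifetime)
        g = np.minimum(tau, self.growth_duration)
        dec = np.clip(tau - self.growth_duration - self.plateau_duration, 0, None)
        val = self.initial_length + self.elongation_rate * g \
            - self.disassembly_rate * dec
        L[alive] = np.maximum(val[alive], 0.3)
        return L

    def stress_at(self, t: np.ndarray) -> np.ndarray:
        """Noise-free local stress (Pa) at absolute movie times; NaN when absent."""
        tau = np.asarray(t, dtype=float) - self.start_time
        S = np.full_like(tau, np.nan)
        alive = (tau >= 0) & (tau <= self.lifetime)
        g = np.minimum(tau, self.growth_duration)
        val = self.loading_rate * g
        dec = self.decay_duration
        if dec > 0:
            fall = np.clip(tau - self.growth_duration - self.plateau_duration,
                           0, None) / dec
            val = val * (1.0 - np.clip(fall, 0, 1))
        S[alive] = np.maximum(val[alive], 0.0)
        return S


@dataclass
class FAScene:
    """A cohort of synthetic adhesions plus a lazily rendered paxillin movie.

    ``movie`` semantics: frames are rendered on demand (``render_frame``)
    so large cohorts never hold a full stack in memory; ``materialize``
    returns the full (n_frames, H, W) array for small scenes.
    """

    params: FASceneParams
    tracks: list[FATrackTruth]
    stress_traces: list[np.ndarray]      # per track, noisy Pa at track frames
    length_traces: list[np.ndarray]      # per track, noisy µm at track frames
    pixel_size: float
    image_shape: tuple[int, int]
    minor_sigma: float                   # µm, fixed footprint width
    amplitude: float
    background: float
    noise_sd: float
    _noise_seed: int

    @property
    def n_frames(self) -> int:
        return self.params.n_frames

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.params.frame_interval_min

    def track_frames(self, tr: FATrackTruth) -> np.ndarray:
        """Frame indices at which a track is present."""
        t = self.times()
        return np.nonzero((t >= tr.start_time) & (t <= tr.end_time))[0]

    def render_frame(self, i: int) -> np.ndarray:
        """Render frame ``i``: live adhesions as anisotropic Gaussians.

        The ground-truth "length" of an adhesion is the major-axis FWHM of
        its Gaussian: σ_major = L / (2√(2 ln 2)).
        """
        t = i * self.params.frame_interval_min
        img = np.full(self.image_shape, self.background)
        px = self.pixel_size
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        for tr, lengths in zip(self.tracks, self.length_traces):
            frames = self.track_frames(tr)
            if i not in frames:
                continue
            L = lengths[np.searchsorted(frames, i)]
            sa = max(L, 0.2) / fwhm / px            # σ_major, px
            sb = self.minor_sigma / px              # σ_minor, px
            ca, sn = np.cos(tr.angle), np.sin(tr.angle)
            half = int(np.ceil(4.0 * max(sa, sb))) + 1
            r0 = int(round(tr.center[1] / px))
            c0 = int(round(tr.center[0] / px))
            rlo, rhi = max(0, r0 - half), min(self.image_shape[0], r0 + half + 1)
            clo, chi = max(0, c0 - half), min(self.image_shape[1], c0 + half + 1)
            rr = np.arange(rlo, rhi)[:, None] - tr.center[1] / px
            cc = np.arange(clo, chi)[None, :] - tr.center[0] / px
            xp = ca * cc + sn * rr
            yp = -sn * cc + ca * rr
            img[rlo:rhi, clo:chi] += self.amplitude * np.exp(
                -0.5 * ((xp / sa) ** 2 + (yp / sb) ** 2))
        if self.noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([self._noise_seed, i]))
            img = img + rng.normal(0.0, self.noise_sd, img.shape)
        return img

    def materialize(self) -> np.ndarray:
        return np.stack([self.render_frame(i) for i in range(self.n_frames)])


def synthesize_fa_tracks(params: FASceneParams,
                         pixel_size: float = 0.1,
                         tile_um: float = 12.0,
                         minor_sigma: float = 0.17,
                         amplitude: float = 1000.0,
                         background: float = 100.0,
                         noise_sd: float = 15.0) -> FAScene:
    """Generate a cohort of focal adhesion tracks and their paxillin movie.

    Each adhesion appears as a nascent punctum, elongates linearly at a
    rate drawn from the elongation distribution while its local stress
    rises at the loading rate, plateaus, then shrinks at the disassembly
    rate; total on-screen time is drawn from the lifetime distribution
    (resampled if shorter than 3 frames). Adhesions are laid out one per
    ``tile_um`` × ``tile_um`` tile of the mosaic image so the automated
    length measurement sees isolated objects.

    Returns an :class:`FAScene` carrying the ground truths, noisy
    per-frame length and stress traces, and the lazily rendered stack.
    """
    rng = np.random.default_rng(params.seed)
    sig = np.sqrt(np.log(1.0 + params.cv ** 2))

    def draw(mean: float, n: int) -> np.ndarray:
        return np.exp(rng.normal(np.log(mean) - 0.5 * sig ** 2, sig, n))

    n = params.n_adhesions
    n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    shape = (int(round(n_rows * tile_um / pixel_size)),
             int(round(n_cols * tile_um / pixel_size)))

    min_life = 3 * params.frame_interval_min
    tracks: list[FATrackTruth] = []
    for i in range(n):
        T = float(draw(params.lifetime_mean, 1)[0])
        while T < min_life:
            T = float(draw(params.lifetime_mean, 1)[0])
        re = float(draw(params.elongation_rate_mean, 1)[0])
        rl = float(draw(params.loading_rate_mean, 1)[0])
        rd = float(draw(params.disassembly_rate_mean, 1)[0])
        t0 = float(rng.uniform(0.0, params.start_span))
        grow = 0.3 * T
        # cap the shrinkage phase so the length stays above the nascent
        # punctum size: the decay is then genuinely linear at rate rd
        peak_len = params.initial_length + re * grow
        decay = min(0.3 * T, max(peak_len - 0.35, 0.0) / rd)
        plateau = T - grow - decay
        row, col = divmod(i, n_cols)
        jitter = rng.uniform(-1.0, 1.0, 2)
        center = ((col + 0.5) * tile_um + jitter[0],
                  (row + 0.5) * tile_um + jitter[1])
        angle = float(rng.uniform(0.0, np.pi))
        tracks.append(FATrackTruth(
            track_id=i, center=center, angle=angle, start_time=t0,
            lifetime=T, elongation_rate=re, loading_rate=rl,
            disassembly_rate=rd, growth_duration=grow,
            plateau_duration=plateau, decay_duration=decay,
            initial_length=params.initial_length))

    times = np.arange(params.n_frames) * params.frame_interval_min
    length_traces, stress_traces = [], []
    for tr in tracks:
        alive = (times >= tr.start_time) & (times <= tr.end_time)
        tt = times[alive]
        L = tr.length_at(tt)
        S = tr.stress_at(tt)
        L = np.maximum(L + rng.normal(0.0, params.length_noise_sd, L.shape), 0.2)
        S = np.maximum(S + rng.normal(0.0, params.stress_noise_sd, S.shape), 0.0)
        length_traces.append(L)
        stress_traces.append(S)

    return FAScene(params=params, tracks=tracks, stress_traces=stress_traces,
                   length_traces=length_traces, pixel_size=pixel_size,
                   image_shape=shape, minor_sigma=minor_sigma,
                   amplitude=amplitude, background=background,
                   noise_sd=noise_sd, _noise_seed=params.seed)
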