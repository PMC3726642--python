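import numpy as np
import pytest

from tfmlab import GelSubstrate, RegularGrid, TractionFocus, TractionScene


@pytest.fixture(scope="session")
def gel() -> GelSubstrate:
    return GelSubstrate()


@pytest.fixture(scope="session")
def dipole_scene() -> TractionScene:
    """Equal-and-opposite x-directed traction pair on a 30×30 µm domain."""
    return TractionScene(
        (TractionFocus((11.0, 15.0), 0.0, 200.0, (1.2, 1.2)),
         TractionFocus((19.0, 15.0), np.pi, 200.0, (1.2, 1.2))),
        (30.0, 30.0))


def make_bead_frame(shape=(120, 120), n_beads=140, sigma=1.5, seed=0,
                    margin=10):
    """Noise-free image of Gaussian beads at random sub-pixel positions."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r, c in rng.uniform(margin, min(shape) - margin, (n_beads, 2)):
        img += np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma ** 2))
    return img


@pytest.fixture(scope="session")
def bead_frame() -> np.ndarray:
    return make_bead_frame()


def render_adhesion(length_um, angle=0.3, amplitude=1000.0, background=100.0,
                    noise_sd=15.0, pixel_size=0.1, minor_sigma=0.17,
                    pad_um=4.0, seed=0):
    """One anisotropic-Gaussian adhesion; 'length' is the major-axis FWHM."""
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
    n = int(round((length_um + 2 * pad_um) / pixel_size))
    ctr = n * pixel_size / 2.0
    sa = length_um / fwhm / pixel_size
    sb = minor_sigma / pixel_size
    rr, cc = np.mgrid[0:n, 0:n]
    ca, sn = np.cos(angle), np.sin(angle)
    xp = ca * (cc - ctr / pixel_size) + sn * (rr - ctr / pixel_size)
    yp = -sn * (cc - ctr / pixel_size) + ca * (rr - ctr / pixel_size)
    img = background + amplitude * np.exp(-0.5 * ((xp / sa) ** 2 +
                                                  (yp / sb) ** 2))
    if noise_sd > 0:
        img = img + np.random.default_rng(seed).normal(0, noise_sd, img.shape)
    return img, (ctr, ctr)
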