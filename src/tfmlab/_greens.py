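"""Fourier-space Green's tensor of the elastic half space.

Both the forward substrate model and the traction reconstruction share this
kernel, so the forward/inverse pair is exactly consistent on a common grid.
"""

from __future__ import annotations

import numpy as np

from .core import GelSubstrate


def greens_fourier(kx: np.ndarray, ky: np.ndarray,
                   gel: GelSubstrate) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface-displacement response to surface traction, per wavevector.

    Standard half-space (Boussinesq) solution used by Fourier-transform
    traction cytometry:

        G(k) = 2(1+ν) / (E k³) · [[(1−ν)k² + ν·ky²,  −ν·kx·ky],
                                  [−ν·kx·ky,  (1−ν)k² + ν·kx²]]

    with E = 2·G_shear·(1+ν). With k in rad/µm and tractions in Pa the
    entries are in µm/Pa. The k = 0 entry (free rigid-body mode) is set to
    zero; callers must treat the zero frequency separately.

    Returns the symmetric tensor components ``(Gxx, Gxy, Gyy)`` with the
    broadcast shape of ``kx``/``ky``.
    """
    nu = gel.poisson_ratio
    E = gel.youngs_modulus
    k2 = kx ** 2 + ky ** 2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k ** 3)
        Gxx = pref * ((1.0 - nu) * k2 + nu * ky ** 2)
        Gxy = pref * (-nu * kx * ky)
        Gyy = pref * ((1.0 - nu) * k2 + nu * kx ** 2)
    zero = k2 == 0
    for comp in (Gxx, Gxy, Gyy):
        comp[zero] = 0.0
    return Gxx, Gxy, Gyy


def greens_max_singular_value(kx: np.ndarray, ky: np.ndarray,
                              gel: GelSubstrate) -> float:
    """Largest singular value of G(k) over the nonzero wavevectors.

    The eigenvalues of G(k) are 2(1+ν)/(E·k) and 2(1+ν)(1−ν)/(E·k), so the
    maximum is attained at the smallest nonzero |k|. Used to express the
    Tikhonov parameter on a dimensionless, grid-independent scale.
    """
    k = np.hypot(kx, ky)
    kmin = k[k > 0].min()
    return 2.0 * (1.0 + gel.poisson_ratio) / (gel.youngs_modulus * kmin)


def boussinesq_kernel_realspace(x: np.ndarray, y: np.ndarray,
                                gel: GelSubstrate) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real-space Boussinesq surface kernel K(r), µm displacement per (Pa·µm²).

        K = (1+ν) / (π E r³) · [[(1−ν)r² + ν x²,  ν x y],
                                [ν x y,  (1−ν)r² + ν y²]]

    Singular (integrably) at r = 0; the r = 0 entry is returned as 0 and
    must be handled by the caller (e.g. analytic cell self-term). This is
    the inverse Fourier transform of :func:`greens_fourier` and serves as
    an independent cross-check of the spectral forward model.
    """
    nu = gel.poisson_ratio
    E = gel.youngs_modulus
    r2 = x ** 2 + y ** 2
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = (1.0 + nu) / (np.pi * E * r ** 3)
        Kxx = pref * ((1.0 - nu) * r2 + nu * x ** 2)
        Kxy = pref * (nu * x * y)
        Kyy = pref * ((1.0 - nu) * r2 + nu * y ** 2)
    zero = r2 == 0
    for comp in (Kxx, Kxy, Kyy):
        comp[zero] = 0.0
    return Kxx, Kxy, Kyy
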