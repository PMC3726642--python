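"""Traction reconstruction by regularized Fourier-transform traction cytometry.

The inverse problem (displacement → traction on an elastic half space) is
solved wavevector-by-wavevector with zeroth-order (Tikhonov) regularization,

    t(k) = (G(k)ᵀ G(k) + λ'² I)⁻¹ G(k)ᵀ u(k),

using the same Green's tensor as the forward model so that the
forward/inverse pair is exact at λ = 0 on a common (periodic) grid. λ is
supplied on a normalized, grid-independent scale: the value actually
applied is λ' = λ · s_max with s_max the largest singular value of G over
the grid's wavevectors.

Derived quantities follow the conventions of cell traction work: total
force as the background-subtracted sum of stress magnitudes times area,
per-adhesion stress via Gaussian-weighted interpolation, and per-adhesion
force as peak stress times stress-footprint area (1 Pa·µm² = 1e-3 nN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from skimage import measure

from ._greens import greens_fourier, greens_max_singular_value
from .core import (PA_UM2_TO_NN, DisplacementField, GelSubstrate,
                   RegularGrid, TractionField)

__all__ = ["ForceSummary", "FAStress", "fttc_inverse", "select_lambda_lcurve",
           "select_lambda_discrepancy", "total_force", "fa_stress", "fa_force",
           "stress_footprint"]


@dataclass(frozen=True)
class ForceSummary:
    """Total traction force of one cell."""

    total_force: float      # nN
    area: float             # µm² covered by the cell mask
    background: float       # Pa subtracted per node

    def __post_init__(self) -> None:
        if self.total_force < 0:
            raise ValueError("total_force must be >= 0")


@dataclass(frozen=True)
class FAStress:
    """Gaussian-weighted local stress at one adhesion."""

    weighted_mean: float    # Pa
    peak: float             # Pa, max |t| within 2σ of the centre
    center: tuple[float, float]
    sigma: float


def _spectral_pair(grid: RegularGrid, gel: GelSubstrate, pad_factor: float):
    if pad_factor == 1.0:
        pny, pnx = grid.shape  # unpadded: exact counterpart of the forward map
    else:
        pny = sfft.next_fast_len(int(np.ceil(grid.shape[0] * pad_factor)))
        pnx = sfft.next_fast_len(int(np.ceil(grid.shape[1] * pad_factor)))
    kx = 2.0 * np.pi * sfft.fftfreq(pnx, d=grid.spacing)[None, :]
    ky = 2.0 * np.pi * sfft.fftfreq(pny, d=grid.spacing)[:, None]
    return (pny, pnx), kx, ky


def fttc_inverse(displacement: DisplacementField, gel: GelSubstrate,
                 lam: float = 0.0, pad_factor: float = 2.0) -> TractionField:
    """Reconstruct the traction field from a gridded displacement field.

    Invalid displacement nodes are filled by nearest-valid interpolation
    before the transform (holes would otherwise leak spectrally), the
    field is zero-padded by ``pad_factor``, and the Tikhonov-regularized
    per-wavevector solve above is applied. The zero-frequency traction is
    set to zero and the result cropped back to the input grid.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not np.isfinite(displacement.ux[displacement.valid]).all() or \
       not np.isfinite(displacement.uy[displacement.valid]).all():
        raise ValueError("displacement field contains non-finite values")
    if lam == 0:
        warnings.warn("λ = 0: unregularized inversion amplifies "
                      "high-frequency noise", stacklevel=2)
    filled = displacement.filled() if not displacement.valid.all() \
        else displacement
    if not np.isfinite(filled.ux).all() or not np.isfinite(filled.uy).all():
        raise ValueError("displacement field contains non-finite values")
    grid = displacement.grid
    (pny, pnx), kx, ky = _spectral_pair(grid, gel, pad_factor)
    Gxx, Gxy, Gyy = greens_fourier(kx, ky, gel)
    lam_applied = lam * greens_max_singular_value(kx, ky, gel)

    Ux = sfft.fft2(filled.ux, s=(pny, pnx))
    Uy = sfft.fft2(filled.uy, s=(pny, pnx))
    # per-k normal equations for the symmetric 2×2 system
    Axx = Gxx * Gxx + Gxy * Gxy + lam_applied ** 2
    Axy = Gxy * (Gxx + Gyy)
    Ayy = Gyy * Gyy + Gxy * Gxy + lam_applied ** 2
    bx = Gxx * Ux + Gxy * Uy
    by = Gxy * Ux + Gyy * Uy
    det = Axx * Ayy - Axy ** 2
    zero = det == 0.0  # only the k = 0 mode; G is invertible elsewhere
    det[zero] = 1.0
    Tx = (Ayy * bx - Axy * by) / det
    Ty = (-Axy * bx + Axx * by) / det
    Tx[zero] = 0.0
    Ty[zero] = 0.0
    Tx[0, 0] = Ty[0, 0] = 0.0
    ny, nx = grid.shape
    tx = sfft.ifft2(Tx).real[:ny, :nx]
    ty = sfft.ifft2(Ty).real[:ny, :nx]
    return TractionField(grid, tx, ty, lam=lam)


def select_lambda_lcurve(displacement: DisplacementField, gel: GelSubstrate,
                         lambdas: np.ndarray | None = None,
                         pad_factor: float = 2.0) -> float:
    """Pick λ at the corner (max curvature) of the L-curve.

    Sweeps λ over a log grid, records (log residual norm ‖Gt − u‖,
    log solution norm ‖t‖) and returns the λ of maximum curvature of that
    parametric curve — the standard compromise between data fidelity and
    amplification of noise.
    """
    if lambdas is None:
        lambdas = np.logspace(-5, -0.5, 20)
    grid = displacement.grid
    filled = displacement.filled() if not displacement.valid.all() \
        else displacement
    (pny, pnx), kx, ky = _spectral_pair(grid, gel, pad_factor)
    Gxx, Gxy, Gyy = greens_fourier(kx, ky, gel)
    smax = greens_max_singular_value(kx, ky, gel)
    Ux = sfft.fft2(filled.ux, s=(pny, pnx))
    Uy = sfft.fft2(filled.uy, s=(pny, pnx))
    res_n, sol_n = [], []
    for lam in lambdas:
        la = lam * smax
        Axx = Gxx * Gxx + Gxy * Gxy + la ** 2
        Axy = Gxy * (Gxx + Gyy)
        Ayy = Gyy * Gyy + Gxy * Gxy + la ** 2
        bx = Gxx * Ux + Gxy * Uy
        by = Gxy * Ux + Gyy * Uy
        det = Axx * Ayy - Axy ** 2
        det[det == 0] = 1.0
        Tx = (Ayy * bx - Axy * by) / det
        Ty = (-Axy * bx + Axx * by) / det
        Tx[0, 0] = Ty[0, 0] = 0.0
        Rx = Gxx * Tx + Gxy * Ty - Ux
        Ry = Gxy * Tx + Gyy * Ty - Uy
        Rx[0, 0] = Ry[0, 0] = 0.0
        res_n.append(np.sqrt((np.abs(Rx) ** 2 + np.abs(Ry) ** 2).sum()))
        sol_n.append(np.sqrt((np.abs(Tx) ** 2 + np.abs(Ty) ** 2).sum()))
    x = np.log10(np.maximum(res_n, 1e-300))
    y = np.log10(np.maximum(sol_n, 1e-300))
    t = np.log10(lambdas)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx ** 2 + dy ** 2) ** 1.5
    denom[denom == 0] = np.inf
    curvature = (dx * ddy - dy * ddx) / denom
    interior = slice(1, len(lambdas) - 1)  # endpoints have one-sided stencils
    return float(lambdas[interior][int(np.argmax(curvature[interior]))])


def select_lambda_discrepancy(displacement: DisplacementField,
                              gel: GelSubstrate, noise_sd: float,
                              tau: float = 1.0,
                              lambdas: np.ndarray | None = None,
                              pad_factor: float = 2.0) -> float:
    """Morozov discrepancy principle: smallest λ whose residual matches noise.

    Picks λ such that ‖G t_λ − u‖ ≈ τ · ‖n‖ with ‖n‖ the norm of a
    displacement-noise field of per-component sd ``noise_sd`` (µm, e.g.
    from :func:`tfmlab.displacement.estimate_noise_um`). More robust than
    the L-curve corner when the displacement field has been pre-smoothed
    (kriging), which leaves the L-curve without a distinct corner.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if lambdas is None:
        lambdas = np.logspace(-5, 0, 40)
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    grid = displacement.grid
    filled = displacement.filled() if not displacement.valid.all() \
        else displacement
    (pny, pnx), kx, ky = _spectral_pair(grid, gel, pad_factor)
    Gxx, Gxy, Gyy = greens_fourier(kx, ky, gel)
    smax = greens_max_singular_value(kx, ky, gel)
    Ux = sfft.fft2(filled.ux, s=(pny, pnx))
    Uy = sfft.fft2(filled.uy, s=(pny, pnx))
    ny, nx = grid.shape
    target = tau * noise_sd * np.sqrt(2.0 * ny * nx) * np.sqrt(pny * pnx)
    for lam in lambdas:  # residual norm is increasing in λ
        la = lam * smax
        Axx = Gxx * Gxx + Gxy * Gxy + la ** 2
        Axy = Gxy * (Gxx + Gyy)
        Ayy = Gyy * Gyy + Gxy * Gxy + la ** 2
        bx = Gxx * Ux + Gxy * Uy
        by = Gxy * Ux + Gyy * Uy
        det = Axx * Ayy - Axy ** 2
        det[det == 0] = 1.0
        Tx = (Ayy * bx - Axy * by) / det
        Ty = (-Axy * bx + Axx * by) / det
        Tx[0, 0] = Ty[0, 0] = 0.0
        Rx = Gxx * Tx + Gxy * Ty - Ux
        Ry = Gxy * Tx + Gyy * Ty - Uy
        Rx[0, 0] = Ry[0, 0] = 0.0
        if np.sqrt((np.abs(Rx) ** 2 + np.abs(Ry) ** 2).sum()) >= target:
            return float(lam)
    return float(lambdas[-1])


def total_force(traction: TractionField, cell_mask: np.ndarray,
                background_region: np.ndarray) -> ForceSummary:
    """Background-subtracted total traction force under a cell mask.

    background = mean |t| over ``background_region`` (outside the cell);
    total = Σ over the mask of max(|t| − background, 0) × cell area, nN.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    background_region = np.asarray(background_region, dtype=bool)
    if cell_mask.shape != traction.grid.shape or \
       background_region.shape != traction.grid.shape:
        raise ValueError("masks must match the traction grid shape")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if not background_region.any():
        raise ValueError("empty background region")
    if (cell_mask & background_region).any():
        raise ValueError("cell mask and background region must be disjoint")
    mag = traction.magnitude()
    bg = float(mag[background_region].mean())
    excess = np.clip(mag[cell_mask] - bg, 0.0, None)
    force = float(excess.sum() * traction.grid.cell_area * PA_UM2_TO_NN)
    return ForceSummary(total_force=force,
                        area=float(cell_mask.sum() * traction.grid.cell_area),
                        background=bg)


def fa_stress(traction: TractionField, fa_center: tuple[float, float],
              gaussian_sigma: float = 1.0) -> FAStress:
    """Local stress at an adhesion by Gaussian-weighted interpolation.

    Returns both the Gaussian-weighted mean of |t| centred at
    ``fa_center`` (x, y in µm) and the peak |t| within 2σ of the centre
    (the value that feeds :func:`fa_force`). Weights are renormalized, so
    kernels truncated at the grid boundary stay unbiased (a warning is
    issued when the centre sits within σ of the boundary).
    """
    grid = traction.grid
    x0, y0 = fa_center
    if not (grid.x[0] <= x0 <= grid.x[-1] and grid.y[0] <= y0 <= grid.y[-1]):
        raise ValueError("fa_center lies outside the grid")
    if (x0 - grid.x[0] < gaussian_sigma or grid.x[-1] - x0 < gaussian_sigma or
            y0 - grid.y[0] < gaussian_sigma or grid.y[-1] - y0 < gaussian_sigma):
        warnings.warn("fa_center within σ of the grid boundary; kernel "
                      "truncated (weights renormalized)", stacklevel=2)
    X, Y = grid.meshgrid()
    r2 = (X - x0) ** 2 + (Y - y0) ** 2
    w = np.exp(-0.5 * r2 / gaussian_sigma ** 2)
    mag = traction.magnitude()
    weighted = float((w * mag).sum() / w.sum())
    near = r2 <= (2.0 * gaussian_sigma) ** 2
    peak = float(mag[near].max()) if near.any() else weighted
    return FAStress(weighted_mean=weighted, peak=peak, center=fa_center,
                    sigma=gaussian_sigma)


def fa_force(peak_stress: float, footprint_area: float) -> float:
    """Adhesion force (nN) = peak stress (Pa) × stress-footprint area (µm²)."""
    if peak_stress <= 0 or footprint_area <= 0:
        raise ValueError("peak_stress and footprint_area must be positive")
    return peak_stress * footprint_area * PA_UM2_TO_NN


def stress_footprint(traction: TractionField, fa_center: tuple[float, float],
                     threshold_fraction: float = 0.5,
                     background: float | None = None,
                     search_radius: float = 2.0,
                     max_domain_fraction: float = 0.25) -> float:
    """Area (µm²) of the stress footprint attributed to one adhesion.

    The footprint is the connected region around ``fa_center`` where
    |t| − background ≥ threshold_fraction × (peak − background), with the
    peak taken as the largest |t| within ``search_radius`` µm of the
    centre. A region spanning more than ``max_domain_fraction`` of the
    grid is rejected as non-localized (e.g. a uniform field).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    grid = traction.grid
    bg = traction.background if background is None else background
    mag = traction.magnitude()
    X, Y = grid.meshgrid()
    near = (X - fa_center[0]) ** 2 + (Y - fa_center[1]) ** 2 \
        <= search_radius ** 2
    if not near.any():
        raise ValueError("fa_center outside the grid")
    peak = float(mag[near].max())
    if peak - bg <= 0:
        raise ValueError("no stress above background near fa_center")
    above = mag - bg >= threshold_fraction * (peak - bg)
    labels = measure.label(above, connectivity=1)
    peak_idx = np.unravel_index(np.argmax(np.where(near, mag, -np.inf)),
                                mag.shape)
    lab = labels[peak_idx]
    if lab == 0:
        raise ValueError("no connected region above threshold at fa_center")
    comp = labels == lab
    if comp.mean() > max_domain_fraction:
        raise ValueError("stress footprint is not localized "
                         f"(covers {comp.mean():.0%} of the domain)")
    return float(comp.sum() * grid.cell_area)
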