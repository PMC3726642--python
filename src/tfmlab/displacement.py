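"""Substrate displacement estimation from strained/unstrained bead images.

The stages mirror standard traction-microscopy practice: rigid drift
alignment, block-matching particle image velocimetry with the minimum
quadratic differences (MQD) criterion plus paraboloid sub-pixel
refinement, outlier filtering by the normalized-median test, and ordinary
kriging of the surviving vectors onto a regular physical grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

from .core import DisplacementField, RegularGrid

__all__ = ["RawVectorField", "align_drift", "piv_mqd", "filter_vectors",
           "krige_to_grid", "subpixel_refine"]


@dataclass
class RawVectorField:
    """PIV vectors on the interrogation-window grid, in pixel units.

    All arrays share the 2-D window-grid shape. ``x``/``y`` are window
    centres (pixels), ``u``/``v`` displacements (pixels, x right / y
    down), ``quality`` the ratio of the second-lowest to the lowest local
    minimum of the MQD surface (≥ 1; higher = less ambiguous).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    quality: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shp = self.x.shape
        for a in (self.y, self.u, self.v, self.quality, self.valid):
            if a.shape != shp:
                raise ValueError("all RawVectorField arrays must share a shape")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def subpixel_refine(surface: np.ndarray, idx: tuple[int, int],
                    minimum: bool = True) -> np.ndarray:
    """Three-point parabola fit per axis around an extremum.

    Returns the (row, col) sub-pixel offset from ``idx``. The guarded
    one-dimensional fit is the standard PIV refinement: offsets are
    bounded to (−0.5, 0.5) by construction when ``idx`` is a true local
    extremum, and degenerate (flat) neighbourhoods yield zero offset.
    Border extrema are returned unrefined.
    """
    r, c = idx
    out = np.zeros(2)
    if not (0 < r < surface.shape[0] - 1 and 0 < c < surface.shape[1] - 1):
        return out
    sgn = 1.0 if minimum else -1.0
    if minimum and surface[r, c] == 0.0:
        return out  # exact match; nothing to refine
    for ax, (m, z, p) in enumerate([
            (surface[r - 1, c], surface[r, c], surface[r + 1, c]),
            (surface[r, c - 1], surface[r, c], surface[r, c + 1])]):
        denom = sgn * (m - 2.0 * z + p)
        if denom > 1e-300:
            off = sgn * (m - p) / (2.0 * denom)
            if np.isfinite(off) and abs(off) <= 1.0:
                out[ax] = off
    return out


def _xcorr_peak_ratio(corr: np.ndarray) -> tuple[tuple[int, int], float]:
    """Peak location and primary/secondary peak ratio of a correlation map."""
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    footprint = np.ones((3, 3), bool)
    local_max = (ndimage.maximum_filter(corr, footprint=footprint) == corr)
    vals = np.sort(corr[local_max])[::-1]
    if len(vals) < 2 or vals[1] <= 0:
        return peak, np.inf
    return peak, float(vals[0] / vals[1])


def align_drift(reference: np.ndarray, strained: np.ndarray,
                mask: np.ndarray | None = None,
                peak_ratio_min: float = 1.1,
                upsample: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove whole-image rigid drift between an image pair.

    The translation is estimated by cross-correlation of the reference
    against the strained image, restricted to ``mask`` (a region outside
    the cell) when given, and removed from the strained image by Fourier
    shifting. Returns ``(reference, aligned_strained, drift)`` with drift
    as ``(dx, dy)`` in pixels (the shift of the strained image relative to
    the reference). When the correlation peak is ambiguous (primary /
    secondary peak ratio below ``peak_ratio_min``) a warning is issued and
    zero drift is returned.
    """
    if reference.shape != strained.shape:
        raise ValueError("images must have identical dimensions")
    a = np.where(mask, reference, 0.0) if mask is not None else reference
    b = np.where(mask, strained, 0.0) if mask is not None else strained
    a = a - a.mean()
    b = b - b.mean()
    F = sfft.fft2(a) * np.conj(sfft.fft2(b))
    corr = sfft.ifft2(F / np.maximum(np.abs(F), 1e-12)).real  # phase correlation
    peak, ratio = _xcorr_peak_ratio(corr)
    if ratio < peak_ratio_min:
        warnings.warn("ambiguous drift correlation peak "
                      f"(ratio {ratio:.3f} < {peak_ratio_min}); assuming zero "
                      "drift", stacklevel=2)
        return reference, strained, np.zeros(2)
    # integer peak (wrapped), then sub-pixel by local upsampled correlation
    shifts = np.array(peak, dtype=float)
    for ax, n in zip((0, 1), corr.shape):
        if shifts[ax] > n // 2:
            shifts[ax] -= n
    sub = subpixel_refine(np.roll(corr, (1 - peak[0], 1 - peak[1]), (0, 1))[:3, :3],
                          (1, 1), minimum=False)
    shifts += sub
    # corr peak at s means strained(x) ≈ reference(x + s): drift = -s in
    # (row, col); report (dx, dy)
    drift = np.array([-shifts[1], -shifts[0]])
    ky = sfft.fftfreq(strained.shape[0])[:, None]
    kx = sfft.fftfreq(strained.shape[1])[None, :]
    aligned = sfft.ifft2(sfft.fft2(strained) *
                         np.exp(2j * np.pi * (kx * drift[0] + ky * drift[1]))).real
    return reference, aligned, drift


def piv_mqd(reference: np.ndarray, strained: np.ndarray,
            window_size: int = 16, grid_spacing: float = 0.8,
            pixel_size: float = 0.1, search_range: int = 6,
            min_window_std: float = 1e-3,
            subpixel: bool = True) -> RawVectorField:
    """Block-matching PIV with the minimum-quadratic-differences criterion.

    For each interrogation window centred on a regular grid (spacing
    ``grid_spacing`` µm), the window of the strained image is compared
    against shifted windows of the reference; the integer shift minimizing
    the mean squared intensity difference is refined to sub-pixel
    precision by a paraboloid fit of the MQD surface around its minimum.
    The reported vector is the bead displacement from reference to
    strained. Quality is the ratio of the second-lowest to the lowest
    local minimum of the MQD surface; windows with near-flat content (no
    beads, std below ``min_window_std``) are flagged invalid.
    """
    if window_size < 8:
        raise ValueError("window_size must be >= 8 pixels")
    if reference.shape != strained.shape:
        raise ValueError("images must have identical dimensions")
    h = window_size // 2
    R = search_range
    step = max(1, int(round(grid_spacing / pixel_size)))
    ny, nx = reference.shape
    margin = h + R
    rows = np.arange(margin, ny - margin - (window_size % 2) + 1, step)
    cols = np.arange(margin, nx - margin - (window_size % 2) + 1, step)
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("images too small for the requested window/search")

    shape = (len(rows), len(cols))
    u = np.zeros(shape)
    v = np.zeros(shape)
    q = np.zeros(shape)
    valid = np.ones(shape, dtype=bool)
    footprint = np.ones((3, 3), bool)

    for j, r in enumerate(rows):
        for i, c in enumerate(cols):
            win = strained[r - h:r - h + window_size,
                           c - h:c - h + window_size]
            if win.std() < min_window_std:
                valid[j, i] = False
                continue
            region = reference[r - h - R:r - h + window_size + R,
                               c - h - R:c - h + window_size + R]
            cand = sliding_window_view(region, (window_size, window_size))
            ssd = ((cand - win[None, None]) ** 2).mean(axis=(2, 3))
            jmin, imin = np.unravel_index(np.argmin(ssd), ssd.shape)
            local_min = (ndimage.minimum_filter(ssd, footprint=footprint) == ssd)
            vals = np.sort(ssd[local_min])
            q[j, i] = float(vals[1] / max(vals[0], 1e-12)) if len(vals) > 1 \
                else np.inf
            sub = subpixel_refine(ssd, (jmin, imin), minimum=True) \
                if subpixel else np.zeros(2)
            # ssd minimum at offset o ⇒ strained window matches reference at
            # centre + o ⇒ beads moved by −o
            v[j, i] = -(jmin - R + sub[0])
            u[j, i] = -(imin - R + sub[1])

    X, Y = np.meshgrid(cols.astype(float), rows.astype(float))
    return RawVectorField(X, Y, u, v, q, valid)


def filter_vectors(raw: RawVectorField, quality_min: float = 1.05,
                   neighbor_deviation_max: float = 2.0,
                   eps_px: float = 0.1,
                   max_invalid_fraction: float = 0.5) -> RawVectorField:
    """Flag spurious vectors by quality and the normalized-median test.

    A vector is invalidated when its MQD quality ratio falls below
    ``quality_min`` or when its normalized residual from the median of its
    8 grid neighbours,
    ``r = |v − med| / (median |v_nb − med| + eps)``, exceeds
    ``neighbor_deviation_max`` (the universal PIV outlier test). Raises if
    more than ``max_invalid_fraction`` of the field ends up invalid.
    """
    valid = raw.valid & (raw.quality >= quality_min)
    ny, nx = raw.u.shape
    upad = np.pad(raw.u, 1, constant_values=np.nan)
    vpad = np.pad(raw.v, 1, constant_values=np.nan)
    vmask = np.pad(valid, 1, constant_values=False)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]
    nb_u = np.stack([np.where(vmask[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx],
                              upad[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx],
                              np.nan) for dr, dc in offsets])
    nb_v = np.stack([np.where(vmask[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx],
                              vpad[1 + dr:1 + dr + ny, 1 + dc:1 + dc + nx],
                              np.nan) for dr, dc in offsets])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med_u = np.nanmedian(nb_u, axis=0)
        med_v = np.nanmedian(nb_v, axis=0)
        res_u = np.nanmedian(np.abs(nb_u - med_u), axis=0)
        res_v = np.nanmedian(np.abs(nb_v - med_v), axis=0)
    norm_res = np.hypot(
        np.where(np.isnan(med_u), 0.0, (raw.u - np.nan_to_num(med_u))) /
        (np.nan_to_num(res_u) + eps_px),
        np.where(np.isnan(med_v), 0.0, (raw.v - np.nan_to_num(med_v))) /
        (np.nan_to_num(res_v) + eps_px))
    has_neighbors = ~np.isnan(med_u)
    outlier = has_neighbors & (norm_res > neighbor_deviation_max)
    new_valid = valid & ~outlier
    frac_invalid = 1.0 - new_valid.mean()
    if frac_invalid > max_invalid_fraction:
        raise ValueError(f"{frac_invalid:.0%} of vectors invalid; "
                         "displacement field unusable")
    return RawVectorField(raw.x, raw.y, raw.u, raw.v, raw.quality, new_valid)


def estimate_noise_um(filtered: RawVectorField, pixel_size: float = 0.1) -> float:
    """Per-component displacement noise (µm) from neighbour-median residuals.

    The robust (MAD-based) spread of each vector around the median of its
    8 neighbours estimates the PIV measurement noise, since the true
    elastic field is smooth on the window-grid scale. Feeds the
    discrepancy-principle choice of the regularization parameter.
    """
    sel = filtered.valid
    u, v = filtered.u.copy(), filtered.v.copy()
    u[~sel] = np.nan
    v[~sel] = np.nan
    res = []
    for comp in (u, v):
        pad = np.pad(comp, 1, constant_values=np.nan)
        nb = np.stack([pad[1 + dr:1 + dr + comp.shape[0],
                           1 + dc:1 + dc + comp.shape[1]]
                       for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                       if (dr, dc) != (0, 0)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(nb, axis=0)
        r = np.abs(comp - med)
        res.append(r[np.isfinite(r)])
    mad = np.median(np.concatenate(res))
    return float(1.4826 * mad * pixel_size)


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def _exponential_variogram(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-h / np.maximum(rng, 1e-9)))


def _fit_variogram(pos: np.ndarray, val: np.ndarray, n_lags: int = 15,
                   max_pairs: int = 1500) -> tuple[float, float, float]:
    """Least-squares exponential-model fit to the empirical variogram."""
    n = len(pos)
    if n > max_pairs:
        rs = np.random.default_rng(0)
        keep = rs.choice(n, max_pairs, replace=False)
        pos, val = pos[keep], val[keep]
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    g = 0.5 * (val[:, None] - val[None, :]) ** 2
    iu = np.triu_indices(len(pos), 1)
    d, g = d[iu], g[iu]
    hmax = d.max()
    edges = np.linspace(0, hmax / 2.0, n_lags + 1)
    centers, gamma = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() >= 5:
            centers.append(d[sel].mean())
            gamma.append(g[sel].mean())
    centers = np.asarray(centers)
    gamma = np.asarray(gamma)
    if len(centers) < 3 or gamma.max() <= 0:
        # degenerate (e.g. constant field): flat variogram
        return 0.0, max(gamma.max() if len(gamma) else 0.0, 1e-12), hmax / 4.0
    p0 = (0.0, float(gamma.max()), float(centers.mean()))
    try:
        popt, _ = curve_fit(_exponential_variogram, centers, gamma, p0=p0,
                            bounds=([0, 1e-12, 1e-6],
                                    [gamma.max(), 10 * gamma.max(), 10 * hmax]),
                            maxfev=5000)
        return tuple(popt)  # type: ignore[return-value]
    except RuntimeError:
        return 0.0, float(gamma.max()), float(centers.mean())


def krige_to_grid(filtered: RawVectorField, grid: RegularGrid,
                  pixel_size: float = 0.1, nugget: float | None = 0.0,
                  min_vectors: int = 10) -> DisplacementField:
    """Ordinary kriging of filtered PIV vectors onto a regular µm grid.

    Each displacement component is interpolated independently with an
    exponential-variogram ordinary-kriging model whose sill and range are
    fit by least squares to the empirical variogram (nugget defaults to 0,
    making the interpolant exact at the sample locations). Duplicate
    sample positions are averaged before solving. Input positions and
    vectors are in pixels; output is in µm via ``pixel_size``.
    """
    sel = filtered.valid
    if sel.sum() < min_vectors:
        raise ValueError(f"need at least {min_vectors} valid vectors")
    pos = np.column_stack([filtered.x[sel], filtered.y[sel]]) * pixel_size
    vals = np.column_stack([filtered.u[sel], filtered.v[sel]]) * pixel_size

    # deduplicate identical positions (averaging their values)
    _, inv, counts = np.unique(np.round(pos, 9), axis=0, return_inverse=True,
                               return_counts=True)
    if (counts > 1).any():
        acc = np.zeros((len(counts), 2))
        np.add.at(acc, inv, vals)
        vals = acc / counts[:, None]
        upos = np.zeros((len(counts), 2))
        np.add.at(upos, inv, pos)
        pos = upos / counts[:, None]

    n = len(pos)
    d = cdist(pos, pos)
    X, Y = grid.meshgrid()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    dt = cdist(targets, pos)

    out = []
    for comp in range(2):
        v = vals[:, comp]
        fit_nug, sill, vrange = _fit_variogram(pos, v)
        nug = fit_nug if nugget is None else nugget
        # covariance form of the exponential model
        C = sill * np.exp(-d / vrange)
        C[np.diag_indices(n)] += nug
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = C
        A[n, :n] = A[:n, n] = 1.0
        rhs = np.append(v, 0.0)
        try:
            w = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular kriging system") from exc
        Ct = sill * np.exp(-dt / vrange)
        est = Ct @ w[:n] + w[n]
        out.append(est.reshape(grid.shape))
    return DisplacementField(grid, out[0], out[1])
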