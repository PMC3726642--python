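"""High-level in-memory pipelines combining the analysis stages.

These helpers wire the individual modules together with their default
settings; the file-based CLI stages reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DisplacementField, GelSubstrate, RegularGrid
from .displacement import (RawVectorField, align_drift, estimate_noise_um,
                           filter_vectors, krige_to_grid, piv_mqd)
from .synthetic import TractionScene, boussinesq_forward, render_bead_images
from .traction import (ForceSummary, TractionField, fttc_inverse,
                       select_lambda_discrepancy, total_force)


@dataclass
class TFMResult:
    """Everything the bead-pair → traction pipeline produced."""

    displacement: DisplacementField
    traction: TractionField
    raw_vectors: RawVectorField
    force: ForceSummary
    drift: np.ndarray
    lam: float
    noise_um: float


def displacement_from_beads(reference: np.ndarray, strained: np.ndarray,
                            pixel_size: float = 0.1,
                            window_size: int = 16,
                            search_range: int = 8,
                            grid_spacing: float = 0.86,
                            grid_inset: float = 2.0,
                            quality_min: float = 1.05,
                            neighbor_deviation_max: float = 2.0,
                            ) -> tuple[DisplacementField, RawVectorField,
                                       np.ndarray, float]:
    """Bead image pair → gridded displacement field (µm).

    Runs drift alignment, MQD PIV (50% window overlap), normalized-median
    filtering and ordinary kriging onto a regular grid inset by
    ``grid_inset`` µm from the image border (PIV cannot measure inside
    the window/search margin, and kriging should not extrapolate there).
    Returns ``(field, filtered_vectors, drift_px, noise_um)``.
    """
    ref, strained, drift = align_drift(reference, strained)
    raw = piv_mqd(ref, strained, window_size=window_size,
                  grid_spacing=window_size * pixel_size / 2.0,
                  pixel_size=pixel_size, search_range=search_range)
    filt = filter_vectors(raw, quality_min=quality_min,
                          neighbor_deviation_max=neighbor_deviation_max)
    noise = estimate_noise_um(filt, pixel_size)
    extent_x = (reference.shape[1] - 1) * pixel_size - 2 * grid_inset
    extent_y = (reference.shape[0] - 1) * pixel_size - 2 * grid_inset
    grid = RegularGrid((int(round(extent_y / grid_spacing)) + 1,
                        int(round(extent_x / grid_spacing)) + 1),
                       grid_spacing, origin=(grid_inset, grid_inset))
    field = krige_to_grid(filt, grid, pixel_size=pixel_size)
    return field, filt, drift, noise


def cell_masks(grid: RegularGrid, center: tuple[float, float],
               cell_radii: tuple[float, float], mask_margin: float = 6.0,
               corner_size: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Cell mask ("under and near the cell") and corner background region.

    The cell outline (an ellipse) is dilated by ``mask_margin`` µm so the
    traction footprints at the cell edge are fully counted; background is
    taken from the four ``corner_size`` µm corner squares of the grid,
    well away from both the cell and the tapered field border.
    """
    X, Y = grid.meshgrid()
    cx, cy = center
    a, b = cell_radii
    cell = ((X - cx) / (a + mask_margin)) ** 2 + \
           ((Y - cy) / (b + mask_margin)) ** 2 <= 1.0
    x0, x1 = grid.x[0], grid.x[-1]
    y0, y1 = grid.y[0], grid.y[-1]
    corners = ((X < x0 + corner_size) | (X > x1 - corner_size)) & \
              ((Y < y0 + corner_size) | (Y > y1 - corner_size))
    corners &= ~cell
    return cell, corners


def recover_total_force(scene: TractionScene, gel: GelSubstrate,
                        seed: int = 0, bead_density: float = 2.0,
                        image_noise_sd: float = 0.05,
                        forward_spacing: float = 0.2,
                        lam: float | None = None) -> TFMResult:
    """Forward-render a traction scene and recover its total force.

    The full inverse chain on synthetic data: elastic forward model →
    bead image pair → drift alignment → MQD PIV → filtering → kriging →
    regularized FTTC (λ by the discrepancy principle unless given) →
    background-subtracted total force under the (known) cell mask.
    """
    disp_true = boussinesq_forward(scene, gel, grid_spacing=forward_spacing)
    ref, strained = render_bead_images(disp_true, bead_density=bead_density,
                                       seed=seed, pixel_size=gel.pixel_size,
                                       noise_sd=image_noise_sd)
    field, filt, drift, noise = displacement_from_beads(
        ref, strained, pixel_size=gel.pixel_size)
    if lam is None:
        lam = select_lambda_discrepancy(field, gel, noise_sd=noise)
    tf = fttc_inverse(field, gel, lam=lam)
    if scene.cell_radii is None:
        raise ValueError("scene has no cell_radii; cannot build masks")
    center = (scene.domain_size[0] / 2.0, scene.domain_size[1] / 2.0)
    cell, corners = cell_masks(tf.grid, center, scene.cell_radii)
    force = total_force(tf, cell, corners)
    tf.background = force.background
    return TFMResult(displacement=field, traction=tf, raw_vectors=filt,
                     force=force, drift=drift, lam=lam, noise_um=noise)
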