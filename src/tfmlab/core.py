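"""Shared containers for substrate mechanics and gridded vector fields.

Conventions used throughout the package:

* image arrays are indexed ``[row, col]``; physical coordinates are
  ``x = col * pixel_size`` and ``y = row * pixel_size`` (µm, y increasing
  downward, origin at the top-left pixel centre);
* physical units are µm for lengths and displacements, Pa for stresses,
  nN for forces and minutes for times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class GelSubstrate:
    """Linear-elastic half-space model of a compliant polyacrylamide gel.

    Parameters
    ----------
    shear_modulus : float
        Shear elastic modulus G of the gel in Pa. Default 2800 Pa, a
        2.8 kPa polyacrylamide substrate typical of cell traction work.
    poisson_ratio : float
        Poisson ratio ν in [0, 0.5]. Default 0.5 (incompressible), the
        standard assumption for hydrated polyacrylamide.
    pixel_size : float
        Camera calibration in µm per pixel. Default 0.1 µm/px. All
        physics is carried in µm/Pa, so this only fixes the sampling.
    """

    shear_modulus: float = 2800.0
    poisson_ratio: float = 0.5
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        if not self.shear_modulus > 0:
            raise ValueError("shear_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def youngs_modulus(self) -> float:
        """Young's modulus E = 2 G (1 + ν) in Pa."""
        return 2.0 * self.shear_modulus * (1.0 + self.poisson_ratio)


@dataclass(frozen=True)
class RegularGrid:
    """Regular sampling grid in physical (µm) coordinates.

    ``shape`` is ``(ny, nx)``; node ``[j, i]`` sits at
    ``(origin[0] + i * spacing, origin[1] + j * spacing)``.
    """

    shape: tuple[int, int]
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if min(self.shape) < 2:
            raise ValueError("grid needs at least 2 nodes per axis")

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.spacing * np.arange(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.spacing * np.arange(self.shape[0])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y)

    @property
    def cell_area(self) -> float:
        """Area of one grid cell in µm²."""
        return self.spacing ** 2

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the sampled domain in µm."""
        return ((self.shape[1] - 1) * self.spacing,
                (self.shape[0] - 1) * self.spacing)


def _nearest_fill(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid nodes with the nearest valid value (no extrapolation art)."""
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("cannot fill a field with no valid nodes")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return values[tuple(idx)]


@dataclass
class DisplacementField:
    """Substrate displacement vectors (µm) on a :class:`RegularGrid`."""

    grid: RegularGrid
    ux: np.ndarray
    uy: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        for a in (self.ux, self.uy, self.valid):
            if a.shape != self.grid.shape:
                raise ValueError("field shape does not match grid shape")
        if not np.isfinite(self.ux[self.valid]).all() or \
           not np.isfinite(self.uy[self.valid]).all():
            raise ValueError("displacement vectors must be finite where valid")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)

    def filled(self) -> "DisplacementField":
        """Return a copy with invalid nodes filled by nearest-valid values."""
        return DisplacementField(
            self.grid,
            _nearest_fill(self.ux, self.valid),
            _nearest_fill(self.uy, self.valid),
            np.ones(self.grid.shape, dtype=bool),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write node table plus a JSON sidecar with the grid specification."""
        path = Path(path)
        X, Y = self.grid.meshgrid()
        pd.DataFrame({
            "x_um": X.ravel(), "y_um": Y.ravel(),
            "ux_um": self.ux.ravel(), "uy_um": self.uy.ravel(),
            "valid": self.valid.ravel().astype(int),
        }).to_csv(path, index=False)
        header = {
            "units": {"position": "um", "displacement": "um"},
            "grid": {"shape": list(self.grid.shape),
                     "spacing_um": self.grid.spacing,
                     "origin_um": list(self.grid.origin)},
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DisplacementField":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        grid = RegularGrid(tuple(header["grid"]["shape"]),
                           header["grid"]["spacing_um"],
                           tuple(header["grid"]["origin_um"]))
        df = pd.read_csv(path)
        shp = grid.shape
        return cls(grid,
                   df["ux_um"].to_numpy().reshape(shp),
                   df["uy_um"].to_numpy().reshape(shp),
                   df["valid"].to_numpy().astype(bool).reshape(shp))


@dataclass
class TractionField:
    """Traction stress vectors (Pa) on the displacement grid.

    ``background`` is the estimated background stress magnitude in Pa and
    ``lam`` the dimensionless Tikhonov parameter of the inversion (as
    applied to the normalized system; see :mod:`tfmlab.traction`).
    """

    grid: RegularGrid
    tx: np.ndarray
    ty: np.ndarray
    background: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        if self.tx.shape != self.grid.shape or self.ty.shape != self.grid.shape:
            raise ValueError("field shape does not match grid shape")
        if self.background < 0 or self.lam < 0:
            raise ValueError("background and lam must be >= 0")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        X, Y = self.grid.meshgrid()
        pd.DataFrame({
            "x_um": X.ravel(), "y_um": Y.ravel(),
            "tx_Pa": self.tx.ravel(), "ty_Pa": self.ty.ravel(),
        }).to_csv(path, index=False)
        header = {
            "units": {"position": "um", "traction": "Pa"},
            "grid": {"shape": list(self.grid.shape),
                     "spacing_um": self.grid.spacing,
                     "origin_um": list(self.grid.origin)},
            "background_Pa": self.background,
            "lambda": self.lam,
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TractionField":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        grid = RegularGrid(tuple(header["grid"]["shape"]),
                           header["grid"]["spacing_um"],
                           tuple(header["grid"]["origin_um"]))
        df = pd.read_csv(path)
        return cls(grid,
                   df["tx_Pa"].to_numpy().reshape(grid.shape),
                   df["ty_Pa"].to_numpy().reshape(grid.shape),
                   background=header.get("background_Pa", 0.0),
                   lam=header.get("lambda", 0.0))


PA_UM2_TO_NN = 1e-3
"""Force conversion: 1 Pa × 1 µm² = 1e-12 N = 1e-3 nN."""
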