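"""TIFF / CSV / JSON input-output helpers.

All writers put physical units in the file or its JSON sidecar header;
the readers round-trip losslessly. Image stacks are multi-page TIFF,
tables CSV, metadata JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DisplacementField, TractionField  # noqa: F401  (re-export)


def write_stack(path: str | Path, stack: np.ndarray,
                pixel_size: float, frame_interval: float | None = None) -> None:
    """Write a (frames, H, W) float stack as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")
    meta = {"pixel_size_um": pixel_size}
    if frame_interval is not None:
        meta["frame_interval_s"] = frame_interval
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return stack, meta


def write_image_pair(directory: str | Path, reference: np.ndarray,
                     strained: np.ndarray, pixel_size: float) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(directory / "beads_reference.tif",
                reference[None], pixel_size)
    write_stack(directory / "beads_strained.tif",
                strained[None], pixel_size)


def read_image_pair(directory: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    directory = Path(directory)
    ref, meta = read_stack(directory / "beads_reference.tif")
    strained, _ = read_stack(directory / "beads_strained.tif")
    return ref[0], strained[0], meta.get("pixel_size_um", 0.1)


def write_flow_vectors(path: str | Path, vectors: pd.DataFrame,
                       summary: dict) -> None:
    path = Path(path)
    vectors.to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def save_traction_heatmap(path: str | Path, traction: TractionField) -> None:
    """Optional stress-magnitude heatmap (PNG) for quick inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    w, h = traction.grid.extent
    im = ax.imshow(traction.magnitude(), extent=(0, w, h, 0), cmap="inferno")
    fig.colorbar(im, ax=ax, label="|t| (Pa)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
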