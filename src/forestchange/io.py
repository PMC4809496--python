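"""Scene-stack persistence: per-date TIFF rasters plus a CSV manifest.

A scene directory holds one multi-band TIFF per acquisition date (six
reflectance bands as pages), one single-band validity-mask TIFF per
date, optional truth grids for synthetic scenes, and ``manifest.csv``
with columns ``date, decimal_year, sensor, band_path, mask_path``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import REFLECTANCE_BANDS, SceneStack, from_decimal_year
from .synthetic_data import SyntheticScene

TRUTH_LEGEND = {"DEF": 1, "DEG": 2, "NOCH": 3, "NONFOREST": 4}


def save_scene(scene: SceneStack | SyntheticScene, directory) -> Path:
    """Write a scene stack (and truth grids, if synthetic) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = scene.stack if isinstance(scene, SyntheticScene) else scene
    rows = []
    for i, t in enumerate(stack.dates):
        date = from_decimal_year(float(t))
        band_path = f"bands_{i:04d}_{date.isoformat()}.tif"
        mask_path = f"mask_{i:04d}_{date.isoformat()}.tif"
        cube = np.stack(
            [stack.bands[b][i] for b in REFLECTANCE_BANDS]
        ).astype(np.float32)
        tifffile.imwrite(directory / band_path, cube, photometric="minisblack")
        tifffile.imwrite(
            directory / mask_path, stack.valid_mask[i].astype(np.uint8)
        )
        rows.append(
            {
                "date": date.isoformat(),
                "decimal_year": float(t),
                "sensor": stack.sensors[i],
                "band_path": band_path,
                "mask_path": mask_path,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    if isinstance(scene, SyntheticScene):
        coded = np.vectorize(TRUTH_LEGEND.__getitem__)(scene.truth_class)
        tifffile.imwrite(directory / "truth_class.tif", coded.astype(np.uint8))
        (directory / "truth_legend.json").write_text(json.dumps(TRUTH_LEGEND))
    return directory


def load_scene(directory) -> SceneStack:
    """Read a scene stack written by :func:`save_scene`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    dates = manifest["decimal_year"].to_numpy(float)
    cubes, masks = [], []
    for _, row in manifest.iterrows():
        cubes.append(tifffile.imread(directory / row["band_path"]))
        masks.append(tifffile.imread(directory / row["mask_path"]).astype(bool))
    cube = np.stack(cubes)  # (n_dates, 6, rows, cols)
    bands = {
        b: cube[:, k].astype(float) for k, b in enumerate(REFLECTANCE_BANDS)
    }
    return SceneStack(
        dates=dates,
        bands=bands,
        valid_mask=np.stack(masks),
        sensors=[str(s) for s in manifest["sensor"]],
    )


def load_truth_class(directory) -> np.ndarray:
    """Read the truth-class grid of a saved synthetic scene."""
    directory = Path(directory)
    coded = tifffile.imread(directory / "truth_class.tif")
    legend = json.loads((directory / "truth_legend.json").read_text())
    inverse = {v: k for k, v in legend.items()}
    return np.vectorize(inverse.__getitem__)(coded).astype(object)


def save_probability_maps(maps, directory, prefix: str = "probability") -> None:
    """Write one float TIFF per class plus a composite (NaN = nodata)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grids = []
    for cls, grid in maps.probabilities.items():
        out = np.where(maps.nodata, np.nan, grid).astype(np.float32)
        tifffile.imwrite(directory / f"{prefix}_{cls}.tif", out)
        grids.append(out)
    tifffile.imwrite(
        directory / f"{prefix}_composite.tif",
        np.stack(grids),
        photometric="minisblack",
    )


__all__ = [
    "save_scene",
    "load_scene",
    "load_truth_class",
    "save_probability_maps",
    "TRUTH_LEGEND",
]
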