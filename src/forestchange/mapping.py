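"""Scene-wide change-probability mapping behind a baseline forest mask.

A trained (typically reduced-covariate) model is applied to every
forest pixel of a scene: the pixel's valid observations are extracted
per band, spectral-temporal metrics are derived, and the forest's
vote-fraction probabilities for deforestation, degradation and stable
forest are written to per-class probability grids.  Non-forest pixels
and pixels with too few observations are nodata in all classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .change_model import ChangeModel, predict_probabilities
from .core import DERIVED_BANDS, METRIC_NAMES, IrregularTimeSeries, SceneStack
from .preprocessing import (
    TasseledCapCoefficients,
    add_indices,
    compute_index,
    extract_pixel_series,
)
from .temporal_metrics import extract_metrics, metrics_frame

logger = logging.getLogger(__name__)


@dataclass
class ForestMask:
    """Boolean baseline-forest grid (True = forest)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("forest mask must be 2-D")


@dataclass
class ProbabilityMaps:
    """Per-class probability grids with a shared nodata mask."""

    probabilities: dict[str, np.ndarray]
    nodata: np.ndarray
    n_insufficient: int = 0

    def __post_init__(self) -> None:
        for grid in self.probabilities.values():
            if grid.shape != self.nodata.shape:
                raise ValueError("probability grids must share the nodata shape")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.probabilities)

    def modal_class(self) -> np.ndarray:
        """Most-probable class per valid pixel (nodata -> empty string)."""
        classes = list(self.probabilities)
        stack = np.stack([self.probabilities[c] for c in classes])
        out = np.full(self.nodata.shape, "", dtype=object)
        valid = ~self.nodata
        idx = np.nanargmax(np.where(np.isnan(stack), -np.inf, stack), axis=0)
        for k, c in enumerate(classes):
            out[(idx == k) & valid] = c
        return out


def build_forest_mask(
    stack: SceneStack,
    baseline_date: float,
    ndvi_threshold: float = 0.6,
    tolerance: float = 1.5,
    coeffs: TasseledCapCoefficients | None = None,
) -> ForestMask:
    """Threshold baseline NDVI to separate forest from stable non-forest.

    For each pixel the valid NDVI observation nearest ``baseline_date``
    (within ``tolerance`` years) is compared to ``ndvi_threshold``;
    pixels at or above the threshold are forest.  Pixels with no valid
    observation in the window are non-forest.
    """
    near = np.abs(stack.dates - baseline_date) <= tolerance
    if not near.any():
        raise ValueError(
            f"no acquisition within {tolerance} yr of baseline {baseline_date}"
        )
    ndvi = compute_index(stack, "NDVI", coeffs)
    dist = np.abs(stack.dates - baseline_date)
    ok = stack.valid_mask & np.isfinite(ndvi) & near[:, None, None]
    # nearest-in-time valid NDVI per pixel
    penalised = np.where(ok, dist[:, None, None], np.inf)
    best = np.argmin(penalised, axis=0)
    rows, cols = np.indices(stack.shape)
    baseline_ndvi = ndvi[best, rows, cols]
    any_ok = ok.any(axis=0)
    mask = any_ok & (baseline_ndvi >= ndvi_threshold)
    return ForestMask(mask=mask)


def _bands_in_schema(schema: tuple[str, ...]) -> list[str]:
    bands = []
    for col in schema:
        for metric in METRIC_NAMES:
            suffix = f"_{metric}"
            if col.endswith(suffix):
                band = col[: -len(suffix)]
                if band not in bands:
                    bands.append(band)
                break
        else:
            raise ValueError(f"covariate column {col!r} is not <band>_<metric>")
    return bands


def pixel_metrics(
    stack: SceneStack,
    pixels: list[tuple[int, int]],
    bands: list[str],
    min_obs: int = 12,
    min_seg_frac: float = 0.15,
) -> pd.DataFrame:
    """Spectral-temporal metrics for a list of pixels.

    Rows are indexed by ``(row, col)``; pixels with fewer than
    ``min_obs`` valid observations in any requested band get NaN rows.
    """
    vectors = {}
    for (r, c) in pixels:
        series = {}
        for band in bands:
            ts = extract_pixel_series(stack, r, c, band)
            if len(ts) < min_obs:
                ts = IrregularTimeSeries([], [], band=band)
            series[band] = ts
        vectors[(r, c)] = extract_metrics(series, min_seg_frac=min_seg_frac)
    frame = metrics_frame(vectors)
    cols = [f"{b}_{m}" for b in bands for m in METRIC_NAMES]
    return frame.loc[:, cols]


def map_change(
    stack: SceneStack,
    model: ChangeModel,
    mask: ForestMask,
    coeffs: TasseledCapCoefficients | None = None,
    min_obs: int = 12,
    chunk_size: int = 256,
) -> ProbabilityMaps:
    """Predict per-class change probabilities for every forest pixel.

    Derived index bands required by the model schema are computed once
    for the whole stack; pixels are then processed in fixed-size chunks
    (the chunking is a memory contract only — output is identical for
    any chunk size).  Forest pixels with insufficient observations are
    nodata and counted.
    """
    if mask.mask.shape != stack.shape:
        raise ValueError("forest mask dimensions must match the scene")
    bands = _bands_in_schema(model.schema)
    needed_indices = [b for b in bands if b in DERIVED_BANDS]
    work = add_indices(stack, needed_indices, coeffs) if needed_indices else stack
    for band in bands:
        if band not in work.bands:
            raise KeyError(f"model requires band {band!r} not present in stack")

    n_rows, n_cols = stack.shape
    classes = model.classes
    probs = {c: np.full((n_rows, n_cols), np.nan) for c in classes}
    nodata = np.ones((n_rows, n_cols), dtype=bool)
    pixels = [(r, c) for r in range(n_rows) for c in range(n_cols) if mask.mask[r, c]]
    n_insufficient = 0
    for start in range(0, len(pixels), chunk_size):
        chunk = pixels[start : start + chunk_size]
        frame = pixel_metrics(work, chunk, bands, min_obs=min_obs)
        complete = ~frame.isna().any(axis=1)
        n_insufficient += int((~complete).sum())
        good = frame.loc[complete]
        if len(good) == 0:
            continue
        p = predict_probabilities(model, good)
        for (r, c), row in p.iterrows():
            for cls in classes:
                probs[cls][r, c] = row[cls]
            nodata[r, c] = False
    if n_insufficient:
        logger.info("%d forest pixels had insufficient observations", n_insufficient)
    return ProbabilityMaps(
        probabilities=probs, nodata=nodata, n_insufficient=n_insufficient
    )


def summarize_probabilities(
    maps: ProbabilityMaps, bin_width: float = 0.05
) -> pd.DataFrame:
    """Histogram the per-class probabilities over [0, 1].

    Returns a DataFrame with bin edges and one count column per class;
    nodata pixels are excluded, so each class column sums to the number
    of valid pixels.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    data = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for cls, grid in maps.probabilities.items():
        vals = grid[~maps.nodata]
        vals = vals[np.isfinite(vals)]
        counts, _ = np.histogram(vals, bins=edges)
        data[cls] = counts
    return pd.DataFrame(data)


__all__ = [
    "ForestMask",
    "ProbabilityMaps",
    "build_forest_mask",
    "pixel_metrics",
    "map_change",
    "summarize_probabilities",
]
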