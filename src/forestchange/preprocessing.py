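"""Validity-mask sieving and spectral-index computation.

The sieve removes small isolated clusters of valid pixels — typically
unmasked cloud remnants inside scan-line gaps — from per-date validity
masks.  The index routines derive the normalized-difference indices and
tasseled-cap transforms used as model covariates from the six
reflectance bands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    ALL_BANDS,
    DERIVED_BANDS,
    REFLECTANCE_BANDS,
    IrregularTimeSeries,
    SceneStack,
)

#: Band order of the packaged coefficient columns b1..b6.
TASSELED_CAP_BAND_ORDER: tuple[str, ...] = ("B", "R", "G", "NIR", "SWIR1", "SWIR2")


@dataclass(frozen=True)
class TasseledCapCoefficients:
    """Linear coefficients for brightness, greenness and wetness.

    Each attribute holds six coefficients applied to the reflectance
    bands in :data:`TASSELED_CAP_BAND_ORDER`.
    """

    brightness: np.ndarray
    greenness: np.ndarray
    wetness: np.ndarray

    def __post_init__(self) -> None:
        for name in ("brightness", "greenness", "wetness"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (6,):
                raise ValueError(f"{name} must have exactly six coefficients")
            object.__setattr__(self, name, vec)

    @classmethod
    def from_csv(cls, path) -> "TasseledCapCoefficients":
        table = pd.read_csv(path).set_index("index")
        cols = [f"b{i}" for i in range(1, 7)]
        return cls(
            brightness=table.loc["TCB", cols].to_numpy(float),
            greenness=table.loc["TCG", cols].to_numpy(float),
            wetness=table.loc["TCW", cols].to_numpy(float),
        )

    @classmethod
    def default(cls) -> "TasseledCapCoefficients":
        """Packaged surface-reflectance coefficients (Crist 1985)."""
        ref = importlib.resources.files("forestchange.data").joinpath(
            "tasseled_cap_coefficients.csv"
        )
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


def apply_sieve(mask: np.ndarray, min_cluster: int = 5) -> np.ndarray:
    """Remove small isolated clusters of valid pixels from a boolean mask.

    Connected clusters (4-connectivity) of valid pixels whose size is at
    most ``min_cluster`` and which are entirely surrounded by invalid
    pixels or the image edge are marked invalid.  All other pixels are
    unchanged.

    Parameters
    ----------
    mask
        2-D boolean validity grid (True = valid).
    min_cluster
        Largest cluster size removed (default 5 pixels).

    Returns
    -------
    numpy.ndarray
        Sieved copy of ``mask``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    # 4-connected labelling; every component is by construction bounded by
    # invalid pixels or the image edge.
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes[1:] <= min_cluster) + 1
    out = mask.copy()
    out[np.isin(labels, small)] = False
    return out


def _require(band_arrays: dict[str, np.ndarray], *names: str) -> list[np.ndarray]:
    out = []
    for name in names:
        if name not in band_arrays:
            raise KeyError(f"missing source band {name!r}")
        out.append(band_arrays[name])
    return out


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom == 0, np.nan, (a - b) / denom)
    return out


def compute_index(
    stack: SceneStack,
    index: str,
    coeffs: TasseledCapCoefficients | None = None,
    tca_literature_convention: bool = False,
) -> np.ndarray:
    """Compute a derived spectral index for every date of a scene stack.

    Normalized-difference indices: NDVI = (NIR-R)/(NIR+R),
    NDMI = (NIR-SWIR1)/(NIR+SWIR1), NBR = (NIR-SWIR2)/(NIR+SWIR2),
    NBR2 = (SWIR1-SWIR2)/(SWIR1+SWIR2).  TCB/TCG/TCW are linear
    combinations of the six reflectance bands; TCA = arctan(TCB/TCG)
    by default, or arctan(TCG/TCB) under the literature convention.

    Invalid pixels and zero denominators propagate as NaN.
    """
    if index not in DERIVED_BANDS:
        raise ValueError(f"{index!r} is not a derived band")
    if coeffs is None:
        coeffs = TasseledCapCoefficients.default()
    b = stack.bands
    if index == "NDVI":
        nir, r = _require(b, "NIR", "R")
        out = _normalized_difference(nir, r)
    elif index == "NDMI":
        nir, s1 = _require(b, "NIR", "SWIR1")
        out = _normalized_difference(nir, s1)
    elif index == "NBR":
        nir, s2 = _require(b, "NIR", "SWIR2")
        out = _normalized_difference(nir, s2)
    elif index == "NBR2":
        s1, s2 = _require(b, "SWIR1", "SWIR2")
        out = _normalized_difference(s1, s2)
    elif index in ("TCB", "TCG", "TCW"):
        out = _tasseled_cap(b, _tc_vector(coeffs, index))
    elif index == "TCA":
        tcb = _tasseled_cap(b, coeffs.brightness)
        tcg = _tasseled_cap(b, coeffs.greenness)
        num, den = (tcg, tcb) if tca_literature_convention else (tcb, tcg)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den == 0, np.nan, np.arctan(num / den))
    else:  # pragma: no cover - DERIVED_BANDS is exhaustive
        raise AssertionError(index)
    out = np.where(stack.valid_mask, out, np.nan)
    return out


def _tc_vector(coeffs: TasseledCapCoefficients, index: str) -> np.ndarray:
    return {
        "TCB": coeffs.brightness,
        "TCG": coeffs.greenness,
        "TCW": coeffs.wetness,
    }[index]


def _tasseled_cap(band_arrays: dict[str, np.ndarray], vec: np.ndarray) -> np.ndarray:
    grids = _require(band_arrays, *TASSELED_CAP_BAND_ORDER)
    out = np.zeros_like(grids[0], dtype=float)
    for c, grid in zip(vec, grids):
        out = out + c * grid
    return out


def add_indices(
    stack: SceneStack,
    indices: list[str] | tuple[str, ...] | None = None,
    coeffs: TasseledCapCoefficients | None = None,
    tca_literature_convention: bool = False,
) -> SceneStack:
    """Return a stack with derived index bands added alongside reflectance."""
    if indices is None:
        indices = [b for b in DERIVED_BANDS]
    bands = dict(stack.bands)
    for index in indices:
        if index in bands:
            continue
        bands[index] = compute_index(
            stack, index, coeffs, tca_literature_convention=tca_literature_convention
        )
    return SceneStack(
        dates=stack.dates,
        bands=bands,
        valid_mask=stack.valid_mask,
        sensors=list(stack.sensors),
    )


def extract_pixel_series(
    stack: SceneStack, row: int, col: int, band: str
) -> IrregularTimeSeries:
    """Extract the valid observations of one pixel as a time series.

    Only dates where the validity mask is true and the stored value is
    finite are returned; a pixel with no valid observations yields an
    empty series (downstream code decides how to handle it).
    """
    if band not in stack.bands:
        if band in ALL_BANDS:
            raise KeyError(
                f"band {band!r} not present in stack; derive it with add_indices()"
            )
        raise KeyError(f"unknown band {band!r}")
    n_rows, n_cols = stack.shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise IndexError(f"pixel ({row}, {col}) outside scene {stack.shape}")
    values = stack.bands[band][:, row, col]
    keep = stack.valid_mask[:, row, col] & np.isfinite(values)
    return IrregularTimeSeries(stack.dates[keep], values[keep], band=band)


__all__ = [
    "TasseledCapCoefficients",
    "TASSELED_CAP_BAND_ORDER",
    "apply_sieve",
    "compute_index",
    "add_indices",
    "extract_pixel_series",
    "REFLECTANCE_BANDS",
]
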