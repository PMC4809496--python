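"""End-to-end helpers tying the generator, metrics and models together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .change_model import TrainingSet
from .core import DERIVED_BANDS, METRIC_NAMES, SceneStack
from .mapping import pixel_metrics
from .preprocessing import TasseledCapCoefficients, add_indices
from .synthetic_data import (
    SamplingModel,
    SyntheticReportStream,
    draw_trajectory_params,
    generate_timeseries,
)
from .temporal_metrics import extract_metrics, metrics_frame


def report_metrics(
    stack: SceneStack,
    table: pd.DataFrame,
    bands: list[str],
    coeffs: TasseledCapCoefficients | None = None,
    min_obs: int = 12,
) -> pd.DataFrame:
    """Spectral-temporal metrics at labelled report locations.

    ``table`` is the labelled-location frame from
    :func:`forestchange.report_ingest.filter_for_training` (or any frame
    with ``report_id``, ``pixel_row`` and ``pixel_col`` columns).
    Returns a metrics DataFrame indexed by ``report_id``.
    """
    needed = [b for b in bands if b in DERIVED_BANDS]
    work = add_indices(stack, needed, coeffs) if needed else stack
    pixels = sorted(
        {(int(r), int(c)) for r, c in zip(table["pixel_row"], table["pixel_col"])}
    )
    per_pixel = pixel_metrics(work, pixels, bands, min_obs=min_obs)
    rows = {
        rid: per_pixel.loc[[(int(r), int(c))]].iloc[0]
        for rid, r, c in zip(
            table["report_id"], table["pixel_row"], table["pixel_col"]
        )
    }
    out = pd.DataFrame(rows).T
    out.index.name = "report_id"
    return out


def training_set_from_stream(
    stream: SyntheticReportStream,
    metrics_source: pd.DataFrame,
) -> TrainingSet:
    """Assemble a TrainingSet from a report stream and per-report metrics.

    ``metrics_source`` must be indexed by report id; labels and
    timestamps come from the reports' final labels.
    """
    rids = [r.report_id for r in stream.reports]
    missing = [rid for rid in rids if rid not in metrics_source.index]
    if missing:
        raise KeyError(f"metrics missing for report ids {missing[:5]}...")
    covariates = metrics_source.loc[rids]
    labels = np.array([r.final_label for r in stream.reports], dtype=object)
    timestamps = np.array([r.timestamp for r in stream.reports])
    return TrainingSet(
        covariates=covariates,
        labels=labels,
        timestamps=timestamps,
        location_ids=np.array(rids, dtype=object),
    )


def simulate_training_metrics(
    n_per_class: int,
    bands: list[str] | tuple[str, ...] = ("SWIR2",),
    seed: int = 0,
    sampling: SamplingModel | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw labelled trajectories and derive their metric vectors.

    Generates ``n_per_class`` pixels per change class (DEF, DEG, NOCH)
    from the class-conditional trajectory distributions, samples each
    band's series under ``sampling`` and extracts the six metrics per
    band.  Returns ``(metrics, labels)``.
    """
    if sampling is None:
        sampling = SamplingModel(seed=seed)
    root = np.random.default_rng(seed)
    vectors = {}
    labels = []
    classes = ("DEF", "DEG", "NOCH")
    for i in range(n_per_class * len(classes)):
        label = classes[i % len(classes)]
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        delta = rng.uniform(-np.pi, np.pi)
        lo = sampling.start_time + 0.2 * sampling.window
        hi = sampling.start_time + 0.8 * sampling.window
        bt = float(rng.uniform(lo, hi)) if label != "NOCH" else None
        deg_frac = float(rng.uniform(0.35, 0.6))
        series = {}
        for band in bands:
            params = draw_trajectory_params(label, band, delta, bt, deg_frac, rng)
            series[band] = generate_timeseries(params, sampling, rng=rng)
        vectors[i] = extract_metrics(series)
        labels.append(label)
    frame = metrics_frame(vectors)
    cols = [f"{b}_{m}" for b in bands for m in METRIC_NAMES]
    return frame.loc[:, cols], np.array(labels, dtype=object)


__all__ = [
    "report_metrics",
    "training_set_from_stream",
    "simulate_training_metrics",
]
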