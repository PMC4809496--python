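"""Spectral-temporal metric extraction from irregular pixel time series.

For each spectral band the pipeline derives six covariates:

* ``rlm_intercept``, ``rlm_slope`` — a robust (Huber M-estimator) linear
  fit to the entire series, intercept reported at the 1999.0 origin;
* ``gamma1``, ``gamma2`` — seasonal amplitude of each segment of a
  single-break season-trend model ``y = a + b*t + gamma*sin(2*pi*t + delta)``;
* ``beta1``, ``beta2`` — linear trend of each segment.

At most one structural break is allowed per series.  Candidate break
positions are scanned exhaustively; each candidate is scored with the
Bayesian Information Criterion of least-squares season-trend fits to
both segments, and a break is accepted only when the one-break BIC is
strictly below the no-break BIC.  Segments are then refit robustly.
When no break is found the second-segment parameters duplicate the
first (``gamma2 = gamma1``, ``beta2 = beta1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    BASELINE_YEAR,
    METRIC_NAMES,
    InsufficientDataError,
    IrregularTimeSeries,
    SeasonalUnidentifiableError,
)

#: Huber tuning constant (95% efficiency at the normal).
HUBER_T = 1.345
#: IRLS convergence tolerance and iteration cap.
IRLS_TOL = 1e-8
IRLS_MAXITER = 50
#: Minimum observations for the robust linear trend.
MIN_OBS_TREND = 4
#: Minimum observations for a season-trend fit (4 parameters + slack).
MIN_OBS_SEASON = 8


@dataclass(frozen=True)
class SeasonTrendFit:
    """Season-trend model parameters for one segment.

    ``alpha`` is the intercept at the fit origin ``t0`` (decimal years),
    ``beta`` the linear slope per year, ``gamma >= 0`` the amplitude of
    the annual harmonic and ``delta`` its phase in ``(-pi, pi]``.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    n_obs: int
    scale: float
    t0: float = BASELINE_YEAR

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return (
            self.alpha
            + self.beta * (t - self.t0)
            + self.gamma * np.sin(2 * np.pi * t + self.delta)
        )


@dataclass(frozen=True)
class BreakResult:
    """Outcome of the single-break BIC test.

    ``has_break`` holds iff ``bic1 < bic0``; ties favour the simpler
    no-break model.  ``break_index`` is the index of the first
    observation of the second segment.  ``degenerate`` flags series too
    short to run the scan.
    """

    has_break: bool
    break_time: float | None
    bic0: float
    bic1: float | None
    break_index: int | None = None
    degenerate: bool = False


@dataclass
class MetricVector:
    """The six spectral-temporal covariates for each band of one pixel."""

    metrics: dict[str, dict[str, float]]
    missing_bands: list[str] = field(default_factory=list)

    def to_series(self) -> pd.Series:
        """Flatten to a Series indexed ``<band>_<metric>`` in band order."""
        data = {}
        for band, vals in self.metrics.items():
            for name in METRIC_NAMES:
                data[f"{band}_{name}"] = vals[name]
        return pd.Series(data, dtype=float)

    def __len__(self) -> int:
        return len(self.metrics) * len(METRIC_NAMES)


def _season_design(times: np.ndarray, t0: float) -> np.ndarray:
    w = 2 * np.pi * times
    return np.column_stack(
        [np.ones_like(times), times - t0, np.sin(w), np.cos(w)]
    )


def _rlm_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Huber M-estimator fit; returns (params, robust scale)."""
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(HUBER_T))
    res = model.fit(
        scale_est="mad", conv="coefs", tol=IRLS_TOL, maxiter=IRLS_MAXITER
    )
    return np.asarray(res.params, dtype=float), float(res.scale)


def fit_rlm_trend(ts: IrregularTimeSeries) -> tuple[float, float]:
    """Robust linear trend over the full series.

    Returns ``(intercept, slope)`` with the intercept evaluated at the
    1999.0 baseline origin.
    """
    if len(ts) < MIN_OBS_TREND:
        raise InsufficientDataError(
            f"robust trend needs >= {MIN_OBS_TREND} observations, got {len(ts)}"
        )
    X = np.column_stack([np.ones(len(ts)), ts.times - BASELINE_YEAR])
    params, _ = _rlm_fit(ts.values, X)
    return float(params[0]), float(params[1])


def fit_season_trend(
    ts: IrregularTimeSeries, t0: float = BASELINE_YEAR
) -> SeasonTrendFit:
    """Robust fit of the annual season-trend model to one segment.

    The harmonic is parameterized as ``a*sin(2*pi*t) + b*cos(2*pi*t)``
    so the fit is linear; amplitude and phase are recovered as
    ``gamma = hypot(a, b)`` and ``delta = atan2(b, a)``.
    """
    if len(ts) < MIN_OBS_SEASON:
        raise InsufficientDataError(
            f"season-trend fit needs >= {MIN_OBS_SEASON} observations, got {len(ts)}"
        )
    if ts.span < 1.0:
        raise SeasonalUnidentifiableError(
            f"observation window {ts.span:.2f} yr is shorter than one annual cycle"
        )
    X = _season_design(ts.times, t0)
    params, scale = _rlm_fit(ts.values, X)
    a, b = params[2], params[3]
    return SeasonTrendFit(
        alpha=float(params[0]),
        beta=float(params[1]),
        gamma=float(math.hypot(a, b)),
        delta=float(math.atan2(b, a)),
        n_obs=len(ts),
        scale=scale,
        t0=t0,
    )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, residuals, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if residuals.size:
        return float(residuals[0])
    resid = y - X @ coef
    return float(resid @ resid)


def detect_single_break(
    ts: IrregularTimeSeries, min_seg_frac: float = 0.15
) -> BreakResult:
    """Test a series for the presence of at most one structural break.

    Every admissible split point (each segment keeping at least
    ``max(ceil(min_seg_frac * n), 8)`` observations) is scored by
    fitting least-squares season-trend models to the two segments and
    computing ``BIC = n*ln(RSS/n) + k*ln(n)`` with ``k = 9`` (two
    4-parameter segment models plus the break position) against the
    ``k = 4`` no-break fit.  A break is accepted only when the best
    one-break BIC is strictly lower.  ``break_time`` is the midpoint
    between the two observations flanking the selected split.
    """
    n = len(ts)
    min_seg = max(math.ceil(min_seg_frac * n), MIN_OBS_SEASON)
    y = ts.values
    X = _season_design(ts.times, BASELINE_YEAR)
    if n < MIN_OBS_SEASON:
        return BreakResult(False, None, math.nan, None, degenerate=True)
    rss0 = _ols_rss(y, X)
    bic0 = n * math.log(max(rss0, 1e-300) / n) + 4 * math.log(n)
    if n < 2 * min_seg:
        return BreakResult(False, None, bic0, None, degenerate=True)

    best_bic1 = math.inf
    best_split = None
    log_n = math.log(n)
    for split in range(min_seg, n - min_seg + 1):
        rss = _ols_rss(y[:split], X[:split]) + _ols_rss(y[split:], X[split:])
        bic1 = n * math.log(max(rss, 1e-300) / n) + 9 * log_n
        if bic1 < best_bic1:
            best_bic1 = bic1
            best_split = split
    has_break = best_bic1 < bic0
    if not has_break:
        return BreakResult(False, None, bic0, best_bic1)
    break_time = 0.5 * (ts.times[best_split - 1] + ts.times[best_split])
    return BreakResult(True, float(break_time), bic0, best_bic1, best_split)


def _segment(ts: IrregularTimeSeries, sl: slice) -> IrregularTimeSeries:
    return IrregularTimeSeries(ts.times[sl], ts.values[sl], band=ts.band)


def extract_metrics(
    series_by_band: dict[str, IrregularTimeSeries],
    min_seg_frac: float = 0.15,
) -> MetricVector:
    """Derive the six spectral-temporal metrics for every band.

    Bands whose series are too short (or whose segment fits are
    unidentifiable) get NaN metrics and are listed in
    ``missing_bands``; the remaining bands are unaffected.
    """
    metrics: dict[str, dict[str, float]] = {}
    missing: list[str] = []
    nan_row = {name: math.nan for name in METRIC_NAMES}
    for band, ts in series_by_band.items():
        try:
            intercept, slope = fit_rlm_trend(ts)
            brk = detect_single_break(ts, min_seg_frac=min_seg_frac)
            if brk.has_break:
                fit1 = fit_season_trend(_segment(ts, slice(None, brk.break_index)))
                fit2 = fit_season_trend(_segment(ts, slice(brk.break_index, None)))
            else:
                fit1 = fit_season_trend(ts)
                fit2 = fit1
        except (InsufficientDataError, SeasonalUnidentifiableError):
            metrics[band] = dict(nan_row)
            missing.append(band)
            continue
        metrics[band] = {
            "rlm_intercept": intercept,
            "rlm_slope": slope,
            "gamma1": fit1.gamma,
            "gamma2": fit2.gamma,
            "beta1": fit1.beta,
            "beta2": fit2.beta,
        }
    return MetricVector(metrics=metrics, missing_bands=missing)


def metrics_frame(
    vectors: dict[object, MetricVector],
) -> pd.DataFrame:
    """Stack per-location metric vectors into a DataFrame (rows = locations)."""
    return pd.DataFrame({k: v.to_series() for k, v in vectors.items()}).T


__all__ = [
    "SeasonTrendFit",
    "BreakResult",
    "MetricVector",
    "fit_rlm_trend",
    "fit_season_trend",
    "detect_single_break",
    "extract_metrics",
    "metrics_frame",
    "HUBER_T",
]
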