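"""Synthetic scenes, pixel trajectories and expert-report streams.

The generator emulates the statistical structure the analysis assumes:
per-pixel reflectance trajectories following a piecewise season-trend
model with at most one structural break, irregular sampling with
cloud-like one-sided outliers and random gaps, and a time-stamped
stream of ground reports whose labels derive from the known per-pixel
truth.  Everything is deterministic under a fixed seed.

Class-conditional trajectory distributions encode the three change
processes: deforestation (DEF) is a large persistent spectral shift —
the canopy-loss analogue of crossing a 20% cover threshold — with NIR
dropping and SWIR rising; degradation (DEG) is a partial shift in the
same direction; stable forest (NOCH) has identical segments.  Stable
non-forest pixels (NONFOREST) carry the post-clearing spectrum for the
whole record and low NDVI, so a baseline NDVI mask excludes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    ALL_LABELS,
    BASELINE_YEAR,
    CHANGE_CLASSES,
    REFLECTANCE_BANDS,
    IrregularTimeSeries,
    SceneStack,
)
from .report_ingest import DisturbanceReport

#: Mean forest / cleared surface reflectance per band (unitless, 0-1).
FOREST_SPECTRUM = {
    "B": 0.030, "G": 0.050, "R": 0.040, "NIR": 0.350,
    "SWIR1": 0.150, "SWIR2": 0.070,
}
CLEARED_SPECTRUM = {
    "B": 0.080, "G": 0.100, "R": 0.120, "NIR": 0.250,
    "SWIR1": 0.280, "SWIR2": 0.200,
}
#: Seasonal amplitude of the annual harmonic per band (reflectance units).
SEASONAL_AMPLITUDE = {
    "B": 0.004, "G": 0.006, "R": 0.006, "NIR": 0.030,
    "SWIR1": 0.012, "SWIR2": 0.008,
}
#: Bands whose cloud-like outliers shift upward (bright in SWIR/visible);
#: NIR and vegetation indices shift downward.
POSITIVE_OUTLIER_BANDS = frozenset({"B", "G", "R", "SWIR1", "SWIR2"})


@dataclass(frozen=True)
class TrajectoryParams:
    """Piecewise season-trend trajectory for one pixel and one band.

    Segment parameters follow the season-trend model
    ``y = alpha_j + beta_j * (t - 1999) + gamma_j * sin(2*pi*t + delta_j)``
    with the break (if any) strictly inside the observation window.
    A no-change trajectory has identical segments.
    """

    alpha1: float
    beta1: float
    gamma1: float
    delta1: float
    alpha2: float
    beta2: float
    gamma2: float
    delta2: float
    break_time: float | None
    change_class: str

    def __post_init__(self) -> None:
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("seasonal amplitudes must be non-negative")
        if self.change_class not in ALL_LABELS:
            raise ValueError(f"unknown change class {self.change_class!r}")
        if self.change_class in ("NOCH", "NONFOREST"):
            same = (
                self.alpha1 == self.alpha2
                and self.beta1 == self.beta2
                and self.gamma1 == self.gamma2
                and self.delta1 == self.delta2
            )
            if not same or self.break_time is not None:
                raise ValueError("stable classes must have identical segments")

    def evaluate(self, times: np.ndarray) -> np.ndarray:
        """Noise-free trajectory values at the given decimal-year times."""
        t = np.asarray(times, dtype=float)
        seg2 = (
            np.zeros(t.shape, dtype=bool)
            if self.break_time is None
            else t >= self.break_time
        )
        out = np.empty_like(t)
        for mask, (a, b, g, d) in (
            (~seg2, (self.alpha1, self.beta1, self.gamma1, self.delta1)),
            (seg2, (self.alpha2, self.beta2, self.gamma2, self.delta2)),
        ):
            out[mask] = (
                a
                + b * (t[mask] - BASELINE_YEAR)
                + g * np.sin(2 * np.pi * t[mask] + d)
            )
        return out


def stable_params(
    alpha: float, beta: float, gamma: float, delta: float, change_class: str = "NOCH"
) -> TrajectoryParams:
    """Convenience constructor for a no-change trajectory."""
    return TrajectoryParams(
        alpha1=alpha, beta1=beta, gamma1=gamma, delta1=delta,
        alpha2=alpha, beta2=beta, gamma2=gamma, delta2=delta,
        break_time=None, change_class=change_class,
    )


@dataclass(frozen=True)
class SamplingModel:
    """Acquisition and noise model for irregular sampling.

    ``mean_revisit`` is the nominal days between acquisitions;
    ``dropout_prob`` removes observations at random (gaps and full-scene
    cloud cover), ``outlier_prob`` injects cloud-like contamination
    shifted by ``outlier_shift`` (one-sided per band), and ``noise_sd``
    is the Gaussian observation noise.
    """

    start_time: float = 1999.0
    end_time: float = 2015.0
    mean_revisit: float = 16.0
    dropout_prob: float = 0.3
    outlier_prob: float = 0.05
    outlier_shift: float = 0.1
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_time <= self.start_time:
            raise ValueError("end_time must exceed start_time")
        for name in ("dropout_prob", "outlier_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def window(self) -> float:
        return self.end_time - self.start_time


def generate_timeseries(
    params: TrajectoryParams,
    sampling: SamplingModel,
    rng: np.random.Generator | None = None,
    band: str = "NIR",
) -> IrregularTimeSeries:
    """Sample one irregular time series from a trajectory.

    Acquisition times are laid out at the nominal revisit interval with
    small jitter, thinned by ``dropout_prob``; values are the trajectory
    curve plus Gaussian noise, with an ``outlier_prob`` fraction shifted
    by ``outlier_shift`` (negative in NIR-like space, mimicking unmasked
    clouds).  Identical seeds give bit-identical output.
    """
    if sampling.window < 1.0:
        raise ValueError(
            "observation window shorter than one year: no seasonal cycle identifiable"
        )
    if params.break_time is not None and not (
        sampling.start_time < params.break_time < sampling.end_time
    ):
        raise ValueError("break_time must lie strictly inside the window")
    if rng is None:
        rng = np.random.default_rng(sampling.seed)
    step = sampling.mean_revisit / 365.25
    times = np.arange(sampling.start_time, sampling.end_time, step)
    times = times + rng.uniform(-0.3 * step, 0.3 * step, times.size)
    times = np.sort(times)
    keep = rng.random(times.size) >= sampling.dropout_prob
    times = times[keep]
    # jitter can in principle create ties; enforce strict monotonicity
    times = np.unique(times)
    values = params.evaluate(times)
    if sampling.noise_sd > 0:
        values = values + rng.normal(0.0, sampling.noise_sd, times.size)
    if sampling.outlier_prob > 0:
        hit = rng.random(times.size) < sampling.outlier_prob
        values = values + np.where(hit, sampling.outlier_shift, 0.0)
    return IrregularTimeSeries(times, values, band=band)


@dataclass
class SyntheticScene:
    """A scene stack with per-pixel ground truth attached."""

    stack: SceneStack
    truth_class: np.ndarray
    truth_params: dict[str, np.ndarray]
    sampling: SamplingModel

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape


def _class_counts(
    n_pixels: int, class_fractions: dict[str, float]
) -> dict[str, int]:
    fracs = {k: float(v) for k, v in class_fractions.items() if v > 0}
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    for name in fracs:
        if name not in ALL_LABELS:
            raise ValueError(f"unknown class {name!r}")
    # largest-remainder apportionment
    raw = {k: v * n_pixels for k, v in fracs.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n_pixels - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    for k, c in counts.items():
        if c == 0:
            raise ValueError(f"requested class {k!r} received zero pixels")
    return counts


def draw_trajectory_params(
    label: str,
    band: str,
    delta: float,
    break_time: float | None,
    deg_fraction: float,
    rng: np.random.Generator,
) -> TrajectoryParams:
    """Draw one pixel's trajectory from the class-conditional distribution.

    DEF pixels shift fully from the forest to the cleared spectrum at
    the break; DEG pixels shift by ``deg_fraction`` of that distance
    and keep a mild continuing trend; NOCH/NONFOREST pixels are stable.
    """
    forest = FOREST_SPECTRUM[band]
    cleared = CLEARED_SPECTRUM[band]
    gamma = SEASONAL_AMPLITUDE[band]
    jitter = 0.15 * abs(forest)
    a1 = forest + rng.normal(0.0, jitter)
    if label == "NONFOREST":
        a_nf = cleared + rng.normal(0.0, 0.15 * abs(cleared))
        return stable_params(a_nf, 0.0, gamma, delta, "NONFOREST")
    if label == "NOCH":
        return stable_params(a1, 0.0, gamma, delta, "NOCH")
    if label == "DEF":
        frac = 1.0
        beta2 = 0.0
    else:  # DEG: partial shift plus a mild continuing trend
        frac = deg_fraction
        beta2 = 0.15 * (cleared - forest) / 10.0
    a2 = a1 + frac * (cleared - forest) * (1.0 + rng.normal(0.0, 0.1))
    gamma2 = gamma * (0.5 if label == "DEF" else 0.8)
    return TrajectoryParams(
        alpha1=a1, beta1=0.0, gamma1=gamma, delta1=delta,
        alpha2=a2, beta2=beta2, gamma2=gamma2, delta2=delta,
        break_time=break_time, change_class=label,
    )


def generate_scene(
    n_rows: int,
    n_cols: int,
    n_dates: int,
    class_fractions: dict[str, float] | None = None,
    sampling: SamplingModel | None = None,
) -> SyntheticScene:
    """Generate a small scene stack with known per-pixel truth.

    Pixels are assigned classes by largest-remainder apportionment of
    ``class_fractions`` and shuffled spatially; per-pixel trajectories
    are drawn from class-conditional parameter distributions.  All six
    reflectance bands share one validity-gap pattern per date, and the
    truth grids share the stack's dimensions.
    """
    if class_fractions is None:
        class_fractions = {"DEF": 0.25, "DEG": 0.25, "NOCH": 0.4, "NONFOREST": 0.1}
    if sampling is None:
        sampling = SamplingModel()
    if n_dates < 24:
        raise ValueError("need at least 24 acquisition dates")
    rng = np.random.default_rng(sampling.seed)
    n_pixels = n_rows * n_cols
    counts = _class_counts(n_pixels, class_fractions)
    labels = np.concatenate([np.repeat(k, c) for k, c in counts.items()])
    rng.shuffle(labels)
    truth_class = labels.reshape(n_rows, n_cols)

    dates = np.linspace(sampling.start_time, sampling.end_time, n_dates)
    valid = rng.random((n_dates, n_rows, n_cols)) >= sampling.dropout_prob

    # per-pixel shared phase and break time (common across bands)
    deltas = rng.uniform(-math.pi, math.pi, (n_rows, n_cols))
    lo = sampling.start_time + 0.2 * sampling.window
    hi = sampling.start_time + 0.8 * sampling.window
    break_times = rng.uniform(lo, hi, (n_rows, n_cols))
    deg_fracs = rng.uniform(0.35, 0.6, (n_rows, n_cols))

    truth_params: dict[str, np.ndarray] = {
        band: np.empty((n_rows, n_cols), dtype=object)
        for band in REFLECTANCE_BANDS
    }
    bands = {
        band: np.full((n_dates, n_rows, n_cols), np.nan)
        for band in REFLECTANCE_BANDS
    }
    for r in range(n_rows):
        for c in range(n_cols):
            label = truth_class[r, c]
            bt = break_times[r, c] if label in ("DEF", "DEG") else None
            for band in REFLECTANCE_BANDS:
                p = draw_trajectory_params(
                    label, band, deltas[r, c], bt, deg_fracs[r, c], rng
                )
                truth_params[band][r, c] = p
                curve = p.evaluate(dates)
                noise = rng.normal(0.0, sampling.noise_sd, n_dates)
                vals = curve + noise
                if sampling.outlier_prob > 0:
                    hit = rng.random(n_dates) < sampling.outlier_prob
                    shift = (
                        sampling.outlier_shift
                        if band in POSITIVE_OUTLIER_BANDS
                        else -sampling.outlier_shift
                    )
                    vals = vals + np.where(hit, shift, 0.0)
                vals[~valid[:, r, c]] = np.nan
                bands[band][:, r, c] = vals

    stack = SceneStack(dates=dates, bands=bands, valid_mask=valid)
    return SyntheticScene(
        stack=stack,
        truth_class=truth_class,
        truth_params=truth_params,
        sampling=sampling,
    )


@dataclass
class SyntheticReportStream:
    """Time-ordered expert reports tied to a companion scene."""

    reports: list[DisturbanceReport]
    phase_boundaries: tuple[float, float]

    def __post_init__(self) -> None:
        ts = [r.timestamp for r in self.reports]
        if ts != sorted(ts):
            raise ValueError("reports must be sorted by timestamp")
        a, b = self.phase_boundaries
        if not a < b:
            raise ValueError("phase boundaries must be increasing")

    def periods(self) -> tuple[list[DisturbanceReport], ...]:
        """Split the stream into periods A, B and C."""
        a, b = self.phase_boundaries
        pa = [r for r in self.reports if r.timestamp < a]
        pb = [r for r in self.reports if a <= r.timestamp < b]
        pc = [r for r in self.reports if r.timestamp >= b]
        return pa, pb, pc


def _canopy_for_label(label: str, rng: np.random.Generator) -> float:
    if label == "DEF":
        return float(rng.uniform(0.0, 15.0))
    if label == "DEG":
        return float(rng.uniform(25.0, 70.0))
    return float(rng.uniform(70.0, 95.0))


def generate_reports(
    scene: SyntheticScene,
    n_reports: int,
    label_noise: float = 0.0,
    phase_boundaries: tuple[float, float] | None = None,
    seed: int = 0,
    noch_fraction: float = 0.3,
    accessibility_gradient: float = 4.0,
    uniform_sampling: bool = False,
) -> SyntheticReportStream:
    """Generate a purposive stream of expert reports over a scene.

    Report locations are drawn without replacement from change pixels
    (DEF/DEG) plus a ``noch_fraction`` share of stable-forest pixels,
    weighted by a logistic accessibility gradient across the scene
    (uniform sampling available as a flag).  Timestamps are stratified
    over the three monitoring periods so each is represented; report
    labels equal the pixel truth except for a ``label_noise`` fraction
    flipped to another change class.
    """
    if not 0.0 <= label_noise <= 1.0:
        raise ValueError("label_noise must lie in [0, 1]")
    truth = scene.truth_class
    if truth.size == 0:
        raise ValueError("empty scene")
    sampling = scene.sampling
    if phase_boundaries is None:
        w = sampling.window
        phase_boundaries = (
            sampling.start_time + w / 3.0,
            sampling.start_time + 2.0 * w / 3.0,
        )
    rng = np.random.default_rng(seed)

    rows, cols = np.nonzero(np.isin(truth, ("DEF", "DEG")))
    nrows_s, ncols_s = truth.shape
    n_noch = int(round(n_reports * noch_fraction))
    n_change = n_reports - n_noch
    if n_change > rows.size:
        raise ValueError(
            f"requested {n_change} change reports but only {rows.size} change pixels"
        )
    noch_rows, noch_cols = np.nonzero(truth == "NOCH")
    if n_noch > noch_rows.size:
        raise ValueError("not enough stable-forest pixels for no-change reports")

    def _pick(r: np.ndarray, c: np.ndarray, k: int) -> np.ndarray:
        if k == 0:
            return np.array([], dtype=int)
        if uniform_sampling:
            w = np.ones(r.size)
        else:
            x = c / max(ncols_s - 1, 1) - 0.5
            w = 1.0 / (1.0 + np.exp(-accessibility_gradient * x))
        w = w / w.sum()
        return rng.choice(r.size, size=k, replace=False, p=w)

    sel_change = _pick(rows, cols, n_change)
    sel_noch = _pick(noch_rows, noch_cols, n_noch)
    change_px = [(int(rows[i]), int(cols[i])) for i in sel_change]
    noch_px = [(int(noch_rows[i]), int(noch_cols[i])) for i in sel_noch]
    # interleave the classes evenly over the stream so every monitoring
    # period records deforestation, degradation and no-change plots
    groups: dict[str, list[tuple[int, int]]] = {}
    for p in change_px:
        groups.setdefault(str(truth[p]), []).append(p)
    if noch_px:
        groups["NOCH"] = noch_px
    keyed = []
    for group in groups.values():
        u = rng.random()
        for j, p in enumerate(group):
            keyed.append(((j + u) / len(group), p))
    px = [p for _, p in sorted(keyed, key=lambda kv: kv[0])]

    # stratify timestamps across the three periods (each non-empty)
    a, b = phase_boundaries
    edges = [(sampling.start_time, a), (a, b), (b, sampling.end_time)]
    durations = np.array([hi - lo for lo, hi in edges])
    counts = np.maximum(
        np.floor(durations / durations.sum() * n_reports).astype(int),
        1 if n_reports >= 3 else 0,
    )
    while counts.sum() > n_reports:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_reports:
        counts[np.argmin(counts)] += 1
    stamps = np.concatenate(
        [rng.uniform(lo, hi, k) for (lo, hi), k in zip(edges, counts)]
    )
    stamps = np.sort(stamps)

    reports = []
    for i, ((r, c), t) in enumerate(zip(px, stamps)):
        true_label = str(truth[r, c])
        label = true_label
        if label_noise > 0 and rng.random() < label_noise:
            others = [k for k in CHANGE_CLASSES if k != true_label]
            label = others[int(rng.integers(len(others)))]
        canopy = _canopy_for_label(label, rng)
        reports.append(
            DisturbanceReport(
                report_id=f"RPT{i:05d}",
                lon=c + 0.5,
                lat=nrows_s - r - 0.5,
                timestamp=float(t),
                canopy_cover_pct=canopy,
                disturbance_evidence=label in ("DEF", "DEG"),
                forest_status="FOREST",
                pixel=(r, c),
                provisional_label=label,
                final_label=label,
            )
        )
    return SyntheticReportStream(reports=reports, phase_boundaries=phase_boundaries)


__all__ = [
    "TrajectoryParams",
    "SamplingModel",
    "SyntheticScene",
    "SyntheticReportStream",
    "stable_params",
    "draw_trajectory_params",
    "generate_timeseries",
    "generate_scene",
    "generate_reports",
    "FOREST_SPECTRUM",
    "CLEARED_SPECTRUM",
]
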