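"""Random-forest change classification and band-importance scoring.

The change model is a bagged ensemble of classification trees (7000 by
default) predicting deforestation, degradation or stable forest from
spectral-temporal metrics.  Accuracy is assessed internally with the
out-of-bag (OOB) sample; class probabilities are vote fractions across
trees.  Band importance is scored by repeatedly fitting single-band
forests and averaging the normalized rank of each band's accuracy:

    S[j, crit] = mean_i (x[i, j] - 1) / (n - 1)

where x[i, j] is the rank of band j in iteration i (bottom rank 1, top
rank n), so S = 1 means a band was top-ranked in every iteration and
S = 0 bottom-ranked in every iteration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .core import ALL_BANDS, CHANGE_CLASSES, METRIC_NAMES

logger = logging.getLogger(__name__)

#: Criteria over which bands are ranked: overall accuracy plus the
#: class-specific accuracies.
SCORE_CRITERIA: tuple[str, ...] = ("OVERALL",) + CHANGE_CLASSES

#: Covariate columns of the reduced mapping model: all six metrics of
#: SWIR2 and TCW plus the robust intercept/trend of the green band.
REDUCED_COVARIATES: tuple[str, ...] = tuple(
    [f"SWIR2_{m}" for m in METRIC_NAMES]
    + [f"TCW_{m}" for m in METRIC_NAMES]
    + ["G_rlm_intercept", "G_rlm_slope"]
)


@dataclass
class TrainingSet:
    """Labelled covariate matrix for model training.

    ``covariates`` rows correspond to labelled locations; ``labels``
    are change classes, ``timestamps`` report dates (decimal years) and
    ``location_ids`` stable identifiers.
    """

    covariates: pd.DataFrame
    labels: np.ndarray
    timestamps: np.ndarray | None = None
    location_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.covariates)
        if self.labels.shape != (n,):
            raise ValueError("labels length must match covariate rows")
        if self.timestamps is None:
            self.timestamps = np.full(n, np.nan)
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.location_ids is None:
            self.location_ids = np.asarray(self.covariates.index, dtype=object)
        else:
            self.location_ids = np.asarray(self.location_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.covariates)

    def dropna(self) -> "TrainingSet":
        """Drop rows with any missing covariate (forests need complete rows)."""
        keep = ~self.covariates.isna().any(axis=1).to_numpy()
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d rows with missing covariates", n_dropped)
        return TrainingSet(
            covariates=self.covariates.loc[keep],
            labels=self.labels[keep],
            timestamps=self.timestamps[keep],
            location_ids=self.location_ids[keep],
        )


@dataclass
class ChangeModel:
    """A trained forest with its covariate schema."""

    estimator: RandomForestClassifier
    schema: tuple[str, ...]
    n_trees: int
    seed: int | None

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.estimator.classes_)


@dataclass
class OOBReport:
    """Out-of-bag accuracy summary of a trained forest."""

    overall_error: float
    class_errors: dict[str, float]
    confusion: pd.DataFrame
    n_samples: int


def _check_training(data: TrainingSet, min_per_class: int = 10) -> TrainingSet:
    data = data.dropna()
    classes, counts = np.unique(data.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    lacking = [f"{c} ({k})" for c, k in zip(classes, counts) if k < min_per_class]
    if lacking:
        raise ValueError(
            f"need >= {min_per_class} samples per class; short: {', '.join(lacking)}"
        )
    return data


def train_model(
    data: TrainingSet, n_trees: int = 7000, seed: int | None = None
) -> tuple[ChangeModel, OOBReport]:
    """Fit the bagged-tree change classifier and its OOB report.

    The OOB error is computed from out-of-bag votes: each training
    sample is classified only by trees whose bootstrap excluded it.
    Per-class errors come from the OOB confusion-matrix rows.
    """
    data = _check_training(data)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(data.covariates.to_numpy(float), data.labels.astype(str))
    report = _oob_report(forest, data.labels.astype(str))
    model = ChangeModel(
        estimator=forest,
        schema=tuple(data.covariates.columns),
        n_trees=n_trees,
        seed=seed,
    )
    return model, report


def _oob_report(forest: RandomForestClassifier, labels: np.ndarray) -> OOBReport:
    votes = forest.oob_decision_function_
    classes = forest.classes_
    seen = np.isfinite(votes).all(axis=1) & (votes.sum(axis=1) > 0)
    if not seen.all():  # pragma: no cover - vanishing probability at >=100 trees
        logger.warning("%d samples never out-of-bag; excluded", int((~seen).sum()))
    pred = classes[np.argmax(votes[seen], axis=1)]
    truth = labels[seen]
    cm = confusion_matrix(truth, pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore"):
        class_err = 1.0 - np.where(row_sums > 0, np.diag(cm) / row_sums, np.nan)
    overall = 1.0 - np.trace(cm) / cm.sum()
    return OOBReport(
        overall_error=float(overall),
        class_errors={c: float(e) for c, e in zip(classes, class_err)},
        confusion=confusion,
        n_samples=int(seen.sum()),
    )


def predict_probabilities(
    model: ChangeModel, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Vote-fraction class probabilities for rows of metric values.

    Columns are the model's classes; every row sums to 1.  Trees are
    grown to purity, so the averaged leaf distributions equal the
    fraction of trees voting for each class.
    """
    for col in model.schema:
        if col not in metrics.columns:
            raise KeyError(f"missing covariate column {col!r}")
    X = metrics.loc[:, list(model.schema)]
    if len(X) == 0:
        return pd.DataFrame(columns=model.classes, index=X.index, dtype=float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns {bad}")
    probs = model.estimator.predict_proba(X.to_numpy(float))
    return pd.DataFrame(probs, columns=model.classes, index=metrics.index)


@dataclass
class PhaseResult:
    """One phase of the iterative-updating protocol."""

    model: ChangeModel
    oob: OOBReport
    probabilities: pd.DataFrame
    reference_labels: pd.Series


def iterative_update(
    data: TrainingSet,
    phase_boundaries: tuple[float, float],
    n_trees: int = 7000,
    seed: int | None = None,
) -> dict[str, PhaseResult]:
    """Run the two-phase iterative model-updating protocol.

    The labelled stream is split by timestamp into periods A, B and C.
    Training phase: fit on period A and predict class probabilities for
    period-B locations, grouped by their reference labels.  Operational
    phase: fit on A union B and predict for period-C locations.  Per
    phase the held-out probability distributions (the boxplot data of
    the calibration/validation comparison) are returned.
    """
    t1, t2 = phase_boundaries
    if not t1 < t2:
        raise ValueError("phase boundaries must be increasing")
    ts = data.timestamps
    if np.any(np.isnan(ts)):
        raise ValueError("iterative updating requires timestamps for every row")
    in_a = ts < t1
    in_b = (ts >= t1) & (ts < t2)
    in_c = ts >= t2
    if not in_a.any():
        raise ValueError("period A is empty")
    if not in_b.any():
        raise ValueError("period B is empty")

    def _slice(mask: np.ndarray) -> TrainingSet:
        return TrainingSet(
            covariates=data.covariates.loc[mask],
            labels=data.labels[mask],
            timestamps=ts[mask],
            location_ids=data.location_ids[mask],
        )

    results: dict[str, PhaseResult] = {}
    train_a = _slice(in_a)
    model_a, oob_a = train_model(train_a, n_trees=n_trees, seed=seed)
    val_b = _slice(in_b)
    probs_b = predict_probabilities(model_a, val_b.covariates)
    results["training"] = PhaseResult(
        model=model_a,
        oob=oob_a,
        probabilities=probs_b,
        reference_labels=pd.Series(
            val_b.labels, index=val_b.covariates.index, name="reference"
        ),
    )

    train_ab = _slice(in_a | in_b)
    seed_ab = None if seed is None else seed + 1
    model_ab, oob_ab = train_model(train_ab, n_trees=n_trees, seed=seed_ab)
    if in_c.any():
        val_c = _slice(in_c)
        probs_c = predict_probabilities(model_ab, val_c.covariates)
        ref_c = pd.Series(val_c.labels, index=val_c.covariates.index, name="reference")
    else:
        logger.warning("period C is empty; operational validation skipped")
        probs_c = pd.DataFrame(columns=model_ab.classes, dtype=float)
        ref_c = pd.Series(dtype=object, name="reference")
    results["operational"] = PhaseResult(
        model=model_ab, oob=oob_ab, probabilities=probs_c, reference_labels=ref_c
    )
    return results


def iterative_update_stream(
    stream,
    metrics_source: pd.DataFrame,
    n_trees: int = 7000,
    seed: int | None = None,
) -> dict[str, PhaseResult]:
    """Run :func:`iterative_update` directly on a report stream.

    ``stream`` is any object with ``reports`` (carrying ``report_id``,
    ``timestamp`` and ``final_label``) and ``phase_boundaries``;
    ``metrics_source`` is a covariate DataFrame indexed by report id.
    """
    rids = [r.report_id for r in stream.reports]
    missing = [rid for rid in rids if rid not in metrics_source.index]
    if missing:
        raise KeyError(f"metrics missing for report ids {missing[:5]}")
    data = TrainingSet(
        covariates=metrics_source.loc[rids],
        labels=np.array([r.final_label for r in stream.reports], dtype=object),
        timestamps=np.array([r.timestamp for r in stream.reports]),
        location_ids=np.array(rids, dtype=object),
    )
    return iterative_update(
        data, stream.phase_boundaries, n_trees=n_trees, seed=seed
    )


def correct_class_probability(phase: PhaseResult) -> pd.Series:
    """P(reference class) per held-out location of a phase."""
    probs = phase.probabilities
    out = np.array(
        [
            probs.at[idx, lab] if lab in probs.columns else 0.0
            for idx, lab in phase.reference_labels.items()
        ]
    )
    return pd.Series(out, index=probs.index, name="p_correct")


# ---------------------------------------------------------------------------
# Normalized-rank band importance

@dataclass(frozen=True)
class RankMatrix:
    """Integer ranks x[i, j] of band j in iteration i (bottom 1, top n)."""

    ranks: np.ndarray
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks, dtype=int)
        object.__setattr__(self, "ranks", ranks)
        if ranks.ndim != 2 or ranks.shape[1] != len(self.bands):
            raise ValueError("ranks must be (N iterations, n bands)")
        n = len(self.bands)
        if n < 2:
            raise ValueError("need at least two bands to rank")
        if ranks.min() < 1 or ranks.max() > n:
            raise ValueError("ranks must lie in [1, n]")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_iterations(self) -> int:
        return int(self.ranks.shape[0])


def score_from_ranks(rank_matrix: RankMatrix) -> pd.Series:
    """Mean normalized rank S[j] = mean_i (x[i,j] - 1) / (n - 1)."""
    n = rank_matrix.n_bands
    s = (rank_matrix.ranks - 1).mean(axis=0) / (n - 1)
    return pd.Series(s, index=list(rank_matrix.bands), name="S")


def _rank_bottom_one(accuracies: np.ndarray) -> np.ndarray:
    """Ranks with bottom accuracy -> 1, top -> n.

    Ties break deterministically by canonical band position: among tied
    accuracies the band listed earlier receives the lower rank.
    """
    n = accuracies.size
    order = np.lexsort((np.arange(n), accuracies))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def score_band_importance(
    per_band_training: dict[str, TrainingSet],
    n_iterations: int = 1000,
    seed: int | None = None,
    n_trees: int = 500,
) -> tuple[pd.DataFrame, dict[str, RankMatrix]]:
    """Score band importance by repeated single-band forest ranking.

    For each iteration one forest is fit per band using only that
    band's metrics; bands are ranked by overall OOB accuracy and by
    each class-specific OOB accuracy (bottom rank 1, top rank n), and
    the score table is the mean normalized rank per band and criterion.
    Each iteration reseeds the forests' bootstrap; the training rows
    themselves are fixed.

    Returns ``(scores, rank_matrices)`` where ``scores`` is a band-by-
    criterion DataFrame in [0, 1] and ``rank_matrices`` the underlying
    per-criterion rank matrices.
    """
    bands = [b for b in ALL_BANDS if b in per_band_training]
    bands += [b for b in per_band_training if b not in ALL_BANDS]
    n = len(bands)
    if n < 2:
        raise ValueError("importance scoring needs at least two bands")
    checked = {b: _check_training(per_band_training[b]) for b in bands}
    ref_labels = checked[bands[0]].labels
    for b in bands[1:]:
        if not np.array_equal(checked[b].labels, ref_labels):
            raise ValueError("per-band training sets must share rows and labels")
    classes = [c for c in CHANGE_CLASSES if c in set(ref_labels)]
    criteria = ["OVERALL"] + classes
    rng = np.random.default_rng(seed)
    ranks = {crit: np.empty((n_iterations, n), dtype=int) for crit in criteria}
    for i in range(n_iterations):
        acc = {crit: np.empty(n) for crit in criteria}
        for j, band in enumerate(bands):
            it_seed = int(rng.integers(0, 2**31 - 1))
            _, oob = train_model(checked[band], n_trees=n_trees, seed=it_seed)
            acc["OVERALL"][j] = 1.0 - oob.overall_error
            for c in classes:
                acc[c][j] = 1.0 - oob.class_errors.get(c, np.nan)
        for crit in criteria:
            ranks[crit][i] = _rank_bottom_one(acc[crit])
    matrices = {
        crit: RankMatrix(ranks=ranks[crit], bands=tuple(bands)) for crit in criteria
    }
    scores = pd.DataFrame(
        {crit: score_from_ranks(matrices[crit]) for crit in criteria}
    )
    return scores, matrices


def reduce_covariates(
    data: TrainingSet, keep: list[str | tuple[str, str]]
) -> TrainingSet:
    """Column-subset copy of a training set (rows/labels preserved).

    ``keep`` entries are either column names ``"<band>_<metric>"`` or
    ``(band, metric)`` tuples.
    """
    if not keep:
        raise ValueError("keep must name at least one covariate column")
    cols = []
    for item in keep:
        name = item if isinstance(item, str) else f"{item[0]}_{item[1]}"
        if name not in data.covariates.columns:
            raise KeyError(f"unknown covariate column {name!r}")
        cols.append(name)
    return TrainingSet(
        covariates=data.covariates.loc[:, cols],
        labels=data.labels.copy(),
        timestamps=data.timestamps.copy(),
        location_ids=data.location_ids.copy(),
    )


# ---------------------------------------------------------------------------
# Persistence

def save_model(model: ChangeModel, path) -> None:
    """Persist a model (joblib binary) with a JSON schema sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "format_version": 1,
        "schema": list(model.schema),
        "classes": list(model.classes),
        "n_trees": model.n_trees,
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path) -> ChangeModel:
    path = Path(path)
    estimator = joblib.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ChangeModel(
        estimator=estimator,
        schema=tuple(sidecar["schema"]),
        n_trees=int(sidecar["n_trees"]),
        seed=sidecar.get("seed"),
    )


__all__ = [
    "TrainingSet",
    "ChangeModel",
    "OOBReport",
    "PhaseResult",
    "RankMatrix",
    "REDUCED_COVARIATES",
    "SCORE_CRITERIA",
    "train_model",
    "predict_probabilities",
    "iterative_update",
    "iterative_update_stream",
    "correct_class_probability",
    "score_from_ranks",
    "score_band_importance",
    "reduce_covariates",
    "save_model",
    "load_model",
]
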