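"""Random-forest training, prediction, updating and importance scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import forestchange as fc
from forestchange.change_model import (
    REDUCED_COVARIATES,
    RankMatrix,
    TrainingSet,
    correct_class_probability,
    iterative_update,
    load_model,
    save_model,
    score_from_ranks,
)
from forestchange.core import METRIC_NAMES


@pytest.fixture(scope="module")
def fitted(training_metrics):
    X, y = training_metrics
    data = TrainingSet(X, y)
    model, oob = fc.train_model(data, n_trees=300, seed=7)
    return data, model, oob


class TestTrainModel:
    def test_separable_classes_give_low_oob_error(self, fitted):
        _, _, oob = fitted
        assert oob.overall_error <= 0.10

    def test_confusion_rows_sum_to_class_counts(self, fitted):
        data, _, oob = fitted
        counts = pd.Series(data.labels).value_counts()
        for cls in oob.confusion.index:
            assert oob.confusion.loc[cls].sum() == counts[cls]

    def test_same_seed_reproduces_report(self, training_metrics):
        X, y = training_metrics
        a = fc.train_model(TrainingSet(X, y), n_trees=100, seed=3)[1]
        b = fc.train_model(TrainingSet(X, y), n_trees=100, seed=3)[1]
        assert a.overall_error == b.overall_error
        pd.testing.assert_frame_equal(a.confusion, b.confusion)

    def test_single_class_rejected(self, training_metrics):
        X, y = training_metrics
        only = y == "DEF"
        with pytest.raises(ValueError, match="two classes"):
            fc.train_model(TrainingSet(X.loc[only], y[only]), n_trees=50)

    def test_undersized_class_rejected(self, training_metrics):
        X, y = training_metrics
        keep = np.ones(len(y), dtype=bool)
        keep[np.nonzero(y == "DEG")[0][5:]] = False
        with pytest.raises(ValueError, match=">= 10 samples"):
            fc.train_model(TrainingSet(X.loc[keep], y[keep]), n_trees=50)

    def test_rows_with_missing_covariates_dropped(self, training_metrics):
        X, y = training_metrics
        X = X.copy()
        X.iloc[0, 0] = np.nan
        _, oob = fc.train_model(TrainingSet(X, y), n_trees=100, seed=1)
        assert oob.n_samples == len(y) - 1


class TestPredictProbabilities:
    def test_rows_sum_to_one(self, fitted):
        data, model, _ = fitted
        probs = fc.predict_probabilities(model, data.covariates.iloc[:25])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_interior_point_predicted_as_own_class(self, fitted):
        data, model, _ = fitted
        probs = fc.predict_probabilities(model, data.covariates)
        modal = probs.idxmax(axis=1).to_numpy()
        # training points are overwhelmingly assigned their own label
        assert (modal == data.labels.astype(str)).mean() >= 0.95

    def test_empty_input_gives_empty_output(self, fitted):
        _, model, _ = fitted
        probs = fc.predict_probabilities(model, pd.DataFrame(columns=model.schema))
        assert len(probs) == 0
        assert tuple(probs.columns) == model.classes

    def test_missing_column_named_in_error(self, fitted):
        data, model, _ = fitted
        bad = data.covariates.drop(columns=[model.schema[0]])
        with pytest.raises(KeyError, match=model.schema[0]):
            fc.predict_probabilities(model, bad)


class TestIterativeUpdate:
    @staticmethod
    def _data(training_metrics, t1=2004.0, t2=2010.0):
        X, y = training_metrics
        rng = np.random.default_rng(0)
        # spread timestamps so all classes occur in all periods
        ts = np.empty(len(y))
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            ts[idx] = np.linspace(1999.5, 2014.5, idx.size)
        return TrainingSet(X, y, timestamps=ts)

    def test_phases_train_on_growing_data(self, training_metrics):
        data = self._data(training_metrics)
        phases = iterative_update(data, (2004.0, 2010.0), n_trees=200, seed=1)
        n_a = phases["training"].oob.n_samples
        n_ab = phases["operational"].oob.n_samples
        assert n_a < n_ab

    def test_validation_probabilities_cover_held_out_reports(self, training_metrics):
        data = self._data(training_metrics)
        phases = iterative_update(data, (2004.0, 2010.0), n_trees=200, seed=1)
        t1, t2 = 2004.0, 2010.0
        n_b = int(((data.timestamps >= t1) & (data.timestamps < t2)).sum())
        assert len(phases["training"].probabilities) == n_b
        p = correct_class_probability(phases["training"])
        assert ((0 <= p) & (p <= 1)).all()

    def test_empty_period_b_rejected(self, training_metrics):
        data = self._data(training_metrics)
        with pytest.raises(ValueError, match="period B"):
            iterative_update(data, (2020.0, 2021.0), n_trees=100)

    def test_empty_period_a_rejected(self, training_metrics):
        data = self._data(training_metrics)
        with pytest.raises(ValueError, match="period A"):
            iterative_update(data, (1990.0, 2010.0), n_trees=100)


class TestImportanceScore:
    def test_top_ranked_band_scores_one(self):
        ranks = np.tile([3, 1, 2], (10, 1))
        rm = RankMatrix(ranks=ranks, bands=("SWIR2", "NIR", "G"))
        s = score_from_ranks(rm)
        assert s["SWIR2"] == 1.0

    def test_bottom_ranked_band_scores_zero(self):
        ranks = np.tile([3, 1, 2], (10, 1))
        rm = RankMatrix(ranks=ranks, bands=("SWIR2", "NIR", "G"))
        assert score_from_ranks(rm)["NIR"] == 0.0

    def test_alternating_extremes_average_to_half(self):
        rm = RankMatrix(
            ranks=np.array([[3, 1, 2], [1, 3, 2]]), bands=("A", "B", "C")
        )
        assert score_from_ranks(rm)["A"] == 0.5

    @given(st.integers(0, 10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, N = int(rng.integers(2, 15)), int(rng.integers(1, 40))
        ranks = np.stack([rng.permutation(n) + 1 for _ in range(N)])
        bands = tuple(f"b{j}" for j in range(n))
        s = score_from_ranks(RankMatrix(ranks=ranks, bands=bands))
        for j in range(n):
            expected = sum((ranks[i, j] - 1) / (n - 1) for i in range(N)) / N
            assert s.iloc[j] == pytest.approx(expected, abs=1e-12)

    def test_ranks_outside_range_rejected(self):
        with pytest.raises(ValueError, match="ranks"):
            RankMatrix(ranks=np.array([[0, 1]]), bands=("A", "B"))

    def test_single_band_scoring_rejected(self, training_metrics):
        X, y = training_metrics
        data = {"SWIR2": TrainingSet(X, y)}
        with pytest.raises(ValueError, match="two bands"):
            fc.score_band_importance(data, n_iterations=1)

    def test_band_forests_rank_informative_band_higher(self, training_metrics):
        """A real band outranks pure-noise covariates in nearly every iteration."""
        X, y = training_metrics
        rng = np.random.default_rng(3)
        noise = pd.DataFrame(
            rng.normal(size=X.shape),
            index=X.index,
            columns=[c.replace("SWIR2", "NIR") for c in X.columns],
        )
        per_band = {"SWIR2": TrainingSet(X, y), "NIR": TrainingSet(noise, y)}
        scores, matrices = fc.score_band_importance(
            per_band, n_iterations=5, seed=2, n_trees=100
        )
        assert scores.loc["SWIR2", "OVERALL"] == 1.0
        assert scores.loc["NIR", "OVERALL"] == 0.0
        # per-iteration ranks are permutations of 1..n
        for rm in matrices.values():
            for row in rm.ranks:
                assert sorted(row) == [1, 2]

    def test_scores_bounded(self, training_metrics):
        X, y = training_metrics
        half = X.iloc[:, :3].copy()
        other = X.iloc[:, 3:].copy()
        other.columns = [c.replace("SWIR2", "TCW") for c in other.columns]
        per_band = {"SWIR2": TrainingSet(half, y), "TCW": TrainingSet(other, y)}
        scores, _ = fc.score_band_importance(
            per_band, n_iterations=3, seed=0, n_trees=50
        )
        assert ((scores >= 0) & (scores <= 1)).all().all()


class TestReduceCovariates:
    @staticmethod
    def _full_set(n=30):
        rng = np.random.default_rng(0)
        cols = [f"{b}_{m}" for b in fc.ALL_BANDS for m in METRIC_NAMES]
        X = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        y = np.array(["DEF", "DEG", "NOCH"] * (n // 3))
        return TrainingSet(X, y)

    def test_reduced_model_set_has_14_columns(self):
        data = self._full_set()
        reduced = fc.reduce_covariates(data, list(REDUCED_COVARIATES))
        assert len(reduced.covariates.columns) == 14
        assert set(c.split("_")[0] for c in reduced.covariates.columns) == {
            "SWIR2", "TCW", "G",
        }

    def test_keep_all_is_identity(self):
        data = self._full_set()
        out = fc.reduce_covariates(data, list(data.covariates.columns))
        pd.testing.assert_frame_equal(out.covariates, data.covariates)
        np.testing.assert_array_equal(out.labels, data.labels)

    def test_empty_keep_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fc.reduce_covariates(self._full_set(), [])

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError, match="bogus"):
            fc.reduce_covariates(self._full_set(), ["bogus_column"])

    def test_tuple_form_accepted(self):
        data = self._full_set()
        out = fc.reduce_covariates(data, [("SWIR2", "gamma1"), ("G", "rlm_slope")])
        assert list(out.covariates.columns) == ["SWIR2_gamma1", "G_rlm_slope"]


def test_model_round_trips_through_persistence(fitted, tmp_path):
    data, model, _ = fitted
    path = tmp_path / "model.joblib"
    save_model(model, path)
    loaded = load_model(path)
    assert loaded.schema == model.schema
    a = fc.predict_probabilities(model, data.covariates.iloc[:5])
    b = fc.predict_probabilities(loaded, data.covariates.iloc[:5])
    pd.testing.assert_frame_equal(a, b)
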