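import numpy as np
import pytest

from chemconform import conformal
from chemconform.evaluate import (
    calibration_stats,
    classification_metrics,
    default_rbf_grid,
    grid_search,
    regression_metrics,
    run_validation,
    significance_grid,
)
from chemconform.conformal import ConformalClassifier
from chemconform.scorers import ScorerConfig
from chemconform.synthetic import SyntheticSpec, gen_numeric_classification


class TestClassificationMetrics:
    def test_observed_fuzziness_is_mean_false_label_mass(self):
        p = np.array([[0.9, 0.2], [0.8, 0.4]])
        met = classification_metrics(p, ["A", "A"], ["A", "B"], grid=np.array([0.1]))
        assert met["observed_fuzziness"] == pytest.approx(0.3)

    def test_set_counting_example(self):
        # sets {A},{A,B},{} with true labels A,A,B
        p = np.array([[0.5, 0.05], [0.5, 0.5], [0.05, 0.08]])
        met = classification_metrics(p, ["A", "A", "B"], ["A", "B"], grid=np.array([0.1]))
        row = met["per_epsilon"].iloc[0]
        assert row["average_c"] == pytest.approx(1.0)
        assert row["single_ratio"] == pytest.approx(1 / 3)
        assert row["error_rate"] == pytest.approx(1 / 3)
        assert row["multi_ratio"] == pytest.approx(1 / 3)
        assert row["empty_ratio"] == pytest.approx(1 / 3)

    def test_zero_fuzziness(self):
        p = np.array([[1.0, 0.0], [0.7, 0.0]])
        met = classification_metrics(p, ["A", "A"], ["A", "B"], grid=np.array([0.2]))
        assert met["observed_fuzziness"] == 0.0

    def test_confusion_counts_sum_to_class_counts(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=(50, 2))
        y = np.array(["A"] * 30 + ["B"] * 20)
        met = classification_metrics(p, y, ["A", "B"], grid=np.array([0.2]))
        conf = met["confusion"][0.2]
        totals = conf[["correct_single", "wrong_single", "multi", "empty"]].sum(axis=1)
        assert totals.tolist() == [30, 20]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.array([[0.5, 0.5]]), ["C"], ["A", "B"])

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=(40, 3))
        y = np.array(list("ABC") * 13 + ["A"])
        met = classification_metrics(p, y, ["A", "B", "C"])
        df = met["per_epsilon"]
        assert np.allclose(df["single_ratio"] + df["multi_ratio"] + df["empty_ratio"], 1.0)


class TestRegressionMetrics:
    def test_worked_example(self):
        iv = {0.2: np.array([[1.0, 0.0, 2.0], [2.0, 1.0, 3.0]])}
        df = regression_metrics(iv, np.array([1.0, 5.0]))
        assert df["error_rate"].iloc[0] == pytest.approx(0.5)
        assert df["mean_width"].iloc[0] == pytest.approx(2.0)

    def test_infinite_intervals_always_cover(self):
        iv = {0.1: np.array([[0.0, -np.inf, np.inf]] * 3)}
        df = regression_metrics(iv, np.array([1e6, -1e6, 0.0]))
        assert df["error_rate"].iloc[0] == 0.0
        assert df["n_infinite"].iloc[0] == 3

    def test_median_width_robust(self):
        iv = {0.2: np.array([[0, 0, 2], [0, 0, 4], [0, 0, 100]], dtype=float)}
        df = regression_metrics(iv, np.zeros(3))
        assert df["median_width"].iloc[0] == pytest.approx(4.0)


class TestCalibrationStats:
    def test_capped_rmse_example(self):
        stats = calibration_stats([0.05, 0.25], [0.1, 0.2])
        assert stats.capped_rmse == pytest.approx(np.sqrt(0.05**2 / 2), abs=1e-6)
        assert stats.capped_rmse == pytest.approx(0.0354, abs=1e-4)

    def test_perfect_calibration_all_zero(self):
        grid = significance_grid()
        stats = calibration_stats(grid, grid)
        assert stats.rmse == 0.0 and stats.capped_rmse == 0.0
        assert stats.max_signed_deviation == 0.0

    def test_conservative_has_zero_capped(self):
        stats = calibration_stats([0.0, 0.05], [0.1, 0.2])
        assert stats.capped_rmse == 0.0
        assert stats.rmse > 0.0

    def test_capped_never_exceeds_rmse(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            grid = significance_grid()
            err = np.clip(grid + rng.normal(0, 0.05, size=len(grid)), 0, 1)
            stats = calibration_stats(err, grid)
            assert stats.capped_rmse <= stats.rmse + 1e-12

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            calibration_stats([0.1], [0.1, 0.2])


class TestSignificanceGrid:
    def test_ranges(self):
        clf = significance_grid("classification")
        reg = significance_grid("regression")
        assert clf[0] == 0.01 and clf[-1] == 0.30 and len(clf) == 30
        assert reg[0] == 0.05 and reg[-1] == 0.30 and len(reg) == 26


@pytest.fixture(scope="module")
def data():
    m = gen_numeric_classification(SyntheticSpec(n=200, seed=91))
    return m.X, m.y


class TestRunValidation:

    def test_loo_runs_n_evaluations(self):
        from chemconform.data import SamplingStrategy

        m = gen_numeric_classification(SyntheticSpec(n=25, seed=92))
        # stratified calibration so both classes appear in every tiny split
        model = ConformalClassifier(
            sampling=SamplingStrategy(kind="random-stratified", calibration_ratio=0.3, seed=1),
            seed=1,
        )
        res = run_validation(m.X, m.y, model, scheme="loo", grid=np.array([0.2]))
        assert res["n_folds"] == 25

    def test_kfold_reproducible(self, data):
        X, y = data
        model = ConformalClassifier(seed=0)
        grid = np.array([0.1, 0.2])
        a = run_validation(X, y, model, scheme="kfold", k=3, grid=grid, seed=5)
        b = run_validation(X, y, model, scheme="kfold", k=3, grid=grid, seed=5)
        assert a["summary"] == b["summary"]

    def test_split_scheme_with_repetitions(self, data):
        X, y = data
        model = ConformalClassifier(seed=0)
        res = run_validation(X, y, model, scheme="split", repetitions=3,
                             grid=np.array([0.2]), seed=2)
        assert res["n_folds"] == 3
        assert "observed_fuzziness" in res["summary"]

    def test_bad_scheme_params(self, data):
        X, y = data
        with pytest.raises(ValueError):
            run_validation(X, y, ConformalClassifier(), scheme="kfold", k=10_000)
        with pytest.raises(ValueError):
            run_validation(X, y, ConformalClassifier(), scheme="split", test_fraction=1.5)


class TestGridSearch:
    def test_default_rbf_grid_size(self):
        grid = default_rbf_grid()
        assert len(grid["C"]) * len(grid["gamma"]) == 60

    def test_scorer_only_finds_separating_C(self):
        # nearly separable data: large C wins, tiny C underfits
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 2))
        y = np.where(X[:, 0] + 0.05 * rng.standard_normal(120) > 0, "pos", "neg")
        res = grid_search(X, y, ScorerConfig(), grid={"C": [1e-4, 10.0]}, k=3, seed=0)
        assert res["best"]["params"]["C"] == 10.0

    def test_tie_broken_by_enumeration_order(self, monkeypatch):
        m = gen_numeric_classification(SyntheticSpec(n=60, seed=93))
        res = grid_search(m.X, m.y, ScorerConfig(), grid={"C": [1.0, 1.0]}, k=3, seed=0)
        assert res["results"][0]["value"] == res["results"][1]["value"]
        assert res["best"] is res["results"][0]

    def test_scorer_only_never_calibrates(self, monkeypatch):
        calls = []
        monkeypatch.setattr(
            ConformalClassifier, "fit",
            lambda self, X, y: calls.append(1),
        )
        m = gen_numeric_classification(SyntheticSpec(n=60, seed=94))
        grid_search(m.X, m.y, ScorerConfig(), grid={"C": [1.0]}, mode="scorer-only", k=3)
        assert calls == []

    def test_full_predictor_mode(self):
        m = gen_numeric_classification(SyntheticSpec(n=150, seed=95))
        res = grid_search(
            m.X, m.y, ScorerConfig(), grid={"C": [0.1, 1.0]},
            mode="full-predictor", k=3, seed=1,
        )
        assert res["n_combinations"] == 2
        assert "observed_fuzziness" not in res  # objective folded into values
        assert np.isfinite(res["best"]["value"])

    def test_unknown_parameter(self):
        m = gen_numeric_classification(SyntheticSpec(n=40, seed=96))
        with pytest.raises(ValueError):
            grid_search(m.X, m.y, ScorerConfig(), grid={"depth": [1]})
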