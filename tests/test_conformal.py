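import numpy as np
import pytest
import scipy.stats

from chemconform.conformal import (
    ConformalClassifier,
    ConformalRegressor,
    TCPClassifier,
    interval_multiplier,
    prediction_set,
)
from chemconform.data import SamplingStrategy
from chemconform.scorers import ScorerConfig
from chemconform.synthetic import SyntheticSpec, gen_numeric_classification, gen_numeric_regression


def _error_rate(model, matrix, eps):
    p = model.predict_p(matrix.X)
    classes = list(model.classes_)
    idx = np.array([classes.index(v) for v in matrix.y])
    return (p[np.arange(len(matrix.y)), idx] < eps).mean()


class TestPredictionSet:
    def test_set_rule_examples(self):
        p = np.array([[0.4, 0.05]])
        assert prediction_set(p, 0.1).tolist() == [[True, False]]
        assert prediction_set(p, 0.02).tolist() == [[True, True]]
        assert prediction_set(p, 0.5).tolist() == [[False, False]]

    def test_epsilon_range(self):
        with pytest.raises(ValueError):
            prediction_set(np.array([[0.5]]), 1.5)


class TestClassifierFit:
    def test_acp_one_split_equals_icp(self, gaussian_classification, gaussian_classification_test):
        m = gaussian_classification
        strat = SamplingStrategy(kind="random", calibration_ratio=0.2, n_splits=1, seed=5)
        icp = ConformalClassifier(sampling=strat, seed=5).fit(m.X, m.y)
        acp = ConformalClassifier(sampling=strat, aggregation="mean", seed=5).fit(m.X, m.y)
        assert np.array_equal(
            icp.predict_p(gaussian_classification_test.X),
            acp.predict_p(gaussian_classification_test.X),
        )

    def test_mondrian_store_sizes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 3))
        y = np.array(["A"] * 60 + ["B"] * 20)
        X[:60, 0] += 2
        train_idx = np.concatenate([np.arange(30), np.arange(60, 70)])
        cal_idx = np.concatenate([np.arange(30, 60), np.arange(70, 80)])  # 30 A, 10 B
        strat = SamplingStrategy(kind="predefined", predefined=[(train_idx, cal_idx)])
        model = ConformalClassifier(sampling=strat).fit(X, y)
        _, stores = model.models_[0]
        assert len(stores["A"]) == 30
        assert len(stores["B"]) == 10

    def test_lower_bound_on_pvalues(self, gaussian_classification, gaussian_classification_test):
        m = gaussian_classification
        model = ConformalClassifier(seed=2).fit(m.X, m.y)
        p = model.predict_p(gaussian_classification_test.X)
        for j, c in enumerate(model.classes_):
            n_c = model.calibration_sizes_[c][0]
            assert (p[:, j] >= 1 / (n_c + 1) - 1e-12).all()

    def test_duplicate_of_calibration_object_ties(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 3))
        y = np.array(["A"] * 50 + ["B"] * 50)
        X[:50, 0] += 2
        X[50:, 0] -= 2
        tr = np.concatenate([np.arange(0, 40), np.arange(50, 90)])
        ca = np.concatenate([np.arange(40, 50), np.arange(90, 100)])
        strat = SamplingStrategy(kind="predefined", predefined=[(tr, ca)])
        model = ConformalClassifier(sampling=strat).fit(X, y)
        dup = X[95]  # a calibration object
        cls = y[95]
        j = list(model.classes_).index(cls)
        p = model.predict_p(dup.reshape(1, -1))[0, j]
        n_c = model.calibration_sizes_[cls][0]
        assert p >= 2 / (n_c + 1) - 1e-12

    def test_missing_class_in_calibration_errors(self):
        X = np.random.default_rng(0).standard_normal((20, 2))
        y = np.array(["A"] * 18 + ["B"] * 2)
        strat = SamplingStrategy(kind="predefined", predefined=[(np.arange(2, 20), np.arange(2))])
        with pytest.raises(ValueError, match="absent"):
            ConformalClassifier(sampling=strat).fit(X, y)

    def test_aggregation_mean(self, gaussian_classification, gaussian_classification_test):
        m = gaussian_classification
        strat = SamplingStrategy(n_splits=3, seed=9)
        model = ConformalClassifier(sampling=strat, seed=9).fit(m.X, m.y)
        X1 = gaussian_classification_test.X[:5]
        p = model.predict_p(X1)
        per_split = []
        for scorer, stores in model.models_:
            single = ConformalClassifier(seed=9)
            single.classes_ = model.classes_
            single.models_ = [(scorer, stores)]
            single.ncm = model.ncm
            single.pvalue_mode = "standard"
            per_split.append(single.predict_p(X1))
        assert np.allclose(p, np.mean(per_split, axis=0))


class TestSmoothedUniformity:
    def test_smoothed_pvalues_uniform_under_exchangeability(self):
        """Smoothed p-values of exchangeable draws are exactly U(0,1).

        Each of the m=5000 test nonconformities is ranked against a fresh
        calibration sample from the same distribution, so the p-values are
        independent and the KS statistic must fall below the 1% critical
        value 1.63/sqrt(m). (With a single shared calibration set the
        p-values are dependent and the plain KS test does not apply.)
        """
        from chemconform.pvalues import pvalue_smoothed

        rng = np.random.default_rng(33)
        m, n_cal = 5000, 25
        p = np.empty(m)
        for i in range(m):
            calib = rng.standard_normal(n_cal)
            p[i] = pvalue_smoothed(calib, rng.standard_normal(), rng.uniform())
        stat = scipy.stats.kstest(p, "uniform").statistic
        assert stat < 1.63 / np.sqrt(m)


class TestRegressor:
    def test_interval_multiplier_examples(self):
        store = [1, 2, 3, 4, 5]
        assert interval_multiplier(store, 0.5) == 3.0
        assert interval_multiplier(store, 0.3) == 5.0
        assert interval_multiplier(store, 0.15) == np.inf
        # smallest feasible significance is 1/6
        assert np.isfinite(interval_multiplier(store, 1 / 6))

    def test_interpolated_multiplier(self):
        store = [1.0, 2.0, 3.0, 4.0, 5.0]
        # q = (1-eps)*6; at eps=0.25, q=4.5 -> between 4 and 5
        assert interval_multiplier(store, 0.25, "linear-interpolated") == pytest.approx(4.5)
        assert interval_multiplier(store, 0.15, "linear-interpolated") == np.inf

    def test_normalized_halfwidth_arithmetic(self):
        # sigma = ehat + beta = 2.01, multiplier 3 -> half-width 6.03
        assert 3 * (2.0 + 0.01) == pytest.approx(6.03)

    def test_calibration_store_self_consistent(self, linear_regression_data):
        m = linear_regression_data
        strat = SamplingStrategy(calibration_ratio=0.2, seed=5)
        model = ConformalRegressor(sampling=strat, seed=5).fit(m.X, m.y)
        scorer, err, alphas = model.models_[0]
        assert len(alphas) == 120
        assert np.all(np.diff(alphas) >= 0)

    def test_interval_width_monotone_in_epsilon(self, linear_regression_data):
        m = linear_regression_data
        model = ConformalRegressor(seed=1).fit(m.X, m.y)
        X1 = m.X[:10]
        for mode in ("standard", "linear-interpolated"):
            model.interval_mode = mode
            widths = []
            for eps in (0.05, 0.1, 0.2, 0.3, 0.5):
                iv = model.predict_interval(X1, eps)
                widths.append(iv[:, 2] - iv[:, 1])
            for w1, w2 in zip(widths, widths[1:]):
                assert np.all(w1 >= w2 - 1e-9)

    def test_midpoint_inside_interval(self, linear_regression_data):
        m = linear_regression_data
        model = ConformalRegressor(seed=1).fit(m.X, m.y)
        iv = model.predict_interval(m.X[:20], 0.2)
        assert np.all(iv[:, 1] <= iv[:, 0] + 1e-9)
        assert np.all(iv[:, 0] <= iv[:, 2] + 1e-9)

    def test_normalized_beats_absdiff_on_heteroscedastic(self):
        spec = SyntheticSpec(task="regression", n=1500, noise=1.0, heteroscedastic=True, seed=41)
        train = gen_numeric_regression(spec)
        test = gen_numeric_regression(SyntheticSpec(
            task="regression", n=800, noise=1.0, heteroscedastic=True, seed=42))
        strat = SamplingStrategy(calibration_ratio=0.25, seed=4)
        err_cfg = ScorerConfig(algorithm="svr", kernel="rbf", C=10.0)
        difficulty = 1.0 + np.abs(test.X.toarray()[:, 0])  # true noise scale
        widths, coverage = {}, {}
        for ncm in ("abs-diff", "normalized"):
            model = ConformalRegressor(
                ncm=ncm, sampling=strat, seed=4, error_scorer_config=err_cfg,
            ).fit(train.X, train.y)
            iv = model.predict_interval(test.X, 0.2)
            widths[ncm] = iv[:, 2] - iv[:, 1]
            coverage[ncm] = float(((test.y >= iv[:, 1]) & (test.y <= iv[:, 2])).mean())
        # abs-diff intervals have one global width; normalized intervals
        # adapt, tracking the true per-object noise scale while keeping
        # coverage — the point of training an error model
        assert np.ptp(widths["abs-diff"]) < 1e-9
        assert np.corrcoef(widths["normalized"], difficulty)[0, 1] > 0.5
        easy = difficulty < np.median(difficulty)
        assert widths["normalized"][easy].mean() < widths["abs-diff"][easy].mean()
        assert coverage["normalized"] >= 0.8 - 0.05
        assert coverage["abs-diff"] >= 0.8 - 0.05

    def test_log_normalized_fits_and_covers(self, linear_regression_data):
        m = linear_regression_data
        model = ConformalRegressor(ncm="log-normalized", seed=2).fit(m.X, m.y)
        test = gen_numeric_regression(SyntheticSpec(task="regression", n=300, noise=0.5, seed=55))
        iv = model.predict_interval(test.X, 0.2)
        cov = ((test.y >= iv[:, 1]) & (test.y <= iv[:, 2])).mean()
        assert cov >= 0.8 - 0.07


@pytest.fixture(scope="module")
def small_data():
    m = gen_numeric_classification(SyntheticSpec(n=30, seed=71))
    return m.X.toarray(), m.y


class TestTCP:

    def test_deterministic(self, small_data):
        X, y = small_data
        tcp = TCPClassifier().fit(X, y)
        row = X[:2]
        assert np.array_equal(tcp.predict_p(row), tcp.predict_p(row))

    def test_pvalue_denominator(self, small_data):
        X, y = small_data
        tcp = TCPClassifier().fit(X, y)
        p = tcp.predict_p(X[:3])
        for j, c in enumerate(tcp.classes_):
            n_c = (y == c).sum()
            scaled = p[:, j] * (n_c + 1)
            assert np.allclose(scaled, np.round(scaled))

    def test_training_duplicate_has_high_pvalue(self, small_data):
        X, y = small_data
        tcp = TCPClassifier().fit(X, y)
        p = tcp.predict_p(X[4:5])
        j = list(tcp.classes_).index(y[4])
        n_c = (y == y[4]).sum()
        assert p[0, j] >= 2 / (n_c + 1) - 1e-12
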