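import numpy as np
import pytest

from mixqspr import ann_model as am


def hp(init="glorot-uniform", h1=100, h2=10, opt="adamax"):
    return am.HyperParams(init, h1, h2, opt)


class TestHyperParams:
    def test_full_grid_size(self):
        assert len(am.full_grid()) == 72

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError):
            am.HyperParams("glorot-uniform", 150, 10, "adamax")
        with pytest.raises(ValueError):
            am.HyperParams("orthogonal", 100, 10, "adamax")
        with pytest.raises(ValueError):
            am.HyperParams("glorot-uniform", 100, 10, "adam")


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(0)
    x = rng.uniform(size=(5000, 3))
    y = 0.2 + 0.3 * x[:, 0] + 0.25 * x[:, 1] - 0.15 * x[:, 2]
    return x, y


class TestTrainFold:

    def test_recovers_planted_linear_map(self, linear_problem):
        x, y = linear_problem
        cfg = am.TrainingConfig(task="regression", epochs=100, seed=0)
        model = am.train_fold(x, y, hp(), cfg)
        assert np.mean(np.abs(model.predict(x) - y)) < 0.05

    def test_deterministic_given_seed(self, linear_problem):
        x, y = linear_problem
        cfg = am.TrainingConfig(task="regression", epochs=5, seed=4)
        a = am.train_fold(x[:500], y[:500], hp(), cfg)
        b = am.train_fold(x[:500], y[:500], hp(), cfg)
        np.testing.assert_array_equal(a.predict(x[:50]), b.predict(x[:50]))

    def test_constant_target_reproduced(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(400, 4))
        folds = [(np.arange(400), np.arange(400))] * 5
        ens = am.train_ensemble(
            x, np.full(400, 2.5), folds, hp(), am.TrainingConfig(task="regression", epochs=5, seed=1)
        )
        assert np.all(np.abs(ens.predict(x) - 2.5) < 0.05)

    def test_non_finite_inputs_rejected(self):
        x = np.array([[0.1, np.nan]])
        with pytest.raises(ValueError):
            am.train_fold(x, np.array([0.5]), hp(), am.TrainingConfig(epochs=1))

    @pytest.mark.parametrize("optimizer", ["rmsprop", "adamax", "adadelta", "sgd"])
    def test_every_optimizer_reduces_loss(self, optimizer):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(600, 2))
        y = 0.3 + 0.4 * x[:, 0]
        cfg = am.TrainingConfig(task="regression", epochs=60, seed=2, batch_size=200)
        model = am.train_fold(x, y, hp(opt=optimizer), cfg)
        baseline = np.mean(np.abs(y.mean() - y))
        assert np.mean(np.abs(model.predict(x) - y)) < baseline


class TestEnsemble:
    def make_ensemble(self, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=(300, 3))
        y = x[:, 0]
        folds = [(np.arange(0, 250), np.arange(250, 300))] * 5
        cfg = am.TrainingConfig(task="regression", epochs=10, seed=seed, batch_size=100)
        return am.train_ensemble(x, y, folds, hp(), cfg), x

    def test_prediction_is_fold_mean(self):
        ens, x = self.make_ensemble()
        per_fold = np.array([m.predict(x) for m in ens.models])
        expected = per_fold.mean(axis=0) * ens.target_range + ens.target_min
        np.testing.assert_allclose(ens.predict(x), expected)

    def test_permutation_invariant_in_fold_order(self):
        ens, x = self.make_ensemble()
        shuffled = am.FoldEnsemble(
            models=ens.models[::-1],
            task=ens.task,
            target_min=ens.target_min,
            target_range=ens.target_range,
        )
        np.testing.assert_allclose(ens.predict(x), shuffled.predict(x))

    def test_identical_folds_equal_single_model(self):
        ens, x = self.make_ensemble()
        single = am.FoldEnsemble(
            models=[ens.models[0]] * 5,
            task="regression",
            target_min=ens.target_min,
            target_range=ens.target_range,
        )
        one = ens.models[0].predict(x) * ens.target_range + ens.target_min
        np.testing.assert_allclose(single.predict(x), one)

    def test_classification_threshold_contract(self):
        class Stub:
            def __init__(self, value):
                self.value = value

            def predict(self, x):
                return np.full(len(np.atleast_2d(x)), self.value)

        low = am.FoldEnsemble(models=[Stub(0.49)] * 5, task="bigidac")
        high = am.FoldEnsemble(models=[Stub(0.51)] * 5, task="bigidac")
        _, flags_low = low.predict(np.zeros((1, 3)))
        _, flags_high = high.predict(np.zeros((1, 3)))
        assert not flags_low[0] and flags_high[0]

    def test_save_load_round_trip(self, tmp_path):
        ens, x = self.make_ensemble()
        am.save_ensemble(ens, tmp_path / "m")
        again = am.load_ensemble(tmp_path / "m")
        np.testing.assert_allclose(again.predict(x), ens.predict(x))


class TestGridSearch:
    @pytest.fixture(scope="class")
    def toy_problem(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(400, 3))
        y = 0.5 * x[:, 0] + 0.3 * x[:, 1]
        folds = [(np.arange(0, 320), np.arange(320, 400))] * 5
        labels = np.repeat(["A", "B"], 40)
        t = rng.uniform(290, 350, size=80)
        return x[:320], y[:320], folds, x[320:], y[320:], labels[:80], t

    def test_singleton_grid_is_identity(self, toy_problem):
        x, y, folds, xo, yo, labels, t = toy_problem
        folds = [(np.arange(len(x)), np.arange(len(x)))] * 5
        cfg = am.TrainingConfig(task="regression", epochs=3, seed=0, batch_size=100)
        best, _, report = am.grid_search(x, y, folds, xo, yo, labels, cfg, [hp()], t)
        assert best == hp()
        assert len(report) == 1

    def test_best_matches_report_argmin(self, toy_problem):
        x, y, folds, xo, yo, labels, t = toy_problem
        folds = [(np.arange(len(x)), np.arange(len(x)))] * 5
        grid = [hp(opt="adamax"), hp(opt="sgd"), hp(init="he-uniform", opt="rmsprop"), hp(h2=20)]
        cfg = am.TrainingConfig(task="regression", epochs=5, seed=1, batch_size=100)
        best, _, report = am.grid_search(x, y, folds, xo, yo, labels, cfg, grid, t)
        assert best == grid[int(report["df"].idxmin())]

    def test_empty_grid_rejected(self, toy_problem):
        x, y, folds, xo, yo, labels, t = toy_problem
        cfg = am.TrainingConfig(task="regression", epochs=1, seed=0)
        with pytest.raises(ValueError):
            am.grid_search(x, y, folds, xo, yo, labels, cfg, [], t)


class TestConfidenceInterval:
    def test_reproduces_reported_interval(self):
        # five values with mean 0.164 and sample sd 0.002
        a = 0.002 / np.sqrt(2.5)
        values = [0.164 - 2 * a, 0.164 - a, 0.164, 0.164 + a, 0.164 + 2 * a]
        assert np.mean(values) == pytest.approx(0.164)
        assert np.std(values, ddof=1) == pytest.approx(0.002)
        assert am.ci_of_mae(values) == (0.162, 0.166)

    def test_zero_spread_degenerate_interval(self):
        assert am.ci_of_mae([0.2] * 5) == (0.2, 0.2)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            am.ci_of_mae([0.1])
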