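import numpy as np
import pytest

from seldikit.core_io import SpectrumSet, Stage
from seldikit.features import FeatureScaler
from seldikit.nn_validator import (
    DEFAULT_HIDDEN_UNITS,
    LabeledSet,
    NNModel,
    cost,
    default_lambda_grid,
    evaluate_accuracy,
    forward,
    gradient,
    select_lambda,
    split_data,
    train,
    validate_cluster,
)

from conftest import make_spectrum


def _sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def _random_model(rng, d=6, hidden=4, lam=0.0):
    return NNModel(
        theta1=rng.normal(size=(hidden, d + 1)),
        theta2=rng.normal(size=(1, hidden + 1)),
        d=d, hidden_units=hidden, lam=lam,
    )


class TestForward:
    def test_zero_weights_give_half(self, rng):
        m = NNModel(theta1=np.zeros((4, 7)), theta2=np.zeros((1, 5)),
                    d=6, hidden_units=4)
        assert forward(rng.normal(size=6), m) == pytest.approx(0.5)

    def test_output_bias_drives_p_to_one(self, rng):
        x = rng.normal(size=6)
        probs = []
        for bias in (0.0, 2.0, 10.0, 50.0):
            m = NNModel(theta1=np.zeros((4, 7)),
                        theta2=np.hstack([[[bias]], np.zeros((1, 4))]),
                        d=6, hidden_units=4)
            probs.append(forward(x, m))
        assert all(b > a for a, b in zip(probs, probs[1:]))
        assert probs[-1] > 1.0 - 1e-10

    def test_matches_two_loop_oracle(self, rng):
        m = _random_model(rng)
        x = rng.normal(size=6)
        hidden_vals = []
        for j in range(4):
            acc = m.theta1[j, 0]
            for k in range(6):
                acc += m.theta1[j, k + 1] * x[k]
            hidden_vals.append(_sigmoid(acc))
        out = m.theta2[0, 0]
        for j in range(4):
            out += m.theta2[0, j + 1] * hidden_vals[j]
        assert forward(x, m) == pytest.approx(_sigmoid(out), abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        m = _random_model(rng)
        with pytest.raises(ValueError):
            forward(np.zeros(5), m)


class TestCost:
    def test_ln2_at_half(self):
        m = NNModel(theta1=np.zeros((4, 7)), theta2=np.zeros((1, 5)),
                    d=6, hidden_units=4, lam=0.0)
        J = cost(m, np.zeros((1, 6)), np.array([1.0]))
        assert J == pytest.approx(np.log(2.0), abs=1e-12)

    def test_lambda_adds_exact_penalty(self, rng):
        m = _random_model(rng)
        X = rng.normal(size=(10, 6))
        t = rng.integers(0, 2, 10).astype(float)
        J0 = cost(m, X, t, lam=0.0)
        lam = 3.7
        expected_pen = (lam / (2 * 10)) * (
            np.sum(m.theta1[:, 1:] ** 2) + np.sum(m.theta2[:, 1:] ** 2))
        assert cost(m, X, t, lam=lam) == pytest.approx(J0 + expected_pen, rel=1e-12)

    def test_matches_per_example_loop_oracle(self, rng):
        m = _random_model(rng, lam=0.5)
        X = rng.normal(size=(7, 6))
        t = rng.integers(0, 2, 7).astype(float)
        total = 0.0
        for i in range(7):
            p = forward(X[i], m)
            total += -(t[i] * np.log(p) + (1 - t[i]) * np.log(1 - p))
        total /= 7
        total += (0.5 / (2 * 7)) * (np.sum(m.theta1[:, 1:] ** 2)
                                    + np.sum(m.theta2[:, 1:] ** 2))
        assert cost(m, X, t) == pytest.approx(total, rel=1e-10)


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        m = _random_model(rng, lam=0.8)
        X = rng.normal(size=(12, 6))
        t = rng.integers(0, 2, 12).astype(float)
        g1, g2 = gradient(m, X, t)
        flat_g = np.concatenate([g1.ravel(), g2.ravel()])
        flat_w = m.pack()
        h = 1e-5
        idx = rng.choice(flat_w.size, size=20, replace=False)
        for i in idx:
            wp, wm = flat_w.copy(), flat_w.copy()
            wp[i] += h
            wm[i] -= h
            Jp = cost(NNModel.unpack(wp, 6, 4, lam=0.8), X, t)
            Jm = cost(NNModel.unpack(wm, 6, 4, lam=0.8), X, t)
            fd = (Jp - Jm) / (2 * h)
            assert abs(flat_g[i] - fd) <= 1e-6 * max(1.0, abs(fd))

    def test_regularization_term_analytic(self, rng):
        m = _random_model(rng)
        X = rng.normal(size=(5, 6))
        t = rng.integers(0, 2, 5).astype(float)
        g1a, g2a = gradient(m, X, t, lam=0.0)
        lam = 2.0
        g1b, g2b = gradient(m, X, t, lam=lam)
        assert np.allclose(g1b[:, 1:] - g1a[:, 1:], (lam / 5) * m.theta1[:, 1:])
        assert np.allclose(g1b[:, 0], g1a[:, 0])  # bias column unregularized
        assert np.allclose(g2b[:, 1:] - g2a[:, 1:], (lam / 5) * m.theta2[:, 1:])

    def test_gradient_small_at_trained_minimum(self, rng):
        X = rng.normal(size=(40, 4))
        w = np.array([1.0, -2.0, 0.5, 1.5])
        t = (X @ w > 0).astype(float)
        m = train(X, t, lam=0.0, max_iter=400, seed=3, hidden=4)
        g1, g2 = gradient(m, X, t)
        assert np.linalg.norm(np.concatenate([g1.ravel(), g2.ravel()])) < 1e-3


class TestTrain:
    def test_separable_toy_reaches_100pct(self, rng):
        n = 60
        X = np.zeros((n, 62))
        X[:, 0] = np.concatenate([rng.normal(-3, 0.3, n // 2),
                                  rng.normal(3, 0.3, n // 2)])
        X[:, 1] = rng.normal(size=n)
        t = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        m = train(X, t, lam=0.0, max_iter=400, seed=1)
        assert evaluate_accuracy(m, X, t) == 1.0

    def test_cost_trace_non_increasing(self, rng):
        X = rng.normal(size=(30, 5))
        t = rng.integers(0, 2, 30).astype(float)
        m = train(X, t, lam=0.1, max_iter=50, seed=2, hidden=3)
        trace = np.array(m.history["J_trace"])
        assert np.all(np.diff(trace) <= 1e-10)

    def test_same_seed_identical_weights(self, rng):
        X = rng.normal(size=(20, 4))
        t = rng.integers(0, 2, 20).astype(float)
        a = train(X, t, lam=0.5, max_iter=30, seed=9, hidden=3)
        b = train(X, t, lam=0.5, max_iter=30, seed=9, hidden=3)
        assert np.array_equal(a.pack(), b.pack())


class TestSelectLambda:
    def _toy_set(self, rng, n=80):
        X = np.zeros((n, 10))
        X[:, 0] = np.concatenate([rng.normal(-2, 1.0, n // 2),
                                  rng.normal(2, 1.0, n // 2)])
        X[:, 1:] = rng.normal(size=(n, 9))
        t = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
        return split_data(X, t, seed=4)

    def test_single_value_grid(self, rng):
        data = self._toy_set(rng)
        model, lam = select_lambda(data, grid=np.array([0.1]), max_iter=50, hidden=3)
        assert lam == 0.1
        assert model.lam == 0.1

    def test_default_grid_shape(self):
        grid = default_lambda_grid()
        assert len(grid) == 13
        assert grid[0] == pytest.approx(0.003)
        assert grid[-1] == pytest.approx(10.0)

    def test_huge_lambda_not_selected_when_underfitting(self, rng):
        data = self._toy_set(rng, n=120)
        grid = np.array([0.01, 1e4])
        _, lam = select_lambda(data, grid=grid, max_iter=100, hidden=3)
        assert lam < grid[-1]


class TestSplitData:
    def test_exact_counts_m100(self, rng):
        data = split_data(rng.normal(size=(100, 3)),
                          rng.integers(0, 2, 100), seed=0)
        counts = {w: int(np.sum(data.split == w)) for w in ("train", "val", "test")}
        assert counts == {"train": 50, "val": 25, "test": 25}

    def test_same_seed_identical(self, rng):
        X = rng.normal(size=(40, 3))
        t = rng.integers(0, 2, 40)
        a = split_data(X, t, seed=5)
        b = split_data(X, t, seed=5)
        assert np.array_equal(a.split, b.split)

    def test_label_balance_within_4_sd(self, rng):
        m = 400
        X = rng.normal(size=(m, 2))
        t = rng.integers(0, 2, m)
        data = split_data(X, t, seed=6)
        overall = np.mean(t)
        for w, frac in (("train", 0.5), ("val", 0.25), ("test", 0.25)):
            _, tw = data.subset(w)
            n = len(tw)
            sd = np.sqrt(overall * (1 - overall) / n)
            assert abs(np.mean(tw) - overall) <= 4 * sd


class TestEvaluateAccuracy:
    def test_constant_half_counts_as_class_one(self):
        m = NNModel(theta1=np.zeros((4, 7)), theta2=np.zeros((1, 5)),
                    d=6, hidden_units=4)
        X = np.zeros((10, 6))
        t = np.array([1] * 3 + [0] * 7)
        # p = 0.5 exactly -> predicted class 1 -> accuracy = fraction of 1s
        assert evaluate_accuracy(m, X, t) == pytest.approx(0.3)

    def test_matches_loop_oracle(self, rng):
        m = _random_model(rng)
        X = rng.normal(size=(25, 6))
        t = rng.integers(0, 2, 25)
        correct = 0
        for i in range(25):
            pred = 1 if forward(X[i], m) >= 0.5 else 0
            correct += pred == t[i]
        assert evaluate_accuracy(m, X, t) == pytest.approx(correct / 25)


class TestValidateCluster:
    def _paired_sets(self, present_mask, c=5000.0):
        """Spectra with a clean peak at c present per mask."""
        grid = np.linspace(4800.0, 5200.0, 1024)
        raws, procs = [], []
        for i, present in enumerate(present_mask):
            y = np.full(len(grid), 1.0)
            if present:
                y = y + 40.0 * np.exp(-0.5 * ((grid - c) / 5.0) ** 2)
            raws.append(make_spectrum(grid, y, sid=f"s{i}"))
            procs.append(make_spectrum(grid, y, sid=f"s{i}", stage=Stage.SMOOTHED))
        return (SpectrumSet(spectra=raws, common_grid=grid),
                SpectrumSet(spectra=procs, common_grid=grid))

    def _always_yes_model(self):
        scaler = FeatureScaler(means=np.zeros(62), sds=np.ones(62))
        theta2 = np.zeros((1, DEFAULT_HIDDEN_UNITS + 1))
        theta2[0, 0] = 10.0  # output bias forces p ~ 1
        return NNModel(theta1=np.zeros((DEFAULT_HIDDEN_UNITS, 63)),
                       theta2=theta2, scaler=scaler)

    def test_15_of_16_gives_prevalence_0938(self):
        mask = [True] * 15 + [False]
        raw_set, proc_set = self._paired_sets(mask)
        cl = validate_cluster(raw_set, proc_set, 5000.0, self._always_yes_model())
        assert len(cl.members) == 15
        assert cl.prevalence == pytest.approx(15 / 16)
        assert round(cl.prevalence, 3) == 0.938

    def test_no_local_maxima_empty_cluster(self):
        raw_set, proc_set = self._paired_sets([False] * 4)
        cl = validate_cluster(raw_set, proc_set, 5000.0, self._always_yes_model())
        assert cl.members == []
        assert cl.prevalence == 0.0

    def test_threshold_half_keeps_peak(self):
        # all-zero weights -> p = 0.5 exactly -> kept (>= convention)
        scaler = FeatureScaler(means=np.zeros(62), sds=np.ones(62))
        m = NNModel(theta1=np.zeros((DEFAULT_HIDDEN_UNITS, 63)),
                    theta2=np.zeros((1, DEFAULT_HIDDEN_UNITS + 1)), scaler=scaler)
        raw_set, proc_set = self._paired_sets([True] * 3)
        cl = validate_cluster(raw_set, proc_set, 5000.0, m)
        assert len(cl.members) == 3

    def test_one_member_per_spectrum_and_prevalence_bounds(self):
        raw_set, proc_set = self._paired_sets([True] * 8)
        cl = validate_cluster(raw_set, proc_set, 5000.0, self._always_yes_model())
        sids = [p.spectrum_id for p in cl.members]
        assert len(sids) == len(set(sids))
        assert 0.0 <= cl.prevalence <= 1.0

    def test_members_have_heights_and_areas(self):
        raw_set, proc_set = self._paired_sets([True] * 2)
        cl = validate_cluster(raw_set, proc_set, 5000.0, self._always_yes_model())
        for p in cl.members:
            assert np.isfinite(p.area)
            assert p.height > 10.0
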