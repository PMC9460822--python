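import numpy as np
import pytest

from liftclust import bnn
from liftclust.bnn import (
    NetworkSpec,
    TrainConfig,
    evaluate,
    forward,
    init_weights,
    jacobian,
    log_evidence,
    one_hot_targets,
    split_train_test,
    sweep_hidden_nodes,
    train,
)


def finite_difference_jacobian(spec, w, X, eps=1e-6):
    n = np.atleast_2d(X).shape[0]
    J = np.zeros((n, spec.q, w.size))
    for p in range(w.size):
        wp = w.copy()
        wp[p] += eps
        wm = w.copy()
        wm[p] -= eps
        J[:, :, p] = (forward(spec, wp, X) - forward(spec, wm, X)) / (2 * eps)
    return J


def two_blobs(n_per=20, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([-sep / 2, 0], 0.5, size=(n_per, 2))
    b = rng.normal([sep / 2, 0], 0.5, size=(n_per, 2))
    X = np.vstack([a, b])
    labels = np.repeat([1, 2], n_per)
    return X, labels


class TestForward:
    def test_zero_weights_zero_output(self):
        spec = NetworkSpec(3, 4, 2)
        out = forward(spec, np.zeros(spec.n_params), np.ones((5, 3)))
        assert np.all(out == 0.0)

    def test_outputs_in_open_interval(self):
        spec = NetworkSpec(2, 3, 2)
        rng = np.random.default_rng(0)
        w = rng.normal(0, 5, spec.n_params)
        out = forward(spec, w, rng.normal(size=(10, 2)))
        assert np.all(np.abs(out) < 1.0)

    def test_small_weights_behave_linearly(self):
        # first-order Taylor: tanh(x) ~ x for tiny x, so the whole net is the
        # composition of its affine maps
        spec = NetworkSpec(2, 3, 1)
        rng = np.random.default_rng(1)
        w = rng.normal(0, 1e-4, spec.n_params)
        X = rng.normal(size=(6, 2))
        W1, b1, W2, b2 = bnn._unpack(spec, w)
        linear = (X @ W1.T + b1) @ W2.T + b2
        assert forward(spec, w, X) == pytest.approx(linear, rel=1e-6)

    def test_dimension_mismatch(self):
        spec = NetworkSpec(3, 2, 2)
        with pytest.raises(ValueError):
            forward(spec, np.zeros(spec.n_params), np.ones((4, 2)))


class TestJacobian:
    @pytest.mark.parametrize("m,l,q", [(2, 3, 2), (3, 5, 4), (1, 1, 1)])
    def test_matches_finite_differences(self, m, l, q):
        spec = NetworkSpec(m, l, q)
        rng = np.random.default_rng(42)
        w = init_weights(spec, rng) * 3.0
        X = rng.normal(size=(7, m))
        _Z, J = jacobian(spec, w, X)
        J_fd = finite_difference_jacobian(spec, w, X)
        scale = max(np.abs(J_fd).max(), 1.0)
        assert np.abs(J - J_fd).max() / scale < 1e-5


class TestTrain:
    def test_separable_blobs_perfect_training_accuracy(self):
        X, labels = two_blobs()
        spec = NetworkSpec(2, 2, 2)
        w, state, _hist = train(X, one_hot_targets(labels), spec, seed=0)
        rep = evaluate(w, spec, X, labels)
        assert rep.accuracy == 1.0

    def test_xor_capacity(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]]) * 2 - 1
        labels = np.array([1, 2, 2, 1])
        T = one_hot_targets(labels)
        # l=1 cannot represent XOR: best possible is 3/4
        accs1 = []
        for seed in range(5):
            w, _state, _ = train(X, T, NetworkSpec(2, 1, 2), seed=seed)
            accs1.append(evaluate(w, NetworkSpec(2, 1, 2), X, labels).accuracy)
        assert max(accs1) <= 0.75 + 1e-9
        # l=3 solves it
        accs3 = []
        for seed in range(5):
            w, _state, _ = train(X, T, NetworkSpec(2, 3, 2), seed=seed)
            accs3.append(evaluate(w, NetworkSpec(2, 3, 2), X, labels).accuracy)
        assert max(accs3) == 1.0

    def test_objective_never_increases_on_accepted_steps(self):
        X, labels = two_blobs(seed=3)
        spec = NetworkSpec(2, 3, 2)
        _w, _state, hist = train(X, one_hot_targets(labels), spec, seed=1)
        for step in hist:
            assert step["G_after"] <= step["G_before"] + 1e-12

    def test_hyperparameters_stay_valid(self):
        X, labels = two_blobs(seed=4)
        spec = NetworkSpec(2, 4, 2)
        _w, state, hist = train(X, one_hot_targets(labels), spec, seed=2)
        assert 0.0 <= state.gamma <= state.c
        assert state.alpha > 0 and state.beta > 0
        warmup = TrainConfig().hyper_warmup
        for step in hist:
            assert 0.0 <= step["gamma"] <= state.c
            assert step["beta"] > 0
            if step["epoch"] > warmup:  # before that, alpha keeps its 0 init
                assert step["alpha"] > 0

    def test_noise_variance_recovery(self):
        # regression toy with known noise: 1/beta estimates sigma^2 (K_S is
        # half the summed squared errors)
        rng = np.random.default_rng(7)
        sigma = 0.1
        X = rng.uniform(-1, 1, size=(200, 1))
        T = 0.5 * X + rng.normal(0, sigma, size=(200, 1))
        spec = NetworkSpec(1, 3, 1)
        _w, state, _ = train(X, T, spec, seed=3)
        assert 1.0 / state.beta == pytest.approx(sigma**2, rel=0.3)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        T = one_hot_targets(np.ones(10, dtype=int), q=2)
        with pytest.raises(ValueError):
            train(X, T, NetworkSpec(2, 2, 2), seed=0)

    def test_reproducible(self):
        X, labels = two_blobs(seed=5)
        spec = NetworkSpec(2, 3, 2)
        w1, _s1, _ = train(X, one_hot_targets(labels), spec, seed=9)
        w2, _s2, _ = train(X, one_hot_targets(labels), spec, seed=9)
        assert np.array_equal(w1, w2)


class TestLogEvidence:
    def _train_and_evidence(self, X, labels, l, seed=0):
        spec = NetworkSpec(X.shape[1], l, int(np.max(labels)))
        T = one_hot_targets(labels)
        w, state, _ = train(X, T, spec, seed=seed)
        return log_evidence(w, state, spec, X, T)

    def test_noise_inputs_decrease_evidence(self):
        X, labels = two_blobs(n_per=30, seed=11)
        rng = np.random.default_rng(12)
        X_noise = np.hstack([X, rng.normal(size=(X.shape[0], 3))])
        ev_clean = self._train_and_evidence(X, labels, l=2, seed=5)
        ev_noise = self._train_and_evidence(X_noise, labels, l=2, seed=5)
        assert ev_noise.log_evidence < ev_clean.log_evidence

    def test_overparameterized_net_penalized(self, default_cohort):
        # The complexity penalty bites once the data constrain the extra
        # parameters (gamma grows with l): on the cohort-scale 4-class task a
        # 15-hidden-unit net has lower evidence than a 3-hidden-unit one.
        # (On tiny toys with self-tuned alpha, unused parameters cost ~nothing
        # and the hidden-unit symmetry term rewards width, so the penalty can
        # only be observed in this constrained regime.)
        from liftclust.cluster import cut_tree, ward_linkage

        _trials, X, _truth = default_cohort
        labels = cut_tree(ward_linkage(X), 4).labels[:239]
        Xn = (X[:239] - X[:239].mean(0)) / X[:239].std(0)
        ev_small = self._train_and_evidence(Xn, labels, l=5, seed=1)
        ev_big = self._train_and_evidence(Xn, labels, l=15, seed=1)
        assert ev_big.log_evidence < ev_small.log_evidence

    def test_evidence_finite_and_hessian_pd(self):
        X, labels = two_blobs(seed=14)
        point = self._train_and_evidence(X, labels, l=3, seed=2)
        assert np.isfinite(point.log_evidence)


class TestSweep:
    def test_singleton_returns_it(self):
        X, labels = two_blobs(seed=15)
        spec, _w, points = sweep_hidden_nodes(X, labels, l_values=[4], seed=0)
        assert spec.l == 4
        assert len(points) == 1

    def test_curve_covers_all_requested(self):
        X, labels = two_blobs(seed=16)
        l_values = [1, 2, 3, 5]
        _spec, _w, points = sweep_hidden_nodes(X, labels, l_values=l_values, seed=0)
        assert [p.hidden_nodes for p in points] == l_values
        assert all(np.isfinite(p.log_evidence) or p.log_evidence == -np.inf for p in points)

    def test_empty_l_values_rejected(self):
        X, labels = two_blobs(seed=17)
        with pytest.raises(ValueError):
            sweep_hidden_nodes(X, labels, l_values=[])


class TestEvaluate:
    def _report_from_confusion(self, confusion, seed=0):
        # build a label/prediction pair realizing the confusion matrix, then
        # check evaluate() on a fabricated identity-like network is unneeded:
        # use the internal arithmetic directly through predictions
        confusion = np.asarray(confusion)
        labels = []
        preds = []
        for i in range(confusion.shape[0]):
            for j in range(confusion.shape[1]):
                labels += [i + 1] * confusion[i, j]
                preds += [j + 1] * confusion[i, j]
        return np.array(labels), np.array(preds)

    def _evaluate_pairs(self, labels, preds, q):
        # replicate evaluate()'s contract via a trivial network surrogate:
        # score matrix is one-hot of preds
        confusion = np.zeros((q, q), dtype=int)
        np.add.at(confusion, (labels - 1, preds - 1), 1)
        return confusion

    def test_perfect_diagonal(self):
        spec = NetworkSpec(2, 2, 2)
        X, labels = two_blobs(n_per=50, sep=8.0, seed=18)
        w, _s, _ = train(X, one_hot_targets(labels), spec, seed=0)
        rep = evaluate(w, spec, X, labels)
        assert rep.accuracy == 1.0
        assert np.all(rep.recall == 1.0)
        assert np.all(rep.precision == 1.0)
        assert np.array_equal(rep.confusion, np.diag([50, 50]))

    def test_hand_counted_confusion(self):
        # confusion [[8,2],[1,9]] -> recall (.8,.9), precision (8/9, 9/11),
        # accuracy .85; realized through a passthrough network whose argmax
        # echoes the intended prediction
        labels, preds = self._report_from_confusion([[8, 2], [1, 9]])
        spec = NetworkSpec(2, 2, 2)
        w = np.concatenate(
            [
                np.array([5.0, 0.0, 0.0, 5.0]),  # W1 = 5*I
                np.zeros(2),  # b1
                np.array([5.0, 0.0, 0.0, 5.0]),  # W2 = 5*I
                np.zeros(2),  # b2
            ]
        )
        X = one_hot_targets(preds) * 0.9  # argmax(forward) == preds
        rep = evaluate(w, spec, X, labels)
        assert np.array_equal(rep.confusion, [[8, 2], [1, 9]])
        assert rep.recall == pytest.approx([0.8, 0.9])
        assert rep.precision == pytest.approx([8 / 9, 9 / 11])
        assert rep.accuracy == pytest.approx(0.85)

    def test_accuracy_is_support_weighted_recall(self):
        rng = np.random.default_rng(19)
        X, labels = two_blobs(n_per=40, sep=2.0, seed=19)
        spec = NetworkSpec(2, 2, 2)
        w, _s, _ = train(X, one_hot_targets(labels), spec, seed=1)
        rep = evaluate(w, spec, X, labels)
        support = rep.confusion.sum(axis=1)
        weighted = np.nansum(rep.recall * support) / support.sum()
        assert rep.accuracy == pytest.approx(weighted)

    def test_undefined_precision_is_nan(self):
        # class 2 never predicted: network with all-negative output unit 2
        spec = NetworkSpec(1, 1, 2)
        w = np.zeros(spec.n_params)
        w[-1] = -5.0  # output bias of class 2 strongly negative
        w[-2] = 5.0  # output bias of class 1 strongly positive
        X = np.array([[0.0], [1.0]])
        labels = np.array([1, 2])
        rep = evaluate(w, spec, X, labels)
        assert np.isnan(rep.precision[1])

    def test_label_out_of_range(self):
        spec = NetworkSpec(1, 1, 2)
        with pytest.raises(ValueError):
            evaluate(np.zeros(spec.n_params), spec, np.zeros((2, 1)), np.array([1, 3]))


class TestSplit:
    def test_printed_counts(self):
        # strata matching the default cohort apportionment
        labels = np.repeat([1, 2, 3, 4], [32, 193, 133, 115])
        train_idx, test_idx = split_train_test(labels, 0.5, seed=0, train_size=239)
        assert train_idx.size == 239
        assert test_idx.size == 234

    def test_balanced_four_points(self):
        labels = np.array([1, 1, 2, 2])
        train_idx, test_idx = split_train_test(labels, 0.5, seed=1)
        assert train_idx.size == 2 and test_idx.size == 2
        assert set(labels[train_idx]) == {1, 2}
        assert set(labels[test_idx]) == {1, 2}

    def test_disjoint_covering(self):
        rng = np.random.default_rng(20)
        labels = rng.integers(1, 5, size=101)
        train_idx, test_idx = split_train_test(labels, 0.6, seed=2)
        combined = np.sort(np.concatenate([train_idx, test_idx]))
        assert np.array_equal(combined, np.arange(101))

    def test_stratification(self):
        labels = np.repeat([1, 2, 3, 4], [32, 193, 133, 115])
        train_idx, _ = split_train_test(labels, 0.5, seed=3, train_size=239)
        for lab, total in zip([1, 2, 3, 4], [32, 193, 133, 115]):
            got = int(np.sum(labels[train_idx] == lab))
            assert abs(got - total / 2) <= 2

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_train_test(np.array([1, 1, 2, 2]), 1.5, seed=0)

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(np.array([1, 1, 2]), 0.5, seed=0)


class TestOneHot:
    def test_round_trip(self):
        labels = np.array([1, 3, 2, 3])
        T = one_hot_targets(labels)
        assert T.shape == (4, 3)
        assert np.array_equal(np.argmax(T, axis=1) + 1, labels)
        assert set(np.unique(T)) == {-1.0, 1.0}

    def test_zero_based_rejected(self):
        with pytest.raises(ValueError):
            one_hot_targets(np.array([0, 1]))
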