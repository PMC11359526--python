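import math

import numpy as np
import pytest

from mosdet import model as mdl
from mosdet.preprocess import WindowedDataset


def zero_params(hidden=2, inputs=2, activation="sigmoid"):
    return mdl.LSTMParams(
        W={g: np.zeros((hidden, inputs)) for g in mdl.GATES},
        R={g: np.zeros((hidden, hidden)) for g in mdl.GATES},
        b_input={g: (np.ones(hidden) if g == "f" else np.zeros(hidden))
                 for g in mdl.GATES},
        b_hidden={g: np.zeros(hidden) for g in mdl.GATES},
        readout_w=np.zeros(hidden),
        readout_b=0.0,
        cell_input_activation=activation,
    )


def scalar_oracle_step(params, x, h_prev, c_prev):
    """Independent straight-line re-implementation with scalar loops."""
    H, I = params.hidden_size, params.input_size
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    out = {}
    for g in mdl.GATES:
        pre = []
        for j in range(H):
            s = params.b_input[g][j] + params.b_hidden[g][j]
            for k in range(I):
                s += params.W[g][j, k] * x[k]
            for k in range(H):
                s += params.R[g][j, k] * h_prev[k]
            pre.append(s)
        if g == "z" and params.cell_input_activation == "tanh":
            out[g] = [math.tanh(v) for v in pre]
        else:
            out[g] = [sig(v) for v in pre]
    c = [out["f"][j] * c_prev[j] + out["i"][j] * out["z"][j] for j in range(H)]
    h = [out["o"][j] * math.tanh(c[j]) for j in range(H)]
    return out, c, h


class TestInit:
    def test_recurrent_orthogonal(self):
        p = mdl.init_params(2, 8, rng_seed=0)
        for g in mdl.GATES:
            np.testing.assert_allclose(p.R[g].T @ p.R[g], np.eye(8), atol=1e-6)

    def test_forget_bias_one_rest_zero(self):
        p = mdl.init_params(2, 8, rng_seed=0)
        np.testing.assert_array_equal(p.b_input["f"], np.ones(8))
        for g in ("i", "z", "o"):
            np.testing.assert_array_equal(p.b_input[g], np.zeros(8))
        for g in mdl.GATES:
            np.testing.assert_array_equal(p.b_hidden[g], np.zeros(8))

    def test_xavier_scale(self):
        p = mdl.init_params(4, 16, rng_seed=0)
        limit = np.sqrt(6.0 / (4 + 16))
        for g in mdl.GATES:
            assert np.all(np.abs(p.W[g]) <= limit)

    def test_bad_activation_rejected(self):
        with pytest.raises(ValueError):
            mdl.init_params(2, 4, cell_input_activation="relu")


class TestLstmStep:
    def test_hand_computed_zero_weight_instance(self):
        st = mdl.lstm_step(zero_params(), np.zeros(2), np.zeros(2), np.zeros(2))
        np.testing.assert_allclose(st.i_t, 0.5, atol=1e-6)
        np.testing.assert_allclose(st.f_t, 0.7310585786, atol=1e-6)
        np.testing.assert_allclose(st.z_t, 0.5, atol=1e-6)
        np.testing.assert_allclose(st.o_t, 0.5, atol=1e-6)
        np.testing.assert_allclose(st.c_t, 0.25, atol=1e-6)
        np.testing.assert_allclose(st.h_t, 0.5 * np.tanh(0.25), atol=1e-6)

    def test_input_gate_closed_copies_cell(self, rng):
        p = mdl.init_params(2, 3, rng_seed=1)
        p.b_input["i"][:] = -1e3  # force i_t -> 0
        c_prev = rng.normal(size=3)
        st = mdl.lstm_step(p, rng.normal(size=2), np.zeros(3), c_prev)
        np.testing.assert_allclose(st.c_t, st.f_t * c_prev, atol=1e-12)

    @pytest.mark.parametrize("activation", ["sigmoid", "tanh"])
    def test_matches_scalar_oracle(self, activation, rng):
        p = mdl.init_params(2, 3, rng_seed=5, cell_input_activation=activation)
        for _ in range(10):
            x = rng.normal(size=2)
            h_prev = rng.normal(size=3)
            c_prev = rng.normal(size=3)
            st = mdl.lstm_step(p, x, h_prev, c_prev)
            gates, c, h = scalar_oracle_step(p, x, h_prev, c_prev)
            np.testing.assert_allclose(st.i_t, gates["i"], atol=1e-6)
            np.testing.assert_allclose(st.f_t, gates["f"], atol=1e-6)
            np.testing.assert_allclose(st.z_t, gates["z"], atol=1e-6)
            np.testing.assert_allclose(st.o_t, gates["o"], atol=1e-6)
            np.testing.assert_allclose(st.c_t, c, atol=1e-6)
            np.testing.assert_allclose(st.h_t, h, atol=1e-6)

    def test_gate_ranges(self, rng):
        p = mdl.init_params(2, 4, rng_seed=2)
        st = mdl.lstm_step(p, rng.normal(size=2) * 5, rng.normal(size=4),
                           rng.normal(size=4))
        for arr in (st.i_t, st.f_t, st.o_t):
            assert np.all((arr > 0) & (arr < 1))
        assert np.all(np.abs(st.h_t) < 1)

    def test_dimension_mismatch_rejected(self):
        p = mdl.init_params(2, 3, rng_seed=0)
        with pytest.raises(ValueError, match="dimension"):
            mdl.lstm_step(p, np.zeros(5), np.zeros(3), np.zeros(3))


class TestForward:
    def test_zero_window_zero_readout_is_half(self):
        prob = mdl.forward(zero_params(), np.zeros((16, 2)))
        assert prob == pytest.approx(0.5)

    def test_probability_range(self, rng):
        p = mdl.init_params(2, 8, rng_seed=3)
        probs = mdl.forward(p, rng.normal(size=(20, 16, 2)) * 3)
        assert np.all((probs > 0) & (probs < 1))

    def test_batched_equals_per_window(self, rng):
        p = mdl.init_params(2, 8, rng_seed=4)
        batch = rng.normal(size=(10, 16, 2))
        batched = mdl.forward(p, batch)
        looped = np.array([mdl.forward(p, w) for w in batch])
        assert np.max(np.abs(batched - looped)) < 1e-6

    def test_wrong_length_rejected(self):
        p = mdl.init_params(2, 4, rng_seed=0)
        with pytest.raises(ValueError, match="length"):
            mdl.forward(p, np.zeros((10, 2)))


def _finite_diff_param_check(activation, rtol=1e-4):
    rng = np.random.default_rng(0)
    p = mdl.init_params(2, 3, rng_seed=7, cell_input_activation=activation)
    x = rng.normal(size=(2, 4, 2))
    y = np.array([0.0, 1.0])
    w = np.array([1.0, 2.0])
    _, grads = mdl.loss_and_grads(p, x, y, w)

    def flatten(g):
        parts = [g[k][gate].ravel() for k in ("W", "R", "b_input", "b_hidden")
                 for gate in mdl.GATES]
        parts.append(np.atleast_1d(g["readout_w"]).ravel())
        parts.append(np.atleast_1d(g["readout_b"]).ravel())
        return np.concatenate(parts)

    analytic = flatten(grads)
    eps = 1e-6
    numeric = np.zeros_like(analytic)
    idx = 0
    # match flatten() ordering: per-kind per-gate
    arrays = ([p.W[g] for g in mdl.GATES] + [p.R[g] for g in mdl.GATES]
              + [p.b_input[g] for g in mdl.GATES]
              + [p.b_hidden[g] for g in mdl.GATES] + [p.readout_w])
    for arr in arrays:
        flat = arr.ravel()
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + eps
            lp, _ = mdl.loss_and_grads(p, x, y, w)
            flat[j] = orig - eps
            lm, _ = mdl.loss_and_grads(p, x, y, w)
            flat[j] = orig
            numeric[idx] = (lp - lm) / (2 * eps)
            idx += 1
    p.readout_b += eps
    lp, _ = mdl.loss_and_grads(p, x, y, w)
    p.readout_b -= 2 * eps
    lm, _ = mdl.loss_and_grads(p, x, y, w)
    p.readout_b += eps
    numeric[idx] = (lp - lm) / (2 * eps)

    scale = np.maximum(np.abs(numeric), 1e-6)
    assert np.max(np.abs(analytic - numeric) / scale) < rtol


class TestGradients:
    @pytest.mark.parametrize("activation", ["sigmoid", "tanh"])
    def test_param_gradients_match_finite_differences(self, activation):
        _finite_diff_param_check(activation)

    def test_input_gradients_match_finite_differences(self, rng):
        p = mdl.init_params(2, 3, rng_seed=9)
        x = rng.normal(size=(5, 2))

        analytic = mdl.input_gradients(p, x, of="probability")
        eps = 1e-6
        numeric = np.zeros_like(x)
        for t in range(x.shape[0]):
            for c in range(x.shape[1]):
                xp = x.copy(); xp[t, c] += eps
                xm = x.copy(); xm[t, c] -= eps
                fp = mdl.forward(p, xp, expected_len=None)
                fm = mdl.forward(p, xm, expected_len=None)
                numeric[t, c] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-4, atol=1e-9)


def separable_dataset(n_per_class=40, subjects=4):
    """Positives carry a constant +3 ramp, negatives are zeros."""
    T, C = 16, 2
    ramp = np.linspace(0, 3, T)[:, None] * np.ones((1, C))
    pos = np.tile(ramp, (n_per_class, 1, 1))
    neg = np.zeros((n_per_class, T, C))
    windows = np.concatenate([pos, neg])
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    n = len(labels)
    sids = np.array([f"S{i % subjects:02d}" for i in range(n)], dtype=object)
    return WindowedDataset(windows, labels, np.arange(n, dtype=float), sids)


class TestTrain:
    def test_separable_toy_reaches_perfect_accuracy(self):
        ds = separable_dataset()
        hp = mdl.Hyperparams(hidden_size=8, max_epochs=50, patience=50,
                             batch_size=16, learning_rate=0.01)
        clf = mdl.train(ds, hp, rng_seed=0)
        assert np.array_equal(clf.predict(ds.windows), ds.labels)

    def test_zero_learning_rate_keeps_params(self):
        ds = separable_dataset(10)
        hp = mdl.Hyperparams(hidden_size=4, max_epochs=3, learning_rate=0.0,
                             patience=3)
        clf = mdl.train(ds, hp, rng_seed=5)
        fresh = mdl.init_params(2, 4, np.random.default_rng(5), "sigmoid")
        # same rng stream used for split first; compare against a re-run
        clf2 = mdl.train(ds, hp, rng_seed=5)
        for g in mdl.GATES:
            np.testing.assert_array_equal(clf.params.W[g], clf2.params.W[g])
        logs = np.array([list(map(float, row)) for row in clf.training_log])
        assert np.allclose(logs[:, 1], logs[0, 1])  # loss frozen

    def test_same_seed_identical_training_log(self):
        ds = separable_dataset(20)
        hp = mdl.Hyperparams(hidden_size=4, max_epochs=5, patience=5)
        log1 = mdl.train(ds, hp, rng_seed=2).training_log
        log2 = mdl.train(ds, hp, rng_seed=2).training_log
        assert log1 == log2

    def test_single_class_rejected(self):
        ds = separable_dataset(10)
        ds = ds.subset(ds.labels == 0)
        with pytest.raises(ValueError, match="both classes"):
            mdl.train(ds)

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            mdl.TrainedClassifier(zero_params(), 1.5, [], "x", mdl.Hyperparams())


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        ds = separable_dataset(20)
        hp = mdl.Hyperparams(hidden_size=4, max_epochs=3, patience=3)
        clf = mdl.train(ds, hp, rng_seed=1)
        mdl.save_classifier(clf, tmp_path / "clf.npz")
        back = mdl.load_classifier(tmp_path / "clf.npz")
        np.testing.assert_array_equal(
            back.predict_proba(ds.windows), clf.predict_proba(ds.windows))
        assert back.config_fingerprint == clf.config_fingerprint
        assert back.training_log == clf.training_log
        assert back.hyperparams == clf.hyperparams


class TestSplits:
    def test_five_folds_of_28_subjects(self):
        sids = np.repeat([f"S{i:02d}" for i in range(28)], 3)
        folds = mdl.subject_level_folds(sids, 5, rng_seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [5, 5, 6, 6, 6]
        all_subj = np.concatenate(folds)
        assert len(all_subj) == len(set(all_subj)) == 28

    def test_train_test_split_is_partition(self):
        sids = np.array([f"S{i:02d}" for i in range(28)])
        train, test = mdl.subject_level_split(sids, 10, rng_seed=1)
        assert len(test) == 10 and len(train) == 18
        assert not set(train) & set(test)

    def test_no_window_leakage(self, easy_windows):
        train, test = mdl.subject_level_split(easy_windows.subject_ids, 2,
                                              rng_seed=0)
        train_mask = np.isin(easy_windows.subject_ids.astype(str), train)
        assert not set(easy_windows.subject_ids[train_mask]) & set(
            easy_windows.subject_ids[~train_mask])


class TestGridSearch:
    def test_singleton_grid_returned(self):
        ds = separable_dataset(20, subjects=4)
        hp = mdl.Hyperparams(hidden_size=4, max_epochs=3, patience=3)
        best, results = mdl.grid_search_cv(ds, [hp], k_folds=2, rng_seed=0)
        assert best is hp
        assert len(results) == 1

    def test_dominant_point_wins(self):
        ds = separable_dataset(30, subjects=6)
        # lr=0 cannot learn; lr>0 solves the separable toy on every fold
        weak = mdl.Hyperparams(hidden_size=4, max_epochs=5, patience=5,
                               learning_rate=0.0)
        strong = mdl.Hyperparams(hidden_size=8, max_epochs=30, patience=30,
                                 learning_rate=0.01, batch_size=16)
        best, results = mdl.grid_search_cv(ds, [weak, strong], k_folds=2,
                                           rng_seed=0)
        by_point = {r["point"]: r["mean_f1"] for r in results}
        assert by_point[1] > by_point[0]
        assert best is strong

    def test_empty_grid_rejected(self):
        ds = separable_dataset(10)
        with pytest.raises(ValueError, match="empty"):
            mdl.grid_search_cv(ds, [], k_folds=2)
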