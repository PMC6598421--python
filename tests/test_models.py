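import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dealerscan as ds
from dealerscan._nn import TwoBranchLSTM, bce_grad, bce_loss
from dealerscan.models import (
    ModelConfig,
    load_checkpoint,
    save_checkpoint,
    term_presence_features,
)
from dealerscan.preprocess import CleanPost

_DESK = dict(desk_scale=True)


def tiny_config(**kw):
    return ModelConfig(
        l_text=6, l_hash=3, embedding_dim=4, lstm_units=5, dense_units=3,
        lstm_dropout=0.0, lstm_recurrent_dropout=0.0, max_epochs=5,
        learning_rate=1e-2, batch_size=4, seed=1, **kw
    )


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        assert ds.binary_cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_worst_case_is_log_eps(self):
        assert ds.binary_cross_entropy(0, 1.0) == pytest.approx(-math.log(1e-7))

    def test_half_probability_gives_ln2(self):
        assert ds.binary_cross_entropy(1, 0.5) == pytest.approx(math.log(2), abs=1e-12)

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.floats(0.0, 1.0)), min_size=1, max_size=30)
    )
    def test_matches_printed_formula_and_batch_mean(self, pairs):
        y = np.array([p[0] for p in pairs], dtype=float)
        p = np.array([p[1] for p in pairs], dtype=float)
        # independent scalar-loop evaluation of the printed formula
        eps = 1e-7
        per_example = [
            -(yi * math.log(min(max(pi, eps), 1 - eps))
              + (1 - yi) * math.log(1 - min(max(pi, eps), 1 - eps)))
            for yi, pi in zip(y, p)
        ]
        expected = sum(per_example) / len(per_example)
        assert ds.binary_cross_entropy(y, p) == pytest.approx(expected, abs=1e-9)
        assert ds.binary_cross_entropy(y, p) >= 0.0


class TestEarlyStopping:
    def test_fires_on_constructed_sequence_at_epoch_six(self):
        losses = [0.9, 0.5, 0.4, 0.45, 0.43, 0.95]
        assert not any(
            ds.should_stop_early(losses[:i], window=4) for i in range(1, 6)
        )
        assert ds.should_stop_early(losses, window=4)

    def test_never_fires_on_monotone_decreasing(self):
        losses = [1.0 / (i + 1) for i in range(30)]
        assert not any(
            ds.should_stop_early(losses[: i + 1], window=4) for i in range(30)
        )

    def test_needs_strictly_greater_than_all_window_losses(self):
        # 0.44 is below the 0.45 two epochs back: keep training
        assert not ds.should_stop_early([0.5, 0.4, 0.45, 0.43, 0.42, 0.44], window=4)


class TestBuildDeepModel:
    def test_interface_returns_probability(self):
        config = tiny_config()
        model = ds.build_deep_model(config, vocab_size=100)
        xt = np.array([[1, 2, 3, 0, 0, 0]])
        xh = np.array([[4, 5, 0]])
        p = model.predict_proba(xt, xh)
        assert p.shape == (1,) and 0.0 <= p[0] <= 1.0

    def test_identical_seed_identical_parameters(self):
        a = ds.build_deep_model(tiny_config(), 50)
        b = ds.build_deep_model(tiny_config(), 50)
        for k in a.net.params:
            np.testing.assert_array_equal(a.net.params[k], b.net.params[k])

    def test_parameter_count_matches_layer_arithmetic(self):
        config = tiny_config()
        vocab_size = 100
        model = ds.build_deep_model(config, vocab_size)
        D, H, U = config.embedding_dim, config.lstm_units, config.dense_units
        rows = vocab_size + 2  # padding 0 and unknown size+1
        counts = model.param_count_breakdown()
        assert counts["E_t"] + counts["E_h"] == rows * D * 2
        expected = (
            2 * rows * D                     # embeddings
            + 2 * (D * 4 * H + H * 4 * H + 4 * H)  # LSTM kernels + biases
            + 2 * (H * U + U)                # branch dense layers
            + (2 * U) * U + U                # merge dense
            + U + 1                          # output unit
        )
        assert model.n_params == expected

    def test_mask_invariance_to_trailing_padding(self):
        model = ds.build_deep_model(tiny_config(), 20)
        xt = np.array([[3, 7, 0, 0, 0, 0]])
        xh = np.array([[2, 0, 0]])
        p_full = model.predict_proba(xt, xh)
        p_trim = model.net.forward(xt[:, :2], xh[:, :1])[0]
        assert p_full[0] == pytest.approx(p_trim[0], abs=1e-12)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        net = TwoBranchLSTM(vocab_rows=7, emb_dim=3, hidden=4, dense_units=2,
                            dropout=0.0, recurrent_dropout=0.0, seed=1)
        rng = np.random.default_rng(0)
        xt = rng.integers(0, 7, size=(5, 6))
        xt[:, 4:] = 0  # exercise the padding mask
        xh = rng.integers(0, 7, size=(5, 3))
        y = rng.integers(0, 2, size=5).astype(float)
        _, cache = net.forward(xt, xh)
        grads = net.backward(cache, bce_grad(y, cache["z4"]))
        eps = 1e-5
        for name, P in net.params.items():
            ana = grads[name].reshape(P.shape)
            for fi in range(0, P.size, max(1, P.size // 5)):
                idx = np.unravel_index(fi, P.shape)
                old = P[idx]
                P[idx] = old + eps
                lp = bce_loss(y, net.forward(xt, xh)[0])
                P[idx] = old - eps
                lm = bce_loss(y, net.forward(xt, xh)[0])
                P[idx] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - ana[idx]) <= 1e-7 * max(1.0, abs(num)), name


class TestTrainDeep:
    def test_loss_decreases_on_separable_set(self):
        rng = np.random.default_rng(3)
        n, config = 200, tiny_config()
        y = rng.integers(0, 2, size=n)
        # class-specific tokens make the set linearly separable
        xt = np.where(y[:, None] == 1, 1, 2) * np.ones((n, config.l_text), dtype=np.int64)
        xh = np.zeros((n, config.l_hash), dtype=np.int64)
        model = ds.build_deep_model(config, vocab_size=5)
        model, state = ds.train_deep(model, (xt[:150], xh[:150], y[:150]),
                                     (xt[150:], xh[150:], y[150:]))
        assert state.train_losses[-1] < state.train_losses[0]
        assert state.epochs_run == len(state.val_losses)

    def test_empty_split_rejected(self):
        model = ds.build_deep_model(tiny_config(), 5)
        empty = (np.empty((0, 6), int), np.empty((0, 3), int), np.empty(0, int))
        with pytest.raises(ValueError):
            ds.train_deep(model, empty, empty)

    def test_training_reproducible_with_fixed_seed(self):
        rng = np.random.default_rng(4)
        xt = rng.integers(0, 5, size=(40, 6))
        xh = rng.integers(0, 5, size=(40, 3))
        y = rng.integers(0, 2, size=40)
        probs = []
        for _ in range(2):
            model = ds.build_deep_model(tiny_config(), 5)
            model, _ = ds.train_deep(model, (xt[:30], xh[:30], y[:30]),
                                     (xt[30:], xh[30:], y[30:]))
            probs.append(model.predict_proba(xt, xh))
        np.testing.assert_array_equal(probs[0], probs[1])


class TestPredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def model():
        return ds.build_deep_model(tiny_config(), 10)

    def test_threshold_strict(self):
        class Fixed:
            config = tiny_config()
            def __init__(self, probs): self._p = np.asarray(probs)
            def predict_proba(self, xt, xh): return self._p

        xt = np.zeros((3, 6), int)
        xh = np.zeros((3, 3), int)
        preds = ds.predict(Fixed([0.6, 0.5, 0.49]), (xt, xh, np.zeros(3, int)))
        assert [p.label for p in preds] == [1, 0, 0]

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_labels_equal_elementwise_thresholding(self, probs):
        class Fixed:
            config = tiny_config()
            def __init__(self, p): self._p = np.asarray(p)
            def predict_proba(self, xt, xh): return self._p

        n = len(probs)
        preds = ds.predict(
            Fixed(probs), (np.zeros((n, 6), int), np.zeros((n, 3), int), np.zeros(n, int))
        )
        for pr, p in zip(preds, probs):
            assert pr.label == (1 if p > 0.5 else 0)

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((2, 7), int), np.zeros((2, 3), int))


class TestBaselines:
    @staticmethod
    def _features(records):
        vocab = ds.build_vocabulary(records)
        X = term_presence_features(records, vocab)
        y = np.array([r.label for r in records])
        return X, y

    def test_decision_tree_fits_separable_toy_set(self):
        records = [
            CleanPost(f"p{i}", ("signal",) if i % 2 else ("noise",), (), label=i % 2)
            for i in range(10)
        ]
        X, y = self._features(records)
        clf = ds.train_baseline("decision_tree", X, y)
        assert ([p.label for p in clf.predict(X)] == y).all()

    def test_single_tree_forest_equals_decision_tree(self):
        rng = np.random.default_rng(0)
        records = [
            CleanPost(
                f"p{i}",
                tuple(rng.choice(["a", "b", "c", "d"], size=3)),
                (),
                label=int(rng.integers(2)),
            )
            for i in range(40)
        ]
        X, y = self._features(records)
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.tree import DecisionTreeClassifier

        forest = RandomForestClassifier(
            n_estimators=1, bootstrap=False, random_state=0, max_features=None
        ).fit(X, y)
        tree = DecisionTreeClassifier(random_state=0).fit(X, y)
        np.testing.assert_array_equal(forest.predict(X), tree.predict(X))

    def test_svm_separates_two_points(self):
        records = [
            CleanPost("p0", ("left",), (), label=0),
            CleanPost("p1", ("right",), (), label=1),
        ]
        X, y = self._features(records)
        clf = ds.train_baseline("svm", X, y)
        assert [p.label for p in clf.predict(X)] == [0, 1]

    def test_all_baselines_expose_probabilities(self):
        rng = np.random.default_rng(1)
        records = [
            CleanPost(f"p{i}", tuple(rng.choice(["a", "b", "c"], size=2)), (),
                      label=int(rng.integers(2)))
            for i in range(30)
        ]
        X, y = self._features(records)
        for kind in ("decision_tree", "random_forest", "svm"):
            p = ds.train_baseline(kind, X, y).predict_proba_matrix(X)
            assert p.shape == (30,)
            assert ((p >= 0) & (p <= 1)).all()

    def test_unknown_kind_rejected(self):
        X, y = self._features([CleanPost("p", ("a",), (), label=0),
                               CleanPost("q", ("b",), (), label=1)])
        with pytest.raises(ValueError):
            ds.train_baseline("naive_bayes", X, y)


def test_checkpoint_round_trip(tmp_path):
    config = tiny_config()
    model = ds.build_deep_model(config, 20)
    rng = np.random.default_rng(5)
    xt = rng.integers(0, 20, size=(8, 6))
    xh = rng.integers(0, 20, size=(8, 3))
    save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(tmp_path / "ckpt")
    np.testing.assert_array_equal(
        model.predict_proba(xt, xh), restored.predict_proba(xt, xh)
    )
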