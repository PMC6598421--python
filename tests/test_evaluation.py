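import numpy as np
import pytest
from hypothesis import given, strategies as st

import dealerscan as ds
from dealerscan.evaluation import MODEL_KINDS, rank_auc
from dealerscan.models import ModelConfig
from dealerscan.preprocess import CleanPost


class TestMakeFolds:
    def test_singleton_folds(self):
        plan = ds.make_folds(10, 10, seed=0)
        assert sorted(np.bincount(plan.assignments)) == [1] * 10

    def test_pigeonhole_sizes(self):
        plan = ds.make_folds(12, 10, seed=0)
        assert sorted(np.bincount(plan.assignments), reverse=True) == [2, 2] + [1] * 8

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            ds.make_folds(5, 10)

    @given(st.integers(2, 10), st.integers(0, 50), st.integers(0, 1000))
    def test_partition_property(self, k, extra, seed):
        n = k + extra
        plan = ds.make_folds(n, k, seed)
        sizes = np.bincount(plan.assignments, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        # determinism per seed
        np.testing.assert_array_equal(
            plan.assignments, ds.make_folds(n, k, seed).assignments
        )


class TestComputeMetrics:
    def test_forced_arithmetic(self):
        m = ds.compute_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert m.precision == pytest.approx(100.0)
        assert m.recall == pytest.approx(50.0)
        assert m.f1 == pytest.approx(200 / 3, abs=0.01)

    def test_perfect_probs_give_full_auc(self):
        labels = [1, 1, 0, 0]
        m = ds.compute_metrics(labels, labels, probs=labels)
        assert m.auc == pytest.approx(100.0)

    def test_single_class_auc_missing(self):
        m = ds.compute_metrics([1, 1], [1, 0], probs=[0.9, 0.2])
        assert m.auc is None
        assert m.recall == pytest.approx(50.0)

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            m = ds.compute_metrics([0, 0], [0, 0], probs=None)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.floats(0.0, 1.0).map(lambda x: round(x, 2))),
            min_size=2,
            max_size=200,
        )
    )
    def test_auc_rank_formula_equals_pairwise_enumeration(self, data):
        labels = np.array([d[0] for d in data])
        probs = np.array([d[1] for d in data])
        got = rank_auc(labels, probs)
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        if len(pos) == 0 or len(neg) == 0:
            assert got is None
            return
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert got == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1), st.floats(0.01, 0.99)),
            min_size=5,
            max_size=200,
        )
    )
    def test_agrees_with_sklearn_reference(self, data):
        """Dual route: our formula-based metrics vs the library implementations."""
        from sklearn.metrics import precision_score, recall_score, f1_score, roc_auc_score

        y = np.array([d[0] for d in data])
        yhat = np.array([d[1] for d in data])
        probs = np.array([d[2] for d in data])
        if y.sum() in (0, len(y)) or yhat.sum() == 0:
            return
        m = ds.compute_metrics(y, yhat, probs)
        assert m.precision == pytest.approx(100 * precision_score(y, yhat), abs=1e-9)
        assert m.recall == pytest.approx(100 * recall_score(y, yhat), abs=1e-9)
        assert m.f1 == pytest.approx(100 * f1_score(y, yhat), abs=1e-9)
        assert m.auc == pytest.approx(100 * roc_auc_score(y, probs), abs=1e-9)

    def test_f1_is_harmonic_mean_of_reported_pr(self):
        m = ds.compute_metrics([1, 1, 1, 0, 0], [1, 1, 0, 1, 0])
        harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
        assert m.f1 == pytest.approx(harmonic, abs=0.01)


def _separable_corpus(n=60, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        label = int(rng.integers(2))
        word = "order" if label else "sunset"
        extra = str(rng.choice(["a", "b", "c"]))
        records.append(CleanPost(f"p{i}", (word, extra), (extra + "tag",), label=label))
    return records


class TestCrossValidate:
    def test_separable_corpus_scores_perfectly(self):
        corpus = _separable_corpus()
        vocab = ds.build_vocabulary(corpus)
        variant = ds.make_variants(corpus, vocab)["text_with_hashtags"]
        plan = ds.make_folds(len(variant.records), k=5, seed=0)
        config = ModelConfig(desk_scale=True, seed=0)
        metrics, oof = ds.cross_validate(variant, "decision_tree", plan, config)
        assert metrics.precision == pytest.approx(100.0)
        assert metrics.recall == pytest.approx(100.0)
        assert metrics.f1 == pytest.approx(100.0)

    def test_one_out_of_fold_prediction_per_example(self):
        corpus = _separable_corpus()
        vocab = ds.build_vocabulary(corpus)
        variant = ds.make_variants(corpus, vocab)["text_with_hashtags"]
        plan = ds.make_folds(len(variant.records), k=5, seed=1)
        config = ModelConfig(desk_scale=True, seed=0)
        _, oof = ds.cross_validate(variant, "svm", plan, config)
        assert len(oof) == len(variant.records)
        assert oof["prob"].notna().all()
        assert set(oof["fold"]) == set(range(5))

    def test_metrics_recomputable_from_oof_table(self, tmp_path):
        """End-to-end recomputation oracle: dumped out-of-fold predictions
        reproduce the reported metrics exactly."""
        corpus = _separable_corpus(seed=3)
        vocab = ds.build_vocabulary(corpus)
        variant = ds.make_variants(corpus, vocab)["text_with_hashtags"]
        plan = ds.make_folds(len(variant.records), k=4, seed=2)
        config = ModelConfig(desk_scale=True, seed=0)
        metrics, oof = ds.cross_validate(variant, "random_forest", plan, config)
        path = tmp_path / "oof.csv"
        oof.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        re_metrics = ds.compute_metrics(back["label"], back["pred"], back["prob"])
        assert re_metrics == metrics

    def test_plan_must_cover_variant(self):
        corpus = _separable_corpus()
        vocab = ds.build_vocabulary(corpus)
        variant = ds.make_variants(corpus, vocab)["text_with_hashtags"]
        plan = ds.make_folds(10, k=5, seed=0)
        with pytest.raises(ValueError):
            ds.cross_validate(variant, "svm", plan, ModelConfig(desk_scale=True))

    def test_unknown_model_kind_rejected(self):
        corpus = _separable_corpus()
        vocab = ds.build_vocabulary(corpus)
        variant = ds.make_variants(corpus, vocab)["text_with_hashtags"]
        plan = ds.make_folds(len(variant.records), k=5, seed=0)
        with pytest.raises(ValueError):
            ds.cross_validate(variant, "mlp", plan, ModelConfig(desk_scale=True))


class TestCompareVariants:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_table():
        posts, _ = ds.generate_corpus(ds.SyntheticConfig(n_posts=250, seed=7))
        clean = ds.clean_posts(posts)
        config = ModelConfig(desk_scale=True, seed=0, max_epochs=6)
        return ds.compare_variants(
            clean, config=config, model_kinds=("decision_tree", "svm"), k=4, seed=0
        )

    def test_table_shape_and_population(self, small_table):
        table, oof = small_table
        assert len(table) == 2 * 3
        assert set(table["variant"]) == set(ds.VARIANT_NAMES)
        assert table[["precision", "recall", "f1"]].notna().all().all()
        assert len(oof) == 6

    def test_rerun_reproduces_table(self, small_table):
        table, _ = small_table
        posts, _ = ds.generate_corpus(ds.SyntheticConfig(n_posts=250, seed=7))
        clean = ds.clean_posts(posts)
        config = ModelConfig(desk_scale=True, seed=0, max_epochs=6)
        table2, _ = ds.compare_variants(
            clean, config=config, model_kinds=("decision_tree", "svm"), k=4, seed=0
        )
        assert table.equals(table2)
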