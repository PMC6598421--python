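"""Cross-validation protocol and metrics for the model x variant comparison.

Each dataset variant is shuffled and split into k near-equal folds. For
every iteration one fold is held out as the test set and the model is
reset and retrained on the rest; the deep model further splits its
training folds 70/30 (stratified) into an inner training and validation
set for early stopping. Every example therefore receives exactly one
out-of-fold prediction, and precision, recall and F1 are computed from the
pooled out-of-fold predictions. AUC — the probability that a random
positive is ranked above a random negative, ties counting one half — is
computed over the pooled out-of-fold probabilities of the whole dataset
(``auc_mode="resubstitution"`` instead trains one model on everything and
scores it on everything, the literal whole-dataset reading).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from . import models as _models
from .preprocess import (
    CleanPost,
    DatasetVariant,
    Vocabulary,
    build_vocabulary,
    encode,
    make_variants,
)
from .models import ModelConfig

__all__ = [
    "FoldPlan",
    "Metrics",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "compare_variants",
    "MODEL_KINDS",
]

MODEL_KINDS = ("decision_tree", "random_forest", "svm", "deep")


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of example indices to k folds, sizes differing by <= 1."""

    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(n: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Uniform seeded shuffle followed by a near-equal contiguous split."""
    if k < 2 or n < k:
        raise ValueError(f"need n >= k >= 2, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[order[start : start + size]] = fold
        start += size
    return FoldPlan(k=k, assignments=assignments, seed=seed)


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F1/AUC as percentages; AUC is None for single-class labels."""

    precision: float
    recall: float
    f1: float
    auc: float | None


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has zero denominator; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def rank_auc(labels: np.ndarray, probs: np.ndarray) -> float | None:
    """Mann-Whitney AUC via average ranks; ties count one half."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(probs)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    labels: Sequence[int],
    pred_labels: Sequence[int],
    probs: Sequence[float] | None = None,
) -> Metrics:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), all in %.

    A zero denominator yields 0 with a warning; AUC needs both classes and
    is reported as None otherwise.
    """
    y = np.asarray(labels, dtype=np.int64)
    yhat = np.asarray(pred_labels, dtype=np.int64)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions differ in length")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    precision = _safe_ratio(tp, tp + fp, "precision")
    recall = _safe_ratio(tp, tp + fn, "recall")
    f1 = _safe_ratio(2 * precision * recall, precision + recall, "F1")
    auc = None
    if probs is not None:
        auc = rank_auc(y, np.asarray(probs, dtype=np.float64))
    return Metrics(
        precision=100.0 * precision,
        recall=100.0 * recall,
        f1=100.0 * f1,
        auc=None if auc is None else 100.0 * auc,
    )


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def _encode_variant(
    records: Sequence[CleanPost], vocab: Vocabulary, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x_text = np.stack([encode(r.text_tokens, vocab, config.l_text) for r in records])
    x_hash = np.stack([encode(r.hashtag_tokens, vocab, config.l_hash) for r in records])
    y = np.array([r.label for r in records], dtype=np.int64)
    return x_text, x_hash, y


def _fit_predict_fold(
    model_kind: str,
    records: list[CleanPost],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: ModelConfig,
    seed: int,
) -> np.ndarray:
    """Reset, train on the training folds, return probabilities on the test fold."""
    train_records = [records[i] for i in train_idx]
    test_records = [records[i] for i in test_idx]
    if config.vocab_scope == "train_only":
        vocab = build_vocabulary(train_records)
    else:
        vocab = build_vocabulary(records)
    if model_kind == "deep":
        xt, xh, y = _encode_variant(train_records, vocab, config)
        strat = y if min(np.bincount(y, minlength=2)) >= 2 else None
        idx_tr, idx_va = train_test_split(
            np.arange(len(y)), test_size=0.3, random_state=seed, stratify=strat
        )
        fold_config = ModelConfig(**{**config.__dict__, "seed": seed})
        model = _models.build_deep_model(fold_config, vocab.size)
        _models.train_deep(
            model, (xt[idx_tr], xh[idx_tr], y[idx_tr]), (xt[idx_va], xh[idx_va], y[idx_va])
        )
        xt_te, xh_te, _ = _encode_variant(test_records, vocab, config)
        return model.predict_proba(xt_te, xh_te)
    l_text = config.l_text if config.baseline_truncated else None
    l_hash = config.l_hash if config.baseline_truncated else None
    X_tr = _models.term_presence_features(
        train_records, vocab, binary=config.baseline_binary, l_text=l_text, l_hash=l_hash
    )
    y_tr = np.array([r.label for r in train_records], dtype=np.int64)
    fold_config = ModelConfig(**{**config.__dict__, "seed": seed})
    clf = _models.train_baseline(model_kind, X_tr, y_tr, fold_config)
    X_te = _models.term_presence_features(
        test_records, vocab, binary=config.baseline_binary, l_text=l_text, l_hash=l_hash
    )
    return clf.predict_proba_matrix(X_te)


def cross_validate(
    variant: DatasetVariant,
    model_kind: str,
    plan: FoldPlan,
    config: ModelConfig,
    auc_mode: Literal["pooled_oof", "resubstitution"] = "pooled_oof",
    metric_aggregation: Literal["pooled", "fold_mean"] = "pooled",
) -> tuple[Metrics, pd.DataFrame]:
    """k-fold cross-validation of one model on one variant.

    Returns the metrics row and the out-of-fold prediction table
    (``post_id, label, prob, pred, fold``) it was computed from.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    records = variant.records
    n = len(records)
    if len(plan.assignments) != n:
        raise ValueError("fold plan does not cover the variant")
    labels = variant.labels
    probs = np.full(n, np.nan)
    for fold in range(plan.k):
        test_idx = plan.test_indices(fold)
        train_idx = plan.train_indices(fold)
        try:
            probs[test_idx] = _fit_predict_fold(
                model_kind, records, train_idx, test_idx, config, _fold_seed(config.seed, fold)
            )
        except Exception as exc:  # pragma: no cover - propagation contract
            raise RuntimeError(f"model {model_kind} failed in fold {fold}: {exc}") from exc
    preds = (probs > config.decision_threshold).astype(np.int64)
    oof = pd.DataFrame(
        {
            "post_id": variant.post_ids,
            "label": labels,
            "prob": probs,
            "pred": preds,
            "fold": plan.assignments,
        }
    )
    if metric_aggregation == "pooled":
        metrics = compute_metrics(labels, preds, probs)
    else:
        rows = [
            compute_metrics(
                labels[plan.test_indices(f)], preds[plan.test_indices(f)], None
            )
            for f in range(plan.k)
        ]
        metrics = Metrics(
            precision=float(np.mean([r.precision for r in rows])),
            recall=float(np.mean([r.recall for r in rows])),
            f1=float(np.mean([r.f1 for r in rows])),
            auc=_pct_or_none(rank_auc(labels, probs)),
        )
    if auc_mode == "resubstitution":
        all_idx = np.arange(n)
        resub_probs = _fit_predict_fold(
            model_kind, records, all_idx, all_idx, config, _fold_seed(config.seed, plan.k)
        )
        metrics = Metrics(
            precision=metrics.precision,
            recall=metrics.recall,
            f1=metrics.f1,
            auc=_pct_or_none(rank_auc(labels, resub_probs)),
        )
    return metrics, oof


def _pct_or_none(x: float | None) -> float | None:
    return None if x is None else 100.0 * x


def compare_variants(
    corpus: Sequence[CleanPost],
    config: ModelConfig | None = None,
    model_kinds: Sequence[str] = MODEL_KINDS,
    k: int = 10,
    seed: int = 0,
    auc_mode: Literal["pooled_oof", "resubstitution"] = "pooled_oof",
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame]]:
    """Run every model on every ablation variant.

    Returns the model x variant metrics table (12 rows for the default four
    models and three variants) and the out-of-fold prediction tables keyed
    by ``(model, variant)``.
    """
    config = config or ModelConfig(desk_scale=True, seed=seed)
    vocab = build_vocabulary(corpus)
    variants = make_variants(corpus, vocab, l_text=config.l_text, l_hash=config.l_hash)
    rows = []
    oof_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for variant_name, variant in variants.items():
        plan = make_folds(len(variant.records), k=k, seed=seed)
        for model_kind in model_kinds:
            metrics, oof = cross_validate(
                variant, model_kind, plan, config, auc_mode=auc_mode
            )
            rows.append(
                {
                    "model": model_kind,
                    "variant": variant_name,
                    "precision": round(metrics.precision, 2),
                    "recall": round(metrics.recall, 2),
                    "f1": round(metrics.f1, 2),
                    "auc": None if metrics.auc is None else round(metrics.auc, 2),
                }
            )
            oof_tables[(model_kind, variant_name)] = oof
    return pd.DataFrame(rows), oof_tables
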