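"""Classifiers: the two-branch recurrent model and three classical baselines.

The deep model reads the text part and the hashtag part of a post through
separate embedding + LSTM + dense branches, concatenates the two branch
vectors, and maps them through two further sigmoid dense layers to a
dealer probability. It is trained with mean binary cross-entropy

    Loss = -(y * log(p) + (1 - y) * log(1 - p))

under Adam, and stops early when the most recent validation loss exceeds
each of the previous ``early_stop_window`` validation losses (the loss is
continually increasing), restoring the best-validation-loss weights.

The baselines — decision tree, random forest, and a linear-kernel SVM —
consume binary term-presence vectors over the shared vocabulary and all
expose a predicted probability so AUC is computable for every model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ._nn import Adam, TwoBranchLSTM, bce_grad, bce_loss, sigmoid
from .preprocess import CleanPost, EncodedExample, Vocabulary

__all__ = [
    "ModelConfig",
    "Prediction",
    "TrainState",
    "DeepClassifier",
    "BaselineClassifier",
    "binary_cross_entropy",
    "build_deep_model",
    "train_deep",
    "predict",
    "should_stop_early",
    "term_presence_features",
    "train_baseline",
    "save_checkpoint",
    "load_checkpoint",
]

# (embedding_dim, lstm_units, dense_units, learning_rate, max_epochs)
_PAPER_SCALE = (400, 800, 200, 1e-4, 50)
# ~25x narrower for commodity-CPU runs; the learning rate scales up with
# the narrower layers so Adam converges within the smaller epoch budget.
_DESK_SCALE = (32, 32, 16, 1e-3, 15)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Dimension/learning fields left as ``None`` take full-scale defaults
    (embedding 400, LSTM 800, dense 200, Adam lr 1e-4, 50 epochs) or, when
    ``desk_scale`` is set, reduced defaults (32/32/16, lr 1e-3, 15 epochs).
    """

    l_text: int = 50
    l_hash: int = 15
    embedding_dim: int | None = None
    lstm_units: int | None = None
    dense_units: int | None = None
    lstm_dropout: float = 0.2
    lstm_recurrent_dropout: float = 0.2
    learning_rate: float | None = None
    decision_threshold: float = 0.5
    early_stop_window: int = 4
    max_epochs: int | None = None
    batch_size: int = 32
    seed: int = 0
    desk_scale: bool = False
    vocab_scope: Literal["train_only", "full_corpus"] = "train_only"
    baseline_binary: bool = True
    baseline_truncated: bool = False

    def __post_init__(self) -> None:
        scale = _DESK_SCALE if self.desk_scale else _PAPER_SCALE
        if self.embedding_dim is None:
            self.embedding_dim = scale[0]
        if self.lstm_units is None:
            self.lstm_units = scale[1]
        if self.dense_units is None:
            self.dense_units = scale[2]
        if self.learning_rate is None:
            self.learning_rate = scale[3]
        if self.max_epochs is None:
            self.max_epochs = scale[4]
        if min(self.l_text, self.l_hash, self.embedding_dim, self.lstm_units,
               self.dense_units, self.max_epochs, self.batch_size) < 1:
            raise ValueError("all dimensions and budgets must be positive")
        for rate in (self.lstm_dropout, self.lstm_recurrent_dropout):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must be in [0, 1)")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class Prediction:
    """A dealer probability and its thresholded label (strict ``p > t``)."""

    probability: float
    label: int


@dataclass
class TrainState:
    """Per-epoch training record; one validation loss per completed epoch."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    stopped_early: bool = False
    best_epoch: int = 0

    @property
    def epochs_run(self) -> int:
        return len(self.val_losses)


def binary_cross_entropy(y, p, eps: float = 1e-7) -> float:
    """Binary cross-entropy; mean over examples for array inputs.

    ``p`` is clipped to ``[eps, 1 - eps]`` before the logarithms so the
    loss stays finite at hard 0/1 predictions.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=np.float64))
    p_arr = np.atleast_1d(np.asarray(p, dtype=np.float64))
    return bce_loss(y_arr, p_arr, eps=eps)


def should_stop_early(val_losses: Sequence[float], window: int = 4) -> bool:
    """True when the latest validation loss exceeds each of the previous
    ``window`` losses — the continually-increasing-loss stopping rule."""
    if len(val_losses) < window + 1:
        return False
    latest = val_losses[-1]
    return all(latest > prev for prev in val_losses[-window - 1 : -1])


def _as_arrays(
    examples: Sequence[EncodedExample] | tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(examples, tuple):
        return examples
    x_text = np.stack([e.text_indices for e in examples])
    x_hash = np.stack([e.hashtag_indices for e in examples])
    y = np.array([e.label for e in examples], dtype=np.int64)
    return x_text, x_hash, y


def _trim(x: np.ndarray) -> np.ndarray:
    """Drop trailing all-padding columns (pure speed-up; masking makes the
    recurrence invariant to them)."""
    nonzero = (x > 0).any(axis=0)
    if not nonzero.any():
        return x[:, :1]
    return x[:, : int(np.max(np.nonzero(nonzero)) + 1)]


class DeepClassifier:
    """The two-branch recurrent classifier bound to a config and vocabulary size."""

    def __init__(self, config: ModelConfig, vocab_size: int):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.config = config
        self.vocab_size = vocab_size
        # rows: padding 0, tokens 1..size, unknown size+1
        self.net = TwoBranchLSTM(
            vocab_rows=vocab_size + 2,
            emb_dim=config.embedding_dim,
            hidden=config.lstm_units,
            dense_units=config.dense_units,
            dropout=config.lstm_dropout,
            recurrent_dropout=config.lstm_recurrent_dropout,
            seed=config.seed,
        )

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def param_count_breakdown(self) -> dict[str, int]:
        return self.net.param_count_breakdown()

    def predict_proba(
        self, x_text: np.ndarray, x_hash: np.ndarray, batch_size: int = 512
    ) -> np.ndarray:
        self._check_lengths(x_text, x_hash)
        probs = np.empty(x_text.shape[0])
        for start in range(0, x_text.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            p, _ = self.net.forward(_trim(x_text[sl]), _trim(x_hash[sl]), train=False)
            probs[sl] = p
        return probs

    def _check_lengths(self, x_text: np.ndarray, x_hash: np.ndarray) -> None:
        if x_text.shape[1] != self.config.l_text or x_hash.shape[1] != self.config.l_hash:
            raise ValueError(
                f"encoded lengths {x_text.shape[1]}/{x_hash.shape[1]} do not match "
                f"config l_text={self.config.l_text}, l_hash={self.config.l_hash}"
            )


def build_deep_model(config: ModelConfig, vocab_size: int) -> DeepClassifier:
    """Build an untrained two-branch classifier; identical config and seed
    give identical initial parameters."""
    return DeepClassifier(config, vocab_size)


def train_deep(
    model: DeepClassifier,
    train: Sequence[EncodedExample] | tuple[np.ndarray, np.ndarray, np.ndarray],
    val: Sequence[EncodedExample] | tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ModelConfig | None = None,
) -> tuple[DeepClassifier, TrainState]:
    """Train with Adam on mean binary cross-entropy.

    After each epoch the validation loss is appended to the state; training
    stops when :func:`should_stop_early` fires or at ``max_epochs``. The
    weights of the best-validation-loss epoch are restored before return.
    """
    config = config or model.config
    xt_tr, xh_tr, y_tr = _as_arrays(train)
    xt_va, xh_va, y_va = _as_arrays(val)
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    model._check_lengths(xt_tr, xh_tr)
    rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(lr=config.learning_rate)
    state = TrainState()
    best_loss = np.inf
    best_weights = model.net.get_weights()
    n = len(y_tr)
    y_tr_f = y_tr.astype(np.float64)
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb_t, xb_h, yb = xt_tr[idx], xh_tr[idx], y_tr_f[idx]
            p, cache = model.net.forward(_trim(xb_t), _trim(xb_h), train=True, rng=rng)
            total_loss += bce_loss(yb, p) * len(idx)
            grads = model.net.backward(cache, bce_grad(yb, cache["z4"]))
            optimizer.step(model.net.params, grads)
        state.train_losses.append(total_loss / n)
        val_p = model.predict_proba(xt_va, xh_va)
        val_loss = bce_loss(y_va.astype(np.float64), val_p)
        state.val_losses.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.net.get_weights()
            state.best_epoch = epoch
        if should_stop_early(state.val_losses, config.early_stop_window):
            state.stopped_early = True
            break
    model.net.set_weights(best_weights)
    return model, state


def predict(
    model,
    examples: Sequence[EncodedExample] | tuple[np.ndarray, np.ndarray, np.ndarray],
    threshold: float | None = None,
) -> list[Prediction]:
    """One prediction per example; label 1 iff probability strictly exceeds
    the decision threshold (p = 0.5 exactly maps to label 0)."""
    xt, xh, _ = _as_arrays(examples)
    if threshold is None:
        threshold = getattr(getattr(model, "config", None), "decision_threshold", 0.5)
    probs = model.predict_proba(xt, xh)
    return [Prediction(float(p), int(p > threshold)) for p in probs]


# ----------------------------------------------------------------- baselines


def term_presence_features(
    records: Sequence[CleanPost],
    vocab: Vocabulary,
    binary: bool = True,
    l_text: int | None = None,
    l_hash: int | None = None,
) -> sp.csr_matrix:
    """Sparse term features over the vocabulary (column j = token index j+1,
    last column = unknown). Untruncated by default; pass ``l_text``/``l_hash``
    to apply the deep model's truncation to the baseline features too."""
    n_cols = vocab.size + 1
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for r, rec in enumerate(records):
        text = rec.text_tokens if l_text is None else rec.text_tokens[:l_text]
        tags = rec.hashtag_tokens if l_hash is None else rec.hashtag_tokens[:l_hash]
        counts: dict[int, int] = {}
        for tok in (*text, *tags):
            counts[vocab.index(tok) - 1] = counts.get(vocab.index(tok) - 1, 0) + 1
        for col, cnt in counts.items():
            rows.append(r)
            cols.append(col)
            vals.append(1.0 if binary else float(cnt))
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(records), n_cols))


class BaselineClassifier:
    """A fitted classical model exposing a positive-class probability."""

    def __init__(self, kind: str, estimator, config: ModelConfig):
        self.kind = kind
        self.estimator = estimator
        self.config = config

    def predict_proba_matrix(self, X: sp.csr_matrix) -> np.ndarray:
        if self.kind == "svm":
            # logistic link over the margin; monotone, so AUC-faithful
            return sigmoid(self.estimator.decision_function(X))
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: sp.csr_matrix) -> list[Prediction]:
        t = self.config.decision_threshold
        return [Prediction(float(p), int(p > t)) for p in self.predict_proba_matrix(X)]


def train_baseline(
    kind: Literal["decision_tree", "random_forest", "svm"],
    X: sp.csr_matrix,
    y: np.ndarray,
    config: ModelConfig | None = None,
) -> BaselineClassifier:
    """Fit a classical baseline on term features.

    Probabilities come from leaf class frequencies (decision tree), tree
    vote fractions (random forest), or the SVM margin through a logistic
    link, so AUC is computable for all of them.
    """
    config = config or ModelConfig(desk_scale=True)
    if X.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    if kind == "decision_tree":
        est = DecisionTreeClassifier(random_state=config.seed)
    elif kind == "random_forest":
        est = RandomForestClassifier(n_estimators=100, random_state=config.seed)
    elif kind == "svm":
        est = SVC(kernel="linear", C=1.0, random_state=config.seed)
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    est.fit(X, y)
    return BaselineClassifier(kind, est, config)


# --------------------------------------------------------------- checkpoints


def save_checkpoint(model: DeepClassifier, directory: str | Path) -> None:
    """Persist config (JSON) and weights (npz); loading restores predict exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = asdict(model.config)
    meta["vocab_size"] = model.vocab_size
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    np.savez(directory / "weights.npz", **model.net.params)


def load_checkpoint(directory: str | Path) -> DeepClassifier:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    vocab_size = meta.pop("vocab_size")
    model = DeepClassifier(ModelConfig(**meta), vocab_size)
    with np.load(directory / "weights.npz") as data:
        model.net.set_weights({k: data[k] for k in data.files})
    return model
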