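"""Self-contained numpy implementation of the two-branch recurrent classifier.

The network reads two fixed-length index sequences per example — the text
part and the hashtag part of a post — through separate branches, each an
embedding layer followed by an LSTM and a sigmoid dense layer. The two
branch vectors are concatenated and passed through two further sigmoid
dense layers; the final single unit emits the dealer probability ``p``.

Details that matter numerically:

* padding index 0 is masked out of the recurrence — at a padded timestep
  the hidden and cell states carry through unchanged, so trailing zeros
  never dilute short posts;
* dropout on the LSTM inputs and recurrent connections uses one mask per
  sequence (variational / Gal-style), which keeps training deterministic
  under a seeded generator;
* gradients come from full backpropagation through time; correctness is
  pinned down by a finite-difference check in the test suite;
* optimization is Adam with the standard moment estimates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TwoBranchLSTM", "Adam", "sigmoid", "bce_loss", "bce_grad"]

_EPS = 1e-7


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss(y: np.ndarray, p: np.ndarray, eps: float = _EPS) -> float:
    """Mean binary cross-entropy with probability clipping."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def bce_grad(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """d(mean BCE)/dz for p = sigmoid(z) — the numerically stable (p-y)/n."""
    return (sigmoid(z) - y) / y.shape[0]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class TwoBranchLSTM:
    """Two-branch embedding + LSTM + dense network emitting one probability."""

    def __init__(
        self,
        vocab_rows: int,
        emb_dim: int,
        hidden: int,
        dense_units: int,
        dropout: float = 0.2,
        recurrent_dropout: float = 0.2,
        seed: int = 0,
    ):
        if min(vocab_rows, emb_dim, hidden, dense_units) < 1:
            raise ValueError("all layer dimensions must be positive")
        if not (0.0 <= dropout < 1.0 and 0.0 <= recurrent_dropout < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        self.vocab_rows = vocab_rows
        self.emb_dim = emb_dim
        self.hidden = hidden
        self.dense_units = dense_units
        self.dropout = dropout
        self.recurrent_dropout = recurrent_dropout
        rng = np.random.default_rng(seed)
        D, H, U = emb_dim, hidden, dense_units
        p: dict[str, np.ndarray] = {}
        for b in ("t", "h"):
            p[f"E_{b}"] = rng.normal(0.0, 0.05, size=(vocab_rows, D))
            p[f"E_{b}"][0] = 0.0  # padding row
            p[f"Wx_{b}"] = _glorot(rng, D, 4 * H)
            p[f"Wh_{b}"] = _glorot(rng, H, 4 * H)
            p[f"b_{b}"] = np.zeros(4 * H)
            p[f"b_{b}"][H : 2 * H] = 1.0  # forget-gate bias
        p["W1"] = _glorot(rng, H, U)
        p["b1"] = np.zeros(U)
        p["W2"] = _glorot(rng, H, U)
        p["b2"] = np.zeros(U)
        p["W3"] = _glorot(rng, 2 * U, U)
        p["b3"] = np.zeros(U)
        p["W4"] = _glorot(rng, U, 1)
        p["b4"] = np.zeros(1)
        self.params = p

    # ---------------------------------------------------------------- info
    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def param_count_breakdown(self) -> dict[str, int]:
        return {k: int(v.size) for k, v in self.params.items()}

    # ------------------------------------------------------------- forward
    def _branch_forward(
        self,
        X: np.ndarray,
        branch: str,
        train: bool,
        rng: np.random.Generator | None,
    ) -> tuple[np.ndarray, dict]:
        p = self.params
        E, Wx, Wh, b = p[f"E_{branch}"], p[f"Wx_{branch}"], p[f"Wh_{branch}"], p[f"b_{branch}"]
        B, T = X.shape
        H = self.hidden
        emb = E[X]  # (B, T, D)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            din = (rng.random((B, 1, self.emb_dim)) < keep) / keep
        else:
            din = None
        if train and self.recurrent_dropout > 0:
            keep_r = 1.0 - self.recurrent_dropout
            drec = (rng.random((B, H)) < keep_r) / keep_r
        else:
            drec = None
        emb_in = emb if din is None else emb * din
        Zx = emb_in @ Wx  # (B, T, 4H)
        mask = (X > 0).astype(np.float64)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            h_in = h if drec is None else h * drec
            a = Zx[:, t] + h_in @ Wh + b
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t][:, None]
            steps.append(
                {"i": i, "f": f, "g": g, "o": o, "tc": tc,
                 "c_prev": c, "h_prev": h, "h_in": h_in, "m": m}
            )
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        cache = {"X": X, "emb_in": emb_in, "din": din, "drec": drec,
                 "steps": steps, "branch": branch}
        return h, cache

    def _branch_backward(self, dh_T: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        branch = cache["branch"]
        Wx, Wh = p[f"Wx_{branch}"], p[f"Wh_{branch}"]
        X, emb_in, drec = cache["X"], cache["emb_in"], cache["drec"]
        B, T = X.shape
        H = self.hidden
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dZx = np.zeros((B, T, 4 * H))
        dh = dh_T.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            s = cache["steps"][t]
            m = s["m"]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dc_new = dc * m
            dc_prev = dc * (1.0 - m)
            do = dh_new * s["tc"]
            dc_new = dc_new + dh_new * s["o"] * (1.0 - s["tc"] ** 2)
            df = dc_new * s["c_prev"]
            dc_prev = dc_prev + dc_new * s["f"]
            di = dc_new * s["g"]
            dg = dc_new * s["i"]
            da = np.concatenate(
                [
                    di * s["i"] * (1.0 - s["i"]),
                    df * s["f"] * (1.0 - s["f"]),
                    dg * (1.0 - s["g"] ** 2),
                    do * s["o"] * (1.0 - s["o"]),
                ],
                axis=1,
            )
            dZx[:, t] = da
            dWh += s["h_in"].T @ da
            db += da.sum(axis=0)
            dh_in = da @ Wh.T
            if drec is not None:
                dh_in = dh_in * drec
            dh = dh_prev + dh_in
            dc = dc_prev
        dWx = emb_in.reshape(B * T, -1).T @ dZx.reshape(B * T, -1)
        demb_in = dZx @ Wx.T  # (B, T, D)
        if cache["din"] is not None:
            demb = demb_in * cache["din"]
        else:
            demb = demb_in
        dE = np.zeros_like(p[f"E_{branch}"])
        np.add.at(dE, X.ravel(), demb.reshape(B * T, -1))
        dE[0] = 0.0
        return {f"E_{branch}": dE, f"Wx_{branch}": dWx, f"Wh_{branch}": dWh, f"b_{branch}": db}

    def forward(
        self,
        x_text: np.ndarray,
        x_hash: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return (probabilities, cache). ``cache`` feeds :meth:`backward`."""
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        p = self.params
        ht, cache_t = self._branch_forward(x_text, "t", train, rng)
        hh, cache_h = self._branch_forward(x_hash, "h", train, rng)
        a1 = sigmoid(ht @ p["W1"] + p["b1"])
        a2 = sigmoid(hh @ p["W2"] + p["b2"])
        merged = np.concatenate([a1, a2], axis=1)
        a3 = sigmoid(merged @ p["W3"] + p["b3"])
        z4 = (a3 @ p["W4"] + p["b4"]).ravel()
        prob = sigmoid(z4)
        cache = {"cache_t": cache_t, "cache_h": cache_h, "ht": ht, "hh": hh,
                 "a1": a1, "a2": a2, "merged": merged, "a3": a3, "z4": z4}
        return prob, cache

    def backward(self, cache: dict, dz4: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/dz4 through the whole network."""
        p = self.params
        U = self.dense_units
        a3, merged, a1, a2 = cache["a3"], cache["merged"], cache["a1"], cache["a2"]
        dz4 = dz4[:, None]
        grads: dict[str, np.ndarray] = {}
        grads["W4"] = a3.T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * a3 * (1.0 - a3)
        grads["W3"] = merged.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dmerged = dz3 @ p["W3"].T
        da1, da2 = dmerged[:, :U], dmerged[:, U:]
        dz1 = da1 * a1 * (1.0 - a1)
        dz2 = da2 * a2 * (1.0 - a2)
        grads["W1"] = cache["ht"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        grads["W2"] = cache["hh"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        dht = dz1 @ p["W1"].T
        dhh = dz2 @ p["W2"].T
        grads.update(self._branch_backward(dht, cache["cache_t"]))
        grads.update(self._branch_backward(dhh, cache["cache_h"]))
        return grads

    # --------------------------------------------------------- persistence
    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()


class Adam:
    """Adam optimizer over a named-parameter dictionary."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            g = g.reshape(params[k].shape)
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
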