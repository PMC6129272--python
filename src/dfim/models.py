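"""Model contract and small reference network implementations.

Any trained sequence-to-activity model enters the interaction engine
through :class:`SequenceModel`: a batched ``predict`` returning the
scalar output Y (the regression value, or for classifiers the
pre-sigmoid logit — never the probability, which would crush gradients
under sigmoid saturation) and a batched ``input_gradient`` returning
dY/dX.  Both must accept fractional (non-one-hot) input columns, since
GC-background mutations and integrated-gradients interpolation produce
them.

Two trainable architectures are implemented directly in numpy with
analytic forward/backward passes: a one-convolutional-layer CNN for
motif classification and a dense feed-forward net for regression on
short fixed-length sequences.  Gradients are exact (verified by central
finite differences); Adam is used for fitting.  Models serialize to
JSON.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np


class ModelContractError(RuntimeError):
    """A model produced non-finite predictions or gradients."""


def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2:
        return arr[None, :, :], True
    if arr.ndim == 3:
        return arr, False
    raise ValueError(f"expected (4, L) or (B, 4, L) input, got shape {arr.shape}")


class SequenceModel(ABC):
    """Differentiable scalar-output model over 4 x L one-hot sequences."""

    task_index: int | None = None

    @abstractmethod
    def predict(self, x: np.ndarray) -> np.ndarray | float:
        """Scalar output Y per sequence; (B, 4, L) -> (B,), (4, L) -> float."""

    @abstractmethod
    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """dY/dX per sequence, same shape as the input."""


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


# ---------------------------------------------------------------------------
# Analytic fixtures


class LinearSequenceModel(SequenceModel):
    """Y = sum(weights * X) + bias; gradient is the constant weight matrix.

    The exact first-order model: every attribution backend and every
    interaction score has a closed form on it (all interactions are 0).
    """

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        weights = np.asarray(weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4:
            raise ValueError(f"weights must be 4 x L, got {weights.shape}")
        if not np.all(np.isfinite(weights)) or not np.isfinite(bias):
            raise ValueError("weights and bias must be finite")
        self.weights = weights
        self.bias = float(bias)

    def _check(self, batch: np.ndarray) -> None:
        if batch.shape[1:] != self.weights.shape:
            raise ValueError(
                f"input shape {batch.shape[1:]} does not match weights {self.weights.shape}"
            )

    def predict(self, x):
        batch, single = _as_batch(x)
        self._check(batch)
        y = np.tensordot(batch, self.weights, axes=([1, 2], [0, 1])) + self.bias
        return float(y[0]) if single else y

    def input_gradient(self, x):
        batch, single = _as_batch(x)
        self._check(batch)
        grad = np.broadcast_to(self.weights, batch.shape).copy()
        return grad[0] if single else grad


def wrap_linear_model(weights: np.ndarray, bias: float = 0.0) -> LinearSequenceModel:
    """Wrap a 4 x L weight matrix as a linear :class:`SequenceModel`."""
    return LinearSequenceModel(weights, bias)


def gradient_check(model: SequenceModel, x: np.ndarray, epsilon: float = 1e-5) -> float:
    """Max relative error between analytic and central-difference gradients.

    error = max over entries of |fd - analytic| / (|analytic| + 1e-8).
    """
    if not 0 < epsilon <= 0.1:
        raise ValueError("epsilon must be in (0, 0.1]")
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("gradient_check expects a single (4, L) input")
    analytic = np.asarray(model.input_gradient(x), dtype=float)
    n = x.size
    perturbed = np.repeat(x[None, :, :], 2 * n, axis=0)
    flat = perturbed.reshape(2 * n, -1)
    idx = np.arange(n)
    flat[idx, idx] += epsilon
    flat[n + idx, idx] -= epsilon
    preds = np.asarray(model.predict(perturbed), dtype=float)
    if not np.all(np.isfinite(preds)):
        raise ModelContractError("model returned non-finite predictions")
    fd = (preds[:n] - preds[n:]) / (2.0 * epsilon)
    fd = fd.reshape(x.shape)
    return float(np.max(np.abs(fd - analytic) / (np.abs(analytic) + 1e-8)))


# ---------------------------------------------------------------------------
# One-convolutional-layer CNN


class ConvNet(SequenceModel):
    """conv(F filters, width K) -> ReLU -> global pooling -> dense ReLU -> linear logit.

    Pooling is either a hard global max (``pooling="max"``) or the
    smooth log-sum-exp soft maximum (``pooling="lse"``) at temperature
    tau: pooled = max + log(sum exp(tau*(a - max)))/tau.  Both are
    translation invariant, but they differ in how they treat repeated
    motif instances: a hard max sees only the single best match, so a
    duplicate instance fully buffers a mutated one, whereas log-sum-exp
    pools two equal peaks to peak + log(2)/tau — the logit keeps a
    genuine dependence on every instance, which matters when the
    trained model is later probed for feature interactions.  Larger tau
    approaches the hard max (sharper peaks, less gradient mass on
    background windows); tau -> 0 approaches mean pooling.

    Multi-task variants hold one output row per task; ``task_index``
    selects which logit ``predict``/``input_gradient`` refer to.  The
    hidden dense layer is what lets the logit encode non-additive
    (interaction) structure between motifs captured by different
    filters.
    """

    PARAM_NAMES = ("w_conv", "b_conv", "w_hidden", "b_hidden", "w_out", "b_out")
    POOLING_MODES = ("max", "lse")

    def __init__(
        self,
        seq_length: int,
        n_filters: int = 16,
        filter_width: int = 15,
        n_hidden: int = 32,
        n_tasks: int = 1,
        task_index: int | None = None,
        pooling: str = "max",
        pool_temperature: float = 1.0,
        rng: np.random.Generator | None = None,
        params: dict[str, np.ndarray] | None = None,
    ):
        if filter_width > seq_length:
            raise ValueError("filter width exceeds sequence length")
        if pooling not in self.POOLING_MODES:
            raise ValueError(f"unknown pooling mode {pooling!r}")
        if pool_temperature <= 0:
            raise ValueError("pool_temperature must be positive")
        self.seq_length = seq_length
        self.n_filters = n_filters
        self.filter_width = filter_width
        self.n_hidden = n_hidden
        self.n_tasks = n_tasks
        self.pooling = pooling
        self.pool_temperature = float(pool_temperature)
        self.task_index = 0 if task_index is None else int(task_index)
        if not 0 <= self.task_index < n_tasks:
            raise ValueError(f"task_index {task_index} out of range for {n_tasks} tasks")
        if params is not None:
            self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        else:
            rng = rng or np.random.default_rng()
            # He-style init scaled to fan-in
            self.params = {
                "w_conv": rng.normal(0, np.sqrt(2.0 / (4 * filter_width)), (n_filters, 4, filter_width)),
                "b_conv": np.zeros(n_filters),
                "w_hidden": rng.normal(0, np.sqrt(2.0 / n_filters), (n_hidden, n_filters)),
                "b_hidden": np.zeros(n_hidden),
                "w_out": rng.normal(0, np.sqrt(1.0 / n_hidden), (n_tasks, n_hidden)),
                "b_out": np.zeros(n_tasks),
            }

    # -- forward / backward -------------------------------------------------

    def _forward(self, batch: np.ndarray) -> dict:
        p = self.params
        K = self.filter_width
        win = np.lib.stride_tricks.sliding_window_view(batch, K, axis=2)
        # (B, 4, P, K) -> (B, P, 4*K)
        win = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            batch.shape[0], -1, 4 * K
        )
        wc = p["w_conv"].reshape(self.n_filters, 4 * K)
        z = win @ wc.T + p["b_conv"]          # (B, P, F)
        a = relu(z)
        cache = {"batch": batch, "win": win, "z": z, "a": a}
        if self.pooling == "max":
            pool_idx = np.argmax(a, axis=1)   # (B, F), first max on ties
            pooled = np.take_along_axis(a, pool_idx[:, None, :], axis=1)[:, 0, :]
            cache["pool_idx"] = pool_idx
        else:  # log-sum-exp, stabilized by the per-filter max
            tau = self.pool_temperature
            m = a.max(axis=1, keepdims=True)
            e = np.exp(tau * (a - m))
            ssum = e.sum(axis=1, keepdims=True)
            pooled = (m + np.log(ssum) / tau)[:, 0, :]
            cache["soft"] = e / ssum          # softmax weights, the pool gradient
        h_pre = pooled @ p["w_hidden"].T + p["b_hidden"]
        h = relu(h_pre)
        logits = h @ p["w_out"].T + p["b_out"]  # (B, T)
        cache.update({"pooled": pooled, "h_pre": h_pre, "h": h, "logits": logits})
        return cache

    def predict(self, x):
        batch, single = _as_batch(x)
        y = self._forward(batch)["logits"][:, self.task_index]
        return float(y[0]) if single else y

    def _conv_delta(self, cache: dict, d_logit: np.ndarray) -> np.ndarray:
        """Backprop d_logit (B,) to the conv pre-activations (B, P, F)."""
        p = self.params
        dh = d_logit[:, None] * p["w_out"][self.task_index][None, :]
        dh_pre = dh * (cache["h_pre"] > 0)
        d_pooled = dh_pre @ p["w_hidden"]                      # (B, F)
        if self.pooling == "max":
            da = np.zeros_like(cache["a"])
            np.put_along_axis(
                da, cache["pool_idx"][:, None, :], d_pooled[:, None, :], axis=1
            )
        else:
            da = d_pooled[:, None, :] * cache["soft"]
        return da * (cache["z"] > 0)

    def input_gradient(self, x):
        batch, single = _as_batch(x)
        cache = self._forward(batch)
        dz = self._conv_delta(cache, np.ones(batch.shape[0]))
        K = self.filter_width
        P = cache["z"].shape[1]
        wc = self.params["w_conv"].reshape(self.n_filters, 4 * K)
        dwin = (dz @ wc).reshape(batch.shape[0], P, 4, K)
        dx = np.zeros_like(batch)
        for k in range(K):
            dx[:, :, k:k + P] += dwin[:, :, :, k].transpose(0, 2, 1)
        return dx[0] if single else dx

    def loss_gradients(self, batch: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        """Binary cross-entropy with logits on the selected task."""
        p = self.params
        cache = self._forward(batch)
        z = cache["logits"][:, self.task_index]
        # stable BCE-with-logits
        loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        B = batch.shape[0]
        dz = (1.0 / (1.0 + np.exp(-z)) - y) / B               # (B,)
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["w_out"][self.task_index] = dz @ cache["h"]
        grads["b_out"][self.task_index] = dz.sum()
        dh = dz[:, None] * p["w_out"][self.task_index][None, :]
        dh_pre = dh * (cache["h_pre"] > 0)
        grads["w_hidden"] = dh_pre.T @ cache["pooled"]
        grads["b_hidden"] = dh_pre.sum(axis=0)
        dz_conv = self._conv_delta(cache, dz)                  # (B, P, F)
        K = self.filter_width
        dwc = np.einsum("bpf,bpd->fd", dz_conv, cache["win"])
        grads["w_conv"] = dwc.reshape(self.n_filters, 4, K)
        grads["b_conv"] = dz_conv.sum(axis=(0, 1))
        return loss, grads

    # -- multi-task ---------------------------------------------------------

    def clone_task(self, task: int) -> "ConvNet":
        """Single-output model carrying only output row ``task``."""
        params = {k: v.copy() for k, v in self.params.items()}
        params["w_out"] = params["w_out"][task:task + 1]
        params["b_out"] = params["b_out"][task:task + 1]
        return ConvNet(
            self.seq_length, self.n_filters, self.filter_width, self.n_hidden,
            n_tasks=1, task_index=0, pooling=self.pooling,
            pool_temperature=self.pool_temperature, params=params,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "class": "ConvNet",
            "seq_length": self.seq_length,
            "n_filters": self.n_filters,
            "filter_width": self.filter_width,
            "n_hidden": self.n_hidden,
            "n_tasks": self.n_tasks,
            "task_index": self.task_index,
            "pooling": self.pooling,
            "pool_temperature": self.pool_temperature,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConvNet":
        return cls(
            d["seq_length"], d["n_filters"], d["filter_width"], d["n_hidden"],
            n_tasks=d["n_tasks"], task_index=d["task_index"],
            pooling=d.get("pooling", "max"),
            pool_temperature=d.get("pool_temperature", 1.0),
            params=d["params"],
        )


# ---------------------------------------------------------------------------
# Dense feed-forward regression net


class DenseNet(SequenceModel):
    """Flattened one-hot -> stacked dense ReLU layers -> linear scalar.

    Used for regression on short fixed-length sequences (e.g. motif-flank
    libraries) where positional structure is handled by the dense layers.
    """

    def __init__(
        self,
        seq_length: int,
        hidden_sizes: tuple[int, ...] = (64, 32),
        rng: np.random.Generator | None = None,
        params: dict[str, np.ndarray] | None = None,
    ):
        self.seq_length = seq_length
        self.hidden_sizes = tuple(hidden_sizes)
        sizes = [4 * seq_length, *self.hidden_sizes, 1]
        if params is not None:
            self.params = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        else:
            rng = rng or np.random.default_rng()
            self.params = {}
            for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
                self.params[f"w{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_out, fan_in))
                self.params[f"b{i}"] = np.zeros(fan_out)
        self.n_layers = len(sizes) - 1

    def _forward(self, batch: np.ndarray) -> dict:
        act = batch.reshape(batch.shape[0], -1)
        acts, pres = [act], []
        for i in range(self.n_layers):
            pre = act @ self.params[f"w{i}"].T + self.params[f"b{i}"]
            pres.append(pre)
            act = relu(pre) if i < self.n_layers - 1 else pre
            acts.append(act)
        return {"acts": acts, "pres": pres}

    def predict(self, x):
        batch, single = _as_batch(x)
        y = self._forward(batch)["acts"][-1][:, 0]
        return float(y[0]) if single else y

    def input_gradient(self, x):
        batch, single = _as_batch(x)
        cache = self._forward(batch)
        d = np.ones((batch.shape[0], 1))
        for i in range(self.n_layers - 1, -1, -1):
            d = d @ self.params[f"w{i}"]
            if i > 0:
                d = d * (cache["pres"][i - 1] > 0)
        dx = d.reshape(batch.shape)
        return dx[0] if single else dx

    def loss_gradients(self, batch: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        """Mean squared error."""
        cache = self._forward(batch)
        pred = cache["acts"][-1][:, 0]
        resid = pred - y
        loss = float(np.mean(resid ** 2))
        B = batch.shape[0]
        d = (2.0 * resid / B)[:, None]
        grads = {}
        for i in range(self.n_layers - 1, -1, -1):
            grads[f"w{i}"] = d.T @ cache["acts"][i]
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = (d @ self.params[f"w{i}"]) * (cache["pres"][i - 1] > 0)
        return loss, grads

    def to_dict(self) -> dict:
        return {
            "class": "DenseNet",
            "seq_length": self.seq_length,
            "hidden_sizes": list(self.hidden_sizes),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DenseNet":
        return cls(d["seq_length"], tuple(d["hidden_sizes"]), params=d["params"])


# ---------------------------------------------------------------------------
# Fitting and persistence


def adam_fit(
    model,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int = 128,
    learning_rate: float = 1e-3,
    weight_decay: float = 0.0,
    seed: int = 0,
    callback=None,
) -> list[float]:
    """Minibatch Adam on ``model.loss_gradients``; returns per-epoch losses.

    ``weight_decay`` adds an L2 penalty gradient to weight matrices
    (parameters named ``w*``); biases are not decayed.  Deterministic
    for a fixed seed: shuffling uses its own Generator and updates are
    applied in a fixed parameter order.
    """
    rng = np.random.default_rng(seed)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(val) for k, val in model.params.items()}
    t = 0
    losses = []
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads = model.loss_gradients(X[idx], y[idx])
            epoch_loss += loss * len(idx)
            t += 1
            for k in sorted(model.params):
                g = grads[k]
                if weight_decay and k.startswith("w"):
                    g = g + weight_decay * model.params[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                model.params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)
        if callback is not None and callback(epoch, losses[-1]):
            break
    return losses


_MODEL_CLASSES = {"ConvNet": ConvNet, "DenseNet": DenseNet}


def save_model(model, path: str | Path) -> None:
    """Serialize a trainable model to JSON."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str | Path) -> SequenceModel:
    with open(path) as fh:
        d = json.load(fh)
    cls = _MODEL_CLASSES.get(d.get("class"))
    if cls is None:
        raise ValueError(f"unknown model class {d.get('class')!r} in {path}")
    return cls.from_dict(d)
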