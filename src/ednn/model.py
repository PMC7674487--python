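"""Two-layer fully connected classifier with KL-L1 sparsity regularization.

Architecture: ``k`` selected voxels -> dense(n_hidden, ReLU) -> dense(1,
logistic).  The loss is binary cross-entropy plus ``lambda_reg`` times the
KL-L1 penalty applied to both weight matrices:

    L_KL-L1 = sum_i  p_i log(p_i / eps) + (1 - p_i) log((1 - p_i)/(1 - eps)),

where ``p_i`` is the L1 norm of weight row i, interpreted as a Bernoulli
parameter and pulled toward the sparsity target ``eps``.  Because raw L1
norms are unbounded while the Bernoulli KL needs (0, 1), row norms are
clipped to ``[delta, 1 - delta]`` with ``delta = 1e-6`` before the KL is
evaluated; the penalty (and its gradient) is flat where the clip is active.

Training is full numpy: analytic gradients, Adam, mini-batches shuffled from
a seeded generator, early stopping on the training loss.  Everything is
bit-reproducible given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import DegenerateClassError, FeatureMismatchError

_DELTA = 1e-6


@dataclass
class EDNNConfig:
    """Hyperparameters for the KL-L1 network.

    ``epsilon`` is the sparsity target for the row-wise L1 norms; ``lambda_reg``
    weighs the penalty against the cross-entropy.
    """

    n_hidden: int = 64
    epsilon: float = 0.05
    lambda_reg: float = 1e-3
    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int = 32
    seed: int = 0
    patience: int = 50
    tol: float = 1e-7
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        for name in ("n_hidden", "batch_size", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:  # 0 = evaluate-only (warm-started transfer)
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainedEDNN:
    """Weights of the two dense layers plus the provenance that produced them."""

    W1: np.ndarray  # (n_hidden, k)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (1, n_hidden)
    b2: np.ndarray  # (1,)
    feature_columns: np.ndarray
    config: EDNNConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    # training-split standardization (None = features used raw)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.W1.shape[1]

    def save(self, path: str | Path) -> None:
        """Persist as .npz (arrays) + embedded JSON config."""
        arrays = dict(
            W1=self.W1,
            b1=self.b1,
            W2=self.W2,
            b2=self.b2,
            feature_columns=self.feature_columns,
            config_json=np.array(json.dumps(asdict(self.config))),
            history_json=np.array(json.dumps(self.history)),
        )
        if self.feature_mean is not None:
            arrays["feature_mean"] = self.feature_mean
            arrays["feature_scale"] = self.feature_scale
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEDNN":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                W1=z["W1"],
                b1=z["b1"],
                W2=z["W2"],
                b2=z["b2"],
                feature_columns=z["feature_columns"],
                config=EDNNConfig(**json.loads(str(z["config_json"]))),
                history=json.loads(str(z["history_json"])),
                feature_mean=z["feature_mean"] if "feature_mean" in z else None,
                feature_scale=z["feature_scale"] if "feature_scale" in z else None,
            )


def kl_l1_penalty(W: np.ndarray, epsilon: float) -> float:
    """Bernoulli-KL penalty between clipped row L1 norms and the target eps.

    Zero iff every clipped row norm equals eps; always >= 0.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    p = np.clip(np.abs(W).sum(axis=1), _DELTA, 1.0 - _DELTA)
    kl = p * np.log(p / epsilon) + (1.0 - p) * np.log((1.0 - p) / (1.0 - epsilon))
    return float(np.maximum(kl, 0.0).sum())


def _kl_l1_grad(W: np.ndarray, epsilon: float) -> np.ndarray:
    """Exact dPenalty/dW of the clipped penalty: zero where the clip is
    active (the initialization keeps row norms inside the domain, so the
    flat region is rarely visited)."""
    W = np.asarray(W, dtype=np.float64)
    raw = np.abs(W).sum(axis=1)
    p = np.clip(raw, _DELTA, 1.0 - _DELTA)
    dkl_dp = np.log(p / epsilon) - np.log((1.0 - p) / (1.0 - epsilon))
    dkl_dp = np.where((raw > _DELTA) & (raw < 1.0 - _DELTA), dkl_dp, 0.0)
    return dkl_dp[:, None] * np.sign(W)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(model: TrainedEDNN, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_scale
    h = np.maximum(X @ model.W1.T + model.b1, 0.0)
    p = _sigmoid(h @ model.W2.T + model.b2).ravel()
    return p, h


def predict_proba(model: TrainedEDNN, X: np.ndarray) -> np.ndarray:
    """Per-subject probability of the patient class (label 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.k:
        raise FeatureMismatchError(
            f"model expects {model.k} features, got {X.shape[1]}"
        )
    return _forward(model, X)[0]


def predict_label(
    model: TrainedEDNN, X: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Hard labels; probability >= threshold calls the patient class."""
    return (predict_proba(model, X) >= threshold).astype(np.int64)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def total_loss(
    model: TrainedEDNN, X: np.ndarray, y: np.ndarray, config: EDNNConfig
) -> float:
    """Mean binary cross-entropy + lambda * KL-L1 penalty on both layers."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0] or X.shape[1] != model.k:
        raise FeatureMismatchError("batch shape does not match model")
    p, _ = _forward(model, X)
    reg = kl_l1_penalty(model.W1, config.epsilon) + kl_l1_penalty(
        model.W2, config.epsilon
    )
    return _bce(p, y) + config.lambda_reg * reg


def _init_params(k: int, config: EDNNConfig, rng: np.random.Generator):
    # Rows start with L1 norm 0.5, inside the penalty's (0, 1) domain, so
    # the Bernoulli-KL term is differentiable from the first step.
    W1 = rng.normal(0.0, 1.0, size=(config.n_hidden, k))
    W1 *= 0.5 / np.abs(W1).sum(axis=1, keepdims=True)
    b1 = np.zeros(config.n_hidden)
    W2 = rng.normal(0.0, 1.0, size=(1, config.n_hidden))
    W2 *= 0.5 / np.abs(W2).sum(axis=1, keepdims=True)
    b2 = np.zeros(1)
    return [W1, b1, W2, b2]


def train_ednn(
    X: np.ndarray,
    y: np.ndarray,
    config: EDNNConfig,
    feature_columns: np.ndarray | None = None,
    warm_start: TrainedEDNN | None = None,
) -> TrainedEDNN:
    """Fit the two-layer network with Adam on BCE + lambda * KL-L1.

    ``X`` must already be restricted to the selected feature columns.
    ``warm_start`` seeds the parameters from an existing model (transfer
    retraining); otherwise they are drawn from the config seed.  When
    ``config.standardize`` is on, features are z-scored with training-split
    statistics that travel with the model (a warm start reuses the source
    model's statistics so the inherited weights stay meaningful).  The model
    returned carries the parameters of the epoch with the best training
    loss, and per-epoch loss/accuracy in ``history``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    if np.unique(y).size < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise DegenerateClassError("training set needs >=2 subjects per class")
    if feature_columns is None:
        feature_columns = np.arange(k, dtype=np.int64)

    feature_mean = feature_scale = None
    if warm_start is not None:
        feature_mean, feature_scale = warm_start.feature_mean, warm_start.feature_scale
    elif config.standardize:
        feature_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        feature_scale = np.where(sd > 0, sd, 1.0)
    if feature_mean is not None:
        X = (X - feature_mean) / feature_scale

    rng = np.random.default_rng(config.seed)
    if warm_start is not None:
        if warm_start.k != k:
            raise FeatureMismatchError("warm-start model has different feature count")
        params = [
            warm_start.W1.copy(),
            warm_start.b1.copy(),
            warm_start.W2.copy(),
            warm_start.b2.copy(),
        ]
    else:
        params = _init_params(k, config, rng)

    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    t = 0

    def epoch_eval() -> tuple[float, float]:
        W1, b1, W2, b2 = params
        h = np.maximum(X @ W1.T + b1, 0.0)
        p = _sigmoid(h @ W2.T + b2).ravel()
        reg = kl_l1_penalty(W1, config.epsilon) + kl_l1_penalty(W2, config.epsilon)
        loss = _bce(p, y) + config.lambda_reg * reg
        acc = float(((p >= 0.5).astype(int) == y).mean())
        return loss, acc

    loss0, acc0 = epoch_eval()
    history: dict[str, list[float]] = {"loss": [loss0], "accuracy": [acc0]}
    best_loss = loss0
    best_params = [p.copy() for p in params]
    stall = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, yb = X[idx], y[idx]
            W1, b1, W2, b2 = params

            a1 = Xb @ W1.T + b1
            h = np.maximum(a1, 0.0)
            p = _sigmoid(h @ W2.T + b2).ravel()

            nb = len(idx)
            dlogit = (p - yb)[:, None] / nb  # (nb, 1)
            gW2 = dlogit.T @ h
            gb2 = dlogit.sum(axis=0)
            dh = dlogit @ W2
            da1 = dh * (a1 > 0)
            gW1 = da1.T @ Xb
            gb1 = da1.sum(axis=0)

            gW1 += config.lambda_reg * _kl_l1_grad(W1, config.epsilon)
            gW2 += config.lambda_reg * _kl_l1_grad(W2, config.epsilon)

            t += 1
            for p_i, g_i, m_i, v_i in zip(params, [gW1, gb1, gW2, gb2], m, v):
                m_i *= beta1
                m_i += (1 - beta1) * g_i
                v_i *= beta2
                v_i += (1 - beta2) * g_i**2
                mhat = m_i / (1 - beta1**t)
                vhat = v_i / (1 - beta2**t)
                p_i -= config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)

        loss, acc = epoch_eval()
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        history["loss"].append(loss)
        history["accuracy"].append(acc)
        if loss < best_loss - config.tol:
            best_loss = loss
            best_params = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    W1, b1, W2, b2 = best_params
    return TrainedEDNN(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        feature_columns=np.asarray(feature_columns, dtype=np.int64),
        config=config,
        history=history,
        feature_mean=feature_mean,
        feature_scale=feature_scale,
    )


def combine_tissues(
    p_gm: float, p_wm: float, threshold: float = 0.5
) -> tuple[float, int]:
    """Fuse the per-tissue patient probabilities into one verdict.

    Default rule: arithmetic mean, label 1 (patient) iff the mean >= threshold.
    """
    for p in (p_gm, p_wm):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    combined = 0.5 * (p_gm + p_wm)
    return combined, int(combined >= threshold)
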