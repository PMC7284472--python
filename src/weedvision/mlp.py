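"""Small feed-forward classifier networks.

The networks mirror the MATLAB-style design space searched by the bee
algorithm: one or two hidden layers, per-layer transfer functions
(tansig = tanh, logsig = logistic sigmoid, satlins = symmetric saturating
linear, purelin = identity), a linear 3-unit output layer trained on
one-hot targets under mean squared error, and three batch training
algorithms — resilient backpropagation (Rprop), plain gradient descent
(with optional momentum), and Levenberg–Marquardt (Gauss–Newton with an
adaptive damping term, using the exact per-sample Jacobian).

Inputs are z-score normalized with statistics from the training portion
only; all weight initialization and splitting is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.model_selection import train_test_split

from .tables import FeatureTable

TRANSFER_FUNCTIONS = ("tansig", "logsig", "satlins", "purelin")
TRAINING_ALGORITHMS = ("rprop", "levenberg_marquardt", "gradient_descent")
LEARNING_RULES = ("gd", "gd_momentum")


def _apply(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tansig":
        return np.tanh(z)
    if name == "logsig":
        return expit(z)
    if name == "satlins":
        return np.clip(z, -1.0, 1.0)
    if name == "purelin":
        return z
    raise ValueError(f"unknown transfer function {name!r}")


def _deriv(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "tansig":
        return 1.0 - a ** 2
    if name == "logsig":
        return a * (1.0 - a)
    if name == "satlins":
        return ((z > -1.0) & (z < 1.0)).astype(float)
    if name == "purelin":
        return np.ones_like(z)
    raise ValueError(f"unknown transfer function {name!r}")


@dataclass(frozen=True)
class MLPSpec:
    hidden_sizes: tuple[int, ...] = (10,)
    transfers: tuple[str, ...] = ("tansig",)
    training: str = "levenberg_marquardt"
    learning_rule: str = "gd"
    epochs: int = 200
    learning_rate: float = 0.05
    goal: float = 1e-6
    n_outputs: int = 3

    def __post_init__(self):
        if not (1 <= len(self.hidden_sizes) <= 2):
            raise ValueError("need 1 or 2 hidden layers")
        if len(self.transfers) != len(self.hidden_sizes):
            raise ValueError("one transfer function per hidden layer")
        if any(n < 1 for n in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        for t in self.transfers:
            if t not in TRANSFER_FUNCTIONS:
                raise ValueError(f"unknown transfer {t!r}")
        if self.training not in TRAINING_ALGORITHMS:
            raise ValueError(f"unknown training algorithm {self.training!r}")
        if self.learning_rule not in LEARNING_RULES:
            raise ValueError(f"unknown learning rule {self.learning_rule!r}")

    def to_dict(self) -> dict:
        return {
            "hidden_sizes": list(self.hidden_sizes),
            "transfers": list(self.transfers),
            "training": self.training,
            "learning_rule": self.learning_rule,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "goal": self.goal,
            "n_outputs": self.n_outputs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPSpec":
        return cls(hidden_sizes=tuple(d["hidden_sizes"]),
                   transfers=tuple(d["transfers"]),
                   training=d["training"], learning_rule=d["learning_rule"],
                   epochs=d["epochs"], learning_rate=d["learning_rate"],
                   goal=d["goal"], n_outputs=d["n_outputs"])


def _init_weights(spec: MLPSpec, n_in: int, rng: np.random.Generator):
    sizes = [n_in, *spec.hidden_sizes, spec.n_outputs]
    weights = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (a + b))
        weights.append([rng.uniform(-bound, bound, size=(a, b)),
                        rng.uniform(-bound, bound, size=b)])
    return weights


def _forward(weights, transfers, X):
    acts, pres = [X], []
    a = X
    names = [*transfers, "purelin"]
    for (W, b), nm in zip(weights, names):
        z = a @ W + b
        a = _apply(nm, z)
        pres.append(z)
        acts.append(a)
    return acts, pres


def _gradients(weights, transfers, acts, pres, err):
    """Batch MSE gradients; err = (out - target) / n_samples."""
    names = [*transfers, "purelin"]
    grads = [None] * len(weights)
    delta = err * _deriv(names[-1], pres[-1], acts[-1])
    for l in range(len(weights) - 1, -1, -1):
        grads[l] = [acts[l].T @ delta, delta.sum(axis=0)]
        if l > 0:
            delta = (delta @ weights[l][0].T) * _deriv(names[l - 1], pres[l - 1], acts[l])
    return grads


def _flatten(ws):
    return np.concatenate([np.concatenate([W.ravel(), b.ravel()]) for W, b in ws])


def _unflatten(vec, template):
    out, k = [], 0
    for W, b in template:
        w = vec[k:k + W.size].reshape(W.shape)
        k += W.size
        bb = vec[k:k + b.size]
        k += b.size
        out.append([w.copy(), bb.copy()])
    return out


def _sse(weights, transfers, X, T):
    acts, _ = _forward(weights, transfers, X)
    return float(np.sum((acts[-1] - T) ** 2)), acts[-1]


def _train_gd(weights, spec, X, T):
    # bold-driver step control: back off when the loss increases, so the
    # fixed learning rate cannot diverge on wide inputs
    momentum = 0.9 if spec.learning_rule == "gd_momentum" else 0.0
    lr = spec.learning_rate
    vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    n = len(X)
    prev_loss = np.inf
    snapshot = [[W.copy(), b.copy()] for W, b in weights]
    for _ in range(spec.epochs):
        acts, pres = _forward(weights, spec.transfers, X)
        loss = float(np.sum((acts[-1] - T) ** 2))
        if loss < spec.goal:
            break
        if not np.isfinite(loss) or loss > prev_loss * 1.02:
            weights = [[W.copy(), b.copy()] for W, b in snapshot]
            vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
            lr *= 0.5
            if lr < 1e-8:
                break
            continue
        snapshot = [[W.copy(), b.copy()] for W, b in weights]
        prev_loss = loss
        grads = _gradients(weights, spec.transfers, acts, pres, (acts[-1] - T) / n)
        for l in range(len(weights)):
            for p in range(2):
                vel[l][p] = momentum * vel[l][p] - lr * grads[l][p]
                weights[l][p] = weights[l][p] + vel[l][p]
    return weights


def _train_rprop(weights, spec, X, T):
    """iRprop- : sign-based per-weight step adaptation."""
    eta_plus, eta_minus = 1.2, 0.5
    d_min, d_max = 1e-6, 50.0
    step = [[np.full_like(W, 0.07), np.full_like(b, 0.07)] for W, b in weights]
    prev = [[np.zeros_like(W), np.zeros_like(b)] for W, b in weights]
    n = len(X)
    for _ in range(spec.epochs):
        acts, pres = _forward(weights, spec.transfers, X)
        if np.sum((acts[-1] - T) ** 2) < spec.goal:
            break
        grads = _gradients(weights, spec.transfers, acts, pres, (acts[-1] - T) / n)
        for l in range(len(weights)):
            for p in range(2):
                g, gp = grads[l][p], prev[l][p]
                sgn = g * gp
                step[l][p] = np.where(sgn > 0,
                                      np.minimum(step[l][p] * eta_plus, d_max),
                                      np.where(sgn < 0,
                                               np.maximum(step[l][p] * eta_minus, d_min),
                                               step[l][p]))
                g = np.where(sgn < 0, 0.0, g)
                weights[l][p] = weights[l][p] - np.sign(g) * step[l][p]
                prev[l][p] = g
    return weights


def _per_sample_jacobian(weights, transfers, acts, pres):
    """J[n*K, P]: derivative of each residual w.r.t. every parameter."""
    names = [*transfers, "purelin"]
    n = acts[0].shape[0]
    K = acts[-1].shape[1]
    blocks = []
    for k in range(K):
        delta = np.zeros((n, K))
        delta[:, k] = _deriv(names[-1], pres[-1], acts[-1])[:, k]
        layer_parts = []
        deltas = [None] * len(weights)
        deltas[-1] = delta
        for l in range(len(weights) - 1, 0, -1):
            deltas[l - 1] = (deltas[l] @ weights[l][0].T) * _deriv(
                names[l - 1], pres[l - 1], acts[l])
        for l in range(len(weights)):
            a_prev = acts[l]
            dW = a_prev[:, :, None] * deltas[l][:, None, :]   # (n, in, out)
            layer_parts.append(dW.reshape(n, -1))
            layer_parts.append(deltas[l])
        blocks.append(np.concatenate(layer_parts, axis=1))
    # interleave so row order is residual (sample0 k0..K, sample1 ...)
    P = blocks[0].shape[1]
    J = np.empty((n * K, P))
    for k in range(K):
        J[k::K] = blocks[k]
    return J


def _train_lm(weights, spec, X, T):
    mu, mu_inc, mu_dec, mu_max = 1e-3, 10.0, 0.1, 1e10
    sse, _ = _sse(weights, spec.transfers, X, T)
    max_iter = min(spec.epochs, 100)
    for _ in range(max_iter):
        acts, pres = _forward(weights, spec.transfers, X)
        r = (acts[-1] - T).ravel()
        J = _per_sample_jacobian(weights, spec.transfers, acts, pres)
        g = J.T @ r
        if np.max(np.abs(g)) < 1e-9 or sse < spec.goal:
            break
        JtJ = J.T @ J
        improved = False
        while mu <= mu_max:
            try:
                dw = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), -g)
            except np.linalg.LinAlgError:
                mu *= mu_inc
                continue
            cand = _unflatten(_flatten(weights) + dw, weights)
            new_sse, _ = _sse(cand, spec.transfers, X, T)
            if new_sse < sse:
                weights, sse = cand, new_sse
                mu = max(mu * mu_dec, 1e-12)
                improved = True
                break
            mu *= mu_inc
        if not improved:
            break
    return weights


_TRAINERS = {
    "gradient_descent": _train_gd,
    "rprop": _train_rprop,
    "levenberg_marquardt": _train_lm,
}


@dataclass
class TrainedModel:
    """A trained network plus its preprocessing and provenance."""

    spec: MLPSpec
    weights: list
    norm_mean: np.ndarray
    norm_std: np.ndarray
    feature_indices: list[int] | None = None
    classes: tuple[int, ...] = (1, 2, 3)
    meta: dict = field(default_factory=dict)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_indices is not None and X.shape[1] != len(self.norm_mean):
            X = X[:, self.feature_indices]
        if X.shape[1] != len(self.norm_mean):
            raise ValueError("feature dimension mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        return (X - self.norm_mean) / self.norm_std

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Softmax class scores, one row per sample."""
        acts, _ = _forward(self.weights, self.spec.transfers, self._prepare(X))
        out = acts[-1]
        e = np.exp(out - out.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels; ties resolved toward the lowest class index."""
        s = self.scores(X)
        return np.array(self.classes)[np.argmax(s, axis=1)]

    def save(self, path) -> None:
        payload = {
            "spec": self.spec.to_dict(),
            "weights": [[W.tolist(), b.tolist()] for W, b in self.weights],
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "feature_indices": self.feature_indices,
            "classes": list(self.classes),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, list, dict))},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            spec=MLPSpec.from_dict(d["spec"]),
            weights=[[np.asarray(W), np.asarray(b)] for W, b in d["weights"]],
            norm_mean=np.asarray(d["norm_mean"]),
            norm_std=np.asarray(d["norm_std"]),
            feature_indices=d["feature_indices"],
            classes=tuple(d["classes"]),
            meta=d.get("meta", {}),
        )


def _one_hot(y: np.ndarray, classes=(1, 2, 3)) -> np.ndarray:
    T = np.zeros((len(y), len(classes)))
    for k, c in enumerate(classes):
        T[y == c, k] = 1.0
    return T


def fit_mlp(X: np.ndarray, y: np.ndarray, spec: MLPSpec, seed: int,
            feature_indices: list[int] | None = None) -> TrainedModel:
    """Train a network on (X, y) with z-score normalization fit on X."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std <= 0] = 1.0
    Xn = (X - mean) / std
    T = _one_hot(np.asarray(y))
    rng = np.random.default_rng(seed)
    weights = _init_weights(spec, Xn.shape[1], rng)
    weights = _TRAINERS[spec.training](weights, spec, Xn, T)
    return TrainedModel(spec, weights, mean, std, feature_indices=feature_indices,
                        meta={"seed": seed, "n_train": int(len(X))})


def train_mlp(
    table: FeatureTable,
    spec: MLPSpec,
    seed: int,
    test_fraction: float = 0.3,
) -> TrainedModel:
    """Stratified 70/30 split, train on the 70%, record the split.

    The held-out indices are stored in ``model.meta['test_idx']`` for
    evaluation.
    """
    idx = np.arange(table.n_samples)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed % (2 ** 31),
        stratify=table.labels)
    y_tr = table.labels[train_idx]
    if len(np.unique(y_tr)) < len(np.unique(table.labels)):
        raise ValueError("a class is missing from the training stratum")
    model = fit_mlp(table.values[train_idx], y_tr, spec, seed)
    model.meta["train_idx"] = train_idx.tolist()
    model.meta["test_idx"] = test_idx.tolist()
    return model
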