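"""Bee-algorithm network search and the KNN reference classifier.

The bees algorithm optimizes the MLP architecture (hidden-layer count and
sizes, per-layer transfer functions, training algorithm, weight/bias
learning rule): scout specs are sampled uniformly from the search space,
the best sites recruit neighborhood perturbations (neuron counts nudged,
transfers and algorithms swapped), elite sites more intensively, and the
spec with the best validation accuracy wins. The defaults are standard
bees-algorithm settings; a typical winning network for this problem is
two hidden layers (20 tansig, 12 satlins) trained with resilient
backpropagation.

The KNN reference votes among the k nearest Euclidean neighbors after
z-score normalization with training statistics; ties go to the class with
the smallest mean neighbor distance, then the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .mlp import MLPSpec, TrainedModel, fit_mlp
from .tables import FeatureTable


@dataclass(frozen=True)
class BAConfig:
    n_scouts: int = 20
    n_sites: int = 5
    n_elite: int = 2
    recruits_elite: int = 10
    recruits_other: int = 5
    iterations: int = 50
    neighborhood: int = 4         # +- neurons per perturbation
    shrink: float = 0.9           # neighborhood shrink factor per iteration
    swap_prob: float = 0.3        # chance to swap a categorical knob
    cv_folds: int = 3             # stratified folds for spec fitness
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_elite <= self.n_sites <= self.n_scouts):
            raise ValueError("need elite <= sites <= scouts")
        if self.recruits_elite < 1 or self.recruits_other < 1:
            raise ValueError("recruits must be >= 1")


@dataclass(frozen=True)
class SpecSearchSpace:
    hidden_layer_counts: tuple[int, ...] = (1, 2)
    neurons: tuple[int, int] = (5, 25)
    transfers: tuple[str, ...] = ("tansig", "logsig", "satlins", "purelin")
    trainings: tuple[str, ...] = ("rprop", "levenberg_marquardt", "gradient_descent")
    learning_rules: tuple[str, ...] = ("gd", "gd_momentum")
    epochs: int = 120

    def sample(self, rng: np.random.Generator) -> MLPSpec:
        n_layers = int(rng.choice(self.hidden_layer_counts))
        sizes = tuple(int(rng.integers(self.neurons[0], self.neurons[1] + 1))
                      for _ in range(n_layers))
        transfers = tuple(str(rng.choice(self.transfers)) for _ in range(n_layers))
        return MLPSpec(hidden_sizes=sizes, transfers=transfers,
                       training=str(rng.choice(self.trainings)),
                       learning_rule=str(rng.choice(self.learning_rules)),
                       epochs=self.epochs)

    def perturb(self, spec: MLPSpec, rng: np.random.Generator,
                radius: float, swap_prob: float) -> MLPSpec:
        sizes = list(spec.hidden_sizes)
        for k in range(len(sizes)):
            delta = int(rng.integers(-max(1, round(radius)), max(1, round(radius)) + 1))
            sizes[k] = int(np.clip(sizes[k] + delta, self.neurons[0], self.neurons[1]))
        transfers = list(spec.transfers)
        for k in range(len(transfers)):
            if rng.uniform() < swap_prob:
                transfers[k] = str(rng.choice(self.transfers))
        training = spec.training
        if rng.uniform() < swap_prob:
            training = str(rng.choice(self.trainings))
        rule = spec.learning_rule
        if rng.uniform() < swap_prob:
            rule = str(rng.choice(self.learning_rules))
        return replace(spec, hidden_sizes=tuple(sizes), transfers=tuple(transfers),
                       training=training, learning_rule=rule)


@dataclass
class BAResult:
    best_spec: MLPSpec
    model: TrainedModel
    trace: list[float]
    failures: int = 0


def _inner_folds(y, n_folds, seed):
    """Stratified train/validation folds; one 75/25 split if too few."""
    from sklearn.model_selection import StratifiedKFold

    idx = np.arange(len(y))
    counts = np.bincount(y)[1:]
    if n_folds >= 2 and counts.min() >= n_folds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed % (2 ** 31))
        return list(skf.split(idx, y))
    try:
        tr, val = train_test_split(idx, test_size=0.25,
                                   random_state=seed % (2 ** 31), stratify=y)
    except ValueError:
        tr, val = train_test_split(idx, test_size=0.25,
                                   random_state=seed % (2 ** 31))
    return [(tr, val)]


def ba_optimize(
    table: FeatureTable,
    config: BAConfig | None = None,
    space: SpecSearchSpace | None = None,
    train_idx: np.ndarray | None = None,
) -> BAResult:
    """Search network specs with the bees algorithm.

    Fitness of a spec is its mean validation accuracy over stratified
    folds of the training portion; the winning spec is retrained on the
    full training portion and returned with it. Specs whose training
    fails are scored 0.
    """
    config = config or BAConfig()
    space = space or SpecSearchSpace()
    rng = np.random.default_rng(config.seed)
    if train_idx is None:
        train_idx = np.arange(table.n_samples)
    X = table.values[train_idx]
    y = table.labels[train_idx]
    folds = _inner_folds(y, config.cv_folds, config.seed)
    failures = 0

    def score(spec: MLPSpec) -> float:
        nonlocal failures
        try:
            accs = []
            for tr, val in folds:
                model = fit_mlp(X[tr], y[tr], spec, config.seed)
                accs.append(float(np.mean(model.predict(X[val]) == y[val])))
            return 100.0 * float(np.mean(accs))
        except Exception:
            failures += 1
            return 0.0

    sites = [(score(sp), sp) for sp in (space.sample(rng) for _ in range(config.n_scouts))]
    sites.sort(key=lambda t: -t[0])
    best_fit, best_spec = sites[0]
    trace = [best_fit]
    radius = float(config.neighborhood)
    for _ in range(config.iterations):
        new_sites = []
        for rank, (fit, spec) in enumerate(sites[:config.n_sites]):
            n_rec = config.recruits_elite if rank < config.n_elite else config.recruits_other
            local_best = (fit, spec)
            for _ in range(n_rec):
                cand = space.perturb(spec, rng, radius, config.swap_prob)
                f = score(cand)
                if f > local_best[0]:
                    local_best = (f, cand)
            new_sites.append(local_best)
        for _ in range(config.n_scouts - config.n_sites):
            sp = space.sample(rng)
            new_sites.append((score(sp), sp))
        sites = sorted(new_sites, key=lambda t: -t[0])
        if sites[0][0] > best_fit:
            best_fit, best_spec = sites[0]
        trace.append(best_fit)
        radius = max(1.0, radius * config.shrink)
    model = fit_mlp(X, y, best_spec, config.seed)
    model.meta["train_idx"] = np.asarray(train_idx).tolist()
    return BAResult(best_spec, model, trace, failures)


@dataclass
class KNNModel:
    """Normalized training set plus the vote/tie policy."""

    X: np.ndarray
    y: np.ndarray
    k: int = 5
    mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    std: np.ndarray = field(default=None)   # type: ignore[assignment]
    classes: tuple[int, ...] = (1, 2, 3)

    @classmethod
    def fit(cls, table: FeatureTable, k: int = 5,
            train_idx: np.ndarray | None = None) -> "KNNModel":
        if k < 1:
            raise ValueError("k must be >= 1")
        if train_idx is None:
            train_idx = np.arange(table.n_samples)
        X = table.values[train_idx]
        if k > len(X):
            raise ValueError("k exceeds training size")
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std <= 0] = 1.0
        return cls((X - mean) / std, table.labels[train_idx], k, mean, std)

    def _neighbors(self, X: np.ndarray):
        Xn = (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.std
        nn = NearestNeighbors(n_neighbors=self.k).fit(self.X)
        dist, idx = nn.kneighbors(Xn)
        return dist, idx

    def predict(self, X: np.ndarray) -> np.ndarray:
        dist, idx = self._neighbors(X)
        out = np.empty(len(idx), dtype=int)
        for n, (d, nb) in enumerate(zip(dist, idx)):
            labels = self.y[nb]
            votes = {c: int(np.sum(labels == c)) for c in self.classes}
            top = max(votes.values())
            tied = [c for c in self.classes if votes[c] == top]
            if len(tied) > 1:
                means = {c: float(d[labels == c].mean()) for c in tied}
                lo = min(means.values())
                tied = [c for c in tied if means[c] == lo]
            out[n] = min(tied)
        return out

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Vote fractions per class — the KNN analogue of soft scores."""
        _, idx = self._neighbors(X)
        s = np.zeros((len(idx), len(self.classes)))
        for n, nb in enumerate(idx):
            labels = self.y[nb]
            for k, c in enumerate(self.classes):
                s[n, k] = np.mean(labels == c)
        return s


def knn_classify(train: FeatureTable, test_vec: np.ndarray, k: int = 5) -> int:
    """Label of one test vector under the k-nearest-neighbor rule."""
    model = KNNModel.fit(train, k=k)
    return int(model.predict(np.atleast_2d(test_vec))[0])
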