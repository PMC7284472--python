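"""Wrapper feature selection by particle swarm optimization.

Each particle is a continuous position vector in [0, 1]^n_features. A
position decodes to a feature subset either by thresholding (> 0.5 keeps
the feature; subsets of varying size emerge from the search) or, when a
fixed cardinality is configured, by taking the top-k positions. Subset
quality is the validation accuracy of a small MLP (one hidden layer of
10 neurons, Levenberg–Marquardt training, 3 outputs) trained on a
stratified 70/15/15 train/validation/test split, optionally minus a
parsimony penalty proportional to subset size.

The swarm follows the standard global-best update with velocity clamping
(VelMax = 0.1 x range) and inertia damping; the whole search is
reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from .mlp import MLPSpec, fit_mlp
from .tables import FeatureTable

FITNESS_MLP = MLPSpec(hidden_sizes=(10,), transfers=("tansig",),
                      training="levenberg_marquardt", epochs=30)


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 30
    max_iterations: int = 20
    inertia_weight: float = 1.0
    inertia_damping: float = 1.0
    c1: float = 2.0
    c2: float = 2.0
    var_min: float = 0.0
    var_max: float = 1.0
    decode_threshold: float = 0.5
    subset_size: int | None = None      # fixed cardinality when set
    parsimony_weight: float = 0.0       # accuracy points per selected feature
    mlp_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not np.isfinite([self.var_min, self.var_max]).all() or self.var_max <= self.var_min:
            raise ValueError("invalid variable bounds")

    @property
    def vel_max(self) -> float:
        return 0.1 * (self.var_max - self.var_min)


def reproduction_preset(seed: int = 0) -> PSOConfig:
    """The reproduction preset: fixed 6-feature subsets, full swarm."""
    return PSOConfig(subset_size=6, seed=seed)


@dataclass
class SelectionResult:
    selected_indices: list[int]
    selected_names: list[str]
    best_fitness: float
    trace: list[float]                  # best-so-far per iteration
    split: str = "70/15/15 stratified"


def decode_subset(position: np.ndarray, threshold: float = 0.5,
                  subset_size: int | None = None) -> list[int]:
    """Feature indices encoded by a particle position.

    Thresholding with a non-empty guarantee (the argmax index when no
    coordinate clears the threshold), or the top-k positions when a
    fixed subset size is requested.
    """
    position = np.asarray(position, dtype=float)
    if subset_size is not None:
        k = min(subset_size, position.size)
        top = np.argsort(-position, kind="stable")[:k]
        return sorted(int(i) for i in top)
    idx = np.nonzero(position > threshold)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmax(position))])
    return [int(i) for i in idx]


def _split_701515(table: FeatureTable, seed: int):
    # stratified where sample counts allow it; plain random otherwise
    idx = np.arange(table.n_samples)
    try:
        train_idx, rest = train_test_split(idx, test_size=0.3,
                                           random_state=seed % (2 ** 31),
                                           stratify=table.labels)
    except ValueError:
        train_idx, rest = train_test_split(idx, test_size=0.3,
                                           random_state=seed % (2 ** 31))
    try:
        val_idx, test_idx = train_test_split(rest, test_size=0.5,
                                             random_state=(seed + 1) % (2 ** 31),
                                             stratify=table.labels[rest])
    except ValueError:
        val_idx, test_idx = train_test_split(rest, test_size=0.5,
                                             random_state=(seed + 1) % (2 ** 31))
    return train_idx, val_idx, test_idx


def fitness(subset: list[int], table: FeatureTable, seed: int,
            mlp_epochs: int = 30) -> float:
    """Validation accuracy (percent) of the wrapper MLP on one subset."""
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    train_idx, val_idx, _ = _split_701515(table, seed)
    y_tr = table.labels[train_idx]
    if len(np.unique(y_tr)) < len(np.unique(table.labels)):
        raise ValueError("a class is missing from the training stratum")
    X = table.values[:, subset]
    spec = replace(FITNESS_MLP, epochs=mlp_epochs)
    model = fit_mlp(X[train_idx], y_tr, spec, seed)
    pred = model.predict(X[val_idx])
    return 100.0 * float(np.mean(pred == table.labels[val_idx]))


def pso_select(table: FeatureTable, config: PSOConfig | None = None) -> SelectionResult:
    """Global-best PSO over feature-subset encodings."""
    config = config or PSOConfig()
    rng = np.random.default_rng(config.seed)
    n = table.n_features
    lo, hi = config.var_min, config.var_max
    vmax = config.vel_max
    pos = rng.uniform(lo, hi, size=(config.swarm_size, n))
    vel = rng.uniform(-vmax, vmax, size=(config.swarm_size, n))

    def evaluate(p: np.ndarray) -> tuple[float, list[int]]:
        subset = decode_subset(p, config.decode_threshold, config.subset_size)
        acc = fitness(subset, table, config.seed, config.mlp_epochs)
        return acc - config.parsimony_weight * len(subset), subset

    pbest = pos.copy()
    pbest_fit = np.empty(config.swarm_size)
    subsets = []
    for i in range(config.swarm_size):
        pbest_fit[i], sub = evaluate(pos[i])
        subsets.append(sub)
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit, gbest_subset = pbest[g].copy(), float(pbest_fit[g]), subsets[g]

    w = config.inertia_weight
    trace = [gbest_fit]
    for _ in range(config.max_iterations):
        r1 = rng.uniform(size=(config.swarm_size, n))
        r2 = rng.uniform(size=(config.swarm_size, n))
        vel = (w * vel + config.c1 * r1 * (pbest - pos)
               + config.c2 * r2 * (gbest[None, :] - pos))
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(config.swarm_size):
            fit, sub = evaluate(pos[i])
            if fit > pbest_fit[i]:
                pbest_fit[i] = fit
                pbest[i] = pos[i]
            if fit > gbest_fit:
                gbest_fit, gbest, gbest_subset = float(fit), pos[i].copy(), sub
        w *= config.inertia_damping
        trace.append(gbest_fit)
    names = [table.feature_names[k] for k in gbest_subset]
    return SelectionResult(list(gbest_subset), names, gbest_fit, trace)
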