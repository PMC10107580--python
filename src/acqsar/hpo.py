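"""Hyperparameter optimisation over predefined grids.

Two strategies are provided, both confined to the declared grid:

* ``random`` — uniformly random sampling of grid points (used for the
  forest and nearest-neighbour regressors);
* ``tpe`` — a categorical tree-structured Parzen estimator: past trials are
  split into a good and a bad fraction by objective value, per-parameter
  categorical densities l(x) and g(x) are estimated with add-one smoothing,
  and the candidate maximising the likelihood ratio l(x)/g(x) among draws
  from l is evaluated next (used for the neural models).

The objective is always an inner-validation error computed on a split of
the training data only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

GRID_VERSION = 1

#: Default hyperparameter grids. These are this package's experiment
#: configuration, declared here so runs are reproducible and auditable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "rf": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10, 20],
        "max_features": ["sqrt", 0.5],
    },
    "knn": {
        "n_neighbors": [1, 3, 5, 10, 25],
        "weights": ["uniform", "distance"],
    },
    "mlp": {
        "hidden": [(256, 128), (128, 64), (64,)],
        "batch_size": [32, 64, 128],
        "lr": [1e-2, 3e-3, 1e-3],
        "lr_decay": [1.0, 0.995],
        "weight_decay": [0.0, 1e-4, 1e-2],
        "dropout": [0.0, 0.1, 0.25],
    },
}


@dataclass
class HPOTrial:
    params: dict[str, Any]
    objective: float


@dataclass
class HPOPlan:
    """Search space + budget for one inner hyperparameter-optimisation loop."""

    search_space: dict[str, list]
    n_trials: int = 8
    strategy: str = "random"
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.strategy not in ("random", "tpe"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not self.search_space or any(not v for v in self.search_space.values()):
            raise ValueError("search space must declare at least one value per parameter")


def default_plan(regressor: str, n_trials: int = 8) -> HPOPlan:
    """The shipped default plan: random search for rf/knn, TPE for mlp."""
    grid = {k: list(v) for k, v in DEFAULT_GRIDS[regressor].items()}
    strategy = "tpe" if regressor == "mlp" else "random"
    return HPOPlan(search_space=grid, n_trials=n_trials, strategy=strategy)


def _sample_uniform(space: dict[str, list], rng: np.random.Generator) -> dict[str, Any]:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def _tpe_propose(
    space: dict[str, list],
    trials: list[HPOTrial],
    rng: np.random.Generator,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict[str, Any]:
    n_good = max(1, math.ceil(gamma * len(trials)))
    ranked = sorted(trials, key=lambda t: t.objective)
    good, bad = ranked[:n_good], ranked[n_good:] or ranked[n_good - 1 :]

    def density(subset: list[HPOTrial], key: str) -> np.ndarray:
        values = space[key]
        counts = np.ones(len(values))  # add-one smoothing
        for t in subset:
            counts[values.index(t.params[key])] += 1
        return counts / counts.sum()

    l_dens = {k: density(good, k) for k in space}
    g_dens = {k: density(bad, k) for k in space}

    best_params, best_score = None, -np.inf
    for _ in range(n_candidates):
        cand = {k: v[rng.choice(len(v), p=l_dens[k])] for k, v in space.items()}
        score = sum(
            math.log(l_dens[k][space[k].index(cand[k])]) - math.log(g_dens[k][space[k].index(cand[k])])
            for k in space
        )
        if score > best_score:
            best_params, best_score = cand, score
    return best_params


def run_hpo(
    objective: Callable[[dict[str, Any]], float],
    plan: HPOPlan,
    rng: np.random.Generator,
) -> tuple[dict[str, Any], list[HPOTrial]]:
    """Minimise ``objective`` over the grid; returns (best params, all trials)."""
    trials: list[HPOTrial] = []
    n_startup = max(2, plan.n_trials // 4) if plan.strategy == "tpe" else plan.n_trials
    for i in range(plan.n_trials):
        if plan.strategy == "tpe" and i >= n_startup:
            params = _tpe_propose(plan.search_space, trials, rng)
        else:
            params = _sample_uniform(plan.search_space, rng)
        trials.append(HPOTrial(params=params, objective=float(objective(params))))
    best = min(trials, key=lambda t: t.objective)
    return dict(best.params), trials


def inner_split(
    n: int, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One seeded random train/validation index split of the training set."""
    if n < 2:
        raise ValueError("need at least two training points for an inner split")
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    n_val = min(n_val, n - 1)
    return np.sort(order[n_val:]), np.sort(order[:n_val])
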