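"""Brassy Pelican Optimization: a bounded population optimizer plus a
binary adapter for wrapper feature selection.

The optimizer alternates two phases per iteration.  Exploration moves each
member toward (or away from) a randomly placed prey depending on which has
the better objective; exploitation perturbs each member within a
neighbourhood whose radius shrinks linearly to zero over the iteration
budget.  Both phases use greedy acceptance, so the best objective in the
trace is non-increasing by construction.  Minimization convention
throughout; accuracy-maximizing fitness is wrapped as 1 - accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .preprocess import FeatureTable, SplitSpec, kfold_indices
from .rng import as_generator

# fitness sentinel for rejected (all-zero) feature masks; any real
# 1 - accuracy value lies in [0, 1]
WORST_FITNESS = 2.0


class OptimizationError(ValueError):
    pass


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lower", np.atleast_1d(np.asarray(self.lower, dtype=float)))
        object.__setattr__(self, "upper", np.atleast_1d(np.asarray(self.upper, dtype=float)))
        if self.lower.shape != self.upper.shape:
            raise OptimizationError("lower and upper must have the same shape")
        if not (self.upper > self.lower).all():
            raise OptimizationError("every upper bound must exceed its lower bound")

    @property
    def n(self) -> int:
        return self.lower.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def uniform(self, rng, size=None) -> np.ndarray:
        shape = (self.n,) if size is None else (size, self.n)
        return self.lower + rng.random(shape) * (self.upper - self.lower)


@dataclass
class PelicanPopulation:
    positions: np.ndarray  # G, (m, n)
    objectives: np.ndarray  # Z, (m,)
    bounds: Bounds
    best_position: np.ndarray
    best_objective: float
    itr: int = 0
    max_itr: int = 0
    C: float = 0.2


def _evaluate(objective, x) -> float:
    z = float(objective(np.asarray(x, dtype=float)))
    if not np.isfinite(z):
        raise OptimizationError(f"objective returned non-finite value at {x!r}")
    return z


def init_population(objective, bounds: Bounds, m: int, seed) -> PelicanPopulation:
    """Uniform initial members g_ij = L_j + f * (U_j - L_j), objectives evaluated."""
    if m < 2:
        raise OptimizationError("population size must be >= 2")
    rng = as_generator(seed)
    positions = bounds.uniform(rng, size=m)
    objectives = np.array([_evaluate(objective, g) for g in positions])
    ibest = int(np.argmin(objectives))
    return PelicanPopulation(
        positions=positions,
        objectives=objectives,
        bounds=bounds,
        best_position=positions[ibest].copy(),
        best_objective=float(objectives[ibest]),
    )


def exploration_step(g, prey, prey_objective, own_objective, f, s):
    """Move toward the prey when it is better, away from it otherwise.

    Returns g + f * (prey - s * g) if the prey's objective is smaller,
    else g + f * (g - prey).  Coordinate-wise; the caller clips to bounds.
    """
    g = np.asarray(g, dtype=float)
    prey = np.asarray(prey, dtype=float)
    if prey_objective < own_objective:
        return g + f * (prey - s * g)
    return g + f * (g - prey)


def exploitation_step(g, C, itr, max_itr, f):
    """Local scan g + C * (1 - itr/max_itr) * (2f - 1) * g; radius shrinks to 0."""
    g = np.asarray(g, dtype=float)
    radius = 1.0 - (itr / max_itr if max_itr > 0 else 1.0)
    return g + C * radius * (2.0 * np.asarray(f) - 1.0) * g


def greedy_select(current_position, current_objective, candidate_position, candidate_objective):
    """Keep the candidate only on strict improvement; ties keep the incumbent.

    A NaN candidate objective is rejected with a warning.
    """
    if np.isnan(candidate_objective):
        warnings.warn("candidate objective is NaN; keeping incumbent", stacklevel=2)
        return current_position, current_objective
    if candidate_objective < current_objective:
        return candidate_position, candidate_objective
    return current_position, current_objective


def bpo_optimize(objective, bounds: Bounds, m: int = 40, max_itr: int = 150,
                 C: float = 0.2, seed=0):
    """Run the full optimizer; returns (best_position, best_objective, trace).

    ``trace[k]`` is the best objective after k iterations (``trace[0]`` is
    the initial population's best), hence non-increasing.
    """
    rng = as_generator(seed)
    pop = init_population(objective, bounds, m, rng)
    pop.max_itr = max_itr
    pop.C = C
    trace = [pop.best_objective]
    n = bounds.n
    for itr in range(1, max_itr + 1):
        pop.itr = itr
        prey = bounds.uniform(rng)
        prey_obj = _evaluate(objective, prey)
        for i in range(m):
            # exploration toward / away from the prey
            f = rng.random(n)
            s = rng.random(n)
            cand = bounds.clip(
                exploration_step(pop.positions[i], prey, prey_obj, pop.objectives[i], f, s)
            )
            cand_obj = _evaluate(objective, cand)
            pop.positions[i], pop.objectives[i] = greedy_select(
                pop.positions[i], pop.objectives[i], cand, cand_obj
            )
            # exploitation: shrinking local neighbourhood
            f2 = rng.random(n)
            cand2 = bounds.clip(exploitation_step(pop.positions[i], C, itr, max_itr, f2))
            cand2_obj = _evaluate(objective, cand2)
            pop.positions[i], pop.objectives[i] = greedy_select(
                pop.positions[i], pop.objectives[i], cand2, cand2_obj
            )
        ibest = int(np.argmin(pop.objectives))
        if pop.objectives[ibest] < pop.best_objective:
            pop.best_objective = float(pop.objectives[ibest])
            pop.best_position = pop.positions[ibest].copy()
        trace.append(pop.best_objective)
    return pop.best_position, pop.best_objective, np.array(trace)


@dataclass
class FeatureMask:
    """Binary include/exclude vector over candidate attributes."""

    bits: np.ndarray
    attribute_names: list
    fitness: float  # 1 - CV accuracy of the selected subset

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.size and not self.bits.any():
            raise OptimizationError("all-zero feature masks are not allowed")

    @property
    def selected_names(self) -> list:
        return [n for n, b in zip(self.attribute_names, self.bits) if b]

    def to_dict(self) -> dict:
        return {
            "attribute_names": list(self.attribute_names),
            "bits": [int(b) for b in self.bits],
            "selected": self.selected_names,
            "fitness": self.fitness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMask":
        return cls(np.array(d["bits"], dtype=bool), d["attribute_names"], d["fitness"])


def make_cv_accuracy_evaluator(table: FeatureTable, k: int = 5, seed: int = 0,
                               classifier: str = "logistic", lstm_kwargs=None):
    """Build mask -> cross-validated accuracy on training folds only.

    ``classifier='logistic'`` is a fast linear surrogate; ``'lstm'`` scores
    subsets with the package's own recurrent classifier at a reduced epoch
    cap.  Folds are fixed once, so the evaluator is a deterministic function
    of the mask.
    """
    folds = kfold_indices(table, SplitSpec(train_fraction=0.8, k_folds=k, seed=seed))
    if classifier == "lstm":
        from . import lstm as lstm_mod

        kwargs = {"max_epochs": 20, "patience": 5, "seed": seed}
        kwargs.update(lstm_kwargs or {})

        def evaluate(mask) -> float:
            sub = table.select_attributes(mask)
            accs = []
            for tr, va in folds:
                params, _ = lstm_mod.train(
                    sub.take_rows(tr), sub.take_rows(va), hyper=None, **kwargs
                )
                labels, _ = lstm_mod.predict(sub.take_rows(va), params)
                accs.append(float((labels == sub.outcome[va]).mean()))
            return float(np.mean(accs))

    elif classifier == "logistic":

        def evaluate(mask) -> float:
            X = table.values[:, np.asarray(mask, dtype=bool)]
            y = table.outcome
            accs = []
            for tr, va in folds:
                clf = LogisticRegression(max_iter=500)
                clf.fit(X[tr], y[tr])
                accs.append(float(clf.score(X[va], y[va])))
            return float(np.mean(accs))

    else:
        raise OptimizationError(f"unknown surrogate classifier {classifier!r}")
    return evaluate


def select_features(table: FeatureTable, fitness_evaluator=None, m: int = 40,
                    max_itr: int = 150, C: float = 0.2, seed=0):
    """Wrapper feature selection over [0, 1]^n_attributes.

    Positions decode to masks by thresholding each coordinate at 0.5; the
    objective is 1 - accuracy, with all-zero masks assigned a worst-case
    sentinel so they can never win.  Mask fitness is memoized (the objective
    depends on the position only through its decoded mask).  Ties on fitness
    break toward fewer selected attributes, then lexicographically.

    Returns (FeatureMask, trace).
    """
    n = table.n_attributes
    if n < 2:
        warnings.warn("fewer than 2 attributes: returning the all-ones mask", stacklevel=2)
        mask = np.ones(n, dtype=bool)
        fit = fitness_evaluator(mask) if fitness_evaluator else None
        return FeatureMask(mask, table.attribute_names,
                           1.0 - fit if fit is not None else 0.0), np.array([])
    if fitness_evaluator is None:
        fitness_evaluator = make_cv_accuracy_evaluator(table, seed=int(as_generator(seed).integers(2**31)))

    cache: dict = {}

    def objective(position) -> float:
        bits = tuple(position >= 0.5)
        if bits not in cache:
            if not any(bits):
                cache[bits] = WORST_FITNESS
            else:
                cache[bits] = 1.0 - fitness_evaluator(np.array(bits, dtype=bool))
        return cache[bits]

    bounds = Bounds(np.zeros(n), np.ones(n))
    _, _, trace = bpo_optimize(objective, bounds, m=m, max_itr=max_itr, C=C, seed=seed)
    # best decoded mask among everything evaluated; fewer features win ties
    best_bits = min(
        (b for b in cache if any(b)),
        key=lambda b: (cache[b], sum(b), b),
    )
    mask = FeatureMask(np.array(best_bits, dtype=bool), table.attribute_names,
                       float(cache[best_bits]))
    return mask, trace
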