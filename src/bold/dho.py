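"""Deer Hunting Optimization and LSTM hyperparameter tuning.

A herd of hunters tracks a leader (best position so far) and a successor
(second best).  Each iteration refreshes a wind angle theta = 2*pi*delta,
a position angle, and two coefficient vectors

    C1 = (1/4) * ln(j + 1/m_itr) * h,   h ~ U(-1, 1)
    C2 = 2 * c,                         c ~ U(0, 1)

and each member then moves by one of three rules chosen uniformly at
random — encircling the leader, steering by the position angle, or
exploring around the successor — with greedy acceptance, so the best
objective never worsens.  The tuner runs this optimizer over the unit
4-cube, decoding positions into (learning rate, batch size, units,
dropout) and scoring each configuration by validation RMSE of an LSTM
trained under a reduced epoch cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bpo import Bounds, OptimizationError, WORST_FITNESS, greedy_select
from .lstm import LSTMError, LSTMHyper, forward, train
from .metrics import rmse
from .preprocess import FeatureTable, SplitSpec, stratified_split
from .rng import as_generator

MODES = ("encircle", "angle", "successor")


@dataclass
class DeerHerd:
    positions: np.ndarray  # K, (n, dim)
    objectives: np.ndarray  # (n,)
    bounds: Bounds
    leader: np.ndarray  # K_L
    leader_objective: float
    successor: np.ndarray  # K_s
    successor_objective: float
    theta: float = 0.0  # wind angle
    iteration: int = 0
    m_itr: int = 0


def _evaluate(objective, x) -> float:
    z = float(objective(np.asarray(x, dtype=float)))
    if not np.isfinite(z):
        raise OptimizationError(f"objective returned non-finite value at {x!r}")
    return z


def _refresh_leaders(herd: DeerHerd) -> None:
    order = np.argsort(herd.objectives, kind="stable")
    herd.leader = herd.positions[order[0]].copy()
    herd.leader_objective = float(herd.objectives[order[0]])
    herd.successor = herd.positions[order[1]].copy()
    herd.successor_objective = float(herd.objectives[order[1]])


def init_herd(objective, bounds: Bounds, n: int, seed) -> DeerHerd:
    """Uniform random herd; leader and successor ranked by objective."""
    if n < 3:
        raise OptimizationError("herd size must be >= 3 (leader, successor, follower)")
    rng = as_generator(seed)
    positions = bounds.uniform(rng, size=n)
    objectives = np.array([_evaluate(objective, k) for k in positions])
    herd = DeerHerd(
        positions=positions,
        objectives=objectives,
        bounds=bounds,
        leader=positions[0].copy(),
        leader_objective=float("inf"),
        successor=positions[0].copy(),
        successor_objective=float("inf"),
    )
    _refresh_leaders(herd)
    return herd


def wind_angle(delta: float) -> float:
    """theta = 2*pi*delta for delta in [0, 1]."""
    if not 0.0 <= delta <= 1.0:
        raise OptimizationError("delta must lie in [0, 1]")
    return 2.0 * np.pi * delta


def coefficients(j: int, m_itr: int, h: float, c: float) -> tuple:
    """C1 = (1/4) ln(j + 1/m_itr) h  (natural log),  C2 = 2c."""
    if not 1 <= j <= m_itr:
        raise OptimizationError("iteration j must satisfy 1 <= j <= m_itr")
    c1 = 0.25 * np.log(j + 1.0 / m_itr) * h
    c2 = 2.0 * c
    return float(c1), float(c2)


def position_update(k_j, k_leader, k_successor, mode: str, *, beta=1.0, tau=1.0,
                    c1=1.0, c2=1.0, vartheta=0.0):
    """Candidate position under one of the three movement rules.

    encircle:  K_L - C2 * beta * |C1 * K_L - K_j|
    angle:     K_L - tau * |cos(vartheta)| * (K_L - K_j)
    successor: K_s - C2 * tau * |C1 * K_s - K_j|

    Coordinate-wise; the caller clips to bounds and applies greedy
    acceptance.
    """
    k_j = np.asarray(k_j, dtype=float)
    k_leader = np.asarray(k_leader, dtype=float)
    k_successor = np.asarray(k_successor, dtype=float)
    if mode == "encircle":
        return k_leader - c2 * beta * np.abs(c1 * k_leader - k_j)
    if mode == "angle":
        return k_leader - tau * np.abs(np.cos(vartheta)) * (k_leader - k_j)
    if mode == "successor":
        return k_successor - c2 * tau * np.abs(c1 * k_successor - k_j)
    raise OptimizationError(f"unknown mode {mode!r}")


def dho_optimize(objective, bounds: Bounds, n: int = 30, m_itr: int = 50, seed=0):
    """Run the optimizer; returns (best_position, best_objective, trace).

    ``trace[0]`` is the initial herd's best; greedy per-member acceptance
    keeps the trace non-increasing.
    """
    rng = as_generator(seed)
    herd = init_herd(objective, bounds, n, rng)
    herd.m_itr = m_itr
    trace = [herd.leader_objective]
    for j in range(1, m_itr + 1):
        herd.iteration = j
        herd.theta = wind_angle(rng.random())
        visual = rng.uniform(0.0, np.pi / 8.0)
        vartheta = herd.theta - visual  # position angle: wind minus visual angle
        c1, c2 = coefficients(j, m_itr, h=rng.uniform(-1.0, 1.0), c=rng.random())
        for i in range(n):
            mode = MODES[rng.integers(3)]
            # beta and tau are drawn per coordinate: the update rules act
            # coordinate-wise and the random coefficients are vectors
            beta = rng.uniform(0.0, 2.0, size=bounds.n)
            tau = rng.random(size=bounds.n)
            cand = bounds.clip(
                position_update(
                    herd.positions[i], herd.leader, herd.successor, mode,
                    beta=beta, tau=tau, c1=c1, c2=c2, vartheta=vartheta,
                )
            )
            cand_obj = _evaluate(objective, cand)
            herd.positions[i], herd.objectives[i] = greedy_select(
                herd.positions[i], herd.objectives[i], cand, cand_obj
            )
        _refresh_leaders(herd)
        trace.append(herd.leader_objective)
    return herd.leader, herd.leader_objective, np.array(trace)


@dataclass(frozen=True)
class HyperparameterSpace:
    """The stated search box for the LSTM hyperparameters."""

    lr_range: tuple = (1e-5, 1e-2)  # log scale
    batch_range: tuple = (16, 128)  # integer
    units_range: tuple = (32, 256)  # integer
    dropout_range: tuple = (0.1, 0.5)


def decode_hyperparameters(position, space: HyperparameterSpace | None = None) -> LSTMHyper:
    """Map a point in [0, 1]^4 onto the concrete hyperparameter box.

    Learning rate decodes on a log scale; batch size and unit count round
    to the nearest integer.
    """
    space = space or HyperparameterSpace()
    p = np.asarray(position, dtype=float)
    if p.shape != (4,) or ((p < 0) | (p > 1)).any():
        raise OptimizationError("position must be 4 coordinates in [0, 1]")
    lo, hi = np.log10(space.lr_range[0]), np.log10(space.lr_range[1])
    lr = 10.0 ** (lo + (hi - lo) * p[0])
    batch = int(round(space.batch_range[0] + (space.batch_range[1] - space.batch_range[0]) * p[1]))
    units = int(round(space.units_range[0] + (space.units_range[1] - space.units_range[0]) * p[2]))
    dropout = space.dropout_range[0] + (space.dropout_range[1] - space.dropout_range[0]) * p[3]
    return LSTMHyper(lr=float(lr), batch_size=batch, units=units, dropout=float(dropout))


def make_rmse_objective(train_table: FeatureTable, mask=None, val_fraction: float = 0.15,
                        fitness_epochs: int = 50, patience: int = 10, seed=0,
                        space: HyperparameterSpace | None = None):
    """Position -> validation RMSE of an LSTM trained at the decoded config.

    Carves a stratified validation set out of the training table once, so
    the objective is a deterministic function of the position.  A training
    divergence assigns the worst-case sentinel instead of propagating.
    """
    table = train_table if mask is None else train_table.select_attributes(mask)
    fit_part, val_part = stratified_split(
        table, SplitSpec(train_fraction=1.0 - val_fraction, k_folds=2, seed=int(as_generator(seed).integers(2**31)))
    )
    train_seed = int(as_generator(seed).integers(2**31, size=2)[1])

    def objective(position) -> float:
        hyper = decode_hyperparameters(position, space)
        try:
            params, _ = train(
                fit_part, val_part, hyper,
                max_epochs=fitness_epochs, patience=patience, seed=train_seed,
            )
        except LSTMError as exc:
            warnings.warn(f"training diverged for {hyper}: {exc}", stacklevel=2)
            return WORST_FITNESS
        return rmse(forward(val_part.values, params), val_part.outcome)

    return objective


def tune_hyperparameters(train_table: FeatureTable, mask=None, n: int = 30,
                         m_itr: int = 50, seed=0, fitness_epochs: int = 50,
                         val_fraction: float = 0.15,
                         space: HyperparameterSpace | None = None):
    """Search the hyperparameter box for the lowest validation RMSE.

    Returns (best LSTMHyper, trace of best RMSE per iteration).  With
    ``m_itr=0`` this degenerates to the best of ``n`` random
    configurations.  The caller refits at the full epoch budget.
    """
    objective = make_rmse_objective(
        train_table, mask=mask, val_fraction=val_fraction,
        fitness_epochs=fitness_epochs, seed=seed, space=space,
    )
    bounds = Bounds(np.zeros(4), np.ones(4))
    best_pos, _, trace = dho_optimize(objective, bounds, n=n, m_itr=m_itr, seed=seed)
    return decode_hyperparameters(best_pos, space), trace
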