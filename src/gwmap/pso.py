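"""Particle swarm optimization and the PSO-then-LM network trainer.

The swarm searches the flattened weight/bias space of the tansig network for
a good global starting point; Levenberg–Marquardt then refines the global
best.  Canonical velocity update with Clerc–Kennedy constriction-equivalent
coefficients (w = 0.729, c1 = c2 = 1.49445).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DataPartition, MLPModel, TrainReport, init_model, train_lm


@dataclass
class PSOConfig:
    """Swarm hyperparameters; defaults are the standard constriction values."""

    n_particles: int = 10
    n_iterations: int = 2000
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    bound: float = 2.0            # positions confined to [-B, B]^dim
    velocity_clamp_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_particles < 1 or self.n_iterations < 0:
            raise ValueError("need >= 1 particle and >= 0 iterations")
        if not np.isfinite(self.bound) or self.bound <= 0:
            raise ValueError("position bound must be finite and positive")


def pso_minimize(f, dim: int, cfg: PSOConfig):
    """Minimise ``f`` over the box [-B, B]^dim with a canonical PSO.

    Returns ``(best_position, best_value, trace)`` where trace is the
    monotone nonincreasing global-best value per iteration.  A single
    particle degenerates to pbest = gbest and still works.  Deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    B = cfg.bound
    vmax = cfg.velocity_clamp_frac * B

    def evaluate(x):
        v = float(f(x))
        return v

    X = rng.uniform(-B, B, size=(cfg.n_particles, dim))
    vals = np.array([evaluate(x) for x in X])
    for _ in range(100):
        bad = ~np.isfinite(vals)
        if not bad.any():
            break
        X[bad] = rng.uniform(-B, B, size=(bad.sum(), dim))
        vals[bad] = [evaluate(x) for x in X[bad]]
    else:
        raise RuntimeError("objective non-finite after 100 resampling rounds")

    V = np.zeros_like(X)
    pbest = X.copy()
    pbest_val = vals.copy()
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    trace = []
    for _ in range(cfg.n_iterations):
        r1 = rng.random((cfg.n_particles, dim))
        r2 = rng.random((cfg.n_particles, dim))
        V = (cfg.inertia * V
             + cfg.cognitive * r1 * (pbest - X)
             + cfg.social * r2 * (gbest - X))
        np.clip(V, -vmax, vmax, out=V)
        X = np.clip(X + V, -B, B)
        vals = np.array([evaluate(x) for x in X])
        improved = vals < pbest_val
        pbest[improved] = X[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        trace.append(gbest_val)
    return gbest, gbest_val, np.array(trace)


def train_nn_pso(n_hidden: int, X, y, part: DataPartition, cfg: PSOConfig,
                 lm_kwargs: dict | None = None,
                 ) -> tuple[MLPModel, TrainReport]:
    """PSO global weight search followed by Levenberg–Marquardt refinement.

    The particle is the flattened (W1, b1, W2, b2) vector; fitness is the
    training-partition MSE in scaled units.  With ``cfg.n_iterations = 0``
    this reduces to LM from a random initialisation.  The returned training
    MSE is never worse than the swarm's best (LM only accepts improving
    steps and early-stops on the best-validation weights, whose training MSE
    is reported from the final refit).
    """
    from .nn import _residuals_and_jacobian

    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    model = init_model(X, y, n_hidden, seed=cfg.seed)
    Xs = model.scale_x(X)
    t = model.scale_y(y)
    tr = part.train

    def fitness(theta):
        model.set_params(theta)
        r, _ = _residuals_and_jacobian(model, Xs[tr], t[tr], need_jac=False)
        return float(r @ r) / len(tr)

    if cfg.n_iterations > 0:
        gbest, _, _ = pso_minimize(fitness, model.n_params, cfg)
        model.set_params(gbest)
    return train_lm(model, X, y, part, **(lm_kwargs or {}))
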