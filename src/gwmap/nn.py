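"""Single-hidden-layer tansig network with Levenberg–Marquardt training.

The surrogate model of the hybrid pipeline: a feedforward net
``y = unscale(tanh(W2 tanh(W1 scale(x) + b1) + b2))`` trained by damped
Gauss–Newton (Levenberg–Marquardt) on a 70/15/15 train/validation/test
split, with early stopping when validation error stops improving.  Inputs
are min-max scaled to [-1, 1]; targets to [-0.9, 0.9] so extreme training
targets stay inside the output tansig's range.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DataPartition:
    """Disjoint, exhaustive train/validation/test index sets."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int


def partition_data(n: int, seed: int, fractions=(0.70, 0.15, 0.15)) -> DataPartition:
    """Seeded 70/15/15 split: val and test get floor(0.15 n), rest trains."""
    if n < 7:
        raise ValueError("need at least 7 samples to partition 70/15/15")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    perm = np.random.default_rng(seed).permutation(n)
    return DataPartition(
        train=np.sort(perm[n_val + n_test:]),
        validation=np.sort(perm[:n_val]),
        test=np.sort(perm[n_val:n_val + n_test]),
        seed=seed,
    )


@dataclass
class MLPModel:
    """Weights, biases and the min-max scaling that brackets them."""

    W1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (1, n_hidden)
    b2: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    y_margin: float = 0.9

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    # -- scaling -----------------------------------------------------------
    def scale_x(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.x_max > self.x_min, self.x_max - self.x_min, 1.0)
        return -1.0 + 2.0 * (X - self.x_min) / span

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min if self.y_max > self.y_min else 1.0
        return self.y_margin * (-1.0 + 2.0 * (y - self.y_min) / span)

    def unscale_y(self, t: np.ndarray) -> np.ndarray:
        span = self.y_max - self.y_min if self.y_max > self.y_min else 1.0
        return self.y_min + (t / self.y_margin + 1.0) * span / 2.0

    # -- evaluation --------------------------------------------------------
    def forward_scaled(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scale_x(np.atleast_2d(X))
        if Xs.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} inputs, got {Xs.shape[1]}")
        H = np.tanh(Xs @ self.W1.T + self.b1)
        return np.tanh(H @ self.W2.T + self.b2).ravel()

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Predict in original target units."""
        return self.unscale_y(self.forward_scaled(X))

    # -- flat parameter vector (shared with the PSO) -----------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1,
                               self.W2.ravel(), [self.b2]])

    def set_params(self, theta: np.ndarray) -> "MLPModel":
        nh, ni = self.W1.shape
        k = 0
        self.W1 = theta[k:k + nh * ni].reshape(nh, ni); k += nh * ni
        self.b1 = theta[k:k + nh].copy(); k += nh
        self.W2 = theta[k:k + nh].reshape(1, nh); k += nh
        self.b2 = float(theta[k])
        return self

    @property
    def n_params(self) -> int:
        nh, ni = self.W1.shape
        return nh * ni + nh + nh + 1

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2,
            "x_min": self.x_min.tolist(), "x_max": self.x_max.tolist(),
            "y_min": self.y_min, "y_max": self.y_max, "y_margin": self.y_margin,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path) as fh:
            o = json.load(fh)
        return cls(np.array(o["W1"]), np.array(o["b1"]), np.array(o["W2"]),
                   float(o["b2"]), np.array(o["x_min"]), np.array(o["x_max"]),
                   float(o["y_min"]), float(o["y_max"]), float(o["y_margin"]))


def init_model(X: np.ndarray, y: np.ndarray, n_hidden: int,
               seed: int = 0, weight_scale: float = 0.5,
               identity_scaling: bool = False) -> MLPModel:
    """Random small-weight network with scaling fitted to the data."""
    X = np.atleast_2d(X)
    rng = np.random.default_rng(seed)
    ni = X.shape[1]
    if identity_scaling:
        x_min, x_max = -np.ones(ni), np.ones(ni)
        y_min, y_max, margin = -1.0, 1.0, 1.0
    else:
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        y_min, y_max, margin = float(np.min(y)), float(np.max(y)), 0.9
    return MLPModel(
        W1=weight_scale * rng.standard_normal((n_hidden, ni)),
        b1=weight_scale * rng.standard_normal(n_hidden),
        W2=weight_scale * rng.standard_normal((1, n_hidden)),
        b2=float(weight_scale * rng.standard_normal()),
        x_min=np.asarray(x_min, float), x_max=np.asarray(x_max, float),
        y_min=y_min, y_max=y_max, y_margin=margin,
    )


@dataclass
class TrainReport:
    mse: float
    r_validation: float
    r_testing: float
    iterations: int
    elapsed_seconds: float
    history: list = field(default_factory=list, repr=False)


def _residuals_and_jacobian(m: MLPModel, Xs: np.ndarray, t: np.ndarray,
                            need_jac: bool = True):
    """Scaled-space residuals r = yhat - t and their parameter Jacobian.

    Backpropagation through the two tanh layers, vectorised over samples.
    """
    n, ni = Xs.shape
    nh = m.n_hidden
    A1 = Xs @ m.W1.T + m.b1       # (n, nh)
    H = np.tanh(A1)
    A2 = H @ m.W2.T + m.b2        # (n, 1)
    O = np.tanh(A2).ravel()
    r = O - t
    if not need_jac:
        return r, None
    dO = 1.0 - O**2                                    # (n,)
    dH = (1.0 - H**2)                                  # (n, nh)
    g_h = dO[:, None] * m.W2                            # dO/dH, (n, nh)
    g_a1 = g_h * dH                                     # (n, nh)
    J = np.empty((n, m.n_params))
    J[:, :nh * ni] = (g_a1[:, :, None] * Xs[:, None, :]).reshape(n, nh * ni)
    J[:, nh * ni:nh * ni + nh] = g_a1
    J[:, nh * ni + nh:nh * ni + 2 * nh] = dO[:, None] * H
    J[:, -1] = dO
    return r, J


def train_lm(m: MLPModel, X: np.ndarray, y: np.ndarray, part: DataPartition,
             lambda0: float = 1e-3, max_iter: int = 1000,
             max_val_fail: int = 6, grad_tol: float = 1e-7,
             ) -> tuple[MLPModel, TrainReport]:
    """Levenberg–Marquardt on the training split, early-stopped on validation.

    Damping is multiplied by 10 on a rejected step and divided by 10 on an
    accepted one; the returned model carries the weights with the best
    validation MSE seen.  All internal arithmetic is in scaled units.
    """
    from .metrics import pearson_r

    t0 = time.perf_counter()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    Xs = m.scale_x(X)
    t = m.scale_y(y)
    tr, va, te = part.train, part.validation, part.test
    if len(tr) + len(va) + len(te) != len(y):
        raise ValueError("partition inconsistent with data length")

    lam = lambda0
    theta = m.get_params()
    r, J = _residuals_and_jacobian(m, Xs[tr], t[tr])
    sse = float(r @ r)

    def val_mse(model):
        rv, _ = _residuals_and_jacobian(model, Xs[va], t[va], need_jac=False)
        return float(rv @ rv) / max(len(va), 1)

    best_theta = theta.copy()
    best_val = val_mse(m) if len(va) else np.inf
    val_fails = 0
    history = []
    it = 0
    for it in range(1, max_iter + 1):
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        for _ in range(30):
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(len(theta)), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            trial = theta + step
            m.set_params(trial)
            r_new, _ = _residuals_and_jacobian(m, Xs[tr], t[tr], need_jac=False)
            sse_new = float(r_new @ r_new)
            if not np.isfinite(sse_new):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            if sse_new < sse:
                theta, sse = trial, sse_new
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            m.set_params(theta)
            break
        r, J = _residuals_and_jacobian(m, Xs[tr], t[tr])
        history.append(sse / len(tr))

        if len(va):
            v = val_mse(m)
            if v < best_val:
                best_val = v
                best_theta = theta.copy()
                val_fails = 0
            else:
                val_fails += 1
                if val_fails >= max_val_fail:
                    break
        else:
            best_theta = theta.copy()

    m.set_params(best_theta)
    r_tr, _ = _residuals_and_jacobian(m, Xs[tr], t[tr], need_jac=False)
    mse_final = float(r_tr @ r_tr) / len(tr)

    def safe_r(idx):
        if len(idx) < 3:
            return np.nan
        return pearson_r(m.forward(X[idx]), y[idx], strict=False)

    report = TrainReport(
        mse=mse_final,
        r_validation=safe_r(va),
        r_testing=safe_r(te),
        iterations=it,
        elapsed_seconds=time.perf_counter() - t0,
        history=history,
    )
    return m, report
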