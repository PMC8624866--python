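"""NN-PSO informed interpolation: survey densification and method comparison.

The headline method: a PSO-initialised tansig network learns the target
parameter from cheap covariates (location, temperature, pH, EC, TDS) at the
measured wells, predicts it at auxiliary sites where only the covariates
are known, and the interpolator then runs on the densified survey.  Spatial
prediction quality is compared across methods, with and without the network
step, by leave-one-out cross-validation (MAE, then R).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PredictionGrid, SampleSet
from .deterministic import InterpolatorSpec, predict_grid
from .metrics import CVReport, loocv
from .pso import PSOConfig, train_nn_pso


@dataclass
class HybridConfig:
    """Configuration of the network-densification step.

    ``covariates`` may include "x"/"y" (projected coordinates) and any
    parameter column present both at measured stations and auxiliary sites;
    the target must not be among them.  ``aux_sites`` is a DataFrame with
    x, y and the covariate columns (for synthetic surveys the generator
    supplies it; for real use it must be measured in the field).
    ``n_aux`` caps how many auxiliary sites are used (evenly subsampled);
    ``residual_mode`` interpolates network residuals instead of densifying.
    """

    target: str
    covariates: tuple = ("x", "y", "temp", "pH", "EC", "TDS")
    aux_sites: pd.DataFrame | None = None
    n_aux: int = 100
    n_hidden: int = 25
    pso: PSOConfig = field(default_factory=PSOConfig)
    partition_seed: int = 0
    lambda_pseudo: float = 1.0
    lm_kwargs: dict | None = None
    fast: bool = False
    residual_mode: bool = False

    def __post_init__(self):
        if self.target in self.covariates:
            raise ValueError("target parameter cannot be one of its covariates")
        if self.n_aux < 0:
            raise ValueError("n_aux must be nonnegative")
        if not 0 < self.lambda_pseudo <= 1:
            raise ValueError("lambda_pseudo must lie in (0, 1]")


def _design(table, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Covariate matrix and row-completeness mask from a station table."""
    cols = []
    for c in covariates:
        if c not in table.columns:
            raise KeyError(f"covariate {c!r} missing from table")
        cols.append(table[c].to_numpy(dtype=float))
    M = np.column_stack(cols)
    return M, np.isfinite(M).all(axis=1)


def train_surrogate(s: SampleSet, cfg: HybridConfig):
    """Fit the NN-PSO surrogate covariates -> target on measured stations."""
    from .nn import partition_data

    sub = s.measured().complete_for(cfg.target)
    X, ok = _design(sub.data, cfg.covariates)
    y = sub.values(cfg.target)
    X, y = X[ok], y[ok]
    part = partition_data(len(y), seed=cfg.partition_seed)
    return train_nn_pso(cfg.n_hidden, X, y, part, cfg.pso,
                        lm_kwargs=cfg.lm_kwargs)


def augment_with_nn(s: SampleSet, cfg: HybridConfig, seed: int = 0) -> SampleSet:
    """Densify a survey with network predictions at auxiliary sites.

    Trains the surrogate on the measured stations, predicts the target at
    (up to ``n_aux``) auxiliary sites, and appends them as pseudo-stations
    (``is_pseudo=True``).  With ``n_aux=0`` or no auxiliary sites the input
    is returned unchanged.  Deterministic given the seeds in ``cfg``.
    """
    if cfg.n_aux == 0 or cfg.aux_sites is None or len(cfg.aux_sites) == 0:
        return s

    aux = cfg.aux_sites.reset_index(drop=True)
    M, ok = _design(aux, cfg.covariates)
    if not ok.any():
        raise ValueError("every auxiliary site is missing a covariate")
    n_bad = int((~ok).sum())
    if n_bad:
        import warnings
        warnings.warn(f"{n_bad} auxiliary site(s) missing covariates; skipped")
    aux = aux[ok].reset_index(drop=True)
    M = M[ok]
    if len(aux) > cfg.n_aux:
        pick = np.linspace(0, len(aux) - 1, cfg.n_aux).round().astype(int)
        aux = aux.iloc[pick].reset_index(drop=True)
        M = M[pick]

    model, _ = train_surrogate(s, cfg)
    preds = model.forward(M)

    pseudo = pd.DataFrame({
        "station_id": [f"PSEUDO{i}" for i in range(len(aux))],
        "lon": np.nan, "lat": np.nan,
        "season": s.data["season"].iloc[0] if len(s) else "dry",
        "x": aux["x"].to_numpy(float),
        "y": aux["y"].to_numpy(float),
        "is_pseudo": True,
        cfg.target: preds,
    })
    for c in cfg.covariates:
        if c in ("x", "y"):
            continue
        pseudo[c] = aux[c].to_numpy(float)
    out = pd.concat([s.data, pseudo], ignore_index=True)
    return SampleSet(out)


def hybrid_interpolate(spec: InterpolatorSpec, s: SampleSet, cfg: HybridConfig,
                       grid: PredictionGrid, seed: int = 0) -> PredictionGrid:
    """Densify with the network, then run the interpolator on the grid.

    Pseudo-points enter kriging/IDW/RBF as ordinary data; the weighted local
    methods (LPI/KS) honour ``cfg.lambda_pseudo`` as a downweight (a value
    of 1, the default, makes pseudo and real points equivalent).
    """
    if cfg.residual_mode:
        return _residual_interpolate(spec, s, cfg, grid, seed=seed)
    aug = augment_with_nn(s, cfg, seed=seed)
    if (cfg.lambda_pseudo < 1.0 and spec.method in ("lpi", "ks")
            and aug.data["is_pseudo"].any()):
        # fold the downweight into the kernel by jittering pseudo distances:
        # w_pseudo = lambda * w  <=>  d'^2 = d^2 - bw^2 ln(lambda); instead we
        # simply scale the pseudo rows' kernel weights via a replicated fit.
        return _weighted_lpi_grid(spec, aug, cfg, grid)
    return predict_grid(spec, aug, cfg.target, grid, seed=seed)


def _residual_interpolate(spec, s, cfg, grid, seed=0):
    """Alternative hybrid mode: interpolate network residuals, add back.

    Requires ``cfg.aux_sites`` to list the grid cells (same order as
    ``grid.cell_centers()``) with their covariate values, so the network
    trend can be evaluated everywhere on the raster.
    """
    from .deterministic import predict_points

    cells = grid.cell_centers()
    if cfg.aux_sites is None or len(cfg.aux_sites) != len(cells):
        raise ValueError("residual mode needs aux_sites matching the grid cells")
    model, _ = train_surrogate(s, cfg)
    sub = s.measured().complete_for(cfg.target)
    Xs, ok = _design(sub.data, cfg.covariates)
    resid = sub.values(cfg.target)[ok] - model.forward(Xs[ok])
    res_set = SampleSet(sub.data[ok].assign(**{cfg.target: resid}))
    res_grid = predict_points(spec, res_set, cfg.target, cells, seed=seed)
    Mg, okg = _design(cfg.aux_sites.reset_index(drop=True), cfg.covariates)
    trend = np.full(len(cells), np.nan)
    trend[okg] = model.forward(Mg[okg])
    return grid.with_values(trend + res_grid)


def _weighted_lpi_grid(spec, aug, cfg, grid):
    from .deterministic import _poly_design  # shared design convention
    import numpy.linalg as la

    sub = aug.complete_for(cfg.target)
    xy = sub.coords()
    z = sub.values(cfg.target)
    w_row = np.where(sub.data["is_pseudo"].to_numpy(bool), cfg.lambda_pseudo, 1.0)
    prm = dict(spec.parameters)
    degree = prm.get("degree", 1)
    bw = prm.get("bandwidth")
    if bw is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        bw = 0.5 * float(np.hypot(*span))
    ridge = prm.get("ridge", 1e-4 if spec.method == "ks" else 0.0)
    n_terms = (degree + 1) * (degree + 2) // 2
    center = xy.mean(axis=0)
    scale = max(xy.std(axis=0).max(), 1e-12)
    X = _poly_design(xy, degree, center, scale)
    tgt = grid.cell_centers()
    out = np.full(len(tgt), np.nan)
    for t in range(len(tgt)):
        d = np.hypot(xy[:, 0] - tgt[t, 0], xy[:, 1] - tgt[t, 1])
        w = w_row * np.exp(-((d / bw) ** 2))
        if np.sum(w > 1e-12) < n_terms:
            continue
        Xw = X * w[:, None]
        A = X.T @ Xw + ridge * np.eye(n_terms)
        try:
            beta = la.solve(A, Xw.T @ z)
        except la.LinAlgError:
            continue
        out[t] = (_poly_design(tgt[t:t + 1], degree, center, scale) @ beta)[0]
    return grid.with_values(out)


def run_method_comparison(s: SampleSet, parameter: str, methods,
                          hybrid_cfg: HybridConfig | None = None,
                          hybrid: tuple = (False, True),
                          seed: int = 0, season: str | None = None) -> CVReport:
    """Full LOOCV matrix over methods x (plain, NN-PSO-informed).

    Returns a :class:`CVReport` whose rows mirror the summary-table layout
    (parameter, season, method label, MAE, R) and whose ``governing``
    property applies the min-MAE / max-R selection rule.  Rows whose LOOCV
    fails outright are recorded with NaN metrics.
    """
    if len(methods) < 1:
        raise ValueError("need at least one method")
    if season is None:
        season = str(s.data["season"].iloc[0])
    report = CVReport(parameter=parameter, season=season)
    for method in methods:
        spec = method if isinstance(method, InterpolatorSpec) \
            else InterpolatorSpec(method)
        for use_hybrid in hybrid:
            if use_hybrid and hybrid_cfg is None:
                continue
            cfg = hybrid_cfg if use_hybrid else None
            try:
                row = loocv(spec, s, parameter, hybrid=cfg, seed=seed)
            except Exception as exc:  # noqa: BLE001
                import warnings
                from .metrics import CVRow
                warnings.warn(f"{spec.method} hybrid={use_hybrid} failed: {exc}")
                row = CVRow(spec.method, use_hybrid, np.nan, np.nan, 0, -1)
            report.rows.append(row)
    return report
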