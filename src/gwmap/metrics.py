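"""Error/agreement metrics and leave-one-out cross-validation.

MAE = (1/n) sum |Z_i - Z|, MSE = (1/n) sum e_i^2, and the sample Pearson
correlation R between predicted and measured values are the package's
evaluation currency; the governing interpolation method for a parameter is
the one with minimal LOOCV MAE (ties broken by maximal R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import SampleSet
from .deterministic import InterpolatorSpec, predict_points


def _paired(pred, obs):
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if len(pred) == 0:
        raise ValueError("empty input")
    return pred, obs


def mae(pred, obs) -> float:
    """Mean absolute error, in the parameter's own units."""
    pred, obs = _paired(pred, obs)
    return float(np.mean(np.abs(pred - obs)))


def mse(pred, obs) -> float:
    """Mean squared error."""
    pred, obs = _paired(pred, obs)
    return float(np.mean((obs - pred) ** 2))


def pearson_r(y0, ym, strict: bool = True) -> float:
    """Sample Pearson correlation of predicted (y0) vs measured (ym).

    With ``strict`` (default) a constant input raises; otherwise NaN is
    returned as the undefined-marker.
    """
    y0, ym = _paired(y0, ym)
    if len(y0) < 3:
        if strict:
            raise ValueError("Pearson R needs at least 3 pairs")
        return np.nan
    a = y0 - y0.mean()
    b = ym - ym.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        if strict:
            raise ValueError("Pearson R undefined for constant input")
        return np.nan
    return float((a @ b) / denom)


@dataclass
class CVRow:
    """One LOOCV result: method (+NN-PSO suffix when hybrid), MAE, R."""

    method: str
    hybrid: bool
    mae: float
    r: float
    n_folds: int
    n_failed: int = 0

    @property
    def label(self) -> str:
        return f"{self.method.upper()}+NN-PSO" if self.hybrid else self.method.upper()


@dataclass
class CVReport:
    """Per-method LOOCV rows plus the selected governing method."""

    parameter: str
    season: str
    rows: list = field(default_factory=list)

    @property
    def governing(self) -> CVRow:
        return select_governing(self.rows)

    def to_records(self) -> list[dict]:
        gov = self.governing.label if self.rows else None
        return [
            {
                "parameter": self.parameter, "season": self.season,
                "method": r.label, "MAE": r.mae, "R": r.r,
                "n_folds": r.n_folds, "n_failed": r.n_failed,
                "governing": r.label == gov,
            }
            for r in self.rows
        ]


def select_governing(rows) -> CVRow:
    """Lowest MAE wins; exact ties (within 1e-12) fall to the higher R."""
    rows = list(rows)
    if not rows:
        raise ValueError("no CV rows to select from")
    finite = [r for r in rows if np.isfinite(r.mae)]
    rows = finite or rows
    best = rows[0]
    for row in rows[1:]:
        if row.mae < best.mae - 1e-12:
            best = row
        elif abs(row.mae - best.mae) <= 1e-12:
            r_new = -np.inf if np.isnan(row.r) else row.r
            r_best = -np.inf if np.isnan(best.r) else best.r
            if r_new > r_best:
                best = row
    return best


def loocv(spec: InterpolatorSpec, s: SampleSet, parameter: str,
          hybrid=None, seed: int = 0, max_fail_frac: float = 0.2) -> CVRow:
    """Leave-one-out cross-validation of one method on one parameter.

    Folds iterate over the measured (non-pseudo) stations that carry the
    parameter.  When ``hybrid`` (a :class:`gwmap.hybrid.HybridConfig`) is
    given, the full pipeline — NN-PSO training and pseudo-point generation —
    is refit inside every fold from the remaining stations, so no held-out
    information leaks through the network (hybrid.fast reuses the full-data
    network instead).  Returns MAE and Pearson R over the held-out
    predictions.
    """
    from .hybrid import augment_with_nn

    base = s.measured().complete_for(parameter)
    n = len(base)
    if n < 5:
        raise ValueError("LOOCV needs at least 5 measured stations")

    fast_aug = None
    if hybrid is not None and getattr(hybrid, "fast", False):
        fast_aug = augment_with_nn(s.measured(), hybrid, seed=seed)

    xy = base.coords()
    z = base.values(parameter)
    preds = np.full(n, np.nan)
    failed = 0
    for i in range(n):
        rest = base.drop_stations(i)
        try:
            if hybrid is not None:
                if fast_aug is not None:
                    # fast mode: keep full-data pseudo points, drop the real station
                    sid = base.data["station_id"].iloc[i]
                    keep = ~((~fast_aug.data["is_pseudo"])
                             & (fast_aug.data["station_id"] == sid))
                    train_set = SampleSet(fast_aug.data[keep])
                else:
                    train_set = augment_with_nn(rest, hybrid, seed=seed)
            else:
                train_set = rest
            p = predict_points(spec, train_set, parameter, xy[i:i + 1], seed=seed)
            if not np.isfinite(p[0]):
                raise ValueError("nodata prediction")
            preds[i] = p[0]
        except Exception as exc:  # noqa: BLE001 - fold failures are data
            failed += 1
            warnings.warn(f"fold {i} failed: {exc}")
    if failed > max_fail_frac * n:
        raise RuntimeError(f"{failed}/{n} LOOCV folds failed")
    ok = np.isfinite(preds)
    return CVRow(
        method=spec.method,
        hybrid=hybrid is not None,
        mae=mae(preds[ok], z[ok]),
        r=pearson_r(preds[ok], z[ok], strict=False),
        n_folds=n,
        n_failed=failed,
    )
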