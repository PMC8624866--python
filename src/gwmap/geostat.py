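"""Variogram estimation/fitting and kriging predictors (OK, UK, simplified EBK).

The semivariogram gamma(h) — half the expected squared difference of the
field at separation h — is estimated with the Matheron estimator, fitted by
weighted least squares with Cressie weights N(h)/gamma_model(h)^2 over the
spherical/exponential/gaussian families, and plugged into the ordinary or
universal kriging systems.  The empirical Bayesian variant propagates
variogram-estimation uncertainty with a simulate-and-refit ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .data import SampleSet

_FAMILIES = ("spherical", "exponential", "gaussian", "power")


@dataclass
class VariogramModel:
    """Parametric semivariogram: family + nugget + partial sill + range.

    For the power family ``partial_sill`` is the slope b and ``range_`` the
    exponent alpha in (0, 2); for the bounded families gamma rises from the
    nugget at 0+ to nugget + partial sill at (or asymptotically beyond) the
    range.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.family == "power":
            if not 0 < self.range_ < 2:
                raise ValueError("power exponent must lie in (0, 2)")
        elif self.range_ <= 0:
            raise ValueError("range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag(s) h >= 0; gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        c0, c, a = self.nugget, self.partial_sill, self.range_
        if self.family == "spherical":
            r = np.minimum(h / a, 1.0)
            g = c * (1.5 * r - 0.5 * r**3)
        elif self.family == "exponential":
            g = c * (1.0 - np.exp(-3.0 * h / a))
        elif self.family == "gaussian":
            g = c * (1.0 - np.exp(-3.0 * (h / a) ** 2))
        else:  # power
            g = c * h**a
        return np.where(h > 0, c0 + g, 0.0)


@dataclass
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates."""

    lags: np.ndarray          # bin centres, metres
    semivariances: np.ndarray  # value^2
    counts: np.ndarray         # pairs per bin
    max_lag: float

    def nonempty(self) -> "EmpiricalVariogram":
        m = self.counts > 0
        return EmpiricalVariogram(self.lags[m], self.semivariances[m],
                                  self.counts[m], self.max_lag)


@dataclass
class EBKEnsemble:
    """Equal-weight ensemble of variogram models from simulate-refit rounds."""

    models: list
    base: VariogramModel


def empirical_variogram(s: SampleSet, parameter: str, n_lags: int = 12,
                        max_lag: float | None = None) -> EmpiricalVariogram:
    """Matheron estimator gamma_hat(h) = (1/2N(h)) sum (z_i - z_j)^2, binned.

    Default max lag is half the maximum pairwise distance (standard practice:
    longer lags have too few, spatially clustered pairs).
    """
    sub = s.complete_for(parameter)
    if len(sub) < 10:
        raise ValueError("need at least 10 stations for a variogram")
    xy = sub.coords()
    z = sub.values(parameter)
    iu, ju = np.triu_indices(len(z), k=1)
    d = np.hypot(xy[iu, 0] - xy[ju, 0], xy[iu, 1] - xy[ju, 1])
    sq = (z[iu] - z[ju]) ** 2
    if max_lag is None:
        max_lag = 0.5 * d.max()
    keep = d <= max_lag
    if not keep.any():
        raise ValueError("all station pairs lie beyond max_lag")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    idx = np.clip(np.digitize(d[keep], edges) - 1, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma_hat = np.where(counts > 0, 0.5 * sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma_hat, counts, max_lag)


def fit_variogram(ev: EmpiricalVariogram,
                  families: tuple = ("spherical", "exponential", "gaussian"),
                  ) -> VariogramModel:
    """WLS fit with Cressie weights; best family by weighted SSE.

    Bounded search: nugget in [0, max gamma_hat], partial sill in
    [0, 2 max gamma_hat], range in (0, 2 max lag].  Several starts per family
    guard against local minima of the nonconvex objective.
    """
    ev = ev.nonempty()
    if len(ev.lags) < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit")
    h, g, n = ev.lags, ev.semivariances, ev.counts.astype(float)
    gmax = float(g.max()) if g.max() > 0 else 1.0

    best = None
    best_sse = np.inf
    for family in families:
        def resid(theta, family=family):
            vm = VariogramModel(family, *theta)
            gm = np.maximum(vm.gamma(h), 1e-12 * gmax)
            return np.sqrt(n) / gm * (g - gm)

        starts = [
            (0.1 * gmax, 0.9 * gmax, 0.5 * ev.max_lag),
            (0.0, gmax, ev.max_lag),
            (0.5 * gmax, 0.5 * gmax, 0.25 * ev.max_lag),
        ]
        lo = (0.0, 0.0, 1e-6 * ev.max_lag)
        hi = (gmax, 2.0 * gmax, 2.0 * ev.max_lag)
        for x0 in starts:
            try:
                sol = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                             method="trf", max_nfev=400)
            except Exception:
                continue
            sse = float(np.sum(sol.fun**2))
            if sse < best_sse:
                best_sse = sse
                c0, c, a = np.maximum(sol.x, 0.0)
                if family == "gaussian":
                    # zero-nugget Gaussian variograms make the kriging matrix
                    # catastrophically ill-conditioned; floor the nugget at
                    # 0.1% of the sill (standard conditioning practice)
                    c0 = max(c0, 1e-3 * (c0 + c))
                best = VariogramModel(family, c0, c, a)
    if best is None:
        raise RuntimeError("variogram fit failed for every family")
    return best


# ---------------------------------------------------------------------------
# kriging
# ---------------------------------------------------------------------------

def _pairwise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])


def _check_duplicates(xy: np.ndarray, s: SampleSet | None = None):
    d = _pairwise(xy, xy)
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < 1e-9:
        ids = ""
        if s is not None and "station_id" in s.data.columns:
            ids = f" ({s.data['station_id'].iloc[i]}, {s.data['station_id'].iloc[j]})"
        raise ValueError(
            f"coincident stations {i} and {j}{ids} make the kriging matrix "
            "singular; average duplicates first (dedup_coincident)"
        )


def _kriging_solve(xy, z, vm, targets, drift_terms, exact_at_stations=True):
    """Shared OK/UK solver with polynomial drift columns.

    drift_terms: list of callables f(xy) -> column; [const] gives OK,
    [const, x, y] gives UK with linear drift.
    """
    n = len(xy)
    q = len(drift_terms)
    gamma_dd = vm.gamma(_pairwise(xy, xy))
    np.fill_diagonal(gamma_dd, 0.0)
    F = np.column_stack([f(xy) for f in drift_terms])
    if q > 1 and np.linalg.matrix_rank(F) < q:
        raise ValueError("drift design is rank-deficient (collinear stations?)")
    A = np.zeros((n + q, n + q))
    A[:n, :n] = gamma_dd
    A[:n, n:] = F
    A[n:, :n] = F.T

    tgt = np.asarray(targets, dtype=float)
    d_dt = _pairwise(xy, tgt)
    gamma_dt = vm.gamma(d_dt)
    if not exact_at_stations:
        # nugget-filtered smoothing: treat a zero-lag target like an
        # infinitesimally offset one, so the nugget is not screened out
        gamma_dt = np.where(d_dt < 1e-9, vm.nugget, gamma_dt)
    Ft = np.column_stack([f(tgt) for f in drift_terms])
    B = np.vstack([gamma_dt, Ft.T])

    try:
        lu, piv = linalg.lu_factor(A)
    except linalg.LinAlgError as exc:
        raise ValueError("singular kriging matrix") from exc
    W = linalg.lu_solve((lu, piv), B)
    w, mu = W[:n], W[n:]
    preds = w.T @ z
    var = np.einsum("ij,ij->j", W, B)
    var = np.maximum(var, 0.0)

    if exact_at_stations:
        d_t = _pairwise(tgt, xy)
        at, station = np.nonzero(d_t < 1e-9)
        preds[at] = z[station]
        if vm.nugget == 0:
            var[at] = 0.0
    return preds, var, w


def ok_predict(s: SampleSet, parameter: str, vm: VariogramModel, targets,
               exact_at_stations: bool = True, return_weights: bool = False):
    """Ordinary kriging: BLUP with weights constrained to sum to one.

    Returns (predictions, kriging variances); with ``return_weights`` the
    (n_stations, n_targets) weight matrix is appended.
    """
    sub = s.complete_for(parameter)
    xy = sub.coords()
    _check_duplicates(xy, sub)
    z = sub.values(parameter)
    const = lambda p: np.ones(len(p))
    preds, var, w = _kriging_solve(xy, z, vm, targets, [const],
                                   exact_at_stations=exact_at_stations)
    return (preds, var, w) if return_weights else (preds, var)


def uk_predict(s: SampleSet, parameter: str, vm: VariogramModel, targets,
               drift: str = "linear", exact_at_stations: bool = True,
               return_weights: bool = False):
    """Universal kriging with a deterministic drift in the constraints.

    drift="linear" augments the system with {1, x, y}; drift="constant"
    reduces exactly to ordinary kriging.
    """
    sub = s.complete_for(parameter)
    xy = sub.coords()
    _check_duplicates(xy, sub)
    z = sub.values(parameter)
    if drift == "constant":
        terms = [lambda p: np.ones(len(p))]
    elif drift == "linear":
        if len(sub) < 4:
            raise ValueError("linear drift needs at least 4 non-collinear stations")
        # centre/scale coordinates for conditioning only; affine-invariant drift
        mx, my = xy.mean(axis=0)
        sc = max(xy.std(axis=0).max(), 1.0)
        terms = [
            lambda p: np.ones(len(p)),
            lambda p: (p[:, 0] - mx) / sc,
            lambda p: (p[:, 1] - my) / sc,
        ]
    else:
        raise ValueError(f"unknown drift {drift!r}")
    preds, var, w = _kriging_solve(xy, z, vm, targets, terms,
                                   exact_at_stations=exact_at_stations)
    return (preds, var, w) if return_weights else (preds, var)


def ebk_predict(s: SampleSet, parameter: str, targets, K: int = 100,
                subset_size: int = 50, seed: int = 0,
                families: tuple = ("spherical", "exponential", "gaussian"),
                n_lags: int = 12):
    """Simplified empirical Bayesian kriging.

    Fits a base variogram, then K times draws an unconditional Gaussian
    realisation at the station locations from the current model and refits a
    variogram to it; predictions and variances are the equal-weight mixture
    of ordinary-kriging solutions over the surviving ensemble, with the
    between-member spread folded into the mixture variance.  Deterministic
    given the seed.  With n <= subset_size (the usual case here, n = 36) a
    single subset is used.

    Returns (predictions, variances, EBKEnsemble).
    """
    from .synthetic import gaussian_random_field  # deferred: avoids cycle

    sub = s.complete_for(parameter)
    if len(sub) < 10:
        raise ValueError("EBK needs at least 10 stations")
    if len(sub) > subset_size:
        warnings.warn("n > subset_size: using the full set as a single subset "
                      "(local-subset blending not implemented)")
    ev = empirical_variogram(sub, parameter, n_lags=n_lags)
    base = fit_variogram(ev, families=families)
    if K == 1:
        preds, var = ok_predict(sub, parameter, base, targets)
        return preds, var, EBKEnsemble([base], base)

    xy = sub.coords()
    z = sub.values(parameter)
    zbar = z.mean()
    models = []
    rng = np.random.default_rng(seed)
    for k in range(K):
        sim = zbar + gaussian_random_field(xy, base, seed=int(rng.integers(2**31)))
        sim_set = sub.copy()
        sim_set.data[parameter] = sim
        try:
            mk = fit_variogram(empirical_variogram(sim_set, parameter,
                                                   n_lags=n_lags),
                               families=families)
        except Exception:
            continue
        models.append(mk)
    if len(models) < K / 2:
        raise RuntimeError(f"only {len(models)}/{K} ensemble members fitted")

    P = []
    V = []
    for mk in models:
        p, v = ok_predict(sub, parameter, mk, targets)
        P.append(p)
        V.append(v)
    P = np.array(P)
    V = np.array(V)
    preds = P.mean(axis=0)
    # mixture variance: mean within-member variance + between-member spread
    var = V.mean(axis=0) + P.var(axis=0)
    return preds, var, EBKEnsemble(models, base)
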