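"""Deterministic interpolators: IDW, global/local polynomial, RBF, kernel smoothing.

All methods consume projected survey coordinates (metres) and a target
parameter and emit point predictions; ``predict_grid`` materialises any
method (including the kriging family) on a raster.  Kernel smoothing (KS) is
first-order local polynomial interpolation with a ridge penalty, optionally
using barrier-avoiding shortest-path distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .data import PredictionGrid, SampleSet

_RBF_KERNELS = ("thin_plate_spline", "multiquadric", "inverse_multiquadric",
                "gaussian")


@dataclass
class InterpolatorSpec:
    """Method name + per-method parameters (validated lazily by the method)."""

    method: str  # idw | gpi | lpi | rbf | ks | ok | uk | ebk
    parameters: dict = field(default_factory=dict)
    barriers: list | None = None  # list of ((x1,y1),(x2,y2)) polyline segments

    def __post_init__(self):
        if self.method not in ("idw", "gpi", "lpi", "rbf", "ks", "ok", "uk", "ebk"):
            raise ValueError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# inverse distance weighting
# ---------------------------------------------------------------------------

def idw_predict(s: SampleSet, parameter: str, targets, p: float = 2.0,
                k: int = 15) -> np.ndarray:
    """Inverse-distance-weighted average over the k nearest stations.

    Exact at stations: a target within 1e-9 m of a station returns that
    station's value (coincident duplicate stations are averaged first).
    """
    if p <= 0:
        raise ValueError("IDW power must be positive")
    if len(s.complete_for(parameter)) == 0:
        raise ValueError("empty sample set")
    sub = s.complete_for(parameter).dedup_coincident(parameter, tol=1e-9)
    xy = sub.coords()
    z = sub.values(parameter)
    tgt = np.asarray(targets, dtype=float)
    k_eff = min(k, len(xy))
    tree = cKDTree(xy)
    d, idx = tree.query(tgt, k=k_eff)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d ** (-p)
        out = np.einsum("ij,ij->i", w, z[idx]) / w.sum(axis=1)
    hit = d[:, 0] < 1e-9
    out[hit] = z[idx[hit, 0]]
    return out


# ---------------------------------------------------------------------------
# global polynomial interpolation (trend surface)
# ---------------------------------------------------------------------------

def _poly_design(xy: np.ndarray, degree: int, center: np.ndarray,
                 scale: float) -> np.ndarray:
    u = (xy[:, 0] - center[0]) / scale
    v = (xy[:, 1] - center[1]) / scale
    cols = [np.ones_like(u)]
    for d in range(1, degree + 1):
        for i in range(d + 1):
            cols.append(u ** (d - i) * v**i)
    return np.column_stack(cols)


def gpi_fit_predict(s: SampleSet, parameter: str, targets,
                    degree: int = 1) -> np.ndarray:
    """Global polynomial trend surface by OLS on standardized coordinates."""
    if degree not in (1, 2, 3):
        raise ValueError("GPI degree must be 1, 2 or 3")
    sub = s.complete_for(parameter)
    xy = sub.coords()
    z = sub.values(parameter)
    n_terms = (degree + 1) * (degree + 2) // 2
    if len(sub) < n_terms:
        raise ValueError(f"need >= {n_terms} stations for degree {degree}")
    center = xy.mean(axis=0)
    scale = max(xy.std(axis=0).max(), 1e-12)
    X = _poly_design(xy, degree, center, scale)
    if np.linalg.matrix_rank(X) < n_terms:
        raise ValueError(
            f"rank-deficient polynomial design (degenerate station geometry); "
            f"try degree {degree - 1}"
        )
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    Xt = _poly_design(np.asarray(targets, dtype=float), degree, center, scale)
    return Xt @ beta


# ---------------------------------------------------------------------------
# local polynomial interpolation / kernel smoothing
# ---------------------------------------------------------------------------

def barrier_distance(a: np.ndarray, b: np.ndarray, barriers) -> float:
    """Shortest polyline-avoiding path length between two points.

    Builds the visibility graph over the endpoints {a, b} and every barrier
    vertex; an edge exists where the connecting segment does not cross a
    barrier.  Exact for segment barriers; falls back to Euclidean when no
    barrier blocks the direct segment.
    """
    import networkx as nx
    from shapely.geometry import LineString

    segs = [LineString(seg) for seg in barriers]
    nodes = [tuple(a), tuple(b)]
    for seg in barriers:
        nodes.extend(tuple(v) for v in seg)
    nodes = list(dict.fromkeys(nodes))

    def visible(u, v):
        line = LineString([u, v])
        # blocked only by a proper crossing; touching a barrier endpoint is
        # allowed (paths pivot around endpoints)
        return not any(line.crosses(sg) for sg in segs)

    G = nx.Graph()
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if visible(u, v):
                G.add_edge(u, v, weight=float(np.hypot(u[0] - v[0], u[1] - v[1])))
    try:
        return nx.shortest_path_length(G, tuple(a), tuple(b), weight="weight")
    except nx.NetworkXNoPath:
        return np.inf


def lpi_predict(s: SampleSet, parameter: str, targets, degree: int = 1,
                bandwidth: float | None = None, ridge: float = 0.0,
                barriers=None) -> np.ndarray:
    """Local polynomial regression with a Gaussian kernel.

    At each target a polynomial of the given degree is fitted by weighted
    least squares with weights exp(-(d/bandwidth)^2); ``ridge`` adds delta*I
    to the normal matrix (the kernel-smoothing variant).  Targets with no
    effectively weighted neighbour get NaN with a warning.
    """
    sub = s.complete_for(parameter)
    xy = sub.coords()
    z = sub.values(parameter)
    if bandwidth is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        bandwidth = 0.5 * float(np.hypot(*span))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    n_terms = (degree + 1) * (degree + 2) // 2
    center = xy.mean(axis=0)
    scale = max(xy.std(axis=0).max(), 1e-12)
    X = _poly_design(xy, degree, center, scale)

    tgt = np.asarray(targets, dtype=float)
    out = np.full(len(tgt), np.nan)
    n_skipped = 0
    for t in range(len(tgt)):
        if barriers:
            d = np.array([barrier_distance(tgt[t], pt, barriers) for pt in xy])
        else:
            d = np.hypot(xy[:, 0] - tgt[t, 0], xy[:, 1] - tgt[t, 1])
        w = np.exp(-((d / bandwidth) ** 2))
        if np.sum(w > 1e-12) < n_terms:
            n_skipped += 1
            continue
        Xw = X * w[:, None]
        A = X.T @ Xw + ridge * np.eye(n_terms)
        b = Xw.T @ z
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            n_skipped += 1
            continue
        xt = _poly_design(tgt[t:t + 1], degree, center, scale)
        out[t] = (xt @ beta)[0]
    if n_skipped:
        warnings.warn(f"{n_skipped} target(s) had no in-range neighbours; nodata")
    return out


def ks_predict(s: SampleSet, parameter: str, targets,
               bandwidth: float | None = None, ridge: float | None = None,
               barriers=None) -> np.ndarray:
    """Kernel smoothing: ridge-regularized first-order LPI, barrier-aware.

    With ``ridge=None`` the penalty is chosen by generalized cross-validation
    over a log grid (1e-6 .. 1, scaled by the mean kernel-weighted design
    norm is unnecessary at degree 1 on standardized coordinates).
    """
    if ridge is None:
        ridge = _gcv_ridge(s, parameter, bandwidth)
    return lpi_predict(s, parameter, targets, degree=1, bandwidth=bandwidth,
                       ridge=ridge, barriers=barriers)


def _gcv_ridge(s: SampleSet, parameter: str, bandwidth, grid=None) -> float:
    """Pick the KS ridge penalty by leave-one-out error on a log grid."""
    if grid is None:
        grid = np.logspace(-6, 0, 7)
    sub = s.complete_for(parameter)
    xy = sub.coords()
    z = sub.values(parameter)
    best, best_err = grid[0], np.inf
    for delta in grid:
        errs = []
        for i in range(len(sub)):
            rest = sub.drop_stations(i)
            pred = lpi_predict(rest, parameter, xy[i:i + 1], degree=1,
                               bandwidth=bandwidth, ridge=delta)
            if np.isfinite(pred[0]):
                errs.append(abs(pred[0] - z[i]))
        err = np.mean(errs) if errs else np.inf
        if err < best_err:
            best, best_err = delta, err
    return float(best)


# ---------------------------------------------------------------------------
# radial basis functions
# ---------------------------------------------------------------------------

def rbf_fit_predict(s: SampleSet, parameter: str, targets,
                    kernel: str = "thin_plate_spline",
                    epsilon: float | None = None) -> np.ndarray:
    """Exact RBF interpolation with polynomial drift.

    Thin-plate spline (phi(r) = r^2 log r, affine drift) is the default —
    the minimum-curvature surface.  Shape parameter ``epsilon`` applies to
    the scale-dependent kernels; coincident stations are averaged first.
    """
    if kernel not in _RBF_KERNELS:
        raise ValueError(f"kernel must be one of {_RBF_KERNELS}")
    sub = s.complete_for(parameter).dedup_coincident(parameter, tol=1e-9)
    if len(sub) < 3:
        raise ValueError("RBF needs at least 3 distinct stations")
    xy = sub.coords()
    z = sub.values(parameter)
    kwargs = {"kernel": kernel}
    if kernel != "thin_plate_spline":
        if epsilon is None:
            # default shape: inverse mean nearest-neighbour spacing
            tree = cKDTree(xy)
            d, _ = tree.query(xy, k=2)
            epsilon = 1.0 / max(float(np.mean(d[:, 1])), 1e-12)
        kwargs["epsilon"] = epsilon
    try:
        f = RBFInterpolator(xy, z, **kwargs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular RBF system; de-duplicate coincident stations"
        ) from exc
    return f(np.asarray(targets, dtype=float))


# ---------------------------------------------------------------------------
# grid driver
# ---------------------------------------------------------------------------

def predict_points(spec: InterpolatorSpec, s: SampleSet, parameter: str,
                   targets, seed: int = 0) -> np.ndarray:
    """Dispatch a point prediction through any method named in the spec."""
    from . import geostat

    m, prm = spec.method, dict(spec.parameters)
    if m == "idw":
        return idw_predict(s, parameter, targets, **prm)
    if m == "gpi":
        return gpi_fit_predict(s, parameter, targets, **prm)
    if m == "lpi":
        return lpi_predict(s, parameter, targets, barriers=spec.barriers, **prm)
    if m == "ks":
        prm.setdefault("ridge", 1e-4)
        return ks_predict(s, parameter, targets, barriers=spec.barriers, **prm)
    if m == "rbf":
        return rbf_fit_predict(s, parameter, targets, **prm)

    sub = s.complete_for(parameter).dedup_coincident(parameter, tol=1e-9)
    vm = prm.pop("vm", None)
    if m in ("ok", "uk") and vm is None:
        ev = geostat.empirical_variogram(sub, parameter)
        vm = geostat.fit_variogram(ev)
    if m == "ok":
        return geostat.ok_predict(sub, parameter, vm, targets, **prm)[0]
    if m == "uk":
        return geostat.uk_predict(sub, parameter, vm, targets, **prm)[0]
    if m == "ebk":
        prm.setdefault("seed", seed)
        return geostat.ebk_predict(sub, parameter, targets, **prm)[0]
    raise ValueError(f"unknown method {m!r}")


def predict_grid(spec: InterpolatorSpec, s: SampleSet, parameter: str,
                 grid: PredictionGrid, seed: int = 0) -> PredictionGrid:
    """Predict every cell centre of *grid* with the chosen method."""
    preds = predict_points(spec, s, parameter, grid.cell_centers(), seed=seed)
    return grid.with_values(preds)
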