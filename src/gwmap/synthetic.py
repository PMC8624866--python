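"""Seeded synthetic surveys with the spatial/covariate structure the method assumes.

Real groundwater surveys of this kind are small (a few dozen wells), spatially
autocorrelated, and accompanied by cheap co-measured covariates (pH, EC, TDS,
temperature) that correlate with the expensive target (a heavy-metal
concentration).  The generators here emulate exactly that: a latent Gaussian
random field with nugget/sill/range structure sampled at the Marinduque
station geometry, covariates built as noisy linear (optionally monotone
nonlinear) links of the latent field, and independent measurement noise.
Everything is bit-reproducible given a seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PredictionGrid, SampleSet, make_grid, project_to_utm
from .geostat import VariogramModel

# Groundwater sampling stations, Marinduque Island province (Philippines):
# code, barangay, municipality, latitude °N, longitude °E, elevation m.
_STATIONS_CSV = """\
station_id,barangay,municipality,lat,lon,elevation
BGW1,Tagwak,Boac,13.44552,121.87620,96
BGW2,Maligaya,Boac,13.47936,121.84087,10
BGW3,Puting Buhangin,Boac,13.45117,121.96087,282
BGW4,Balarin,Boac,13.41933,121.82200,17
BGW5,Bantay,Boac,13.43247,121.90953,208
BGW6,Hinapulan,Boac,13.41442,121.94785,242
BGW7,Boton,Boac,13.44292,121.86732,61
MGW1,Sumangga,Mogpog,13.47268,121.87412,68
MGW2,Nangka Dos (Site 1),Mogpog,13.47972,121.85047,24
MGW3,Nangka Dos (Site 2),Mogpog,13.47973,121.85053,24
MGW4,Janagdong,Mogpog,13.46952,121.85326,29
MGW5,Butansapa,Mogpog,13.48100,121.91803,145
MGW6,Putting Buhangin,Mogpog,13.45533,121.95198,265
BVGW1,Malbog (Site 1),Buenavista,13.25813,121.94488,77
BVGW2,Malbog (Site 2),Buenavista,13.26675,121.91648,103
BVGW3,Libas (Site 1),Buenavista,13.25553,121.93958,69
BVGW4,Libas (Site 2),Buenavista,13.26807,121.95612,70
BVGW5,Bagtingon,Buenavista,13.20521,121.99482,85
BVGW6,Sihi,Buenavista,13.25813,121.94488,371
GGW1,Banuyo,Gasan,13.27573,121.89303,5
GGW2,Masiga,Gasan,13.35505,121.82912,16
GGW3,Libtangin,Gasan,13.34647,121.83297,21
GGW4,Matandang Gasan,Gasan,13.32178,121.85268,46
GGW5,Dawis,Gasan,13.28638,121.88908,42
GGW6,Tiguion,Gasan,13.34365,121.86365,86
TGW1,Marlangga,Torrijos,13.32683,122.08442,56
TGW2,Poctoy (Site 1),Torrijos,13.32943,122.09528,37
TGW3,Dampulan,Torrijos,13.22590,122.04562,25
TGW4,Sibuyao,Torrijos,13.34091,122.01261,444
TGW5,Poctoy (Site 2),Torrijos,13.33164,122.01261,34
TGW6,Matuyatuya,Torrijos,13.37778,122.11611,15
SGW1,San Antonio,Santa Cruz,13.44612,121.98055,272
SGW2,Dolores (Site 1),Santa Cruz,13.49177,121.96383,185
SGW3,Dolores (Site 2),Santa Cruz,13.49183,121.96087,191
SGW4,Napo,Santa Cruz,13.43878,122.07607,65
SGW5,Matalaba,Santa Cruz,13.46595,122.05897,53
"""


def marinduque_fixture(projected: bool = True) -> SampleSet:
    """The 36-station Marinduque well survey (coordinates only).

    Station ids, barangay/municipality labels, WGS84 lat/lon and elevation;
    parameter columns are absent.  With ``projected=True`` (default) UTM 51N
    x/y columns are attached.
    """
    df = pd.read_csv(io.StringIO(_STATIONS_CSV))
    df["season"] = "dry"
    s = SampleSet(df)
    return project_to_utm(s) if projected else s


@dataclass
class FieldSpec:
    """Recipe for one synthetic survey realisation.

    The latent target field has variogram ``vm`` around ``mean_level``;
    covariates are linear links ``coef * latent + noise`` with independent
    standard-normal noise scaled by ``covariate_noise_sd``; station
    measurements of the target add iid noise of sd ``noise_sd``.
    ``link_coefficients`` maps covariate name -> slope; a zero slope makes
    that covariate pure noise (the no-free-lunch control).
    """

    vm: VariogramModel = field(
        default_factory=lambda: VariogramModel("spherical", nugget=0.1,
                                               partial_sill=1.0, range_=3000.0)
    )
    mean_level: float = 0.0
    link_coefficients: dict = field(
        default_factory=lambda: {"temp": 0.9, "pH": 0.7, "EC": 0.8, "TDS": 0.6}
    )
    covariate_noise_sd: float = 0.3
    noise_sd: float = 0.05
    nonlinear_link: bool = False
    seed: int = 0


def gaussian_random_field(points: np.ndarray, vm: VariogramModel, seed: int,
                          jitter: float = 1e-10) -> np.ndarray:
    """Exact (covariance-factorisation) GRF draw at arbitrary points.

    Covariance C(h) = sill - gamma(h); a mean-zero multivariate normal is
    drawn via Cholesky of the dense covariance, so the point count is capped
    at 2500.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n > 2500:
        raise ValueError("dense-covariance simulation capped at 2500 points")
    d = np.hypot(pts[:, None, 0] - pts[None, :, 0], pts[:, None, 1] - pts[None, :, 1])
    sill = vm.nugget + vm.partial_sill
    cov = sill - vm.gamma(d)
    np.fill_diagonal(cov, sill)
    try:
        L = np.linalg.cholesky(cov + jitter * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite after jitter") from exc
    rng = np.random.default_rng(seed)
    return L @ rng.standard_normal(n)


def make_survey(spec: FieldSpec,
                stations: SampleSet | None = None,
                cellsize: float = 2000.0,
                season: str = "dry") -> tuple[SampleSet, PredictionGrid, dict]:
    """Generate a survey + truth grid from a :class:`FieldSpec`.

    Returns ``(survey, truth_grid, aux)`` where the survey carries a ``Cd``
    target column and linked covariate columns at the fixture stations, the
    truth grid holds the noise-free latent field on a regular raster, and
    ``aux`` is a dict with the latent/covariate values at every grid cell
    (auxiliary-site covariates for the hybrid pipeline).
    """
    if stations is None:
        stations = marinduque_fixture()
    grid = make_grid(stations, cellsize=cellsize, padding=cellsize)
    cells = grid.cell_centers()
    pts = np.vstack([stations.coords(), cells])
    latent = spec.mean_level + gaussian_random_field(pts, spec.vm, seed=spec.seed)

    n_st = len(stations)
    rng = np.random.default_rng(spec.seed + 1)

    def link(z, coef):
        noise = spec.covariate_noise_sd * rng.standard_normal(len(z))
        base = np.tanh(z) if spec.nonlinear_link else z
        return coef * base + noise

    survey = stations.copy()
    survey.data["season"] = season
    survey.data["Cd"] = latent[:n_st] + spec.noise_sd * rng.standard_normal(n_st)
    aux = {"latent": latent[n_st:]}
    for name, coef in spec.link_coefficients.items():
        both = link(latent, coef)
        survey.data[name] = both[:n_st]
        aux[name] = both[n_st:]

    truth = grid.with_values(latent[n_st:])
    return survey, truth, aux
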