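"""Core containers and I/O: point surveys, prediction grids, guideline limits.

A survey is a table of groundwater stations with WGS84 coordinates, a season
tag and per-parameter measurements (physicochemical: temp, pH, EC, TDS;
heavy metals in ppm: Cr, Cd, Fe, Mn, Ni, Pb, Zn, Cu).  Grids are ESRI ASCII
rasters (plain text), the lingua franca of desktop GIS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import geographic_to_utm

#: canonical parameter schema (column names and units)
PARAMETERS = ("temp", "pH", "EC", "TDS", "Cr", "Cd", "Fe", "Mn", "Ni", "Pb", "Zn", "Cu")
PHYSICOCHEMICAL = ("temp", "pH", "EC", "TDS")
HEAVY_METALS = ("Cr", "Cd", "Fe", "Mn", "Ni", "Pb", "Zn", "Cu")

_REQUIRED_COLUMNS = ("station_id", "lon", "lat", "season")


class SampleSet:
    """Point survey: station ids, coordinates, season, parameter values.

    Wraps a :class:`pandas.DataFrame` whose columns are ``station_id``,
    ``lon``, ``lat``, ``season``, optional projected ``x``/``y`` (metres),
    an ``is_pseudo`` flag (True for network-generated augmentation points)
    and any subset of :data:`PARAMETERS`.  Missing measurements are NaN,
    never zero.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"survey table missing required columns: {missing}")
        data = data.reset_index(drop=True).copy()
        if "is_pseudo" not in data.columns:
            data["is_pseudo"] = False
        data["is_pseudo"] = data["is_pseudo"].astype(bool)
        self.data = data

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        n_pseudo = int(self.data["is_pseudo"].sum())
        return (
            f"SampleSet(n={len(self)}, pseudo={n_pseudo}, "
            f"parameters={self.parameters})"
        )

    @property
    def parameters(self) -> list[str]:
        return [p for p in PARAMETERS if p in self.data.columns]

    @property
    def is_projected(self) -> bool:
        return "x" in self.data.columns and "y" in self.data.columns

    def coords(self) -> np.ndarray:
        """Projected (n, 2) coordinate array in metres."""
        if not self.is_projected:
            raise ValueError("SampleSet not projected; call project_to_utm first")
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def values(self, parameter: str) -> np.ndarray:
        if parameter not in self.data.columns:
            raise KeyError(f"parameter {parameter!r} not in survey")
        return self.data[parameter].to_numpy(dtype=float)

    def measured(self) -> "SampleSet":
        """Subset of real (non-pseudo) stations."""
        return SampleSet(self.data[~self.data["is_pseudo"]])

    def drop_stations(self, indices) -> "SampleSet":
        return SampleSet(self.data.drop(index=np.atleast_1d(indices)))

    def subset(self, mask) -> "SampleSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            return SampleSet(self.data[mask])
        return SampleSet(self.data.iloc[mask])

    def copy(self) -> "SampleSet":
        return SampleSet(self.data.copy())

    # -- parameter-level views --------------------------------------------
    def complete_for(self, parameter: str) -> "SampleSet":
        """Stations with a non-missing value of *parameter*."""
        return SampleSet(self.data[self.data[parameter].notna()])

    def dedup_coincident(self, parameter: str, tol: float = 10.0) -> "SampleSet":
        """Average stations closer than *tol* metres (per parameter).

        Exact interpolators (RBF, zero-nugget kriging) need distinct support
        points; printed survey coordinates can repeat at GPS precision.
        """
        sub = self.complete_for(parameter)
        xy = sub.coords()
        n = len(sub)
        group = -np.ones(n, dtype=int)
        g = 0
        for i in range(n):
            if group[i] >= 0:
                continue
            d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
            group[(d <= tol) & (group < 0)] = g
            g += 1
        rows = []
        for k in range(g):
            block = sub.data[group == k]
            row = block.iloc[0].copy()
            for p in sub.parameters:
                vals = block[p].dropna()
                row[p] = vals.mean() if len(vals) else np.nan
            row["x"] = block["x"].mean()
            row["y"] = block["y"].mean()
            rows.append(row)
        return SampleSet(pd.DataFrame(rows))


@dataclass
class PredictionGrid:
    """Regular raster of predictions, ESRI ASCII layout (row 0 = north)."""

    xll: float
    yll: float
    cellsize: float
    nrows: int
    ncols: int
    values: np.ndarray
    nodata: float = -9999.0
    variance: np.ndarray | None = None

    def __post_init__(self):
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.values.shape:
                raise ValueError("variance shape mismatch")

    def cell_centers(self) -> np.ndarray:
        """(nrows*ncols, 2) centre coordinates, row-major from the north row."""
        xs = self.xll + self.cellsize * (np.arange(self.ncols) + 0.5)
        ys = self.yll + self.cellsize * (np.arange(self.nrows) + 0.5)
        ys = ys[::-1]  # row 0 is northernmost
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def with_values(self, flat_values, flat_variance=None) -> "PredictionGrid":
        v = np.asarray(flat_values, dtype=float).reshape(self.nrows, self.ncols)
        var = None
        if flat_variance is not None:
            var = np.asarray(flat_variance, dtype=float).reshape(self.nrows, self.ncols)
        return PredictionGrid(
            self.xll, self.yll, self.cellsize, self.nrows, self.ncols, v,
            nodata=self.nodata, variance=var,
        )


@dataclass(frozen=True)
class GuidelineLimit:
    """Drinking-water limit: scalar ceiling or (lo, hi) acceptable range."""

    pnsdw: float | tuple[float, float] | None
    who: float | tuple[float, float] | None


#: PNSDW 2017 and WHO drinking-water guideline values (metals in ppm,
#: TDS in mg/L, EC in µS/cm, pH as an acceptable range).
GUIDELINES: dict[str, GuidelineLimit] = {
    "pH": GuidelineLimit((6.5, 8.5), (6.5, 9.2)),
    "EC": GuidelineLimit(None, 1500.0),
    "TDS": GuidelineLimit(600.0, 1200.0),
    "Cr": GuidelineLimit(0.050, 0.050),
    "Cd": GuidelineLimit(0.003, 0.003),
    "Fe": GuidelineLimit(1.000, 0.300),
    "Mn": GuidelineLimit(0.400, 0.400),
    "Ni": GuidelineLimit(0.070, 0.070),
    "Pb": GuidelineLimit(0.010, 0.010),
    "Zn": GuidelineLimit(5.000, 3.000),
    "Cu": GuidelineLimit(1.000, 2.000),
}


# ---------------------------------------------------------------------------
# survey readers
# ---------------------------------------------------------------------------

def read_survey(path, format: str | None = None) -> SampleSet:
    """Read a point survey from CSV or GeoJSON.

    CSV needs a header row with at least station_id, lon, lat, season.
    GeoJSON must be a FeatureCollection of Point features with parameters in
    ``properties``.  Unknown parameter columns are carried through with a
    warning; empty files raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".json", ".geojson") else "csv"

    if format == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValueError(f"no records in {path}") from None
        if len(df) == 0:
            raise ValueError(f"no records in {path}")
        for i, row in df.iterrows():
            if pd.isna(row.get("lon")) or pd.isna(row.get("lat")):
                raise ValueError(f"malformed row {i + 2} in {path}: missing lon/lat")
    elif format == "geojson":
        with open(path) as fh:
            gj = json.load(fh)
        feats = gj.get("features", [])
        if not feats:
            raise ValueError(f"no records in {path}")
        rows = []
        for i, f in enumerate(feats):
            geom = f.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"malformed feature {i} in {path}: not a Point")
            lon, lat = geom["coordinates"][:2]
            row = dict(f.get("properties", {}))
            row["lon"], row["lat"] = lon, lat
            rows.append(row)
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {format!r}")

    known = set(_REQUIRED_COLUMNS) | set(PARAMETERS) | {
        "x", "y", "is_pseudo", "barangay", "municipality", "elevation",
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown parameter columns carried through: {unknown}")
    return SampleSet(df)


def write_survey_csv(s: SampleSet, path) -> None:
    s.data.to_csv(path, index=False)


def write_survey_geojson(s: SampleSet, path) -> None:
    feats = []
    for _, row in s.data.iterrows():
        props = {
            k: (None if (isinstance(v, float) and np.isnan(v)) else v)
            for k, v in row.items()
            if k not in ("lon", "lat")
        }
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [row["lon"], row["lat"]]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def project_to_utm(s: SampleSet, zone: int = 51, hemisphere: str = "N") -> SampleSet:
    """Attach UTM easting/northing columns (metres) to a survey."""
    out = s.copy()
    e, n = geographic_to_utm(
        out.data["lon"].to_numpy(), out.data["lat"].to_numpy(), zone, hemisphere
    )
    out.data["x"] = e
    out.data["y"] = n
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(g: PredictionGrid, path, precision: int = 6) -> None:
    """Write an ESRI ASCII grid (six header lines, rows north to south)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xll:.{precision}f}\n")
        fh.write(f"yllcorner {g.yll:.{precision}f}\n")
        fh.write(f"cellsize {g.cellsize:.{precision}f}\n")
        fh.write(f"NODATA_value {g.nodata:.{precision}f}\n")
        vals = np.where(np.isnan(g.values), g.nodata, g.values)
        for r in range(g.nrows):
            fh.write(" ".join(f"{v:.{precision}f}" for v in vals[r]) + "\n")


def read_ascii_grid(path) -> PredictionGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    return PredictionGrid(
        xll=header["xllcorner"], yll=header["yllcorner"],
        cellsize=header["cellsize"], nrows=nrows, ncols=ncols,
        values=values, nodata=header["nodata_value"],
    )


def make_grid(s: SampleSet, cellsize: float, padding: float = 0.0) -> PredictionGrid:
    """Nodata-initialised grid covering the survey bounding box plus padding.

    The box is expanded by *padding* on each side and covered by the minimal
    whole number of cells (ceil), anchored at the padded lower-left corner;
    cells are centre-registered.
    """
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    xy = s.coords()
    xmin, ymin = xy.min(axis=0) - padding
    xmax, ymax = xy.max(axis=0) + padding
    if xmax - xmin <= 0 or ymax - ymin <= 0:
        raise ValueError("degenerate extent: zero-area bounding box, increase padding")
    ncols = max(1, int(np.ceil((xmax - xmin) / cellsize)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cellsize)))
    # inclusive cell centres: a span that is an exact multiple of cellsize
    # still gets a closing cell so both extreme stations sit inside cells
    if np.isclose(ncols * cellsize, xmax - xmin):
        ncols += 1
    if np.isclose(nrows * cellsize, ymax - ymin):
        nrows += 1
    values = np.full((nrows, ncols), np.nan)
    return PredictionGrid(xll=xmin, yll=ymin, cellsize=cellsize,
                          nrows=nrows, ncols=ncols, values=values)
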