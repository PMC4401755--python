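"""Mobile-survey dose processing.

A car-borne record is a 30-s total count ``N_in`` taken inside the
vehicle with GPS coordinates.  Outdoor air kerma rate follows

    K_out [nGy/h] = 2 * N_in * F_shield * F_conv

where the factor 2 converts a 30-s count to counts per minute,
``F_shield`` (default 1.47) removes the car-body attenuation, and
``F_conv`` (default 0.00244 nGy/h per cpm) converts total count rate to
air kerma rate.  Annual effective dose assumes permanent outdoor
occupancy:

    H [mSv/y] = K_out * DCF * T,   DCF = 0.7 Sv/Gy, T = 8760 h.

Both calibration factors are through-origin least-squares slopes: zero
count rate must mean zero kerma, so the regression is forced through
the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurveyPoint",
    "CalibrationConstants",
    "RegionSummary",
    "DoseGrid",
    "fit_shielding_factor",
    "fit_conversion_factor",
    "kerma_from_counts",
    "annual_effective_dose",
    "round_sig",
    "summarize_regions",
    "grid_dose_map",
    "assign_regions_by_polygon",
]


@dataclass(frozen=True)
class SurveyPoint:
    """One 30-s mobile record."""

    timestamp: str
    lat: float
    lon: float
    counts: int
    region: str | None = None
    kerma_ngy_h: float | None = None

    def __post_init__(self) -> None:
        if self.counts < 0 or self.counts != int(self.counts):
            raise ValueError("counts must be a nonnegative integer")
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValueError("lat/lon must be finite")


@dataclass(frozen=True)
class CalibrationConstants:
    """Constants of the count -> kerma -> dose chain."""

    shielding_factor: float = 1.47
    conversion_factor_ngy_h_per_cpm: float = 0.00244
    dcf_sv_per_gy: float = 0.7
    hours_per_year: float = 8760.0

    def __post_init__(self) -> None:
        for name in ("shielding_factor", "conversion_factor_ngy_h_per_cpm",
                     "dcf_sv_per_gy", "hours_per_year"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RegionSummary:
    region: str
    n: int
    mean_msv_y: float
    median_msv_y: float
    min_msv_y: float
    max_msv_y: float
    cv_kerma_percent: float
    fraction_above_1msv: float
    radiation_level: str

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a region summary needs at least one point")
        if not (self.min_msv_y <= self.median_msv_y <= self.max_msv_y):
            raise ValueError("min <= median <= max violated")


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need at least two paired observations")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("count and kerma rates must be nonnegative")
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("degenerate fit: all abscissae are zero")
    return float(x @ y / denom)


def fit_shielding_factor(inside_rates, outside_rates) -> float:
    """Through-origin slope of outside vs inside count rates."""
    return _through_origin_slope(inside_rates, outside_rates)


def fit_conversion_factor(total_cpm, kerma_ngy_h) -> float:
    """Through-origin slope of air kerma rate vs total count rate (cpm)."""
    return _through_origin_slope(total_cpm, kerma_ngy_h)


def kerma_from_counts(counts_30s, constants: CalibrationConstants | None = None,
                      ):
    """Outdoor air kerma rate from a 30-s inside count (scalar or array)."""
    constants = constants or CalibrationConstants()
    n = np.asarray(counts_30s, dtype=float)
    if np.any(n < 0):
        raise ValueError("counts must be nonnegative")
    k = (2.0 * n * constants.shielding_factor
         * constants.conversion_factor_ngy_h_per_cpm)
    return float(k) if np.isscalar(counts_30s) else k


def annual_effective_dose(kerma_ngy_h, constants: CalibrationConstants | None = None,
                          ):
    """Annual effective dose in mSv/y from an outdoor kerma rate in nGy/h."""
    constants = constants or CalibrationConstants()
    k = np.asarray(kerma_ngy_h, dtype=float)
    if np.any(k < 0):
        raise ValueError("kerma rate must be nonnegative")
    h = k * constants.dcf_sv_per_gy * constants.hours_per_year * 1e-6
    return float(h) if np.isscalar(kerma_ngy_h) else h


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - sig + 1)
    return math.floor(abs(x) / scale + 0.5) * scale * (1 if x > 0 else -1)


def summarize_regions(points: list[SurveyPoint],
                      constants: CalibrationConstants | None = None,
                      levels: dict[str, str] | None = None,
                      ) -> list[RegionSummary]:
    """Per-region annual-dose statistics, mirroring how survey reports
    tabulate Panchayat-level results.

    Every point must carry a region label.  Statistics are reported to
    two significant figures; the coefficient of variation is computed on
    the kerma rates.  An empty label set raises; a region that loses all
    points is simply absent.
    """
    constants = constants or CalibrationConstants()
    levels = levels or {}
    rows: dict[str, list[SurveyPoint]] = {}
    for p in points:
        if p.region is None:
            raise ValueError(f"unlabelled point at ({p.lat}, {p.lon})")
        rows.setdefault(p.region, []).append(p)
    out = []
    for region in sorted(rows):
        pts = rows[region]
        kerma = np.array([
            p.kerma_ngy_h if p.kerma_ngy_h is not None
            else kerma_from_counts(p.counts, constants)
            for p in pts])
        dose = annual_effective_dose(kerma, constants)
        mean_k = float(kerma.mean())
        cv = 100.0 * float(kerma.std(ddof=1)) / mean_k \
            if kerma.size > 1 and mean_k > 0 else 0.0
        out.append(RegionSummary(
            region=region,
            n=len(pts),
            mean_msv_y=round_sig(float(np.mean(dose))),
            median_msv_y=round_sig(float(np.median(dose))),
            min_msv_y=round_sig(float(np.min(dose))),
            max_msv_y=round_sig(float(np.max(dose))),
            cv_kerma_percent=cv,
            fraction_above_1msv=float(np.mean(dose > 1.0)),
            radiation_level=levels.get(region, "unclassified"),
        ))
    return out


def summaries_to_frame(summaries: list[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass(frozen=True)
class DoseGrid:
    """Rasterised survey values on fixed lon/lat cells.

    ``values`` holds the cell mean (NaN where no point fell in the
    cell); ``occupancy`` counts the contributing points.
    """

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    values: np.ndarray      # (n_lat, n_lon)
    occupancy: np.ndarray

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    def argmax_cell(self) -> tuple[int, int]:
        """(lat_index, lon_index) of the occupied cell with the highest
        value."""
        masked = np.where(np.isfinite(self.values), self.values, -np.inf)
        return tuple(np.unravel_index(int(np.argmax(masked)),
                                      self.values.shape))

    def to_frame(self) -> pd.DataFrame:
        ilat, ilon = np.nonzero(self.occupancy > 0)
        return pd.DataFrame({
            "lon": self.lon_centers[ilon],
            "lat": self.lat_centers[ilat],
            "value": self.values[ilat, ilon],
            "n": self.occupancy[ilat, ilon],
        })

    def to_geojson(self) -> dict:
        feats = []
        for ilat, ilon in zip(*np.nonzero(self.occupancy > 0)):
            lo_x, hi_x = self.lon_edges[ilon], self.lon_edges[ilon + 1]
            lo_y, hi_y = self.lat_edges[ilat], self.lat_edges[ilat + 1]
            feats.append({
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[lo_x, lo_y], [hi_x, lo_y], [hi_x, hi_y],
                                     [lo_x, hi_y], [lo_x, lo_y]]],
                },
                "properties": {
                    "value": float(self.values[ilat, ilon]),
                    "n": int(self.occupancy[ilat, ilon]),
                },
            })
        return {"type": "FeatureCollection", "features": feats}


def grid_dose_map(points: list[SurveyPoint], cell_deg: float = 0.005,
                  value: str = "kerma",
                  constants: CalibrationConstants | None = None) -> DoseGrid:
    """Average point values onto fixed-size lon/lat cells.

    ``value`` selects ``"kerma"`` (nGy/h) or ``"dose"`` (mSv/y).  Cell
    edges are anchored to multiples of ``cell_deg`` so translating all
    points by a whole number of cells translates the raster identically.
    """
    if not points:
        raise ValueError("need at least one survey point")
    constants = constants or CalibrationConstants()
    lon = np.array([p.lon for p in points])
    lat = np.array([p.lat for p in points])
    kerma = np.array([
        p.kerma_ngy_h if p.kerma_ngy_h is not None
        else kerma_from_counts(p.counts, constants)
        for p in points])
    vals = annual_effective_dose(kerma, constants) if value == "dose" else kerma

    def edges(coord):
        # 1e-6-cell epsilon keeps the anchoring stable against float
        # representation of coordinates that are exact cell multiples
        lo = math.floor(coord.min() / cell_deg + 1e-6) * cell_deg
        hi = math.ceil(coord.max() / cell_deg - 1e-6) * cell_deg + cell_deg / 2
        return np.arange(lo, hi + cell_deg / 2, cell_deg)

    lon_e, lat_e = edges(lon), edges(lat)
    ix = np.clip(np.searchsorted(lon_e, lon, side="right") - 1,
                 0, lon_e.size - 2)
    iy = np.clip(np.searchsorted(lat_e, lat, side="right") - 1,
                 0, lat_e.size - 2)
    occ = np.zeros((lat_e.size - 1, lon_e.size - 1), dtype=int)
    acc = np.zeros_like(occ, dtype=float)
    np.add.at(occ, (iy, ix), 1)
    np.add.at(acc, (iy, ix), vals)
    with np.errstate(invalid="ignore"):
        mean = np.where(occ > 0, acc / np.maximum(occ, 1), np.nan)
    return DoseGrid(lon_e, lat_e, mean, occ)


def assign_regions_by_polygon(points: list[SurveyPoint],
                              feature_collection: dict) -> list[SurveyPoint]:
    """Label points with the name of the GeoJSON polygon containing
    them.  Features need a ``name`` property; points outside every
    polygon keep their existing label."""
    from shapely.geometry import Point, shape

    polys = [(f["properties"]["name"], shape(f["geometry"]))
             for f in feature_collection["features"]]
    out = []
    for p in points:
        label = p.region
        pt = Point(p.lon, p.lat)
        for name, poly in polys:
            if poly.contains(pt):
                label = name
                break
        out.append(SurveyPoint(p.timestamp, p.lat, p.lon, p.counts,
                               region=label, kerma_ngy_h=p.kerma_ngy_h))
    return out
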