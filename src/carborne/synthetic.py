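"""Synthetic measurement generator.

No raw survey data accompany this package, so every input the pipeline
consumes is generated here with known ground truth: spot pulse-height
spectra on 1024 channels (photopeaks, Compton continua, cosmic and
photomultiplier K-40 backgrounds, gain drift, Poisson noise) and 30-s
car-borne count/GPS tracks over a heterogeneous activity field with
coastal Th-232 hotspots.

The spot-spectrum forward model is the same analytic detector response
used by the unfolding stage, evaluated on channel energy edges instead
of the 22 analysis bins, so a noiseless simulation round-trips through
the analysis chain by construction and a noisy one differs only by
counting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import EnergyCalibration, PulseHeightSpectrum
from .response import (
    EnergyBinScheme,
    ResolutionModel,
    ResponseMatrix,
    UnitFluxLibrary,
    _response_column,
    build_energy_bins,
)
from .nucdata import NUCLIDES
from .survey import CalibrationConstants, SurveyPoint
from .unfolding import COSMIC_THRESHOLD_MEV

__all__ = [
    "GroundTruthScene",
    "Hotspot",
    "ActivityField",
    "DEFAULT_KERMA_COEFFICIENTS",
    "simulate_spot_spectrum",
    "expected_spot_counts",
    "channel_response",
    "cosmic_channel_rate",
    "pmt_channel_rate",
    "pmt_background_rate",
    "make_activity_field",
    "coastal_strip_field",
    "serpentine_route",
    "simulate_survey_track",
    "M_PER_DEG_LAT",
]

#: air kerma rate per unit activity for a semi-infinite ground source,
#: nGy/h per Bq/kg — standard literature conversion coefficients, used by
#: the track simulator so it does not depend on a Monte Carlo run
DEFAULT_KERMA_COEFFICIENTS = {
    "K40": 0.0417,
    "U238_series": 0.462,
    "Th232_series": 0.604,
}

M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class GroundTruthScene:
    """Everything needed to simulate one spot measurement."""

    activities_bq_kg: dict[str, float]
    surface: str = "soil"
    cosmic_bin22_cps: float = 0.3
    pmt_k40_cps: float = 1.0
    gain_ch_per_mev: float = 300.0
    offset_ch: float = 0.0
    fwhm_frac_662: float = 0.075
    live_time_s: float = 300.0
    seed: int = 0
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.surface not in ("soil", "grass", "sand"):
            raise ValueError(f"unknown surface {self.surface!r}")
        for n, a in self.activities_bq_kg.items():
            if n not in NUCLIDES:
                raise ValueError(f"unknown nuclide {n!r}")
            if a < 0:
                raise ValueError("activities must be nonnegative")
        if self.live_time_s <= 0 or self.gain_ch_per_mev <= 0:
            raise ValueError("live time and gain must be positive")
        if self.cosmic_bin22_cps < 0 or self.pmt_k40_cps < 0:
            raise ValueError("background rates must be nonnegative")

    @property
    def activity_vector(self) -> np.ndarray:
        return np.array([self.activities_bq_kg.get(n, 0.0) for n in NUCLIDES])

    @property
    def calibration(self) -> EnergyCalibration:
        return EnergyCalibration(self.gain_ch_per_mev, self.offset_ch)

    @property
    def resolution(self) -> ResolutionModel:
        return ResolutionModel(self.fwhm_frac_662)


def _channel_energy_edges(calibration: EnergyCalibration,
                          n_channels: int) -> np.ndarray:
    ch_edges = np.arange(n_channels + 1, dtype=float) - 0.5
    return calibration.energy_of(ch_edges)


def channel_response(bins: EnergyBinScheme, calibration: EnergyCalibration,
                     resolution: ResolutionModel,
                     n_channels: int = 1024) -> np.ndarray:
    """(n_channels, 22) response: counts per channel per unit incident
    flux density in each energy bin — the channel-resolution analogue of
    the 22x22 analysis matrix."""
    edges = _channel_energy_edges(calibration, n_channels)
    cols = [_response_column(e, edges, resolution)
            for e in bins.representative_energies]
    return np.column_stack(cols)


def cosmic_channel_rate(calibration: EnergyCalibration, bin22_cps: float,
                        n_channels: int = 1024,
                        bins: EnergyBinScheme | None = None) -> np.ndarray:
    """Cosmic continuum in channel space: flat in energy between
    0.5 MeV and the top of the analysis range, with amplitude set by its
    content in the 3.0-3.2 MeV index bin."""
    bins = bins or build_energy_bins()
    e_lo, e_hi = COSMIC_THRESHOLD_MEV, float(bins.edges[-1])
    bin22_width = float(bins.edges[-1] - bins.edges[-2])
    rate_per_mev = bin22_cps / bin22_width
    edges = _channel_energy_edges(calibration, n_channels)
    lo = np.clip(edges[:-1], e_lo, e_hi)
    hi = np.clip(edges[1:], e_lo, e_hi)
    return rate_per_mev * np.clip(hi - lo, 0.0, None)


def _pmt_shape(out_edges: np.ndarray, resolution: ResolutionModel) -> np.ndarray:
    col = _response_column(1.464, out_edges, resolution)
    s = col.sum()
    return col / s if s > 0 else col


def pmt_channel_rate(calibration: EnergyCalibration,
                     resolution: ResolutionModel, pmt_cps: float,
                     n_channels: int = 1024) -> np.ndarray:
    """Photomultiplier K-40 contamination in channel space: a pure K-40
    response shape normalised to ``pmt_cps`` total counts per second."""
    edges = _channel_energy_edges(calibration, n_channels)
    return pmt_cps * _pmt_shape(edges, resolution)


def pmt_background_rate(bins: EnergyBinScheme, resolution: ResolutionModel,
                        pmt_cps: float) -> np.ndarray:
    """The same instrument background expressed on the 22 analysis bins
    (what a background measurement of this instrument would yield)."""
    return pmt_cps * _pmt_shape(bins.edges, resolution)


def expected_spot_counts(scene: GroundTruthScene, response: ResponseMatrix,
                         flux_library: UnitFluxLibrary,
                         n_channels: int = 1024) -> np.ndarray:
    """Noise-free expected channel counts for a scene."""
    if not np.allclose(response.bins.edges, flux_library.bins.edges):
        raise ValueError(
            "response matrix and flux library use different bin edges")
    calib = scene.calibration
    r_ch = channel_response(response.bins, calib, scene.resolution, n_channels)
    flux = flux_library.flux.T @ scene.activity_vector
    rate = (r_ch @ flux
            + cosmic_channel_rate(calib, scene.cosmic_bin22_cps, n_channels,
                                  response.bins)
            + pmt_channel_rate(calib, scene.resolution, scene.pmt_k40_cps,
                               n_channels))
    return scene.live_time_s * rate


def simulate_spot_spectrum(scene: GroundTruthScene, response: ResponseMatrix,
                           flux_library: UnitFluxLibrary,
                           n_channels: int = 1024,
                           poisson: bool = True) -> PulseHeightSpectrum:
    """Simulate a spot pulse-height spectrum.

    Expected channel counts are live time x (response applied to the
    activity-weighted unit fluxes + cosmic template + PMT template),
    Poisson-sampled with the scene seed (or rounded when
    ``poisson=False`` for noise-free checks).
    """
    expected = expected_spot_counts(scene, response, flux_library, n_channels)
    if poisson:
        rng = np.random.default_rng(scene.seed)
        counts = rng.poisson(expected)
    else:
        counts = np.round(expected).astype(np.int64)
    return PulseHeightSpectrum(
        counts=counts,
        live_time_s=scene.live_time_s,
        gain_hint_ch_per_mev=scene.gain_ch_per_mev,
        lat=scene.lat, lon=scene.lon,
    )


# --- activity fields and car-borne tracks ----------------------------------


@dataclass(frozen=True)
class Hotspot:
    """Gaussian activity anomaly (a monazite-sand patch, for instance)."""

    lon: float
    lat: float
    radius_deg: float
    peak_bq_kg: dict[str, float]

    def __post_init__(self) -> None:
        if self.radius_deg <= 0:
            raise ValueError("hotspot radius must be positive")
        if any(v < 0 for v in self.peak_bq_kg.values()):
            raise ValueError("hotspot peaks must be nonnegative")


@dataclass(frozen=True)
class ActivityField:
    """Per-nuclide activity concentration on a lon/lat grid (Bq/kg)."""

    lon_edges: np.ndarray
    lat_edges: np.ndarray
    activity: dict[str, np.ndarray]   # (n_lat, n_lon) each
    hotspots: tuple[Hotspot, ...] = ()

    def __post_init__(self) -> None:
        for n, g in self.activity.items():
            if np.any(g < 0):
                raise ValueError(f"negative activity in field for {n}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (float(self.lon_edges[0]), float(self.lon_edges[-1]),
                float(self.lat_edges[0]), float(self.lat_edges[-1]))

    def contains(self, lon, lat) -> np.ndarray:
        w, e, s, n = self.extent
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        return (lon >= w) & (lon <= e) & (lat >= s) & (lat <= n)

    def activity_at(self, lon, lat, nuclide: str) -> np.ndarray:
        """Nearest-cell lookup of the activity concentration."""
        g = self.activity[nuclide]
        ix = np.clip(np.searchsorted(self.lon_edges, lon, side="right") - 1,
                     0, g.shape[1] - 1)
        iy = np.clip(np.searchsorted(self.lat_edges, lat, side="right") - 1,
                     0, g.shape[0] - 1)
        return g[iy, ix]

    def kerma_at(self, lon, lat,
                 kerma_coefficients: dict[str, float] | None = None,
                 ) -> np.ndarray:
        """Outdoor air kerma rate (nGy/h) from the local activities."""
        coeffs = {**DEFAULT_KERMA_COEFFICIENTS, **(kerma_coefficients or {})}
        lon = np.asarray(lon, float)
        total = np.zeros(np.broadcast(lon, np.asarray(lat, float)).shape)
        for n in self.activity:
            total = total + coeffs[n] * self.activity_at(lon, lat, n)
        return total

    def kerma_grid(self, kerma_coefficients: dict[str, float] | None = None,
                   ) -> np.ndarray:
        coeffs = {**DEFAULT_KERMA_COEFFICIENTS, **(kerma_coefficients or {})}
        return sum(coeffs[n] * g for n, g in self.activity.items())


def make_activity_field(background_bq_kg: dict[str, float],
                        hotspots: list[Hotspot] | None = None,
                        extent: tuple[float, float, float, float] = (
                            76.45, 76.65, 8.95, 9.15),
                        n_lon: int = 120, n_lat: int = 120,
                        background_cv: float = 0.0,
                        seed: int = 0) -> ActivityField:
    """Smooth background plus Gaussian hotspots on a lon/lat grid.

    ``background_cv`` adds a smooth lognormal-ish spatial modulation of
    the background (coarse noise, bilinearly upsampled) with that
    coefficient of variation; 0 gives an exactly constant background.
    """
    if n_lon < 2 or n_lat < 2:
        raise ValueError("grid must have at least 2x2 cells")
    for n, a in background_bq_kg.items():
        if n not in NUCLIDES:
            raise ValueError(f"unknown nuclide {n!r}")
        if a < 0:
            raise ValueError("background activities must be nonnegative")
    hotspots = list(hotspots or [])
    w, e, s, nn = extent
    lon_edges = np.linspace(w, e, n_lon + 1)
    lat_edges = np.linspace(s, nn, n_lat + 1)
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    glon, glat = np.meshgrid(lon_c, lat_c)

    rng = np.random.default_rng(seed)
    if background_cv > 0:
        coarse = rng.normal(0.0, 1.0, (6, 6))
        yi = np.linspace(0, 5, n_lat)
        xi = np.linspace(0, 5, n_lon)
        # separable bilinear upsample of the coarse noise
        rows = np.empty((6, n_lon))
        for r in range(6):
            rows[r] = np.interp(xi, np.arange(6), coarse[r])
        smooth = np.empty((n_lat, n_lon))
        for c in range(n_lon):
            smooth[:, c] = np.interp(yi, np.arange(6), rows[:, c])
        modulation = np.exp(background_cv * smooth
                            - 0.5 * background_cv**2)
    else:
        modulation = np.ones((n_lat, n_lon))

    activity = {}
    for n in NUCLIDES:
        base = background_bq_kg.get(n, 0.0)
        g = base * modulation
        for h in hotspots:
            peak = h.peak_bq_kg.get(n, 0.0)
            if peak:
                d2 = (glon - h.lon) ** 2 + (glat - h.lat) ** 2
                g = g + peak * np.exp(-0.5 * d2 / h.radius_deg**2)
        activity[n] = g
    return ActivityField(lon_edges, lat_edges, activity, tuple(hotspots))


def coastal_strip_field(seed: int = 0, coast_lon: float = 76.52,
                        ) -> tuple[ActivityField, float]:
    """Preset field emulating a coastal high-background strip: typical
    soil activities inland, monazite-like Th-232 hotspots hugging the
    west (coastal) edge.  Returns the field and the coast longitude that
    separates the ``coastal`` and ``inland`` report regions."""
    hotspots = [
        Hotspot(76.468, 8.993, 0.010, {"Th232_series": 2300.0,
                                       "U238_series": 1200.0, "K40": 900.0}),
        Hotspot(76.470, 9.045, 0.008, {"Th232_series": 1500.0,
                                       "U238_series": 800.0}),
        Hotspot(76.472, 9.105, 0.007, {"Th232_series": 900.0,
                                       "U238_series": 450.0}),
    ]
    field_ = make_activity_field(
        {"K40": 400.0, "U238_series": 35.0, "Th232_series": 60.0},
        hotspots=hotspots, background_cv=0.10, seed=seed)
    return field_, coast_lon


def serpentine_route(extent: tuple[float, float, float, float] | None = None,
                     n_legs: int = 6, margin: float = 0.01) -> np.ndarray:
    """North-south serpentine polyline covering an extent, as (lon, lat)
    vertices — a stand-in for a road network that visits the whole area."""
    if extent is None:
        extent = (76.45, 76.65, 8.95, 9.15)
    w, e, s, n = extent
    lons = np.linspace(w + margin, e - margin, n_legs)
    verts = []
    for i, lo in enumerate(lons):
        if i % 2 == 0:
            verts += [(lo, s + margin), (lo, n - margin)]
        else:
            verts += [(lo, n - margin), (lo, s + margin)]
    return np.array(verts)


def _local_scale(lat0: float) -> tuple[float, float]:
    """metres per degree of (lon, lat) under a local equirectangular map."""
    return (M_PER_DEG_LAT * np.cos(np.deg2rad(lat0)), M_PER_DEG_LAT)


def simulate_survey_track(field: ActivityField, route: np.ndarray,
                          speed_kmh: float = 40.0, interval_s: float = 30.0,
                          constants: CalibrationConstants | None = None,
                          kerma_coefficients: dict[str, float] | None = None,
                          seed: int = 0,
                          start_time: str = "2013-09-23T09:00:00",
                          ) -> list[SurveyPoint]:
    """Drive a polyline over the field and record 30-s inside counts.

    Points are spaced ``speed x interval`` apart along the route.  The
    expected inside count is local kerma / (shielding x conversion) x
    interval/60 — the inverse of the count-to-kerma relation — and is
    Poisson-sampled.
    """
    if interval_s <= 0 or speed_kmh <= 0:
        raise ValueError("speed and interval must be positive")
    constants = constants or CalibrationConstants()
    route = np.asarray(route, dtype=float)
    if route.ndim != 2 or route.shape[1] != 2 or route.shape[0] < 2:
        raise ValueError("route must be an (n, 2) polyline of (lon, lat)")
    inside = field.contains(route[:, 0], route[:, 1])
    if not np.all(inside):
        bad = int(np.nonzero(~inside)[0][0])
        raise ValueError(
            f"route vertex {bad} at (lon={route[bad, 0]:.4f}, "
            f"lat={route[bad, 1]:.4f}) lies outside the activity field")

    lat0 = 0.5 * (field.extent[2] + field.extent[3])
    mx, my = _local_scale(lat0)
    deltas = np.diff(route, axis=0)
    seg_len = np.hypot(deltas[:, 0] * mx, deltas[:, 1] * my)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    step_m = speed_kmh / 3.6 * interval_s
    distances = np.arange(0.0, cum[-1], step_m)
    lon = np.interp(distances, cum, route[:, 0])
    lat = np.interp(distances, cum, route[:, 1])

    kerma = field.kerma_at(lon, lat, kerma_coefficients)
    denom = (constants.shielding_factor
             * constants.conversion_factor_ngy_h_per_cpm)
    expected = kerma / denom * (interval_s / 60.0)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)

    t0 = np.datetime64(start_time)
    points = []
    for i in range(distances.size):
        ts = str(t0 + np.timedelta64(int(round(i * interval_s)), "s"))
        points.append(SurveyPoint(ts, float(lat[i]), float(lon[i]),
                                  int(counts[i])))
    return points
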