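"""File dialects and pipeline configuration.

Spectra travel as a small SPE-like two-column text dialect::

    #CARBORNE SPE 1
    #live_time_s 300
    #gain_hint_ch_per_mev 300
    #channels 1024
    # optional: timestamp / lat / lon
    0 12
    1 17
    ...

Tracks are CSV with columns ``iso_time, lat, lon, counts_30s``; spot
activity estimates are emitted as a CSV mirroring the layout of the
published spot table.  The pipeline configuration is a flat dataclass
that round-trips losslessly through YAML and is hashed into every
artifact for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .calibration import PulseHeightSpectrum
from .survey import SurveyPoint
from .unfolding import ActivityEstimate

__all__ = [
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_track",
    "write_track",
    "estimates_to_frame",
    "write_estimates",
    "PipelineConfig",
]

_SPE_MAGIC = "#CARBORNE SPE 1"


class SpectrumFormatError(ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_spectrum(spectrum: PulseHeightSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(_SPE_MAGIC + "\n")
        fh.write(f"#live_time_s {spectrum.live_time_s:.6g}\n")
        if spectrum.gain_hint_ch_per_mev is not None:
            fh.write(f"#gain_hint_ch_per_mev "
                     f"{spectrum.gain_hint_ch_per_mev:.6g}\n")
        fh.write(f"#channels {spectrum.n_channels}\n")
        if spectrum.timestamp is not None:
            fh.write(f"#timestamp {spectrum.timestamp}\n")
        if spectrum.lat is not None:
            fh.write(f"#lat {spectrum.lat:.6f}\n")
        if spectrum.lon is not None:
            fh.write(f"#lon {spectrum.lon:.6f}\n")
        for i, c in enumerate(spectrum.counts):
            fh.write(f"{i} {int(c)}\n")


def read_spectrum(path) -> PulseHeightSpectrum:
    header: dict[str, str] = {}
    counts: list[int] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _SPE_MAGIC:
            raise SpectrumFormatError(
                f"expected {_SPE_MAGIC!r}, got {first!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if len(parts) != 2:
                    raise SpectrumFormatError(
                        f"malformed header {line!r}", lineno)
                header[parts[0]] = parts[1]
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"expected 'channel count', got {line!r}", lineno)
            try:
                ch, c = int(parts[0]), int(parts[1])
            except ValueError:
                raise SpectrumFormatError(
                    f"non-integer data {line!r}", lineno) from None
            if ch != len(counts):
                raise SpectrumFormatError(
                    f"channel {ch} out of order", lineno)
            counts.append(c)
    if "live_time_s" not in header:
        raise SpectrumFormatError("missing live_time_s header", 1)
    n_declared = header.get("channels")
    if n_declared is not None and int(n_declared) != len(counts):
        raise SpectrumFormatError(
            f"declared {n_declared} channels, found {len(counts)}", 1)
    return PulseHeightSpectrum(
        counts=np.array(counts, dtype=np.int64),
        live_time_s=float(header["live_time_s"]),
        gain_hint_ch_per_mev=(float(header["gain_hint_ch_per_mev"])
                              if "gain_hint_ch_per_mev" in header else None),
        timestamp=header.get("timestamp"),
        lat=float(header["lat"]) if "lat" in header else None,
        lon=float(header["lon"]) if "lon" in header else None,
    )


def write_track(points: list[SurveyPoint], path) -> None:
    df = pd.DataFrame({
        "iso_time": [p.timestamp for p in points],
        "lat": [p.lat for p in points],
        "lon": [p.lon for p in points],
        "counts_30s": [p.counts for p in points],
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_track(path) -> list[SurveyPoint]:
    df = pd.read_csv(path)
    required = {"iso_time", "lat", "lon", "counts_30s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track file missing columns: {sorted(missing)}")
    return [SurveyPoint(str(r.iso_time), float(r.lat), float(r.lon),
                        int(r.counts_30s))
            for r in df.itertuples()]


def estimates_to_frame(estimates: list[ActivityEstimate]) -> pd.DataFrame:
    """Spot estimates as a table mirroring the published layout: location,
    per-nuclide kerma, total, percentage contributions, activities with
    errors, surface class."""
    rows = []
    for e in estimates:
        a = e.activities_bq_kg
        k = e.kerma_components_ngy_h
        rows.append({
            "lat": e.lat, "lon": e.lon,
            "kerma_k40": k[0], "kerma_u238": k[1], "kerma_th232": k[2],
            "kerma_total": e.total_kerma_ngy_h,
            "contrib_k40": e.contributions_percent[0],
            "contrib_u238": e.contributions_percent[1],
            "contrib_th232": e.contributions_percent[2],
            "activity_k40": a[0], "activity_u238": a[1], "activity_th232": a[2],
            "activity_k40_err_pct": e.percent_errors[0],
            "activity_u238_err_pct": e.percent_errors[1],
            "activity_th232_err_pct": e.percent_errors[2],
            "surface": e.surface,
            "flags": ";".join(e.flags),
        })
    return pd.DataFrame(rows)


def write_estimates(estimates: list[ActivityEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False,
                                         float_format="%.4f")


@dataclass
class PipelineConfig:
    """Every knob of the synthetic end-to-end pipeline, with defaults.

    Defaults reproduce the survey's stated operating conditions: 30-s
    mobile counts at ~40 km/h, 300-s spot spectra, Eq-1/Eq-2 constants.
    """

    seed: int = 0
    # physics / response
    mc_histories: int = 200_000
    fwhm_frac_662: float = 0.075
    # calibration
    smoothing_terms: int = 128
    gain_ch_per_mev: float = 300.0
    # synthetic scenes
    spot_live_time_s: float = 300.0
    cosmic_bin22_cps: float = 0.3
    pmt_k40_cps: float = 1.0
    n_spots: int = 6
    # survey
    speed_kmh: float = 40.0
    interval_s: float = 30.0
    shielding_factor: float = 1.47
    conversion_factor_ngy_h_per_cpm: float = 0.00244
    dcf_sv_per_gy: float = 0.7
    hours_per_year: float = 8760.0
    map_cell_deg: float = 0.005
    # iteration control
    activity_tol: float = 1e-3
    out_dir: str = "carborne_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location does
        not influence results and is excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
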