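"""Published spot-measurement and regional-dose tables.

The package ships the two small tables printed in the Karunagappally
Taluk car-borne survey report: the 32 spot measurements (air-kerma
decomposition, percentage contributions and activity concentrations on
soil/grass/sand surfaces) and the per-Panchayat annual effective dose
summary.  The raw 2053-point mobile dataset was never deposited, so
these tables are the only real data the pipeline can consume directly;
they anchor the dose arithmetic and the kerma-per-activity ratios.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_spot_measurements",
    "load_panchayat_doses",
    "check_spot_consistency",
    "implied_kerma_coefficients",
]

_NUC_COLS = ("k40", "u238", "th232")


def _read(name: str) -> pd.DataFrame:
    with resources.files("carborne.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_spot_measurements() -> pd.DataFrame:
    """The 32 spot measurements: per-nuclide kerma rates (nGy/h),
    integer percentage contributions, activity concentrations (Bq/kg)
    with absolute errors, surface class and coordinates."""
    return _read("spot_measurements.csv")


def load_panchayat_doses() -> pd.DataFrame:
    """Annual effective dose statistics (mSv/y) per Panchayat."""
    return _read("panchayat_doses.csv")


def check_spot_consistency(df: pd.DataFrame | None = None) -> dict:
    """Internal-consistency audit of the spot table.

    Returns counts of rows whose printed total equals the component sum
    exactly, and whose percentage contributions are reproduced from the
    printed components — exactly, and within +-1 %.  The printed
    percentages were evidently computed before the components were
    rounded to integer nGy/h, so a +-1 slack is inherent in the table
    itself.
    """
    df = load_spot_measurements() if df is None else df
    comps = df[[f"kerma_{n}" for n in _NUC_COLS]].to_numpy(float)
    totals = df["kerma_total"].to_numpy(float)
    printed_pct = df[[f"contrib_{n}" for n in _NUC_COLS]].to_numpy(int)

    sums_exact = int(np.sum(comps.sum(axis=1) == totals))
    recomputed = np.floor(100.0 * comps / totals[:, None] + 0.5).astype(int)
    rows_exact = int(np.sum(np.all(recomputed == printed_pct, axis=1)))
    rows_within_1 = int(np.sum(
        np.all(np.abs(recomputed - printed_pct) <= 1, axis=1)))

    th_pct = printed_pct[:, 2]
    above = totals > 340.0
    return {
        "n_rows": len(df),
        "totals_exact": sums_exact,
        "percent_rows_exact": rows_exact,
        "percent_rows_within_1": rows_within_1,
        "th_percent_min": int(th_pct.min()),
        "th_percent_max": int(th_pct.max()),
        "th_percent_min_above_340": int(th_pct[above].min()),
        "max_total_ngy_h": float(totals.max()),
    }


def implied_kerma_coefficients(df: pd.DataFrame | None = None) -> dict:
    """Kerma rate per unit activity implied by the printed rows
    (component / activity, nGy/h per Bq/kg), averaged over the rows
    where both entries are well above rounding noise."""
    df = load_spot_measurements() if df is None else df
    out = {}
    for col, nuclide in zip(_NUC_COLS, ("K40", "U238_series", "Th232_series")):
        k = df[f"kerma_{col}"].to_numpy(float)
        a = df[f"activity_{col}"].to_numpy(float)
        mask = k >= 10.0  # integer rounding dominates below this
        out[nuclide] = float(np.mean(k[mask] / a[mask]))
    return out
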