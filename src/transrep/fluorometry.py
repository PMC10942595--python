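"""Bulk plate-reader quantification.

Expression is quantified the way the wet-lab protocol prescribes: blank
(medium-only) trajectories are subtracted per channel; normalized
fluorescence is the least-squares slope of fluorescence against absorbance
(valid when fluorophore maturation is fast relative to doubling and there is
no proteolysis), minus an autofluorescence constant; growth rate is the
slope of log absorbance against time in exponential phase.  The Crick-space
decomposition splits expression changes into a translation-rate proxy
(green/red ratio) and a transcription-rate proxy (red times growth rate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "PLATE_COLUMNS",
    "background_correct",
    "normalized_fluorescence",
    "growth_rate",
    "exponential_window",
    "crick_decompose",
    "quantify_plate",
]

PLATE_COLUMNS = ("time_h", "well", "od600", "green_au", "red_au",
                 "dose_uM", "replicate", "is_blank")
_CHANNELS = ("od600", "green_au", "red_au")


def validate_plate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    return df


def background_correct(series: pd.DataFrame) -> pd.DataFrame:
    """Subtract the mean blank-well trajectory from every channel.

    Blank wells are those flagged ``is_blank``; with no blanks the input is
    returned unchanged (so the correction is idempotent on pre-corrected
    data carrying zero blanks).
    """
    series = validate_plate(series)
    blanks = series[series["is_blank"]]
    if blanks.empty:
        return series.copy()
    mean_blank = blanks.groupby("time_h")[list(_CHANNELS)].mean()
    out = series.copy()
    for ch in _CHANNELS:
        out[ch] = out[ch] - out["time_h"].map(mean_blank[ch]).to_numpy()
    return out


def normalized_fluorescence(
    od600,
    fluorescence,
    autofluorescence: float = 0.0,
    od_floor: float = 0.01,
) -> float:
    """Expression estimate: slope of fluorescence vs absorbance (AU per OD),
    minus the autofluorescence of non-transformed cells.

    Points with OD at or below ``od_floor`` are excluded, since early
    noise-dominated readings destabilize the regression.
    """
    od = np.asarray(od600, dtype=float)
    fl = np.asarray(fluorescence, dtype=float)
    keep = od > od_floor
    if keep.sum() < 3:
        raise ValueError("need >= 3 points above the OD floor for the regression")
    slope = linregress(od[keep], fl[keep]).slope
    return float(slope) - autofluorescence


def exponential_window(time_h, od600, min_points: int = 4, r2_min: float = 0.99):
    """Longest contiguous window where log OD is linear in time (R^2 >= r2_min).

    Returns (start_index, stop_index) as a half-open slice into the series.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if np.any(od <= 0):
        raise ValueError("OD must be positive to take logarithms")
    log_od = np.log(od)
    best = None
    n = len(t)
    for i in range(n):
        for j in range(i + min_points, n + 1):
            r = linregress(t[i:j], log_od[i:j])
            if r.rvalue**2 >= r2_min and (best is None or j - i > best[1] - best[0]):
                best = (i, j)
    if best is None:
        raise ValueError("no log-linear window found; supply one explicitly")
    return best


def growth_rate(time_h, od600, window: tuple[int, int] | None = None) -> float:
    """Specific growth rate (per h): slope of ln OD vs time.

    ``window`` is a half-open index range into the series; by default the
    longest log-linear stretch found by ``exponential_window`` is used.
    """
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if window is None:
        window = exponential_window(t, od)
    i, j = window
    seg_od = od[i:j]
    if np.any(seg_od <= 0):
        raise ValueError("OD must be positive inside the regression window")
    if j - i < 3:
        raise ValueError("need >= 3 points in the growth-rate window")
    return float(linregress(t[i:j], np.log(seg_od)).slope)


def crick_decompose(green_norm: float, red_norm: float, growth_rate_per_h: float):
    """Decompose expression into (translation proxy, transcription proxy).

    The red reporter shares the green reporter's promoter but is not
    translationally regulated, so red x growth rate tracks transcription
    (AU/h) while green/red isolates translation.
    """
    if red_norm <= 0:
        raise ValueError("red_norm must be > 0 for the ratio proxy")
    return green_norm / red_norm, red_norm * growth_rate_per_h


def quantify_plate(
    series: pd.DataFrame,
    autofluorescence_green: float = 0.0,
    autofluorescence_red: float = 0.0,
    od_floor: float = 0.01,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Full pipeline per non-blank well: correct, regress, decompose.

    Returns one row per well with normalized green/red expression, growth
    rate, and the Crick-space proxies.  Replicate aggregation is left to the
    caller (per-replicate fits are the default convention).
    """
    corrected = background_correct(series)
    rows = []
    for well, sub in corrected[~corrected["is_blank"]].groupby("well"):
        sub = sub.sort_values("time_h")
        green = normalized_fluorescence(sub["od600"], sub["green_au"],
                                        autofluorescence_green, od_floor)
        red = normalized_fluorescence(sub["od600"], sub["red_au"],
                                      autofluorescence_red, od_floor)
        mu = growth_rate(sub["time_h"], sub["od600"], window)
        tl, tc = crick_decompose(green, red, mu)
        rows.append({
            "well": well,
            "dose_uM": sub["dose_uM"].iloc[0],
            "replicate": sub["replicate"].iloc[0],
            "green_norm": green,
            "red_norm": red,
            "growth_rate_per_h": mu,
            "translation_proxy": tl,
            "transcription_proxy": tc,
        })
    return pd.DataFrame(rows)
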