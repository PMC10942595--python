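"""Hill dose-response models and fitting.

Empirical four-parameter Hill curves describe reporter expression against an
inducer dose (lactose/IPTG driving expression of the repressor protein), and
a two-parameter inhibition curve describes allosteric inactivation of the
repressor by a fatty-acid ligand (half-maximal inhibitory concentration
IC50).  Fitting is ordinary least squares on the linear response scale via
lmfit, with rescaling-invariant parameterization: multiplying all responses
by a constant scales the plateaus and leaves K and n untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import lmfit

__all__ = [
    "HillCurve",
    "InhibitionCurve",
    "HillFitResult",
    "hill_eval",
    "fit_hill",
    "active_fraction",
    "fit_inhibition",
    "validate_dose_table",
]

DOSE_TABLE_COLUMNS = ("dose_uM", "replicate", "response_au")


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter Hill dose-response.

    ``y_max``/``y_min`` are the upper and lower plateaus (y_max >= y_min);
    for ``direction="repression"`` the response starts at y_max at zero dose
    and falls to y_min, for ``"activation"`` it rises from y_min (basal) to
    y_max (plateau).  ``reg_coeff`` is the regulatory coefficient K — the
    dose at which the response is the exact midpoint of the plateaus — and
    ``hill_n`` the Hill coefficient (apparent cooperativity).
    """

    y_max: float
    y_min: float
    reg_coeff: float
    hill_n: float
    direction: str = "repression"

    def __post_init__(self) -> None:
        if self.direction not in ("repression", "activation"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (self.y_max >= self.y_min >= 0):
            raise ValueError("require y_max >= y_min >= 0")
        if not (self.reg_coeff > 0):
            raise ValueError("reg_coeff must be > 0")
        if not (self.hill_n > 0):
            raise ValueError("hill_n must be > 0")

    @property
    def fold(self) -> float:
        """Dynamic range y_max / y_min (infinite for a fully-off floor)."""
        return math.inf if self.y_min == 0 else self.y_max / self.y_min


def hill_eval(curve: HillCurve, dose) -> np.ndarray | float:
    """Evaluate the Hill curve at one dose or an array of doses (same units as K)."""
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    k, n = curve.reg_coeff, curve.hill_n
    with np.errstate(divide="ignore"):
        occ = x**n / (k**n + x**n)  # fraction of the transition completed
    if curve.direction == "repression":
        y = curve.y_max - (curve.y_max - curve.y_min) * occ
    else:
        y = curve.y_min + (curve.y_max - curve.y_min) * occ
    return float(y) if np.isscalar(dose) else y


@dataclass(frozen=True)
class InhibitionCurve:
    """Allosteric-inhibition dose response: active regulator fraction vs inhibitor.

    ``ic50`` is the half-maximal effective inhibitory concentration (mM) and
    ``slope_m`` the inhibition Hill slope (default 1, single-site binding).
    """

    ic50: float
    slope_m: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ic50 > 0):
            raise ValueError("ic50 must be > 0")
        if not (self.slope_m > 0):
            raise ValueError("slope_m must be > 0")


def active_fraction(inh: InhibitionCurve, inhibitor_dose) -> np.ndarray | float:
    """Fraction of regulator remaining active at a given inhibitor dose (mM)."""
    x = np.asarray(inhibitor_dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("inhibitor dose must be >= 0")
    k, m = inh.ic50, inh.slope_m
    frac = k**m / (k**m + x**m)
    return float(frac) if np.isscalar(inhibitor_dose) else frac


@dataclass(frozen=True)
class HillFitResult:
    curve: HillCurve
    stderr: dict
    r_squared: float
    n_points: int

    @property
    def fold(self) -> float:
        return self.curve.fold


def validate_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a dose-response table against the documented schema."""
    missing = [c for c in DOSE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"dose table missing columns {missing}")
    if (table["dose_uM"] < 0).any():
        raise ValueError("doses must be >= 0")
    if table["dose_uM"].nunique() < 2:
        raise ValueError("need >= 2 distinct doses")
    return table


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_hill(
    table: pd.DataFrame,
    direction: str = "repression",
    fix_n: Optional[float] = None,
) -> HillFitResult:
    """Least-squares fit of a Hill curve to a dose-response table.

    Parameters are initialized from the data (K at the geometric mean of the
    nonzero doses, n = 1, plateaus at the data extremes) and bounded to keep
    K within a decade of the dosed range and n in [0.1, 10].  ``fix_n`` pins
    the Hill coefficient (e.g., 1 for a non-cooperative transfer function).
    """
    table = validate_dose_table(table)
    x = table["dose_uM"].to_numpy(dtype=float)
    y = table["response_au"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate (flat) response data: Hill fit is singular")
    n_free = 4 if fix_n is None else 3
    if np.unique(x).size < n_free:
        raise ValueError(
            f"need >= {n_free} distinct doses for {n_free} free parameters"
        )
    nz = x[x > 0]
    k0 = float(np.exp(np.mean(np.log(nz))))
    lo, hi = float(nz.min()) / 10.0, float(nz.max()) * 10.0

    # fit on unit-normalized responses so the result is exactly invariant
    # to rescaling the response channel; plateaus are scaled back after
    scale = float(np.max(np.abs(y)))
    y = y / scale

    params = lmfit.Parameters()
    params.add("y_max", value=float(y.max()), min=0.0)
    params.add("y_min", value=float(y.min()), min=0.0)
    params.add("k", value=k0, min=lo, max=hi)
    params.add("n", value=1.0 if fix_n is None else float(fix_n), min=0.1, max=10.0,
               vary=fix_n is None)

    # plateau ordering is left soft during optimization and checked after
    def model(p):
        k, n = p["k"].value, p["n"].value
        occ = x**n / (k**n + x**n)
        if direction == "repression":
            return p["y_max"].value - (p["y_max"].value - p["y_min"].value) * occ
        return p["y_min"].value + (p["y_max"].value - p["y_min"].value) * occ

    out = lmfit.minimize(lambda p: model(p) - y, params, method="leastsq",
                         xtol=1e-12, ftol=1e-12)
    if not out.success:
        raise RuntimeError(f"Hill fit did not converge: {out.message}")
    p = out.params
    y_max, y_min = p["y_max"].value * scale, p["y_min"].value * scale
    if y_min > y_max:  # plateau ordering violated: data do not support the direction
        raise RuntimeError(
            "fitted plateaus inverted; check the fit direction or the data"
        )
    curve = HillCurve(y_max, y_min, p["k"].value, p["n"].value, direction)
    yhat = np.asarray(hill_eval(curve, x))
    stderr = {
        "y_max": (p["y_max"].stderr or np.nan) * scale,
        "y_min": (p["y_min"].stderr or np.nan) * scale,
        "reg_coeff": p["k"].stderr,
        "hill_n": p["n"].stderr,
    }
    return HillFitResult(curve, stderr, _r_squared(y * scale, yhat), len(y))


def fit_inhibition(
    table: pd.DataFrame,
    fix_slope: Optional[float] = None,
) -> InhibitionCurve:
    """Fit an inhibition curve to residual activity vs inhibitor dose (mM).

    Expects columns ``dose_mM`` and ``response_au`` (residual binding or
    repression, arbitrary scale; amplitude is a free nuisance parameter).
    """
    for col in ("dose_mM", "response_au"):
        if col not in table.columns:
            raise ValueError(f"inhibition table missing column {col!r}")
    x = table["dose_mM"].to_numpy(dtype=float)
    y = table["response_au"].to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be >= 0")
    if np.ptp(y) == 0 or y.max() <= 0:
        raise ValueError("degenerate inhibition data: no response range")
    nz = x[x > 0]
    params = lmfit.Parameters()
    params.add("amp", value=float(y.max()), min=0.0)
    params.add("ic50", value=float(np.exp(np.mean(np.log(nz)))),
               min=float(nz.min()) / 10.0, max=float(nz.max()) * 10.0)
    params.add("m", value=1.0 if fix_slope is None else float(fix_slope),
               min=0.1, max=10.0, vary=fix_slope is None)

    def resid(p):
        inh = InhibitionCurve(p["ic50"].value, p["m"].value)
        return p["amp"].value * np.asarray(active_fraction(inh, x)) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"inhibition fit did not converge: {out.message}")
    return InhibitionCurve(out.params["ic50"].value, out.params["m"].value)
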