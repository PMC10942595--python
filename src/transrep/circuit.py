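"""Bottom-up ODE model of the inducer -> repressor -> reporter cascade.

The cascade: an inducer (lactose/IPTG) relieves LacI repression of the
RNA-binding protein (the translation repressor); the repressor binds the
constitutively transcribed reporter mRNA under quasi-equilibrium and scales
its translation rate by

    rho(p) = (1 + eps * p/K_R) / (1 + p/K_R),   rho in [eps, 1]

where K_R is the repressor-mRNA equilibrium constant and eps the elongation
leakage.  A red reporter transcribed from the same promoter but not
repressed serves as the transcription control (rho = 1).  Population totals
come from multiplying per-cell concentrations by a logistic population
signal N(t).  Calibration adjusts synthesis/growth scales on the two extreme
inducer doses only; the inducer dose law (lac_K, lac_n) is fixed from the
dose-response presets, which is what lets the model predict intermediate
doses it was never fitted to.

Units: nM and minutes inside the ODEs; the public API takes hours for time
grids and per-hour growth rates, micromolar for inducer doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import lmfit
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .dose_response import InhibitionCurve, active_fraction
from .presets import (
    GROWTH_RATES_PER_H,
    HILL_PRESETS,
    INHIBITION_PRESET,
    MRNA_DEGRADATION_PER_MIN,
    MSI_SATURATING_NM,
    ORIGINAL_LEAKAGE,
)
from .units import per_h_to_per_min

__all__ = [
    "CircuitModel",
    "GrowthModel",
    "TransientResult",
    "default_circuit",
    "default_growth",
    "simulate_percell",
    "steady_state",
    "simulate_population",
    "calibrate",
    "predict_and_score",
]

STATE_NAMES = ("m_msi", "p_msi", "m_rep", "green", "red")


@dataclass(frozen=True)
class CircuitModel:
    """Parameterization of the transcription->translation repression cascade.

    Rates are per minute and concentrations nM; ``lac_K`` is in uM (inducer
    scale) and ``inh`` is the oleic-acid inhibition curve (doses in mM).
    """

    lac_K: float  # inducer half-activation constant, uM
    lac_n: float  # inducer Hill coefficient
    basal_frac: float  # promoter leakiness fraction in [0, 1)
    alpha_msi: float  # repressor mRNA synthesis rate, nM/min
    beta_msi: float  # repressor translation rate, per min
    alpha_rep: float  # reporter mRNA synthesis rate, nM/min
    beta_rep: float  # reporter translation rate, per min
    delta_m: float  # mRNA degradation rate, per min
    mu: float  # dilution (growth) rate, per min
    K_R: float  # repressor-mRNA equilibrium constant, nM
    leakage: float  # elongation leakage fraction eps in (0, 1]
    inh: InhibitionCurve

    def __post_init__(self) -> None:
        for name in ("lac_K", "lac_n", "alpha_msi", "beta_msi", "alpha_rep",
                     "beta_rep", "delta_m", "mu", "K_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.basal_frac < 1):
            raise ValueError("basal_frac must be in [0, 1)")
        if not (0 < self.leakage <= 1):
            raise ValueError("leakage must be in (0, 1]")
        if self.delta_m <= self.mu:
            raise ValueError("delta_m must exceed mu (mRNA outpaces dilution)")

    def induction(self, lactose_uM: float) -> float:
        """Active fraction of the repressor promoter at a given inducer dose."""
        if lactose_uM < 0:
            raise ValueError("lactose dose must be >= 0")
        if lactose_uM == 0:
            return self.basal_frac
        occ = lactose_uM**self.lac_n / (self.lac_K**self.lac_n + lactose_uM**self.lac_n)
        return self.basal_frac + (1.0 - self.basal_frac) * occ

    def repression_factor(self, p_active_nM: float) -> float:
        """Quasi-equilibrium translation scaling rho(p), in [leakage, 1]."""
        x = p_active_nM / self.K_R
        return (1.0 + self.leakage * x) / (1.0 + x)


@dataclass(frozen=True)
class GrowthModel:
    """Logistic population growth in instrument signal units.

    ``mu_max`` (per h) is the early-time slope of log N; ``n0`` and
    ``n_cap`` are the initial and carrying-capacity signals.
    """

    mu_max: float
    n0: float
    n_cap: float

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        if self.n0 <= 0:
            raise ValueError("n0 must be > 0")
        if self.n_cap < self.n0:
            raise ValueError("n_cap must be >= n0")

    def population(self, t_h) -> np.ndarray:
        """Closed-form logistic N(t), t in hours."""
        t = np.asarray(t_h, dtype=float)
        return self.n_cap / (1.0 + (self.n_cap / self.n0 - 1.0) * np.exp(-self.mu_max * t))


@dataclass(frozen=True)
class TransientResult:
    """Per-cell trajectories plus population totals on a common time grid."""

    time_h: np.ndarray
    species: pd.DataFrame  # per-cell concentrations, nM; columns STATE_NAMES
    population: np.ndarray
    total_green: np.ndarray
    total_red: np.ndarray


def default_circuit(
    mu_per_h: float | None = None,
    leakage: float = ORIGINAL_LEAKAGE,
    p_saturating_nM: float = MSI_SATURATING_NM,
    beta_msi: float = 2.0,
    alpha_rep: float = 1.0,
    beta_rep: float = 2.0,
    basal_frac: float = 0.0,
    K_R: float = 0.62,
    delta_m: float = MRNA_DEGRADATION_PER_MIN,
    inh: InhibitionCurve = INHIBITION_PRESET,
) -> CircuitModel:
    """Default circuit preset anchored to the study's documented constants.

    The repressor mRNA synthesis rate is solved so that the steady-state
    repressor level at saturating (1 mM) inducer equals ``p_saturating_nM``
    (the study's estimate R > 1 uM at full induction); the inducer dose law
    comes from the original Hill preset.
    """
    hill = HILL_PRESETS["original"]
    mu = per_h_to_per_min(mu_per_h if mu_per_h is not None else GROWTH_RATES_PER_H["time_course"])
    lac_K, lac_n = hill.reg_coeff, hill.hill_n
    occ_sat = 1000.0**lac_n / (lac_K**lac_n + 1000.0**lac_n)
    f_sat = basal_frac + (1 - basal_frac) * occ_sat
    alpha_msi = p_saturating_nM * delta_m * mu / (beta_msi * f_sat)
    return CircuitModel(
        lac_K=lac_K, lac_n=lac_n, basal_frac=basal_frac,
        alpha_msi=alpha_msi, beta_msi=beta_msi,
        alpha_rep=alpha_rep, beta_rep=beta_rep,
        delta_m=delta_m, mu=mu, K_R=K_R, leakage=leakage, inh=inh,
    )


def default_growth(mu_max_per_h: float | None = None) -> GrowthModel:
    """Logistic growth preset: rate from the time-course fit, signal units arbitrary."""
    mu = mu_max_per_h if mu_max_per_h is not None else GROWTH_RATES_PER_H["time_course"]
    return GrowthModel(mu_max=mu, n0=1.0, n_cap=100.0)


def _rhs(t_min, y, model: CircuitModel, f_L: float, oleic_active: float):
    m_msi, p_msi, m_rep, green, red = y
    p_active = p_msi * oleic_active
    rho = model.repression_factor(max(p_active, 0.0))
    return [
        model.alpha_msi * f_L - model.delta_m * m_msi,
        model.beta_msi * m_msi - model.mu * p_msi,
        model.alpha_rep - model.delta_m * m_rep,
        model.beta_rep * m_rep * rho - model.mu * green,
        model.beta_rep * m_rep - model.mu * red,
    ]


def simulate_percell(
    model: CircuitModel,
    lactose_uM: float,
    oleic_mM: float,
    t_grid_h: Sequence[float],
    y0: Sequence[float] | None = None,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate the per-cell ODEs on a time grid (hours); returns nM concentrations."""
    t = np.asarray(t_grid_h, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be 1-D strictly increasing")
    if y0 is None:
        y0 = np.zeros(5)
    y0 = np.asarray(y0, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be >= 0")
    f_L = model.induction(lactose_uM)
    act = float(active_fraction(model.inh, oleic_mM))
    t_min = t * 60.0
    span = (min(t_min[0], 0.0), t_min[-1])
    sol = solve_ivp(
        _rhs, span, y0, t_eval=t_min, args=(model, f_L, act),
        method="LSODA", rtol=rtol, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    df = pd.DataFrame(sol.y.T, columns=STATE_NAMES)
    df.insert(0, "time_h", t)
    return df


def steady_state(model: CircuitModel, lactose_uM: float, oleic_mM: float = 0.0) -> dict:
    """Closed-form steady state of the per-cell cascade (the ODEs are linear
    given the inducer, with the repression factor evaluated at the repressor
    steady state)."""
    f_L = model.induction(lactose_uM)
    m_msi = model.alpha_msi * f_L / model.delta_m
    p_msi = model.beta_msi * m_msi / model.mu
    p_active = p_msi * float(active_fraction(model.inh, oleic_mM))
    rho = model.repression_factor(p_active)
    m_rep = model.alpha_rep / model.delta_m
    red = model.beta_rep * m_rep / model.mu
    green = red * rho
    return {
        "m_msi": m_msi, "p_msi": p_msi, "p_active": p_active,
        "m_rep": m_rep, "green": green, "red": red, "rho": rho,
    }


def headline_fold(model: CircuitModel, saturating_uM: float = 1000.0) -> float:
    """Steady-state reporter ratio between zero and saturating inducer."""
    return steady_state(model, 0.0)["green"] / steady_state(model, saturating_uM)["green"]


def simulate_population(
    model: CircuitModel,
    growth: GrowthModel,
    lactose_uM: float,
    oleic_mM: float,
    t_grid_h: Sequence[float],
) -> TransientResult:
    """Population totals: logistic N(t) times the per-cell trajectories."""
    species = simulate_percell(model, lactose_uM, oleic_mM, t_grid_h)
    t = species["time_h"].to_numpy()
    n = growth.population(t)
    return TransientResult(
        time_h=t,
        species=species,
        population=n,
        total_green=n * species["green"].to_numpy(),
        total_red=n * species["red"].to_numpy(),
    )


CALIBRATABLE = ("alpha_msi", "beta_msi", "alpha_rep", "beta_rep",
                "mu_max", "n0", "n_cap", "leakage", "delta_m")
_CONFOUNDED_PAIRS = (("alpha_rep", "beta_rep"), ("alpha_msi", "beta_msi"))

TOTALS_COLUMNS = ("time_h", "dose_uM", "replicate", "total_green", "total_red")


def _check_totals(observed: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TOTALS_COLUMNS if c not in observed.columns]
    if missing:
        raise ValueError(f"totals table missing columns {missing}")
    return observed


def calibrate(
    model: CircuitModel,
    growth: GrowthModel,
    observed: pd.DataFrame,
    free_params: Sequence[str],
    calibration_doses: tuple[float, float] = (0.0, 1000.0),
) -> tuple[CircuitModel, GrowthModel, float]:
    """Fit the named free parameters against the extreme-dose total curves.

    Only the two calibration doses are used; the inducer dose law (lac_K,
    lac_n) is never free here, by design.  Returns the refitted models and
    the residual sum of squares.  Raises on confounded free-parameter pairs
    whose product alone is identifiable from protein totals.
    """
    observed = _check_totals(observed)
    for pair in _CONFOUNDED_PAIRS:
        if all(p in free_params for p in pair):
            raise ValueError(
                f"free parameters {pair} are confounded (only their product is "
                "identifiable from protein totals); free at most one of them"
            )
    unknown = [p for p in free_params if p not in CALIBRATABLE]
    if unknown:
        raise ValueError(f"unknown free parameters {unknown}; choose from {CALIBRATABLE}")
    subsets = {}
    for dose in calibration_doses:
        sub = observed[observed["dose_uM"] == dose]
        if sub.empty:
            raise ValueError(f"calibration dose {dose} uM absent from observed data")
        subsets[dose] = sub

    current = {**{k: getattr(model, k) for k in CALIBRATABLE if hasattr(model, k)},
               "mu_max": growth.mu_max, "n0": growth.n0, "n_cap": growth.n_cap}
    params = lmfit.Parameters()
    for name in free_params:
        v = current[name]
        hi = 1.0 if name == "leakage" else v * 100.0
        params.add(name, value=v, min=v / 100.0, max=hi)

    def build(p):
        kw = {name: p[name].value for name in free_params if name not in ("mu_max", "n0", "n_cap")}
        m = replace(model, **kw) if kw else model
        gkw = {name: p[name].value for name in free_params if name in ("mu_max", "n0", "n_cap")}
        g = replace(growth, **gkw) if gkw else growth
        return m, g

    def resid(p):
        m, g = build(p)
        out = []
        for dose, sub in subsets.items():
            t = np.sort(sub["time_h"].unique())
            res = simulate_population(m, g, dose, 0.0, t)
            green = dict(zip(t, res.total_green))
            red = dict(zip(t, res.total_red))
            out.append(sub["total_green"].to_numpy()
                       - np.array([green[x] for x in sub["time_h"]]))
            out.append(sub["total_red"].to_numpy()
                       - np.array([red[x] for x in sub["time_h"]]))
        return np.concatenate(out)

    fit = lmfit.minimize(resid, params, method="leastsq")
    if not fit.success:
        raise RuntimeError(f"calibration did not converge: {fit.message}")
    m, g = build(fit.params)
    return m, g, float(np.sum(fit.residual**2))


def predict_and_score(
    model: CircuitModel,
    growth: GrowthModel,
    doses: Iterable[float],
    observed: pd.DataFrame,
    t_min_h: float = 2.0,
    calibration_doses: tuple[float, float] = (0.0, 1000.0),
    include_calibration: bool = False,
) -> dict:
    """Predict total-green transients per dose and pool an R-squared.

    R-squared comes from a linear regression of observed on predicted values
    pooled over all requested doses and times beyond ``t_min_h`` (the early
    low-cell-count points are excluded, as their relative error is large).
    """
    observed = _check_totals(observed)
    doses = [d for d in doses
             if include_calibration or d not in calibration_doses]
    rows = []
    for dose in doses:
        sub = observed[observed["dose_uM"] == dose]
        sub = sub[sub["time_h"] > t_min_h]
        if sub.empty:
            continue
        t = np.sort(sub["time_h"].unique())
        res = simulate_population(model, growth, dose, 0.0, t)
        green = dict(zip(t, res.total_green))
        for _, row in sub.iterrows():
            rows.append((dose, row["time_h"], row["total_green"], green[row["time_h"]]))
    if not rows:
        raise ValueError(f"no observations beyond t = {t_min_h} h at the requested doses")
    table = pd.DataFrame(rows, columns=["dose_uM", "time_h", "observed", "predicted"])
    reg = linregress(table["predicted"], table["observed"])
    return {
        "table": table,
        "r_squared": float(reg.rvalue**2),
        "slope": float(reg.slope),
        "intercept": float(reg.intercept),
    }
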