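"""Seeded generators for every measurement the pipeline consumes.

All stages of the analysis are exercised on synthetic data emulating the
study's measurements: dose-response tables, plate-reader time courses,
flow-cytometry-like single-cell samples, and biosensor binding traces.
Fluorescence noise is multiplicative lognormal (positive support, constant
coefficient of variation); biosensor traces get additive Gaussian noise.
Every generator is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingTrace, simulate_trace
from .circuit import CircuitModel, GrowthModel, simulate_population
from .dose_response import HillCurve, hill_eval
from .foldchange import RegulationKinetics
from .stochastic import CellSample

__all__ = [
    "STUDY_DOSES_UM",
    "lognormal_factors",
    "gen_dose_response",
    "gen_plate_timeseries",
    "gen_cytometry",
    "gen_binding_traces",
]

#: the inducer dose series used throughout the study (uM), plus the zero dose
STUDY_DOSES_UM = (0.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

#: default replicate structure and measurement noise of the emulated assays
DEFAULT_REPLICATES = 3
DEFAULT_NOISE_CV = 0.05


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def gen_dose_response(
    curve: HillCurve,
    doses: Sequence[float] = STUDY_DOSES_UM,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-response table (dose_uM, replicate, response_au) from a Hill curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        clean = np.asarray(hill_eval(curve, np.asarray(doses, dtype=float)))
        noisy = clean * lognormal_factors(rng, noise_cv, clean.shape)
        for d, y in zip(doses, noisy):
            rows.append({"dose_uM": d, "replicate": rep, "response_au": y})
    return pd.DataFrame(rows)


def gen_totals_timeseries(
    model: CircuitModel,
    growth: GrowthModel,
    doses: Sequence[float] = STUDY_DOSES_UM,
    t_grid_h: Sequence[float] | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-total time courses (the transient-response experiment).

    Returns the totals schema (time_h, dose_uM, replicate, total_green,
    total_red): noiseless circuit-plus-growth trajectories times unit-mean
    lognormal noise.
    """
    if t_grid_h is None:
        t_grid_h = np.linspace(0.25, 10.0, 20)
    rng = np.random.default_rng(seed)
    frames = []
    for dose in doses:
        res = simulate_population(model, growth, dose, 0.0, t_grid_h)
        for rep in range(replicates):
            g = res.total_green * lognormal_factors(rng, noise_cv, len(res.time_h))
            r = res.total_red * lognormal_factors(rng, noise_cv, len(res.time_h))
            frames.append(pd.DataFrame({
                "time_h": res.time_h, "dose_uM": dose, "replicate": rep,
                "total_green": g, "total_red": r,
            }))
    return pd.concat(frames, ignore_index=True)


def gen_plate_timeseries(
    model: CircuitModel,
    growth: GrowthModel,
    doses: Sequence[float] = STUDY_DOSES_UM,
    t_grid_h: Sequence[float] | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    od_per_signal: float = 0.01,
    blank_floor: float = 0.5,
    n_blanks: int = 3,
) -> pd.DataFrame:
    """Raw plate-reader table (PLATE_COLUMNS schema) emulating a full run.

    Per-well OD tracks the logistic population signal; green/red channels
    are population totals plus the medium background; blank wells carry the
    background alone.  Multiplicative lognormal noise applies to all
    channels at the requested CV.
    """
    if t_grid_h is None:
        t_grid_h = np.linspace(0.25, 10.0, 20)
    t = np.asarray(t_grid_h, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        res = simulate_population(model, growth, dose, 0.0, t)
        for rep in range(replicates):
            well = f"D{dose:g}R{rep}"
            od = res.population * od_per_signal * lognormal_factors(rng, noise_cv, len(t))
            g = (res.total_green + blank_floor) * lognormal_factors(rng, noise_cv, len(t))
            r = (res.total_red + blank_floor) * lognormal_factors(rng, noise_cv, len(t))
            rows.append(pd.DataFrame({
                "time_h": t, "well": well, "od600": od,
                "green_au": g, "red_au": r,
                "dose_uM": dose, "replicate": rep, "is_blank": False,
            }))
    for blank in range(n_blanks):
        rows.append(pd.DataFrame({
            "time_h": t, "well": f"BLK{blank}",
            "od600": np.zeros_like(t),
            "green_au": blank_floor * lognormal_factors(rng, noise_cv, len(t)),
            "red_au": blank_floor * lognormal_factors(rng, noise_cv, len(t)),
            "dose_uM": 0.0, "replicate": blank, "is_blank": True,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_cytometry(
    mean: float,
    fano: float,
    n_events: int = 10_000,
    seed: int = 0,
) -> CellSample:
    """Flow-cytometry-like single-cell sample with requested mean and Fano.

    fano > 1 draws a gamma-Poisson (negative-binomial-like) mixture, fano = 1
    is pure Poisson, and fano < 1 adds a deterministic floor to a scaled
    Poisson component (sub-Poissonian dispersion).
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if fano < 0:
        raise ValueError("fano must be >= 0")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    if fano == 1.0:
        values = rng.poisson(mean, n_events)
    elif fano > 1.0:
        # Poisson with gamma-distributed intensity: Fano = 1 + mean/shape
        shape = mean / (fano - 1.0)
        lam = rng.gamma(shape, mean / shape, n_events)
        values = rng.poisson(lam)
    else:
        # round(mean*(1-f)) + Poisson(mean*f) has mean ~ mean and Fano ~ f
        fixed = mean * (1.0 - fano)
        values = np.round(fixed).astype(np.int64) + rng.poisson(mean * fano, n_events)
    return CellSample(values.astype(np.int64))


def gen_binding_traces(
    kin: RegulationKinetics,
    concentrations: Sequence[float],
    amplitude: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BindingTrace]:
    """Biosensor run: sample traces per analyte concentration plus a blank
    and a negative control (no specific signal, noise only)."""
    rng = np.random.default_rng(seed)
    traces: list[BindingTrace] = []
    for conc in concentrations:
        pair = simulate_trace(kin.k_on, kin.k_off, conc, amplitude,
                              noise_sd, int(rng.integers(2**31)))
        traces.extend(pair)
    # blank and negative control: flat (noise-only) traces on the same grids
    for role in ("blank", "negative_control"):
        for phase, n in (("association", len(traces[0].time_s)),
                         ("dissociation", len(traces[1].time_s))):
            grid = traces[0].time_s if phase == "association" else traces[1].time_s
            sig = (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n))
            traces.append(BindingTrace(grid, sig, phase, 0.0, role))
    return traces
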