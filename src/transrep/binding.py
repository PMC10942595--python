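"""Biosensor-style protein-RNA binding kinetics: trace simulation and fitting.

A chip-immobilized RNA ligand is exposed to a protein analyte at
concentration C for an association phase, then rinsed for a dissociation
phase.  Mono-exponential models describe both phases:

    association:   S(t) = A * theta_eq * (1 - exp(-k_obs t)),
                   k_obs = k_on*C + k_off,  theta_eq = k_on*C / k_obs
    dissociation:  S(t) = S_end * exp(-k_off t)

Global fitting across analyte concentrations shares (k_on, k_off) with a
per-concentration amplitude; K_D = k_off/k_on and the residence time 1/k_off
are derived.  Time is stored in seconds (1 Hz sampling) and converted to
minutes internally, matching the per-minute rate constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import lmfit

from .units import s_to_min

__all__ = [
    "BindingTrace",
    "KineticsFit",
    "simulate_trace",
    "reference_trace",
    "fit_kinetics",
    "kd_from_rates",
    "residence_from_koff",
    "k_obs",
]


@dataclass(frozen=True)
class BindingTrace:
    """One phase of a biosensor run: signal vs time from phase start."""

    time_s: np.ndarray
    signal: np.ndarray
    phase: str  # association | dissociation
    analyte_conc: float  # nM
    role: str = "sample"  # sample | blank | negative_control

    def __post_init__(self) -> None:
        if self.phase not in ("association", "dissociation"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.role not in ("sample", "blank", "negative_control"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.analyte_conc < 0:
            raise ValueError("analyte_conc must be >= 0")
        t = np.asarray(self.time_s)
        if t.ndim != 1 or len(t) != len(self.signal):
            raise ValueError("time and signal must be 1-D and equally long")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class KineticsFit:
    """Shared-rate fit over one or more binding traces."""

    k_on: float  # per nM per min
    k_off: float  # per min
    amplitudes: dict  # analyte_conc -> fitted amplitude A
    r_squared: dict  # phase -> R^2
    stderr: dict | None = None  # rate -> estimated standard error

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    @property
    def residence_time(self) -> float:
        return 1.0 / self.k_off


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (nM)."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    return k_off / k_on


def residence_from_koff(k_off: float) -> float:
    """Mean bound lifetime 1/k_off (min)."""
    if k_off <= 0:
        raise ValueError("k_off must be > 0")
    return 1.0 / k_off


def k_obs(k_on: float, k_off: float, conc: float) -> float:
    """Observed association relaxation rate k_on*C + k_off (per min)."""
    return k_on * conc + k_off


def _assoc_model(t_min, k_on, k_off, conc, amplitude):
    kobs = k_on * conc + k_off
    theta_eq = k_on * conc / kobs
    return amplitude * theta_eq * (1.0 - np.exp(-kobs * t_min))


def simulate_trace(
    k_on: float,
    k_off: float,
    conc: float,
    amplitude: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_assoc: float = 300.0,
    t_dissoc: float = 900.0,
    rate_hz: float = 1.0,
) -> tuple[BindingTrace, BindingTrace]:
    """Simulate an association/dissociation trace pair (times in seconds).

    Defaults follow the study protocol: 5 min association, 15 min
    dissociation, 1 Hz sampling.  Additive Gaussian noise of standard
    deviation ``noise_sd`` (same units as ``amplitude``) is seeded and
    bit-reproducible; ``noise_sd=0`` returns the exact model.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    if conc <= 0:
        raise ValueError("analyte concentration must be > 0")
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    t_d = np.arange(0.0, t_dissoc + dt / 2, dt)
    s_a = _assoc_model(s_to_min(t_a), k_on, k_off, conc, amplitude)
    s_end = s_a[-1]
    s_d = s_end * np.exp(-k_off * s_to_min(t_d))
    if noise_sd > 0:
        s_a = s_a + rng.normal(0.0, noise_sd, s_a.shape)
        s_d = s_d + rng.normal(0.0, noise_sd, s_d.shape)
    return (
        BindingTrace(t_a, s_a, "association", conc),
        BindingTrace(t_d, s_d, "dissociation", conc),
    )


def reference_trace(
    sample: BindingTrace,
    blank: BindingTrace,
    negative_control: BindingTrace,
) -> BindingTrace:
    """Double-reference a trace: subtract the blank run and the blank-corrected
    negative control, i.e. corrected = sample - blank - (control - blank)."""
    for other in (blank, negative_control):
        if len(other.time_s) != len(sample.time_s) or np.any(
            np.asarray(other.time_s) != np.asarray(sample.time_s)
        ):
            raise ValueError("time grids must match for referencing")
    corrected = (
        np.asarray(sample.signal)
        - np.asarray(blank.signal)
        - (np.asarray(negative_control.signal) - np.asarray(blank.signal))
    )
    return replace(sample, signal=corrected)


def _r2(y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def fit_kinetics(
    traces: Iterable[BindingTrace],
    mode: str = "joint",
    t_assoc_s: float = 300.0,
) -> KineticsFit:
    """Fit shared (k_on, k_off) across traces with per-concentration amplitudes.

    ``mode="joint"`` fits both phases simultaneously; ``"sequential"`` first
    fits k_off on the pooled dissociation phases, then k_on on the
    association phases with k_off fixed.  Both agree on clean data.
    """
    traces = [t for t in traces if t.role == "sample"]
    assoc = [t for t in traces if t.phase == "association"]
    dissoc = [t for t in traces if t.phase == "dissociation"]
    if not dissoc:
        raise ValueError("need at least one dissociation phase")
    if not assoc:
        raise ValueError("k_on is unidentifiable without an association phase")
    concs = sorted({t.analyte_conc for t in assoc})
    if len(concs) == 1 and len(assoc) == 1:
        warnings.warn(
            "single association trace at a single concentration: "
            "k_on and k_off are weakly identifiable",
            stacklevel=2,
        )

    # initial guesses: k_off from the dissociation tail, k_obs from association
    d0 = dissoc[0]
    pos = np.asarray(d0.signal) > 0
    if pos.sum() >= 3:
        slope = np.polyfit(s_to_min(np.asarray(d0.time_s)[pos]),
                           np.log(np.asarray(d0.signal)[pos]), 1)[0]
        koff0 = max(-slope, 1e-3)
    else:
        koff0 = 0.1
    amp0 = {c: max(max(np.max(t.signal) for t in assoc if t.analyte_conc == c), 1e-6)
            for c in concs}

    def build_params(vary_koff=True, koff_value=None):
        p = lmfit.Parameters()
        p.add("k_on", value=koff0 / max(min(concs), 1e-6), min=1e-8, max=1e4)
        p.add("k_off", value=koff_value if koff_value is not None else koff0,
              min=1e-8, max=1e4, vary=vary_koff)
        for i, c in enumerate(concs):
            p.add(f"amp_{i}", value=amp0[c] * 1.2, min=0.0)
        return p

    def residuals(p, use_assoc=True, use_dissoc=True):
        res = []
        kon, koff = p["k_on"].value, p["k_off"].value
        for t in traces:
            if t.analyte_conc not in concs:
                continue
            amp = p[f"amp_{concs.index(t.analyte_conc)}"].value
            tm = s_to_min(np.asarray(t.time_s, dtype=float))
            if t.phase == "association" and use_assoc:
                res.append(_assoc_model(tm, kon, koff, t.analyte_conc, amp)
                           - np.asarray(t.signal))
            elif t.phase == "dissociation" and use_dissoc:
                kobs = kon * t.analyte_conc + koff
                theta = kon * t.analyte_conc / kobs
                s_end = amp * theta * (1.0 - math.exp(-kobs * s_to_min(t_assoc_s)))
                res.append(s_end * np.exp(-koff * tm) - np.asarray(t.signal))
        return np.concatenate(res)

    if mode == "joint":
        out = lmfit.minimize(residuals, build_params(), method="leastsq")
    elif mode == "sequential":
        first = lmfit.minimize(
            lambda p: residuals(p, use_assoc=False), build_params(), method="leastsq"
        )
        out = lmfit.minimize(
            lambda p: residuals(p, use_dissoc=False),
            build_params(vary_koff=False, koff_value=first.params["k_off"].value),
            method="leastsq",
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not out.success:
        raise RuntimeError(f"kinetics fit did not converge: {out.message}")

    p = out.params
    kon, koff = p["k_on"].value, p["k_off"].value
    amps = {c: p[f"amp_{i}"].value for i, c in enumerate(concs)}
    r2 = {}
    for phase, subset in (("association", assoc), ("dissociation", dissoc)):
        y, yhat = [], []
        for t in subset:
            amp = amps[t.analyte_conc]
            tm = s_to_min(np.asarray(t.time_s, dtype=float))
            if phase == "association":
                pred = _assoc_model(tm, kon, koff, t.analyte_conc, amp)
            else:
                kobs = kon * t.analyte_conc + koff
                theta = kon * t.analyte_conc / kobs
                s_end = amp * theta * (1.0 - math.exp(-kobs * s_to_min(t_assoc_s)))
                pred = s_end * np.exp(-koff * tm)
            y.append(np.asarray(t.signal))
            yhat.append(pred)
        r2[phase] = _r2(np.concatenate(y), np.concatenate(yhat))
    stderr = {"k_on": p["k_on"].stderr, "k_off": p["k_off"].stderr}
    return KineticsFit(kon, koff, amps, r2, stderr)


def kobs_regression(traces: Sequence[BindingTrace]) -> tuple[float, float]:
    """Cross-check estimator: per-trace k_obs fit, then the line k_obs = k_on*C + k_off.

    Returns (k_on, k_off).  Requires association traces at >= 2 concentrations.
    """
    assoc = [t for t in traces if t.phase == "association" and t.role == "sample"]
    concs = sorted({t.analyte_conc for t in assoc})
    if len(concs) < 2:
        raise ValueError("k_obs regression needs >= 2 analyte concentrations")
    kobs_vals = []
    for t in assoc:
        p = lmfit.Parameters()
        p.add("kobs", value=1.0, min=1e-8, max=1e4)
        p.add("plateau", value=float(np.max(t.signal)), min=0.0)
        tm = s_to_min(np.asarray(t.time_s, dtype=float))
        sig = np.asarray(t.signal)
        out = lmfit.minimize(
            lambda q: q["plateau"].value * (1 - np.exp(-q["kobs"].value * tm)) - sig,
            p, method="leastsq",
        )
        kobs_vals.append((t.analyte_conc, out.params["kobs"].value))
    c = np.array([v[0] for v in kobs_vals])
    k = np.array([v[1] for v in kobs_vals])
    slope, intercept = np.polyfit(c, k, 1)
    return float(slope), float(intercept)
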