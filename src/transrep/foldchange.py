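"""Steady-state fold-change model for repression of a degradable template.

A regulator (an RNA-binding protein such as Musashi-1, or a transcription
factor in the degradation-free limit) binds a template that is itself turned
over.  With mass-action binding at rates ``k_on``/``k_off``, template
degradation ``delta`` acting equally on free and bound template, and a bound
template still producing output at a fraction ``epsilon`` of the free rate
(elongation leakage), the steady-state fold change in output is the closed
form

    fold = (k_off + delta + k_on*R) / (k_off + delta + epsilon*k_on*R)

which recovers the classical equilibrium result ``1 + R/K_D`` when the
template is stable (delta = 0) and leakage is negligible, and saturates at
``1/epsilon`` as R grows.  ``mass_action_steady_state`` is the brute-force
two-state oracle the closed form is checked against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegulationKinetics",
    "FoldChangeContext",
    "FoldChangeMap",
    "fold_change",
    "max_fold",
    "leakage_from_max_fold",
    "fold_change_map",
    "classify_regime",
    "mass_action_steady_state",
]


def _require_finite_positive(name: str, value: float, strict: bool = True) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if strict and value <= 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")
    if not strict and value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class RegulationKinetics:
    """Association/dissociation rate constants of a regulator-template pair.

    Parameters
    ----------
    k_on : float
        Association rate constant, per nM per min.
    k_off : float
        Dissociation rate constant, per min.

    The equilibrium dissociation constant ``k_d = k_off / k_on`` (nM) and the
    mean bound lifetime ``residence_time = 1 / k_off`` (min) are derived.
    """

    k_on: float
    k_off: float

    def __post_init__(self) -> None:
        _require_finite_positive("k_on", self.k_on)
        _require_finite_positive("k_off", self.k_off)

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    @property
    def residence_time(self) -> float:
        return 1.0 / self.k_off

    @classmethod
    def from_kd(cls, k_on: float, k_d: float) -> "RegulationKinetics":
        _require_finite_positive("k_d", k_d)
        return cls(k_on=k_on, k_off=k_d * k_on)

    @classmethod
    def from_residence(cls, k_on: float, residence_time: float) -> "RegulationKinetics":
        _require_finite_positive("residence_time", residence_time)
        return cls(k_on=k_on, k_off=1.0 / residence_time)


@dataclass(frozen=True)
class FoldChangeContext:
    """Cellular context of the regulation: the fold-change model's free variables.

    regulator_conc
        Free active regulator concentration R, nM (>= 0).
    leakage
        Elongation leakage fraction epsilon: output from bound template
        relative to free template, 0 < epsilon <= 1.
    degradation
        Template degradation rate delta, per min (>= 0; 0 models DNA).
    """

    regulator_conc: float
    leakage: float
    degradation: float

    def __post_init__(self) -> None:
        _require_finite_positive("regulator_conc", self.regulator_conc, strict=False)
        _require_finite_positive("leakage", self.leakage)
        if self.leakage > 1:
            raise ValueError(f"leakage must be <= 1, got {self.leakage!r}")
        _require_finite_positive("degradation", self.degradation, strict=False)


@dataclass(frozen=True)
class FoldChangeMap:
    """Fold change over a grid of first-order association rates and k_off."""

    kon_r_grid: np.ndarray
    koff_grid: np.ndarray
    fold_matrix: np.ndarray
    leakage: float
    degradation: float

    def to_frame(self):
        import pandas as pd

        kon_r, koff = np.meshgrid(self.kon_r_grid, self.koff_grid, indexing="ij")
        return pd.DataFrame(
            {
                "kon_r": kon_r.ravel(),
                "koff": koff.ravel(),
                "fold": self.fold_matrix.ravel(),
            }
        )


def fold_change(kin: RegulationKinetics, ctx: FoldChangeContext) -> float:
    """Steady-state fold change (unregulated over regulated output), >= 1."""
    kon_r = kin.k_on * ctx.regulator_conc
    num = kin.k_off + ctx.degradation + kon_r
    den = kin.k_off + ctx.degradation + ctx.leakage * kon_r
    return num / den


def max_fold(leakage: float) -> float:
    """Fold change at saturating regulator: the R -> infinity limit, 1/leakage."""
    if not math.isfinite(leakage) or leakage <= 0 or leakage > 1:
        raise ValueError(f"leakage must be in (0, 1], got {leakage!r}")
    return 1.0 / leakage


def leakage_from_max_fold(fold_max: float) -> float:
    """Invert ``max_fold``: leakage fraction implied by a saturating fold change."""
    if not math.isfinite(fold_max) or fold_max < 1:
        raise ValueError(f"fold_max must be >= 1, got {fold_max!r}")
    return 1.0 / fold_max


def fold_change_map(
    kon_r_grid,
    koff_grid,
    leakage: float,
    degradation: float,
) -> FoldChangeMap:
    """Evaluate the fold change over a (k_on*R, k_off) grid.

    At delta = 0 the iso-fold contours are straight lines
    ``k_off * (fold - 1) = k_on*R * (1 - leakage*fold)``; degradation bends
    them and caps the achievable fold when k_on*R falls below delta.
    """
    kon_r = np.asarray(kon_r_grid, dtype=float)
    koff = np.asarray(koff_grid, dtype=float)
    if kon_r.size == 0 or koff.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(kon_r <= 0) or np.any(koff <= 0):
        raise ValueError("grids must be strictly positive")
    if np.any(np.diff(kon_r) < 0) or np.any(np.diff(koff) < 0):
        raise ValueError("grids must be sorted ascending")
    if not (0 < leakage <= 1):
        raise ValueError(f"leakage must be in (0, 1], got {leakage!r}")
    if degradation < 0:
        raise ValueError(f"degradation must be >= 0, got {degradation!r}")
    kr, ko = np.meshgrid(kon_r, koff, indexing="ij")
    fold = (ko + degradation + kr) / (ko + degradation + leakage * kr)
    return FoldChangeMap(kon_r, koff, fold, leakage, degradation)


def default_grid(lo: float = 1e-3, hi: float = 10.0, n: int = 100) -> np.ndarray:
    """Log-spaced rate grid (per min) spanning the physiologically relevant range."""
    return np.logspace(math.log10(lo), math.log10(hi), n)


#: multiple of the template half-life beyond which a residence time is treated
#: as "much longer" than the template lifetime (non-equilibrium regime).
NONEQ_RESIDENCE_FACTOR = 2.0


def classify_regime(
    kin: RegulationKinetics,
    ctx: FoldChangeContext,
    residence_factor: float = NONEQ_RESIDENCE_FACTOR,
) -> str:
    """Classify the operating regime of the regulation on a degradable template.

    Returns one of:

    - ``"degradation_limited"``: the template is degraded faster than the
      regulator binds (k_on*R < delta), so functionality is compromised.
    - ``"non_equilibrium"``: the regulator's residence time exceeds
      ``residence_factor`` times the template half-life, so the template is
      degraded before the protein unbinds and K_D no longer characterizes
      the regulation (association-dominated).
    - ``"equilibrium"``: binding equilibrates within the template lifetime.
    """
    if ctx.degradation <= 0:
        raise ValueError("regimes are defined only for degradable templates (delta > 0)")
    kon_r = kin.k_on * ctx.regulator_conc
    if kon_r < ctx.degradation:
        return "degradation_limited"
    half_life = math.log(2.0) / ctx.degradation
    if kin.residence_time >= residence_factor * half_life:
        return "non_equilibrium"
    return "equilibrium"


def mass_action_steady_state(
    kin: RegulationKinetics,
    ctx: FoldChangeContext,
    transcription_rate: float = 1.0,
):
    """Exact steady state of the two-state (free/bound) template system.

    Solves, at steady state,

        dM/dt = alpha - k_on*R*M + k_off*B - delta*M
        dB/dt = k_on*R*M - k_off*B - delta*B

    and returns ``(M, B, flux)`` with output flux proportional to
    ``M + leakage*B``.  Total template M + B = alpha/delta, so the fold
    change equals flux(R=0)/flux(R).
    """
    alpha = transcription_rate
    if alpha <= 0:
        raise ValueError("transcription_rate must be > 0")
    delta = ctx.degradation
    if delta <= 0:
        raise ValueError("no steady state with delta = 0 and alpha > 0")
    kon_r = kin.k_on * ctx.regulator_conc
    koff = kin.k_off
    # linear 2x2 system: (kon_r + delta) M - koff B = alpha ; kon_r M = (koff + delta) B
    b_over_m = kon_r / (koff + delta)
    m = alpha / (kon_r + delta - koff * b_over_m)
    b = b_over_m * m
    flux = m + ctx.leakage * b
    return m, b, flux
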