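# transrep

Quantitative models of protein-mediated **translation repression** in
bacteria, built around a synthetic circuit in which a heterologous
RNA-binding protein (a truncated Musashi-1, transcriptionally controlled by
LacI and induced with lactose/IPTG) represses translation of a green
reporter by binding a consensus motif in the mRNA, while a red reporter
from the same promoter serves as the transcription control. The package is
for synthetic biologists and modelers who want the full quantitative
workflow behind such a circuit — from binding kinetics to population-level
prediction — runnable end to end on seeded synthetic data.

## What it computes

**Fold-change theory.** For a regulator at concentration *R* binding a
template that is itself degraded at rate δ, with elongation leakage ε
(residual output from the bound template), mass-action kinetics give the
steady-state fold change

```
fold = (k_off + δ + k_on·R) / (k_off + δ + ε·k_on·R)
```

which recovers the classical `fold = 1 + R/K_D` for a stable template
(δ = 0, ε → 0), saturates at `1/ε`, and collapses when `k_on·R < δ` (the
template dies before the regulator finds it). A brute-force two-state
mass-action solver serves as the oracle for the closed form, and a regime
classifier separates equilibrium, non-equilibrium (residence time ≫ mRNA
half-life), and degradation-limited operation.

**Dose–response and inhibition.** Four-parameter Hill fits
`y = y_min + (y_max − y_min)·K^n/(K^n + x^n)` for reporter-vs-inducer
tables, and an allosteric-inhibition curve `ic50^m/(ic50^m + dose^m)` for
the fatty-acid ligand that inactivates the repressor.

**Binding kinetics.** Mono-exponential biosensor models
(association `S = A·θ_eq·(1 − e^{−k_obs t})` with `k_obs = k_on·C + k_off`;
dissociation `S = S_end·e^{−k_off t}`), globally fitted across analyte
concentrations with shared rates; K_D = k_off/k_on and residence time
1/k_off are derived.

**Circuit dynamics.** An ODE cascade (inducer → repressor mRNA/protein →
quasi-equilibrium repression factor ρ(p) = (1 + ε·p/K_R)/(1 + p/K_R) on
reporter translation) composed with logistic population growth; calibration
on the two extreme inducer doses and prediction of the intermediate-dose
transients, scored by pooled R².

**Single-cell noise.** An exact Gillespie sampler of the two-state template
scheme, validated against a truncated chemical-master-equation solution,
with Fano factor and %ON summaries and a matched-mean comparison showing
translational repression is quieter than transcriptional attenuation.

**Fluorometry and motifs.** Plate-reader quantification (blank correction,
fluorescence-vs-OD regression slopes, growth rates, Crick-space
decomposition into translation and transcription proxies) and a scanner for
the RU_nAGU consensus motif with point-mutant classification.

## Worked example

```python
from transrep import presets
from transrep.circuit import default_circuit, headline_fold
from transrep.foldchange import leakage_from_max_fold

kin = presets.KINETICS_PRESETS["original"]
print(f"K_D = {kin.k_d:.3f} nM, residence = {kin.residence_time} min")
print(f"leakage from 2.5-fold ceiling: {leakage_from_max_fold(2.5):.0%}")
print(f"circuit steady-state repression: {headline_fold(default_circuit()):.2f}-fold")
```

prints

```
K_D = 0.606 nM, residence = 1.5 min
leakage from 2.5-fold ceiling: 40%
circuit steady-state repression: 2.50-fold
```

i.e. the measured on/off rates put the repressor–mRNA affinity in the
sub-nanomolar range, the saturating 2.5-fold repression implies that a
bound mRNA still translates at 40% of the free rate, and the calibrated
circuit preset reproduces that fold at steady state.

The numbered drivers under `analysis/` run the full study workflow
(fold-change maps and regimes, Hill and kinetics refits, the
calibrate/predict protocol, the noise comparison, and the motif scan) and
write their tables to `results/`:

```
python analysis/01_fold_change_theory.py
python analysis/04_circuit_prediction.py
...
```

A `transrep` command-line interface wraps the same operations
(`transrep gen`, `transrep fit-hill`, `transrep simulate`,
`transrep predict`, `transrep ssa`, `transrep scan`, ...).

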