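# Methods

## Scope and units

The package models a translation-repression circuit: an inducible
RNA-binding repressor, a constitutively transcribed reporter mRNA carrying
the repressor's consensus motif, and a co-transcribed red reporter as
transcription control. Internal units are nanomolar and minutes for all
molecular quantities; inducer doses are micromolar, inhibitor doses
millimolar, growth rates per hour, and biosensor time seconds on disk
(1 Hz sampling), with exact conversions at module boundaries
(`transrep.units`).

## Fold-change model

The two-state template scheme — free mRNA M and repressor-bound mRNA B,
transcription α, equal degradation δ of both states, binding k_on·R,
unbinding k_off, translation β from M and εβ from B — has the steady-state
fold change

    fold = (k_off + δ + k_on·R) / (k_off + δ + ε·k_on·R).

Assumptions: the repressor pool is large enough that R is constant
(pseudo-first-order binding), bound and free mRNA degrade at the same rate,
and translation initiation is proportional to template occupancy. The form
is exercised against `mass_action_steady_state`, an independent linear
solve of the same two-state system, to 1e-8 relative error over random
log-uniform parameter draws. Limits: fold(R=0) = 1; δ = 0, ε → 0 recovers
1 + R/K_D (stable-template, i.e. transcription-factor, regulation);
R → ∞ gives 1/ε, which is what lets a measured maximal fold be inverted
into a leakage fraction (2.5-fold ⇒ ε = 40%).

Regime classification on degradable templates: `degradation_limited` when
k_on·R < δ; `non_equilibrium` when the residence time 1/k_off is at least
twice the template half-life ln2/δ (the factor 2 is a configurable
operationalization of "much longer" that cleanly separates the measured
exemplars, 1.5 min vs 12 min at a 5-min half-life); otherwise
`equilibrium`. Heatmap grids default to 100×100 log-spaced rates over
[1e-3, 10] per min.

## Dose–response fitting

Hill curves are parameterized by the two plateaus, the regulatory
coefficient K (dose at the plateau midpoint) and the Hill coefficient n.
The loss is ordinary least squares on the linear response scale
(levenberg–marquardt via lmfit), with responses unit-normalized internally
so fits are exactly invariant to rescaling the response channel.
Initialization: K at the geometric mean of the nonzero doses, n = 1,
plateaus at the data extremes; bounds keep K within a decade of the dosed
range and n in [0.1, 10]. Zero-dose points enter through the plateau, not
a log-dose transform. Standard errors come from the covariance at the
optimum.

A precision caveat that passing tests make explicit: with the study's
9-dose series, 3 replicates and 5% multiplicative noise, the
Fisher-information limit on K is ≈7.5% relative (original preset,
K = 99 μM, n = 1.7) and ≈13% on n — single synthetic datasets at these
conditions scatter accordingly, and the unit tests assert recovery at
3σ-calibrated bounds rather than pretending tighter precision exists.

The inhibition curve (active fraction `ic50^m/(ic50^m + x^m)`, default
slope 1) is fitted the same way with a free amplitude.

## Binding kinetics

Each biosensor phase is mono-exponential (bi-exponential heterogeneity is
out of scope). The default protocol is a 5-min association and 15-min
dissociation at 1 Hz; the dissociation amplitude is tied to the
association endpoint, so a single per-concentration amplitude A is shared
by both phases. The default estimator fits all phases jointly with shared
(k_on, k_off); a sequential mode (k_off from dissociation first, then
k_on) and a per-trace k_obs-vs-C regression are provided as cross-checks,
and all three agree on clean data. Trace referencing subtracts the blank
run and the blank-corrected negative control. Noise on synthetic traces is
additive Gaussian (instrument noise), unlike the multiplicative model used
for fluorescence.

## Circuit ODEs, growth, and the calibrate/predict workflow

Per-cell species: repressor mRNA and protein, reporter mRNA, green
reporter, red reporter. Induction follows a fixed Hill law in the inducer;
repression acts through the quasi-equilibrium factor
ρ(p) = (1 + ε·p/K_R)/(1 + p/K_R) ∈ [ε, 1], the stable-template fold-change
formula evaluated at the instantaneous repressor level (binding
equilibrates much faster than the hour-scale circuit dynamics).
Fluorophore maturation and inducer depletion are not modeled. Integration
uses LSODA at rtol 1e-8; steady states are evaluated in closed form (the
system is linear given the inducer).

Documented default constants: δ_m = 0.14 /min (5-min mRNA half-life),
μ = 0.80 /h (time-course growth; 0.55 /h preset for the dose-response
setup), K_R = 0.62 nM, ε = 0.4, promoter leakiness 0, repressor steady
state 1 μM at saturating (1 mM) inducer, inducer law K = 99 μM, n = 1.7.
The repressor-synthesis rate is solved from the 1 μM anchor rather than
given directly. Each constant is overridable.

Population growth is logistic (closed form); a Gompertz alternative was
considered and not needed at the smooth, single-phase synthetic conditions
modeled here. Totals are exact products N(t)·per-cell concentration, so
green/red ratios cancel the population factor.

Calibration uses only the 0 and 1 mM curves. Because repression is absent
at one extreme and saturated at the other, those curves cannot identify
the repressor-arm scale — only the reporter-synthesis and growth scales —
so the default free set is {alpha_rep, mu_max, n_cap}, with the repressor
level anchored by the preset and the inducer dose law fixed from the Hill
preset. That fixed dose law is precisely what makes intermediate-dose
prediction a genuine test. Product-confounded pairs (alpha_rep/beta_rep,
alpha_msi/beta_msi) are rejected as free sets. Prediction is scored by
linear regression (with intercept) of observed on predicted total green
fluorescence pooled over doses and times > 2 h; earlier points are
excluded because the low-cell-count signal is relative-error dominated.

## Stochastic single-cell model

Reactions: transcription a; degradation δ_m of free and bound mRNA;
binding k_on·R (fixed pseudo-first-order rate — repressor copy-number
fluctuations are deliberately excluded to isolate the intrinsic mechanism;
an extrinsic-noise hook would replace this constant by a sampled rate);
unbinding k_off; translation β and εβ; protein dilution μ. Sampling is the
exact Gillespie direct method (numba-accelerated when available, with an
identical pure-Python fallback), one terminal observation per cell after a
stationarity burn-in of at least 5/μ (tests use 7–12/μ where the
1 − e^{−μt} start-up transient must sit below the Monte-Carlo error). The
sampler is validated against the stationary distribution of the truncated
chemical master equation (reflecting truncation, sparse linear solve) at
total-variation distance ≤ 0.02 on a small instance (state space ≤
9×9×31, 20,000 cells) — sizes chosen so the check is exact-to-truncation
yet cheap.

The matched-mean comparison constructs transcriptional attenuation
a′ = a·(φ_free + ε·φ_bound) from the closed-form occupancies, so the two
conditions share the stationary mean exactly in expectation; the Fano
ordering (translation repression quieter) follows from burst-size
reduction and is asserted at ≥3 Monte-Carlo standard errors with 5,000
cells per condition. The study's measured Fano reductions are experimental
values and only the ordering is asserted. %ON thresholds are always
user-supplied.

## Fluorometry

Blank (medium) trajectories are averaged per time point and subtracted per
channel. Normalized fluorescence is the least-squares slope of
fluorescence vs OD above a configurable OD floor (default 0.01), minus an
autofluorescence constant; growth rate is the slope of ln OD vs time in a
user-given window, or in the longest window with log-linear R² ≥ 0.99 when
asked to find one automatically. Replicates are fitted separately and
averaged by the caller (pooled fitting is available). Crick-space
decomposition: translation proxy = green/red; transcription proxy =
red × growth rate (AU/h).

## Synthetic data

Generators emulate: dose-response tables at the 9-dose inducer series,
population-total and raw plate time courses from the circuit + growth
presets, cytometry-like samples (~10⁴ events; gamma-Poisson mixture for
Fano > 1, Poisson at 1, deterministic-floor thinning below 1), and
biosensor trace sets with blank and negative control. Fluorescence noise
is multiplicative lognormal with unit mean (positive support, constant
CV — the default CV of 5% is a stated assumption standing in for
unreported replicate scatter); biosensor noise is additive Gaussian. All
generators are bit-deterministic under a fixed seed. What they do not
emulate: instrument artifacts (photobleaching, spectral spillover,
evaporation), growth burden of the repressor, inducer depletion, and
cell-size or division-partitioning noise — so passing tests demonstrate
correctness of the estimation machinery under the stated noise model, not
robustness to every feature of real plate or cytometry data.

The kinetics presets pin the measured constants (original: k_on = 1.1
/nM/min, residence 1.5 min; mutant 1: 1.6, 0.41 min; MS2 coat protein:
0.032, 12 min). For mutant 5 the printed rate ratios (~15× slower on,
~10× faster off) and the printed K_D = 87 nM are mutually inconsistent at
exact ratios; the preset fixes K_D = 87 nM exactly (the headline value)
with k_on = 1.1/15 and k_off derived.

## Degenerate inputs and numerical choices

Flat dose-response data raise a singular-fit error; dissociation-only
trace sets raise an unidentifiability error; single-trace fits warn.
Motif scanning is 0-based half-open, normalizes T→U, never searches the
reverse complement, reports the maximal U-run per start (U-run capped at
10 by default for safety; the consensus itself is unbounded), and
classifies point mutants by whether the UAGU core or only flank positions
changed; indels are rejected. CSV schemas encode units in column names
and reject malformed cells with row/column coordinates.
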