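# Methods

## The question and the approach

Class III antiarrhythmic action — prolonging the ventricular action
potential (AP) — is clinically undermined by *reverse rate dependence*
(RRD): prolongation that is larger at slow heart rates, where it is
proarrhythmic, and smaller at fast rates, where it is needed.  The package
asks, per ionic-model parameter, whether perturbing it prolongs the AP with
reverse (RRD), forward (FRD), or neutral (NRD) rate dependence, and what
mechanisms and model features determine the answer.

The method is a population-of-models sensitivity analysis.  For a myocyte
model with parameter registry of size P, we draw n randomized parameter
sets, pace each variant to steady state at a slow (0.2 Hz) and a fast
(2 Hz) rate, and regress log APD90 on the (standardized, log-transformed)
parameters at each rate.  The standardized coefficient vectors **B**_slow
and **B**_fast summarize, per parameter, how strongly and in which
direction it controls APD at each rate; comparing them classifies each
parameter's rate dependence.

## Myocyte models

Five formulations are implemented behind one interface:

| id | species | lineage | states | registry size |
|----|---------|---------|-------:|--------------:|
| LR91 | guinea pig | phase-1 Luo–Rudy | 8 | 18 |
| LR09 | guinea pig | dynamic Luo–Rudy | 15 | 28 |
| TP06-epi / -mid / -endo | human | ten Tusscher–Panfilov 2006 | 19 | 36 |

Equations are transcribed from the primary publications.  For the
guinea-pig dynamic model the sarcoplasmic-reticulum release flux uses this
package's own phenomenological Ca²⁺-induced-Ca²⁺-release trigger (a
first-order activation variable, τ = 4.75 ms, driven by the L-type trigger
current with half-activation at 0.5 A/F and maximal release rate
8 ms⁻¹); the rest of that model follows the published dynamic Luo–Rudy
formulations.  Transcriptions are verified by grid-refinement convergence,
charge conservation over a pacing cycle, and agreement of resting
potential, AP peak and APD90 with values published for each model
(baseline 1-Hz APD90: LR91 ≈ 360 ms, TP06-epi ≈ 311 ms, LR09 ≈ 164 ms).

### Parameter registries

Three categories of parameters are varied, mirroring how a drug or mutation
can act:

* **G / K** — maximal conductances/permeabilities and maximal transport
  rates (pumps, exchangers, SR fluxes).  Multiplicative; baseline in native
  units.
* **p** — one rate-scale factor per Hodgkin–Huxley gate of the major
  channels.  p multiplies the gate rate (τ_eff = τ/p), so *decreasing*
  p_xs *slows* I_Ks activation.
* **V** — one additive shift (mV) per steady-state activation or
  inactivation curve of the major channels.  The shift moves only the
  steady-state curve (x_inf evaluated at V − ΔV); the time constant is
  evaluated at the unshifted voltage.

The exact per-model lists are reconstructions built by enumerating every
conductance, every transport rate, one p per gate and one V per gating
curve of I_Na, I_CaL, I_Kr, I_Ks and I_to; `ratedep models describe <id>`
prints each registry.

## Numerical integration

Gates advance by Rush–Larsen exponential updates (unconditionally stable
for the stiff activation gates); voltage and concentrations advance by
forward Euler.  The step is 0.02 ms whenever the membrane is active
(during the stimulus, or V > −70 mV, or |dV/dt| > 0.1 mV/ms) and 0.25 ms
in diastole.  Halving both steps changes baseline APD90 by < 0.3 ms
(asserted at 0.5 ms in tests).  APD is measured on the fly: the AP starts
at the maximum-dV/dt point and ends at the first downward crossing of
V_peak − f·(V_peak − V_diastolic), located by linear interpolation; the
default fraction f = 0.90 (APD90).  Captured traces keep the integrator's
own non-uniform grid (so charge integrals are trapezoids over the true
steps), with an optional uniform 0.1-ms resample.

## Pacing protocol

Each simulation rests unstimulated for 50 s from the published initial
conditions, then paces at a fixed cycle length (5000 ms or 500 ms;
stimulus: each model's published amplitude/duration, e.g. −52 A/F × 1 ms
for TP06, −80 A/F × 0.5 ms otherwise) until the relative beat-to-beat APD
change stays below 10⁻³ for three consecutive beats, or a beat cap is
reached.  At the cap, a period-2 APD pattern (|APD_n − APD_{n−1}| > 2 ms
while |APD_n − APD_{n−2}| < 1 ms) flags alternans.  An AP that fails to
repolarize before the next stimulus flags repolarization failure.
Population trials warm-start from the *baseline* steady state at the same
rate, so the rest phase is integrated once per rate; beat caps of 60
(slow) / 200 (fast) are used for population work and recorded in run
metadata.

## Populations and exclusions

Each trial multiplies every G/K/p parameter by an independent log-normal
factor with median 1 and log-SD σ (σ = 0.1 for LR91 and the TP06 layers,
0.1823 for LR09, per the per-model assignment of the study conditions;
~95% of factors span 82–122% of baseline at σ = 0.1 and 70–144% at
0.1823) and adds an independent N(0, 2 mV) shift to every V parameter.
The default population size is 300 trials.  Trials showing alternans,
repolarization failure, or an APD more than 3 SD from the per-rate mean
(single pass over non-failed trials) are removed; a trial excluded at
either rate is removed from both so the regressions stay paired.  At these
settings a few trials per population are typically removed.

## Regression sensitivities

Design matrix X: z-scored log scale factors (G/K/p columns) and z-scored
raw shifts (V columns); output: z-scored natural-log APD90.  Ordinary
least squares gives **B** per rate (with n ≈ 100–300 trials and 18–36
near-orthogonal random inputs, OLS and latent-projection variants
coincide for practical purposes, and OLS is fully determined).  Positive
B means increasing the parameter prolongs the APD.  R² is the squared
Pearson correlation between XB and the observed standardized output.
Because each regression standardizes by its own output spread, **B**_fast
is rescaled by σ_logAPD,fast/σ_logAPD,slow before any cross-rate
comparison; the log-APD spread is used (consistent with the standardized
log-output regression).

## The rate-dependence index B_RD

For each parameter:

* same signs: B_RD = |B_slow| − |B_fast,rescaled| — positive means a
  larger effect at slow pacing (RRD), negative a larger effect at fast
  pacing (FRD);
* opposite signs: B_RD = −(|B_slow| + |B_fast,rescaled|) = −|B_slow −
  B_fast| — always negative, because such a parameter can be perturbed to
  lengthen the APD at fast but not slow pacing, the defining FRD property.

The opposite-sign magnitude is this package's choice (only the sign of
that branch is fixed by the classification's definition); it makes |B_RD|
continuous across the sign boundary.  Zeros count as "same sign".
Classification threshold: 0.01 (analysis default); heat-map displays use a
separate 0.03 display threshold.  Within a model, parameters are ranked
1..P from the highest B_RD (most RRD) to the lowest, normalized by P
(most FRD → 1.0); ranks are averaged across models (with a versioned
cross-model name map, `src/ratedep/data/consensus_names.yaml`) to build
the consensus table.  B_RD magnitudes are never compared across models.

## AP-contour RMSD and FRD capacity

For each model's baseline steady-state APs, the fast AP is rescaled in
time by APD_slow/APD_fast (aligned at maximum dV/dt) and the
root-mean-square voltage deviation from the slow AP is computed on a
uniform 1-ms grid over [0, APD_slow], in mV (voltage not normalized; the
diastolic segment is excluded because contour change is an AP-shape
concept).  A model's FRD capacity is its percentage of FRD-classified
parameters; regressing capacity on RMSD across formulations quantifies
the shape-change/capacity relationship.  With only the five implemented
formulations (two guinea-pig, three human layers, no large-notch canine
models) the RMSD range is narrow, so the package asserts the positive
slope and positive rank correlation rather than the full-scope R².

## Charge flux (Q, ΔQ)

Q is the trapezoidal integral of a current over the AP — stimulus onset to
that condition's own APD end — in pC/nF (A/F × ms); positive Q is net
outward charge.  ΔQ = Q_perturbed − Q_control per current per rate;
positive ΔQ contributes to APD shortening, negative to prolongation, and a
rate-asymmetric ΔQ marks a current as a carrier of the perturbation's rate
dependence.  The showcase perturbations are G_CaL at 271% of baseline,
p_xs at 38%, and V_d −5 mV.

Single- and double-perturbation APD scans classify a perturbation's rate
dependence from percent APD changes (|ΔAPD%_slow| vs |ΔAPD%_fast|, NRD
within 0.5 percentage points).  In this TP06-epi transcription, G_CaL
enhancement to 271% is FRD; graded I_Ks block attenuates that forward
rate dependence monotonically and reverses it to RRD at 70% block; at
≥75% block the combined perturbation's fast-rate AP outlasts the 500-ms
cycle (loss of 1:1 capture), so the APD there is undefined rather than
RRD — the reversal itself is robust, its exact block level is model-
transcription-sensitive.

## Synthetic fixtures

The fixture module generates (a) piecewise-linear AP waveforms
(quadratic-ease upstroke, optional notch, flat plateau, linear
repolarization) whose APD and test-current integrals have closed forms;
(b) log-linear populations (log APD = Xβ + ε at each rate, built on the
same empirical standardization the pipeline uses, so noiseless recovery is
exact to machine precision); and (c) the twelve-case taxonomy of how a
current's response to a perturbation can distribute across rates, with
closed-form ΔQ.  These fixtures share the analysis stack's statistical
structure but none of its electrophysiology: passing fixture tests
validates the statistical machinery, not the ODE models — the model-level
claims are covered by the separate simulation-based tests.

## Problem sizes and determinism

Default study conditions are n = 300 trials, σ per model, 2 mV shifts,
rest 50 s, convergence 10⁻³×3 beats.  The shipped test suite and the
acceptance script run LR91 at the full n = 300 and the heavier models at
n = 100–120 with beat caps 60 (slow) / 200 (fast); every reported quantity
records the n used.  All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning; runs are deterministic given the
seed, and trial results are independent of execution order.

## Known limitations

* Only five of the thirteen formulations of the original comparison are
  implemented; the canine models with prominent I_to notches (the high-RMSD
  end of the capacity relationship) are absent, so the capacity regression
  here spans a compressed range and its R² is not comparable to the
  full-scope value.  The I_to-block experiment is therefore exposed
  generically for any model with a G_to parameter rather than for the
  canine pair.
* The LR09 release formulation is phenomenological (see above); its
  population behavior (mostly RRD, small contour change) matches the
  guinea-pig pattern, but per-parameter values should not be read as exact
  reproductions of the published dynamic model.
* Exact per-model varied-parameter lists, steady-state detection
  algorithms and RMSD windowing conventions of the original study are not
  public; the package documents its own conventions (above) and keeps them
  configurable.
* The regression is linear; strong perturbations (e.g. the 271% G_CaL
  showcase) are analyzed by direct simulation, not by extrapolating B.
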