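# Methods

## The membrane model

Each simulated cell is a single-compartment voltage-clamp model with four
current sources, in the physiological sign convention (inward negative):

1. **Capacitive transient.** A command step ΔV through series resistance
   R_s produces a single-exponential transient of peak ΔV/R_s and decay
   τ = R_s·C_m, at both step edges. Pipette/stray capacitance is ignored —
   the single-exponential form is exactly what the ΔQ/ΔV estimator assumes,
   and the estimator is tested against it (charge, not shape, is the
   measurand; the round trip is also verified to be independent of R_s).
2. **Ohmic leak** g_leak·(V − E_leak).
3. **Kir** (inward rectifier, Kir4.1-like): instantaneous conductance
   g_Kir·r∞(V)·(V − E_K) with Boltzmann r∞ centered at E_K and negative
   slope, i.e. rectification without gating dynamics. E_K comes from the
   Nernst equation at the bath/pipette K⁺ of the emulated experiment
   (25/140 mM → ≈ −44 mV at 22 °C). Blocked fully by Ba²⁺ and by Cs⁺.
4. **HCN** (I_h): first-order gate dm/dt = (m∞(V) − m)/τ with
   m∞(V) = 1/(1 + e^{−(V − V_0.5)/S}), S < 0, voltage-independent τ.
   Blocked fully by Cs⁺, insensitive to Ba²⁺.

White Gaussian noise (per-sample SD `noise_sd_pa`) is added before an
optional causal second-order Butterworth low-pass emulating the amplifier's
output filter. Bath conditions are the four salines of the emulated
protocol: high-K control, +CsCl, +BaCl₂, +BaCl₂+CsCl; a condition's blocker
set scales each channel by its unblocked fraction (independent blockers
multiply).

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| holding / steps | −40; −60, −80, −100, −120 | mV | the emulated step protocol |
| step duration | 2000 (pre/post 100) | ms | near steady state for τ ≤ ~300 ms |
| sampling / filter | 1000 / 300 | Hz | the emulated acquisition chain |
| HCN V_0.5, S, τ, E_rev | −90, −8, 300, −30 | mV, mV, ms, mV | activation in the −60…−120 mV window; τ longer than 50 ms, well under the 2 s step |
| Kir V_0.5 = E_rev = E_K, S | ≈ −44, −15 | mV | rectification developing below E_K |
| leak g, E | 0.2, −40 | nS, mV | small leak, quiet at holding |
| C_m, R_s | U(3, 7), U(50, 80) | pF, MΩ | the plausible cell/pipette ranges for these recordings |
| noise SD | 2 | pA | typical perforated-patch noise at this bandwidth |

Units are chosen so products need no conversion factors: nS·mV = pA,
MΩ·pF = µs, pA·ms = fC, fC/mV = pF.

### The capacitance test

`simulate_cap_test` applies +20 mV for 25 ms from holding. Unlike the main
protocol it is sampled wideband (50 kHz, no output filter): τ = R_s·C_m is
0.15–0.56 ms over the default parameter ranges and cannot be
charge-integrated at 1 kHz. Sixteen noisy repeats are averaged into the
stored trace, as amplifiers do for test pulses; this brings the noisy ΔQ/ΔV
error comfortably under the few-percent level.

## The measurement chain

* **Steady-state IV**: mean of the final 200 ms of each step (window
  configurable, must not exceed the step).
* **I_HYP isolation**: element-wise subtraction of the +Cs IV from the
  control IV on an identical voltage grid; no interpolation is ever done.
* **Chord conductance**: G = I/(V − E_HYP) with E_HYP fixed at −30 mV by
  convention, *even when the generative reversal differs* — the fixed
  reversal is part of the method being implemented. The induced bias is the
  driving-force ratio (V − E_true)/(V − E_HYP); it is characterized by a
  test rather than corrected.
* **Boltzmann fit**: trust-region least squares with g_max bounded at 0 and
  the deterministic initialization g_max⁰ = max G, v_half⁰ = voltage nearest
  half-max (ties toward the more hyperpolarized point), S⁰ = −8 mV. The fit
  is invariant to input ordering (points are sorted internally). All-zero
  curves return g_max = 0 with v_half/S marked missing rather than garbage.
* **C_m = ΔQ/ΔV**: baseline = mean of the final 5 ms of the step (≥ 9 decay
  constants at the slowest default transient); ΔQ = trapezoidal integral of
  (current − baseline) over the step. A `settled` flag is cleared when no
  transient is detectable or the plateau still drifts under the baseline
  window.
* **Ba²⁺ decomposition** at the most hyperpolarized common voltage (both
  components largest): i_Kir = I_K − I_Ba, i_h = I_Ba − I_BaCs; the fraction
  i_Kir/(i_Kir+i_h) is defined only when both components are inward;
  components below a 1 pA noise floor are treated as absent, so a pure-HCN
  cell reports 0 rather than an indeterminate flag driven by noise.
* **Classification**: MG-like if G_MAX/C_m < 0.02 nS/pF ("lacks I_HYP");
  hybrid if the Ba²⁺ fraction lies in [0.15, 1]; rod-like otherwise;
  unclassified when inputs are missing. Both thresholds are explicit
  configuration. The floor is ~a tenth of a typical rod-track G_MAX/C_m
  (≈0.2 nS/pF); the band's lower edge sits far above the noise-induced
  Ba²⁺ fraction of rod cells (≲0.02) and far below the hybrid track's
  (≈0.7–0.8). Because both quantities are per-capacitance or dimensionless,
  the call is invariant to cell size.

## Expression model and statistics

−ΔCt = −(Ct_gene − Ct_Actb); each unit is one PCR doubling, so −ΔCt is a
log₂ relative abundance and missing Cts propagate as missing, never imputed.
The cohort generator draws per-gene −ΔCt as Normal(mean, SD) with
mean = base + div_slope·(DIV − DIV₀) + density_effect·[4×]; defaults put a
−5 cycle density effect on c-Kit and Mcam (the strongly suppressed
immaturity genes), a ≈+1/day DIV slope on Rho, and none elsewhere. Realized
HCN conductance couples to the Hcn1 draw as base·2^{(−ΔCt − offset)·strength}
with lognormal cell noise — positive strength on the rod track, negative on
the hybrid track, where a ~1 nS Kir with the same negative coupling takes
over. A cell is assigned the hybrid trajectory with probability
`hybrid_fraction` (default 5/19) only in the low-density, late-DIV group.

Two-way ANOVA uses an OLS fit with Type-II sums of squares (the emulated
designs are unbalanced; `balanced` mode enforces equal cell counts and is
then identical). The interaction is included whenever estimable. A constant
response is defined to give F = 0. Pairwise contrasts are two-tailed
pooled-variance t tests Bonferroni-corrected over the declared contrast
count; a singleton group flags the contrast not-computable instead of
silently shrinking the correction. Normality screening is left to the user
as a diagnostic; no automatic branching. The over-representation test is a
one-sided hypergeometric upper tail per caller-provided gene set with BH
adjustment across sets; no ontology handling is built in.

## What the generator does and does not emulate

It emulates: the step protocol and acquisition chain; pharmacological
isolation with complete block at the stated blocker concentrations; the
cell-size and access-resistance ranges; density- and time-structured
single-cell expression; the coupling between channel-gene expression and
conductance; and the hybrid derailment as a discrete per-cell trajectory.

It does not emulate: partial or voltage-dependent block, channel rundown,
seal/leak drift, liquid-junction potentials, space-clamp error, voltage
dependence of the HCN time constant, single-channel stochasticity, or
biological covariance between genes beyond the shared group means.
Passing recovery tests therefore shows the *analysis chain* is correct and
well-calibrated under these idealized conditions — not that real recordings
meet them; on real data the pharmacology is the binding assumption.

## Numerical choices

- Currents serialized at 6 decimals (pA), derived quantities at 4; study
  outputs are timestamp-free by default so fixed-seed reruns are
  byte-identical.
- Noise seeds for recordings are drawn from an RNG stream separate from the
  cell-level draws, so the realized cohort is identical whether or not
  sweeps are generated.
- The low-pass filter is initialized at each sweep's first sample to avoid a
  spurious start-up transient.
- Degenerate inputs are rejected loudly: zero driving force, mismatched
  voltage grids, <3 fit points, non-finite parameters, unknown condition
  names, unknown config/sidecar keys (named in the error).

## Problem sizes used in the benchmarks

Noisy Boltzmann recovery uses 500 simulated cells; capacitance uses a
5 × 4 (C_m × R_s) grid; classification uses a 200-cell DIV8/1× cohort;
trend-sign rates use 200 replicate cohorts of 12 cells per track; ANOVA
type-I calibration uses 2000 replicate balanced 2×2 designs. Together these
run in about a minute on one CPU, and each metric is stable to well within
its tolerance across seeds.

## Known limitations

- The Boltzmann fit is local least squares; with pathological curves
  (non-monotone G–V from strong noise at few voltages) it can converge to a
  boundary. The convergence flag is honest; the benchmarks quantify the
  practical error at study conditions.
- `ba_fraction` at a single voltage inherits any voltage dependence of the
  Kir/HCN ratio; the default (most hyperpolarized common voltage) maximizes
  signal but is a choice, not a measurement-free quantity.
- The fixed −30 mV analysis reversal biases G_MAX multiplicatively when the
  true reversal differs; comparisons across cells remain valid because the
  bias is shared.
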