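# Methods

## Model structure and assumptions

The package couples three scales. At the molecular scale, receptor–ligand
binding between a CAR T cell (R receptor copies) and a target cell (H antigen
copies) is assumed to reach steady state fast compared with killing and
proliferation (signalling equilibrates in minutes; lysis and division take
hours to days), so only the steady-state complex abundances enter the cell
-scale rates. The bound complex solves the conjugation quadratic
C₀² − (R+H+K_D)C₀ + RH = 0 (smaller root, so 0 ≤ C₀ ≤ min(R, H)). Under
kinetic proofreading the complex additionally survives N sequential
first-order modifications at rate k_p, with unbinding resetting the chain;
at steady state the active end complex is C_N = C₀ αᴺ with
α = k_p/(k_off + k_p), the unmodified bound pool is C₀/β with
β = 1 + k_p/k_off, and the total bound pool is still C₀. These identities
are re-derived in the test suite by integrating the full mass-action chain
(`kp_chain_oracle`) to steady state: the oracle integrates with LSODA over
doubling time windows until the state stops changing, then polishes the
fixed point of the same right-hand side with a Newton-type solve, and agrees
with the closed forms to better than 1e-12 relative over randomized
parameters.

At the cell scale, per-pair lysis and proliferation rates are linear in the
signalling complex: λ_RH = λ_c C and ρ_RH = ρ_c C, with C = C₀ (variant NKP)
or C = C_N (variant KP). Affinity discrimination is therefore entirely
carried by the proofreading factor αᴺ; in the NKP variant two CARs with
K_D ≪ R produce nearly identical responses regardless of k_off, which is the
mechanism probed by the model-selection tests.

At the population scale, cells are binned by copy number (T over a CAR grid,
U over an antigen grid) and evolve by
dU_H/dt = rU_H − Σ_R λ_RH T_R U_H, dT_R/dt = Σ_H ρ_RH U_H T_R − δT_R.
Bin identity is inherited at division — no flux between bins — which is an
explicit modelling assumption (protein mixing across generations is slow
relative to the 3–5 day assays simulated here). N is treated as real-valued
in the closed forms, because calibration produces non-integer best fits; the
mechanistic chain and its ODE oracle are defined only at integer N, and
oracle tests run at N ∈ {0, 1, 3, 7}.

## Units

Binding and modification rates are per second; response constants λ_c, ρ_c
are per day per complex; abundances are molecules/cell. Because the binding
steady state is a pure copy-number quantity (it depends on rates only through
the ratios K_D and α), the per-second and per-day scales never need to be
mixed inside the ODEs, and time is measured in days throughout the population
layer.

Affinities quoted in nM are converted to molecules/cell with a single
calibrated factor, 2.39/17.6 ≈ 0.1358 copies per nM, anchored so that
17.6 nM ↦ 2.39 molecules/cell; this reproduces the companion conversions
(210 nM ↦ 28.5; k_on = k_off/K_D gives 3.77e-5 and 2.39e-5
(molecules/cell)⁻¹s⁻¹). A purely geometric alternative — concentration ×
synapse contact volume, 0.6 (molecules/µm³ per nM) × ½·4π(3.5 µm)²·0.002 µm ≈
0.0924 copies/nM — is exposed in `pascar.units` but is ~32% smaller than the
calibrated factor; the geometric bookkeeping (how the half-participation of
each cell's molecules enters) is underdetermined, so the calibrated factor is
the default and the geometry route is for sensitivity analysis only.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| k_off | complex unbinding rate | s⁻¹ | 9.0e-5 (high), 6.8e-4 (low), 2.2e-5 (highest affinity) |
| K_D | dissociation constant | molecules/cell | 2.39 / 28.47 / 0.258 |
| k_p | proofreading modification rate | s⁻¹ | 7.4e-3 |
| N | proofreading steps | — | 7.1961 |
| λ_c | lysis rate per complex | day⁻¹ | 2.09e-8 |
| ρ_c | proliferation rate per complex | day⁻¹ | 5.31e-9 |
| μ_c, σ_R | constitutive CAR log-abundance mean/SD | ln copies | 7.3589, 0.4672 |
| μ_s, K_H, n_H | synNotch induction plateau/threshold/sharpness | ln copies, copies, — | 6.5367, 2.46e5, 3.8795 |
| σ_R(synN) | induced CAR log-abundance SD | ln copies | 1.1257 |
| r, δ | target replication / effector death | day⁻¹ | 0 |

The CAR distribution parameters are interpreted as mean and SD of the
*natural* log of abundance. This is a flagged convention choice: the source
calibration tables do not state the base, and the two headline mean-CAR
figures quoted alongside them (≈5,000 and 3,038 copies) are not mutually
consistent with any single reading (exp(7.3589 + 0.4672²/2) ≈ 1,750). All
log-base bookkeeping in the synthetic generators is explicit
(`DistributionSpec(base="natural"|"10")`).

r and δ default to zero. The three-to-five-day assays modelled here are fully
determined without them and no calibrated values exist for them; both are
configurable on `PopulationParams`.

## Numerics

Grids are log-spaced, by default 100 bins per axis spanning μ ± 6σ of the
underlying log-abundance distribution, with geometric-mean bin centers.
Discretisation assigns each bin its exact lognormal CDF mass, renormalised to
the population size; a grid covering less than 99% of the mass raises.
Percent lysis changes by <0.5 percentage points when the bin count doubles
(asserted in tests).

The production integrator is adaptive RK45 at rtol 1e-8 with nonnegativity
enforced by clipping solver-tolerance undershoots. Fitting and design loops
use a fixed-step classical RK4 instead (default 120 steps per 3-day assay,
all assay conditions advanced simultaneously in one vectorised sweep): the
fixed step makes the cost function smooth in the parameters (no adaptive
step-count jitter) and an order of magnitude faster, and it matches the tight
-tolerance adaptive solution to ~1e-11 relative on the reference problem
(asserted in tests). Explosive parameter corners visited by multistart
optimisation can overflow the fixed-step scheme; non-finite residuals are
mapped to large finite values so the optimiser retreats.

## Calibration workflow

The cost is the sum over assay conditions of squared standardized residuals
of percent lysis and the day-3 CAR mean and variance, each divided by its
noise scale η. Optimisation uses scipy's trust-region-reflective
least-squares on that residual vector with rates (λ_c, ρ_c, k_p, K_H) in
log10 space and (N, μ, σ, n_H) linear, bounded, optionally multistarted;
AIC = n[ln(SSR/n) + ln 2π + 1] + 2k compares variants (k = 4 for NKP, 6 for
KP on the constitutive panel, n = number of scalar observations).
Confidence intervals are the t-based asymptotics
ẑ ± t_{n−k} √(diag(SSR/(n−k)·(JᵀJ)⁻¹)) computed in the optimizer's
transformed coordinates and mapped back through the monotone transform, so
coverage is preserved. Parameter correlations are estimated by a
nonparametric bootstrap that resamples conditions with replacement and
refits from the full-data optimum; this is the "sampling with replacement"
resampling scheme implemented as a plain bootstrap.

### Identifiability and the reference panel

Every rate in the dynamics enters as λ_c·α(k_off)ᴺ or ρ_c·α(k_off)ᴺ. With
only two distinct unbinding rates, the four parameters (λ_c, ρ_c, k_p, N)
therefore have an exact one-dimensional degeneracy: moving (k_p, N) along
the curve that preserves the ratio α(k_off₁)ᴺ/α(k_off₂)ᴺ while rescaling
λ_c and ρ_c leaves every prediction unchanged. The reference synthetic
calibration panel (`constitutive_conditions`) consequently uses three
affinities — high and low at five antigen levels each, plus the highest
-affinity CAR (K_D 1.9 nM, k_off 2.2e-5 s⁻¹, the affinity used in the
E:T-ratio prediction experiments) at two levels — giving 12 conditions × 3
observables = 36 scalar observations and full local identifiability of all
six constitutive parameters.

## Synthetic data

The generator emulates the study conditions: 10,000 effectors vs 20,000
targets, 3-day duration, target antigen lognormals at mean levels
10^4.7–10^6.9 with SD 0.3 in log10 units, and measurement noise of 3
percentage points on lysis, 5% relative on the day-3 CAR mean and 15%
relative on its variance (plausible replicate-well and flow-moment noise;
the study conditions do not state these scales). Weights η² are estimated
from replicate draws, mimicking how replicate wells would be used. What the
generator does *not* emulate: fluorescence-to-copy-number calibration error,
spectral spillover, doublets, non-lognormal abundance tails, and any
systematic model misspecification — so passing recovery/coverage tests shows
the estimation machinery is correct and calibrated *under the model*, not
that the model is correct for real cytometry data.

SynNotch induction is treated as instantaneous: the induced CAR
log-abundance mean is the Hill function μ_s·μ_Hⁿ/(μ_Hⁿ + K_Hⁿ) of the target
population's antigen level, with a fixed induced spread σ_R(synN)
independent of μ_H; induction/decay kinetics are out of scope.

## Pareto design optimisation

The in-silico mixed assay co-cultures 10,000 effectors with 20,000 targets
split 1:1 (configurable 1:4/4:1) between healthy (mean 10^4.5 copies) and
tumour cells for 5 days; both target classes are separate structured vectors
sharing one effector pool. The tumour antigen mean defaults to 10^6.9
(in-source alternatives 10^6.5 and 10^6.2 exist; the value is configurable).
SynNotch effectors in the mixed assay express CAR according to the *tumour*
antigen level. Objectives f₁ = % healthy lysed and f₂ = 1/(% tumour lysed)
are both minimised; f₂ is capped at 1e6 when tumour lysis is numerically
zero.

Fronts are computed either by a seeded NSGA-II implemented in-package (fast
non-dominated sort, crowding distance, binary tournament, SBX crossover
η=15, polynomial mutation η=20; defaults population 40, 60 generations) or
by a deterministic log-spaced grid search followed by an O(n²) dominance
filter, which doubles as the brute-force oracle for the evolutionary mode.
NSGA-II was written here because no multi-objective-optimisation library is
part of the dependency set; it is validated against the grid oracle in the
tests.

## Problem sizes used in tests and the acceptance script

Fitting studies run on 16 CAR × 14 antigen bins with 60 RK4 steps; design
studies on 24–40 × 20–32 bins with 120–200 steps; the coverage study uses
100 noisy replicates refit from the known truth (the fits are local and the
quantity under test is the CI, not the optimiser's global behaviour); the
oracle-equivalence study uses 100 random parameter sets at integer
N ∈ {0, 1, 3, 7}. These sizes were chosen as the smallest at which the
grid-refinement and integrator-consistency checks pass with margin.

## Known limitations

- Contact kinetics are mass-action on population totals; a weighted-sum
  contact model (finite conjugation capacity per effector) is not included.
- CAR dilution/mixing at division, spatial synapse structure,
  receptor clustering, exhaustion and memory phenotypes are out of scope.
- Diffusion corrections to the binding rates are not implemented (reported
  to change rates by ≤20% with negligible effect on the active complex).
- The two-k_off degeneracy above means fits to datasets with only two
  affinities report enormous, strongly correlated CIs for (k_p, N); this is
  a property of the experiment design, not a solver failure.
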