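# pascar

Abundance-structured population dynamics for CAR T cell cytotoxicity, with
kinetic proofreading, weighted least-squares calibration, and Pareto design
optimisation of CAR constructs.

## The problem

CAR (chimeric antigen receptor) T cells kill target cells that display a
cognate antigen such as HER2, but healthy cells express the same antigen at
lower copy numbers and get killed too. Both the receptor abundance *R* across
a CAR T cell population and the antigen abundance *H* across target cells
vary over orders of magnitude cell-to-cell, so bulk models with a single mean
abundance miss the biology. `pascar` is for quantitative immunologists and
systems biologists who want to (i) simulate co-culture cytotoxicity assays of
heterogeneous effector/target populations, (ii) calibrate the model to
percent-lysis and flow-cytometry readouts, and (iii) search the CAR design
space (affinity, induction threshold) for constructs that kill tumour cells
while sparing healthy ones.

## The model

A CAR T cell with *R* receptors conjugating a target cell with *H* antigens
forms receptor–ligand complexes with dissociation constant
K<sub>D</sub> = k<sub>off</sub>/k<sub>on</sub> (all in molecules/cell units).
The steady-state bound complex is the smaller root of

    C₀² − (R + H + K_D) C₀ + R·H = 0.

Two signalling variants map complexes to cell responses:

* **NKP** — output ∝ C₀;
* **KP** (kinetic proofreading) — the complex must survive *N* sequential
  modifications at rate k<sub>p</sub> before becoming the active complex
  C<sub>N</sub> = C₀·αᴺ with α = k<sub>p</sub>/(k<sub>off</sub>+k<sub>p</sub>);
  unbinding resets the chain. Short-lived (high-k<sub>off</sub>) complexes are
  filtered out, which is what discriminates ligand affinities at equal K_D
  occupancy.

Per-cell-pair lysis and proliferation rates are linear in the signalling
complex, λ_RH = λ_c·C and ρ_RH = ρ_c·C (day⁻¹), and the populations evolve by
the structured ODEs (no mixing between abundance bins; daughters inherit the
mother's CAR abundance):

    dU_H/dt = r·U_H − Σ_R λ_RH T_R U_H
    dT_R/dt = Σ_H ρ_RH U_H T_R − δ·T_R

Percent lysis is measured against an effector-free control:
100·(1 − ΣU(t) / (ΣU(0)·e^{rt})).

On top of the forward model sit: a weighted least-squares calibration of
(λ_c, ρ_c, k_p, N) and the initial CAR distribution from percent-lysis and
day-3 CAR moments (cost standardised by per-observable noise scales η), AIC
model comparison AIC = n[ln(SSR/n) + ln 2π + 1] + 2k, asymptotic confidence
intervals, a condition-resampling bootstrap for parameter correlations, and a
two-objective Pareto optimisation (NSGA-II or grid search) minimising healthy
-cell lysis and 1/(tumour-cell lysis) in an in-silico mixed assay.

## Worked example

Simulate the reference co-culture: 10,000 constitutive CAR T cells
(high-affinity CAR, K_D = 17.6 nM) against 20,000 targets at a mean antigen
level of 10^6.2 molecules/cell, for 3 days:

```python
import numpy as np
from pascar import (
    AbundanceGrid, BindingParams, KPParams, PopulationParams, ResponseParams,
    StructuredPopulation, car_moments, discretize_lognormal, integrate,
    kd_to_copies, percent_lysis,
)

binding = BindingParams(k_off=9.0e-5, K_D=kd_to_copies(17.6))  # 2.39 copies
kp = KPParams(k_p=0.0072, N=6.9031)                            # ~7-step chain
params = PopulationParams(
    binding=binding, kp=kp,
    resp=ResponseParams(lambda_c=1.33e-8, rho_c=1.52e-8))

grid_R = AbundanceGrid.log_spaced(7.2479, 0.4841, n_bins=100)  # CAR copies
grid_H = AbundanceGrid.log_spaced(6.2 * np.log(10), 0.69, n_bins=100)
pop0 = StructuredPopulation(
    grid_R, grid_H,
    discretize_lognormal(7.2479, 0.4841, 10_000, grid_R),
    discretize_lognormal(6.2 * np.log(10), 0.69, 20_000, grid_H))

traj = integrate(pop0, params, [0.0, 1.0, 2.0, 3.0])
print(f"percent lysis at day 3: {percent_lysis(traj, 3.0):.1f}")
mean, var = car_moments(traj.state_at(3.0))
print(f"day-3 CAR mean {mean:.0f} copies, variance {var:.3g}")
```

Output:

```
percent lysis at day 3: 72.8
day-3 CAR mean 2237 copies, variance 2.94e+06
```

72.8% of targets are lysed by day 3; proliferation driven by target
engagement expands the effector pool ~2.7-fold and shifts its CAR
distribution upward (initial mean ≈ 1590 copies → 2237), because
high-abundance subpopulations proliferate faster.

The same machinery is exposed on the command line:

```bash
pascar convert --kd-nm 17.6 --koff 9e-5        # affinity unit conversion
pascar synth --seed 7 --out data.csv           # synthetic calibration panel
pascar fit --data data.csv --variant kp --out fit.json
pascar pareto --scenario constitutive_koff_sweep --mode grid --out front.csv
```

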