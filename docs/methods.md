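# Methods

## The model and its assumptions

`gliotwin` simulates a glioma as a well-mixed ecology of tumor cells and
tumor-associated macrophages. The assumptions worth keeping in mind:

* **Cooperative Gompertzian growth.** Neither tumor cells nor macrophages
  proliferate alone: each growth term is bilinear in the two populations
  and carries the factor `ln(K/V)`, so all proliferation shuts off as the
  total volume `V` approaches the carrying capacity `K`. A consequence is
  that the per-capita tumor growth rate scales with the pro-tumor
  macrophage count, which itself scales with tumor size — growth
  self-accelerates until the Gompertz factor wins. This drives two
  practical choices documented below (group-specific `ρ_T` scales, and
  the shape of the synthetic follow-up design).
* **Binary macrophage phenotypes.** Macrophages are either anti-tumor
  (`A`, killing tumor cells at rate `μ` per cell per day) or pro-tumor
  (`P`); conversion A→P is Michaelis–Menten in tumor burden,
  `λ·A·T·K_λ/(K_λ+T)`, saturating because only a limited number of
  microglia can be reprogrammed. The alternative algebraic reading
  `λ·A·T/(K_λ+T)` is available via
  `ModelParams(conversion_form="michaelis")`; the saturating form is the
  default because its large-`T` limit (`λ·A·K_λ`) expresses that cap
  directly.
* **MDM influx.** Monocyte-derived macrophages enter in proportion to
  tumor burden, `φ·T`, and are pro-tumor on arrival. The `P1`/`P2` split
  records provenance (MG-derived vs MDM-derived) without altering pooled
  dynamics: conversion feeds `P1`, influx feeds `P2`, proliferation and
  decay apportion pro rata — integrating the pool as a single equation
  gives the same `P` to solver precision (tested).
* **Recruitment coupling.** Tumor expansion recruits fresh microglia into
  `A` through `ξ·dT/dt`, with `dT/dt` substituted analytically from the
  tumor equation so the system stays an explicit ODE. A shrinking tumor
  recruits nothing: the term is clamped at zero by default
  (`clamp_recruitment=False` disables this), and impulsive IR jumps never
  feed it.
* **Radiation as impulses.** Each fraction instantly moves `1−S_T` of
  tumor cells and `1−S_M` of live macrophages into damaged pools that
  still occupy volume but do nothing else, and decay with time constants
  `τ_TD`, `τ_MD`. Total cell count is conserved at the instant; volume is
  continuous across a fraction and declines only as damaged cells clear.
  Dose is not modeled (no linear-quadratic relation): survival fractions
  are the primitive. The influx coefficient escalates per fraction by
  `1/S_T`, compounding over a course with no cap; inflammation adds
  `φ_D·(TD+MD)` to the `A` equation from the first fraction onward.
* **Therapies are parameter modifiers** active on half-open windows
  `[start, end)`. Neutral settings are exact no-ops at the parameter
  level, so baseline trajectories are reproduced bit-for-bit (tested).

## Default parameters

The two killing-rate presets are group-specific: `μ = 1.2e-4`
/day/cell for untreated (control) tumors and `μ = 5e-7` for the
irradiated group, selected automatically by `ModelParams.for_group`. The
remaining fixed parameters are not identifiable from volumetric data
alone; the shipped defaults are this package's calibration, chosen once
by forward simulation so the synthetic study conditions hold (control
tumors grow from ~3 mm³ toward fatal volumes in ~2 weeks; irradiated
tumors dip during the 5-fraction course and recur around day 30; MDMs
dominate the macrophage pool at recurrence; macrophage-mediated killing
sits below ~1 %/day under the IR-group `μ`).

| parameter | default | units | role |
| --- | --- | --- | --- |
| `rho_T` | 3e-4 (control regime) | /d/cell | tumor proliferation; the per-subject free parameter |
| `rho_P`, `rho_A` | 1e-7, 2e-7 | /d/cell | macrophage proliferation coefficients |
| `lam`, `K_lam` | 3e-6, 1e4 | /d/cell, cells | A→P conversion and its saturation |
| `phi` | 3e-4 | /d | MDM influx coefficient; escalates at IR fractions |
| `xi` | 5e-4 | – | microglia recruited per net new tumor cell |
| `tau_M` | 15 | d | macrophage lifespan |
| `K` | 300 | mm³ | carrying capacity (intracranial mouse scale) |
| `v_T`, `v_M` | 1e-4 | mm³ | effective volume per cell including local stroma |
| `tau_TD`, `tau_MD` | 3 | d | damaged-pool clearance |
| `S_M` | 0.8 | – | macrophage survival per fraction |
| `phi_D` | 2e-3 | /d | inflammation flux from damaged cells into A |

The unit volumes are deliberately large (1e-4 mm³ per cell): they are
effective volumes that make cell *counts* consistent with the killing
scale the `μ` presets imply (`μ·A` of order 0.1–1 %/day for irradiated
tumors with `A ≈ 1e4`).

Two structural facts about the defaults:

* **Group-specific `ρ_T` scale.** Because `dT/dt ∝ T·P` and `P` scales
  with volume, a tumor seeded at 41.5 mm³ carries a ~14× larger `P` than
  one at 3 mm³, and the same `ρ_T` would give it a ~14× larger per-capita
  growth rate. Realistic treated-group dynamics therefore need `ρ_T`
  around 5e-6 /d/cell, versus 3e-4 for controls — the same kind of
  group-level difference that motivates the two `μ` presets. The
  synthetic generator encodes this with per-group log-normal medians.
* **Soft ceiling at `K`.** The influx term `φ·T` carries no Gompertz
  factor, so the equilibrium volume sits a sliver above `K` (relative
  overshoot `≈ v_M·φ·T·τ_M/K ≈ 4e-5` at defaults). Tests assert the
  ceiling with a 1e-4 relative margin.

## Initial conditions and fitting

A single observed volume `V0` seeds the six compartments through
population fractions: `T0 = f_T·V0/(v_T f_T + v_M f_A + v_M f_P)` and
analogously for `A0`, `P0` (all macrophage unit volumes equal), `P0`
split equally MG/MDM, damaged pools empty. For small untreated tumors
the fractions are the experimental values `f_T = 0.96`, `f_A = 0.035`,
`f_P = 0.005`. Irradiated animals start much larger, so their fractions
are predicted from pooled ordinary-least-squares regressions of live-pool
count fraction on relative volume `V/V_max`, learned from the fitted
control trajectories; a treated subject's relative volume is taken
against the maximum volume of the largest control (the pairing rule is
configurable — the data offer no canonical pairing).

Fits minimize the RMSE between model and observed volume with
Nelder–Mead (max 500 iterations, x-tolerance 1e-6, f-tolerance 1e-8) on
unconstrained scales — `log ρ_T`, and `logit S_T` for the two-parameter
treated fits — with three deterministic starts around the initial guess.
Multi-start is an engineering addition over the original single-start
procedure; on well-conditioned synthetic cases the log/logit and
box-constrained parameterizations agree. Subjects need at least three
observation points. The fitting loop integrates at `rtol=1e-6` for
speed; reported trajectories default to `rtol=1e-8`, `atol=1e-3` cells
with an adaptive RK45 solver, integrated piecewise between events and
restarted from the post-impulse state at each fraction.

## Biomarker panel

The in silico analogues of the experimental markers are count-based
package definitions (versioned here; they are not experimentally derived
formulas):

* macrophage % (Iba1⁺ analogue): `100·(P1+P2+A+MD)/(T+TD+P1+P2+A+MD)`
* apoptosis % (CC3⁺ analogue): `100·(TD+MD)/total`
* proliferation % (Ki67⁺ analogue): `100·ρ_T·P·ln(K/V)·τ_cycle`, clipped
  to [0, 100], with `τ_cycle = 1` day converting an instantaneous
  per-cell rate into a labeled fraction
* killing %/day: `100·μ_eff·A`, the per-day fractional tumor loss to the
  kill term; time averages use the trapezoid rule
* MG/MDM split: `A + P1` vs `P2` of the live macrophage pool (sums to
  100 by construction)

Epochs on a treated trajectory: `control` = first observation,
`post_course` = last fraction time, `day21` = 21 days after IR
initiation, `recurrence` = first post-course time the volume re-attains
its value at the first fraction.

## Digital twins and trials

A twin carries a subject's fitted `ρ_T` (and `S_T`), the shared fixed
parameters, its initial state, and a death threshold of 1.2× the last
observed volume (ground-truth final volume for synthetic twins). Trials
are paired: every twin is simulated under both arms with identical
solver settings, death is the bisection-located first crossing of the
threshold (0.01-day precision; censored at the horizon, default 200
days), and results report per-twin paired gains alongside the unpaired
Kaplan–Meier/log-rank comparison — the paired gains remain meaningful
when the log-rank test, designed for independent samples, is not
significant. Cohen's d uses the pooled-SD convention (first group minus
second) with a 95 % CI from noncentral-t inversion, labeled `inc` when
the CI spans zero. Benefit prediction regresses gains on `log ρ_T` (OLS,
F-test) and reports the ROC AUC of `ρ_T` against a median (therapies) or
sign (protraction) split of the gains.

## The synthetic cohort

`CohortSpec` defaults emulate the reference study's shape: 4 controls
with initial volumes log-normal around 3 mm³, 10 treated subjects with
log-normal initial volumes of mean 41.5 mm³, 4–7 irregular observation
points per subject, heterogeneity concentrated in `ρ_T` (log-normal,
log-sd 0.25, per-group medians as above), per-subject radiosensitivity
`S_T ~ U(0.55, 0.8)`, and multiplicative log-normal measurement noise
with `σ = 0.1` (~10 % volumetric error, typical of small-animal
volumetry). Controls are observed over 16 days; treated subjects are
followed to a regrowth endpoint — the first post-course time the tumor
re-exceeds 1.5× its baseline volume (floored at 15, capped at 150 days)
— so the last observation is the largest, as in animals followed to a
humane endpoint, and the 1.2× death threshold always exceeds the initial
volume while staying well below `K`. Each subject draws its design and
noise from independent seeded substreams, so changing the noise level
leaves the sampling design untouched.

What the generator does **not** emulate: observation-level correlated
errors, measurement dropout, tumors that durably regress (the model's
feedback always regrows them), inter-subject variation in the fixed
parameters, or the real mice's actual curves. Passing recovery tests
therefore show that the fitting machinery inverts the model's own
forward map under realistic noise and sampling — not that the model is
identified by any particular real dataset.

## Numerical choices

* Solver RK45, `rtol=1e-8`/`atol=1e-3` (reporting) or `1e-6`/`1` cells
  (fitting and trial loops); tolerances are arguments everywhere.
* Degenerate volume: growth terms are defined as 0 when `V ≤ 0` (empty
  system) instead of evaluating `ln(K/0)`; tiny negative solver
  excursions are clamped at segment boundaries and in the reported
  states.
* Events: impulses are applied atomically at `t_j`; integration restarts
  from the mapped state; reported states at an event time follow the
  right-continuous (post-impulse) convention; therapy windows are
  `[start, end)` and simulations split at window boundaries equal
  unsplit ones.
* Trial grids are 0.25-day; death times are refined by bisection on the
  interpolated volume to 0.01 days.
* Fit failure inside the objective returns a large penalty (1e12) so the
  simplex retreats rather than crashing.

## Known limitations

* No spatial structure, no dose dependence, no monocyte or lymphocyte
  compartments, binary M1/M2 phenotypes.
* The bilinear cooperative coupling makes growth super-exponential until
  the Gompertz factor dominates; volumes traverse the mid-range quickly,
  so sparse designs can land most observations near the floor or the
  ceiling of the growth curve.
* Under the default calibration, protracting the inter-fraction interval
  *reduces* survival for every synthetic twin (the regrowth between
  spaced fractions outweighs the delayed influx escalation); whether
  protraction helps is parameter-regime-dependent, and this calibration
  sits in the unfavorable regime.
* The manual iterative calibration of fixed parameters against
  group-level biomarkers is exposed as a workflow (simulate → compare →
  adjust → refit), not an algorithm; it is inherently judgment-driven.
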