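# Methods

## Coupled feast–famine flux balance model

Growth over one feast–famine cycle is represented by two average flux
distributions, one per phase, each satisfying the steady-state balance
`S·v = 0` over the *internal, non-polymer* metabolites with the model's
flux bounds. This deliberately ignores within-phase dynamics: a phase is a
single averaged metabolic state, and the cycle is assumed periodic
(storage levels return to their starting point every cycle). Biomass
growth within the cycle is not compounded into the phase weighting — the
weights are the time fractions alone, since the averaged-flux picture
gives no principled biomass weighting and specific (per-g-DW) rates are
the measured quantities.

Storage polymers are the one deviation from steady state: their rows are
removed from the per-phase balance and replaced by a cross-phase coupling
constraint per pool,

    f · a_F(pool) + (1 − f) · a_N(pool) = 0,

with `f` the feast time fraction and `a(pool)` the polymer's net
production rate under the phase fluxes. Feast accumulation therefore
exactly funds famine consumption.

Phase policy: during famine, substrate uptake reactions (those the feast
phase constrains) are closed unless explicitly overridden, and storage
*synthesis* is disabled; during feast, storage *degradation* is disabled.
This prevents futile simultaneous synthesis/degradation cycling that the
L1 sub-objectives would otherwise have to suppress, and both switches are
exposed as per-phase flags for sensitivity analysis, since one can
alternatively leave both directions open and rely on the sub-objective.

### Objectives

Step 1 maximises the time-weighted cycle growth rate
`μ_cycle = f·μ_F + (1 − f)·μ_N`. Step 2 fixes that optimum and minimises
one of three sub-objectives: `min_fluxes` (`|v_F|₁ + |v_N|₁`),
`env_moma` (`|v_F − v_N|₁`, environmental minimisation of metabolic
adjustment) or `combined` (their sum). The growth optimum is fixed by the
inequality `μ_cycle ≥ (1 − 10⁻⁶)·μ*_cycle` rather than an equality — the
standard lexicographic guard against round-off infeasibility; the
fixing fraction is configurable in `LPSettings`. When a target cycle
growth rate is supplied (e.g. 1/SRT for a chemostat-like constraint) it
is imposed as an equality instead and step 1 is skipped.

All L1 terms are linearised with epigraph auxiliaries (`t ≥ v`, `t ≥ −v`,
minimise `Σt`), which gives the same optimal norm value as
positive/negative flux splitting with fewer variables. The norm runs over
*all* reactions, exchanges included, with a flag to exclude exchanges.
The optimal norm value is unique; the minimising flux vector need not be,
and ties are left to the solver (scipy's HiGHS).

### Units

Internally all fluxes are mmol/(g-DW·h) and growth rates share the
model's time base. User-facing storage fluxes are also reported in
g-COD/(g-COD-biomass·d): a monomer's COD content is its theoretical
oxygen demand `8·(4C + H − 2O − 3N)` g-O₂/mol (oxidation to CO₂/H₂O with
nitrogen to NH₃ — the no-nitrification convention of COD analytics), and
biomass is converted with a configurable COD factor defaulting to
1.42 g-COD/g-DW, the classical oxygen equivalence of biomass of
composition CH₁.₈O₀.₅N₀.₂.

### Maintenance calibration

`calibrate_maintenance` evaluates the coupled problem over a (GAM, NGAM)
grid at the required cycle growth rate and returns the pair whose
predicted total storage COD flux is closest to the observed one, with
ties broken toward smaller GAM then smaller NGAM. An exact fit is not
guaranteed (the fit is a nearest point on a finite grid and the response
is piecewise linear); a non-zero residual is returned with a warning
flag. Note that the total storage flux can be insensitive to GAM in
regimes where famine growth is zero — reported fits should be read
together with the residual and the grid.

## Toy models

The generator builds three variants of a minimal network (substrate
uptake capped at `q`; catabolism S → 2 ATP; biomass S + GAM·ATP → X;
maintenance ATP sink at NGAM; storage S + ATP ⇌ back to S). The linear
variant has the closed-form optimum `μ* = (2q − NGAM)/(2 + GAM)`; the
redundant variant adds a second catabolic route of identical net
stoichiometry (alternate optima); the two-pool variant adds a second,
stoichiometrically identical storage pool (two-axis storage scans). For
the reference cycle (f = 0.5, q = 10, GAM = 2, NGAM = 1) the phase
balances give `μ_F = (19 − 3s)/4` and `μ_N = (2s − 1)/4` at forced feast
storage `s`, hence `μ_cycle = (18 − s)/8` on the feasible range
`s ∈ [1/2, 19/3]`; the famine maintenance requirement sets the lower end
and non-negative feast growth the upper end. These closed forms are the
package's primary correctness anchors, alongside brute-force vertex
enumeration of the LP polytopes on instances of ≤ 9 reactions.

## Data reconciliation

Measured conversions `y` with independent standard errors (diagonal Σ —
no covariance structure is assumed) are reconciled against linear
conservation balances `E·x = 0` built from elemental compositions; rows
may be any conserved quantities (C, H, O, N, charge, COD/degree of
reduction), and the module is unit-agnostic as long as the table is
internally consistent. Unmeasured conversions are projected out through
the left null space of their column block; a conversion is *calculable*
iff its coordinate is orthogonal to the null space of that block. The
reduced system `R` on measured conversions gives the constrained weighted
least-squares adjustment in closed form and the gross-error statistic

    h = εᵀ (R Σ Rᵀ)⁻¹ ε,   ε = R y,

which is χ² with df = rank(R) under balanced truth; the test uses
α = 0.01 by default (99 % confidence). Calculable unmeasured conversions
are solved from the reconciled vector with first-order SE propagation
through the reconciled covariance `Σ − ΣRᵀ(RΣRᵀ)⁻¹RΣ`. Serial
elimination of multiple simultaneous gross errors is out of scope: the
test flags inconsistency, it does not localise several offenders.

## Objective discrimination

Candidate objective functions are compared through posterior probability
shares with independent Gaussian likelihoods: each observed storage flux
contributes `log N(y_i | m_ki, se_i²)` to candidate `k`, priors are equal
by default, and shares are normalised likelihoods computed via
log-sum-exp (stable for residuals of 100 SE and beyond). This is the
simplest member of the Bayesian discrimination family; the likelihood
choice is isolated behind one function and an SE floor flag supports
sensitivity analysis when an observable's printed SE is near zero. On the
shipped *R. jostii* RHA1 storage-flux table the environmental-MOMA
candidate receives a share ≥ 99.999 %; the exact magnitude of the losing
share depends on the likelihood family, so only the winner's dominance
should be interpreted.

## Synthetic measurement campaigns

`simulate_measurements` converts a solved cycle into feast-phase
converted carbon per cycle (substrate, biomass, storage pools; a CO₂
term closes the carbon balance exactly, as respirometry would) over a
default 6-hour cycle, then adds independent additive Gaussian noise at
given SEs, deterministically per seed. Because the truth balances
exactly, zero noise reconciles with `h = 0` and noisy replicates make the
χ² test's false-rejection rate directly checkable (it is 0.99 % over
10⁴ replicates at α = 1 %). The generator emulates measurement error
only: it does not model within-phase dynamics, sampling-time bias, or
correlated analytics errors, so passing tests demonstrate the statistics
are correctly calibrated under the stated error model rather than
robustness to real-data pathologies.

## Problem sizes and numerical choices

The test and acceptance workloads run on toy networks of 7–9 reactions,
grids of ≤ 20 cells and 1000-replicate Monte-Carlo loops — sizes chosen
so the full suite solves in seconds while still exercising every code
path; the solvers themselves are generic and accept genome-scale SBML-FBC
input (storage-pool and maintenance annotations supplied as
configuration, since plain SBML cannot express them). Feasibility
tolerance is 10⁻⁹ in HiGHS; mass-balance residuals of optimal solutions
are asserted ≤ 10⁻⁶; rank decisions in reconciliation use an
SVD threshold scaled by the matrix size. Preset feast fractions are 0.38
(glucose) and 0.40 (acetate), the observed values for the two reference
substrates.

## Known limitations

- Exactly two phases per cycle; the LP assembly would extend to more but
  the v1 interface fixes two.
- No Euclidean (QP) MOMA, loopless FBA, gene–protein–reaction rules or
  thermodynamic constraints.
- Maintenance calibration is a grid search, not a continuous optimiser;
  resolution is the caller's grid.
- The discrimination likelihood treats observation SEs as exact known
  standard deviations; no marginalisation over model parameters.
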