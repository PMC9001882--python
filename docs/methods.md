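# Methods

## Models

Both systems are deterministic ODE models in molecules per cell (cells
for the population variable), with time in minutes.  Every intracellular
species carries a first-order dilution term `−µ·s` from growth at
specific rate µ, plus its own degradation constant (defaults may
coincide, but each species has its own knob).  The population grows
logistically, `dx/dt = µ·x·(1 − x/x_max)`, and all cells are identical,
so population sums reduce to `x·(per-cell amount)`.

### Merging pathway (6 states: S1, P, E, σ, aσ, X)

Constant precursor uptake `K_S1`; a two-substrate Michaelis–Menten flux
`V = kcat·E·S1·S2/(Km1·Km2 + Km2·S1 + Km1·S2 + S1·S2)` produces P.  The
secondary substrate S2 is an externally set availability (a parameter,
not a state): perturbations act on it directly, which matches a sudden
environmental change and keeps the disturbance channel explicit.  Enzyme
expression is a copy-number-scaled Hill function of free σ,
`CN·a0 + CN·a1·σ²/(kd20²·CN² + σ²)` (half-activation at σ = kd20·CN); σ
is expressed constitutively (`CN·k_σ`), anti-σ from a product-inducible
promoter `CN·k_aσ·CN²(1+P/kdp)²/(CN²(1+P/kdp)² + TF²)`, and the pair
annihilates at rate `γ·σ·aσ`.  The repressing transcription factor TF is
modeled as a constant pool: it is constitutive, and giving it its own
ODE changes nothing at steady state.

Subtracting the two controller equations shows the integral action:
`d(σ−aσ)/dt = CN·k_σ − CN·k_aσ·f(P) − d·(…)`; with degradation and
dilution removed, equilibrium forces `f(P*) = k_σ/k_aσ` — a setpoint on
P independent of S2.  Dilution adds a leak proportional to µ, which is
the quantitative trade-off the tuning explores.

### Naringenin system (16 states)

Five metabolic balances (L-tyrosine → p-coumaric acid → p-coumaroyl-CoA
→ naringenin chalcone → naringenin) with Michaelis–Menten fluxes and
fixed enzyme pools except CHS, the actuated merging enzyme, whose flux
is the two-substrate form with the malonyl-CoA availability `Ma` as the
external disturbance input.  The extended biosensor drains a small
fraction of naringenin through F3H/FLS to kaempferol (Ka), which
inactivates the QdoR repressor of the anti-σ promoter; QdoR itself is
constitutive.  The controller has an explicit σ·aσ complex: binding at
`(k₋c/kdc)·σ·aσ`, unbinding at `k₋c·complex`, its own clearance; σ is
driven by the AHL/LuxR-activated P_Lux promoter and anti-σ by the
QdoR-repressed P_qdoI promoter, both with leakage fraction α (promoter
activity `α + (1−α)·f`, so the effective activation lives in [α, 1]).
CHS expression adds a constitutive baseline (fraction β) to the
σ-activated P20 term.  AHL diffuses across the membrane
(`dA/dt = D·(Vc·Ae − A) − (d_A+µ)A` with `Vc = V_cell/V_ext`) and the
external pool is drained by the whole population
(`dAe/dt = D·x·Vc·(A − Ae) − d_Ae·Ae`).

Promoter-occupancy groupings are concentrated in `pathtune.kernels`
(`f_lux`, `f_qdo`, `f_p20`, `hill_activation`, `biosensor_fraction`):
each is one named function, so an alternative reading of how copy
numbers and dissociation constants combine in a denominator is a
one-line change that every caller inherits.  Inside `f_qdo` the
biosensor-plasmid copy number is used (the QdoR device characterization
belongs to the biosensor); LuxR is expressed from the controller
plasmid.

## Simulation protocol

`Protocol` integrates on [0, t_end] with LSODA at rtol 1e-8 / atol 1e-6
(all configurable).  A perturbation is a parameter step: integrate to
t_pert once, rescale the target availability by (1−reduction), restart
the solver.  `run_paired` shares the pre-perturbation segment, so the
unperturbed and perturbed trajectories are *identical* (same floats) up
to the split.  Defaults: merging — 60% S2 step at 2000 min, evaluated at
t_end = 4000 min; naringenin — 60% malonyl-CoA step at 65 h (3900 min),
evaluated at 130 h.  The evaluation time T defaults to t_end, chosen to
leave room for post-perturbation settling.

Numerical notes: solver trial states may undershoot zero, so the RHS
clamps inputs to the nonlinear kernels at zero while keeping linear
clearance on the raw value (any undershoot decays back); output states
are clipped at zero, with a warning if the undershoot exceeds 1e-9
molecules.  In the dilution-free integral limit (controller degradation
zero, µ = 1e-6) LSODA's stiffness detection thrashes on the σ/aσ
annihilation manifold; the `method="BDF"` protocol option is used for
that regime.  Endpoints are stable to better than 0.01% under tolerance
halving (tested).

## Objectives and constraints

* `J1 = |target − K·P(T)|`, absolute value so the error is sign-free.
  For naringenin `K_Nar = mw·x(T)/(N_A·V_ext)` converts molecules per
  cell to g/L: the per-liter titer needs the culture volume, so K_Nar
  includes a division by V_ext.
* `J2 = (P_unp(T) − P_pert(T))/P_unp(T)`, kept signed: a perturbation-
  induced production *gain* is a negative loss and the optimizer may
  exploit it.
* `J3`: the pre-perturbation σ series is clipped to
  `X(k) = (sign(mean(σ) − σ(k)) + 1)/2` and
  `J3 = ½·Σ (X(k) − X(k−1))²`; every mean-crossing contributes ½, ties
  (`sign(0)`) map to 0.5 and consecutive ties contribute nothing (ties
  are measure-zero on real trajectories).  Note a monotone, overdamped
  approach to steady state crosses its own mean exactly once and scores
  0.5; J3 = 0 requires an exactly constant series.
* Constraints (naringenin): min σ ≥ 4.5 µM and σ(t) ≥ aσ(t), evaluated
  on the pre-perturbation window after a 10% burn-in (the transient from
  an empty initial state is not meaningful); shortfalls are reported in
  µM and summed.  Conversions use molecules = conc·N_A·V_cell with
  V_cell = 1.1e-15 L by default.
* The 180 µM enzyme ceiling of the merging problem is reported as a
  diagnostic flag, never enforced: it marks designs a practitioner would
  reject without distorting the optimization geometry.

Decision spaces: merging θ = (a1, kd20, k_aσ, µ) with bounds
a1 ∈ [90, 160] min⁻¹, kd20 ∈ [1e5, 3.5e5] molecules,
k_aσ ∈ [700, 1500] min⁻¹, µ ∈ [0.005, 0.01] min⁻¹; naringenin θ =
(p_aσ, CN_aσ, p_H, CN_h, k₋c, kd20, µ) with p ∈ [0.1, 20] min⁻¹,
CN ∈ [1, 15] copies (integers, rounded before evaluation),
k₋c ∈ [0.01, 20] min⁻¹, kd20 ∈ [1e-2, 1e4] molecules,
µ ∈ [0.0069, 0.0231] min⁻¹.  Failed integrations yield +∞ sentinel
objectives rather than exclusion, keeping archive bookkeeping simple.

## Optimizer

rand/1/bin differential evolution (defaults F = 0.8, CR = 0.9 — standard
robust settings, config-exposed) with: bounds enforced by reflection,
integer coordinates rounded, evaluation caching on θ rounded to 12
significant digits, Deb feasibility rules for constrained selection
(feasible beats infeasible; infeasibles compare by total violation), and
an external archive whose members join the mutation parent pool.
Spherical pruning maintains spread: archive objectives are min–max
normalized to the ideal/nadir box, mapped to hyperspherical sector
indices (each of the m−1 angles binned uniformly over [0, π/2] into
`arcs` divisions, default 50), and each sector keeps the member with the
smallest normalized norm (ties to the smaller evaluation id).  The
working archive is pruned whenever it exceeds its capacity (default
100).

The *returned* archive is the capacity-pruned cumulative non-dominated
front of all feasible evaluations.  A capacity-pruned working archive
can later re-admit candidates dominated by points it discarded; the
cumulative front guarantees the final library is globally non-dominated
over the whole run.  For the same reason the recorded per-generation
hypervolume (`hv_history`, exact, computed against a fixed user-supplied
reference point) is measured on the cumulative front, where it is
provably non-decreasing; the hypervolume of a pruned working archive can
dip at pruning events by construction.

Everything is driven by one `numpy` generator seeded from the config;
identical seeds give byte-identical archives (tested).

## Default parameter registry

Numeric kinetic values ship as the package's own calibrated registry
entries (`merging-default`, `naringenin-default`, YAML with units in
comments).  The calibration targets qualitative behavior, not any
measured dataset:

* merging: a steady product level (~7.8e3 molecules/cell, titer 0.78 in
  model units against a target of 1.0 with K = 1e-4) reached well before
  the perturbation; J2 ≈ 0.011 at default dilution versus ~5e-9 in the
  dilution-free limit; S2 is set equal to its Michaelis constant so the
  60% step actually bites (a saturated step would hide the disturbance).
  Basal enzyme expression a0 = 0 in the simplified loop, so the
  controller has full authority over the merging flux.
* naringenin: ~0.85 g/L unperturbed titer against the 1 g/L target
  (deliberately sub-target: the default is the untuned baseline the
  optimizer improves), σ above both the 4.5 µM floor and anti-σ
  throughout the evaluation window, malonyl-CoA at ~20 µM with
  Km_Ma ≈ Ma so the CHS step is sensitive, and the signature transient
  after the 65-h step: σ rises (~3.3e3 → ~5.7e3 molecules), CHS
  transiently increases (~44e3 → ~53e3), production partially recovers
  (J2 ≈ 0.32).

What the defaults do *not* emulate: stochastic single-cell
heterogeneity (the population is homogeneous and deterministic),
host-level resource competition, and any quantitative enzyme kinetics
fitted to measurements — passing tests demonstrate the control-theoretic
and algorithmic properties, not predictions for a specific strain.

## Analysis

Level diagrams: objectives min–max normalized over the front itself,
p-norm per solution (default p = 2; the ∞-norm is supported), one panel
per objective and per decision variable with a common y-value per
solution.  A degenerate objective (max = min on the front) normalizes to
zero with a warning.  Representatives are the per-objective argmins plus
the minimum-norm compromise, ties broken by solution id.  Trade-off
statistics are pairwise Spearman rank correlations (exactly −1 for any
strictly non-dominated two-objective front).  `label_regimes` k-means
labels (deterministic, seeded) are a plotting convenience only.  Archive
CSVs are written with 17 significant digits and re-read with pandas'
round-trip parser, so export → import is bit-exact.

## Problem sizes used in the shipped checks

The tuning runs exercised by the test suite and the acceptance script
are scaled-down study conditions chosen to keep a full desk run in
minutes: the analytic-front check uses a 2000-evaluation budget, and the
merging tuning run uses a 20-member population for ~300 evaluations
(15 generations).  These sizes produce an archive that already spans the
full J1–J2 trade-off (≥ 10 distinct designs in practice).  The
naringenin system ships with single-design evaluation in the acceptance
path; its full MOP is run the same way via `pathtune optimize
--override model=naringenin` with a budget of the user's choosing.

## Known limitations

* The naringenin default σ floor margin is thin (min σ ≈ 4.67 µM against
  the 4.5 µM constraint); strongly perturbed parameterizations can go
  infeasible, which the optimizer handles by feasibility dominance.
* J2's sign convention lets the optimizer chase perturbation-induced
  gains; if that is undesirable, clamp at zero in a custom problem.
* The deterministic, homogeneous-population assumption means σ levels of
  a few thousand molecules carry no intrinsic noise; real antithetic
  implementations show stochastic effects at these copy numbers.
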