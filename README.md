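# pathtune

Model-based multiobjective tuning of biomolecular controllers for the
dynamic regulation of metabolic pathways.

## The problem

Microbial cell factories that over-express a heterologous pathway are
exposed to fluctuations in shared precursors.  In a *merging* pathway
motif, two substrates — a primary precursor and an essential secondary
metabolite (e.g. malonyl-CoA in flavonoid production) — are jointly
consumed by one enzymatic step.  The secondary metabolite is tightly
regulated by the host and cannot be over-supplied, so a drop in its
availability cuts production.  Dynamic regulation closes a feedback loop
around the pathway: a biosensor reads the product level and a
biomolecular *antithetic controller* — a σ factor and an anti-σ factor
that annihilate by stoichiometric sequestration — adjusts the expression
of the merging enzyme.  The σ/anti-σ imbalance integrates the control
error, giving (quasi-)perfect adaptation; growth dilution leaks the
integrator and degrades it.

Choosing the controller and biosensor parts (expression strengths,
plasmid copy numbers, dissociation constants, unbinding rates) is a
genuine multiobjective problem.  `pathtune` implements the whole tuning
pipeline for two deterministic ODE systems:

* a **simplified merging pathway** (6 states) with a TF-based product
  biosensor and a reduced antithetic controller, and
* the **full naringenin system** (16 states): the four-step pathway from
  L-tyrosine with the CHS/malonyl-CoA merging step, an extended
  kaempferol/QdoR biosensor, a realistic antithetic controller with an
  explicit σ·anti-σ complex and leaky saturating promoters, and an
  AHL/LuxR reference input with membrane diffusion and logistic growth.

Designs are scored on paired (unperturbed/perturbed) simulations:

* `J1 = |target − K·P(T)|` — titer target error at the end of the run
  (g/L for naringenin via `K_Nar = mw·x(T)/(N_A·V_ext)`),
* `J2 = (P_unp(T) − P_pert(T))/P_unp(T)` — fractional production loss
  after a 60% step reduction of the secondary substrate,
* `J3` — number of oscillations of free σ before the perturbation
  (mean-crossings of the clipped binary signal, ½ per crossing), a
  stability proxy for the naringenin MOP,

subject (naringenin) to `σ ≥ 4.5 µM` and `σ(t) ≥ anti-σ(t)`.  A
constrained multiobjective differential-evolution optimizer
(rand/1/bin, external non-dominated archive, feasibility dominance,
spherical pruning for spread) approximates the Pareto front, and the
analysis layer provides level diagrams, representative-design selection
and trade-off statistics — the decision-support step for picking one
design out of the optimal library.

## Worked example

```bash
python examples/perfect_adaptation.py
```

prints

```
production loss, ideal integral limit (d=0, mu=1e-6): 4.92e-09
production loss, default dilution (mu=0.0075/min):    0.0111
degradation of adaptation by dilution:                2251338x
```

With controller degradation removed and dilution made negligible the
antithetic loop rejects a 60% substrate step essentially perfectly
(J2 ≈ 5·10⁻⁹); at the default growth rate the same loop loses 1.1% of
end-point product — the leaky-integrator error that motivates tuning.
The other examples cover the closed-loop merging simulation
(`merging_closed_loop.py`), a small Pareto-library build
(`tune_merging_library.py`), the full naringenin response to the 65-h
malonyl-CoA drop (`naringenin_response.py`, titer 0.853 g/L, J2 0.32,
feasible constraints), and level-diagram decision support
(`level_diagrams.py`).

The same pipeline is scriptable from a shell:

```bash
pathtune simulate --override model=naringenin --outdir out/sim
pathtune optimize --seed 1 --override model=merging \
    --override moea.max_evaluations=300 --override moea.population_size=20 \
    --outdir out/opt
pathtune analyze out/opt/archive.csv --outdir out/analysis
```

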