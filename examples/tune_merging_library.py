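"""Build a small library of controller/biosensor designs for the merging MOP.

Runs the archive-assisted differential-evolution optimizer on the
bi-objective merging problem — minimize the titer target error J1 and
the post-perturbation production loss J2 over (a1, kd20, k_asigma, mu) —
with a deliberately small budget so the example finishes in about a
minute.  Every archived design is a different J1/J2 trade-off.
"""

from pathtune.moea import MOEAConfig, run_moea
from pathtune.objectives import MergingProblem

problem = MergingProblem()
config = MOEAConfig(population_size=10, generations=5, max_evaluations=60, seed=7)
result = run_moea(problem, config)

frame = result.archive_frame()
print(frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(
    f"{result.n_evaluations} model evaluations produced {len(result.archive)} "
    "mutually non-dominated designs.\n"
    "Moving down the table, the titer target error J1 trades against the\n"
    "production loss J2: no archived design improves one without the other."
)
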