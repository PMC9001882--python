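"""Closed-loop regulation of the simplified merging pathway.

Simulates the default antithetic controller/biosensor design through the
standard protocol: grow to steady production, then cut the secondary
substrate S2 by 60% at t = 2000 min, and compare the perturbed run with
an unperturbed twin at t = 4000 min.
"""

from pathtune import registry
from pathtune.models import MERGING
from pathtune.objectives import default_merging_protocol, j2_production_loss
from pathtune.simulate import run_paired

params = registry.default_params("merging")
protocol = default_merging_protocol()

unperturbed, perturbed = run_paired(MERGING, params, protocol)
T = protocol.t_end
iP = MERGING.index("P")
P_unp = unperturbed.endpoint(T)[iP]
P_pert = perturbed.endpoint(T)[iP]
j2 = j2_production_loss(P_unp, P_pert)

print(f"product per cell, unperturbed run:  {P_unp:10.1f} molecules")
print(f"product per cell, after 60% S2 cut: {P_pert:10.1f} molecules")
print(f"production loss J2:                 {j2:10.4f}")
print()
print(
    "J2 is the fractional end-point product lost to the perturbation; the\n"
    "antithetic loop holds it to a few percent, while an unregulated enzyme\n"
    "level would lose roughly the same fraction as the flux drop (~40%)."
)
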