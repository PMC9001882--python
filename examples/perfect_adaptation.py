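"""Dilution destroys the antithetic controller's perfect adaptation.

The sigma/anti-sigma annihilation motif implements integral feedback:
with no controller degradation and negligible growth dilution, the
product recovers exactly from a step disturbance.  At a realistic growth
rate the integral action leaks and a steady-state error returns.
"""

import dataclasses

from pathtune import registry
from pathtune.models import MERGING
from pathtune.objectives import default_merging_protocol, j2_production_loss
from pathtune.simulate import run_paired

base = registry.default_params("merging")
iP = MERGING.index("P")


def loss(params, protocol):
    unp, pert = run_paired(MERGING, params, protocol)
    T = protocol.t_end
    return j2_production_loss(unp.endpoint(T)[iP], pert.endpoint(T)[iP])


ideal = dataclasses.replace(base, d_sigma=0.0, d_asigma=0.0, mu=1e-6)
j2_ideal = loss(ideal, default_merging_protocol(method="BDF"))
j2_dilut = loss(base, default_merging_protocol())

print(f"production loss, ideal integral limit (d=0, mu=1e-6): {abs(j2_ideal):.2e}")
print(f"production loss, default dilution (mu=0.0075/min):    {abs(j2_dilut):.4f}")
print(f"degradation of adaptation by dilution:                {abs(j2_dilut/j2_ideal):.0f}x")
print()
print(
    "In the ideal limit the controller rejects the 60% substrate step almost\n"
    "perfectly; growth dilution of sigma and anti-sigma turns the integrator\n"
    "into a leaky one and the rejection becomes partial."
)
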