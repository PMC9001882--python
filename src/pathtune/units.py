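"""Unit conversions between molecule counts and concentrations.

The models track amounts in molecules per cell; several published
constraints and bounds are quoted in micromolar.  Conversions use
molecules = conc · N_A · V_cell with a default cell volume of
1.1e-15 L (an E. coli cell), overridable everywhere it is used.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # mol^-1
DEFAULT_VCELL_L = 1.1e-15  # L, typical E. coli cytoplasmic volume


def micromolar_to_molecules(conc_uM: float, vcell_L: float = DEFAULT_VCELL_L) -> float:
    """Convert a micromolar intracellular concentration to molecules/cell."""
    return conc_uM * 1e-6 * AVOGADRO * vcell_L


def molecules_to_micromolar(n: float, vcell_L: float = DEFAULT_VCELL_L) -> float:
    """Convert molecules/cell to an intracellular micromolar concentration."""
    return n / (AVOGADRO * vcell_L) * 1e6
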