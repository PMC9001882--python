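"""Simplified merging-pathway model under antithetic feedback regulation.

Two substrates — a primary precursor S1 taken up at constant rate and a
secondary essential metabolite S2 (an externally set availability, the
disturbance channel) — are merged into a product P by an enzyme E.  E is
expressed from a sigma-factor-activated promoter; a constitutively
expressed sigma factor is sequestered by an anti-sigma factor whose
expression is induced by the product through a TF-based biosensor.  The
sigma/anti-sigma annihilation implements integral feedback: at vanishing
dilution and degradation the product adapts perfectly to the setpoint
encoded by the sigma/anti-sigma expression ratio, while growth-rate
dilution degrades that adaptation.

State (molecules per cell; X in cells): S1, P, E, sigma, asigma, X.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..kernels import bisubstrate_flux, biosensor_fraction, hill_activation

SPECIES = ("S1", "P", "E", "sigma", "asigma", "X")


@dataclass
class MergingParams:
    """Kinetic, expression and population constants of the merging model.

    Units: molecule amounts in molecules/cell, times in minutes; expression
    strengths in molecules·min⁻¹·copy⁻¹, dissociation constants in
    molecules, first-order rates in min⁻¹.
    """

    K_S1: float        # constant precursor uptake rate (molecules/min)
    kcat: float        # enzyme turnover (1/min)
    Km_S1: float       # Michaelis constant for S1 (molecules)
    Km_S2: float       # Michaelis constant for S2 (molecules)
    S2_level: float    # secondary substrate availability (external input)
    CN: float          # plasmid copy number (copies)
    a0: float          # basal enzyme expression strength
    a1: float          # sigma-induced enzyme expression strength
    kd20: float        # sigma / enzyme-promoter dissociation constant
    k_sigma: float     # constitutive sigma expression rate (1/min/copy)
    gamma: float       # sigma/anti-sigma association rate (1/molecule/min)
    k_asigma: float    # anti-sigma expression strength (1/min)
    kdp: float         # product / TF dissociation constant (molecules)
    TF_total: float    # constitutive transcription-factor pool (molecules)
    d_E: float         # enzyme degradation rate (1/min)
    d_sigma: float     # sigma degradation rate (1/min)
    d_asigma: float    # anti-sigma degradation rate (1/min)
    mu: float          # specific growth rate (1/min)
    Xmax: float        # population carrying capacity (cells)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"MergingParams.{f.name} must be finite and >= 0")
        if self.CN < 1:
            raise ValueError("CN must be >= 1")
        if self.Xmax < 1:
            raise ValueError("Xmax must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class MergingState:
    S1: float
    P: float
    E: float
    sigma: float
    asigma: float
    X: float

    def to_array(self) -> np.ndarray:
        return np.array([self.S1, self.P, self.E, self.sigma, self.asigma, self.X])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "MergingState":
        return cls(*map(float, y))


def merging_rhs(state, params: MergingParams) -> np.ndarray:
    """Time derivative of the merging-model state.

    Accepts a :class:`MergingState` or a length-6 array ordered as
    ``SPECIES``; returns the derivative as an array in the same order.
    """
    y = state.to_array() if isinstance(state, MergingState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to merging_rhs")
    S1, P, E, sigma, asigma, X = y
    p = params

    # nonlinear kernels see states clamped at 0 (implicit solvers probe
    # slightly negative trial states); linear clearance keeps the raw value
    # so any undershoot decays back.
    S1c, Pc, Ec, sigc, asigc = (max(v, 0.0) for v in (S1, P, E, sigma, asigma))
    V = bisubstrate_flux(Ec, S1c, p.S2_level, p.kcat, p.Km_S1, p.Km_S2)
    annihilation = p.gamma * sigc * asigc

    dS1 = p.K_S1 - V - p.mu * S1
    dP = V - p.mu * P
    dE = hill_activation(sigc, p.CN, p.a0, p.a1, p.kd20) - (p.d_E + p.mu) * E
    dsigma = p.CN * p.k_sigma - annihilation - (p.d_sigma + p.mu) * sigma
    dasigma = (
        p.CN * p.k_asigma * biosensor_fraction(Pc, p.CN, p.kdp, p.TF_total)
        - annihilation
        - (p.d_asigma + p.mu) * asigma
    )
    dX = p.mu * X * (1.0 - X / p.Xmax)
    return np.array([dS1, dP, dE, dsigma, dasigma, dX])


def default_initial_state(params: MergingParams) -> np.ndarray:
    """Clean-slate inoculation: no pathway species, 1% of carrying capacity."""
    y0 = np.zeros(len(SPECIES))
    y0[SPECIES.index("X")] = 0.01 * params.Xmax
    return y0
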