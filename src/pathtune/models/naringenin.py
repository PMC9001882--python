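"""Naringenin biosynthesis pathway with extended biosensor and antithetic control.

Full E. coli production model: a four-step enzymatic chain from L-tyrosine
to naringenin whose merging step (chalcone synthase, CHS) consumes the
essential co-substrate malonyl-CoA — the disturbance channel.  Naringenin
is read out indirectly through an extended biosensor (naringenin →
dihydrokaempferol → kaempferol, sensed by the QdoR transcription factor
repressing the anti-sigma promoter).  A realistic antithetic controller
(explicit sigma·anti-sigma complex with finite unbinding, leaky saturating
promoters, mRNA-lumped expression, dilution of every species) actuates CHS
expression on top of a constitutive baseline.  The controller reference is
set by externally dosed AHL diffusing across the membrane and binding
LuxR; the population grows logistically and all cells are identical.

State (molecules per cell; x in cells):
Lt, pC, pA, Nc, N, Di, Ka, Q, sigma, asigma, complex_sa, CHS, R, A, Ae, x.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..kernels import (
    bisubstrate_flux,
    effective_activation,
    f_lux,
    f_p20,
    f_qdo,
    mm_flux,
)
from ..units import AVOGADRO

SPECIES = (
    "Lt", "pC", "pA", "Nc", "N", "Di", "Ka", "Q",
    "sigma", "asigma", "complex_sa", "CHS", "R", "A", "Ae", "x",
)

NARINGENIN_MW = 272.25  # g/mol


def _check_group(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{f.name} must be finite and >= 0")


@dataclass
class MetabolicParams:
    """Pathway kinetics: fixed enzyme pools and Michaelis–Menten constants."""

    K_Lt: float        # constant L-tyrosine influx (molecules/min)
    kcat_TAL: float
    kcat_4CL: float
    kcat_CHS: float
    kcat_CHI: float
    kcat_F3H: float
    kcat_FLS: float
    Km_Lt: float
    Km_pC: float
    Km_pA: float
    Km_Ma: float
    Km_Nc: float
    Km_N: float
    Km_Di: float
    TAL: float         # fixed enzyme levels (molecules)
    FCL: float         # 4CL ligase
    CHI: float
    F3H: float
    FLS: float
    Ma_level: float    # malonyl-CoA availability (external input, molecules)

    def __post_init__(self) -> None:
        _check_group(self)


@dataclass
class BiosensorParams:
    """QdoR expression and promoter dissociation constants."""

    pQ: float          # QdoR translation rate (1/min)
    kQ: float          # QdoR transcription rate (1/min)
    dmQ: float         # QdoR mRNA degradation (1/min)
    dQ: float          # QdoR protein degradation (1/min)
    kdq: float         # QdoR / P_qdoI dissociation constant (molecules)
    kdk: float         # kaempferol / QdoR dissociation constant (molecules)
    CN: float          # biosensor plasmid copy number

    def __post_init__(self) -> None:
        _check_group(self)


@dataclass
class ControllerParams:
    """Antithetic sigma / anti-sigma device."""

    p_sigma: float     # sigma translation rate (1/min)
    k_sigma_n: float   # sigma transcription rate (1/min)
    dm_sigma: float
    d_sigma: float
    alpha: float       # promoter leakage fraction in [0, 1]
    kdlux: float       # LuxR·AHL / P_Lux dissociation constant
    kd2: float
    kdc: float         # sigma·anti-sigma complex dissociation constant
    k_minus_c: float   # complex unbinding rate (1/min)
    d_c: float         # complex degradation (1/min)
    p_asigma: float    # anti-sigma translation rate (1/min)
    CN_asigma: float   # anti-sigma plasmid copy number
    k_asigma_n: float  # anti-sigma transcription rate (1/min)
    dm_asigma: float
    d_asigma: float
    CN: float          # controller plasmid copy number (sigma, LuxR)

    def __post_init__(self) -> None:
        _check_group(self)
        if self.alpha > 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class ActuatorParams:
    """CHS expression: constitutive baseline plus sigma-activated overdrive."""

    beta: float        # constitutive fraction in [0, 1]
    p_Hc: float        # constitutive CHS translation rate (1/min)
    p_H: float         # regulated CHS translation rate (1/min)
    CN_h: float        # CHS plasmid copy number
    k_H: float         # CHS transcription rate (1/min)
    dm_H: float
    d_H: float
    kd20_n: float      # sigma / P20 dissociation constant (molecules)
    kd_sigma: float    # auxiliary P20 occupancy constant (molecules)

    def __post_init__(self) -> None:
        _check_group(self)
        if self.beta > 1:
            raise ValueError("beta must be in [0, 1]")


@dataclass
class AhlParams:
    """LuxR expression and AHL membrane diffusion."""

    p_R: float
    k_R: float
    dm_R: float
    d_R: float
    D: float           # membrane diffusion rate (1/min)
    Vcell: float       # L
    Vext: float        # L
    d_A: float         # intracellular AHL degradation (1/min)
    d_Ae: float        # extracellular AHL degradation (1/min)
    Ae_dose: float     # external AHL input (molecules)

    def __post_init__(self) -> None:
        _check_group(self)
        if self.Vcell >= self.Vext:
            raise ValueError("Vcell must be < Vext")


@dataclass
class GlobalParams:
    mu: float          # specific growth rate (1/min)
    xmax: float        # carrying capacity (cells)
    mw: float = NARINGENIN_MW
    Av: float = AVOGADRO

    def __post_init__(self) -> None:
        _check_group(self)
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class NaringeninParams:
    metabolic: MetabolicParams
    biosensor: BiosensorParams
    controller: ControllerParams
    actuator: ActuatorParams
    ahl: AhlParams
    glob: GlobalParams


@dataclass
class NaringeninState:
    Lt: float
    pC: float
    pA: float
    Nc: float
    N: float
    Di: float
    Ka: float
    Q: float
    sigma: float
    asigma: float
    complex_sa: float
    CHS: float
    R: float
    A: float
    Ae: float
    x: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NaringeninState":
        return cls(*map(float, y))


def naringenin_rhs(state, params: NaringeninParams) -> np.ndarray:
    """Time derivative of the full naringenin-system state.

    Accepts a :class:`NaringeninState` or a length-16 array ordered as
    ``SPECIES``; returns the derivative as an array in the same order.
    """
    y = state.to_array() if isinstance(state, NaringeninState) else np.asarray(state, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to naringenin_rhs")
    (Lt, pC, pA, Nc, N, Di, Ka, Q, sigma, asigma, complex_sa,
     CHS, R, A, Ae, x) = y
    # nonlinear kernels see states clamped at 0 (implicit solvers probe
    # slightly negative trial states); linear clearance keeps raw values.
    (Ltc, pCc, pAc, Ncc, Nc_, Dic, Kac, Qc, sigc, asigc, cplxc,
     CHSc, Rc, Ac, Aec, xc) = (max(v, 0.0) for v in y)
    m, b, c, a, h, g = (
        params.metabolic, params.biosensor, params.controller,
        params.actuator, params.ahl, params.glob,
    )
    mu = g.mu

    # metabolic chain fluxes
    V_Lt = mm_flux(m.TAL, Ltc, m.kcat_TAL, m.Km_Lt)
    V_pC = mm_flux(m.FCL, pCc, m.kcat_4CL, m.Km_pC)
    V_pA = bisubstrate_flux(CHSc, pAc, m.Ma_level, m.kcat_CHS, m.Km_pA, m.Km_Ma)
    V_Nc = mm_flux(m.CHI, Ncc, m.kcat_CHI, m.Km_Nc)
    V_N = mm_flux(m.F3H, Nc_, m.kcat_F3H, m.Km_N)
    V_Di = mm_flux(m.FLS, Dic, m.kcat_FLS, m.Km_Di)

    dLt = m.K_Lt - V_Lt - mu * Lt
    dpC = V_Lt - V_pC - mu * pC
    dpA = V_pC - V_pA - mu * pA
    dNc = V_pA - V_Nc - mu * Nc
    dN = V_Nc - V_N - mu * N

    # extended biosensor
    dDi = V_N - V_Di - mu * Di
    dKa = V_Di - mu * Ka
    dQ = b.pQ * b.CN * b.kQ / (b.dmQ + mu) - (b.dQ + mu) * Q

    # antithetic controller
    k_on = c.k_minus_c / c.kdc
    binding = k_on * sigc * asigc
    unbinding = c.k_minus_c * complex_sa
    u_sigma = (
        c.p_sigma * c.CN * c.k_sigma_n / (c.dm_sigma + mu)
        * effective_activation(c.alpha, f_lux(Ac, Rc, c.kdlux, c.kd2, c.CN))
    )
    u_asigma = (
        c.p_asigma * c.CN_asigma * c.k_asigma_n / (c.dm_asigma + mu)
        * effective_activation(c.alpha, f_qdo(Kac, Qc, b.kdq, b.kdk, b.CN))
    )
    dcomplex = binding - unbinding - (c.d_c + mu) * complex_sa
    dsigma = u_sigma - binding + unbinding - (c.d_sigma + mu) * sigma
    dasigma = u_asigma - binding + unbinding - (c.d_asigma + mu) * asigma

    # actuator: CHS expression
    dCHS = (
        a.beta * a.p_Hc * a.CN_h * a.k_H / (a.dm_H + mu)
        + a.p_H * a.CN_h * a.k_H / (a.dm_H + mu)
        * effective_activation(c.alpha, f_p20(sigc, a.kd20_n, a.kd_sigma, a.CN_h))
        - (a.d_H + mu) * CHS
    )

    # AHL reference and population
    Vc = h.Vcell / h.Vext
    dR = h.p_R * c.CN * h.k_R / (h.dm_R + mu) - (h.d_R + mu) * R
    dA = h.D * (Vc * Ae - A) - (h.d_A + mu) * A
    dAe = h.D * x * Vc * (A - Ae) - h.d_Ae * Ae
    dx = mu * (1.0 - x / g.xmax) * x

    return np.array([
        dLt, dpC, dpA, dNc, dN, dDi, dKa, dQ,
        dsigma, dasigma, dcomplex, dCHS, dR, dA, dAe, dx,
    ])


def default_initial_state(params: NaringeninParams) -> np.ndarray:
    """Inoculation: empty pathway, AHL dose in the medium, 1% of xmax."""
    y0 = np.zeros(len(SPECIES))
    y0[SPECIES.index("Ae")] = params.ahl.Ae_dose
    y0[SPECIES.index("x")] = 0.01 * params.glob.xmax
    return y0
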