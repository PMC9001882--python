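"""Reusable kinetic-flux and promoter-occupancy kernels.

Every Hill/occupancy grouping used by the two pathway models lives in this
module, isolated in a single named function.  The typeset forms of some of
the promoter activation functions in the source models are ambiguous in how
the dissociation constants and copy numbers combine in the denominator;
concentrating each reading here makes an alternative grouping a one-line
change without touching the right-hand sides.

All amounts are molecules (per cell), rates are per minute.
"""

from __future__ import annotations

import numbers

import numpy as np

__all__ = [
    "mm_flux",
    "bisubstrate_flux",
    "hill_activation",
    "biosensor_fraction",
    "f_lux",
    "f_qdo",
    "f_p20",
]


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if isinstance(value, numbers.Real) and value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")


def mm_flux(E: float, S: float, kcat: float, Km: float) -> float:
    """Michaelis–Menten flux kcat·E·S/(Km + S) in molecules·min⁻¹.

    Bounded above by kcat·E and monotone nondecreasing in the substrate S.
    """
    _check_nonnegative(E=E, S=S, kcat=kcat)
    if Km <= 0:
        raise ValueError(f"Km must be > 0, got {Km!r}")
    return kcat * E * S / (Km + S)


def bisubstrate_flux(
    E: float, S1: float, S2: float, kcat: float, Km1: float, Km2: float
) -> float:
    """Two-substrate Michaelis–Menten flux of a merging enzymatic step.

    kcat·E·S1·S2 / (Km1·Km2 + Km2·S1 + Km1·S2 + S1·S2).  Vanishes when
    either substrate is absent; reduces to :func:`mm_flux` in S1 when S2
    saturates, and is bounded by kcat·E.
    """
    _check_nonnegative(E=E, S1=S1, S2=S2, kcat=kcat)
    if Km1 <= 0 or Km2 <= 0:
        raise ValueError("Michaelis constants must be > 0")
    denom = Km1 * Km2 + Km2 * S1 + Km1 * S2 + S1 * S2
    return kcat * E * S1 * S2 / denom


def hill_activation(sigma: float, CN: float, a0: float, a1: float, kd20: float) -> float:
    """Copy-number-scaled promoter activation by free sigma factor.

    CN·a0 + CN·a1·σ² / (kd20²·CN² + σ²): basal expression plus a
    cooperative (n = 2) activation term whose half-activation point is
    σ = kd20·CN.  Output lies in [CN·a0, CN·(a0 + a1)).
    """
    _check_nonnegative(sigma=sigma, CN=CN, a0=a0, a1=a1, kd20=kd20)
    denom = (kd20 * CN) ** 2 + sigma * sigma
    if denom == 0.0:
        return CN * a0
    return CN * a0 + CN * a1 * sigma * sigma / denom


def biosensor_fraction(P: float, CN: float, kdp: float, TF: float) -> float:
    """Active fraction of the product-inducible anti-sigma promoter.

    CN²(1 + P/kdp)² / (CN²(1 + P/kdp)² + TF²): a constitutive
    transcription factor TF represses the promoter; binding of the product
    P to the TF relieves repression, so the fraction increases with P and
    decreases with TF.  Lies in (0, 1] for CN > 0.
    """
    _check_nonnegative(P=P, CN=CN, TF=TF)
    if kdp <= 0:
        raise ValueError(f"kdp must be > 0, got {kdp!r}")
    act = (CN * (1.0 + P / kdp)) ** 2
    denom = act + TF * TF
    if denom == 0.0:
        return 1.0
    return act / denom


def f_lux(A: float, R: float, kdlux: float, kd2: float, CN: float) -> float:
    """AHL/LuxR activation fraction of the P_Lux promoter, in [0, 1].

    A²/(kdlux·kd2·CN/R² + A²).  The LuxR·AHL dimer activates the promoter;
    more receptor R lowers the effective half-activation AHL level.
    """
    # computed as A²R²/(kdlux·kd2·CN + A²R²): same grouping, no division
    # by R² (robust to underflow at tiny receptor levels)
    num = (A * R) ** 2
    if not np.isfinite(num):
        return 1.0
    denom = kdlux * kd2 * CN + num
    if denom == 0.0:
        return 0.0
    return num / denom


def f_qdo(Ka: float, Q: float, kdq: float, kdk: float, CN: float) -> float:
    """P_qdoI promoter activity under QdoR repression, in (0, 1].

    (kdq·CN²·kdk + Ka²) / (kdq·CN²·kdk + Ka² + kdk·Q²).  Free QdoR (Q)
    represses; kaempferol (Ka) sequesters QdoR, so activity rises with Ka.
    """
    base = kdq * CN * CN * kdk + Ka * Ka
    denom = base + kdk * Q * Q
    if denom == 0.0:
        return 1.0
    return base / denom


def f_p20(sigma: float, kd20: float, kd_sigma: float, CN_h: float) -> float:
    """Sigma-factor activation fraction of the P20 actuator promoter.

    σ²/(kd20·kd_sigma·CN_h² + σ²), in [0, 1); half-activation at
    σ = CN_h·sqrt(kd20·kd_sigma).
    """
    denom = kd20 * kd_sigma * CN_h * CN_h + sigma * sigma
    if denom == 0.0:
        return 0.0
    return sigma * sigma / denom


def effective_activation(alpha: float, fraction: float) -> float:
    """Leaky promoter response alpha + (1 - alpha)·fraction, in [alpha, 1]."""
    return alpha + (1.0 - alpha) * fraction
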