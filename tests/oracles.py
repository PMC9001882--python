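"""Independently constructed symbolic oracles for the model derivatives.

The right-hand sides of both pathway models are rebuilt here from scratch
in sympy — term by term from the model equations, sharing no code with
the package — and evaluated in high-precision arithmetic from exact
rational inputs.  Tests compare the package's float implementations
against these references.
"""

from __future__ import annotations

from fractions import Fraction

import sympy as sp


def _sym(names: str):
    return sp.symbols(names, positive=True)


def merging_oracle_exprs():
    """Symbolic state derivatives of the merging model.

    Returns (state_symbols, param_symbols, expressions) with parameter
    symbols keyed by the package's field names.
    """
    S1, P, E, sigma, asigma, X = sp.symbols("S1 P E sigma asigma X", nonnegative=True)
    names = (
        "K_S1 kcat Km_S1 Km_S2 S2_level CN a0 a1 kd20 k_sigma gamma "
        "k_asigma kdp TF_total d_E d_sigma d_asigma mu Xmax"
    )
    p = dict(zip(names.split(), _sym(names)))

    V = (
        p["kcat"] * E * S1 * p["S2_level"]
        / (
            p["Km_S1"] * p["Km_S2"]
            + p["Km_S2"] * S1
            + p["Km_S1"] * p["S2_level"]
            + S1 * p["S2_level"]
        )
    )
    hill = p["CN"] * p["a0"] + p["CN"] * p["a1"] * sigma**2 / (
        p["kd20"] ** 2 * p["CN"] ** 2 + sigma**2
    )
    occupancy = (p["CN"] * (1 + P / p["kdp"])) ** 2
    sensor = occupancy / (occupancy + p["TF_total"] ** 2)
    ann = p["gamma"] * sigma * asigma

    exprs = [
        p["K_S1"] - V - p["mu"] * S1,
        V - p["mu"] * P,
        hill - (p["d_E"] + p["mu"]) * E,
        p["CN"] * p["k_sigma"] - ann - (p["d_sigma"] + p["mu"]) * sigma,
        p["CN"] * p["k_asigma"] * sensor - ann - (p["d_asigma"] + p["mu"]) * asigma,
        p["mu"] * X * (1 - X / p["Xmax"]),
    ]
    return (S1, P, E, sigma, asigma, X), p, exprs


def naringenin_oracle_exprs():
    """Symbolic state derivatives of the full naringenin system."""
    state = sp.symbols(
        "Lt pC pA Nc N Di Ka Q sigma asigma complex_sa CHS R A Ae x",
        nonnegative=True,
    )
    (Lt, pC, pA, Nc, N, Di, Ka, Q, sigma, asigma, complex_sa, CHS, R, A, Ae, x) = state
    names = (
        "K_Lt kcat_TAL kcat_4CL kcat_CHS kcat_CHI kcat_F3H kcat_FLS "
        "Km_Lt Km_pC Km_pA Km_Ma Km_Nc Km_N Km_Di TAL FCL CHI F3H FLS Ma_level "
        "pQ kQ dmQ dQ kdq kdk CN_b "
        "p_sigma k_sigma_n dm_sigma d_sigma alpha kdlux kd2 kdc k_minus_c d_c "
        "p_asigma CN_asigma k_asigma_n dm_asigma d_asigma CN_c "
        "beta p_Hc p_H CN_h k_H dm_H d_H kd20_n kd_sigma "
        "p_R k_R dm_R d_R D Vcell Vext d_A d_Ae mu xmax"
    )
    p = dict(zip(names.split(), _sym(names)))
    mu = p["mu"]

    def mm(Etot, S, kcat, Km):
        return kcat * Etot * S / (Km + S)

    V_Lt = mm(p["TAL"], Lt, p["kcat_TAL"], p["Km_Lt"])
    V_pC = mm(p["FCL"], pC, p["kcat_4CL"], p["Km_pC"])
    V_pA = (
        p["kcat_CHS"] * CHS * pA * p["Ma_level"]
        / (
            p["Km_pA"] * p["Km_Ma"]
            + p["Km_Ma"] * pA
            + p["Km_pA"] * p["Ma_level"]
            + pA * p["Ma_level"]
        )
    )
    V_Nc = mm(p["CHI"], Nc, p["kcat_CHI"], p["Km_Nc"])
    V_N = mm(p["F3H"], N, p["kcat_F3H"], p["Km_N"])
    V_Di = mm(p["FLS"], Di, p["kcat_FLS"], p["Km_Di"])

    lux = A**2 / (p["kdlux"] * p["kd2"] * p["CN_c"] / R**2 + A**2)
    qdo_base = p["kdq"] * p["CN_b"] ** 2 * p["kdk"] + Ka**2
    qdo = qdo_base / (qdo_base + p["kdk"] * Q**2)
    p20 = sigma**2 / (p["kd20_n"] * p["kd_sigma"] * p["CN_h"] ** 2 + sigma**2)

    def leaky(f):
        return p["alpha"] + (1 - p["alpha"]) * f

    k_on = p["k_minus_c"] / p["kdc"]
    binding = k_on * sigma * asigma
    unbinding = p["k_minus_c"] * complex_sa
    u_sigma = p["p_sigma"] * p["CN_c"] * p["k_sigma_n"] / (p["dm_sigma"] + mu) * leaky(lux)
    u_asigma = (
        p["p_asigma"] * p["CN_asigma"] * p["k_asigma_n"] / (p["dm_asigma"] + mu) * leaky(qdo)
    )
    Vc = p["Vcell"] / p["Vext"]

    exprs = [
        p["K_Lt"] - V_Lt - mu * Lt,
        V_Lt - V_pC - mu * pC,
        V_pC - V_pA - mu * pA,
        V_pA - V_Nc - mu * Nc,
        V_Nc - V_N - mu * N,
        V_N - V_Di - mu * Di,
        V_Di - mu * Ka,
        p["pQ"] * p["CN_b"] * p["kQ"] / (p["dmQ"] + mu) - (p["dQ"] + mu) * Q,
        u_sigma - binding + unbinding - (p["d_sigma"] + mu) * sigma,
        u_asigma - binding + unbinding - (p["d_asigma"] + mu) * asigma,
        binding - unbinding - (p["d_c"] + mu) * complex_sa,
        p["beta"] * p["p_Hc"] * p["CN_h"] * p["k_H"] / (p["dm_H"] + mu)
        + p["p_H"] * p["CN_h"] * p["k_H"] / (p["dm_H"] + mu) * leaky(p20)
        - (p["d_H"] + mu) * CHS,
        p["p_R"] * p["CN_c"] * p["k_R"] / (p["dm_R"] + mu) - (p["d_R"] + mu) * R,
        p["D"] * (Vc * Ae - A) - (p["d_A"] + mu) * A,
        p["D"] * x * Vc * (A - Ae) - p["d_Ae"] * Ae,
        mu * (1 - x / p["xmax"]) * x,
    ]
    return state, p, exprs


def brute_force_prune(members, arcs):
    """Sector-assignment oracle for spherical pruning.

    Explicit min–max normalization, angle binning and per-sector argmin,
    written independently of the package implementation.
    """
    import numpy as np

    obj = np.array([m.objectives for m in members], float)
    ideal, nadir = obj.min(axis=0), obj.max(axis=0)
    span = nadir - ideal
    norm = np.zeros_like(obj)
    for j in range(obj.shape[1]):
        if span[j] > 0:
            norm[:, j] = (obj[:, j] - ideal[j]) / span[j]
    chosen = {}
    for m, v in zip(members, norm):
        angles = []
        for k in range(len(v) - 1):
            tail = np.sqrt(np.sum(v[k + 1:] ** 2))
            ang = np.arctan2(tail, v[k])
            angles.append(min(int(ang / (np.pi / 2) * arcs), arcs - 1))
        key = tuple(angles)
        cand = (float(np.linalg.norm(v)), m.eval_id, m)
        if key not in chosen or cand[:2] < chosen[key][:2]:
            chosen[key] = cand
    return sorted((c[2] for c in chosen.values()), key=lambda m: m.eval_id)


def random_nondominated(rng, n, m):
    """Random mutually non-dominated objective-vector set of size n."""
    import numpy as np

    from pathtune.moea import Individual, dominates

    pts = []
    while len(pts) < n:
        p = tuple(rng.random(m))
        if any(dominates(q, p) or dominates(p, q) or q == p for q in pts):
            continue
        pts.append(p)
    return [Individual(np.zeros(1), p, 0.0, eval_id=i) for i, p in enumerate(pts)]


def _rationalize(value: float) -> sp.Rational:
    return sp.Rational(Fraction(float(value)))


def evaluate_exprs(state_syms, param_syms, exprs, state_values, param_values, digits=30):
    """Evaluate oracle expressions at exact rational inputs to ``digits``."""
    import warnings

    subs = {}
    for sym, v in zip(state_syms, state_values):
        subs[sym] = _rationalize(v)
    for key, sym in param_syms.items():
        subs[sym] = _rationalize(param_values[key])
    with warnings.catch_warnings():
        # mpmath's deprecated bitcount is exercised by evalf internals
        warnings.simplefilter("ignore", DeprecationWarning)
        return [float(e.evalf(digits, subs=subs)) for e in exprs]
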