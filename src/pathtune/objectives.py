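"""Objective functions, constraints and decision spaces for the two MOPs.

Three jointly minimized objectives quantify a controller/biosensor design:

* ``J1`` — titer target error ``|target − K·P(T)|``: distance of the
  end-of-run product titer from the desired target (g/L for naringenin,
  model units for the merging motif).
* ``J2`` — production loss ``(P_unp(T) − P_pert(T))/P_unp(T)``: fractional
  end-point product drop caused by the secondary-substrate perturbation
  (kept signed; a negative value is a production gain).
* ``J3`` — oscillation count of the free sigma factor before the
  perturbation, a proxy for the damping of the closed loop: the sigma
  series is clipped to a binary signal around its mean and each mean
  crossing contributes one half.

The naringenin MOP additionally imposes two feasibility constraints on
the unperturbed run: the free sigma level must stay at or above 4.5 uM
and must dominate the anti-sigma level throughout the evaluation window
(the pre-perturbation segment after a 10% burn-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .models import MERGING, NARINGENIN, patch_params
from .simulate import IntegrationError, PerturbationSpec, Protocol, Trajectory, run_paired
from .units import DEFAULT_VCELL_L, molecules_to_micromolar

SIGMA_FLOOR_UM = 4.5  # minimum free sigma concentration (uM) for the controller

INVALID = float("inf")  # sentinel objective value for failed evaluations


# ---------------------------------------------------------------------------
# scalar objective kernels
# ---------------------------------------------------------------------------

def j1_titer_error(P_T: float, K: float, target: float) -> float:
    """Absolute titer target error |target − K·P_T|."""
    if P_T < 0:
        raise ValueError("P_T must be >= 0")
    if K <= 0:
        raise ValueError("K must be > 0")
    return abs(target - K * P_T)


def j2_production_loss(P_unp_T: float, P_pert_T: float) -> float:
    """Signed fractional production loss after the perturbation."""
    if P_unp_T <= 0:
        raise ValueError("production loss undefined for P_unperturbed(T) <= 0")
    return (P_unp_T - P_pert_T) / P_unp_T


def clip_binary(series: Sequence[float], reference: Optional[float] = None) -> np.ndarray:
    """Clipped binary version of a series around a reference level.

    ``X(k) = (sign(reference − s(k)) + 1)/2`` with the series mean as the
    default reference; exact ties map to 0.5.
    """
    s = np.asarray(series, float)
    if s.size == 0:
        raise ValueError("series must be nonempty")
    ref = float(np.mean(s)) if reference is None else float(reference)
    return (np.sign(ref - s) + 1.0) / 2.0


def j3_count_oscillations(series: Sequence[float], reference: Optional[float] = None) -> float:
    """Oscillation count: half the summed squared jumps of the clipped signal.

    Each crossing of the reference level contributes 1/2, so a full
    oscillation period (two crossings) counts as 1.
    """
    s = np.asarray(series, float)
    if s.size < 2:
        raise ValueError("series must have length >= 2")
    X = clip_binary(s, reference)
    return 0.5 * float(np.sum(np.diff(X) ** 2))


def knar_conversion(
    x_T: float,
    mw: float = 272.25,
    Av: float = 6.02214076e23,
    Vext: float = 1.0,
) -> float:
    """Molecules-per-cell to g/L conversion constant K = mw·x(T)/(Av·Vext)."""
    if x_T < 1:
        raise ValueError("x_T must be >= 1 cell")
    if Vext <= 0:
        raise ValueError("Vext must be > 0")
    return mw * x_T / (Av * Vext)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveVector:
    J1: float
    J2: float
    J3: Optional[float] = None

    def as_tuple(self) -> Tuple[float, ...]:
        return (self.J1, self.J2) if self.J3 is None else (self.J1, self.J2, self.J3)


@dataclass(frozen=True)
class ConstraintReport:
    feasible: bool
    violation: float                       # total shortfall magnitude (uM)
    per_constraint: Dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DecisionSpace:
    """Named decision variables with per-component bounds.

    ``integer`` marks copy-number coordinates, which are counts and are
    rounded before any model evaluation.
    """

    names: Tuple[str, ...]
    lower: Tuple[float, ...]
    upper: Tuple[float, ...]
    integer: Tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.lower) == len(self.upper) == len(self.integer) == n):
            raise ValueError("inconsistent decision-space component counts")
        if any(lo > up for lo, up in zip(self.lower, self.upper)):
            raise ValueError("lower bound exceeds upper bound")

    def __len__(self) -> int:
        return len(self.names)

    def round_integers(self, theta: np.ndarray) -> np.ndarray:
        out = np.array(theta, float)
        for i, is_int in enumerate(self.integer):
            if is_int:
                out[i] = np.round(out[i])
        return out

    def contains(self, theta: np.ndarray, tol: float = 0.0) -> bool:
        t = np.asarray(theta, float)
        return bool(
            np.all(t >= np.asarray(self.lower) - tol)
            and np.all(t <= np.asarray(self.upper) + tol)
        )

    def as_dict(self, theta: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.names, map(float, theta)))


# tuning ranges for the simplified merging MOP
MERGING_DECISION = DecisionSpace(
    names=("a1", "kd20", "k_asigma", "mu"),
    lower=(90.0, 1.0e5, 700.0, 0.005),
    upper=(160.0, 3.5e5, 1500.0, 0.01),
    integer=(False, False, False, False),
)

# tuning ranges for the naringenin MOP (kd20 here is the actuator's kd20_n;
# k_minus_c is the sigma.anti-sigma complex unbinding rate)
NARINGENIN_DECISION = DecisionSpace(
    names=("p_asigma", "CN_asigma", "p_H", "CN_h", "k_minus_c", "kd20_n", "mu"),
    lower=(0.1, 1.0, 0.1, 1.0, 0.01, 1.0e-2, 0.0069),
    upper=(20.0, 15.0, 20.0, 15.0, 20.0, 1.0e4, 0.0231),
    integer=(False, True, False, True, False, False, False),
)


def default_merging_protocol(**overrides) -> Protocol:
    """60% S2 step at 2000 min, evaluated at 4000 min."""
    kw = dict(
        t_end=4000.0,
        n_points=800,
        perturbation=PerturbationSpec(t_pert=2000.0, target="S2_level", reduction=0.6),
    )
    kw.update(overrides)
    return Protocol(**kw)


def default_naringenin_protocol(**overrides) -> Protocol:
    """60% malonyl-CoA step at 65 h (3900 min), evaluated at 130 h."""
    kw = dict(
        t_end=7800.0,
        n_points=800,
        perturbation=PerturbationSpec(t_pert=3900.0, target="Ma_level", reduction=0.6),
    )
    kw.update(overrides)
    return Protocol(**kw)


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def evaluate_constraints(
    traj: Trajectory,
    t_pert: Optional[float] = None,
    vcell_L: float = DEFAULT_VCELL_L,
    sigma_floor_uM: float = SIGMA_FLOOR_UM,
) -> ConstraintReport:
    """Antithetic-controller feasibility on the unperturbed trajectory.

    Over the evaluation window (pre-perturbation segment after a 10%
    burn-in): (1) free sigma must stay at or above ``sigma_floor_uM``;
    (2) sigma must stay at or above anti-sigma.  Shortfalls are reported
    in uM and summed into a total violation.
    """
    t_hi = float(traj.times[-1]) if t_pert is None else float(t_pert)
    window = (traj.times >= 0.1 * t_hi) & (traj.times <= t_hi)
    if not np.any(window):
        raise ValueError("empty constraint evaluation window")
    sigma_uM = molecules_to_micromolar(traj["sigma"][window], vcell_L)
    asigma_uM = molecules_to_micromolar(traj["asigma"][window], vcell_L)

    floor_short = max(0.0, sigma_floor_uM - float(np.min(sigma_uM)))
    dominance_short = max(0.0, float(np.max(asigma_uM - sigma_uM)))
    violation = floor_short + dominance_short
    return ConstraintReport(
        feasible=violation == 0.0,
        violation=violation,
        per_constraint={
            "sigma_floor_uM": floor_short,
            "sigma_dominance_uM": dominance_short,
        },
    )


# ---------------------------------------------------------------------------
# full design evaluations
# ---------------------------------------------------------------------------

def evaluate_merging(
    theta,
    base_params=None,
    protocol: Optional[Protocol] = None,
    target: float = 1.0,
    K: float = 1.0e-4,
    enzyme_cap_uM: float = 180.0,
    vcell_L: float = DEFAULT_VCELL_L,
):
    """Evaluate a merging-MOP design; returns (ObjectiveVector, diagnostics).

    ``theta`` is ordered as ``MERGING_DECISION.names``.  Integration
    failures yield +inf sentinel objectives rather than an exception.
    The 180 uM enzyme ceiling is a reported-only diagnostic
    (``diagnostics['enzyme_cap_exceeded']``), never a hard constraint.
    """
    from .registry import default_params

    params = base_params if base_params is not None else default_params("merging")
    protocol = protocol if protocol is not None else default_merging_protocol()
    theta = np.asarray(theta, float)
    if not MERGING_DECISION.contains(theta, tol=1e-9):
        raise ValueError("theta outside the merging decision-variable bounds")
    params = patch_params(params, MERGING_DECISION.as_dict(theta))
    try:
        traj_unp, traj_pert = run_paired(MERGING, params, protocol)
        T = protocol.t_end
        P_unp = float(traj_unp.endpoint(T)[MERGING.index("P")])
        P_pert = float(traj_pert.endpoint(T)[MERGING.index("P")])
        J1 = j1_titer_error(P_unp, K, target)
        J2 = j2_production_loss(P_unp, P_pert)
    except (IntegrationError, ValueError) as exc:
        return ObjectiveVector(INVALID, INVALID), {"error": str(exc)}
    E_max_uM = molecules_to_micromolar(float(np.max(traj_unp["E"])), vcell_L)
    diagnostics = {
        "P_unperturbed_T": P_unp,
        "P_perturbed_T": P_pert,
        "titer": K * P_unp,
        "E_max_uM": E_max_uM,
        "enzyme_cap_exceeded": bool(E_max_uM > enzyme_cap_uM),
    }
    return ObjectiveVector(J1, J2), diagnostics


def evaluate_naringenin(
    theta,
    base_params=None,
    protocol: Optional[Protocol] = None,
    target: float = 1.0,
):
    """Evaluate a naringenin-MOP design.

    Returns ``(ObjectiveVector(J1, J2, J3), ConstraintReport, diagnostics)``.
    Copy-number coordinates are rounded before evaluation; J1 is in g/L via
    the cell-count-dependent conversion K_Nar; J3 counts sigma oscillations
    on the pre-perturbation segment of the unperturbed run.
    """
    from .registry import default_params

    params = base_params if base_params is not None else default_params("naringenin")
    protocol = protocol if protocol is not None else default_naringenin_protocol()
    theta = NARINGENIN_DECISION.round_integers(np.asarray(theta, float))
    if not NARINGENIN_DECISION.contains(theta, tol=1e-9):
        raise ValueError("theta outside the naringenin decision-variable bounds")
    params = patch_params(params, NARINGENIN_DECISION.as_dict(theta))
    vcell = params.ahl.Vcell
    try:
        traj_unp, traj_pert = run_paired(NARINGENIN, params, protocol)
        T = protocol.t_end
        t_pert = protocol.perturbation.t_pert
        end_unp = traj_unp.endpoint(T)
        end_pert = traj_pert.endpoint(T)
        N_unp = float(end_unp[NARINGENIN.index("N")])
        N_pert = float(end_pert[NARINGENIN.index("N")])
        x_T = float(end_unp[NARINGENIN.index("x")])
        K_nar = knar_conversion(x_T, params.glob.mw, params.glob.Av, params.ahl.Vext)
        J1 = j1_titer_error(N_unp, K_nar, target)
        J2 = j2_production_loss(N_unp, N_pert)
        pre = traj_unp.times <= t_pert
        J3 = j3_count_oscillations(traj_unp["sigma"][pre])
        report = evaluate_constraints(traj_unp, t_pert=t_pert, vcell_L=vcell)
    except (IntegrationError, ValueError) as exc:
        return (
            ObjectiveVector(INVALID, INVALID, INVALID),
            ConstraintReport(feasible=False, violation=INVALID),
            {"error": str(exc)},
        )
    diagnostics = {
        "N_unperturbed_T": N_unp,
        "N_perturbed_T": N_pert,
        "titer_g_per_L": K_nar * N_unp,
        "x_T": x_T,
        "sigma_min_uM": molecules_to_micromolar(
            float(np.min(traj_unp["sigma"][pre])), vcell
        ),
    }
    return ObjectiveVector(J1, J2, J3), report, diagnostics


# ---------------------------------------------------------------------------
# MOP problem objects consumed by the optimizer
# ---------------------------------------------------------------------------

class MergingProblem:
    """Bi-objective merging MOP: min (J1, J2) over (a1, kd20, k_asigma, mu)."""

    objective_names = ("J1", "J2")

    def __init__(self, base_params=None, protocol=None, target=1.0, K=1.0e-4):
        from .registry import default_params

        self.bounds = MERGING_DECISION
        self.base_params = base_params if base_params is not None else default_params("merging")
        self.protocol = protocol if protocol is not None else default_merging_protocol()
        self.target = target
        self.K = K

    def evaluate(self, theta) -> Tuple[Tuple[float, ...], float]:
        objs, _ = evaluate_merging(
            theta, self.base_params, self.protocol, self.target, self.K
        )
        return objs.as_tuple(), 0.0


class NaringeninProblem:
    """Tri-objective constrained naringenin MOP: min (J1, J2, J3)."""

    objective_names = ("J1", "J2", "J3")

    def __init__(self, base_params=None, protocol=None, target=1.0):
        from .registry import default_params

        self.bounds = NARINGENIN_DECISION
        self.base_params = (
            base_params if base_params is not None else default_params("naringenin")
        )
        self.protocol = protocol if protocol is not None else default_naringenin_protocol()
        self.target = target

    def evaluate(self, theta) -> Tuple[Tuple[float, ...], float]:
        objs, report, _ = evaluate_naringenin(
            theta, self.base_params, self.protocol, self.target
        )
        return objs.as_tuple(), report.violation
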