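"""Perturbation-rejection simulation protocols.

A protocol integrates a pathway model from inoculation to a final time
``t_end`` and may apply a single mid-course step perturbation: the
availability of the secondary substrate (``S2_level`` in the merging
model, ``Ma_level`` for malonyl-CoA in the naringenin system) is reduced
by a fixed fraction at ``t_pert`` and held there.  Objective evaluation
uses *paired* trajectories — one unperturbed, one perturbed — that share
the identical solver path up to the perturbation time.

Integration uses a stiff-capable implicit solver (LSODA) with tight
default tolerances; the perturbation is implemented as a parameter step
with a solver restart, matching a sudden availability change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import Model, patch_params

NEG_TOL = 1e-9  # tolerated integration undershoot below zero, clipped on output


class IntegrationError(RuntimeError):
    """ODE solver failure, annotated with the time at which it occurred."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g} min)")
        self.t_fail = t_fail


@dataclass(frozen=True)
class PerturbationSpec:
    """Step reduction of an availability parameter at a fixed time."""

    t_pert: float          # min
    target: str            # parameter name, e.g. "S2_level" or "Ma_level"
    reduction: float       # fraction in [0, 1]; new level = (1-reduction)*old

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction <= 1.0:
            raise ValueError("reduction must be in [0, 1]")
        if self.t_pert < 0:
            raise ValueError("t_pert must be >= 0")


@dataclass(frozen=True)
class Protocol:
    """Simulation protocol: horizon, output grid, initial state, perturbation."""

    t_end: float
    n_points: int = 800
    initial_state: Optional[Sequence[float]] = None   # model default when None
    ahl_dose: Optional[float] = None                  # naringenin only
    perturbation: Optional[PerturbationSpec] = None
    rtol: float = 1e-8
    atol: float = 1e-6
    method: str = "LSODA"  # any stiff-capable scipy method; BDF for the
    #                        dilution-free controller limit, where LSODA's
    #                        stiffness detection thrashes
    steady_state_check: bool = False  # warn if ||rhs|| is not small at t_pert

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.perturbation is not None and not (
            self.perturbation.t_pert < self.t_end
        ):
            raise ValueError("perturbation time must lie before t_end")


@dataclass
class Trajectory:
    """Time grid, state matrix and event annotations of one integration."""

    times: np.ndarray                    # (n,), minutes, strictly increasing
    states: np.ndarray                   # (n, n_species), clipped at 0
    species_names: Tuple[str, ...]
    events: List[Tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.species_names)):
            raise ValueError("states shape does not match times/species")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, self.species_names.index(species)]

    def endpoint(self, T: float) -> np.ndarray:
        """State at time T, linearly interpolated (exact at grid nodes)."""
        if not (self.times[0] <= T <= self.times[-1]):
            raise ValueError(
                f"T={T:g} outside trajectory range "
                f"[{self.times[0]:g}, {self.times[-1]:g}]"
            )
        k = np.searchsorted(self.times, T)
        if k < self.times.size and self.times[k] == T:
            return self.states[k].copy()
        t0, t1 = self.times[k - 1], self.times[k]
        w = (T - t0) / (t1 - t0)
        return (1.0 - w) * self.states[k - 1] + w * self.states[k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species_names))
        df.insert(0, "time_min", self.times)
        return df

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        df = pd.read_csv(path_or_buf)
        if df.columns[0] != "time_min":
            raise ValueError("trajectory CSV must start with a 'time_min' column")
        return cls(
            times=df["time_min"].to_numpy(),
            states=df.iloc[:, 1:].to_numpy(),
            species_names=tuple(df.columns[1:]),
        )


def endpoint(traj: Trajectory, T: float) -> np.ndarray:
    """Module-level alias for :meth:`Trajectory.endpoint`."""
    return traj.endpoint(T)


def _solve_segment(model, params, t_span, y0, t_eval, rtol, atol, method):
    def fun(t, y):
        return model.rhs(y, params)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LSODA chatter on stiffness switches
        sol = solve_ivp(
            fun, t_span, y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else t_span[0]
        raise IntegrationError(f"integration failed: {sol.message}", float(t_fail))
    return sol


def _grid(protocol: Protocol) -> np.ndarray:
    g = np.linspace(0.0, protocol.t_end, protocol.n_points)
    if protocol.perturbation is not None:
        g = np.union1d(g, [protocol.perturbation.t_pert])
    return g


def _initial_state(model: Model, params, protocol: Protocol) -> np.ndarray:
    if protocol.initial_state is not None:
        y0 = np.asarray(protocol.initial_state, float)
        if y0.shape != (len(model.species),):
            raise ValueError("initial_state length does not match model species")
    else:
        y0 = model.default_initial_state(params)
    if protocol.ahl_dose is not None:
        if "Ae" not in model.species:
            raise ValueError(f"model {model.name!r} has no AHL compartment")
        y0 = y0.copy()
        y0[model.index("Ae")] = float(protocol.ahl_dose)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")
    return y0


def _clip(states: np.ndarray) -> np.ndarray:
    low = states.min(initial=0.0)
    if low < -NEG_TOL:
        warnings.warn(
            f"trajectory undershoots zero by {-low:.3g} molecules; clipping",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.maximum(states, 0.0)


def integrate(model: Model, params, protocol: Protocol) -> Trajectory:
    """Integrate one trajectory over the protocol (perturbed if specified)."""
    if protocol.perturbation is None:
        grid = _grid(protocol)
        y0 = _initial_state(model, params, protocol)
        sol = _solve_segment(
            model, params, (0.0, protocol.t_end), y0, grid,
            protocol.rtol, protocol.atol, protocol.method,
        )
        return Trajectory(grid, _clip(sol.y.T), tuple(model.species))
    _, pert_traj = run_paired(model, params, protocol, unperturbed=False)
    return pert_traj


def run_paired(
    model: Model, params, protocol: Protocol, unperturbed: bool = True
) -> Tuple[Optional[Trajectory], Trajectory]:
    """Integrate the unperturbed/perturbed trajectory pair.

    Both trajectories share the identical solver path on ``[0, t_pert]``:
    the pre-perturbation segment is integrated once and both branches are
    restarted from its final state.  Set ``unperturbed=False`` to skip the
    unperturbed branch (its slot is then ``None``).
    """
    pert = protocol.perturbation
    if pert is None:
        raise ValueError("protocol has no perturbation; use integrate() instead")
    from .models import get_param  # local import to avoid cycle at module load

    grid = _grid(protocol)
    pre_mask = grid <= pert.t_pert
    pre_grid = grid[pre_mask]
    post_grid = grid[~pre_mask]

    y0 = _initial_state(model, params, protocol)
    sol_pre = _solve_segment(
        model, params, (0.0, pert.t_pert), y0, pre_grid,
        protocol.rtol, protocol.atol, protocol.method,
    )
    y_split = sol_pre.y[:, -1]

    if protocol.steady_state_check:
        deriv = model.rhs(np.maximum(y_split, 0.0), params)
        scale = np.maximum(np.abs(y_split), 1.0)
        if np.max(np.abs(deriv) / scale) > 1e-6:
            warnings.warn(
                "system is not at steady state at the perturbation time",
                RuntimeWarning,
                stacklevel=2,
            )

    old = get_param(params, pert.target)
    pert_params = patch_params(params, {pert.target: (1.0 - pert.reduction) * old})

    branches = {}
    specs = [("perturbed", pert_params)] + ([("unperturbed", params)] if unperturbed else [])
    for label, branch_params in specs:
        sol_post = _solve_segment(
            model,
            branch_params,
            (pert.t_pert, protocol.t_end),
            y_split,
            post_grid,
            protocol.rtol,
            protocol.atol,
            protocol.method,
        )
        states = np.vstack([sol_pre.y.T, sol_post.y.T])
        times = np.concatenate([pre_grid, post_grid])
        events = [(0.0, "inoculation")]
        if label == "perturbed":
            events.append(
                (
                    pert.t_pert,
                    f"{pert.target} reduced by {100 * pert.reduction:g}% "
                    f"({old:g} -> {(1 - pert.reduction) * old:g})",
                )
            )
        branches[label] = Trajectory(times, _clip(states), tuple(model.species), events)
    return branches.get("unperturbed"), branches["perturbed"]
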