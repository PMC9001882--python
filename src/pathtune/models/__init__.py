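"""Dynamical models of regulated metabolic pathways.

Each model is exposed as a :class:`Model` bundle (name, right-hand side,
species order, default initial state) so the simulation layer can treat
the simplified merging pathway and the full naringenin system uniformly.
Tunable parameters are addressed by flat names (e.g. ``"k_asigma"`` or
``"p_H"``); :func:`patch_params` resolves them into the possibly nested
parameter dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from . import merging, naringenin
from .merging import MergingParams, MergingState, merging_rhs
from .naringenin import (
    AhlParams,
    ActuatorParams,
    BiosensorParams,
    ControllerParams,
    GlobalParams,
    MetabolicParams,
    NaringeninParams,
    NaringeninState,
    naringenin_rhs,
)

__all__ = [
    "Model",
    "MERGING",
    "NARINGENIN",
    "MODELS",
    "MergingParams",
    "MergingState",
    "merging_rhs",
    "NaringeninParams",
    "NaringeninState",
    "naringenin_rhs",
    "get_param",
    "patch_params",
]


@dataclass(frozen=True)
class Model:
    """A named ODE model: RHS, species ordering, default initial state."""

    name: str
    rhs: Callable[[np.ndarray, object], np.ndarray]
    species: Sequence[str]
    default_initial_state: Callable[[object], np.ndarray]

    def index(self, species_name: str) -> int:
        return list(self.species).index(species_name)


MERGING = Model(
    name="merging",
    rhs=merging_rhs,
    species=merging.SPECIES,
    default_initial_state=merging.default_initial_state,
)

NARINGENIN = Model(
    name="naringenin",
    rhs=naringenin_rhs,
    species=naringenin.SPECIES,
    default_initial_state=naringenin.default_initial_state,
)

MODELS = {m.name: m for m in (MERGING, NARINGENIN)}


def get_param(params, name: str) -> float:
    """Read a parameter by flat name, searching nested groups.

    Raises ``KeyError`` for unknown names and ``ValueError`` when a name
    occurs in more than one group.
    """
    hits = []
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if f.name == name and not dataclasses.is_dataclass(v):
            hits.append(v)
        elif dataclasses.is_dataclass(v) and _has_leaf(v, name):
            hits.append(get_param(v, name))
    if not hits:
        raise KeyError(f"parameter {name!r} not found")
    if len(hits) > 1:
        raise ValueError(f"parameter {name!r} is ambiguous across groups")
    return hits[0]


def patch_params(params, updates: Mapping[str, float]):
    """Return a copy of ``params`` with flat-named fields replaced.

    Raises ``KeyError`` for unknown names and ``ValueError`` when a name is
    ambiguous across parameter groups.
    """
    out = params
    for name, value in updates.items():
        out = _patch_one(out, name, float(value))
    return out


def _patch_one(params, name: str, value: float):
    direct = dataclasses.is_dataclass(params) and name in {
        f.name for f in dataclasses.fields(params)
    } and not dataclasses.is_dataclass(getattr(params, name))
    hits = []
    if direct:
        hits.append(None)
    if dataclasses.is_dataclass(params):
        for f in dataclasses.fields(params):
            v = getattr(params, f.name)
            if dataclasses.is_dataclass(v) and _has_leaf(v, name):
                hits.append(f.name)
    if not hits:
        raise KeyError(f"parameter {name!r} not found")
    if len(hits) > 1:
        raise ValueError(f"parameter {name!r} is ambiguous across groups {hits}")
    hit = hits[0]
    if hit is None:
        return dataclasses.replace(params, **{name: value})
    sub = _patch_one(getattr(params, hit), name, value)
    return dataclasses.replace(params, **{hit: sub})


def _has_leaf(params, name: str) -> bool:
    for f in dataclasses.fields(params):
        v = getattr(params, f.name)
        if f.name == name and not dataclasses.is_dataclass(v):
            return True
        if dataclasses.is_dataclass(v) and _has_leaf(v, name):
            return True
    return False
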