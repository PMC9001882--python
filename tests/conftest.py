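"""Shared fixtures: default parameter sets and shortened protocols."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pathtune import registry
from pathtune.objectives import default_merging_protocol, default_naringenin_protocol
from pathtune.simulate import PerturbationSpec, Protocol


@pytest.fixture(scope="session")
def merging_params():
    return registry.default_params("merging")


@pytest.fixture(scope="session")
def naringenin_params():
    return registry.default_params("naringenin")


@pytest.fixture(scope="session")
def merging_protocol():
    return default_merging_protocol()


@pytest.fixture(scope="session")
def naringenin_protocol():
    return default_naringenin_protocol()


@pytest.fixture(scope="session")
def short_merging_protocol():
    """Reduced-horizon merging protocol for fast unit tests."""
    return Protocol(
        t_end=1000.0,
        n_points=120,
        perturbation=PerturbationSpec(t_pert=500.0, target="S2_level", reduction=0.6),
    )


def random_merging_params(rng: np.random.Generator):
    """A random positive merging parameter set (log-uniform scales)."""
    from pathtune.models.merging import MergingParams

    def u(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return MergingParams(
        K_S1=u(100, 5000),
        kcat=u(1, 100),
        Km_S1=u(1e3, 1e5),
        Km_S2=u(1e3, 1e5),
        S2_level=u(1e3, 1e5),
        CN=float(rng.integers(1, 20)),
        a0=u(0.01, 1.0),
        a1=u(50, 200),
        kd20=u(1e4, 1e6),
        k_sigma=u(50, 1000),
        gamma=u(1e-4, 1e-2),
        k_asigma=u(500, 2000),
        kdp=u(10, 1000),
        TF_total=u(10, 1000),
        d_E=u(0.001, 0.1),
        d_sigma=u(0.001, 0.1),
        d_asigma=u(0.001, 0.1),
        mu=u(0.001, 0.05),
        Xmax=u(1e10, 1e13),
    )


def random_merging_state(rng: np.random.Generator) -> np.ndarray:
    scales = np.array([1e5, 1e4, 1e2, 1e4, 1e3, 1e11])
    return scales * np.exp(rng.uniform(np.log(0.01), np.log(2.0), size=6))


def random_naringenin_params(rng: np.random.Generator, base):
    """Randomly rescale every naringenin parameter (structure-preserving)."""

    def scale_group(group):
        updates = {}
        for f in dataclasses.fields(group):
            v = getattr(group, f.name)
            factor = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
            updates[f.name] = v * factor
        return dataclasses.replace(group, **updates)

    out = dataclasses.replace(
        base,
        **{
            g.name: scale_group(getattr(base, g.name))
            for g in dataclasses.fields(base)
        },
    )
    # respect the fraction/volume invariants after rescaling
    ctrl = dataclasses.replace(out.controller, alpha=min(out.controller.alpha, 1.0))
    act = dataclasses.replace(out.actuator, beta=min(out.actuator.beta, 1.0))
    ahl = dataclasses.replace(out.ahl, Vcell=min(out.ahl.Vcell, out.ahl.Vext * 1e-9))
    return dataclasses.replace(out, controller=ctrl, actuator=act, ahl=ahl)


def random_naringenin_state(rng: np.random.Generator) -> np.ndarray:
    scales = np.array(
        [1e6, 1e6, 1e8, 1e6, 1e9, 1e6, 1e7, 1e4, 5e3, 2e3, 1e4, 5e4, 3e3, 2e2, 1e17, 1e11]
    )
    return scales * np.exp(rng.uniform(np.log(0.01), np.log(2.0), size=16))
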