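"""Structural properties of the model right-hand sides and parameter plumbing."""

import dataclasses

import numpy as np
import pytest

from conftest import (
    random_merging_params,
    random_merging_state,
    random_naringenin_params,
    random_naringenin_state,
)
from pathtune import registry
from pathtune.models import (
    MERGING,
    NARINGENIN,
    MergingState,
    get_param,
    patch_params,
)
from pathtune.models.naringenin import NaringeninState


class TestMergingRHS:
    def test_origin_is_fixed_point_without_sources(self, merging_params):
        p = dataclasses.replace(
            merging_params, K_S1=0.0, a0=0.0, k_sigma=0.0, TF_total=1e12
        )
        dy = MERGING.rhs(np.zeros(6), p)
        assert np.allclose(dy, 0.0, atol=1e-20)

    def test_carrying_capacity_is_population_equilibrium(self, merging_params):
        y = np.array([10.0, 5.0, 1.0, 2.0, 3.0, merging_params.Xmax])
        assert MERGING.rhs(y, merging_params)[MERGING.index("X")] == 0.0

    def test_accepts_state_dataclass(self, merging_params):
        s = MergingState(S1=10, P=5, E=1, sigma=2, asigma=3, X=1e10)
        assert np.array_equal(
            MERGING.rhs(s, merging_params), MERGING.rhs(s.to_array(), merging_params)
        )

    def test_nonfinite_state_rejected(self, merging_params):
        with pytest.raises(ValueError):
            MERGING.rhs(np.array([1, np.nan, 1, 1, 1, 1]), merging_params)

    def test_nonnegativity_preserved_at_boundary(self):
        # each species with value 0 must have a nonnegative derivative
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = random_merging_params(rng)
            y = random_merging_state(rng)
            for i in range(6):
                yb = y.copy()
                yb[i] = 0.0
                assert MERGING.rhs(yb, p)[i] >= 0.0


class TestNaringeninRHS:
    def test_no_malonyl_no_merging_flux(self, naringenin_params):
        p = patch_params(naringenin_params, {"Ma_level": 0.0})
        y = np.zeros(16)
        y[NARINGENIN.index("Nc")] = 1e5
        y[NARINGENIN.index("x")] = 1e10
        m = p.metabolic
        dNc = NARINGENIN.rhs(y, p)[NARINGENIN.index("Nc")]
        expected = -(m.kcat_CHI * m.CHI * 1e5 / (m.Km_Nc + 1e5)) - p.glob.mu * 1e5
        assert dNc == pytest.approx(expected, rel=1e-12)

    def test_carrying_capacity(self, naringenin_params):
        y = np.ones(16)
        y[NARINGENIN.index("x")] = naringenin_params.glob.xmax
        assert NARINGENIN.rhs(y, naringenin_params)[NARINGENIN.index("x")] == 0.0

    def test_accepts_state_dataclass(self, naringenin_params):
        y = np.arange(1.0, 17.0)
        s = NaringeninState.from_array(y)
        assert np.array_equal(
            NARINGENIN.rhs(s, naringenin_params), NARINGENIN.rhs(y, naringenin_params)
        )

    def test_nonnegativity_preserved_at_boundary(self, naringenin_params):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = random_naringenin_params(rng, naringenin_params)
            y = random_naringenin_state(rng)
            for i in range(16):
                yb = y.copy()
                yb[i] = 0.0
                assert NARINGENIN.rhs(yb, p)[i] >= 0.0

    def test_flux_bounds(self, naringenin_params):
        # every enzymatic flux is bounded by its step's kcat * E
        rng = np.random.default_rng(3)
        m = naringenin_params.metabolic
        y = random_naringenin_state(rng)
        dy = NARINGENIN.rhs(y, naringenin_params)
        mu = naringenin_params.glob.mu
        Lt = y[NARINGENIN.index("Lt")]
        V_Lt = m.K_Lt - dy[NARINGENIN.index("Lt")] - mu * Lt
        assert 0.0 <= V_Lt <= m.kcat_TAL * m.TAL


class TestParamPlumbing:
    def test_patch_flat_and_nested(self, merging_params, naringenin_params):
        p2 = patch_params(merging_params, {"a1": 100.0, "mu": 0.006})
        assert p2.a1 == 100.0 and p2.mu == 0.006
        assert merging_params.a1 != 100.0  # original untouched
        n2 = patch_params(naringenin_params, {"p_H": 7.0, "mu": 0.01, "Ma_level": 1.0})
        assert n2.actuator.p_H == 7.0
        assert n2.glob.mu == 0.01
        assert n2.metabolic.Ma_level == 1.0

    def test_unknown_and_ambiguous_names(self, naringenin_params):
        with pytest.raises(KeyError):
            patch_params(naringenin_params, {"nonexistent": 1.0})
        with pytest.raises(ValueError):
            # CN exists in both the biosensor and the controller groups
            patch_params(naringenin_params, {"CN": 3.0})

    def test_get_param_roundtrip(self, naringenin_params):
        assert get_param(naringenin_params, "kdc") == naringenin_params.controller.kdc

    def test_invalid_params_rejected(self, merging_params):
        with pytest.raises(ValueError):
            dataclasses.replace(merging_params, mu=0.0)
        with pytest.raises(ValueError):
            dataclasses.replace(merging_params, kcat=-1.0)


class TestRegistry:
    def test_builtin_entries_load(self):
        for name in registry.available():
            model, params = registry.load(name)
            assert model in ("merging", "naringenin")

    def test_roundtrip_through_yaml(self, tmp_path, naringenin_params):
        path = tmp_path / "custom.yaml"
        registry.save(naringenin_params, path)
        model, loaded = registry.load(str(path))
        assert model == "naringenin"
        assert loaded == naringenin_params

    def test_unknown_entry_raises(self):
        with pytest.raises(registry.RegistryError):
            registry.load("no-such-entry")
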