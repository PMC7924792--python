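"""Growth-rate responses, right-hand sides, parameter plumbing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evorescue import (
    ModelParams,
    PopulationState,
    VARIANTS,
    cheater_derivatives,
    classify_regime,
    cooperation_derivatives,
    derivatives,
    growth_rate_smooth,
    growth_rate_step,
    initial_state,
    mutualism_derivatives,
)


class TestGrowthRateStep:
    @pytest.mark.parametrize(
        "r,N_ref,N_c,rho,expected",
        [
            (1.0, 150.0, 100.0, 0.9, 1.0),   # above the critical size
            (1.0, 50.0, 100.0, 0.9, 0.1),    # reduced branch: r * (1 - rho)
            (0.7, 12.0, 100.0, 0.0, 0.7),    # rho = 0 removes the Allee effect
            (0.7, 3e6, 100.0, 0.0, 0.7),
        ],
    )
    def test_branches(self, r, N_ref, N_c, rho, expected):
        assert growth_rate_step(r, N_ref, N_c, rho) == pytest.approx(expected)

    def test_boundary_takes_reduced_branch(self):
        # the high branch applies strictly above N_c
        assert growth_rate_step(1.0, 100.0, 100.0, 0.4) == pytest.approx(0.6)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            growth_rate_step(-1.0, 10.0, 5.0, 0.5)
        with pytest.raises(ValueError):
            growth_rate_step(1.0, 10.0, 5.0, 1.5)


class TestGrowthRateSmooth:
    def test_midpoint_value_at_critical_size(self):
        # Hill form gives r * (1 - rho / 2) exactly at N_ref = N_c
        assert growth_rate_smooth(1.0, 100.0, 100.0, 0.8, 4.0) == pytest.approx(0.6)

    def test_limits(self):
        assert growth_rate_smooth(1.0, 0.0, 100.0, 0.8, 4.0) == pytest.approx(0.2)
        assert growth_rate_smooth(1.0, 1e9, 100.0, 0.8, 4.0) == pytest.approx(1.0)
        assert growth_rate_smooth(1.0, 57.0, 100.0, 0.0, 4.0) == pytest.approx(1.0)

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(ValueError):
            growth_rate_smooth(1.0, 10.0, 5.0, 0.5, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        N_ref=st.floats(0.0, 1e4),
        rho=st.floats(0.0, 1.0),
        h=st.floats(0.5, 30.0),
    )
    def test_monotone_and_bounded(self, N_ref, rho, h):
        v = growth_rate_smooth(1.0, N_ref, 100.0, rho, h)
        v2 = growth_rate_smooth(1.0, N_ref + 1.0, 100.0, rho, h)
        assert (1.0 - rho) - 1e-12 <= v <= 1.0 + 1e-12
        assert v2 >= v - 1e-12  # non-decreasing in the reference density

    @settings(derandomize=True, max_examples=50)
    @given(
        N_ref=st.floats(1.0, 1e4),
        rho=st.floats(0.0, 1.0),
    )
    def test_converges_to_step(self, N_ref, rho):
        # pointwise limit away from the threshold as the steepness grows
        if abs(N_ref - 100.0) < 5.0:
            N_ref += 10.0
        step = growth_rate_step(1.0, N_ref, 100.0, rho)
        smooth = growth_rate_smooth(1.0, N_ref, 100.0, rho, 600.0)
        assert smooth == pytest.approx(step, abs=1e-6)


class TestDerivatives:
    def test_logistic_equilibrium(self):
        p = ModelParams(model_variant="cooperation", delta=0.0)
        s = PopulationState(0.0, [p.K, 0.0], "cooperation")
        assert cooperation_derivatives(s, p) == pytest.approx([0.0, 0.0])

    def test_cooperation_above_threshold(self):
        # r_A * A * (1 - N_T/K) - delta * A by hand
        p = ModelParams(
            model_variant="cooperation", r_A=1.0, K=1000.0, N_c=50.0,
            rho=0.5, delta=1.5, r_M=2.0,
        )
        s = PopulationState(0.0, [100.0, 0.0], "cooperation")
        dA, dM = cooperation_derivatives(s, p)
        assert dA == pytest.approx(1.0 * 100 * 0.9 - 1.5 * 100)  # -60
        assert dM == 0.0

    def test_cooperation_below_threshold(self):
        p = ModelParams(
            model_variant="cooperation", r_A=1.0, K=1000.0, N_c=50.0,
            rho=0.5, delta=1.5, r_M=2.0,
        )
        s = PopulationState(0.0, [40.0, 0.0], "cooperation")
        dA, _ = cooperation_derivatives(s, p)
        assert dA == pytest.approx(0.5 * 40 * 0.96 - 1.5 * 40)  # -40.8

    def test_mutualism_partner_reference(self):
        # species 1's partner (30) is below N_c, species 2's partner (200) above
        p = ModelParams(
            model_variant="mutualism", r_A=1.0, r_M=2.0, K=1000.0,
            N_c=50.0, rho=0.5, delta=0.0,
        )
        s = PopulationState(0.0, [200.0, 0.0, 30.0, 0.0], "mutualism")
        d = mutualism_derivatives(s, p)
        assert d[0] == pytest.approx(0.5 * 200 * (1 - 230 / 1000))  # 77
        assert d[2] == pytest.approx(1.0 * 30 * (1 - 230 / 1000))   # 23.1

    def test_no_competition_uses_per_species_logistic(self):
        p = ModelParams(
            model_variant="mutualism_no_competition", r_A=1.0, r_M=2.0,
            K=1000.0, N_c=50.0, rho=0.5, delta=0.0,
        )
        s = PopulationState(
            0.0, [200.0, 0.0, 30.0, 0.0], "mutualism_no_competition"
        )
        d = mutualism_derivatives(s, p)
        assert d[0] == pytest.approx(0.5 * 200 * (1 - 200 / 1000))  # 80

    def test_mutualism_symmetry(self):
        p = ModelParams(model_variant="mutualism")
        s = PopulationState(0.0, [300.0, 5.0, 300.0, 5.0], "mutualism")
        d = mutualism_derivatives(s, p)
        assert d[0] == pytest.approx(d[2])
        assert d[1] == pytest.approx(d[3])

    def test_cheater_rate_structure(self):
        p = ModelParams(
            model_variant="cheater", r_A=1.0, r_M=2.0, a=0.3, b=0.5,
            N_c=100.0, rho=0.7, delta=0.2, K=1000.0,
        )
        # cooperators above N_c: cheater per-capita birth is (1+b) times theirs
        hi = PopulationState(0.0, [200.0, 0.0, 50.0, 0.0], "cheater")
        d = cheater_derivatives(hi, p)
        coop_pc = d[0] / 200.0 + p.delta
        cheat_pc = d[2] / 50.0 + p.delta
        assert cheat_pc == pytest.approx((1 + p.b) * coop_pc)
        # cooperators below N_c: cheater multiplier is (1-a) times r(1-rho)
        lo = PopulationState(0.0, [50.0, 0.0, 50.0, 0.0], "cheater")
        d = cheater_derivatives(lo, p)
        coop_pc = d[0] / 50.0 + p.delta
        cheat_pc = d[2] / 50.0 + p.delta
        assert cheat_pc == pytest.approx((1 - p.a) * coop_pc)

    def test_cheater_degenerate_advantages(self):
        p = ModelParams(model_variant="cheater", a=0.0, b=0.0)
        s = PopulationState(0.0, [120.0, 7.0, 60.0, 3.0], "cheater")
        d = cheater_derivatives(s, p)
        assert d[2] / 60.0 == pytest.approx(d[0] / 120.0)
        assert d[3] / 3.0 == pytest.approx(d[1] / 7.0)

    def test_variant_mismatch_rejected(self):
        p = ModelParams(model_variant="mutualism")
        s = PopulationState(0.0, [10.0, 0.0], "cooperation")
        with pytest.raises(ValueError):
            mutualism_derivatives(s, p)

    @settings(derandomize=True, max_examples=30)
    @given(
        variant=st.sampled_from(VARIANTS),
        data=st.data(),
    )
    def test_zero_compartments_stay_zero(self, variant, data):
        # no spontaneous generation: a compartment at 0 has derivative 0
        from evorescue import compartment_labels

        n = len(compartment_labels(variant))
        y = np.array(
            data.draw(
                st.lists(st.floats(0.0, 2000.0), min_size=n, max_size=n)
            )
        )
        k = data.draw(st.integers(0, n - 1))
        y[k] = 0.0
        p = ModelParams(model_variant=variant, rho=0.0 if variant == "baseline" else 0.7)
        assert derivatives(y, p)[k] == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(
        variant=st.sampled_from(VARIANTS),
        data=st.data(),
        form=st.sampled_from(["step", "smooth"]),
    )
    def test_total_is_logistic_without_allee_or_death(self, variant, data, form):
        # with rho=0, delta=0 and one shared rate r, the grand total obeys
        # plain logistic growth in every variant
        from evorescue import compartment_labels

        n = len(compartment_labels(variant))
        y = np.array(
            data.draw(st.lists(st.floats(0.0, 900.0), min_size=n, max_size=n))
        )
        r, K = 0.8, 2000.0
        p = ModelParams(
            model_variant=variant, r_A=r, r_M=r, rho=0.0, delta=0.0,
            K=K, a=0.0, b=0.0, allee_form=form,
        )
        if variant == "mutualism_no_competition":
            # per-species logistic instead of a shared one
            for sp in (0, 1):
                tot = y[2 * sp] + y[2 * sp + 1]
                expect = r * tot * (1 - tot / K)
                got = derivatives(y, p)[2 * sp : 2 * sp + 2].sum()
                assert got == pytest.approx(expect, rel=1e-9, abs=1e-9)
        else:
            NT = y.sum()
            got = derivatives(y, p).sum()
            assert got == pytest.approx(r * NT * (1 - NT / K), rel=1e-9, abs=1e-9)


class TestModelParams:
    def test_roundtrip_and_unknown_keys(self):
        p = ModelParams(model_variant="mutualism", r_A2=0.4, mu2=1e-4)
        assert ModelParams.from_dict(p.to_dict()) == p
        assert ModelParams.from_json(p.to_json()) == p
        with pytest.raises(ValueError, match="unknown parameter"):
            ModelParams.from_dict({"r_A": 0.5, "growth": 1.0})

    @pytest.mark.parametrize(
        "bad",
        [
            {"rho": 1.5},
            {"r_A": -0.1},
            {"K": 0.0},
            {"dt": 0.0},
            {"model_variant": "commensalism"},
            {"model_variant": "baseline"},  # default rho > 0 must be rejected
            {"model_variant": "cooperation", "r_A2": 0.3},
            {"allee_form": "linear"},
        ],
    )
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_species_rates_defaults_to_species_one(self):
        p = ModelParams(model_variant="mutualism", r_A=0.5, r_A2=0.7)
        rA, rM, mu = p.species_rates()
        assert list(rA) == [0.5, 0.7]
        assert list(rM) == [p.r_M] * 2
        assert list(mu) == [p.mu] * 2


class TestStateAndRegime:
    def test_state_mapping_and_totals(self):
        s = PopulationState.from_mapping(
            1.0, {("sp1", "ancestor"): 10.0, ("sp2", "mutant"): 4.0}, "mutualism"
        )
        assert s.total == 14.0
        assert s.species_total("sp1") == 10.0
        assert s[("sp2", "mutant")] == 4.0
        with pytest.raises(ValueError):
            PopulationState(0.0, [-1.0, 0.0], "cooperation")

    def test_initial_states(self):
        assert initial_state(ModelParams()).abundances.tolist() == [1000.0, 0.0]
        m = initial_state(ModelParams(model_variant="mutualism"))
        assert m.abundances.tolist() == [500.0, 0.0, 500.0, 0.0]
        nc = initial_state(ModelParams(model_variant="mutualism_no_competition"))
        assert nc.abundances.tolist() == [1000.0, 0.0, 1000.0, 0.0]
        ch = initial_state(ModelParams(model_variant="cheater", N_c=50.0))
        assert ch.abundances.tolist() == [50.0, 0.0, 5.0, 0.0]

    @pytest.mark.parametrize(
        "changes,regime",
        [
            ({"delta": 0.0}, "no_stress"),
            ({"delta": 0.1}, "trivially_safe"),          # below r_A(1-rho)
            ({"delta": 0.45, "N_c": 20.0}, "trivially_safe"),  # equilibrium > N_c
            ({"r_M": 0.8}, "deterministic_extinction"),
            ({}, "rescue_relevant"),
        ],
    )
    def test_classify_regime(self, changes, regime):
        assert classify_regime(ModelParams(**changes)) == regime
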