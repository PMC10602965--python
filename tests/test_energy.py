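import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npgsim.energy import (
    EnergyParams,
    FLAT_GOLD,
    SCENARIOS,
    activation_ratio,
    association_energy,
    binding_energy,
    pair_step_probabilities,
    reverse_rate,
    scenario_params,
    step_probability,
)

P = EnergyParams()


class TestActivationRatio:
    def test_default_is_boltzmann_factor_of_3kT(self):
        assert activation_ratio(P) == pytest.approx(math.exp(-3.0), rel=1e-12)
        assert activation_ratio(P) == pytest.approx(0.049787, abs=1e-6)

    def test_zero_energy_gives_unity(self):
        assert activation_ratio(EnergyParams(E_a=0.0)) == 1.0

    @given(st.floats(0.0, 10.0), st.floats(0.01, 5.0))
    def test_strictly_decreasing_in_energy(self, e, de):
        lo = activation_ratio(EnergyParams(E_a=e))
        hi = activation_ratio(EnergyParams(E_a=e + de))
        assert hi < lo


class TestBindingEnergy:
    @pytest.mark.parametrize(
        "r_p, expected",
        [(150.0, 3.42), (20.0, 2.9), (75.0, -12 / 75 + 3.5), (FLAT_GOLD, 3.5)],
    )
    def test_pure_gold_values(self, r_p, expected):
        assert binding_energy(r_p, 1.0, P) == pytest.approx(expected, rel=1e-12)

    def test_vanishes_over_a_pore(self):
        # both terms scale with the local gold concentration
        assert binding_energy(75.0, 0.0, P) == 0.0

    def test_nonpositive_pore_size_rejected(self):
        with pytest.raises(ValueError):
            binding_energy(0.0, 1.0, P)
        with pytest.raises(ValueError):
            binding_energy(-5.0, 1.0, P)

    @given(
        st.floats(20.0, 149.0),
        st.floats(0.5, 100.0),
        st.floats(0.0, 1.0),
        st.sampled_from([0.5, 1.0, 2.5]),
    )
    def test_monotone_increasing_in_pore_size(self, r_p, dr, c, alpha):
        # B < 0, so the penalty 1/r_p weakens binding at small pores
        p = EnergyParams(alpha=alpha)
        assert binding_energy(r_p + dr, c, p) >= binding_energy(r_p, c, p)


class TestAssociationEnergy:
    def test_value_at_r_max_recovers_the_constant(self):
        assert association_energy(150.0, 1.0, P) == pytest.approx(6.2, abs=1e-12)

    def test_half_r_max(self):
        assert association_energy(75.0, 1.0, P) == pytest.approx(5.7, rel=1e-12)

    def test_zero_concentration_keeps_offset(self):
        assert association_energy(75.0, 0.0, P) == pytest.approx(5.2, rel=1e-12)

    def test_constant_mode_ignores_inputs(self):
        p = EnergyParams(beta=2.0)
        for r_p in (20.0, 75.0, FLAT_GOLD):
            assert association_energy(r_p, 0.3, p, constant_mode=True) == 6.2

    def test_flat_gold_maps_to_r_max(self):
        assert association_energy(FLAT_GOLD, 1.0, P) == association_energy(150.0, 1.0, P)

    @given(st.floats(20.0, 149.0), st.floats(0.5, 100.0), st.sampled_from([0.5, 1.0, 2.0]))
    def test_monotone_increasing_in_pore_size(self, r_p, dr, beta):
        p = EnergyParams(beta=beta)
        assert association_energy(r_p + dr, 1.0, p) >= association_energy(r_p, 1.0, p)


class TestReverseRate:
    def test_zero_energy_symmetric(self):
        assert reverse_rate(10.0, 0.0, "favors_forward") == 10.0

    def test_activation_reverse(self):
        assert reverse_rate(10.0, 3.0, "favors_reverse") == pytest.approx(200.855, abs=1e-2)

    def test_association_reverse(self):
        assert reverse_rate(1.0, 6.2, "favors_forward") == pytest.approx(2.029e-3, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reverse_rate(0.0, 1.0, "favors_forward")
        with pytest.raises(ValueError):
            reverse_rate(1.0, 1.0, "sideways")


class TestStepProbability:
    @pytest.mark.parametrize(
        "k, dt, expected",
        [(0.0, 0.01, 0.0), (10.0, 0.01, 0.09516), (200.86, 0.01, 0.8659)],
    )
    def test_values(self, k, dt, expected):
        assert step_probability(k, dt) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(0.0, 500.0), st.floats(1e-6, 0.05))
    def test_always_a_probability(self, k, dt):
        # below fp saturation (k*dt <~ 30) the bound is strict
        p = step_probability(k, dt)
        assert 0.0 <= p < 1.0


class TestPairStepProbabilities:
    def test_preserves_equilibrium_ratio_at_full_step(self):
        # the engine's mapping: forward/reverse ratio is exact at any dt
        k_f, k_r = 10.0, 10.0 * math.exp(3.0)
        p_f, p_r = pair_step_probabilities(k_f, k_r, 0.01)
        assert p_f / p_r == pytest.approx(k_f / k_r, rel=1e-12)
        assert p_f + p_r < 1.0

    @given(
        st.floats(1e-3, 1e3), st.floats(1e-3, 1e3), st.floats(1e-6, 1.0)
    )
    def test_ratio_exact_and_probabilities_valid(self, k_f, k_r, dt):
        p_f, p_r = pair_step_probabilities(k_f, k_r, dt)
        assert 0.0 <= p_f and 0.0 <= p_r and p_f + p_r <= 1.0
        assert p_f / p_r == pytest.approx(k_f / k_r, rel=1e-9)

    def test_small_dt_limit_matches_linear_rates(self):
        # both mappings agree with k*dt as dt -> 0; the detailed-balance
        # ratio of the single-channel form recovers k_f/k_r at dt = 1e-5 s
        for k_f, k_r in [(10.0, 200.855), (10.0, 0.327), (1.0, 2.03e-3)]:
            p_f, p_r = pair_step_probabilities(k_f, k_r, 1e-6)
            assert p_f == pytest.approx(k_f * 1e-6, rel=1e-3)
            assert p_r == pytest.approx(k_r * 1e-6, rel=1e-3)
            assert step_probability(k_f, 1e-5) / step_probability(k_r, 1e-5) == \
                pytest.approx(k_f / k_r, rel=1e-3)


class TestScenarios:
    def test_presets(self):
        assert set(SCENARIOS) == {"fig5b", "fig5c", "fig5d", "fig5e"}
        b = scenario_params("fig5b")
        assert b.constant_Ec and b.alpha == 1.0
        d = scenario_params("fig5d")
        assert (d.alpha, d.beta) == (0.5, 0.5)
        e = scenario_params("fig5e")
        assert (e.alpha, e.beta) == (2.5, 2.0)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            scenario_params("fig5z")

    def test_energy_ranges_admissible_for_all_scenarios(self):
        # the model keeps both substrate-dependent energies within 0-10 kT
        r = np.linspace(20.0, 150.0, 53)
        c = np.linspace(0.0, 1.0, 11)
        for name in SCENARIOS:
            p = scenario_params(name)
            eb = [binding_energy(rp, cc, p) for rp in r for cc in c]
            ec = [association_energy(rp, cc, p, constant_mode=False) for rp in r for cc in c]
            assert 0.0 <= min(eb) and max(eb) <= 10.0
            assert 0.0 <= min(ec) and max(ec) <= 10.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(dt=0.0)
        with pytest.raises(ValueError):
            EnergyParams(k_b_plus=-1.0)
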