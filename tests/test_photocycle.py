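"""Kinetic network propagation, branching algebra and preset schemes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from photokin import photocycle as pc
from photokin import spectra as sp

from conftest import all_preset_schemes, rk4_fixed_step


def two_state_scheme(k: float) -> pc.KineticScheme:
    return pc.KineticScheme(
        name="AtoB", states=("A", "B"),
        species={"A": (sp.FAD_ANION,), "B": (sp.FAD_OX,)},
        transitions=(pc.Transition("A", "B", k),),
        initial_population=np.array([1.0, 0.0]), ground_state="B")


class TestPropagate:
    def test_two_state_closed_form(self):
        traj = pc.propagate(two_state_scheme(1.0), [0.0, 1.0, 2.0])
        np.testing.assert_allclose(traj.state("A"), np.exp(-np.array([0.0, 1.0, 2.0])),
                                   rtol=1e-12)

    def test_time_zero_returns_initial_population(self):
        for scheme in all_preset_schemes():
            traj = pc.propagate(scheme, [0.0, scheme.slowest_tau()])
            np.testing.assert_allclose(traj.populations[0], scheme.initial_population,
                                       atol=1e-12)

    def test_parallel_deprotonation_and_recombination_decay_at_350ps(self):
        """Intrinsic 0.41 ns and 2.33 ns channels combine to the observed 350 ps."""
        scheme = pc.KineticScheme(
            name="pair", states=("pair", "trp", "ground"),
            species={"pair": (sp.FAD_ANION, sp.TRPH_CATION),
                     "trp": (sp.FAD_ANION, sp.TRP_NEUTRAL),
                     "ground": (sp.FAD_OX,)},
            transitions=(pc.Transition("pair", "trp", 1.0 / 0.4118e-9),
                         pc.Transition("pair", "ground", 1.0 / 2.333e-9)),
            initial_population=np.array([1.0, 0.0, 0.0]))
        t = 350e-12
        traj = pc.propagate(scheme, [t])
        assert traj.state("pair")[0] == pytest.approx(np.exp(-1.0), rel=2e-3)

    def test_population_conservation_on_all_presets(self):
        for scheme in all_preset_schemes():
            tau_max = scheme.slowest_tau()
            times = np.geomspace(1e-12, 5 * tau_max, 60)
            traj = pc.propagate(scheme, times)
            np.testing.assert_allclose(traj.populations.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(traj.populations >= 0.0)
            assert np.all(traj.populations <= 1.0 + 1e-9)

    def test_propagate_matches_fixed_step_rk4_oracle(self):
        """Eigen-solution agrees with a fixed-step RK4 integrator ≤ 1e-8
        (compared inside the horizon where the oracle itself holds 1e-8)."""
        from conftest import rk4_valid_horizon
        for scheme in all_preset_schemes():
            K = scheme.rate_matrix()
            p0 = scheme.initial_population
            tau_min = min(t.tau for t in scheme.transitions)
            h = tau_min / 100.0
            t_hi = min(3 * scheme.slowest_tau(), rk4_valid_horizon(h))
            times = np.geomspace(tau_min, t_hi, 7)
            traj = pc.propagate(scheme, times)
            for i, t in enumerate(times):
                oracle = rk4_fixed_step(K, p0, t, h)
                np.testing.assert_allclose(traj.populations[i], oracle,
                                           rtol=0, atol=1e-8, err_msg=scheme.name)

    def test_propagate_matches_stiff_integrator_over_full_range(self):
        """Radau at rtol 1e-12 confirms the slow (ms–s) dynamics too."""
        from conftest import radau_oracle
        for scheme in all_preset_schemes():
            tau_min = min(t.tau for t in scheme.transitions)
            times = np.geomspace(tau_min, 3 * scheme.slowest_tau(), 7)
            traj = pc.propagate(scheme, times)
            oracle = radau_oracle(scheme.rate_matrix(),
                                  scheme.initial_population, times)
            np.testing.assert_allclose(traj.populations, oracle,
                                       rtol=0, atol=1e-8, err_msg=scheme.name)

    @given(k1=st.floats(0.1, 10.0), k2=st.floats(0.1, 10.0))
    def test_asymptotic_yields_match_branching_fractions(self, k1, k2):
        scheme = pc.KineticScheme(
            name="branch", states=("A", "B", "C"),
            species={"A": (), "B": (), "C": ()},
            transitions=(pc.Transition("A", "B", k1), pc.Transition("A", "C", k2)),
            initial_population=np.array([1.0, 0.0, 0.0]), ground_state="C")
        t_end = 60.0 / min(k1, k2)
        traj = pc.propagate(scheme, [t_end])
        assert traj.state("B")[0] == pytest.approx(
            pc.branching_fraction(k1, [k1, k2]), abs=1e-9)
        assert traj.state("C")[0] == pytest.approx(
            pc.branching_fraction(k2, [k1, k2]), abs=1e-9)

    def test_negative_time_rejected(self, wt_scheme):
        with pytest.raises(ValueError):
            pc.propagate(wt_scheme, [-1.0])


class TestBranchingAlgebra:
    def test_deprotonation_branching_is_85_percent(self):
        k_dep, k_rec = 1.0 / 0.4118e-9, 1.0 / 2.333e-9
        assert pc.branching_fraction(k_dep, [k_dep, k_rec]) == pytest.approx(0.85, abs=5e-3)

    def test_equal_rates_and_single_path(self):
        assert pc.branching_fraction(2.0, [2.0, 2.0]) == 0.5
        assert pc.branching_fraction(3.0, [3.0]) == 1.0

    def test_observed_to_intrinsic_wild_type_channels(self):
        assert pc.observed_to_intrinsic(350e-12, 0.85) == pytest.approx(412e-12, rel=1e-3)
        assert pc.observed_to_intrinsic(350e-12, 0.15) == pytest.approx(2333e-12, rel=1e-3)
        assert pc.observed_to_intrinsic(1e-9, 1.0) == 1e-9

    def test_parallel_observed_tau(self):
        assert pc.parallel_observed_tau([300e-6, 1000e-6]) == pytest.approx(230.8e-6, rel=1e-3)
        assert pc.parallel_observed_tau([5e-3]) == 5e-3
        assert pc.parallel_observed_tau([2e-3, 2e-3]) == pytest.approx(1e-3)

    def test_cascade_and_inverse_cascade_yields(self):
        assert pc.cascade_yield([0.65, 0.85]) == pytest.approx(0.5525)
        assert pc.cascade_yield([1.0, 1.0, 1.0]) == 1.0
        assert pc.upstream_yield(0.554, [0.85]) == pytest.approx(0.652, abs=1e-3)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5))
    def test_cascade_yield_never_exceeds_any_stage(self, fractions):
        y = pc.cascade_yield(fractions)
        assert 0.0 < y <= min(fractions) + 1e-15

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            pc.branching_fraction(1.0, [])
        with pytest.raises(ValueError):
            pc.observed_to_intrinsic(1e-9, 0.0)
        with pytest.raises(ValueError):
            pc.parallel_observed_tau([])
        with pytest.raises(ValueError):
            pc.cascade_yield([1.2])


class TestKie:
    def test_solvent_isotope_effect_of_the_fast_phase(self):
        result = pc.kie(350e-12, 800e-12)
        assert result.rounded == 2.3
        assert not result.inverse

    def test_identity_and_inverse(self):
        assert pc.kie(1e-9, 1e-9).value == 1.0
        inv = pc.kie(800e-12, 350e-12)
        assert inv.inverse
        assert inv.value == pytest.approx(0.4375)


class TestPresets:
    def test_wild_type_states_and_time_constants(self, wt_scheme):
        assert set(wt_scheme.states) == {"excited", "pair_trpH", "pair_trp",
                                         "pair_tyr", "ground"}
        taus = wt_scheme.time_constants()
        for expected in (350e-12 / 0.85, 350e-12 / 0.15, 300e-6, 1e-3, 1.1e-3):
            assert np.any(np.isclose(taus, expected, rtol=1e-6)), expected
        # observed eigen-constants: 350 ps fast phase and the 231 μs / 1.1 ms pair
        rates, _ = pc.exponential_components(wt_scheme)
        eigen_taus = np.sort(1.0 / rates[rates > 0])
        assert np.any(np.isclose(eigen_taus, 350e-12, rtol=1e-6))
        assert np.any(np.isclose(eigen_taus, 230.77e-6, rtol=1e-3))
        assert np.any(np.isclose(eigen_taus, 1.1e-3, rtol=1e-6))

    def test_w388f_recombination_vs_side_et(self):
        scheme = pc.preset_scheme("W388F")
        taus = scheme.time_constants()
        assert np.any(np.isclose(taus, 1.2e-9, rtol=1e-9))
        assert np.any(np.isclose(taus, 15e-9, rtol=1e-9))
        assert 10e-9 <= 15e-9 <= 20e-9

    def test_w388f_tyr_pair_yield_brackets_4_percent(self):
        """Cascade yield stays in [3 %, 6 %] across the 10–20 ns side-ET window."""
        for tau_side in (10e-9, 15e-9, 20e-9):
            scheme = pc.preset_scheme("W388F", tau_side_et=tau_side)
            traj = pc.propagate(scheme, [1e-6])  # side ET finished, Tyr pair intact
            y = traj.state("pair_tyr")[0]
            assert 0.03 <= y <= 0.06, (tau_side, y)

    def test_y345f_is_monoexponential_near_250us(self):
        """Without the tyrosine channel the μs/ms decay is a single 250 μs phase."""
        scheme = pc.preset_scheme("Y345F")
        rates, _ = pc.exponential_components(scheme)
        micro = np.sort(1.0 / rates[rates > 0])
        slow = micro[micro > 1e-6]
        assert slow.size == 1
        assert slow[0] == pytest.approx(250e-6, rel=0.1)

    def test_removing_tyr_transition_from_wt_collapses_to_single_phase(self):
        scheme = pc.preset_scheme("WT", tau_tyr_ox=None)
        rates, _ = pc.exponential_components(scheme)
        slow = np.sort(1.0 / rates[rates > 0])
        slow = slow[slow > 1e-6]
        assert slow.size == 1
        assert slow[0] == pytest.approx(300e-6, rel=1e-6)

    def test_cysteine_zero_concentration_matches_wild_type_observables(self):
        # compared at trace level in test_synthgen; here: no scavenging states fed
        scheme = pc.preset_scheme("WT_cysteine", cysteine_molar=0.0)
        traj = pc.propagate(scheme, [10e-3])
        assert traj.state("fad_anion_s")[0] == 0.0
        assert traj.state("fadh")[0] == 0.0

    def test_cysteine_scavenging_rate_scales_with_concentration(self):
        s1 = pc.preset_scheme("WT_cysteine", cysteine_molar=0.1)
        s2 = pc.preset_scheme("WT_cysteine", cysteine_molar=0.3)
        k1 = [t.rate for t in s1.transitions
              if t.source == "pair_trp_s" and t.target == "fad_anion_s"][0]
        k2 = [t.rate for t in s2.transitions
              if t.source == "pair_trp_s" and t.target == "fad_anion_s"][0]
        assert k2 == pytest.approx(3.0 * k1, rel=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            pc.preset_scheme("W999X")

    def test_every_rate_overridable(self):
        scheme = pc.preset_scheme("WT", tau_fast=500e-12, tau_trp_rec=400e-6)
        taus = scheme.time_constants()
        assert np.any(np.isclose(taus, 500e-12 / 0.85, rtol=1e-9))
        assert np.any(np.isclose(taus, 400e-6, rtol=1e-9))


class TestSchemeValidation:
    def test_initial_population_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pc.KineticScheme(
                name="bad", states=("A", "B"), species={"A": (), "B": ()},
                transitions=(pc.Transition("A", "B", 1.0),),
                initial_population=np.array([0.9, 0.0]))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            pc.KineticScheme(
                name="bad", states=("A", "B"), species={"A": (), "B": ()},
                transitions=(pc.Transition("A", "B", -1.0),),
                initial_population=np.array([1.0, 0.0]))

    def test_scheme_without_absorbing_state_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            pc.KineticScheme(
                name="loop", states=("A", "B"), species={"A": (), "B": ()},
                transitions=(pc.Transition("A", "B", 1.0),
                             pc.Transition("B", "A", 1.0)),
                initial_population=np.array([1.0, 0.0]))
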