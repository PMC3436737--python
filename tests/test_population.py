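import numpy as np
import pytest

from tcellfate import (
    PopulationConfig,
    SignalProtocol,
    ProtocolStage,
    PhenotypeComposition,
    sample_population,
    equilibrate_naive,
    run_protocol,
    composition,
    composition_grid,
    count_attractors_map,
)
from tcellfate.population import ModelError


class TestSampling:
    def test_zero_cv_gives_identical_cells(self, generic1):
        pop = sample_population(generic1, PopulationConfig(n_cells=5, cv=0.0, seed=1))
        for k in range(5):
            assert np.array_equal(pop.omega[k], generic1.omega)
            assert np.array_equal(pop.sigma[k], generic1.sigma)

    def test_same_seed_bit_identical(self, generic1):
        cfg = PopulationConfig(n_cells=20, cv=0.05, seed=99)
        a = sample_population(generic1, cfg)
        b = sample_population(generic1, cfg)
        for name in ("omega", "omega0", "signal_omega", "sigma", "gamma"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_sample_means_near_basal(self, generic1):
        n = 200
        cv = 0.05
        pop = sample_population(generic1, PopulationConfig(n_cells=n, cv=cv, seed=3))
        for name in ("omega", "omega0", "signal_omega"):
            basal = getattr(generic1, name)
            draw = getattr(pop, name)
            nz = basal != 0
            tol = 3 * cv * np.abs(basal[nz]) / np.sqrt(n)
            assert np.all(np.abs(draw.mean(axis=0)[nz] - basal[nz]) <= tol)

    def test_zero_parameters_never_perturbed(self, generic1):
        pop = sample_population(generic1, PopulationConfig(n_cells=50, cv=0.05, seed=4))
        assert np.all(pop.omega[:, 0, 0] == 0.0)  # no auto-activation edge in model 1
        assert np.all(pop.signal_omega[:, 1, 1] == 0.0)  # S2 does not touch Y

    def test_sign_constrained_parameters_stay_positive(self, generic1):
        pop = sample_population(generic1, PopulationConfig(n_cells=500, cv=0.3, seed=5))
        assert np.all(pop.sigma > 0) and np.all(pop.gamma > 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_cells=0)
        with pytest.raises(ValueError):
            PopulationConfig(cv=-0.1)


class TestEquilibration:
    def test_all_cells_rest_naive(self, generic1):
        pop = sample_population(generic1, PopulationConfig(n_cells=50, cv=0.05, seed=7))
        equilibrate_naive(pop)
        comp = composition(pop.states, generic1)
        assert comp.counts["naive"] == 50
        # residual check: every cell is genuinely at rest
        assert np.max(np.abs(pop.rhs(pop.states, np.zeros(3)))) < 1e-9

    def test_cv_zero_population_rests_at_basal_fixed_point(self, generic1):
        from tcellfate import find_steady_states

        pop = sample_population(generic1, PopulationConfig(n_cells=3, cv=0.0, seed=1))
        equilibrate_naive(pop)
        ref = find_steady_states(generic1, {})[0].x
        assert np.allclose(pop.states, ref, atol=1e-7)

    def test_model_without_naive_state_reported(self, generic1):
        # a strongly positive basal weight leaves no double-negative state
        broken = generic1.replace(omega0=np.array([2.0, 2.0]))
        pop = sample_population(broken, PopulationConfig(n_cells=3, cv=0.0, seed=1))
        with pytest.raises(ModelError):
            equilibrate_naive(pop)


class TestProtocols:
    def test_single_stage_equals_plain_integration(self, generic1):
        from tcellfate import integrate

        cfg = PopulationConfig(n_cells=4, cv=0.05, seed=11)
        pop = sample_population(generic1, cfg)
        equilibrate_naive(pop)
        start = pop.states.copy()
        run_protocol(pop, SignalProtocol.simultaneous({"S1": 1.5}))
        for k in range(4):
            traj = integrate(pop.cell_network(k), start[k], {"S1": 1.5}, record=False)
            assert np.allclose(pop.states[k], traj.final.x, atol=1e-6)

    def test_sequential_polarizing_then_primary_matches_simultaneous(self, generic1):
        cfg = PopulationConfig(n_cells=60, cv=0.05, seed=13)
        pop_seq = sample_population(generic1, cfg)
        equilibrate_naive(pop_seq)
        run_protocol(pop_seq, SignalProtocol.sequential({"S2": 1.0}, {"S1": 1.5, "S2": 1.0}))
        pop_sim = sample_population(generic1, cfg)
        equilibrate_naive(pop_sim)
        run_protocol(pop_sim, SignalProtocol.simultaneous({"S1": 1.5, "S2": 1.0}))
        c_seq = composition(pop_seq.states, generic1).counts
        c_sim = composition(pop_sim.states, generic1).counts
        assert c_seq == c_sim
        assert c_seq["XSP"] == 60  # homogeneous single-positive outcome

    def test_primary_then_subthreshold_polarizing_is_hysteretic(self, generic1):
        # inside the bistable region the late polarizing signal cannot reprogram
        cfg = PopulationConfig(n_cells=60, cv=0.05, seed=17)
        pop = sample_population(generic1, cfg)
        equilibrate_naive(pop)
        run_protocol(pop, SignalProtocol.simultaneous({"S1": 1.5}))
        before = composition(pop.states, generic1).counts
        assert before["XSP"] > 0 and before["YSP"] > 0
        run_protocol(pop, SignalProtocol.simultaneous({"S1": 1.5, "S2": 0.2}))
        after = composition(pop.states, generic1).counts
        assert after == before

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            ProtocolStage(signals={"S1": -0.5})

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            SignalProtocol(stages=())


class TestComposition:
    def test_all_naive(self, generic1):
        comp = composition(np.zeros((10, 2)), generic1)
        assert comp.counts == {"naive": 10, "XSP": 0, "YSP": 0, "DP": 0}

    def test_one_of_each(self, generic1):
        states = np.array([[0.8, 0.2], [0.2, 0.8], [0.8, 0.8], [0.2, 0.2]])
        comp = composition(states, generic1)
        assert all(comp.counts[lab] == 1 for lab in ("naive", "XSP", "YSP", "DP"))

    def test_order_independence(self, generic1, rng):
        states = rng.uniform(size=(30, 2))
        a = composition(states, generic1).counts
        b = composition(states[rng.permutation(30)], generic1).counts
        assert a == b

    def test_counts_must_sum(self):
        with pytest.raises(ValueError):
            PhenotypeComposition(counts={"naive": 5, "XSP": 0, "YSP": 0, "DP": 0}, total=10)


class TestCompositionGrid:
    def test_determinism_and_sums(self, generic1):
        cfg = PopulationConfig(n_cells=20, cv=0.05, seed=23)
        axes = (("S1", np.linspace(0.8, 2.2, 4)), ("S2", np.linspace(0.0, 0.6, 3)))
        a = composition_grid(generic1, cfg, *axes)
        b = composition_grid(generic1, cfg, *axes)
        for idx, comp in np.ndenumerate(a.cells):
            assert comp.total == 20
            assert sum(comp.counts.values()) == 20
            assert comp.counts == b.cells[idx].counts

    def test_heterogeneous_on_axis_homogeneous_off_axis(self, generic1):
        cfg = PopulationConfig(n_cells=40, cv=0.05, seed=29)
        grid = composition_grid(
            generic1, cfg, ("S1", np.array([1.5])), ("S2", np.array([0.0, 0.8]))
        )
        on_axis = grid.cells[0, 0]
        off_axis = grid.cells[0, 1]
        assert on_axis.counts["XSP"] > 5 and on_axis.counts["YSP"] > 5
        assert off_axis.counts["XSP"] == 40

    def test_cv_zero_degenerate_compositions(self, generic1):
        # away from basin boundaries every cell shares the basal fate
        cfg = PopulationConfig(n_cells=10, cv=0.0, seed=31)
        grid = composition_grid(
            generic1, cfg, ("S1", np.array([0.3, 2.8])), ("S2", np.array([0.5]))
        )
        for comp in grid.cells.ravel():
            assert max(comp.counts.values()) == 10

    def test_gamma_asymmetry_changes_compositions_not_diagram(self, generic1):
        # relaxation-rate asymmetry biases the basin race without moving the
        # average cell's attractor structure
        skewed = generic1.replace(gamma=np.array([9.0, 2.0]))
        axes = (("S1", np.linspace(0.8, 2.2, 8)), ("S2", np.array([0.0, 0.2])))
        map_ref = count_attractors_map(generic1, *axes)
        map_skew = count_attractors_map(skewed, *axes)
        assert np.array_equal(map_ref.cells, map_skew.cells)
        cfg = PopulationConfig(n_cells=60, cv=0.05, seed=37)
        comp_ref = composition_grid(generic1, cfg, ("S1", np.array([1.2])), ("S2", np.array([0.0])))
        comp_skew = composition_grid(skewed, cfg, ("S1", np.array([1.2])), ("S2", np.array([0.0])))
        frac_ref = comp_ref.cells[0, 0].fraction("XSP")
        frac_skew = comp_skew.cells[0, 0].fraction("XSP")
        assert frac_skew > frac_ref  # the fast regulator wins the race more often
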