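import numpy as np
import pytest

from tcellfate import (
    get_model,
    list_models,
    apply_mutation,
    MutationSpec,
    calibrate_generic1,
    calibrate_generic3,
    find_steady_states,
    trace_branch,
    GATA3_AUTOACTIVATION_KNOCKDOWN,
    TBET_KNOCKOUT,
)
from tcellfate.models import GENERIC1, GENERIC3


class TestRegistry:
    def test_registry_names(self):
        assert list_models() == [
            "generic1",
            "generic2",
            "generic3",
            "prototype1_th1_th2",
            "prototype2_th1_th17",
            "prototype3_itreg_th17",
        ]
        assert get_model("prototype2").name == "prototype2_th1_th17"
        with pytest.raises(KeyError):
            get_model("generic99")

    def test_generic1_is_perfectly_symmetric(self):
        assert get_model("generic1").network.is_symmetric()

    def test_generic2_is_asymmetric(self):
        assert not get_model("generic2").network.is_symmetric()

    def test_generic_models_share_relaxation_rate_five(self):
        for name in ("generic1", "generic2", "generic3"):
            net = get_model(name).network
            assert np.all(net.gamma == 5.0)

    def test_prototype2_tbet_basal_weight(self):
        net = get_model("prototype2_th1_th17").network
        assert net.omega0[net.node_index("Tbet")] == pytest.approx(-1.7)

    def test_generic3_auto_weight_override(self):
        net = get_model("generic3", auto_weight=3.2).network
        assert net.omega[0, 0] == 3.2 and net.omega[1, 1] == 3.2
        assert net.is_symmetric()

    def test_provenance_recorded(self):
        for name in list_models():
            assert get_model(name).provenance == "calibrated"

    def test_biological_names_cover_nodes_and_signals(self):
        for name in list_models():
            b = get_model(name)
            for key in b.network.node_names + b.network.signal_names:
                assert key in b.biological_names


class TestMutations:
    def test_gata3_knockdown_scales_auto_activation_tenfold_down(self):
        b = get_model("prototype1_th1_th2")
        mut = apply_mutation(b, GATA3_AUTOACTIVATION_KNOCKDOWN)
        i = b.network.node_index("GATA3")
        assert mut.network.omega[i, i] == pytest.approx(0.1 * b.network.omega[i, i])
        # original untouched, mutation logged
        assert b.network.omega[i, i] == get_model("prototype1_th1_th2").network.omega[i, i]
        assert mut.mutations and "GATA3" in mut.mutations[0]

    def test_tbet_knockout_sets_basal(self):
        b = get_model("prototype2_th1_th17")
        mut = apply_mutation(b, TBET_KNOCKOUT)
        assert mut.network.omega0[mut.network.node_index("Tbet")] == -17.0

    def test_identity_mutation_is_a_no_op(self):
        b = get_model("generic3")
        mut = apply_mutation(b, MutationSpec("scale_weight", ("omega", "X", "X"), 1.0))
        assert np.array_equal(mut.network.omega, b.network.omega)

    def test_invalid_target_rejected(self):
        b = get_model("generic1")
        with pytest.raises(ValueError):
            apply_mutation(b, MutationSpec("scale_weight", ("omega", "X", "Z"), 0.5))
        with pytest.raises(ValueError):
            apply_mutation(b, MutationSpec("set_basal", ("omega", "X", "X"), 0.5))


class TestGeneric2Shape:
    def test_broken_pitchfork_shows_folds_on_disconnected_branch(self):
        net = get_model("generic2").network
        # the branch through the naive state is smooth (no special points)...
        start = find_steady_states(net, {"S1": 0.0})[0]
        smooth = trace_branch(net, {}, "S1", (0.0, 3.0), start)
        assert all(sp.kind != "pitchfork" for sp in smooth.special_points)
        # ...while the disfavored single-positive branch ends in folds
        states = find_steady_states(net, {"S1": 1.4})
        xsp = [s for s in states if s.is_stable and s.x[0] > s.x[1]][0]
        down = trace_branch(net, {}, "S1", (1.4, 0.0), xsp)
        up = trace_branch(net, {}, "S1", (1.4, 3.0), xsp)
        folds = [sp.param for sp in down.special_points + up.special_points if sp.kind == "fold"]
        assert len(folds) == 2
        assert min(folds) < 1.4 < max(folds)

    def test_bistable_region_tilts_across_the_axis(self):
        from tcellfate import count_attractors_map

        net = get_model("generic2").network
        vals1 = np.linspace(0, 3, 41)
        up = count_attractors_map(net, ("S1", vals1), ("S2", np.linspace(0, 0.8, 17)))
        lo = count_attractors_map(net, ("S1", vals1), ("S3", np.linspace(0, 0.8, 17)))
        up_extent = up.axis2[1][np.flatnonzero((up.n_stable >= 2).any(axis=0)).max()]
        lo_extent = lo.axis2[1][np.flatnonzero((lo.n_stable >= 2).any(axis=0)).max()]
        # the cusp ordinates of the two halves differ: the region is tilted
        assert up_extent > 2 * lo_extent


class TestCalibration:
    def test_generic1_calibration_reproduces_frozen_values(self):
        net = calibrate_generic1()
        assert -net.omega[0, 1] == pytest.approx(GENERIC1["w_inhibit"], abs=1e-9)
        assert net.omega0[0] == pytest.approx(GENERIC1["omega0"], abs=1e-9)
        assert net.signal_omega[1, 0] == pytest.approx(GENERIC1["polarizing_weight"], abs=1e-6)
        assert net.is_symmetric()

    def test_generic3_calibration_reproduces_frozen_values(self):
        net = calibrate_generic3()
        assert -net.omega[0, 1] == pytest.approx(GENERIC3["w_inhibit"], abs=1e-8)
        assert net.omega0[0] == pytest.approx(GENERIC3["omega0"], abs=1e-8)
        assert net.sigma[0] == pytest.approx(GENERIC3["sigma"], abs=1e-8)

    def test_generic1_calibrated_pitchforks(self):
        net = calibrate_generic1()
        start = find_steady_states(net, {"S1": 0.0})[0]
        branch = trace_branch(net, {}, "S1", (0.0, 3.0), start, classify=False)
        pfs = sorted(sp.param for sp in branch.special_points if sp.kind == "pitchfork")
        assert pfs[0] == pytest.approx(0.704, abs=1e-3)
        assert pfs[1] == pytest.approx(2.396, abs=1e-3)

    def test_generic3_weak_mutual_inhibition_alone_is_monostable(self):
        # without auto-activation the mutual inhibition cannot create bistability
        net = get_model("generic3", auto_weight=1e-12).network
        for s1 in np.linspace(0, 4, 17):
            states = find_steady_states(net, {"S1": s1})
            assert sum(s.is_stable for s in states) == 1

    def test_generic3_bistable_region_grows_with_auto_activation(self):
        s1s = np.linspace(0.0, 4.0, 161)
        widths = []
        for wa in (1.5, 2.0, 2.6, 3.2):
            net = get_model("generic3", auto_weight=wa).network
            bi = [
                s1
                for s1 in s1s
                if sum(s.is_stable for s in find_steady_states(net, {"S1": s1})) >= 2
            ]
            widths.append(max(bi) - min(bi))
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_generic3_tetrastable_at_extreme_auto_activation(self):
        net = get_model("generic3", auto_weight=4.5).network
        states = find_steady_states(net, {"S1": 0.4375}, points_per_dim=9)
        assert sum(s.is_stable for s in states) == 4


class TestModelFileRoundTrip:
    def test_all_registry_models_round_trip(self, tmp_path):
        from tcellfate import save_model, load_model

        for name in list_models():
            net = get_model(name).network
            path = tmp_path / f"{name}.yaml"
            save_model(net, path)
            loaded = load_model(path)
            assert loaded.node_names == net.node_names
            assert loaded.signal_names == net.signal_names
            for field in ("omega", "omega0", "signal_omega", "sigma", "gamma"):
                assert np.allclose(getattr(loaded, field), getattr(net, field), atol=1e-12)
            assert loaded.regulator_pair == net.regulator_pair
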