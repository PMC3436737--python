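import numpy as np
import pytest

from tcellfate import (
    InfluenceNetwork,
    find_steady_states,
    trace_branch,
    continue_fold_locus,
    trace_pitchfork_coalescence,
    count_attractors_map,
    assemble_bidirectional,
    PitchforkProblem,
    NetParam,
    sigmoid,
)


def one_node_self_activation(s_level=0.0):
    """dx/dt = F(4(-2 + S + 4x)) - x: a classic bistable self-activation switch."""
    return InfluenceNetwork(
        node_names=("X",),
        signal_names=("S",),
        omega=[[4.0]],
        omega0=[-2.0],
        signal_omega=[[1.0]],
        sigma=4.0,
        gamma=1.0,
        regulator_pair=None,
    )


def fold_scan_oracle(net, s_range, n=4001, refine=1e-8):
    """1-D bisection oracle: fold positions where the root count of
    F(sigma W(x)) - x changes along a dense S scan."""

    def roots(s):
        x = np.linspace(-0.05, 1.05, 3000)
        g = sigmoid(net.sigma[0] * (net.omega0[0] + s + net.omega[0, 0] * x)) - x
        sign_changes = np.flatnonzero(np.sign(g[:-1]) != np.sign(g[1:]))
        return len(sign_changes)

    ss = np.linspace(*s_range, n)
    counts = np.array([roots(s) for s in ss])
    folds = []
    for k in np.flatnonzero(np.diff(counts) != 0):
        lo, hi = ss[k], ss[k + 1]
        c_lo = counts[k]
        while hi - lo > refine:
            mid = 0.5 * (lo + hi)
            if roots(mid) == c_lo:
                lo = mid
            else:
                hi = mid
        folds.append(0.5 * (lo + hi))
    return folds


class TestTraceBranch:
    def test_one_node_fold_pair_matches_bisection_oracle(self):
        net = one_node_self_activation()
        oracle = fold_scan_oracle(net, (-2.0, 3.0))
        assert len(oracle) == 2
        start = find_steady_states(net, {"S": -2.0})[0]
        branch = trace_branch(net, {}, "S", (-2.0, 3.0), start)
        folds = sorted(sp.param for sp in branch.special_points if sp.kind == "fold")
        assert len(folds) == 2
        for f, o in zip(folds, sorted(oracle)):
            assert f == pytest.approx(o, abs=1e-5)

    def test_no_feedback_has_no_special_points(self, one_node_factory):
        net = one_node_factory(omega0=-1.0, auto=0.0, sigma=3.0)
        start = find_steady_states(net, {"S": 0.0})[0]
        branch = trace_branch(net, {}, "S", (0.0, 3.0), start)
        assert branch.special_points == []
        # branch covers the requested range
        assert branch.params.max() >= 3.0 - 1e-9

    def test_generic1_symmetric_branch_pitchforks(self, generic1):
        start = find_steady_states(generic1, {"S1": 0.0})[0]
        branch = trace_branch(generic1, {}, "S1", (0.0, 3.0), start)
        pfs = sorted(sp.param for sp in branch.special_points if sp.kind == "pitchfork")
        assert len(pfs) == 2
        assert pfs[0] == pytest.approx(0.704, abs=1e-3)
        assert pfs[1] == pytest.approx(2.396, abs=1e-3)

    def test_start_not_a_steady_state_rejected(self, generic1):
        with pytest.raises(ValueError):
            trace_branch(generic1, {}, "S1", (0.0, 3.0), np.array([10.0, -4.0]))


class TestClassifyPitchfork:
    def test_supercritical_normal_form(self):
        # dx/dt = p x - x^3, reflection x -> -x: the textbook supercritical case
        pf = PitchforkProblem(
            g=lambda x, p: np.array([p * x[0] - x[0] ** 3]),
            reflection=np.array([[-1.0]]),
            x_star=np.zeros(1),
            p_star=0.0,
        )
        assert pf.classify() == "supercritical"

    def test_subcritical_normal_form(self):
        pf = PitchforkProblem(
            g=lambda x, p: np.array([p * x[0] + x[0] ** 3 - 0.2 * x[0] ** 5]),
            reflection=np.array([[-1.0]]),
            x_star=np.zeros(1),
            p_star=0.0,
        )
        assert pf.classify() == "subcritical"

    def test_generic3_criticality_switch(self, generic3_factory):
        for weight, expected in ((1.5, "supercritical"), (3.2, "subcritical")):
            net = generic3_factory(weight)
            start = find_steady_states(net, {"S1": 0.0})[0]
            branch = trace_branch(net, {}, "S1", (0.0, 4.0), start)
            pfs = [sp for sp in branch.special_points if sp.kind == "pitchfork"]
            assert len(pfs) == 2
            assert all(sp.criticality == expected for sp in pfs)


class TestFoldLocus:
    def test_one_node_fold_locus_matches_grid_scan(self):
        # continue the upper fold of the self-activation switch in (S, w_auto)
        net = one_node_self_activation()
        start = find_steady_states(net, {"S": -2.0})[0]
        branch = trace_branch(net, {}, "S", (-2.0, 3.0), start)
        fold = [sp for sp in branch.special_points if sp.kind == "fold"][0]
        locus = continue_fold_locus(
            net, {}, (fold.x, fold.param), ("S", NetParam("omega", (0, 0))), (4.0, 5.0), step2=0.1
        )
        assert locus.terminal_event == "range_boundary"
        # oracle: at several auto-activation weights, re-scan folds in S
        for p1, p2, _x in locus.points[1:]:
            net2 = net.replace(omega=np.array([[p2]]))
            oracle = fold_scan_oracle(net2, (p1 - 0.3, p1 + 0.3), n=601)
            assert any(abs(p1 - o) < 1e-5 for o in oracle)

    def test_generic1_coalescence_at_cusp(self, generic1):
        start = find_steady_states(generic1, {"S1": 0.0})[0]
        branch = trace_branch(generic1, {}, "S1", (0.0, 3.0), start, classify=False)
        pfs = [sp for sp in branch.special_points if sp.kind == "pitchfork"]
        res = trace_pitchfork_coalescence(generic1, {}, pfs, ("S1", "S2"))
        assert res.cusp_param2 == pytest.approx(0.357, abs=1e-2)
        # loci rise from the two pitchforks and approach each other
        assert res.locus_low.points[0][0] == pytest.approx(0.704, abs=0.05)
        assert res.locus_high.points[0][0] == pytest.approx(2.396, abs=0.05)
        assert res.separation_reached < 1e-3

    def test_symmetric_mirror_locus(self, generic1):
        # the (S1, S3) locus is the mirror image of the (S1, S2) locus
        start = find_steady_states(generic1, {"S1": 0.0})[0]
        branch = trace_branch(generic1, {}, "S1", (0.0, 3.0), start, classify=False)
        pfs = [sp for sp in branch.special_points if sp.kind == "pitchfork"]
        res2 = trace_pitchfork_coalescence(generic1, {}, pfs, ("S1", "S2"))
        res3 = trace_pitchfork_coalescence(generic1, {}, pfs, ("S1", "S3"))
        assert res2.cusp_param2 == pytest.approx(res3.cusp_param2, abs=1e-6)
        assert res2.cusp_param1 == pytest.approx(res3.cusp_param1, abs=1e-6)


class TestStabilityMaps:
    def test_monostable_toy_model_counts_one_everywhere(self, one_node_factory):
        net = InfluenceNetwork(
            ("X", "Y"), ("S1", "S2"), np.zeros((2, 2)), [-0.5, -0.5],
            [[1.0, 1.0], [0.5, 0.0]], 2.0, 1.0,
        )
        smap = count_attractors_map(net, ("S1", np.linspace(0, 2, 7)), ("S2", np.linspace(0, 1, 5)))
        assert np.all(smap.n_stable == 1)

    def test_generic1_bistable_region_confined_by_pitchforks(self, generic1):
        smap = count_attractors_map(
            generic1, ("S1", np.linspace(0, 3, 61)), ("S2", np.linspace(0, 1, 21))
        )
        ns = smap.n_stable
        s1 = smap.axis1[1]
        s2 = smap.axis2[1]
        bist = ns >= 2
        # bistability only inside the pitchfork window at S2 = 0
        cols = np.flatnonzero(bist[:, 0])
        assert s1[cols.min()] > 0.704 - 0.06 and s1[cols.max()] < 2.396 + 0.06
        # and only below the cusp ordinate in S2
        rows = np.flatnonzero(bist.any(axis=0))
        assert s2[rows.max()] < 0.357 + 0.06
        # monostable far left and far right
        assert np.all(ns[0, :] == 1) and np.all(ns[-1, :] == 1)

    def test_map_boundary_brackets_continuation_locus(self, generic1):
        # continuation-free cross-check: the grid boundary of the bistable
        # region lies within one grid cell of the fold locus
        start = find_steady_states(generic1, {"S1": 0.0})[0]
        branch = trace_branch(generic1, {}, "S1", (0.0, 3.0), start, classify=False)
        pfs = [sp for sp in branch.special_points if sp.kind == "pitchfork"]
        res = trace_pitchfork_coalescence(generic1, {}, pfs, ("S1", "S2"))
        s1_grid = np.linspace(0.5, 2.6, 106)  # spacing 0.02
        h = s1_grid[1] - s1_grid[0]
        for p1, p2, _x in res.locus_low.points[::4]:
            if p2 > 0.3:
                continue
            smap = count_attractors_map(generic1, ("S1", s1_grid), ("S2", np.array([p2])))
            cols = np.flatnonzero(smap.n_stable[:, 0] >= 2)
            assert cols.size, f"no bistability found at S2={p2}"
            assert abs(s1_grid[cols.min()] - p1) <= 2 * h

    def test_symmetric_model_mirrored_halves(self, generic1):
        vals1 = np.linspace(0, 3, 31)
        vals2 = np.linspace(0, 0.8, 9)
        up = count_attractors_map(generic1, ("S1", vals1), ("S2", vals2))
        lo = count_attractors_map(generic1, ("S1", vals1), ("S3", vals2))
        swap = {"XSP": "YSP", "YSP": "XSP", "naive": "naive", "DP": "DP"}
        for idx, cell in np.ndenumerate(up.cells):
            mirrored = tuple(sorted(swap[lab] for lab in cell))
            assert mirrored == lo.cells[idx]

    def test_bidirectional_requires_shared_axis(self, generic1):
        up = count_attractors_map(generic1, ("S1", np.linspace(0, 3, 5)), ("S2", np.linspace(0, 1, 3)))
        lo = count_attractors_map(generic1, ("S1", np.linspace(0, 2, 5)), ("S3", np.linspace(0, 1, 3)))
        with pytest.raises(ValueError):
            assemble_bidirectional(up, lo)

    def test_generic1_region_sequence_along_axis(self, generic1):
        vals1 = np.linspace(0, 3, 61)
        vals2 = np.linspace(0, 0.6, 7)
        up = count_attractors_map(generic1, ("S1", vals1), ("S2", vals2))
        lo = count_attractors_map(generic1, ("S1", vals1), ("S3", vals2))
        dia = assemble_bidirectional(up, lo)
        axis = up.cells[:, 0]
        # left edge: single naive-like state; right edge: single DP state;
        # middle: the XSP/YSP reprogramming pair
        assert axis[0] == ("naive",)
        assert axis[-1] == ("DP",)
        assert ("XSP", "YSP") in set(axis)
        assert {("naive",), ("DP",), ("XSP", "YSP")} <= dia.signatures()
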