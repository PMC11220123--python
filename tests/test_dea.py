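import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import crs_ratio_te, vertex_dea_single_input
from phcdea import dea
from phcdea.panel import PanelDataset


class TestSolveRadial:
    def test_single_dmu_self_efficient(self):
        X, Y = np.array([[3.0, 1.0]]), np.array([[2.0]])
        for frontier in ("crs", "vrs"):
            theta, lam = dea.solve_radial(X, Y, 0, frontier)
            assert theta == 1.0

    @pytest.mark.parametrize("frontier", ["crs", "vrs"])
    def test_toy_target_b_half(self, toy_1x1, frontier):
        X, Y = toy_1x1
        theta, _ = dea.solve_radial(X, Y, 1, frontier)
        assert theta == pytest.approx(0.5, abs=1e-8)

    def test_crs_matches_ratio_closed_form(self, toy_1x1):
        X, Y = toy_1x1
        for t in range(3):
            theta, _ = dea.solve_radial(X, Y, t, "crs")
            assert theta == pytest.approx(crs_ratio_te(X, Y, t), abs=1e-8)

    def test_vrs_at_least_crs(self, default_panel):
        panel, _ = default_panel
        X, Y = panel.inputs_matrix(2012), panel.outputs_matrix(2012)
        for t in range(0, len(X), 7):
            crs, _ = dea.solve_radial(X, Y, t, "crs")
            vrs, _ = dea.solve_radial(X, Y, t, "vrs")
            assert crs <= vrs + 1e-9

    def test_envelopment_constraints_hold(self, toy_1x1):
        X, Y = toy_1x1
        theta, lam = dea.solve_radial(X, Y, 1, "crs")
        assert np.all(lam @ X <= theta * X[1] + 1e-9)
        assert np.all(lam @ Y >= Y[1] - 1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dea.solve_radial(np.array([[1.0], [-2.0]]), np.ones((2, 1)), 0)

    @given(st.integers(2, 5), st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_closed_form_oracle_random_1x1(self, n, seed):
        """LP agrees with the single-ratio closed form on random 1x1 data."""
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.5, 10, (n, 1))
        Y = rng.uniform(0.5, 10, (n, 1))
        t = int(rng.integers(n))
        theta, _ = dea.solve_radial(X, Y, t, "crs")
        assert theta == pytest.approx(min(1.0, crs_ratio_te(X, Y, t)), abs=1e-8)

    @given(st.integers(3, 5), st.integers(0, 10 ** 6),
           st.sampled_from(["crs", "vrs"]))
    @settings(max_examples=40, deadline=None)
    def test_vertex_oracle_single_input(self, n, seed, frontier):
        """LP agrees with vertex enumeration for 1 input, 2 outputs."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 10, (n, 1))
        Y = rng.uniform(1, 10, (n, 2))
        t = int(rng.integers(n))
        theta, _ = dea.solve_radial(x, Y, t, frontier)
        oracle = vertex_dea_single_input(x, Y, t, frontier)
        assert theta == pytest.approx(min(1.0, oracle), abs=1e-8)


class TestSlacks:
    def test_strongly_efficient_zero_slack(self, toy_1x1):
        X, Y = toy_1x1
        theta, _ = dea.solve_radial(X, Y, 2, "vrs")
        s_in, s_out = dea.max_slacks(X, Y, 2, theta, "vrs")
        assert np.allclose(s_in, 0, atol=1e-9) and np.allclose(s_out, 0, atol=1e-9)

    def test_nonradial_dominance_slack(self):
        """D(4,1;1) is radially efficient under VRS but B(3,1;1) leaves
        one unit of input-1 slack."""
        X = np.array([[1.0, 3.0], [3.0, 1.0], [4.0, 1.0]])
        Y = np.ones((3, 1))
        theta, _ = dea.solve_radial(X, Y, 2, "vrs")
        assert theta == pytest.approx(1.0)
        s_in, s_out = dea.max_slacks(X, Y, 2, theta, "vrs")
        assert s_in == pytest.approx([1.0, 0.0], abs=1e-8)
        assert s_out == pytest.approx([0.0], abs=1e-8)

    def test_slack_invariant_to_peer_order(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 5, (6, 2))
        Y = rng.uniform(1, 5, (6, 2))
        theta, _ = dea.solve_radial(X, Y, 0, "vrs")
        s1 = dea.max_slacks(X, Y, 0, theta, "vrs")
        perm = np.r_[0, 1 + rng.permutation(5)]
        Xp, Yp = X[perm], Y[perm]
        s2 = dea.max_slacks(Xp, Yp, 0, theta, "vrs")
        np.testing.assert_allclose(s1[0], s2[0], atol=1e-7)
        np.testing.assert_allclose(s1[1], s2[1], atol=1e-7)


class TestRTS:
    def test_sum_one_is_crs(self):
        assert dea.classify_rts(np.array([0.4, 0.6])) == "crs"

    def test_toy_perturbed_irs(self, toy_1x1):
        X, Y = toy_1x1
        _, lam = dea.solve_radial(X, Y, 1, "crs")
        assert dea.classify_rts(lam) == "crs"      # lam on A sums to 1
        Y2 = Y.copy()
        Y2[1, 0] = 1.8
        _, lam2 = dea.solve_radial(X, Y2, 1, "crs")
        assert lam2.sum() == pytest.approx(0.9, abs=1e-6)
        assert dea.classify_rts(lam2) == "irs"

    def test_tolerance_band(self):
        tau = dea.RTS_TOL
        assert dea.classify_rts(np.array([1.0 + tau / 2])) == "crs"
        assert dea.classify_rts(np.array([1.0 - tau / 2])) == "crs"

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            dea.classify_rts(np.array([-0.5, 1.0]))


class TestRunByYear:
    def _tiny_panel(self, X, Y):
        import pandas as pd
        rows = []
        for i in range(len(X)):
            rows.append({"dmu": f"d{i}", "year": 2000, "region": "east",
                         "i1": X[i, 0], "o1": Y[i, 0], "z1": 1.0 + i})
        return PanelDataset(pd.DataFrame(rows), input_cols=("i1",),
                            output_cols=("o1",), env_cols=("z1",))

    def test_identical_dmus_all_efficient(self):
        X = np.full((4, 1), 2.0)
        Y = np.full((4, 1), 3.0)
        records, _ = dea.run_dea_by_year(self._tiny_panel(X, Y))
        for r in records:
            assert r.te == r.pte == r.se == 1.0

    def test_toy_panel_scores(self, toy_1x1):
        X, Y = toy_1x1
        records, _ = dea.run_dea_by_year(self._tiny_panel(X, Y))
        b = next(r for r in records if r.dmu == "d1")
        assert b.te == pytest.approx(0.5, abs=1e-8)
        assert b.pte == pytest.approx(0.5, abs=1e-8)
        assert b.se == pytest.approx(1.0, abs=1e-8)

    def test_units_invariance(self, default_panel):
        """Rescaling an input column (unit change) moves no radial score."""
        panel, _ = default_panel
        year = 2013
        X, Y = panel.inputs_matrix(year), panel.outputs_matrix(year)
        X2 = X.copy()
        X2[:, 0] *= 1000.0
        for t in (0, 7, 25):
            for f in ("crs", "vrs"):
                t1, _ = dea.solve_radial(X, Y, t, f)
                t2, _ = dea.solve_radial(X2, Y, t, f)
                assert t1 == pytest.approx(t2, abs=1e-7)

    def test_dominated_dmu_changes_nothing(self, default_panel):
        panel, _ = default_panel
        X, Y = panel.inputs_matrix(2012), panel.outputs_matrix(2012)
        Xd = np.vstack([X, X[0] * 2.0])     # strictly worse copy of DMU 0
        Yd = np.vstack([Y, Y[0] * 0.5])
        for t in (0, 10, 20):
            for f in ("crs", "vrs"):
                a, _ = dea.solve_radial(X, Y, t, f)
                b, _ = dea.solve_radial(Xd, Yd, t, f)
                assert a == pytest.approx(b, abs=1e-8)

    def test_score_contracts_hold(self, small_run):
        _, _, result = small_run
        df = result.stage1
        assert ((df["te"] > 0) & (df["te"] <= df["pte"] + 1e-9)
                & (df["pte"] <= 1.0)).all()
        np.testing.assert_allclose(df["se"], df["te"] / df["pte"], atol=1e-9)
        assert (df.groupby("year")["pte"].max() == 1.0).all()


class TestMeanScores:
    def test_constant_scores(self):
        import pandas as pd
        df = pd.DataFrame({"dmu": list("abc"), "year": [1] * 3,
                           "te": 0.7, "pte": 0.7, "se": 1.0, "rts": "crs"})
        out = dea.mean_scores(df)
        assert out["te"].iloc[0] == pytest.approx(0.7)

    def test_empty_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            dea.mean_scores(pd.DataFrame(columns=["dmu", "te", "pte", "se"]))
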