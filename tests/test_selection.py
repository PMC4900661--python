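import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halfsib.selection import (
    IndexScenario,
    build_matrices,
    economic_weights,
    paper_scenarios,
    rank_families,
    run_scenarios,
    solve_index,
)


def _random_pd(rng, t=3, scale=1.0):
    A = rng.standard_normal((t, t))
    return A @ A.T + scale * np.eye(t)


def _scn(index_traits, m=(1.0, 1.0, 1.0), goal=("W100S", "SOC", "PEC")):
    return IndexScenario("t", tuple(index_traits), tuple(goal), tuple(m))


class TestEconomicWeights:
    def test_reference_matrix_unit_weights(self, ref_matrices):
        G0, _ = ref_matrices
        w = economic_weights((1.0, 1.0, 1.0), G0)
        assert np.allclose(w, [0.254, 1.669, 1.637], atol=5e-4)

    def test_soc_quadruple_w100s_double(self, ref_matrices):
        G0, _ = ref_matrices
        w1 = economic_weights((1.0, 1.0, 1.0), G0)
        w3 = economic_weights((2.0, 4.0, 1.0), G0)
        assert w3[0] == pytest.approx(2 * w1[0])
        assert w3[1] == pytest.approx(4 * w1[1])
        assert w3[2] == pytest.approx(w1[2])

    def test_identity_genetic_covariance(self):
        w = economic_weights((2.0, 3.0, 4.0), np.eye(3))
        assert np.allclose(w, [2.0, 3.0, 4.0])

    def test_zero_genetic_variance_rejected(self):
        G = np.diag([1.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="zero genetic variance"):
            economic_weights((1.0, 1.0, 1.0), G)


class TestBuildMatrices:
    def test_single_trait_index_rows(self, ref_matrices):
        G0, R0 = ref_matrices
        P, G, C = build_matrices(_scn(["SOC"], goal=("SOC", "W100S", "PEC")), G0, R0)
        assert P.shape == (1, 1) and P[0, 0] == pytest.approx(2.775, abs=1e-3)
        assert np.allclose(G[0], [0.359, 0.891, -0.004])
        assert np.allclose(C, G0[np.ix_([1, 0, 2], [1, 0, 2])])

    def test_full_index_makes_G_equal_C(self, ref_matrices):
        G0, R0 = ref_matrices
        P, G, C = build_matrices(_scn(["W100S", "SOC", "PEC"]), G0, R0)
        assert np.allclose(G, C)
        assert np.allclose(P, G0 + R0)

    def test_zero_residual_collapses_P_to_C(self, ref_matrices):
        G0, _ = ref_matrices
        # a strictly PD stand-in for "no residual variance"
        R0 = 1e-12 * np.eye(3)
        P, G, C = build_matrices(_scn(["W100S", "SOC", "PEC"]), G0, R0)
        assert np.allclose(P, C, atol=1e-10)

    def test_unknown_trait_rejected(self, ref_matrices):
        G0, R0 = ref_matrices
        with pytest.raises(KeyError, match="unknown trait"):
            build_matrices(_scn(["HEIGHT"]), G0, R0)


class TestSolveIndex:
    def test_scenario1_accuracy(self, ref_matrices):
        G0, R0 = ref_matrices
        res = solve_index(_scn(["SOC"]), G0, R0)
        assert res.R_IH == pytest.approx(0.2641, abs=3e-4)

    def test_single_trait_index_closed_form(self, ref_matrices):
        """Index = goal = one trait: R_IH = sqrt(h2) and
        S = i * h2 * sigma_P."""
        G0, R0 = ref_matrices
        scn = IndexScenario("one", ("PEC",), ("PEC",), (1.0,))
        res = solve_index(scn, G0, R0)
        h2 = G0[2, 2] / (G0[2, 2] + R0[2, 2])
        sigma_p = math.sqrt(G0[2, 2] + R0[2, 2])
        assert res.R_IH == pytest.approx(math.sqrt(h2))
        assert res.S["PEC"] == pytest.approx(1.75 * h2 * sigma_p)

    def test_scenario2_coefficients_and_response(self, ref_matrices):
        """2x2 system solved by hand from the reference inputs."""
        G0, R0 = ref_matrices
        res = solve_index(_scn(["SOC", "W100S"]), G0, R0)
        assert res.b == pytest.approx([0.229, 0.204], abs=1e-3)
        assert res.S["W100S"] == pytest.approx(5.43, abs=0.03)

    def test_b_matches_explicit_inverse(self, rng):
        G0 = _random_pd(rng)
        R0 = _random_pd(rng)
        scn = _scn(["W100S", "SOC"])
        res = solve_index(scn, G0, R0)
        P, G, C = build_matrices(scn, G0, R0)
        w = economic_weights(scn.monetary_units, G0, scn.goal_traits)
        assert np.allclose(res.b, np.linalg.inv(P) @ G @ w)

    def test_no_genetic_covariance_means_no_correlated_response(self, ref_matrices):
        _, R0 = ref_matrices
        G0 = np.diag([15.0, 0.4, 0.4])
        res = solve_index(_scn(["SOC"]), G0, R0)
        assert res.S["W100S"] == pytest.approx(0.0, abs=1e-12)
        assert res.S["PEC"] == pytest.approx(0.0, abs=1e-12)
        assert res.S["SOC"] > 0

    def test_gain_identity(self, rng):
        """delta_G = i * R_IH * sigma_H = i * b'Gw / sigma_I for the
        optimal index."""
        G0 = _random_pd(rng)
        R0 = _random_pd(rng)
        scn = _scn(["W100S", "PEC"], m=(1.0, 2.0, 0.5))
        res = solve_index(scn, G0, R0)
        P, G, C = build_matrices(scn, G0, R0)
        w = economic_weights(scn.monetary_units, G0, scn.goal_traits)
        assert res.delta_G == pytest.approx(scn.intensity * res.sigma_I)
        assert res.delta_G == pytest.approx(scn.intensity * float(res.b @ G @ w) / res.sigma_I)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_accuracy_bounded_and_optimal(self, seed):
        """R_IH lies in [0, 1] and no random linear index beats the
        optimal one."""
        rng = np.random.default_rng(seed)
        G0 = _random_pd(rng)
        R0 = _random_pd(rng)
        scn = _scn(["W100S", "SOC"])
        res = solve_index(scn, G0, R0)
        assert 0.0 <= res.R_IH <= 1.0 + 1e-12
        P, G, C = build_matrices(scn, G0, R0)
        w = economic_weights(scn.monetary_units, G0, scn.goal_traits)
        sH = math.sqrt(w @ C @ w)
        for _ in range(200):
            b = rng.standard_normal(2)
            r = abs(b @ G @ w) / (math.sqrt(b @ P @ b) * sH)
            assert r <= res.R_IH + 1e-9

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_adding_a_trait_never_hurts(self, seed):
        rng = np.random.default_rng(seed)
        G0 = _random_pd(rng)
        R0 = _random_pd(rng)
        r1 = solve_index(_scn(["SOC"]), G0, R0).R_IH
        r2 = solve_index(_scn(["SOC", "W100S"]), G0, R0).R_IH
        r3 = solve_index(_scn(["SOC", "W100S", "PEC"]), G0, R0).R_IH
        assert r2 >= r1 - 1e-9
        assert r3 >= r2 - 1e-9


class TestRunScenarios:
    def test_scenario1_responses_weight_invariant(self, ref_matrices):
        """A scalar index rescales b with the weights, so scenario-1
        responses repeat across weight sets."""
        G0, R0 = ref_matrices
        table = run_scenarios(G0, R0).set_index("scenario")
        for col in ("S_W100S", "S_SOC", "S_PEC"):
            vals = [table.loc[f"{w}/scenario1", col] for w in ("w1", "w2", "w3")]
            assert np.allclose(vals, vals[0])

    def test_accuracy_grows_with_index_traits(self, ref_matrices):
        G0, R0 = ref_matrices
        table = run_scenarios(G0, R0).set_index("scenario")
        for w in ("w1", "w2", "w3"):
            r = [table.loc[f"{w}/scenario{s}", "R_IH"] for s in "123"]
            assert r[0] < r[1] < r[2]

    def test_grid_layout(self, ref_matrices):
        G0, R0 = ref_matrices
        table = run_scenarios(G0, R0)
        assert len(table) == 9
        assert {"R_IH", "delta_G", "S_W100S", "S_SOC", "S_PEC"} <= set(table.columns)


class TestRankFamilies:
    def _gv(self, values):
        values = np.asarray(values, float)
        idx = [f"F{j:03d}" for j in range(1, len(values) + 1)]
        return pd.DataFrame(values, index=pd.Index(idx, name="family_id"),
                            columns=["W100S", "SOC", "PEC"])

    def test_unit_coefficient_ranks_on_single_trait(self, rng, ref_matrices):
        G0, R0 = ref_matrices
        gv = self._gv(rng.standard_normal((10, 3)))
        scn = _scn(["W100S", "SOC", "PEC"])
        res = solve_index(scn, G0, R0)
        res.b = np.array([1.0, 0.0, 0.0])
        out = rank_families(gv, res, scn)
        expected = gv["W100S"].sort_values(ascending=False).index
        assert list(out["family_id"]) == list(expected)

    def test_top_fraction_count(self, rng, ref_matrices):
        G0, R0 = ref_matrices
        gv = self._gv(rng.standard_normal((179, 3)))
        scn = _scn(["W100S", "SOC", "PEC"])
        res = solve_index(scn, G0, R0)
        out = rank_families(gv, res, scn, top_fraction=0.10)
        assert out["selected"].sum() == 18  # ceil(17.9)

    def test_ties_break_lexicographically(self, ref_matrices):
        G0, R0 = ref_matrices
        gv = self._gv(np.ones((5, 3)))
        scn = _scn(["W100S", "SOC", "PEC"])
        res = solve_index(scn, G0, R0)
        out = rank_families(gv, res, scn)
        assert list(out["family_id"]) == sorted(gv.index)

    def test_missing_index_trait_rejected(self, ref_matrices):
        G0, R0 = ref_matrices
        scn = _scn(["W100S", "SOC", "PEC"])
        res = solve_index(scn, G0, R0)
        gv = self._gv(np.ones((4, 3))).drop(columns=["PEC"])
        with pytest.raises(ValueError, match="missing index traits"):
            rank_families(gv, res, scn)


class TestScenarioValidation:
    def test_paper_grid(self):
        scns = paper_scenarios()
        assert len(scns) == 9
        assert all(s.goal_traits == ("W100S", "SOC", "PEC") for s in scns)

    def test_invalid_scenarios(self):
        with pytest.raises(ValueError):
            IndexScenario("bad", (), ("SOC",), (1.0,))
        with pytest.raises(ValueError):
            IndexScenario("bad", ("SOC",), ("SOC",), (1.0, 2.0))
        with pytest.raises(ValueError):
            IndexScenario("bad", ("SOC",), ("SOC",), (1.0,), intensity=0.0)
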