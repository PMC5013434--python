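"""Correlation screen, BH adjustment, CE classification and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clinexp import screen
from clinexp.screen import UntestableError

from oracles import bh_reference, pearson_reference


class TestCorrelate:
    def test_linear_increase_gives_r_one(self, latitudes):
        r, p = screen.correlate_transcript(2.0 * latitudes + 1.0, latitudes)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_decreasing_gives_rho_minus_one(self):
        lat = np.array([40.0, 44.0, 48.0, 52.0, 56.0, 60.0])
        expr = np.array([100.0, 52.0, 40.0, 9.0, 3.0, 1.0])  # monotone down
        rho, _ = screen.correlate_transcript(expr, lat, method="spearman")
        assert rho == pytest.approx(-1.0)

    def test_six_point_formula_oracle(self):
        rng = np.random.default_rng(3)
        lat = np.array([39.5, 43.8, 47.5, 51.2, 55.5, 59.8])
        for _ in range(10):
            expr = rng.normal(size=6)
            r, _ = screen.correlate_transcript(expr, lat)
            assert r == pytest.approx(pearson_reference(expr, lat), abs=1e-12)

    def test_constant_expression_untestable(self, latitudes):
        with pytest.raises(UntestableError):
            screen.correlate_transcript(np.full(18, 7.0), latitudes)

    def test_antisymmetry_in_expression(self, latitudes):
        rng = np.random.default_rng(4)
        expr = rng.normal(size=18)
        r1, _ = screen.correlate_transcript(expr, latitudes)
        r2, _ = screen.correlate_transcript(-expr, latitudes)
        assert r1 == pytest.approx(-r2)


class TestBH:
    def test_hand_computed_example(self):
        q = screen.bh_adjust([0.001, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(screen.bh_adjust([1.0, 1.0]), [1.0, 1.0])
        assert screen.bh_adjust([0.123]).tolist() == [0.123]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            screen.bh_adjust([0.1, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_textbook_reference(self, pvals):
        np.testing.assert_allclose(screen.bh_adjust(pvals), bh_reference(pvals), atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        perm = rng.permutation(50)
        q = screen.bh_adjust(p)
        q_perm = screen.bh_adjust(p[perm])
        np.testing.assert_allclose(q[perm], q_perm)

    def test_q_bounds(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        q = screen.bh_adjust(p)
        assert np.all((q >= 0) & (q <= 1))
        assert q[np.argmax(p)] >= p.max()


class TestClassify:
    def make_results(self, r, p):
        return pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(len(r))],
             "r_pearson": r, "p_pearson": p, "rho_spearman": r, "p_primary": p}
        )

    def test_direction_assignment(self):
        res = screen.classify_ce(
            self.make_results([0.9, -0.9, 0.5], [0.0001, 0.0001, 0.5]), fdr=0.01
        )
        assert res["direction"].tolist() == ["+CE", "-CE", "NS"]
        assert (res.loc[res.direction != "NS", "q"] <= 0.01).all()

    def test_q_above_fdr_is_ns(self):
        res = screen.classify_ce(self.make_results([0.9], [0.02]), fdr=0.01)
        assert res["direction"].tolist() == ["NS"]

    def test_fdr_one_flags_all_fdr_zero_none(self, latitudes):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(size=(30, 18)), index=[f"t{i}" for i in range(30)])
        all_on = screen.screen_latitude(values, latitudes, fdr=1.0)
        assert set(all_on["direction"]) <= {"+CE", "-CE"}
        none_on = screen.screen_latitude(values, latitudes, fdr=0.0)
        assert set(none_on["direction"]) == {"NS"}


class TestScreenMatrix:
    def test_vectorized_matches_scipy_rowwise(self, latitudes):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(size=(40, 18)), index=[f"t{i}" for i in range(40)])
        res = screen.screen_latitude(values, latitudes)
        for i in range(40):
            r, p = stats.pearsonr(values.iloc[i], latitudes)
            rho, _ = stats.spearmanr(values.iloc[i], latitudes)
            assert res["r_pearson"].iloc[i] == pytest.approx(r, abs=1e-10)
            assert res["p_pearson"].iloc[i] == pytest.approx(p, rel=1e-8)
            assert res["rho_spearman"].iloc[i] == pytest.approx(rho, abs=1e-10)

    def test_constant_rows_marked_untestable(self, latitudes):
        values = pd.DataFrame(
            np.vstack([np.full(18, 3.0), np.arange(18.0)]), index=["const", "var"]
        )
        res = screen.screen_latitude(values, latitudes)
        assert res.set_index("transcript_id").loc["const", "direction"] == "untestable"
        assert res.set_index("transcript_id").loc["var", "direction"] != "untestable"


class TestNormality:
    def test_gaussian_vs_skewed_flag_rates(self, latitudes):
        rng = np.random.default_rng(9)
        gauss = pd.DataFrame(rng.normal(size=(2000, 18)))
        skewed = pd.DataFrame(np.exp(rng.normal(0, 2.0, size=(2000, 18))))
        f_gauss = screen.normality_screen(gauss)["departs"].mean()
        f_skew = screen.normality_screen(skewed)["departs"].mean()
        assert f_gauss < 0.005
        assert f_skew > 10 * max(f_gauss, 0.01)

    def test_constant_untestable(self, latitudes):
        values = pd.DataFrame(np.vstack([np.full(18, 1.0), np.arange(18.0)]))
        res = screen.normality_screen(values)
        assert not res["testable"].iloc[0]
        assert not res["departs"].iloc[0]


class TestConcordance:
    def test_identical_and_negated(self):
        v = np.array([0.1, -0.5, 0.9])
        assert screen.method_concordance(v, v) == pytest.approx(1.0)
        assert screen.method_concordance(v, -v) == pytest.approx(-1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            screen.method_concordance(np.ones(3), np.ones(4))

    def test_monotone_clines_concord_above_point_nine(self, latitudes):
        rng = np.random.default_rng(10)
        n = 500
        slopes = rng.uniform(-1, 1, n)
        values = pd.DataFrame(
            slopes[:, None] * (latitudes - latitudes.mean()) + rng.normal(0, 2.0, (n, 18))
        )
        res = screen.screen_latitude(values, latitudes)
        conc = screen.method_concordance(res["r_pearson"], res["rho_spearman"])
        assert conc > 0.9


class TestOverlap:
    def test_hand_contingency_example(self):
        universe = {f"t{i}" for i in range(20)}
        a = {f"t{i}" for i in range(5)}
        b = {"t0", "t1", "t2", "t10"}
        res = screen.overlap_test(a, b, universe)
        assert res.observed_overlap == 3
        assert res.expected_overlap == pytest.approx(1.0)
        # hand 2x2: [[3, 2], [1, 14]]
        np.testing.assert_array_equal(res.observed, [[3, 2], [1, 14]])
        chi2, _, _, _ = stats.chi2_contingency(np.array([[3, 2], [1, 14]]))
        assert res.chi2 == pytest.approx(chi2)

    def test_identical_half_universe_sets(self):
        universe = {f"t{i}" for i in range(100)}
        a = {f"t{i}" for i in range(50)}
        res = screen.overlap_test(a, a, universe)
        assert res.observed_overlap == 50
        assert res.residuals[0, 0] > 0
        assert res.p < 1e-10

    def test_independent_sets_p_uniform(self):
        rng = np.random.default_rng(11)
        universe = {f"t{i}" for i in range(400)}
        ids = sorted(universe)
        ps = []
        for _ in range(200):
            a = set(rng.choice(ids, 80, replace=False))
            b = set(rng.choice(ids, 80, replace=False))
            ps.append(screen.overlap_test(a, b, universe).p)
        # Yates-corrected p is conservative; demand no inflation of small p
        assert np.mean(np.array(ps) < 0.05) <= 0.08

    def test_empty_universe(self):
        with pytest.raises(ValueError, match="universe"):
            screen.overlap_test({"a"}, {"b"}, set())
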