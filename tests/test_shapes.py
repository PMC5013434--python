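"""Rescaling, per-model ML fits, and AIC cline-shape selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinexp import shapes
from clinexp.shapes import (
    ClineFit,
    ModelFit,
    fit_linear,
    fit_null,
    fit_sigmoid,
    fit_step,
    fit_transcript,
    gaussian_loglik,
    rescale,
    select_shape,
)

LAT6 = np.array([39.5, 43.8, 47.5, 51.2, 55.5, 59.8])
LAT18 = np.repeat(LAT6, 3)


def sigmoid_mean(l, xs, d, kappa, c):
    return xs + (d / 2.0) * (1.0 + np.tanh(kappa * (l - c)))


class TestRescale:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10.0, 20.0, 30.0], [0.0, 0.5, 1.0]),
            ([3.0, 9.0, 6.0], [0.0, 1.0, 0.5]),
        ],
    )
    def test_hand_examples(self, values, expected):
        prof = rescale(np.array(values), np.array([40.0, 50.0, 60.0]))
        np.testing.assert_allclose(prof.x, expected)
        np.testing.assert_allclose(prof.l, [0.0, 10.0, 20.0])

    def test_constant_flagged(self):
        prof = rescale(np.array([5.0, 5.0, 5.0]), np.array([40.0, 50.0, 60.0]))
        assert prof.constant

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=0.01, max_value=100.0),
        st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, a, c):
        rng = np.random.default_rng(0)
        r = rng.random(18) * 100
        p1 = rescale(r, LAT18)
        p2 = rescale(a * r + c, LAT18)
        np.testing.assert_allclose(p1.x, p2.x, atol=1e-9)

    def test_bounds_attained(self):
        rng = np.random.default_rng(1)
        prof = rescale(rng.random(18), LAT18)
        assert prof.x.min() == 0.0 and prof.x.max() == 1.0
        assert prof.l.min() == 0.0


class TestGaussianLoglik:
    def test_two_residual_formula_oracle(self):
        logl, sigma = gaussian_loglik(np.array([1.0, -1.0]))
        # sigma^2 = RSS / n = 1; logL = -(n/2)(log(2 pi) + 1)
        assert sigma == pytest.approx(1.0)
        assert logl == pytest.approx(-(np.log(2 * np.pi) + 1.0))

    def test_zero_residuals_finite_at_floor(self):
        logl, sigma = gaussian_loglik(np.zeros(10), sigma_floor=1e-6)
        assert sigma == pytest.approx(1e-6)
        assert logl == pytest.approx(-(10 / 2) * np.log(2 * np.pi * 1e-12))

    def test_scaling_residuals_decreases_loglik(self):
        r = np.array([0.5, -0.2, 0.3, -0.6])
        assert gaussian_loglik(10 * r)[0] < gaussian_loglik(r)[0]


class TestClosedFormFits:
    def test_noiseless_linear_recovers_slope(self):
        l = LAT18 - LAT18.min()
        prof = rescale(l / l.max(), LAT18)
        fit = fit_linear(prof)
        assert fit.params["b"] == pytest.approx(1.0 / l.max(), abs=1e-12)
        assert fit.params["x_s"] == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma == pytest.approx(shapes.SIGMA_FLOOR)

    def test_linear_equals_closed_form_regression(self):
        rng = np.random.default_rng(2)
        x = rng.random(6)
        prof = rescale(x, LAT6)
        fit = fit_linear(prof)
        l, xv = prof.l, prof.x
        b = np.sum((l - l.mean()) * (xv - xv.mean())) / np.sum((l - l.mean()) ** 2)
        assert fit.params["b"] == pytest.approx(b, abs=1e-12)
        assert fit.params["x_s"] == pytest.approx(xv.mean() - b * l.mean(), abs=1e-12)

    def test_null_is_mean(self):
        rng = np.random.default_rng(3)
        prof = rescale(rng.random(18), LAT18)
        assert fit_null(prof).params["x_s"] == pytest.approx(prof.x.mean())

    def test_noiseless_step_exact(self):
        l = LAT18 - LAT18.min()
        sites = np.unique(l)
        lc_true = (sites[2] + sites[3]) / 2
        x = 0.0 + 1.0 * (l >= lc_true)
        fit = fit_step(rescale(x, LAT18))
        assert fit.params["l_c"] == pytest.approx(lc_true)
        assert fit.params["d"] == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(shapes.SIGMA_FLOOR)

    def test_step_equals_exhaustive_candidate_search(self):
        rng = np.random.default_rng(4)
        x = rng.random(18)
        prof = rescale(x, LAT18)
        fit = fit_step(prof)
        l = prof.l
        sites = np.unique(l)
        rss_all = []
        for lc in (sites[:-1] + sites[1:]) / 2:
            s = l < lc
            rss_all.append(
                np.sum((prof.x[s] - prof.x[s].mean()) ** 2)
                + np.sum((prof.x[~s] - prof.x[~s].mean()) ** 2)
            )
        # the fit's residual RSS equals the exhaustive candidate minimum
        resid_rss = len(x) * fit.sigma**2
        assert resid_rss == pytest.approx(min(rss_all), abs=1e-12)

    def test_flat_data_step_d_near_zero(self):
        rng = np.random.default_rng(5)
        x = 0.5 + rng.normal(0, 0.01, 18)
        prof = rescale(x, LAT18)
        fit = fit_step(prof)
        null = fit_null(prof)
        assert abs(fit.params["d"]) < 0.5
        assert fit.logL >= null.logL  # richer model can only improve likelihood


class TestSigmoid:
    def test_noiseless_parameter_recovery(self):
        l = LAT18 - LAT18.min()
        true = dict(xs=0.05, d=0.9, kappa=0.8, c=9.0)
        x = sigmoid_mean(l, true["xs"], true["d"], true["kappa"], true["c"])
        prof = shapes.RescaledProfile("t", x, l)
        fit = fit_sigmoid(prof)
        assert fit.params["x_s"] == pytest.approx(true["xs"], abs=1e-4)
        assert fit.params["d"] == pytest.approx(true["d"], abs=1e-4)
        assert fit.params["kappa"] == pytest.approx(true["kappa"], abs=1e-3)
        assert fit.params["c"] == pytest.approx(true["c"], abs=1e-3)
        assert fit.params["s"] == pytest.approx(fit.params["d"] * fit.params["kappa"] / 2)

    def test_flat_profile_matches_null_likelihood(self):
        rng = np.random.default_rng(6)
        x = 0.5 + rng.normal(0, 0.005, 18)
        prof = rescale(x, LAT18)
        sig = fit_sigmoid(prof)
        null = fit_null(prof)
        assert sig.logL >= null.logL - 1e-6

    def test_needs_four_distinct_latitudes(self):
        lat = np.repeat([40.0, 50.0, 60.0], 2)
        with pytest.raises(ValueError, match="4 distinct"):
            fit_sigmoid(rescale(np.arange(6.0), lat))


class TestSelection:
    def test_aic_identity(self):
        fit = ModelFit("linear", {}, logL=-10.0, sigma=0.1, k=3)
        assert fit.aic == 26.0

    def test_tie_broken_toward_fewer_parameters(self):
        f2 = ModelFit("null", {}, logL=-5.0, sigma=0.1, k=2)
        f5 = ModelFit("sigmoid", {}, logL=-2.0, sigma=0.1, k=5)  # equal AIC = 14
        winner, _ = select_shape({"null": f2, "linear": ModelFit("linear", {}, -10, 0.1, 3),
                                  "sigmoid": f5})
        assert winner == "null"

    def test_aic_identity_holds_for_stored_fits(self):
        rng = np.random.default_rng(7)
        cf = fit_transcript(rng.random(18), LAT18, "t")
        for fit in cf.fits.values():
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.logL)

    @pytest.mark.parametrize("shape", ["null", "linear", "sigmoid", "step"])
    def test_noiseless_true_shape_selected(self, shape):
        l = LAT18 - LAT18.min()
        if shape == "null":
            # constant data short-circuits to the null model
            x = np.full(18, 0.4)
        elif shape == "linear":
            x = 0.1 + 0.8 * l / l.max()
        elif shape == "sigmoid":
            x = sigmoid_mean(l, 0.0, 1.0, 0.7, 10.0)
        else:
            x = 1.0 * (l >= 9.35)
        cf = fit_transcript(x, LAT18, "t")
        assert cf.selected_model == shape

    def test_steep_noiseless_sigmoid_resolves_as_step(self):
        """A transition too sharp for the site spacing is the step model's job:
        the sigmoid matches its likelihood but pays one extra AIC parameter."""
        l = LAT18 - LAT18.min()
        x = sigmoid_mean(l, 0.0, 1.0, 25.0, 9.35)
        cf = fit_transcript(x, LAT18, "t")
        assert cf.selected_model == "step"

    def test_constant_transcript_assigned_null_directly(self):
        cf = fit_transcript(np.full(18, 2.0), LAT18, "t")
        assert cf.selected_model == "null"
        assert set(cf.fits) == {"null"}

    def test_requires_null_and_linear(self):
        with pytest.raises(ValueError):
            select_shape({"null": ModelFit("null", {}, -1, 0.1, 2)})


class TestFitAll:
    def test_tidy_output_columns(self, latitudes):
        rng = np.random.default_rng(9)
        import pandas as pd

        values = pd.DataFrame(rng.random((5, 18)), index=[f"t{i}" for i in range(5)])
        res = shapes.fit_all(values, latitudes)
        assert list(res["transcript_id"]) == [f"t{i}" for i in range(5)]
        for col in ["selected_model", "delta_aic", "aic_null", "aic_linear", "aic_step", "aic_sigmoid"]:
            assert col in res.columns
        assert res["selected_model"].isin(["null", "linear", "step", "sigmoid"]).all()

    def test_subset_restriction(self, latitudes):
        import pandas as pd

        rng = np.random.default_rng(10)
        values = pd.DataFrame(rng.random((6, 18)), index=[f"t{i}" for i in range(6)])
        res = shapes.fit_all(values, latitudes, transcript_ids=["t1", "t3"])
        assert res["transcript_id"].tolist() == ["t1", "t3"]
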