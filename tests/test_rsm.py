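"""Quadratic surface fitting, ANOVA decomposition, uncoding, optimization."""

import numpy as np
import pytest
import statsmodels.api as sm

from keraopt.design import Factor, ResponseTable, generate_ccd
from keraopt.rsm import (
    QuadraticModel,
    anova_quadratic,
    contour_grid,
    fit_quadratic,
    goodness_quadratic,
    optimize_response,
    quadratic_model_matrix,
    uncode_model,
)
from keraopt.simulate import SurfaceTruth, simulate_ccd_response


def random_quadratic(rng, factors):
    names = [f.name for f in factors]
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    return QuadraticModel(
        factor_names=names,
        beta0=float(rng.normal(scale=10)),
        linear={n: float(rng.normal(scale=5)) for n in names},
        square={n: float(rng.normal(scale=5)) for n in names},
        interaction={p: float(rng.normal(scale=5)) for p in pairs},
        coding=factors,
    )


class TestFitQuadratic:
    def test_matches_independent_ols(self, rccd, quad_model):
        design, responses, _ = rccd
        X, _ = quadratic_model_matrix(design.coded)
        oracle = sm.OLS(responses.response, X).fit().params
        got = [quad_model.beta0]
        got += [quad_model.linear[n] for n in design.factor_names]
        got += [quad_model.square[n] for n in design.factor_names]
        got += list(quad_model.interaction.values())
        np.testing.assert_allclose(got, oracle, rtol=1e-9)

    def test_center_prediction_equals_intercept(self, quad_model):
        assert quad_model.predict_coded([0.0, 0.0, 0.0]) == pytest.approx(quad_model.beta0)

    def test_noise_free_recovery_is_exact(self, rng):
        factors = [Factor(n) for n in "abc"]
        truth = random_quadratic(rng, factors)
        design = generate_ccd(factors, n_center=6, n_replicates=2)
        resp = simulate_ccd_response(SurfaceTruth(truth, noise_sd=0.0, seed=1), design)
        model = fit_quadratic(design, resp)
        assert model.beta0 == pytest.approx(truth.beta0, abs=1e-8)
        for n in truth.factor_names:
            assert model.linear[n] == pytest.approx(truth.linear[n], abs=1e-8)
            assert model.square[n] == pytest.approx(truth.square[n], abs=1e-8)
        for p in truth.interaction:
            assert model.interaction[p] == pytest.approx(truth.interaction[p], abs=1e-8)

    def test_ols_equivalence_random_designs(self, rng):
        # pseudo-inverse oracle over random (non-orthogonal) small designs
        for _ in range(30):
            n = int(rng.integers(12, 25))
            coded = rng.normal(size=(n, 2))
            design_factors = [Factor("a"), Factor("b")]
            from keraopt.design import DesignMatrix

            d = DesignMatrix(factors=design_factors, coded=coded)
            y = rng.normal(size=n)
            model = fit_quadratic(d, ResponseTable(response=y))
            X, _ = quadratic_model_matrix(coded)
            oracle = np.linalg.pinv(X) @ y
            assert model.beta0 == pytest.approx(oracle[0], abs=1e-7)

    def test_rank_deficient_design_rejected(self):
        from keraopt.design import DesignMatrix

        coded = np.zeros((15, 2))
        coded[:, 0] = np.arange(15)
        coded[:, 1] = coded[:, 0]  # collinear
        d = DesignMatrix(factors=[Factor("a"), Factor("b")], coded=coded)
        with pytest.raises(ValueError, match="rank"):
            fit_quadratic(d, ResponseTable(response=np.arange(15.0)))


class TestAnova:
    def test_additivity_invariants(self, rccd, quad_model):
        design, responses, _ = rccd
        a = anova_quadratic(quad_model, design, responses)
        assert a.loc["model", "df"] + a.loc["error", "df"] == a.loc["total", "df"]
        assert a.loc["model", "ss"] + a.loc["error", "ss"] == pytest.approx(
            a.loc["total", "ss"], rel=1e-9
        )
        assert a.loc["lack_of_fit", "ss"] + a.loc["pure_error", "ss"] == pytest.approx(
            a.loc["error", "ss"], rel=1e-9
        )
        assert a.loc["lack_of_fit", "df"] + a.loc["pure_error", "df"] == a.loc["error", "df"]

    def test_pure_error_depends_only_on_replicate_groups(self, rccd, quad_model):
        design, responses, _ = rccd
        a = anova_quadratic(quad_model, design, responses)
        y = responses.response
        ss = sum(
            float(np.sum((y[g] - y[g].mean()) ** 2))
            for g in design.replicate_groups()
            if len(g) >= 2
        )
        assert a.loc["pure_error", "ss"] == pytest.approx(ss, rel=1e-12)

    def test_unreplicated_design_warns_and_omits_split(self, rng):
        factors = [Factor(n) for n in "abc"]
        d = generate_ccd(factors, n_center=1, n_replicates=1)
        r = ResponseTable(response=rng.normal(size=d.n_runs))
        m = fit_quadratic(d, r)
        with pytest.warns(UserWarning):
            a = anova_quadratic(m, d, r)
        assert "lack_of_fit" not in a.index

    def test_group_rows_match_partial_f_tests(self, rccd, quad_model):
        # oracle: statsmodels F-test for dropping each whole group
        design, responses, _ = rccd
        X, _ = quadratic_model_matrix(design.coded)
        fit = sm.OLS(responses.response, X).fit()
        a = anova_quadratic(quad_model, design, responses)
        k = 3
        blocks = {
            "linear": range(1, 1 + k),
            "square": range(1 + k, 1 + 2 * k),
            "interaction": range(1 + 2 * k, 1 + 2 * k + 3),
        }
        for name, cols in blocks.items():
            R = np.zeros((len(list(cols)), X.shape[1]))
            for r_i, c in enumerate(cols):
                R[r_i, c] = 1.0
            ftest = fit.f_test(R)
            assert a.loc[name, "f"] == pytest.approx(float(ftest.fvalue), rel=1e-8)
            assert a.loc[name, "p"] == pytest.approx(float(ftest.pvalue), rel=1e-6, abs=1e-12)


class TestGoodness:
    def test_invariants(self, rccd, quad_model):
        design, responses, _ = rccd
        g = goodness_quadratic(quad_model, design, responses)
        a = anova_quadratic(quad_model, design, responses)
        assert g.press >= a.loc["error", "ss"]
        assert g.adj_r2 <= g.r2

    def test_perfect_fit(self, rng):
        factors = [Factor(n) for n in "abc"]
        truth = random_quadratic(rng, factors)
        design = generate_ccd(factors, n_center=6, n_replicates=2)
        resp = simulate_ccd_response(SurfaceTruth(truth, noise_sd=0.0, seed=3), design)
        model = fit_quadratic(design, resp)
        g = goodness_quadratic(model, design, resp)
        assert g.r2 == pytest.approx(100.0, abs=1e-8)
        assert g.press == pytest.approx(0.0, abs=1e-6)

    def test_press_matches_explicit_leave_one_out(self, rccd, quad_model):
        design, responses, _ = rccd
        g = goodness_quadratic(quad_model, design, responses)
        X, _ = quadratic_model_matrix(design.coded)
        y = responses.response
        press = 0.0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            press += (y[i] - X[i] @ beta) ** 2
        assert g.press == pytest.approx(press, rel=1e-9)


class TestUncode:
    def test_identity_coding_leaves_coefficients_unchanged(self, rng):
        factors = [Factor(n, center=0.0, step=1.0) for n in "ab"]
        m = random_quadratic(rng, factors)
        un = uncode_model(m)
        assert un["intercept"] == pytest.approx(m.beta0)
        for n in m.factor_names:
            assert un["linear"][n] == pytest.approx(m.linear[n])
            assert un["square"][n] == pytest.approx(m.square[n])

    def test_coded_and_uncoded_predictions_agree_everywhere(self, rng):
        factors = [
            Factor("a", center=float(rng.normal()), step=float(rng.uniform(0.1, 3))),
            Factor("b", center=float(rng.normal()), step=float(rng.uniform(0.1, 3))),
            Factor("c", center=float(rng.normal()), step=float(rng.uniform(0.1, 3))),
        ]
        m = random_quadratic(rng, factors)
        un = uncode_model(m)
        names = m.factor_names
        for _ in range(100):
            actual = rng.normal(scale=3, size=3)
            coded = np.array([factors[j].code(actual[j]) for j in range(3)])
            direct = m.predict_coded(coded)
            via = un["intercept"]
            via += sum(un["linear"][n] * actual[j] for j, n in enumerate(names))
            via += sum(un["square"][n] * actual[j] ** 2 for j, n in enumerate(names))
            for (a, b), coef in un["interaction"].items():
                via += coef * actual[names.index(a)] * actual[names.index(b)]
            assert direct == pytest.approx(via, rel=1e-8, abs=1e-8)


class TestContourGrid:
    def test_peak_near_center_for_study_surface(self, quad_model):
        grid = contour_grid(quad_model, "NH4Cl", "time", hold={"KH2PO4": 0.55}, grid_n=41)
        best = grid.loc[grid["prediction"].idxmax()]
        assert abs(best["NH4Cl"] - 1.5) < 0.5
        assert abs(best["time"] - 10.5) < 3.0

    def test_single_cell_at_center_is_intercept(self, quad_model):
        grid = contour_grid(quad_model, "KH2PO4", "NH4Cl", hold={"time": 10.5}, grid_n=1)
        assert len(grid) == 1
        assert grid["prediction"].iloc[0] == pytest.approx(quad_model.beta0)

    def test_grid_never_exceeds_stationary_value(self, quad_model):
        # concave surface: the unconstrained stationary point is the global max
        g, B = quad_model.gradient_terms()
        xs = np.linalg.solve(-2 * B, g)
        peak = quad_model.predict_coded(xs)
        grid = contour_grid(quad_model, "KH2PO4", "time", hold={"NH4Cl": 1.5}, grid_n=61)
        assert grid["prediction"].max() <= peak + 1e-9

    def test_missing_hold_value(self, quad_model):
        with pytest.raises(ValueError, match="hold"):
            contour_grid(quad_model, "KH2PO4", "NH4Cl", hold={})


class TestOptimize:
    def test_study_optimum_is_interior_near_center(self, quad_model):
        opt = optimize_response(quad_model, region="cuboid", radius=1.682)
        assert not opt.on_boundary
        # independent oracle: solve grad = 0 for the concave quadratic
        g, B = quad_model.gradient_terms()
        xs = np.linalg.solve(-2 * B, g)
        np.testing.assert_allclose(opt.coded, xs, atol=1e-6)

    def test_pure_concave_bowl_optimum_at_origin(self):
        m = QuadraticModel(
            factor_names=["a", "b"],
            beta0=7.0,
            linear={"a": 0.0, "b": 0.0},
            square={"a": -1.0, "b": -1.0},
            interaction={},
        )
        opt = optimize_response(m, radius=1.0)
        np.testing.assert_allclose(opt.coded, 0.0, atol=1e-8)
        assert opt.predicted_response == pytest.approx(7.0)
        assert not opt.on_boundary

    def test_linear_ridge_pushes_to_boundary(self):
        m = QuadraticModel(
            factor_names=["a", "b", "c"],
            beta0=0.0,
            linear={"a": 0.0, "b": 0.0, "c": 5.0},
            square={"a": 0.0, "b": 0.0, "c": 0.0},
            interaction={},
        )
        opt = optimize_response(m, region="cuboid", radius=1.682)
        assert opt.coded[2] == pytest.approx(1.682, abs=1e-6)
        assert opt.on_boundary
        assert opt.predicted_response == pytest.approx(5.0 * 1.682, rel=1e-6)

    def test_sphere_region_constrains_norm(self):
        m = QuadraticModel(
            factor_names=["a", "b"],
            beta0=0.0,
            linear={"a": 3.0, "b": 4.0},
            square={"a": 0.0, "b": 0.0},
            interaction={},
        )
        opt = optimize_response(m, region="sphere", radius=2.0)
        assert np.linalg.norm(opt.coded) == pytest.approx(2.0, abs=1e-6)
        # optimum along the gradient direction: value = |g| * radius
        assert opt.predicted_response == pytest.approx(10.0, rel=1e-5)

    def test_never_below_best_design_point(self, rccd, quad_model):
        design, responses, _ = rccd
        opt = optimize_response(quad_model, radius=1.682)
        assert opt.predicted_response >= quad_model.predict(design).max() - 1e-9

    def test_invalid_region_or_radius(self, quad_model):
        with pytest.raises(ValueError):
            optimize_response(quad_model, region="torus")
        with pytest.raises(ValueError):
            optimize_response(quad_model, radius=0.0)
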