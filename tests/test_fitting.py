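"""Fitting engine: recovery, oracles, nesting, dispersion, Wald inference."""

import warnings

import numpy as np
import pytest

from countcompare import (
    FitResult,
    ModelSpec,
    fit,
    loglik_poisson,
    pearson_dispersion,
    predict_mean,
    wald_tests,
)
from conftest import make_dataset


def _manual_fit(family, params, names, cov=None, **kw):
    k = len(params)
    params = np.asarray(params, dtype=float)
    cov = np.eye(k) if cov is None else np.asarray(cov)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
    defaults = dict(
        family=family, param_names=names, params=params,
        beta_hat=params, gamma_hat=None, alpha_hat=None,
        loglik=-1.0, converged=True, boundary=False, n_iter=5,
        cov_matrix=cov, se=se, z=params / se,
        p=np.ones(k), aic=0.0, bic=0.0, n=100, k=k,
    )
    defaults.update(kw)
    return FitResult(**defaults)


class TestFit:
    def test_poisson_parameter_recovery_within_wald_band(self):
        ds = make_dataset("poisson", n=5000, seed=77)
        res = fit(ModelSpec("poisson"), ds)
        assert res.converged
        for est, se, true in zip(res.beta_hat, res.se[:3], (2.1, -0.001, 0.03)):
            assert abs(est - true) < 3 * se

    def test_score_vanishes_at_optimum(self):
        ds = make_dataset("poisson", n=500, seed=78)
        res = fit(ModelSpec("poisson"), ds)
        _, score = loglik_poisson(res.beta_hat, ds.y, ds.X)
        assert np.max(np.abs(score)) < 1e-4 * ds.n

    @pytest.mark.parametrize("family,alpha,phi", [
        ("poisson", None, None), ("nb", 1.0, None),
        ("zip", None, 0.3), ("zinb", 1.0, 0.3),
    ])
    def test_aic_bic_definitions(self, family, alpha, phi):
        ds = make_dataset(family, n=400, seed=79, alpha=alpha, phi=phi)
        res = fit(ModelSpec(family), ds)
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k, abs=1e-9)
        assert res.bic == pytest.approx(-2 * res.loglik + res.k * np.log(res.n), abs=1e-9)
        assert res.aic - res.bic == pytest.approx(2 * res.k - res.k * np.log(res.n), abs=1e-9)

    def test_nesting_of_maximized_likelihoods(self, nb_dataset_50):
        lls = {
            fam: fit(ModelSpec(fam), nb_dataset_50).loglik
            for fam in ("poisson", "nb", "zip", "zinb")
        }
        tol = 1e-4
        assert lls["nb"] >= lls["poisson"] - tol
        assert lls["zip"] >= lls["poisson"] - tol
        assert lls["zinb"] >= lls["zip"] - tol
        assert lls["zinb"] >= lls["nb"] - tol

    def test_all_zero_outcome_flagged_not_raised(self):
        ds = make_dataset("poisson", n=50, seed=80)
        ds.y = np.zeros_like(ds.y)
        for fam in ("poisson", "nb"):
            res = fit(ModelSpec(fam), ds)
            assert not res.converged
            assert res.failure_reason == "all_zero_outcome"

    def test_rank_deficient_design_names_columns(self):
        import pandas as pd

        df = pd.DataFrame({"y": [1, 2, 0, 3] * 10, "a": 1.0, "b": 2.0})
        df["b"] = df["a"] * 2
        with pytest.raises(ValueError, match="collinear"):
            fit(ModelSpec("poisson", count_covariates=["a", "b"]), df)

    def test_dispersion_boundary_on_equidispersed_data(self):
        # NB fitted to Poisson data: alpha collapses to the Poisson limit
        ds = make_dataset("poisson", n=2000, seed=81)
        res = fit(ModelSpec("nb"), ds)
        assert not res.converged
        assert res.failure_reason == "dispersion_boundary"

    def test_zero_part_boundary_counted_converged(self):
        # ZIP fitted to Poisson data: mixture weight drifts to the boundary
        ds = make_dataset("poisson", n=200, seed=82)
        res = fit(ModelSpec("zip"), ds)
        assert res.converged


class TestReferenceImplementation:
    """Cross-validation against statsmodels on fixed small datasets."""

    def test_poisson_and_nb_match_reference_glm(self, nb_dataset_50):
        import statsmodels.api as sm

        ds = make_dataset("nb", n=20, seed=11, alpha=1.0)
        ours_p = fit(ModelSpec("poisson"), ds)
        ref_p = sm.GLM(ds.y, ds.X, family=sm.families.Poisson()).fit()
        assert abs(ours_p.loglik - ref_p.llf) < 1e-6

        ours_nb = fit(ModelSpec("nb"), ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_nb = sm.NegativeBinomial(ds.y, ds.X).fit(
                disp=0, maxiter=500, method="bfgs", gtol=1e-10
            )
        assert abs(ours_nb.loglik - ref_nb.llf) < 1e-6

    def test_zip_and_zinb_match_reference(self, zinb_dataset_50):
        from statsmodels.discrete.count_model import (
            ZeroInflatedNegativeBinomialP,
            ZeroInflatedPoisson,
        )

        ds = zinb_dataset_50
        Z = np.ones((ds.n, 1))
        ours_zip = fit(ModelSpec("zip"), ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_zip = ZeroInflatedPoisson(ds.y, ds.X, exog_infl=Z).fit(
                disp=0, maxiter=500, method="bfgs", gtol=1e-10
            )
        assert abs(ours_zip.loglik - ref_zip.llf) < 1e-4

        ours_zinb = fit(ModelSpec("zinb"), ds)
        model = ZeroInflatedNegativeBinomialP(ds.y, ds.X, exog_infl=Z, p=2)
        packed = np.r_[ours_zinb.gamma_hat, ours_zinb.beta_hat, ours_zinb.alpha_hat]
        # likelihood-value agreement at our optimum ...
        assert abs(model.loglike(packed) - ours_zinb.loglik) < 1e-6
        # ... and agreement of the maximized value
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref_zinb = model.fit(start_params=packed, disp=0, maxiter=500,
                                 method="bfgs", gtol=1e-10)
        assert abs(ours_zinb.loglik - ref_zinb.llf) < 1e-4


class TestPredictMean:
    def test_poisson_predictions_are_exp_linear_predictor(self):
        ds = make_dataset("poisson", n=300, seed=83)
        res = fit(ModelSpec("poisson"), ds)
        np.testing.assert_allclose(predict_mean(res), np.exp(ds.X @ res.beta_hat))

    def test_dispersion_does_not_enter_the_mean(self):
        X = make_dataset("poisson", n=10, seed=84).X
        beta = np.array([1.5, -0.002, 0.1])
        pois = _manual_fit("poisson", beta, ["b0", "b1", "b2"], _X=X)
        nb = _manual_fit("nb", np.r_[beta, 2.0], ["b0", "b1", "b2", "alpha"],
                         cov=np.eye(4), alpha_hat=2.0, _X=X)
        nb.beta_hat = beta
        np.testing.assert_allclose(predict_mean(pois), predict_mean(nb))

    def test_zip_mean_is_thinned_by_the_mixture_weight(self):
        X = np.ones((5, 1))
        Z = np.ones((5, 1))
        res = _manual_fit(
            "zip", np.array([np.log(3.0), 0.0]), ["b0", "g0"],
            beta_hat=np.array([np.log(3.0)]), gamma_hat=np.array([0.0]),  # phi = 0.5
            _X=X, _Z=Z,
        )
        np.testing.assert_allclose(predict_mean(res), 1.5)

    def test_requires_convergence(self):
        res = _manual_fit("poisson", [0.0], ["b0"], converged=False, _X=np.ones((2, 1)))
        with pytest.raises(ValueError, match="non-converged"):
            predict_mean(res)


class TestPearsonDispersion:
    def test_well_specified_poisson_near_one(self):
        ds = make_dataset("poisson", n=10_000, seed=85)
        res = fit(ModelSpec("poisson"), ds)
        assert 0.9 <= pearson_dispersion(res) <= 1.1

    def test_overdispersion_inflates_the_statistic(self):
        ds = make_dataset("nb", n=10_000, seed=86, beta=(np.log(5.0), 0.0, 0.0), alpha=5.0)
        res = fit(ModelSpec("poisson"), ds)
        assert pearson_dispersion(res) > 2.0  # ~ 1 + alpha mu = 26

    def test_matches_classical_pearson_for_poisson(self):
        ds = make_dataset("poisson", n=500, seed=87)
        res = fit(ModelSpec("poisson"), ds)
        mu = np.exp(ds.X @ res.beta_hat)
        classical = np.sum((ds.y - mu) ** 2 / mu) / (res.n - res.k)
        assert pearson_dispersion(res) == pytest.approx(classical, rel=1e-10)


class TestWald:
    def test_borderline_significance(self):
        res = _manual_fit("poisson", [1.96], ["b0"])
        table = wald_tests(res)
        assert table["p"].iloc[0] == pytest.approx(0.0500, abs=1e-4)

    def test_null_estimate_has_p_one(self):
        res = _manual_fit("poisson", [0.0], ["b0"])
        assert wald_tests(res)["p"].iloc[0] == pytest.approx(1.0)

    def test_nonpositive_variance_flagged(self):
        res = _manual_fit("poisson", [1.0, 2.0], ["b0", "b1"],
                          cov=np.diag([1.0, -1.0]))
        with pytest.raises(ValueError, match="b1"):
            wald_tests(res)

    def test_p_values_invariant_to_covariate_rescaling(self):
        import pandas as pd

        ds = make_dataset("poisson", n=2000, seed=88)
        df = pd.DataFrame({"y": ds.y, "x1": ds.X[:, 1], "x2": ds.X[:, 2]})
        df10 = df.assign(x1=df.x1 / 10.0)
        p_a = wald_tests(fit(ModelSpec("poisson"), df))["p"].to_numpy()
        p_b = wald_tests(fit(ModelSpec("poisson"), df10))["p"].to_numpy()
        np.testing.assert_allclose(p_a, p_b, atol=1e-6)
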