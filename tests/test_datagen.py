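"""Generator correctness: covariate marginals, count processes, emulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from countcompare import (
    CovariateSpec,
    TrueModel,
    generate_counts,
    generate_covariates,
    generate_los_emulator,
    replication_seed,
)
from countcompare.datagen import LOS_ADMISSION, LOS_INSURANCE

CONST_MU = np.ones((100_000, 1))  # intercept-only design, mu = exp(beta0)


def test_covariate_marginals_match_study_design():
    spec = CovariateSpec(n=100_000)
    cov = generate_covariates(spec, seed=5)
    assert abs(cov.x1.mean() - 57.3) < 0.5
    assert abs(cov.x1.var() - 306.25) < 5.0
    assert abs(cov.x2.mean() - 0.43) < 0.01
    assert cov.X.shape == (100_000, 3)
    assert np.all(cov.X[:, 0] == 1.0)


def test_covariates_deterministic_under_seed():
    spec = CovariateSpec(n=1000)
    a = generate_covariates(spec, seed=9)
    b = generate_covariates(spec, seed=9)
    assert np.array_equal(a.X, b.X)


@pytest.mark.parametrize(
    "kwargs,msg",
    [
        (dict(x1_var=-1.0), "x1_var"),
        (dict(x2_p=1.5), "x2_p"),
        (dict(n=0), "n"),
    ],
)
def test_covariate_spec_validation(kwargs, msg):
    with pytest.raises(ValueError, match=msg):
        CovariateSpec(**{**dict(n=10), **kwargs})


def test_true_model_validation():
    with pytest.raises(ValueError, match="alpha"):
        TrueModel("poisson", alpha=1.0)
    with pytest.raises(ValueError, match="phi"):
        TrueModel("zip")
    with pytest.raises(ValueError, match="alpha"):
        TrueModel("nb", alpha=-0.5)
    with pytest.raises(ValueError, match="phi"):
        TrueModel("zip", phi=1.0)


def test_zip_mean_matches_mixture_expectation():
    # constant mu = 3, phi = 0.5: E(Y) = mu (1 - phi) = 1.5
    truth = TrueModel("zip", beta=(np.log(3.0),), phi=0.5)
    ds = generate_counts(truth, CONST_MU, seed=21)
    assert abs(ds.y.mean() - 1.5) < 0.05
    assert np.allclose(ds.true_mean, 1.5)


def test_nb_variance_matches_quadratic_mean_variance():
    # mu = 2, alpha = 5: V = mu (1 + alpha mu) = 22
    truth = TrueModel("nb", beta=(np.log(2.0),), alpha=5.0)
    ds = generate_counts(truth, CONST_MU, seed=22)
    assert abs(np.var(ds.y) - 22.0) < 1.0


def test_zip_with_phi_zero_is_poisson():
    # phi = 0 boundary: the two samplers induce the same distribution
    t_zip = TrueModel("zip", beta=(np.log(3.0),), phi=0.0)
    t_poi = TrueModel("poisson", beta=(np.log(3.0),))
    y_zip = generate_counts(t_zip, CONST_MU, seed=23).y
    y_poi = generate_counts(t_poi, CONST_MU, seed=24).y
    hi = int(max(y_zip.max(), y_poi.max())) + 1
    table = np.array([np.bincount(y_zip, minlength=hi), np.bincount(y_poi, minlength=hi)])
    table = table[:, table.sum(axis=0) >= 10]
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.001


def test_nb_approaches_poisson_as_alpha_vanishes():
    t_nb = TrueModel("nb", beta=(np.log(3.0),), alpha=1e-6)
    t_poi = TrueModel("poisson", beta=(np.log(3.0),))
    y_nb = generate_counts(t_nb, CONST_MU, seed=25).y
    y_poi = generate_counts(t_poi, CONST_MU, seed=26).y
    hi = int(max(y_nb.max(), y_poi.max())) + 1
    table = np.array([np.bincount(y_nb, minlength=hi), np.bincount(y_poi, minlength=hi)])
    table = table[:, table.sum(axis=0) >= 10]
    _, p, _, _ = stats.chi2_contingency(table)
    assert p > 0.001


@pytest.mark.parametrize("family,alpha", [("zip", None), ("zinb", 2.0)])
def test_structural_zero_mask_forces_zero_counts(family, alpha):
    truth = TrueModel(family, beta=(np.log(4.0),), alpha=alpha, phi=0.4)
    ds = generate_counts(truth, CONST_MU[:20_000], seed=31)
    assert ds.structural_zero is not None
    assert np.all(ds.y[ds.structural_zero] == 0)
    phi, n = 0.4, len(ds.y)
    assert np.mean(ds.y == 0) >= phi - 3 * np.sqrt(phi * (1 - phi) / n)


def test_sample_mean_converges_to_true_mean():
    truth = TrueModel("zinb", beta=(np.log(5.0),), alpha=1.0, phi=0.3)
    ds = generate_counts(truth, np.ones((1_000_000, 1)), seed=33)
    rel = abs(ds.y.mean() - ds.true_mean.mean()) / ds.true_mean.mean()
    assert rel < 0.02


def test_generate_counts_validation():
    with pytest.raises(ValueError, match="intercept"):
        generate_counts(TrueModel("poisson"), np.zeros((5, 3)), seed=1)
    with pytest.raises(OverflowError, match="rows"):
        generate_counts(TrueModel("poisson", beta=(800.0, 0.0, 0.0)),
                        np.column_stack([np.ones(3), np.zeros(3), np.zeros(3)]), seed=1)


def test_replication_seed_stable_and_small():
    s1 = replication_seed(42, "nb_n200_d5", 7)
    s2 = replication_seed(42, "nb_n200_d5", 7)
    assert s1 == s2 < 2**31
    assert s1 != replication_seed(42, "nb_n200_d5", 8)
    assert s1 != replication_seed(42, "nb_n200_d1", 7)


def test_dataset_csv_roundtrip(tmp_path):
    truth = TrueModel("zip", phi=0.3)
    X = generate_covariates(CovariateSpec(n=30), seed=3).X
    ds = generate_counts(truth, X, seed=4, scenario_id="zip_n30")
    path = tmp_path / "sample.csv"
    ds.to_csv(path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["y", "x1", "x2", "structural_zero"]
    assert np.array_equal(back["y"].to_numpy(), ds.y)
    meta = (tmp_path / "sample.meta.json").read_text()
    assert '"family": "zip"' in meta and '"seed": 4' in meta


class TestLosEmulator:
    def test_marginal_shape(self):
        df = generate_los_emulator(2167, seed=0)
        assert len(df) == 2167
        assert 7.0 <= df["los"].mean() <= 9.0
        assert df["los"].var() > df["los"].mean()  # overdispersed
        assert df["los"].min() >= 0 and df["los"].max() <= 40
        # right skew
        assert stats.skew(df["los"]) > 0.5

    def test_category_levels(self):
        df = generate_los_emulator(2167, seed=1)
        assert set(df["insurance"]) == set(LOS_INSURANCE)
        assert set(df["admission_type"]) == set(LOS_ADMISSION)
        assert set(df["sex"]) == {"male", "female"}
        # frequencies roughly as configured
        assert abs((df["insurance"] == "medicare").mean() - 0.4435) < 0.05

    def test_deterministic(self):
        a = generate_los_emulator(500, seed=7)
        b = generate_los_emulator(500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n(self):
        with pytest.raises(ValueError, match="n"):
            generate_los_emulator(0, seed=0)
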