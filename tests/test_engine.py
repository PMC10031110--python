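"""ML estimation, fit indices, standardization, robust statistics."""

import numpy as np
import pandas as pd
import pytest

from pubsem import engine
from pubsem.engine import (
    compare_models,
    fit_indices,
    implied_covariance,
    ml_fit,
    sandwich_se,
)
from pubsem.model import ModelSpec


def _fit_cov(text, S, n, **kw):
    return ml_fit(ModelSpec(text), np.asarray(S, float), n, **kw)


# ----------------------------------------------------------------------
# implied covariance
# ----------------------------------------------------------------------
def test_implied_covariance_no_latents_is_diagonal():
    spec = ModelSpec("x1 ~~ x1\nx2 ~~ x2")
    sigma = implied_covariance(spec, np.array([2.0, 3.0]))
    assert np.allclose(sigma, np.diag([2.0, 3.0]))


def test_implied_covariance_path_tracing():
    spec = ModelSpec("f =~ x1 + x2 + x3")
    # loadings (.8,.7,.6), residuals completing unit diagonals
    theta = np.array([0.8, 0.7, 0.6, 1 - 0.64, 1 - 0.49, 1 - 0.36])
    sigma = implied_covariance(spec, theta)
    assert np.allclose(np.diag(sigma), 1.0)
    assert sigma[0, 1] == pytest.approx(0.56)
    assert sigma[0, 2] == pytest.approx(0.48)
    assert sigma[1, 2] == pytest.approx(0.42)


def test_implied_covariance_matches_simulation():
    """Monte-Carlo oracle: implied covariance equals the covariance of data
    simulated from the same loadings/residuals."""
    spec = ModelSpec("f1 =~ x1 + x2\nf2 =~ x3 + x4\nf1 ~~ f2\nx1 ~~ x3")
    values = {"f1=~x1": 0.9, "f1=~x2": 0.6, "f2=~x3": 0.7, "f2=~x4": 0.8,
              "f1~~f2": 0.4, "x1~~x3": 0.1, "x1~~x1": 0.5, "x2~~x2": 0.4,
              "x3~~x3": 0.6, "x4~~x4": 0.5}
    theta = np.array([values[lbl] for lbl in spec.labels])
    sigma = implied_covariance(spec, theta)
    rng = np.random.default_rng(11)
    n = 400_000
    f = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=n)
    lam, bet, psi, tht, nu = spec.matrices(theta)
    eps = rng.multivariate_normal(np.zeros(4), tht, size=n)
    X = f @ lam[:, :2].T + eps
    assert np.abs(np.cov(X.T) - sigma).max() < 0.02


# ----------------------------------------------------------------------
# ML fitting
# ----------------------------------------------------------------------
def test_just_identified_model_is_saturated():
    S = np.array([[1.0, 0.3, 0.4], [0.3, 1.0, 0.2], [0.4, 0.2, 1.0]])
    fit = _fit_cov("f =~ x1 + x2 + x3", S, 500)
    assert fit.df == 0
    assert fit.chi2 == pytest.approx(0.0, abs=1e-6)


def test_equicorrelated_closed_form_loading():
    """3-indicator factor on an equicorrelated matrix: the loading equals
    sqrt(s12*s13/s23) = sqrt(0.5)."""
    S = np.full((3, 3), 0.5)
    np.fill_diagonal(S, 1.0)
    fit = _fit_cov("f =~ x1 + x2 + x3", S, 1000)
    expected = np.sqrt(0.5)
    assert np.allclose(np.abs(fit.theta[:3]), expected, atol=1e-5)
    assert fit.standardized["f=~x1"] == pytest.approx(expected, abs=1e-5)


def test_fixed_point_recovery():
    """Fitting to an exactly model-implied covariance recovers the
    generating parameters with chi2 ~ 0."""
    spec = ModelSpec("f1 =~ x1 + x2 + x3\nf2 =~ x4 + x5 + x6\nf1 ~~ f2")
    theta0 = np.array([0.8, 0.7, 0.75, 0.6, 0.65, 0.7, 0.5,
                       0.36, 0.51, 0.44, 0.64, 0.58, 0.51])
    sigma0 = implied_covariance(spec, theta0)
    fit = ml_fit(spec, sigma0, 10_000)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-5)
    assert np.abs(np.abs(fit.theta) - np.abs(theta0)).max() < 1e-4


def test_sample_size_validation():
    with pytest.raises(ValueError, match="n must exceed"):
        _fit_cov("f =~ x1 + x2 + x3", np.eye(3), 3)


def test_non_pd_sample_matrix_rejected():
    S = np.ones((3, 3))
    with pytest.raises(ValueError, match="positive definite"):
        _fit_cov("f =~ x1 + x2 + x3", S, 100)


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
def test_fit_indices_hand_formulas():
    idx = fit_indices(chi2=50.0, df=10, n=100, q=20,
                      chi2_baseline=500.0, df_baseline=45)
    assert idx.cfi == pytest.approx(1 - 40 / 455, abs=1e-12)
    assert idx.mfi == pytest.approx(np.exp(-0.2), abs=1e-12)
    assert idx.ecvi == pytest.approx(0.90, abs=1e-12)


def test_mfi_is_one_iff_chi2_equals_df():
    idx = fit_indices(chi2=10.0, df=10, n=200, q=5,
                      chi2_baseline=100.0, df_baseline=20)
    assert idx.mfi == pytest.approx(1.0)


def test_perfect_fit_srmr_zero_cfi_one():
    S = np.array([[1.0, 0.5], [0.5, 1.0]])
    idx = fit_indices(chi2=0.0, df=1, n=100, q=2, chi2_baseline=50.0,
                      df_baseline=1, S=S, sigma_hat=S)
    assert idx.srmr == 0.0
    assert idx.cfi == 1.0


def test_index_ranges_on_fitted_model(rng):
    n = 800
    f = rng.standard_normal(n)
    X = np.column_stack([l * f + np.sqrt(1 - l * l) * rng.standard_normal(n)
                         for l in (0.8, 0.7, 0.6, 0.5)])
    fit = _fit_cov("f =~ x1 + x2 + x3 + x4", np.cov(X.T), n)
    assert 0 < fit.indices.cfi <= 1
    assert 0 < fit.indices.mfi <= 1.01
    assert fit.indices.ecvi >= 0
    assert fit.indices.srmr >= 0


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------
def test_standardize_scale_algebra():
    """Loading 2.0 with indicator variance 4 and unit factor variance has
    standardized loading 1.0 (zero residual)."""
    spec = ModelSpec("f =~ x1 + x2")
    theta = np.array([2.0, 1.0, 0.0, 1.0])  # loadings, residuals
    fit = engine.FitResult(spec=spec, theta=theta, labels=list(spec.labels),
                           loglik=None, chi2=0, df=0, n=100, q=4,
                           converged=True, n_iter=0, grad_norm=0, fmin=0)
    std, corr = engine.standardize(fit)
    assert std["f=~x1"] == pytest.approx(1.0)
    assert std["f=~x2"] == pytest.approx(1.0 / np.sqrt(2))


def test_standardized_solution_matches_correlation_metric(rng):
    n = 600
    f = rng.standard_normal(n)
    X = 3.0 * np.column_stack(
        [l * f + np.sqrt(1 - l * l) * rng.standard_normal(n)
         for l in (0.8, 0.7, 0.6)])
    S = np.cov(X.T)
    fit = _fit_cov("f =~ x1 + x2 + x3", S, n)
    sigma = implied_covariance(fit.spec, fit.theta)
    d = np.sqrt(np.diag(sigma))
    corr_implied = sigma / np.outer(d, d)
    lam_std = np.array([fit.standardized[f"f=~x{i}"] for i in (1, 2, 3)])
    assert np.allclose(np.outer(lam_std, lam_std) - np.diag(lam_std**2)
                       + np.eye(3), corr_implied, atol=1e-8)


def test_sign_canonicalization(rng):
    """A factor estimated with all-negative loadings is flipped so the
    standardized solution is orientation-deterministic."""
    n = 500
    f = rng.standard_normal(n)
    X = np.column_stack([-0.8 * f + 0.6 * rng.standard_normal(n),
                         -0.7 * f + 0.7 * rng.standard_normal(n),
                         -0.6 * f + 0.8 * rng.standard_normal(n)])
    fit = _fit_cov("f =~ x1 + x2 + x3", np.cov(X.T), n)
    assert fit.standardized["f=~x1"] > 0


# ----------------------------------------------------------------------
# robust statistics
# ----------------------------------------------------------------------
def test_sandwich_needs_two_cases():
    S = np.eye(3) * 1.0 + 0.3 * (np.ones((3, 3)) - np.eye(3))
    fit = _fit_cov("f =~ x1 + x2 + x3", S, 100)
    with pytest.raises(ValueError, match="two cases"):
        sandwich_se(fit, np.zeros((1, 3)))


def test_sandwich_mean_only_model(rng):
    """Robust SE of a mean equals the classic sandwich value
    sqrt(sum (x-xbar)^2)/n."""
    x = rng.standard_normal(60) * 2.0 + 1.0
    spec = ModelSpec("x ~~ x", meanstructure=True)
    fit = engine.fiml_fit(spec, pd.DataFrame({"x": x}),
                          compute_indices=False)
    se = sandwich_se(fit, x[:, None])
    k = fit.labels.index("x~1")
    expected = np.sqrt(np.sum((x - x.mean()) ** 2)) / len(x)
    assert se[k] == pytest.approx(expected, rel=1e-3)


def test_sandwich_matches_naive_under_normality(rng):
    n = 5000
    f = rng.standard_normal(n)
    X = np.column_stack([l * f + np.sqrt(1 - l * l) * rng.standard_normal(n)
                         for l in (0.8, 0.7, 0.6, 0.5)])
    Xdf = pd.DataFrame(X, columns=[f"x{i}" for i in (1, 2, 3, 4)])
    fit = ml_fit(ModelSpec("f =~ x1 + x2 + x3 + x4"), Xdf.cov(), n,
                 data=Xdf, robust=True)
    ratio = fit.se_robust / fit.se
    assert np.all(np.abs(ratio - 1) < 0.10)
    # mean-scaled chi-square factor converges to 1 under normal data
    assert fit.scaling_factor == pytest.approx(1.0, abs=0.15)


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------
def test_compare_identical_models():
    S = np.eye(3) + 0.4 * (np.ones((3, 3)) - np.eye(3))
    f1 = _fit_cov("f =~ x1 + x2 + x3", S, 300)
    f2 = _fit_cov("f =~ x1 + x2 + x3", S, 300)
    table = compare_models({"a": f1, "b": f2})
    assert table.loc[0, "delta_chi2"] == pytest.approx(0.0, abs=1e-6)
    assert table.loc[0, "delta_df"] == 0


def test_compare_saturated_vs_independence():
    S = np.eye(3) + 0.4 * (np.ones((3, 3)) - np.eye(3))
    sat = _fit_cov("f =~ x1 + x2 + x3", S, 300)  # just-identified: chi2=0
    ind = _fit_cov("x1 ~~ x1\nx2 ~~ x2\nx3 ~~ x3", S, 300)
    table = compare_models({"independence": ind, "saturated": sat})
    assert table.loc[0, "model"] == "independence"
    assert table.loc[0, "delta_chi2"] == pytest.approx(ind.chi2, rel=1e-9)


def test_compare_requires_same_n():
    S = np.eye(3) + 0.4 * (np.ones((3, 3)) - np.eye(3))
    f1 = _fit_cov("f =~ x1 + x2 + x3", S, 300)
    f2 = _fit_cov("f =~ x1 + x2 + x3", S, 400)
    with pytest.raises(ValueError, match="different sample sizes"):
        compare_models({"a": f1, "b": f2})
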