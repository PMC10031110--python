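"""Covariance-structure estimation.

Implements the normal-theory machinery behind confirmatory factor analysis
and structural-equation models:

* model-implied covariance ``sigma = lam (I-B)^-1 psi (I-B)^-T lam' + theta``
  and mean vector,
* maximum-likelihood fitting of a sample covariance matrix
  (``F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``),
* full-information maximum likelihood (FIML) over rows with missing cells,
* Huber-White sandwich standard errors from casewise score contributions,
* a mean-scaled ("robust") chi-square correction from the empirical
  fourth-moment matrix,
* the fit indices CFI, MFI, ECVI and SRMR, and side-by-side model
  comparison with nested chi-square difference tests.

All gradients of the ML and FIML discrepancies are analytic, derived from
the differential ``dF = tr(M dSigma) + m' dmu`` and the chain rule through
the model matrices; the optimizer is quasi-Newton (L-BFGS-B) with an
infinite-barrier guard on non-positive-definite ``Sigma`` (the line search
then halves the step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec

__all__ = [
    "FitIndices",
    "FitResult",
    "implied_covariance",
    "ml_fit",
    "fiml_fit",
    "fiml_loglik",
    "em_mvnorm",
    "fit_indices",
    "standardize",
    "sandwich_se",
    "compare_models",
]

_LN2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# implied moments and gradient chain
# ----------------------------------------------------------------------
def _assemble(spec: ModelSpec, theta: np.ndarray):
    lam, bet, psi, tht, nu = spec.matrices(theta)
    m = spec.n_latent
    ib = np.eye(m) - bet
    try:
        g = np.linalg.inv(ib)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
        raise np.linalg.LinAlgError("singular (I - B) matrix") from exc
    phi = g @ psi @ g.T
    sigma = lam @ phi @ lam.T + tht
    sigma = 0.5 * (sigma + sigma.T)
    return lam, g, psi, phi, tht, nu, sigma


def implied_covariance(spec: ModelSpec, theta: np.ndarray):
    """Model-implied covariance matrix (and mean vector if structured)."""
    *_, nu, sigma = _assemble(spec, theta)
    if spec.meanstructure:
        return sigma, nu
    return sigma


def _chain_gradient(spec, theta, M, mvec=None):
    """Gradient of ``tr(M dSigma) + mvec' dmu`` w.r.t. the free parameters.

    ``M`` must be symmetric.  Handles the implicit dependence of the
    delta-parameterized ordinal residual variances on the other parameters.
    """
    lam, g, psi, phi, tht, nu, sigma = _assemble(spec, theta)
    uv = spec.unit_variance_ordinal()
    if uv:
        # theta_ii = 1 - (lam phi lam')_ii on constrained rows, so those
        # diagonal entries of Sigma are constant: drop them from the chain.
        M = M.copy()
        M[uv, uv] = 0.0
    ML = M @ lam @ phi

    grad = np.empty(spec.n_free)
    lamT_M_lam = None
    for k, c in enumerate(spec.free_cells):
        if c.matrix == "lam":
            grad[k] = 2.0 * ML[c.row, c.col]
        elif c.matrix == "bet":
            if lamT_M_lam is None:
                lamT_M_lam = lam.T @ M @ lam
                T = g.T @ lamT_M_lam @ g          # for psi
                X = phi @ lamT_M_lam @ g          # for beta
            grad[k] = 2.0 * X[c.col, c.row]
        elif c.matrix == "psi":
            if lamT_M_lam is None:
                lamT_M_lam = lam.T @ M @ lam
                T = g.T @ lamT_M_lam @ g
                X = phi @ lamT_M_lam @ g
            grad[k] = T[c.row, c.row] if c.row == c.col else 2.0 * T[c.row, c.col]
        elif c.matrix == "tht":
            grad[k] = M[c.row, c.row] if c.row == c.col else 2.0 * M[c.row, c.col]
        else:  # nu
            grad[k] = 0.0 if mvec is None else mvec[c.row]
    return grad


# ----------------------------------------------------------------------
# results containers
# ----------------------------------------------------------------------
@dataclass
class FitIndices:
    cfi: float
    mfi: float
    ecvi: float
    srmr: float

    def as_dict(self) -> dict[str, float]:
        return {"CFI": self.cfi, "MFI": self.mfi, "ECVI": self.ecvi,
                "SRMR": self.srmr}


@dataclass
class FitResult:
    spec: ModelSpec
    theta: np.ndarray
    labels: list[str]
    loglik: float | None
    chi2: float
    df: int
    n: int
    q: int
    converged: bool
    n_iter: int
    grad_norm: float
    fmin: float
    indices: FitIndices | None = None
    se: np.ndarray | None = None
    se_robust: np.ndarray | None = None
    chi2_scaled: float | None = None
    scaling_factor: float | None = None
    heywood: bool = False
    standardized: dict[str, float] | None = None
    latent_corr: pd.DataFrame | None = None
    sample_cov: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.labels, self.theta))

    def pvalue(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2, self.df))

    def parameter_table(self) -> pd.DataFrame:
        rows = {"parameter": self.labels, "estimate": self.theta}
        if self.se is not None:
            rows["se"] = self.se
        if self.se_robust is not None:
            rows["se_robust"] = self.se_robust
        if self.standardized is not None:
            rows["std"] = [self.standardized.get(l, np.nan) for l in self.labels]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "chi2": self.chi2,
            "df": self.df,
            "n": self.n,
            "q": self.q,
            "converged": self.converged,
            "heywood": self.heywood,
        }
        if self.indices is not None:
            out.update(self.indices.as_dict())
        if self.chi2_scaled is not None:
            out["chi2_scaled"] = self.chi2_scaled
            out["scaling_factor"] = self.scaling_factor
        return out


# ----------------------------------------------------------------------
# ML on a sample covariance
# ----------------------------------------------------------------------
def _chol_inv(sigma):
    """(log-determinant, inverse) via Cholesky; raises LinAlgError unless
    positive definite (a sign-of-determinant test would accept indefinite
    matrices with an even number of negative eigenvalues)."""
    L = np.linalg.cholesky(sigma)
    lndet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Linv = np.linalg.inv(L)
    return lndet, Linv.T @ Linv


def _fml(spec, theta, S, lndetS):
    try:
        sigma = _assemble(spec, theta)[-1]
        lndet, sig_inv = _chol_inv(sigma)
    except np.linalg.LinAlgError:
        return np.inf, None
    p = S.shape[0]
    f = lndet + float(np.sum(sig_inv * S)) - lndetS - p
    return f, sig_inv


def ml_fit(
    spec: ModelSpec,
    S: np.ndarray | pd.DataFrame,
    n: int,
    *,
    data: pd.DataFrame | None = None,
    compute_indices: bool = True,
    robust: bool = False,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 2000,
) -> FitResult:
    """Fit the model to a sample covariance matrix by normal-theory ML.

    ``S`` may be a DataFrame whose rows/columns are aligned to
    ``spec.observed`` by name.  ``chi2 = n * F_ML`` at the minimum.  When
    ``data`` (casewise, complete) is given and ``robust=True``, sandwich
    standard errors and the mean-scaled chi-square are attached.
    """
    if isinstance(S, pd.DataFrame):
        S = S.loc[spec.observed, spec.observed].to_numpy(float)
    S = np.asarray(S, float)
    p = spec.n_observed
    if S.shape != (p, p):
        raise ValueError(f"S has shape {S.shape}, expected ({p}, {p})")
    if n <= p:
        raise ValueError("n must exceed the number of observed variables")
    w = np.linalg.eigvalsh(S)
    if w[0] <= 0 or w[-1] / w[0] > 1e12:
        raise ValueError("sample covariance matrix is not positive definite "
                         "(or numerically singular)")
    lndetS = float(np.sum(np.log(w)))

    if start is None:
        start = spec.start_vector(np.diag(S))

    def objective(th):
        f, sig_inv = _fml(spec, th, S, lndetS)
        if not np.isfinite(f):
            # large finite barrier: the line search then backtracks
            return 1e10, np.zeros_like(th)
        M = sig_inv - sig_inv @ S @ sig_inv
        return f, _chain_gradient(spec, th, M)

    res = optimize.minimize(
        objective, start, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12,
                 "maxcor": 30},
    )
    fmin = float(res.fun)
    theta = res.x
    gnorm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
    converged = bool(res.success) or gnorm < 1e-4
    if not converged:
        warnings.warn(f"ML fit did not converge: {res.message}", RuntimeWarning)

    chi2 = max(n * fmin, 0.0)
    q = spec.n_free
    df = p * (p + 1) // 2 + (p if spec.meanstructure else 0) - q
    fit = FitResult(
        spec=spec, theta=theta, labels=list(spec.labels), loglik=None,
        chi2=chi2, df=df, n=n, q=q, converged=converged,
        n_iter=int(res.nit), grad_norm=gnorm, fmin=fmin, sample_cov=S,
    )
    _flag_heywood(fit)
    fit.standardized, fit.latent_corr = standardize(fit)
    fit.se = _naive_se_ml(spec, theta, S, n)
    if compute_indices:
        fit.indices = _indices_from_cov(spec, theta, S, n, chi2, df, q)
    if data is not None and robust:
        X = data[spec.observed].to_numpy(float)
        fit.se_robust = sandwich_se(fit, X)
        fit.chi2_scaled, fit.scaling_factor = scaled_chi2(fit, X)
    return fit


def _naive_se_ml(spec, theta, S, n):
    """Inverse expected-information standard errors for the ML fit."""
    H = _numeric_hessian(lambda th: _fml(spec, th, S, np.linalg.slogdet(S)[1])[0],
                         theta)
    # information of the loglik = (n/2) * Hessian of F_ML
    try:
        cov = np.linalg.inv(0.5 * n * H)
    except np.linalg.LinAlgError:
        return np.full(spec.n_free, np.nan)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def _numeric_hessian(fun, x, eps=1e-5):
    q = len(x)
    H = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * eps * eps)
    return H


def _hessian_from_grad(gradfun, x, eps=1e-6):
    q = len(x)
    H = np.empty((q, q))
    for i in range(q):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        H[:, i] = (gradfun(xp) - gradfun(xm)) / (2 * eps)
    return 0.5 * (H + H.T)


def _flag_heywood(fit: FitResult) -> None:
    lam, bet, psi, tht, nu = fit.spec.matrices(fit.theta)
    if np.any(np.diag(tht) < -1e-8) or np.any(np.diag(psi) < -1e-8):
        fit.heywood = True
        warnings.warn("improper (Heywood) solution: negative variance",
                      RuntimeWarning)


# ----------------------------------------------------------------------
# FIML
# ----------------------------------------------------------------------
def _patterns(X: np.ndarray):
    """Group rows of ``X`` by missingness pattern."""
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        raise ValueError("every row must have at least one observed cell")
    keys = np.packbits(obs, axis=1)
    order = np.lexsort(keys.T[::-1])
    out = []
    start = 0
    sorted_keys = keys[order]
    for i in range(1, len(order) + 1):
        if i == len(order) or not np.array_equal(sorted_keys[i], sorted_keys[start]):
            rows = order[start:i]
            out.append((np.flatnonzero(obs[rows[0]]), rows))
            start = i
    return out


def fiml_loglik(spec: ModelSpec, theta: np.ndarray,
                data: pd.DataFrame | np.ndarray) -> float:
    """Casewise (full-information) Gaussian log-likelihood with missing data.

    Each row contributes the log-density of its observed subvector under the
    row-specific marginal of the model-implied mean and covariance.
    """
    X = _data_matrix(spec, data)
    *_, nu, sigma = _assemble(spec, theta)
    return _fiml_ll_from_moments(X, nu, sigma)


def _data_matrix(spec, data):
    if isinstance(data, pd.DataFrame):
        return data[spec.observed].to_numpy(float)
    X = np.asarray(data, float)
    if X.shape[1] != spec.n_observed:
        raise ValueError("data has wrong number of columns")
    return X


def _fiml_ll_from_moments(X, mu, sigma, patterns=None):
    ll = 0.0
    for o, rows in patterns or _patterns(X):
        sub = sigma[np.ix_(o, o)]
        try:
            lndet, inv = _chol_inv(sub)
        except np.linalg.LinAlgError:
            return -np.inf
        D = X[np.ix_(rows, o)] - mu[o]
        quad = np.einsum("ij,jk,ik->", D, inv, D)
        ll += -0.5 * (len(o) * _LN2PI + lndet) * len(rows) - 0.5 * quad
    return float(ll)


def fiml_fit(
    spec: ModelSpec,
    data: pd.DataFrame | np.ndarray,
    *,
    compute_indices: bool = True,
    start: np.ndarray | None = None,
    gtol: float = 1e-6,
    max_iter: int = 2000,
) -> FitResult:
    """Fit the model to casewise data with missing cells by FIML.

    The mean structure must be part of the model (``meanstructure=True``);
    the chi-square is ``2*(loglik_saturated - loglik_model)`` with the
    saturated moments obtained by an EM algorithm for the unrestricted
    multivariate-normal MLE.
    """
    if not spec.meanstructure:
        raise ValueError("FIML requires a model with meanstructure=True")
    X = _data_matrix(spec, data)
    n, p = X.shape
    pats = _patterns(X)

    col_mean = np.nanmean(X, axis=0)
    col_var = np.nanvar(X, axis=0, ddof=1)
    if start is None:
        start = spec.start_vector(col_var, col_mean)

    def objective(th):
        try:
            lam, g, psi, phi, tht, nu, sigma = _assemble(spec, th)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(th)
        M = np.zeros((p, p))
        mvec = np.zeros(p)
        f = 0.0
        for o, rows in pats:
            sub = sigma[np.ix_(o, o)]
            try:
                lndet, inv = _chol_inv(sub)
            except np.linalg.LinAlgError:
                return 1e10, np.zeros_like(th)
            D = X[np.ix_(rows, o)] - nu[o]
            ng = len(rows)
            A = D.T @ D
            f += ng * (len(o) * _LN2PI + lndet)
            f += float(np.einsum("ij,ij->", inv, A))
            W = ng * inv - inv @ A @ inv
            M[np.ix_(o, o)] += W
            mvec[o] += -2.0 * inv @ D.sum(axis=0)
        grad = _chain_gradient(spec, th, M, mvec)
        return f, grad

    res = optimize.minimize(
        objective, start, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12,
                 "maxcor": 30},
    )
    theta = res.x
    gnorm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
    converged = bool(res.success) or gnorm < 1e-4
    if not converged:
        warnings.warn(f"FIML fit did not converge: {res.message}", RuntimeWarning)

    ll = -0.5 * float(res.fun)
    mu_s, sig_s, _ = em_mvnorm(X)
    ll_sat = _fiml_ll_from_moments(X, mu_s, sig_s, pats)
    chi2 = max(2.0 * (ll_sat - ll), 0.0)
    q = spec.n_free
    df = p * (p + 1) // 2 + p - q
    fit = FitResult(
        spec=spec, theta=theta, labels=list(spec.labels), loglik=ll,
        chi2=chi2, df=df, n=n, q=q, converged=converged,
        n_iter=int(res.nit), grad_norm=gnorm, fmin=float(res.fun),
    )
    _flag_heywood(fit)
    fit.standardized, fit.latent_corr = standardize(fit)
    H = _hessian_from_grad(lambda th: objective(th)[1], theta)
    try:
        cov = np.linalg.inv(0.5 * H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        fit.se = np.sqrt(d)
    except np.linalg.LinAlgError:
        fit.se = np.full(q, np.nan)
    if compute_indices:
        # baseline: independence model, closed-form FIML per variable
        ll_base = _fiml_independence_loglik(X)
        chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
        df_b = p * (p + 1) // 2 - p
        fit.indices = fit_indices(
            chi2, df, n, q, chi2_b, df_b,
            S=sig_s, sigma_hat=_assemble(spec, theta)[-1],
        )
        fit.extra["chi2_baseline"] = chi2_b
        fit.extra["df_baseline"] = df_b
    return fit


def _fiml_independence_loglik(X):
    """Closed-form FIML log-likelihood of the independence model: each
    variable is Gaussian with its own observed-case mean and ML variance."""
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        v = x.var()  # ML variance
        ll += -0.5 * len(x) * (_LN2PI + np.log(v) + 1.0)
    return float(ll)


def em_mvnorm(X: np.ndarray, max_iter: int = 500, tol: float = 1e-8):
    """Unrestricted multivariate-normal MLE (mu, Sigma) under MCAR/MAR
    missingness, by EM on the expected sufficient statistics."""
    X = np.asarray(X, float)
    n, p = X.shape
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), mu, X)
    sigma = np.cov(Xc.T, bias=True) + 1e-6 * np.eye(p)
    pats = _patterns(X)
    ll_old = -np.inf
    for it in range(max_iter):
        S1 = np.zeros(p)
        S2 = np.zeros((p, p))
        for o, rows in pats:
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            Xo = X[np.ix_(rows, o)]
            ng = len(rows)
            if len(m) == 0:
                S1 += Xo.sum(axis=0)
                S2 += Xo.T @ Xo
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            Smm = sigma[np.ix_(m, m)]
            K = np.linalg.solve(Soo, Smo.T).T          # regression coefs
            Em = mu[m] + (Xo - mu[o]) @ K.T            # E[x_m | x_o]
            Vm = Smm - K @ Smo.T                       # conditional cov
            S1[o] += Xo.sum(axis=0)
            S1[m] += Em.sum(axis=0)
            S2[np.ix_(o, o)] += Xo.T @ Xo
            S2[np.ix_(o, m)] += Xo.T @ Em
            S2[np.ix_(m, o)] += Em.T @ Xo
            S2[np.ix_(m, m)] += Em.T @ Em + ng * Vm
        mu = S1 / n
        sigma = S2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        ll = _fiml_ll_from_moments(X, mu, sigma, pats)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, sigma, ll


# ----------------------------------------------------------------------
# fit indices
# ----------------------------------------------------------------------
def fit_indices(
    chi2: float,
    df: int,
    n: int,
    q: int,
    chi2_baseline: float,
    df_baseline: int,
    S: np.ndarray | None = None,
    sigma_hat: np.ndarray | None = None,
) -> FitIndices:
    """CFI, MFI, ECVI and SRMR from chi-square statistics and (for SRMR)
    the sample and implied covariance matrices.

    * ``CFI = 1 - max(chi2-df, 0) / max(chi2_b-df_b, chi2-df, 0)``
    * ``MFI = exp(-(chi2-df) / (2n))``
    * ``ECVI = (chi2 + 2q) / n``
    * ``SRMR``: root mean square of ``(s_ij - sigma_ij)/sqrt(s_ii s_jj)``
      over the unique elements including the diagonal.
    """
    num = max(chi2 - df, 0.0)
    den = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    mfi = float(np.exp(-(chi2 - df) / (2.0 * n)))
    ecvi = (chi2 + 2.0 * q) / n
    srmr = np.nan
    if S is not None and sigma_hat is not None:
        sd = np.sqrt(np.diag(S))
        resid = (S - sigma_hat) / np.outer(sd, sd)
        iu = np.triu_indices_from(resid)
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndices(cfi=cfi, mfi=mfi, ecvi=ecvi, srmr=srmr)


def _indices_from_cov(spec, theta, S, n, chi2, df, q):
    p = S.shape[0]
    # independence baseline: Sigma_B = diag(S), closed form
    f_b = float(np.linalg.slogdet(np.diag(np.diag(S)))[1]
                - np.linalg.slogdet(S)[1])
    chi2_b = n * f_b
    df_b = p * (p + 1) // 2 - p
    sigma_hat = _assemble(spec, theta)[-1]
    return fit_indices(chi2, df, n, q, chi2_b, df_b, S=S, sigma_hat=sigma_hat)


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------
def latent_sign_flips(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Canonical orientation of each latent: +1/-1 so that the sum of its
    standardized loadings (or, for higher-order factors, of its children's
    oriented loadings) is non-negative.  Phantom latents are never flipped."""
    lam, g, psi, phi, tht, nu, sigma = _assemble(spec, theta)
    bet = spec.matrices(theta)[1]
    sd_obs = np.sqrt(np.clip(np.diag(sigma), 1e-300, None))
    sd_lat = np.sqrt(np.clip(np.diag(phi), 1e-300, None))
    lam_s = lam * sd_lat[None, :] / sd_obs[:, None]
    flip = np.ones(spec.n_latent)
    order = sorted(range(spec.n_latent),
                   key=lambda j: 0 if np.any(lam[:, j] != 0) else 1)
    for j in order:
        if spec.latents[j] in spec.phantom:
            continue
        direct = lam_s[:, j].sum()
        if direct == 0.0:
            kids = np.flatnonzero(bet[:, j])
            direct = sum(bet[k, j] * sd_lat[j] / sd_lat[k] * flip[k]
                         for k in kids)
        if direct < 0:
            flip[j] = -1.0
    return flip


def standardize(fit: FitResult):
    """Standardized solution: every latent and observed variable rescaled to
    unit variance; latent covariances become correlations.

    Returns ``(mapping label -> standardized value, latent correlation
    DataFrame)``.  The sign of each latent is made canonical (the sum of its
    standardized loadings is non-negative), so factor orientation is
    deterministic across fits.
    """
    spec = fit.spec
    lam, g, psi, phi, tht, nu, sigma = _assemble(spec, fit.theta)
    sd_obs = np.sqrt(np.clip(np.diag(sigma), 1e-300, None))
    sd_lat = np.sqrt(np.clip(np.diag(phi), 1e-300, None))

    lam_s = lam * sd_lat[None, :] / sd_obs[:, None]
    flip = latent_sign_flips(spec, fit.theta)
    bet = spec.matrices(fit.theta)[1]
    lam_s = lam_s * flip[None, :]
    corr_lat = phi / np.outer(sd_lat, sd_lat)
    corr_lat = corr_lat * np.outer(flip, flip)
    bet_s = bet * (sd_lat[None, :] / sd_lat[:, None]) * np.outer(flip, flip)
    tht_s = tht / np.outer(sd_obs, sd_obs)

    out: dict[str, float] = {}
    for c in spec.cells.values():
        if c.matrix == "lam":
            out[c.label] = float(lam_s[c.row, c.col])
        elif c.matrix == "bet":
            out[c.label] = float(bet_s[c.row, c.col])
        elif c.matrix == "psi":
            out[c.label] = float(corr_lat[c.row, c.col])
        elif c.matrix == "tht":
            out[c.label] = float(tht_s[c.row, c.col])
    latent_corr = pd.DataFrame(corr_lat, index=spec.latents,
                               columns=spec.latents)
    return out, latent_corr


# ----------------------------------------------------------------------
# sandwich standard errors and scaled chi-square
# ----------------------------------------------------------------------
def _casewise_loglik(spec, theta, X):
    *_, nu, sigma = _assemble(spec, theta)
    if not spec.meanstructure:
        nu = X.mean(axis=0)
    try:
        lndet, inv = _chol_inv(sigma)
    except np.linalg.LinAlgError:
        return np.full(X.shape[0], -np.inf)
    D = X - nu
    quad = np.einsum("ij,jk,ik->i", D, inv, D)
    return -0.5 * (X.shape[1] * _LN2PI + lndet + quad)


def sandwich_se(fit: FitResult, X: np.ndarray) -> np.ndarray:
    """Huber-White robust standard errors ``A^-1 B A^-1`` with ``A`` the
    observed information and ``B`` the outer product of casewise scores."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("sandwich estimator needs at least two cases")
    spec, theta = fit.spec, fit.theta
    q = len(theta)
    eps = 1e-5
    scores = np.empty((n, q))
    for k in range(q):
        tp = theta.copy(); tp[k] += eps
        tm = theta.copy(); tm[k] -= eps
        scores[:, k] = (_casewise_loglik(spec, tp, X)
                        - _casewise_loglik(spec, tm, X)) / (2 * eps)
    B = scores.T @ scores

    def total_grad(th):
        # gradient of -loglik via numeric differentiation of casewise sums
        g = np.empty(q)
        for k in range(q):
            tp = th.copy(); tp[k] += eps
            tm = th.copy(); tm[k] -= eps
            g[k] = -(np.sum(_casewise_loglik(spec, tp, X))
                     - np.sum(_casewise_loglik(spec, tm, X))) / (2 * eps)
        return g

    A = _hessian_from_grad(total_grad, theta, eps=1e-4)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular information matrix") from exc
    cov = Ainv @ B @ Ainv
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix: vec(A) = D @ vech(A) for symmetric A, with vech
    in ``np.tril_indices`` (row-major) order to match the rest of the
    module."""
    D = np.zeros((p * p, p * (p + 1) // 2))
    for k, (i, j) in enumerate(zip(*np.tril_indices(p))):
        D[i * p + j, k] = 1.0
        D[j * p + i, k] = 1.0
    return D


def scaled_chi2(fit: FitResult, X: np.ndarray):
    """Mean-scaled ("robust") chi-square.

    The scaling factor is ``c = tr(U Gamma) / df`` with ``Gamma`` the
    empirical asymptotic covariance of vech(S) (fourth moments) and
    ``U = V - V Delta (Delta' V Delta)^-1 Delta' V`` built from the
    normal-theory weight matrix ``V``.  Under multivariate normal data
    ``c -> 1``.  Returns ``(chi2/c, c)``.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    spec, theta = fit.spec, fit.theta
    if fit.df <= 0:
        return fit.chi2, 1.0
    xc = X - X.mean(axis=0)
    iu_rows, iu_cols = np.tril_indices(p)
    W = xc[:, iu_rows] * xc[:, iu_cols]          # casewise vech(d d')
    Wc = W - W.mean(axis=0)
    gamma = (Wc.T @ Wc) / n

    sigma_hat = _assemble(spec, theta)[-1]
    sig_inv = np.linalg.inv(sigma_hat)
    D = _duplication(p)
    V = 0.5 * D.T @ np.kron(sig_inv, sig_inv) @ D

    # Jacobian of vech(sigma) w.r.t. free parameters (central differences)
    q = len(theta)
    delta = np.empty((len(iu_rows), q))
    eps = 1e-6
    for k in range(q):
        tp = theta.copy(); tp[k] += eps
        tm = theta.copy(); tm[k] -= eps
        sp = _assemble(spec, tp)[-1]
        sm = _assemble(spec, tm)[-1]
        delta[:, k] = ((sp - sm) / (2 * eps))[iu_rows, iu_cols]
    VD = V @ delta
    mid = np.linalg.solve(delta.T @ VD, VD.T)
    U = V - VD @ mid
    c = float(np.trace(U @ gamma)) / fit.df
    c = max(c, 1e-12)
    return fit.chi2 / c, c


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------
def compare_models(fits: dict[str, FitResult] | list[FitResult]) -> pd.DataFrame:
    """Side-by-side comparison table with nested chi-square difference tests.

    Fits must be on the same sample size.  Rows are sorted by decreasing df
    (most restrictive first); each row's ``delta_chi2``/``delta_df``/``p``
    compare it with the next less-restrictive model.  The favoured model per
    index is flagged in the ``best_*`` columns of the attributes.
    """
    if isinstance(fits, list):
        fits = {f"model_{i}": f for i, f in enumerate(fits)}
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits are on different sample sizes: {sorted(ns)}")
    rows = []
    for name, f in fits.items():
        row = {
            "model": name, "chi2": f.chi2, "df": f.df,
            "CFI": np.nan, "MFI": np.nan, "ECVI": np.nan, "SRMR": np.nan,
            "converged": f.converged,
        }
        if f.indices is not None:
            row.update(f.indices.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("df", ascending=False,
                                           kind="stable").reset_index(drop=True)
    d_chi2, d_df, pvals = [], [], []
    for i in range(len(table)):
        if i + 1 < len(table):
            dc = table.loc[i, "chi2"] - table.loc[i + 1, "chi2"]
            dd = int(table.loc[i, "df"] - table.loc[i + 1, "df"])
            d_chi2.append(dc)
            d_df.append(dd)
            pvals.append(float(stats.chi2.sf(max(dc, 0.0), dd)) if dd > 0
                         else np.nan)
        else:
            d_chi2.append(np.nan)
            d_df.append(0)
            pvals.append(np.nan)
    table["delta_chi2"] = d_chi2
    table["delta_df"] = d_df
    table["p_delta"] = pvals
    best = {}
    for col, smaller in (("chi2", True), ("SRMR", True), ("ECVI", True),
                         ("CFI", False), ("MFI", False)):
        vals = table[col]
        if vals.notna().any():
            best[col] = table.loc[vals.idxmin() if smaller else vals.idxmax(),
                                  "model"]
    table.attrs["favoured"] = best
    return table
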