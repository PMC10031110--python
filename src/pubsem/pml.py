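"""Pairwise maximum likelihood for ordinal and mixed indicators.

Ordinal questionnaire items are modelled as thresholded standard-normal
latent responses.  The pairwise likelihood sums, over all variable pairs and
all cases observed on both members, the log bivariate-normal probability of
the observed pair:

* ordinal x ordinal  — the rectangle probability implied by the two
  threshold vectors and the model-implied polychoric correlation,
* continuous x continuous — the bivariate normal log-density,
* ordinal x continuous — the normal density of the continuous member times
  the conditional probability of the ordinal member's threshold interval.

Pairs with a missing member are dropped casewise (pairwise-present), which
is how ordinal self-report models accommodate item-level missingness.

The bivariate normal CDF is computed by Genz's Gauss-Legendre quadrature
(the standard BVND algorithm), vectorized over arrays, with absolute
accuracy well below 1e-8.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import FitResult, _assemble, standardize
from .model import ModelSpec

__all__ = ["bvn_cdf", "pml_fit", "pml_objective"]

_SQ2PI = np.sqrt(2.0 * np.pi)

# Gauss-Legendre abscissae/weights (20-point, halved range), per Genz
_GL_X = np.array([
    0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
    0.5108670019508271, 0.3737060887154196, 0.2277858511416451,
    0.07652652113349733,
])
_GL_W = np.array([
    0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
    0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
    0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
    0.1527533871307259,
])


def _phi(x):
    return stats.norm.cdf(x)


def _bvnu_regular(dh, dk, r):
    """P(X > dh, Y > dk) for |r| <= 0.925, vectorized."""
    hk = dh * dk
    hs = (dh * dh + dk * dk) / 2.0
    asr = np.arcsin(r)
    total = np.zeros_like(dh, dtype=float)
    for xi, wi in zip(_GL_X, _GL_W):
        for sgn in (-1.0, 1.0):
            sn = np.sin(asr * (1.0 + sgn * xi) / 2.0)
            total += wi * np.exp((sn * hk - hs) / (1.0 - sn * sn))
    return total * asr / (4.0 * np.pi) + _phi(-dh) * _phi(-dk)


def _bvnu_singular(dh, dk, r):
    """Scalar P(X > dh, Y > dk) for |r| > 0.925 (Genz's expansion)."""
    if r >= 1.0:
        return float(_phi(-max(dh, dk)))
    if r <= -1.0:
        return float(max(0.0, _phi(-dh) - _phi(dk)))
    twopi = 2.0 * np.pi
    h, k = dh, dk
    hk = h * k
    bvn = 0.0
    if r < 0.0:
        k = -k
        hk = -hk
    a_sq = (1.0 - r) * (1.0 + r)
    a = np.sqrt(a_sq)
    bs = (h - k) ** 2
    c = (4.0 - hk) / 8.0
    d = (12.0 - hk) / 16.0
    asr = -(bs / a_sq + hk) / 2.0
    if asr > -100.0:
        bvn = a * np.exp(asr) * (1.0 - c * (bs - a_sq) * (1.0 - d * bs / 5.0) / 3.0
                                 + c * d * a_sq * a_sq / 5.0)
    if -hk < 100.0:
        b = np.sqrt(bs)
        bvn -= np.exp(-hk / 2.0) * _SQ2PI * _phi(-b / a) * b \
            * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
    a /= 2.0
    for xi, wi in zip(_GL_X, _GL_W):
        for sgn in (-1.0, 1.0):
            xs = (a * (1.0 + sgn * xi)) ** 2
            rs = np.sqrt(1.0 - xs)
            asr1 = -(bs / xs + hk) / 2.0
            if asr1 > -100.0:
                sp = 1.0 + c * xs * (1.0 + d * xs)
                ep = np.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                bvn += a * wi * np.exp(asr1) * (ep - sp)
    bvn = -bvn / twopi
    if r > 0.0:
        bvn += _phi(-max(h, k))
    else:
        bvn = -bvn
        if k > h:
            bvn += _phi(k) - _phi(h)
    return float(max(0.0, min(1.0, bvn)))


def bvn_cdf(x, y, rho):
    """P(X <= x, Y <= y) for standard bivariate normal with correlation rho.

    Vectorized over broadcastable arrays; ``±inf`` bounds are handled.
    """
    x, y, rho = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float),
                                    np.asarray(rho, float))
    dh, dk = -x, -y  # upper-tail convention
    out = np.empty(dh.shape, float)
    flat_h, flat_k, flat_r, flat_o = (dh.ravel(), dk.ravel(), rho.ravel(),
                                      out.ravel())
    pos_inf = (flat_h == np.inf) | (flat_k == np.inf)
    flat_o[pos_inf] = 0.0
    h_ninf = (flat_h == -np.inf) & ~pos_inf
    k_ninf = (flat_k == -np.inf) & ~pos_inf
    flat_o[h_ninf] = _phi(-flat_k[h_ninf])
    flat_o[k_ninf] = _phi(-flat_h[k_ninf])
    flat_o[h_ninf & k_ninf] = 1.0
    rest = ~(pos_inf | h_ninf | k_ninf)
    reg = rest & (np.abs(flat_r) <= 0.925)
    if reg.any():
        flat_o[reg] = _bvnu_regular(flat_h[reg], flat_k[reg], flat_r[reg])
    sing = rest & ~reg
    for i in np.flatnonzero(sing):
        flat_o[i] = _bvnu_singular(flat_h[i], flat_k[i], flat_r[i])
    return out.reshape(x.shape) if out.shape else float(out)


# ----------------------------------------------------------------------
# threshold parameterization
# ----------------------------------------------------------------------
def _tau_to_free(tau: np.ndarray) -> np.ndarray:
    """Strictly increasing thresholds -> unconstrained vector."""
    t = np.empty_like(tau)
    t[0] = tau[0]
    if len(tau) > 1:
        t[1:] = np.log(np.diff(tau))
    return t


def _free_to_tau(t: np.ndarray) -> np.ndarray:
    tau = np.empty_like(t)
    tau[0] = t[0]
    if len(t) > 1:
        tau[1:] = t[0] + np.cumsum(np.exp(t[1:]))
    return tau


# ----------------------------------------------------------------------
# data preparation
# ----------------------------------------------------------------------
class _PairData:
    """Precomputed casewise structures for every variable pair."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.ordinal = [v for v in spec.observed if v in spec.ordinal]
        self.continuous = [v for v in spec.observed if v not in spec.ordinal]
        self.codes: dict[str, np.ndarray] = {}
        self.levels: dict[str, np.ndarray] = {}
        for v in self.ordinal:
            k = spec.ordinal[v]
            col = data[v]
            lev = np.sort(col.dropna().unique())
            if len(lev) != k:
                raise ValueError(
                    f"ordinal variable {v!r} has {len(lev)} observed "
                    f"categories but {k} declared; empty categories make "
                    f"thresholds unidentifiable - merge categories first"
                )
            self.levels[v] = lev
            codes = np.full(len(col), -1)
            vals = col.to_numpy()
            for a, l in enumerate(lev):
                codes[vals == l] = a
            self.codes[v] = codes
        self.cont: dict[str, np.ndarray] = {}
        for v in self.continuous:
            x = data[v].to_numpy(float)
            self.cont[v] = x - np.nanmean(x)  # centered; means not modelled

        self.oo: dict[tuple[str, str], np.ndarray] = {}
        self.cc: dict[tuple[str, str], tuple] = {}
        self.oc: dict[tuple[str, str], list] = {}
        for a, b in combinations(spec.observed, 2):
            a_ord, b_ord = a in spec.ordinal, b in spec.ordinal
            if a_ord and b_ord:
                ca, cb = self.codes[a], self.codes[b]
                ok = (ca >= 0) & (cb >= 0)
                tab = np.zeros((spec.ordinal[a], spec.ordinal[b]))
                np.add.at(tab, (ca[ok], cb[ok]), 1.0)
                self.oo[(a, b)] = tab
            elif not a_ord and not b_ord:
                xa, xb = self.cont[a], self.cont[b]
                ok = ~(np.isnan(xa) | np.isnan(xb))
                x, y = xa[ok], xb[ok]
                self.cc[(a, b)] = (len(x), float(x @ x), float(y @ y),
                                   float(x @ y))
            else:
                o, c = (a, b) if a_ord else (b, a)
                co, xc = self.codes[o], self.cont[c]
                ok = (co >= 0) & ~np.isnan(xc)
                groups = [xc[ok & (co == lvl)]
                          for lvl in range(spec.ordinal[o])]
                self.oc[(o, c)] = groups

    def start_thresholds(self) -> dict[str, np.ndarray]:
        out = {}
        for v in self.ordinal:
            codes = self.codes[v]
            codes = codes[codes >= 0]
            k = self.spec.ordinal[v]
            freq = np.bincount(codes, minlength=k) / len(codes)
            cum = np.clip(np.cumsum(freq)[:-1], 1e-4, 1 - 1e-4)
            out[v] = stats.norm.ppf(cum)
        return out


def pml_objective(spec: ModelSpec, theta_model: np.ndarray,
                  thresholds: dict[str, np.ndarray],
                  pairs: _PairData) -> float:
    """Negative pairwise log-likelihood (lower is better)."""
    try:
        *_, tht, nu, sigma = _assemble(spec, theta_model)
    except np.linalg.LinAlgError:
        return np.inf
    diag = np.diag(sigma)
    if np.any(diag <= 0):
        return np.inf
    oi = spec._oi
    neg_ll = 0.0

    def tau_ext(v):
        t = thresholds[v]
        return np.concatenate(([-np.inf], t, [np.inf]))

    for (a, b), tab in pairs.oo.items():
        rho = sigma[oi[a], oi[b]]  # both unit variance under delta rule
        if not (-0.999 < rho < 0.999):
            return np.inf
        ta, tb = tau_ext(a), tau_ext(b)
        grid = bvn_cdf(ta[:, None], tb[None, :], rho)
        p = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
        p = np.clip(p, 1e-300, None)
        neg_ll -= float(np.sum(tab * np.log(p)))

    for (a, b), (n_ab, sxx, syy, sxy) in pairs.cc.items():
        ia, ib = oi[a], oi[b]
        s11, s22, s12 = sigma[ia, ia], sigma[ib, ib], sigma[ia, ib]
        det = s11 * s22 - s12 * s12
        if det <= 0:
            return np.inf
        quad = (s22 * sxx - 2.0 * s12 * sxy + s11 * syy) / det
        neg_ll += 0.5 * (n_ab * (np.log(det) + 2.0 * np.log(2.0 * np.pi))
                         + quad)

    for (o, c), groups in pairs.oc.items():
        io, ic = oi[o], oi[c]
        s_cc = sigma[ic, ic]
        rho = sigma[io, ic] / np.sqrt(s_cc)
        if not (-0.999 < rho < 0.999):
            return np.inf
        t = tau_ext(o)
        cond_sd = np.sqrt(1.0 - rho * rho)
        sd_c = np.sqrt(s_cc)
        for lvl, y in enumerate(groups):
            if len(y) == 0:
                continue
            z = y / sd_c
            lo = (t[lvl] - rho * z) / cond_sd
            hi = (t[lvl + 1] - rho * z) / cond_sd
            pcond = np.clip(stats.norm.cdf(hi) - stats.norm.cdf(lo),
                            1e-300, None)
            dens = stats.norm.logpdf(y, scale=sd_c)
            neg_ll -= float(np.sum(dens + np.log(pcond)))

    return neg_ll


def pml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    gtol: float = 1e-5,
    max_iter: int = 1000,
) -> FitResult:
    """Fit the model by pairwise maximum likelihood.

    Ordinal variables (declared in ``spec.ordinal``) get free, strictly
    increasing thresholds; their latent responses have unit variance (delta
    parameterization).  Returns a :class:`FitResult` whose ``loglik`` is the
    maximized pairwise log-likelihood; chi-square based fit indices are not
    defined for this estimator and are left unset.  Estimated thresholds are
    in ``fit.extra["thresholds"]``.
    """
    if spec.estimator != "pml":
        raise ValueError("spec.estimator must be 'pml'")
    pairs = _PairData(spec, data)
    tau0 = pairs.start_thresholds()
    ord_vars = pairs.ordinal

    var0 = np.array([
        1.0 if v in spec.ordinal else np.nanvar(data[v].to_numpy(float), ddof=1)
        for v in spec.observed
    ])
    theta0 = spec.start_vector(var0)
    # keep ordinal loadings inside the unit-communality region at the start
    for k, c in enumerate(spec.free_cells):
        if c.matrix == "lam" and spec.observed[c.row] in spec.ordinal:
            theta0[k] = min(theta0[k], 0.6)

    slices: dict[str, slice] = {}
    pos = spec.n_free
    packed = [theta0]
    for v in ord_vars:
        t = _tau_to_free(tau0[v])
        slices[v] = slice(pos, pos + len(t))
        pos += len(t)
        packed.append(t)
    x0 = np.concatenate(packed)

    def unpack(x):
        th = x[: spec.n_free]
        taus = {v: _free_to_tau(x[slices[v]]) for v in ord_vars}
        return th, taus

    def objective(x):
        th, taus = unpack(x)
        val = pml_objective(spec, th, taus, pairs)
        return val if np.isfinite(val) else 1e12

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-11,
                 "maxcor": 30},
    )
    theta, taus = unpack(res.x)
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"PML fit did not converge: {res.message}",
                      RuntimeWarning)
    n = len(data)
    fit = FitResult(
        spec=spec, theta=theta, labels=list(spec.labels), loglik=-float(res.fun),
        chi2=np.nan, df=-1, n=n, q=spec.n_free + sum(len(t) for t in taus.values()),
        converged=converged, n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))), fmin=float(res.fun),
    )
    fit.standardized, fit.latent_corr = standardize(fit)
    fit.extra["thresholds"] = taus
    fit.extra["implied_corr"] = implied_pair_correlations(spec, theta)
    return fit


def implied_pair_correlations(spec: ModelSpec, theta: np.ndarray) -> pd.DataFrame:
    """Model-implied correlation matrix over observed variables (polychoric
    scale for ordinal variables under the delta rule)."""
    *_, sigma = _assemble(spec, theta)
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    return pd.DataFrame(corr, index=spec.observed, columns=spec.observed)
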