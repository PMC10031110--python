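"""Synthetic multi-method pubertal cohort generator.

Emulates the statistical structure of a cross-sectional early-adolescent
cohort (girls, ages 10-13) measured with:

* ordinal self-report items — PDS items 1-4 (4-point), the binary menarche
  item PDS6, and two 5-point Tanner line-drawing items (LD1 breast, LD2
  pubic hair),
* four repeated saliva samples per hormone (DHEA, testosterone, estradiol),
  log-normal on the raw scale, with residual correlation among samples
  collected on the same day,
* one hair concentration per hormone with deliberately low loadings,
* regional cortical thickness for the 68 Desikan-Killiany regions.

The truth is a hierarchical factor model: per-hormone first-order saliva
factors and self-report adrenarche/gonadarche factors, loading on
second-order ADR and GON factors that correlate ~0.95 with each other and
0.58/0.70 with age.  Thickness regions correlate with the overall pubertal
dimension (default: -0.3 in posterior cortex, 0 elsewhere) and optionally
with age, so age-mediation scenarios can be simulated.

Each random block (factors, saliva residuals, hair, items, thickness,
outliers, missingness) has its own seed substream derived from the single
global seed, so enabling or resizing one block does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .regions import POSTERIOR_REGIONS, region_columns

__all__ = [
    "GeneratorConfig",
    "SALIVA_COLUMNS",
    "HAIR_COLUMNS",
    "ITEM_COLUMNS",
    "ITEM_CATEGORIES",
    "implied_population_covariance",
    "generate_cohort",
    "inject_missingness",
]

HORMONES = ("dhea", "t", "e2")
SALIVA_COLUMNS = tuple(f"saliva_{h}_{k}" for h in HORMONES for k in (1, 2, 3, 4))
HAIR_COLUMNS = tuple(f"hair_{h}" for h in HORMONES)
ITEM_COLUMNS = ("pds1", "pds2", "pds3", "pds4", "pds6", "ld1", "ld2")
#: category count per ordinal item (PDS 4-point, menarche binary, LD 5-point)
ITEM_CATEGORIES = {"pds1": 4, "pds2": 4, "pds3": 4, "pds4": 4,
                   "pds6": 2, "ld1": 5, "ld2": 5}
#: lowest coded category per item (PDS/LD code from 1; menarche is 0/1)
ITEM_BASE = {"pds1": 1, "pds2": 1, "pds3": 1, "pds4": 1,
             "pds6": 0, "ld1": 1, "ld2": 1}

_FIRST_ORDER_PARENT = {"sDHEA": "ADR", "sT": "ADR", "srADR": "ADR",
                       "sE2": "GON", "srGON": "GON"}
_ITEM_FACTOR = {"pds2": "srADR", "pds3": "srADR", "ld2": "srADR",
                "pds1": "srGON", "pds4": "srGON", "pds6": "srGON",
                "ld1": "srGON"}
_HAIR_FACTOR = {"hair_dhea": "sDHEA", "hair_t": "sT", "hair_e2": "sE2"}

# substream ids; a fixed registry so adding blocks never renumbers old ones
_STREAMS = {"factors": 0, "saliva": 1, "hair": 2, "items": 3,
            "thickness": 4, "outliers": 5, "missing": 6}


def _default_loadings() -> dict[str, float]:
    lo: dict[str, float] = {}
    for k in (1, 2, 3, 4):
        lo[f"saliva_dhea_{k}"] = 0.90
        lo[f"saliva_t_{k}"] = 0.80
        lo[f"saliva_e2_{k}"] = 0.80
    lo.update({"hair_dhea": 0.20, "hair_t": 0.30, "hair_e2": 0.30})
    lo.update({"pds1": 0.55, "pds2": 0.80, "pds3": 0.70, "pds4": 0.85,
               "pds6": 0.75, "ld1": 0.85, "ld2": 0.80})
    return lo


def _default_thresholds() -> dict[str, tuple[float, ...]]:
    four = (-1.0, 0.0, 1.0)
    five = (-1.5, -0.5, 0.5, 1.5)
    return {"pds1": four, "pds2": four, "pds3": four, "pds4": four,
            "pds6": (0.25,), "ld1": five, "ld2": five}


def _default_thickness_effects() -> dict[str, float]:
    eff = {}
    for col in region_columns():
        region = col.split("_", 1)[1].rsplit("_", 1)[0]
        eff[col] = -0.30 if region in POSTERIOR_REGIONS else 0.0
    return eff


def _default_thickness_marginals() -> dict[str, tuple[float, float]]:
    # plausible FreeSurfer group means (mm); a common scale for all regions
    return {col: (2.6, 0.15) for col in region_columns()}


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of the synthetic cohort.

    Loadings, factor correlations and age correlations are on the
    standardized scale; hormone marginals are raw-scale (pre-log) mean/SD
    pairs, converted internally with the log-normal moment map.
    ``outlier_magnitude`` is the shift, in latent (log-scale) SD units,
    added to randomly selected hormone cells.
    """

    n_participants: int = 174
    true_loadings: dict[str, float] = field(default_factory=_default_loadings)
    second_order_loadings: dict[str, float] = field(default_factory=lambda: {
        "sDHEA": 0.85, "sT": 0.80, "srADR": 0.90,
        "sE2": 0.80, "srGON": 0.90,
    })
    factor_correlation: float = 0.95
    age_correlations: dict[str, float] = field(
        default_factory=lambda: {"ADR": 0.58, "GON": 0.70})
    sameday_residual_corr: float = 0.30
    hormone_marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "saliva_dhea": (104.0, 127.0),
            "saliva_t": (40.4, 24.1),
            "saliva_e2": (0.91, 0.55),
            "hair_dhea": (15.24, 14.84),
            "hair_t": (1.81, 2.88),
            "hair_e2": (37.80, 15.82),
        })
    item_thresholds: dict[str, tuple[float, ...]] = field(
        default_factory=_default_thresholds)
    missing_rates: dict[str, float] = field(default_factory=lambda: {
        "selfreport": 0.02, "saliva": 0.05, "hair": 0.10, "thickness": 0.0})
    outlier_rate: float = 0.01
    outlier_magnitude: float = 4.0
    thickness_effects: dict[str, float] = field(
        default_factory=_default_thickness_effects)
    thickness_age_effects: dict[str, float] = field(default_factory=dict)
    thickness_marginals: dict[str, tuple[float, float]] = field(
        default_factory=_default_thickness_marginals)
    age_mean: float = 11.55
    age_sd: float = 0.81
    age_range: tuple[float, float] = (10.0, 13.0)
    seed: int = 20230309

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not -1.0 <= self.factor_correlation <= 1.0:
            raise ValueError("factor_correlation must be in [-1, 1]")
        if not -1.0 <= self.sameday_residual_corr <= 1.0:
            raise ValueError("sameday_residual_corr must be in [-1, 1]")
        for item, tau in self.item_thresholds.items():
            if item not in ITEM_CATEGORIES:
                raise ValueError(f"unknown ordinal item {item!r}")
            if len(tau) != ITEM_CATEGORIES[item] - 1:
                raise ValueError(
                    f"{item!r} needs {ITEM_CATEGORIES[item] - 1} thresholds, "
                    f"got {len(tau)}")
            if np.any(np.diff(tau) <= 0):
                raise ValueError(f"thresholds of {item!r} must be strictly "
                                 "increasing")
        for block, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {block!r} outside [0, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate outside [0, 1]")
        # PSD and communality checks happen in implied structure assembly
        _implied_structure(self)

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed) % (2**31),
                               spawn_key=(_STREAMS[stream],)))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(m, s) of the underlying normal for a log-normal with given raw
    mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("hormone marginals must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


# ----------------------------------------------------------------------
# implied structure
# ----------------------------------------------------------------------
def _implied_structure(config: GeneratorConfig):
    """Assemble path-model matrices over the model-scale variables.

    Returns ``(variables, lam, bet, psi, tht, latents)`` where every
    observed variable has unit model-scale variance (log-hormone z, latent
    response, age z, thickness z).
    """
    latents = ["ADR", "GON", "AGE", "sDHEA", "sT", "sE2", "srADR", "srGON",
               "PUBc"]
    li = {v: i for i, v in enumerate(latents)}
    variables = (["age"] + list(SALIVA_COLUMNS) + list(HAIR_COLUMNS)
                 + list(ITEM_COLUMNS) + region_columns())
    oi = {v: i for i, v in enumerate(variables)}
    m, p = len(latents), len(variables)

    r = config.factor_correlation
    r_a = config.age_correlations.get("ADR", 0.0)
    r_g = config.age_correlations.get("GON", 0.0)
    psi = np.zeros((m, m))
    for f in ("ADR", "GON", "AGE"):
        psi[li[f], li[f]] = 1.0
    psi[li["ADR"], li["GON"]] = psi[li["GON"], li["ADR"]] = r
    psi[li["ADR"], li["AGE"]] = psi[li["AGE"], li["ADR"]] = r_a
    psi[li["GON"], li["AGE"]] = psi[li["AGE"], li["GON"]] = r_g
    top = psi[np.ix_([li["ADR"], li["GON"], li["AGE"]],
                     [li["ADR"], li["GON"], li["AGE"]])]
    w = np.linalg.eigvalsh(top)
    if w[0] < -1e-10:
        raise ValueError(
            f"factor/age correlations are not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3g})")

    bet = np.zeros((m, m))
    for fo, gamma in config.second_order_loadings.items():
        parent = _FIRST_ORDER_PARENT[fo]
        bet[li[fo], li[parent]] = gamma
        resid = 1.0 - gamma**2
        if resid < 0:
            raise ValueError(f"second-order loading of {fo!r} exceeds 1")
        psi[li[fo], li[fo]] = resid
    # overall puberty dimension: normalized sum of ADR and GON
    a = 1.0 / np.sqrt(2.0 * (1.0 + r)) if r > -1.0 else 0.0
    bet[li["PUBc"], li["ADR"]] = a
    bet[li["PUBc"], li["GON"]] = a
    psi[li["PUBc"], li["PUBc"]] = 0.0

    lam = np.zeros((p, m))
    lam[oi["age"], li["AGE"]] = 1.0
    for col in SALIVA_COLUMNS:
        h = col.split("_")[1]
        fac = {"dhea": "sDHEA", "t": "sT", "e2": "sE2"}[h]
        lam[oi[col], li[fac]] = config.true_loadings.get(col, 0.0)
    for col in HAIR_COLUMNS:
        lam[oi[col], li[_HAIR_FACTOR[col]]] = config.true_loadings.get(col, 0.0)
    for col in ITEM_COLUMNS:
        lam[oi[col], li[_ITEM_FACTOR[col]]] = config.true_loadings.get(col, 0.0)
    for col in region_columns():
        lam[oi[col], li["PUBc"]] = config.thickness_effects.get(col, 0.0)
        lam[oi[col], li["AGE"]] = config.thickness_age_effects.get(col, 0.0)

    ib_inv = np.linalg.inv(np.eye(m) - bet)
    phi = ib_inv @ psi @ ib_inv.T
    comm = np.einsum("ij,jk,ik->i", lam, phi, lam)
    tht = np.zeros((p, p))
    bad = np.flatnonzero(comm > 1.0 + 1e-10)
    if bad.size:
        raise ValueError(
            f"communality of {variables[bad[0]]!r} exceeds 1 "
            f"({comm[bad[0]]:.3f}); reduce loadings/effects")
    np.fill_diagonal(tht, np.clip(1.0 - comm, 0.0, None))
    # same-day saliva residual correlations: all hormones' sample k share day k
    r_sd = config.sameday_residual_corr
    for k in (1, 2, 3, 4):
        day = [oi[f"saliva_{h}_{k}"] for h in HORMONES]
        for ii in range(3):
            for jj in range(ii + 1, 3):
                i, j = day[ii], day[jj]
                cv = r_sd * np.sqrt(tht[i, i] * tht[j, j])
                tht[i, j] = tht[j, i] = cv
    return variables, lam, bet, psi, tht, latents


def _model_scale_sds(config: GeneratorConfig, variables: list[str]) -> np.ndarray:
    """SD of each variable on its output scale (log pg/mL for hormones,
    years for age, mm for thickness, 1 for latent responses)."""
    sds = np.ones(len(variables))
    for i, v in enumerate(variables):
        if v == "age":
            sds[i] = config.age_sd
        elif v.startswith("saliva_") or v.startswith("hair_"):
            key = v.rsplit("_", 1)[0] if v.startswith("saliva_") else v
            sds[i] = _lognormal_params(*config.hormone_marginals[key])[1]
        elif v.endswith("_thickness"):
            sds[i] = config.thickness_marginals[v][1]
    return sds


def implied_population_covariance(config: GeneratorConfig) -> pd.DataFrame:
    """Population covariance over all continuous/latent-response variables.

    Assembled by path tracing from the declared loadings, factor
    correlations and residual covariances; hormones appear on the log scale,
    ordinal items as their standard-normal latent responses.  The matrix is
    verified positive semi-definite (a non-PSD configuration raises, naming
    the offending eigenvalue).
    """
    variables, lam, bet, psi, tht, _ = _implied_structure(config)
    ib_inv = np.linalg.inv(np.eye(len(psi)) - bet)
    phi = ib_inv @ psi @ ib_inv.T
    corr = lam @ phi @ lam.T + tht
    w = np.linalg.eigvalsh(corr)
    if w[0] < -1e-8:
        raise ValueError(
            f"implied covariance is not positive semi-definite "
            f"(smallest eigenvalue {w[0]:.3g})")
    sds = _model_scale_sds(config, variables)
    cov = corr * np.outer(sds, sds)
    return pd.DataFrame(cov, index=variables, columns=variables)


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------
def _draw_model_scale(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the unit-variance model-scale scores block by block."""
    variables, lam, bet, psi, tht, latents = _implied_structure(config)
    li = {v: i for i, v in enumerate(latents)}
    n = config.n_participants

    rng_f = _rng(config, "factors")
    top_names = ["ADR", "GON", "AGE"]
    top_cov = psi[np.ix_([li[v] for v in top_names],
                         [li[v] for v in top_names])]
    w, V = np.linalg.eigh(top_cov)
    L_top = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eta = np.zeros((n, len(latents)))
    eta[:, [li[v] for v in top_names]] = rng_f.standard_normal((n, 3)) @ L_top.T
    for fo, gamma in config.second_order_loadings.items():
        parent = _FIRST_ORDER_PARENT[fo]
        zeta = rng_f.standard_normal(n) * np.sqrt(psi[li[fo], li[fo]])
        eta[:, li[fo]] = gamma * eta[:, li[parent]] + zeta
    a = bet[li["PUBc"], li["ADR"]]
    eta[:, li["PUBc"]] = a * (eta[:, li["ADR"]] + eta[:, li["GON"]])

    z = eta @ lam.T  # structural part; residuals added per block
    oi = {v: i for i, v in enumerate(variables)}

    rng_s = _rng(config, "saliva")
    for k in (1, 2, 3, 4):
        idx = [oi[f"saliva_{h}_{k}"] for h in HORMONES]
        block = tht[np.ix_(idx, idx)]
        wb, Vb = np.linalg.eigh(block)
        Lb = Vb @ np.diag(np.sqrt(np.clip(wb, 0.0, None)))
        z[:, idx] += rng_s.standard_normal((n, 3)) @ Lb.T
    rng_h = _rng(config, "hair")
    for col in HAIR_COLUMNS:
        i = oi[col]
        z[:, i] += rng_h.standard_normal(n) * np.sqrt(tht[i, i])
    rng_i = _rng(config, "items")
    for col in ITEM_COLUMNS:
        i = oi[col]
        z[:, i] += rng_i.standard_normal(n) * np.sqrt(tht[i, i])
    rng_t = _rng(config, "thickness")
    for col in region_columns():
        i = oi[col]
        z[:, i] += rng_t.standard_normal(n) * np.sqrt(tht[i, i])
    return pd.DataFrame(z, columns=variables)


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``(CohortTable, ThicknessTable)``.

    Deterministic given ``config.seed``.  Hormone observables are
    exponentiated log-normal draws; ordinal items are produced by
    thresholding their latent responses; outliers and missingness are
    injected per the configuration.
    """
    config = config or GeneratorConfig()
    config.validate()
    n = config.n_participants
    z = _draw_model_scale(config)

    rng_o = _rng(config, "outliers")
    hormone_cols = list(SALIVA_COLUMNS) + list(HAIR_COLUMNS)
    if config.outlier_rate > 0:
        mask = rng_o.random((n, len(hormone_cols))) < config.outlier_rate
        z.loc[:, hormone_cols] = (
            z[hormone_cols].to_numpy()
            + mask * config.outlier_magnitude
        )

    ids = [f"P{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame({"participant_id": ids})
    age = config.age_mean + config.age_sd * z["age"].to_numpy()
    cohort["age"] = np.clip(age, *config.age_range)
    for item in ITEM_COLUMNS:
        tau = np.asarray(config.item_thresholds[item], float)
        cat = np.searchsorted(tau, z[item].to_numpy(), side="left")
        cohort[item] = cat + ITEM_BASE[item]
    for col in SALIVA_COLUMNS:
        key = col.rsplit("_", 1)[0]
        m, s = _lognormal_params(*config.hormone_marginals[key])
        cohort[col] = np.exp(m + s * z[col].to_numpy())
    for k in (1, 2, 3, 4):
        cohort[f"saliva_day_{k}"] = k
    for col in HAIR_COLUMNS:
        m, s = _lognormal_params(*config.hormone_marginals[col])
        cohort[col] = np.exp(m + s * z[col].to_numpy())

    thickness = pd.DataFrame({"participant_id": ids})
    for col in region_columns():
        mu, sd = config.thickness_marginals[col]
        thickness[col] = mu + sd * z[col].to_numpy()

    cohort = inject_missingness(cohort, config.missing_rates,
                                _rng(config, "missing"))
    t_rate = config.missing_rates.get("thickness", 0.0)
    if t_rate > 0:
        thickness = inject_missingness(thickness, {"thickness": t_rate},
                                       _rng(config, "missing"))
    return cohort, thickness


_BLOCK_COLUMNS = {
    "selfreport": list(ITEM_COLUMNS),
    "saliva": list(SALIVA_COLUMNS),
    "hair": list(HAIR_COLUMNS),
    "age": ["age"],
    "thickness": region_columns(),
}


def inject_missingness(
    table: pd.DataFrame,
    rates: dict[str, float],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Blank out cells completely at random, blockwise.

    ``rates`` maps block names (``selfreport``, ``saliva``, ``hair``,
    ``age``, ``thickness``) to per-cell missingness probabilities.
    Deterministic given the seed; returns a copy.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = table.copy()
    for block, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {block!r} outside [0, 1]")
        if rate == 0.0:
            continue
        cols = [c for c in _BLOCK_COLUMNS.get(block, []) if c in out.columns]
        if not cols:
            continue
        mask = rng.random((len(out), len(cols))) < rate
        block_vals = out[cols].to_numpy(float)
        block_vals[mask] = np.nan
        out[cols] = block_vals
    return out
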