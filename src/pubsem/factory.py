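"""Construction of the analysed model variants and series fitting.

The measurement topology, common to all variants that include the relevant
blocks:

* one first-order factor per saliva hormone (``sDHEA``, ``sT``, ``sE2``),
  each measured by its four repeated samples (plus the hair concentration
  when hair is included);
* self-report factors over the ordinal items — adrenarcheal (``srADR``:
  PDS2 body hair, PDS3 skin, LD2 pubic hair) and gonadarcheal (``srGON``:
  PDS1 growth, PDS4 breasts, PDS6 menarche, LD1 breast drawing), or a
  single ``srPUB`` over all seven items in one-factor schemes;
* second-order factors — two-factor scheme: ``ADR`` over {sDHEA, sT, srADR}
  and ``GON`` over {sE2, srGON}, freely correlated; one-factor scheme:
  ``PUB`` over {sDHEA, sT, sE2, srPUB} (a top factor with only a hormone
  factor and a self-report factor as its two indicators would not be
  locally identified).

Optional residual structure: covariances among the three hormones' samples
collected on the same day (sample k of every hormone shares day k; 12
covariances), and correlated-uniqueness covariances among items of the same
questionnaire.  The hair-DHEA loading can be constrained to zero.  Age can
enter as a correlate of the top-level factors or as their exogenous
predictor.

Estimator ladder: pairwise likelihood for ordinal-only (self-report)
models, ML with optional robust standard errors for continuous-only
(hormone) models, FIML for the full multi-method models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .engine import FitResult, compare_models, fiml_fit, ml_fit
from .model import ModelSpec
from .pml import pml_fit
from .synthetic import ITEM_CATEGORIES, ITEM_COLUMNS

__all__ = [
    "ModelVariant",
    "build_model",
    "check_identification",
    "shared_variance",
    "fit_variant",
    "run_model_series",
    "stratified_fit",
]

_SALIVA_FACTORS = {"sDHEA": "dhea", "sT": "t", "sE2": "e2"}
_SR_TWO = {"srADR": ("pds2", "pds3", "ld2"),
           "srGON": ("pds1", "pds4", "pds6", "ld1")}
_SR_ONE = {"srPUB": ITEM_COLUMNS}

_INDICATOR_SETS = ("selfreport_only", "hormones_saliva_hair",
                   "hormones_saliva_only", "full_multimethod")


@dataclass(frozen=True)
class ModelVariant:
    """One analysed model configuration."""

    factor_scheme: str = "two_factor"  # "one_factor" | "two_factor"
    indicator_set: str = "full_multimethod"
    sameday_saliva: bool = True
    correlated_uniqueness: bool = False
    hair_dhea_constrained_zero: bool = False
    age_mode: str = "none"  # "none" | "correlate" | "regress"
    stratum: str = "all"  # "all" | "pds_stage_ge3" | "pds_stage_lt3"

    def name(self) -> str:
        bits = [self.factor_scheme, self.indicator_set]
        if self.sameday_saliva and "selfreport" not in self.indicator_set:
            bits.append("sameday")
        if self.correlated_uniqueness:
            bits.append("cu")
        if self.hair_dhea_constrained_zero:
            bits.append("hairDHEA0")
        if self.age_mode != "none":
            bits.append(f"age_{self.age_mode}")
        if self.stratum != "all":
            bits.append(self.stratum)
        return "+".join(bits)

    def top_factors(self) -> tuple[str, ...]:
        if self.indicator_set == "selfreport_only":
            return (("srPUB",) if self.factor_scheme == "one_factor"
                    else ("srADR", "srGON"))
        if self.indicator_set.startswith("hormones"):
            return (("HORM",) if self.factor_scheme == "one_factor"
                    else ("ADRh", "sE2"))
        return (("PUB",) if self.factor_scheme == "one_factor"
                else ("ADR", "GON"))


def _variant_lines(variant: ModelVariant) -> list[str]:
    if variant.indicator_set not in _INDICATOR_SETS:
        raise ValueError(f"unknown indicator set {variant.indicator_set!r}")
    if variant.factor_scheme not in ("one_factor", "two_factor"):
        raise ValueError(f"unknown factor scheme {variant.factor_scheme!r}")
    lines: list[str] = []
    has_saliva = variant.indicator_set != "selfreport_only"
    has_hair = variant.indicator_set == "hormones_saliva_hair"
    has_sr = variant.indicator_set in ("selfreport_only", "full_multimethod")

    if has_saliva:
        for fac, h in _SALIVA_FACTORS.items():
            terms = [f"saliva_{h}_{k}" for k in (1, 2, 3, 4)]
            if has_hair:
                hair = f"hair_{h}"
                if hair == "hair_dhea" and variant.hair_dhea_constrained_zero:
                    hair = "0*hair_dhea"
                terms.append(hair)
            lines.append(f"{fac} =~ " + " + ".join(terms))
    if has_sr:
        schemes = _SR_ONE if variant.factor_scheme == "one_factor" else _SR_TWO
        for fac, items in schemes.items():
            lines.append(f"{fac} =~ " + " + ".join(items))

    # structural layer
    if variant.indicator_set == "full_multimethod":
        if variant.factor_scheme == "two_factor":
            lines += ["ADR =~ sDHEA + sT + srADR",
                      "GON =~ sE2 + srGON",
                      "ADR ~~ GON"]
        else:
            # a two-indicator top factor (hormone factor + self-report
            # factor) is not locally identified in a single-group covariance
            # model, so the one-factor scheme loads PUB directly on the
            # saliva factors and the self-report factor
            lines += ["PUB =~ sDHEA + sT + sE2 + srPUB"]
    elif variant.indicator_set.startswith("hormones"):
        if variant.factor_scheme == "two_factor":
            # the gonadal side has a single first-order indicator (the E2
            # factor), so it is represented by that factor itself; the one-
            # and two-factor hormone models are then equivalent
            lines += ["ADRh =~ sDHEA + sT", "ADRh ~~ sE2"]
        else:
            lines += ["HORM =~ sDHEA + sT + sE2"]
    else:  # selfreport_only
        if variant.factor_scheme == "two_factor":
            lines.append("srADR ~~ srGON")

    if variant.sameday_saliva and has_saliva:
        for k in (1, 2, 3, 4):
            for ha, hb in combinations(("dhea", "t", "e2"), 2):
                lines.append(f"saliva_{ha}_{k} ~~ saliva_{hb}_{k}")
    if variant.correlated_uniqueness and has_sr:
        # questionnaire-method residual covariances; restricted to pairs
        # that span the two processes — a full within-questionnaire block
        # trades off one-to-one against the factor variances and is not
        # locally identified
        pds = [i for i in ITEM_COLUMNS if i.startswith("pds")]
        adr_items = set(_SR_TWO["srADR"])
        pairs = [(a, b) for a, b in combinations(pds, 2)
                 if (a in adr_items) != (b in adr_items)]
        for a, b in pairs:
            lines.append(f"{a} ~~ {b}")
        lines.append("ld1 ~~ ld2")

    if variant.age_mode == "correlate":
        for f in variant.top_factors():
            lines.append(f"{f} ~~ age")
    elif variant.age_mode == "regress":
        for f in variant.top_factors():
            lines.append(f"{f} ~ age")
    elif variant.age_mode != "none":
        raise ValueError(f"unknown age mode {variant.age_mode!r}")
    return lines


def default_estimator(variant: ModelVariant) -> str:
    if variant.indicator_set == "selfreport_only" \
            and variant.age_mode == "none":
        return "pml"
    if variant.indicator_set.startswith("hormones"):
        return "mlr"
    return "fiml"


def build_model(variant: ModelVariant, *, estimator: str | None = None,
                identification: str = "unit",
                check: bool = True) -> ModelSpec:
    """Build the :class:`ModelSpec` for a model variant.

    Ordinal category counts are attached for the self-report items (used by
    the PML estimator; ML/FIML treat the items as numeric).  The returned
    spec passes a local identification check (Jacobian rank of the implied
    covariance); an under-identified variant raises with a diagnostic.
    """
    est = estimator or default_estimator(variant)
    lines = _variant_lines(variant)
    spec = ModelSpec(
        "\n".join(lines),
        ordinal={i: ITEM_CATEGORIES[i] for i in ITEM_COLUMNS},
        estimator=est,
        identification=identification,
        meanstructure=(est == "fiml"),
    )
    if check:
        check_identification(spec)
    return spec


def check_identification(spec: ModelSpec, seed: int = 7) -> None:
    """Local identification: the Jacobian of vech(Sigma) (plus means when
    structured) with respect to the free parameters must have full column
    rank at jittered start values."""
    rng = np.random.default_rng(seed)
    theta = spec.start_vector() + 0.05 * rng.standard_normal(spec.n_free)
    p = spec.n_observed
    iu = np.tril_indices(p)
    rows = len(iu[0]) + (p if spec.meanstructure else 0)
    jac = np.empty((rows, spec.n_free))
    eps = 1e-6
    for k in range(spec.n_free):
        tp = theta.copy(); tp[k] += eps
        tm = theta.copy(); tm[k] -= eps
        lam_p = spec.matrices(tp)
        lam_m = spec.matrices(tm)

        def moments(mats):
            lam, bet, psi, tht, nu = mats
            g = np.linalg.inv(np.eye(len(bet)) - bet)
            sig = lam @ g @ psi @ g.T @ lam.T + tht
            vech = sig[iu]
            return np.concatenate([vech, nu]) if spec.meanstructure else vech

        jac[:, k] = (moments(lam_p) - moments(lam_m)) / (2 * eps)
    rank = np.linalg.matrix_rank(jac, tol=1e-8)
    if rank < spec.n_free:
        deficient = spec.n_free - rank
        raise ValueError(
            f"model is not locally identified: Jacobian rank {rank} < "
            f"{spec.n_free} free parameters ({deficient} indeterminate); "
            "check factors with too few indicators or redundant covariances")


def shared_variance(r: float) -> int:
    """Shared variance, in percent, of a correlation or standardized path
    product: ``round(100 * r**2)``."""
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"correlation magnitude exceeds 1: {r!r}")
    return int(round(100.0 * r * r))


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def fit_variant(
    cohort: pd.DataFrame,
    variant: ModelVariant,
    *,
    estimator: str | None = None,
    robust: bool = False,
) -> FitResult:
    """Fit one variant to a preprocessed cohort (hormones already cleaned).

    ML uses listwise-complete rows; FIML uses all rows with at least one
    observed cell; PML uses pairwise-present cases.
    """
    est = estimator or default_estimator(variant)
    spec = build_model(variant, estimator=est)
    data = cohort[spec.observed]
    if est == "pml":
        fit = pml_fit(spec, data)
    elif est == "fiml":
        keep = data.notna().any(axis=1)
        fit = fiml_fit(spec, data.loc[keep])
    else:
        complete = data.dropna()
        S = complete.cov()
        fit = ml_fit(spec, S, len(complete),
                     data=complete, robust=(robust or est == "mlr"))
    fit.extra["variant"] = variant
    return fit


def loading_table(fit: FitResult) -> pd.DataFrame:
    """Standardized loadings (measurement and higher-order), one row per
    declared loading, mirroring a path-diagram annotation."""
    rows = []
    for c in fit.spec.cells.values():
        if c.matrix == "lam" and "(phantom)" not in c.label:
            factor = fit.spec.latents[c.col]
            ind = fit.spec.observed[c.row]
        elif c.matrix == "bet" and "=~" in c.label:
            factor = fit.spec.latents[c.col]
            ind = fit.spec.latents[c.row]
        else:
            continue
        rows.append({
            "factor": factor, "indicator": ind,
            "std_loading": fit.standardized.get(c.label, np.nan),
            "fixed": not c.free,
        })
    return pd.DataFrame(rows)


def run_model_series(
    cohort: pd.DataFrame,
    variants: list[ModelVariant],
    *,
    estimator: str | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit a list of variants and tabulate their comparison.

    Returns the comparison table (chi2/df/CFI/MFI/ECVI/SRMR, nested
    delta-chi2 where df are ordered) plus the individual fits keyed by
    variant name.  Fit failures are annotated, not raised.
    """
    fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for v in variants:
        try:
            fits[v.name()] = fit_variant(cohort, v, estimator=estimator)
        except Exception as exc:  # noqa: BLE001 - annotate and continue
            failures[v.name()] = str(exc)
    comparable = {k: f for k, f in fits.items() if np.isfinite(f.chi2)}
    if len(comparable) >= 2 and len({f.n for f in comparable.values()}) == 1:
        table = compare_models(comparable)
    else:
        table = pd.DataFrame([
            {"model": k, "chi2": f.chi2, "df": f.df, "converged": f.converged}
            for k, f in fits.items()])
    table.attrs["failures"] = failures
    return table, fits


def stratified_fit(
    cohort: pd.DataFrame,
    variant: ModelVariant,
    stratifier: pd.Series,
    *,
    estimator: str | None = None,
) -> dict[str, FitResult]:
    """Independent fits per stratum (e.g. PDS stage >= 3 vs < 3).

    Raises when a stratum is empty or smaller than the free-parameter
    count.
    """
    strata = stratifier.dropna().unique()
    if len(strata) == 0:
        raise ValueError("stratifier defines no strata")
    out: dict[str, FitResult] = {}
    for s in sorted(strata, key=str):
        rows = cohort.loc[stratifier == s]
        spec = build_model(variant, estimator=estimator or "ml", check=False)
        if len(rows) == 0 or len(rows) <= spec.n_free:
            raise ValueError(
                f"stratum {s!r} has {len(rows)} rows, too few for "
                f"{spec.n_free} free parameters")
        out[str(s)] = fit_variant(rows, variant, estimator=estimator)
    return out
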