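"""Region-wise SEM associations between latent pubertal factors and
cortical thickness.

Each of the 68 Desikan-Killiany regions enters the measurement model of the
chosen method set (multi-method, self-report only, or saliva hormones only)
as an additional observed variable covarying with the top-level latent
factor(s); the reported ``r`` is the standardized latent-thickness
correlation from that model.

"Controlling for age" is implemented as: age correlates freely with the
latent factors, the region's thickness is regressed on age, and the
reported ``r`` is the correlation between the factor and the
age-residualized thickness.  When the thickness-factor association runs
entirely through age in the generating process, this adjusted ``r``
attenuates toward zero while the unadjusted one does not — the
stage-versus-timing distinction.

Effect sizes are reported without significance testing, by design; the
sweep reports estimates and (approximate) standard errors only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import _assemble, latent_sign_flips, ml_fit
from .factory import ModelVariant, _variant_lines
from .model import ModelSpec
from .regions import parse_region_column, region_columns
from .synthetic import ITEM_CATEGORIES

__all__ = [
    "AssociationResult",
    "fit_region",
    "brain_sweep",
    "classify_effects",
    "DEFAULT_BANDS",
]

#: |r| band edges and labels; a boundary value goes to the upper band.
DEFAULT_BANDS = ((0.1, 0.3, 0.5), ("weak", "small", "medium", "large"))

_METHOD_VARIANTS = {
    "multimethod": "full_multimethod",
    "selfreport": "selfreport_only",
    "hormones": "hormones_saliva_only",
}


@dataclass
class AssociationResult:
    region: str
    hemi: str
    factor: str
    method_set: str
    age_adjusted: bool
    r: float
    se: float
    converged: bool


def _region_spec(method_set: str, factor_scheme: str, region_col: str,
                 age_adjusted: bool) -> tuple[ModelSpec, tuple[str, ...]]:
    if method_set not in _METHOD_VARIANTS:
        raise ValueError(f"unknown method set {method_set!r}")
    variant = ModelVariant(
        factor_scheme=factor_scheme,
        indicator_set=_METHOD_VARIANTS[method_set],
        sameday_saliva=(method_set != "selfreport"),
        age_mode="none",
    )
    lines = _variant_lines(variant)
    factors = variant.top_factors()
    for f in factors:
        lines.append(f"{f} ~~ {region_col}")
    if age_adjusted:
        for f in factors:
            lines.append(f"{f} ~~ age")
        lines.append(f"{region_col} ~ age")
    spec = ModelSpec(
        "\n".join(lines),
        ordinal={i: k for i, k in ITEM_CATEGORIES.items()},
        estimator="ml",
        identification="unit",
    )
    return spec, factors


def _extract_r(spec: ModelSpec, theta: np.ndarray, factor: str,
               region_col: str, age_adjusted: bool) -> float:
    lam, g, psi, phi, tht, nu, sigma = _assemble(spec, theta)
    flips = latent_sign_flips(spec, theta)
    fi = spec._li[factor]
    ti = spec._li[region_col]
    if age_adjusted:
        # correlation of the factor with the age-residualized thickness
        denom = np.sqrt(max(psi[ti, ti], 1e-300) * max(phi[fi, fi], 1e-300))
        r = psi[ti, fi] / denom
    else:
        r = phi[ti, fi] / np.sqrt(max(phi[ti, ti] * phi[fi, fi], 1e-300))
    return float(r * flips[fi] * flips[ti])


def fit_region(
    cohort: pd.DataFrame,
    thickness: pd.DataFrame,
    region_col: str,
    *,
    method_set: str = "multimethod",
    factor_scheme: str = "one_factor",
    age_adjusted: bool = False,
) -> list[AssociationResult]:
    """Fit one region model; returns one result per top-level factor.

    The cohort (preprocessed, hormones on the cleaned log scale) is joined
    to the thickness table on ``participant_id``; listwise-complete rows
    enter the ML fit.  A fit failure is returned as a flagged result rather
    than raised, so a sweep survives individual regions.
    """
    hemi, region = parse_region_column(region_col)
    spec, factors = _region_spec(method_set, factor_scheme, region_col,
                                 age_adjusted)
    merged = cohort.merge(thickness[["participant_id", region_col]],
                          on="participant_id", how="inner")
    data = merged[spec.observed].dropna()
    n = len(data)
    try:
        fit = ml_fit(spec, data.cov(), n, compute_indices=False)
        results = []
        for f in factors:
            r = _extract_r(spec, fit.theta, f, region_col, age_adjusted)
            se = (1.0 - r * r) / np.sqrt(max(n - 3, 1))  # Fisher approx
            results.append(AssociationResult(
                region=region, hemi=hemi, factor=f, method_set=method_set,
                age_adjusted=age_adjusted, r=r, se=se,
                converged=fit.converged))
        return results
    except Exception:  # noqa: BLE001 - flagged, sweep must survive
        return [AssociationResult(region=region, hemi=hemi, factor=f,
                                  method_set=method_set,
                                  age_adjusted=age_adjusted,
                                  r=np.nan, se=np.nan, converged=False)
                for f in factors]


def brain_sweep(
    cohort: pd.DataFrame,
    thickness: pd.DataFrame,
    *,
    method_sets: tuple[str, ...] = ("multimethod",),
    factor_schemes: tuple[str, ...] = ("one_factor",),
    age_options: tuple[bool, ...] = (False,),
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Full cross of region association maps.

    Returns a long-format table with one row per region x factor x
    method set x age option, with effect-band labels attached.  Missing
    region columns raise, enumerated by name.
    """
    cols = regions if regions is not None else region_columns()
    missing = [c for c in cols if c not in thickness.columns]
    if missing:
        raise ValueError(f"thickness table lacks region columns: {missing}")
    rows = []
    for ms in method_sets:
        for fs in factor_schemes:
            for age in age_options:
                for col in cols:
                    for res in fit_region(cohort, thickness, col,
                                          method_set=ms, factor_scheme=fs,
                                          age_adjusted=age):
                        rows.append(vars(res))
    table = pd.DataFrame(rows)
    return classify_effects(table)


def classify_effects(
    table: pd.DataFrame,
    bands: tuple[tuple[float, ...], tuple[str, ...]] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Label each association by |r| band (default: weak < 0.1 <= small
    < 0.3 <= medium < 0.5 <= large; boundary values go up)."""
    edges, labels = bands
    if len(labels) != len(edges) + 1:
        raise ValueError("need one more label than band edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing "
                         "(overlapping bands)")
    out = table.copy()
    idx = np.searchsorted(edges, np.abs(out["r"].to_numpy(float)),
                          side="right")
    lab = np.array(labels, dtype=object)[np.clip(idx, 0, len(labels) - 1)]
    lab[~np.isfinite(out["r"].to_numpy(float))] = None
    out["band"] = lab
    return out


def summarize_map(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Strongest negative and positive associations per
    (factor, method_set, age option) map."""
    rows = []
    for (f, ms, age), grp in table.groupby(
            ["factor", "method_set", "age_adjusted"]):
        g = grp.dropna(subset=["r"]).sort_values("r")
        for kind, sel in (("strongest_negative", g.head(k)),
                          ("strongest_positive", g.tail(k)[::-1])):
            for _, row in sel.iterrows():
                rows.append({"factor": f, "method_set": ms,
                             "age_adjusted": age, "kind": kind,
                             "region": f"{row.hemi}_{row.region}",
                             "r": row.r})
    return pd.DataFrame(rows)
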