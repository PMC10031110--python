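"""Model variants, shared variance, series fitting, stratification."""

import numpy as np
import pandas as pd
import pytest

from pubsem import GeneratorConfig, generate_cohort
from pubsem.engine import ml_fit
from pubsem.factory import (
    ModelVariant,
    build_model,
    check_identification,
    fit_variant,
    run_model_series,
    shared_variance,
    stratified_fit,
)
from pubsem.model import ModelSpec
from pubsem.preprocess import clean_hormones, pds_stage


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------
def test_two_factor_full_model_counts():
    spec = build_model(ModelVariant("two_factor", "full_multimethod"),
                       estimator="ml")
    assert len(spec.observed) == 19  # 12 saliva + 7 self-report items
    assert len(spec.latents) == 7   # 3 saliva + 2 self-report + ADR + GON


def test_sameday_flag_adds_twelve_residual_covariances():
    with_cov = build_model(ModelVariant("two_factor", "hormones_saliva_only",
                                        sameday_saliva=True), estimator="ml")
    without = build_model(ModelVariant("two_factor", "hormones_saliva_only",
                                       sameday_saliva=False), estimator="ml")
    assert with_cov.n_free - without.n_free == 12


def test_correlated_uniqueness_only_differs_in_residuals():
    base = build_model(ModelVariant("two_factor", "selfreport_only",
                                    correlated_uniqueness=False),
                       estimator="ml")
    cu = build_model(ModelVariant("two_factor", "selfreport_only",
                                  correlated_uniqueness=True),
                     estimator="ml")
    extra = set(cu.labels) - set(base.labels)
    assert extra  # added parameters...
    assert all("~~" in lbl for lbl in extra)  # ...are all covariances
    # among items of the same questionnaire only
    assert all(not (lbl.startswith("pds") and "ld" in lbl) for lbl in extra)


def test_hair_dhea_loading_constrained_to_zero():
    spec = build_model(ModelVariant("two_factor", "hormones_saliva_hair",
                                    hair_dhea_constrained_zero=True),
                       estimator="ml")
    cell = next(c for c in spec.cells.values()
                if c.label == "sDHEA=~hair_dhea")
    assert not cell.free and cell.value == 0.0
    assert "sT=~hair_t" in spec.labels  # other hair loadings stay free


def test_age_modes_add_expected_parameters():
    corr = build_model(ModelVariant("two_factor", "full_multimethod",
                                    age_mode="correlate"), estimator="ml")
    regr = build_model(ModelVariant("two_factor", "full_multimethod",
                                    age_mode="regress"), estimator="ml")
    assert {"ADR~~age", "GON~~age"} <= set(corr.labels)
    assert {"ADR~age", "GON~age"} <= set(regr.labels)


def test_underidentified_model_is_diagnosed():
    # a lone two-indicator factor cannot be identified
    spec = ModelSpec("f =~ x1 + x2")
    with pytest.raises(ValueError, match="not locally identified"):
        check_identification(spec)


# ----------------------------------------------------------------------
# shared variance
# ----------------------------------------------------------------------
@pytest.mark.parametrize("r,expected", [
    (0.579, 34), (0.695, 48), (0.977, 95), (0.0, 0), (1.0, 100),
    (-0.5, 25),
])
def test_shared_variance_percentages(r, expected):
    assert shared_variance(r) == expected


def test_shared_variance_rejects_out_of_range():
    with pytest.raises(ValueError, match="exceeds 1"):
        shared_variance(1.2)


# ----------------------------------------------------------------------
# series fitting
# ----------------------------------------------------------------------
def test_sameday_delta_df_bookkeeping(clean_2000):
    _, clean, _ = clean_2000
    table, fits = run_model_series(clean, [
        ModelVariant("one_factor", "hormones_saliva_only",
                     sameday_saliva=False),
        ModelVariant("one_factor", "hormones_saliva_only",
                     sameday_saliva=True),
    ], estimator="ml")
    assert table.loc[0, "delta_df"] == 12


def test_run_model_series_annotates_failures(clean_2000):
    _, clean, _ = clean_2000
    bad = ModelVariant("one_factor", "no_such_set")
    table, fits = run_model_series(clean, [
        ModelVariant("one_factor", "hormones_saliva_only"), bad,
    ], estimator="ml")
    assert bad.name() in table.attrs["failures"]
    assert len(fits) == 1


def test_collapsed_factor_correlation_equivalence():
    """With a true factor correlation of 1 the free-correlation two-factor
    model is indistinguishable from the collapsed (r fixed to 1) model."""
    cfg = GeneratorConfig(n_participants=2000, missing_rates={},
                          outlier_rate=0.0, factor_correlation=1.0,
                          age_correlations={"ADR": 0.6, "GON": 0.6}, seed=41)
    cohort, _ = generate_cohort(cfg)
    clean = clean_hormones(cohort)
    free = build_model(ModelVariant("two_factor", "full_multimethod"),
                       estimator="ml")
    collapsed_text = free.text.replace("ADR ~~ GON", "ADR ~~ 1*GON")
    collapsed = ModelSpec(collapsed_text, estimator="ml")
    data = clean[free.observed].dropna()
    S, n = data.cov(), len(data)
    f_free = ml_fit(free, S, n, compute_indices=False)
    f_coll = ml_fit(collapsed, S, n, compute_indices=False)
    d_chi2 = f_coll.chi2 - f_free.chi2
    assert f_coll.df - f_free.df == 1
    assert d_chi2 < 6.0  # within chi2(1) reference noise


# ----------------------------------------------------------------------
# stratified fits
# ----------------------------------------------------------------------
def test_constant_stratifier_equals_unstratified(clean_2000):
    _, clean, _ = clean_2000
    sub = clean.iloc[:600]
    variant = ModelVariant("one_factor", "hormones_saliva_only")
    strat = pd.Series("all", index=sub.index)
    fits = stratified_fit(sub, variant, strat, estimator="ml")
    ref = fit_variant(sub, variant, estimator="ml")
    assert list(fits) == ["all"]
    assert np.allclose(fits["all"].theta, ref.theta, atol=1e-8)


def test_equal_truth_strata_have_similar_loadings(clean_2000):
    """Tanner-stage strata generated under one truth: loadings agree within
    sampling error."""
    _, clean, _ = clean_2000
    stage = pd.Series(pds_stage(clean), index=clean.index)
    strat = (stage >= 3).map({True: "ge3", False: "lt3"})
    fits = stratified_fit(clean, ModelVariant(
        "one_factor", "hormones_saliva_only"), strat, estimator="ml")
    lo = {k: np.array([f.standardized[f"sDHEA=~saliva_dhea_{j}"]
                       for j in (1, 2, 3, 4)]) for k, f in fits.items()}
    # stratifying on self-report stage restricts the factor's range, so
    # only rough agreement is expected
    assert np.abs(lo["ge3"] - lo["lt3"]).max() < 0.25


def test_empty_stratum_rejected(clean_2000):
    _, clean, _ = clean_2000
    strat = pd.Series(np.nan, index=clean.index)
    with pytest.raises(ValueError, match="no strata"):
        stratified_fit(clean, ModelVariant("one_factor",
                                           "hormones_saliva_only"), strat)


def test_tiny_stratum_rejected(clean_2000):
    _, clean, _ = clean_2000
    strat = pd.Series("big", index=clean.index)
    strat.iloc[:5] = "tiny"
    with pytest.raises(ValueError, match="too few"):
        stratified_fit(clean, ModelVariant("one_factor",
                                           "hormones_saliva_only"), strat)
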