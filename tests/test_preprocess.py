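"""Hormone cleaning, composites, saliva window, MRI QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from pubsem.preprocess import (
    CompositeMap,
    apply_mri_qc,
    clean_hormones,
    log_transform_hormones,
    make_qc_ledger,
    pds_stage,
    score_composites,
    select_saliva_window,
    winsorize_rank_preserving,
)


# ----------------------------------------------------------------------
# log transform
# ----------------------------------------------------------------------
def test_log_transform_values():
    t = pd.DataFrame({"saliva_dhea_1": [1.0, np.e, 104.0]})
    out = log_transform_hormones(t)
    assert out["saliva_dhea_1"].tolist() == pytest.approx(
        [0.0, 1.0, np.log(104.0)])
    assert np.log(104.0) == pytest.approx(4.644, abs=5e-4)


def test_log_transform_preserves_missing():
    t = pd.DataFrame({"hair_t": [2.0, np.nan, 3.0]})
    out = log_transform_hormones(t)
    assert out["hair_t"].isna().tolist() == [False, True, False]


def test_log_transform_names_offending_cell():
    t = pd.DataFrame({"saliva_e2_2": [0.5, -1.0]})
    with pytest.raises(ValueError, match="saliva_e2_2.*row 1"):
        log_transform_hormones(t)


# ----------------------------------------------------------------------
# winsorization
# ----------------------------------------------------------------------
def test_winsorize_hand_computed_example():
    """19 zeros and one 10: mean 0.5, sample SD sqrt(5), cut 7.2082; the
    outlier becomes the cut plus one increment, ~7.218."""
    x = np.array([0.0] * 19 + [10.0])
    out = winsorize_rank_preserving(x)
    cut = 0.5 + 3 * np.sqrt(5.0)
    assert out[-1] == pytest.approx(cut + 0.01, abs=1e-9)
    assert out[-1] == pytest.approx(7.218, abs=5e-4)
    assert np.all(out[:-1] == 0.0)


def test_winsorize_no_outliers_identity(rng):
    x = rng.standard_normal(50)  # ~never beyond 3 SD at n=50 for this seed
    x = np.clip(x, -2.5, 2.5)
    out = winsorize_rank_preserving(x)
    assert np.array_equal(out, x)


def test_winsorize_tied_outliers_get_ordered_increments():
    x = np.array([0.0] * 30 + [50.0, 50.0])
    out = winsorize_rank_preserving(x)
    mean, sd = x.mean(), x.std(ddof=1)
    cut = mean + 3 * sd
    assert out[30] == pytest.approx(cut + 0.01)
    assert out[31] == pytest.approx(cut + 0.02)


def test_winsorize_symmetric_lower_rule():
    x = np.array([0.0] * 30 + [-50.0, -60.0])
    out = winsorize_rank_preserving(x)
    cut = x.mean() - 3 * x.std(ddof=1)
    assert out[30] == pytest.approx(cut - 0.01)  # less extreme: closer to cut
    assert out[31] == pytest.approx(cut - 0.02)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e4, 1e4), min_size=5, max_size=60, unique=True))
def test_winsorize_preserves_rank_order(values):
    x = np.asarray(values)
    out = winsorize_rank_preserving(x)
    assert np.array_equal(rankdata(out), rankdata(x))


def test_winsorize_validation():
    with pytest.raises(ValueError, match="at least 2"):
        winsorize_rank_preserving([1.0])
    with pytest.raises(ValueError, match="increment"):
        winsorize_rank_preserving([1.0, 2.0, 3.0], increment=0.0)


def test_clean_hormones_alters_few_values(cohort_2000):
    """log + winsorize on the log scale touches at most the outlier mass."""
    _, cohort, _ = cohort_2000
    clean = clean_hormones(cohort)
    raw_log = np.log(cohort["saliva_t_1"])
    changed = (~np.isclose(clean["saliva_t_1"], raw_log)).mean()
    assert changed < 0.02


# ----------------------------------------------------------------------
# saliva window
# ----------------------------------------------------------------------
def _samples(dates):
    return pd.DataFrame({"date": dates, "value": np.arange(len(dates), dtype=float)})


def test_window_keeps_last_four_of_seven():
    out = select_saliva_window(_samples([1, 2, 3, 4, 5, 6, 7]), session2_date=10)
    assert out["date"].tolist() == [4, 5, 6, 7]


def test_window_exactly_four_unchanged():
    out = select_saliva_window(_samples([1, 2, 3, 4]), session2_date=10)
    assert out["date"].tolist() == [1, 2, 3, 4]


def test_window_drops_sample_after_session():
    out = select_saliva_window(_samples([1, 2, 3, 4, 12]), session2_date=10)
    assert out["date"].tolist() == [1, 2, 3, 4]


def test_window_pads_short_series_with_missing():
    out = select_saliva_window(_samples([5, 6]), session2_date=10)
    assert len(out) == 4
    assert out["date"].isna().tolist() == [True, True, False, False]


def test_window_requires_dates():
    with pytest.raises(ValueError, match="no collection date"):
        select_saliva_window(_samples([1, np.nan, 3]), session2_date=10)


# ----------------------------------------------------------------------
# composites
# ----------------------------------------------------------------------
def _items(pds1, pds2, pds3, pds4, pds6, ld1, ld2):
    return pd.DataFrame({"pds1": [pds1], "pds2": [pds2], "pds3": [pds3],
                         "pds4": [pds4], "pds6": [pds6], "ld1": [ld1],
                         "ld2": [ld2]}, dtype=float)


def test_composites_floor_and_ceiling():
    lo = score_composites(_items(1, 1, 1, 1, 0, 1, 1))
    assert lo[["adrenarche_composite", "gonadarche_composite",
               "puberty_composite", "pds_stage"]].iloc[0].tolist() == [1, 1, 1, 1]
    hi = score_composites(_items(4, 4, 4, 4, 1, 5, 5))
    assert hi[["adrenarche_composite", "gonadarche_composite",
               "puberty_composite", "pds_stage"]].iloc[0].tolist() == [5, 5, 5, 5]


def test_puberty_composite_is_mean_of_processes():
    out = score_composites(_items(2, 3, 2, 3, 0, 4, 2))
    assert out["puberty_composite"].iloc[0] == pytest.approx(
        (out["adrenarche_composite"].iloc[0]
         + out["gonadarche_composite"].iloc[0]) / 2)


def test_composites_monotone_in_items():
    base = _items(2, 2, 2, 2, 0, 2, 2)
    bumped = _items(2, 3, 2, 2, 0, 2, 2)  # raise one adrenal item
    a0 = score_composites(base)["adrenarche_composite"].iloc[0]
    a1 = score_composites(bumped)["adrenarche_composite"].iloc[0]
    assert a1 > a0


def test_composites_use_available_items_and_error_when_all_missing():
    part = _items(np.nan, 3, np.nan, 2, 0, 3, 4)
    out = score_composites(part)
    assert np.isfinite(out["adrenarche_composite"].iloc[0])
    allmiss = _items(1, np.nan, np.nan, 2, 0, 3, np.nan)
    with pytest.raises(ValueError, match="adrenarche"):
        score_composites(allmiss)


def test_composite_map_is_configurable():
    items = _items(4, 1, 1, 1, 0, 1, 1)
    default = score_composites(items)
    moved = score_composites(items, CompositeMap(
        adrenarche=("pds1", "pds2", "pds3", "ld2"),
        gonadarche=("pds4", "pds6", "ld1")))
    assert moved["adrenarche_composite"].iloc[0] > \
        default["adrenarche_composite"].iloc[0]


def test_pds_stage_category_table():
    items = pd.DataFrame({
        "pds2": [1, 1, 3, 2, 4],
        "pds4": [1, 2, 2, 3, 4],
        "pds6": [0, 0, 0, 1, 1],
    })
    assert pds_stage(items).tolist() == [1, 2, 3, 4, 5]


def test_synthetic_composites_near_study_band(cohort_2000):
    """Default synthetic cohort composites sit in the neighbourhood of the
    study's descriptive table (~2.9 +/- 1.0); checked as a band."""
    _, cohort, _ = cohort_2000
    out = score_composites(cohort[["pds1", "pds2", "pds3", "pds4",
                                   "pds6", "ld1", "ld2"]])
    m = out["puberty_composite"].mean()
    s = out["puberty_composite"].std()
    assert 2.4 <= m <= 3.5
    assert 0.5 <= s <= 1.5


# ----------------------------------------------------------------------
# MRI QC
# ----------------------------------------------------------------------
def test_qc_cascade_reproduces_study_counts():
    ledger = make_qc_ledger()
    keep, tally = apply_mri_qc(ledger)
    assert tally["enrolled"] == 174
    assert tally["opted_out"] == 10
    assert tally["rating_3"] == 25
    assert tally["rating_2_motion"] == 27
    assert tally["retained"] == len(keep) == 112


def test_qc_empty_ledger():
    empty = make_qc_ledger(0, 0, 0, 0, 0)
    keep, tally = apply_mri_qc(empty)
    assert keep == [] and tally["retained"] == 0


def test_qc_all_rating_one_retained():
    ledger = make_qc_ledger(50, 0, 0, 0, 0)
    keep, tally = apply_mri_qc(ledger)
    assert len(keep) == 50


def test_qc_duplicate_ids_rejected():
    ledger = make_qc_ledger(10, 1, 2, 5, 1)
    ledger.loc[1, "participant_id"] = ledger.loc[0, "participant_id"]
    with pytest.raises(ValueError, match="duplicate"):
        apply_mri_qc(ledger)
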