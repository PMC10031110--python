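"""Hormone cleaning, composite scoring, saliva-window selection and MRI QC.

The cleaning pipeline for hormone concentrations is: natural-log transform
(raw concentrations are positively skewed and kurtotic), then winsorization
of values beyond 3 SD from the mean with small rank-preserving increments,
applied on the log scale.

Self-report composites follow the theory-driven assignment of items to
pubertal processes: adrenarche from body-hair and skin items plus the
pubic-hair line drawing; gonadarche from growth, breast and menarche items
plus the breast line drawing.  Four-point PDS items are linearly rescaled to
the 1-5 range before averaging so they are commensurate with the 5-point
line drawings; the binary menarche item maps 0 -> 1, 1 -> 5.

The PDS-stage table approximating Tanner stages is a reconstruction of the
published category scheme (body hair + breast growth sums with menarche
gates) and can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import HAIR_COLUMNS, SALIVA_COLUMNS

__all__ = [
    "log_transform_hormones",
    "winsorize_rank_preserving",
    "clean_hormones",
    "select_saliva_window",
    "CompositeMap",
    "score_composites",
    "pds_stage",
    "make_qc_ledger",
    "apply_mri_qc",
]

HORMONE_COLUMNS = list(SALIVA_COLUMNS) + list(HAIR_COLUMNS)


# ----------------------------------------------------------------------
# hormone cleaning
# ----------------------------------------------------------------------
def log_transform_hormones(table: pd.DataFrame,
                           columns: list[str] | None = None) -> pd.DataFrame:
    """Natural log of every saliva and hair hormone column; missing values
    are preserved.  A non-positive concentration raises, naming the cell."""
    out = table.copy()
    cols = columns if columns is not None else [
        c for c in HORMONE_COLUMNS if c in table.columns]
    for c in cols:
        vals = out[c].to_numpy(float)
        bad = np.flatnonzero(~np.isnan(vals) & (vals <= 0))
        if bad.size:
            raise ValueError(
                f"non-positive concentration in column {c!r}, row {bad[0]} "
                f"(value {vals[bad[0]]!r}); cannot log-transform")
        out[c] = np.log(vals)
    return out


def winsorize_rank_preserving(values, k_sd: float = 3.0,
                              increment: float = 0.01) -> np.ndarray:
    """Replace values beyond ``mean ± k_sd`` sample SD by the cut value plus
    (above) or minus (below) rank-ordered increments, preserving the
    relative order of all values.

    The j-th smallest upper outlier becomes ``cut_high + j*increment``; the
    symmetric rule applies below with subtraction.  Mean and SD are computed
    once, on the non-missing input.  Idempotence note: re-running moves
    nothing new beyond the cuts as long as ``increment`` is small relative
    to the SD, so the operation is stable in practice.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    x = np.asarray(values, float).copy()
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("winsorization needs at least 2 non-missing values")
    mean = x[obs].mean()
    sd = x[obs].std(ddof=1)
    hi_cut = mean + k_sd * sd
    lo_cut = mean - k_sd * sd

    hi = np.flatnonzero(obs & (x > hi_cut))
    if hi.size:
        order = hi[np.argsort(x[hi], kind="stable")]
        x[order] = hi_cut + increment * np.arange(1, len(order) + 1)
    lo = np.flatnonzero(obs & (x < lo_cut))
    if lo.size:
        order = lo[np.argsort(-x[lo], kind="stable")]
        x[order] = lo_cut - increment * np.arange(1, len(order) + 1)
    return x


def clean_hormones(table: pd.DataFrame, *, k_sd: float = 3.0,
                   increment: float = 0.01) -> pd.DataFrame:
    """Log-transform then winsorize every hormone column (on the log scale)."""
    out = log_transform_hormones(table)
    for c in [c for c in HORMONE_COLUMNS if c in out.columns]:
        if out[c].notna().sum() >= 2:
            out[c] = winsorize_rank_preserving(out[c].to_numpy(float),
                                              k_sd=k_sd, increment=increment)
    return out


# ----------------------------------------------------------------------
# saliva window
# ----------------------------------------------------------------------
def select_saliva_window(samples: pd.DataFrame, session2_date) -> pd.DataFrame:
    """Keep the last four samples collected on or before the second session.

    ``samples`` has one row per sample with a ``date`` column (sortable:
    day index or datetime) plus value columns.  Returns exactly 4 rows in
    chronological order; with fewer than four eligible samples the leading
    rows are missing placeholders.  An undated sample raises.
    """
    if "date" not in samples.columns:
        raise ValueError("samples need a 'date' column")
    if samples["date"].isna().any():
        bad = int(samples.index[samples["date"].isna()][0])
        raise ValueError(f"sample at index {bad} has no collection date")
    eligible = samples[samples["date"] <= session2_date]
    eligible = eligible.sort_values("date", kind="stable").tail(4)
    k = len(eligible)
    if k == 4:
        return eligible.reset_index(drop=True)
    pad = pd.DataFrame({c: [np.nan] * (4 - k) for c in samples.columns})
    return pd.concat([pad, eligible], ignore_index=True)


# ----------------------------------------------------------------------
# composites
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CompositeMap:
    """Assignment of items to the adrenarcheal and gonadarcheal composites.

    PDS1 (height growth) sits on the gonadal composite by convention; it is
    the assignment most open to debate and therefore configurable.
    """

    adrenarche: tuple[str, ...] = ("pds2", "pds3", "ld2")
    gonadarche: tuple[str, ...] = ("pds1", "pds4", "pds6", "ld1")


def _rescale_1to5(item: str, values: np.ndarray) -> np.ndarray:
    """Map an item onto the common 1-5 scale: 4-point PDS linearly, binary
    menarche to {1, 5}, 5-point line drawings unchanged."""
    if item == "pds6":
        return 1.0 + 4.0 * values
    if item.startswith("pds"):
        return 1.0 + (values - 1.0) * (4.0 / 3.0)
    return values.astype(float)


def score_composites(items: pd.DataFrame,
                     composite_map: CompositeMap | None = None) -> pd.DataFrame:
    """Adrenarche, gonadarche and overall puberty composites (all 1-5) plus
    the Tanner-approximating PDS stage.

    Each composite is the mean of its rescaled constituent items over the
    non-missing ones; a row with every item of a composite missing raises.
    The overall puberty composite is the mean of the other two.
    """
    cmap = composite_map or CompositeMap()
    out = pd.DataFrame(index=items.index)
    for name, cols in (("adrenarche_composite", cmap.adrenarche),
                       ("gonadarche_composite", cmap.gonadarche)):
        rescaled = np.column_stack([
            _rescale_1to5(c, items[c].to_numpy(float)) for c in cols])
        all_missing = np.isnan(rescaled).all(axis=1)
        if all_missing.any():
            row = int(np.flatnonzero(all_missing)[0])
            raise ValueError(
                f"all items of {name!r} missing for row {items.index[row]!r}")
        with np.errstate(invalid="ignore"):
            out[name] = np.nanmean(rescaled, axis=1)
    out["puberty_composite"] = (out["adrenarche_composite"]
                                + out["gonadarche_composite"]) / 2.0
    out["pds_stage"] = pds_stage(items)
    return out


def pds_stage(items: pd.DataFrame) -> np.ndarray:
    """Tanner-approximating pubertal stage (1-5) from PDS items only.

    Reconstruction of the published category scheme for girls: the sum of
    body hair (PDS2) and breast growth (PDS4), both 1-4, is gated by
    menarche (PDS6):

    ========================  =====
    condition                 stage
    ========================  =====
    sum = 2, no menarche        1
    sum = 3, no menarche        2
    sum > 3, no menarche        3
    sum <= 7, menarche          4
    sum = 8, menarche           5
    ========================  =====

    Rows with any constituent missing get NaN.
    """
    hair = items["pds2"].to_numpy(float)
    breast = items["pds4"].to_numpy(float)
    men = items["pds6"].to_numpy(float)
    tot = hair + breast
    stage = np.full(len(items), np.nan)
    no_men = men == 0
    yes_men = men == 1
    stage[no_men & (tot == 2)] = 1
    stage[no_men & (tot == 3)] = 2
    stage[no_men & (tot > 3)] = 3
    stage[yes_men & (tot <= 7)] = 4
    stage[yes_men & (tot == 8)] = 5
    return stage


# ----------------------------------------------------------------------
# MRI quality control
# ----------------------------------------------------------------------
def make_qc_ledger(
    n_enrolled: int = 174,
    n_opted_out: int = 10,
    n_rating3: int = 25,
    n_rating2: int = 112,
    n_motion_excluded: int = 27,
    participant_ids: list | None = None,
) -> pd.DataFrame:
    """Deterministic QC ledger from exclusion-cascade counts.

    Defaults encode the study-scale cascade: 174 enrolled, 10 opting out of
    the MRI, 25 worst-rated (3) images excluded, and 27 of the 112
    rating-2 images excluded on re-review for motion, leaving 112 analyzed
    participants.
    """
    n_rated = n_enrolled - n_opted_out
    n_rating1 = n_rated - n_rating3 - n_rating2
    if n_rating1 < 0 or n_motion_excluded > n_rating2:
        raise ValueError("inconsistent QC cascade counts")
    ids = (participant_ids if participant_ids is not None
           else [f"P{i + 1:04d}" for i in range(n_enrolled)])
    opted = [True] * n_opted_out + [False] * n_rated
    rating = ([np.nan] * n_opted_out + [1] * n_rating1 + [2] * n_rating2
              + [3] * n_rating3)
    motion = ([False] * (n_opted_out + n_rating1)
              + [True] * n_motion_excluded
              + [False] * (n_rating2 - n_motion_excluded)
              + [False] * n_rating3)
    return pd.DataFrame({
        "participant_id": ids,
        "opted_out": opted,
        "raw_rating": rating,
        "rating2_motion_excluded": motion,
    })


def apply_mri_qc(ledger: pd.DataFrame) -> tuple[list, dict[str, int]]:
    """Apply the MRI quality-control exclusion cascade.

    ``ledger`` needs columns ``participant_id``, ``opted_out`` (bool),
    ``raw_rating`` (1/2/3 or missing) and ``rating2_motion_excluded``
    (bool).  Excludes participants who opted out of the MRI, whose raw T1
    was rated 3 (worst), or whose rating-2 image was re-reviewed and
    excluded for motion.  Returns the retained ids plus an exclusion tally
    by reason.
    """
    ids = ledger["participant_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate participant id {dup!r} in QC ledger")
    opted = ledger["opted_out"].fillna(False).astype(bool)
    rating = ledger["raw_rating"]
    motion = ledger["rating2_motion_excluded"].fillna(False).astype(bool)
    excl_opt = opted
    excl_r3 = ~excl_opt & (rating == 3)
    excl_motion = ~excl_opt & (rating == 2) & motion
    keep = ~(excl_opt | excl_r3 | excl_motion)
    tally = {
        "enrolled": int(len(ledger)),
        "opted_out": int(excl_opt.sum()),
        "rating_3": int(excl_r3.sum()),
        "rating_2_motion": int(excl_motion.sum()),
        "retained": int(keep.sum()),
    }
    return ledger.loc[keep, "participant_id"].tolist(), tally
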