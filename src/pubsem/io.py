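"""Reading and writing cohort, thickness and QC tables.

All tables are plain text: comma-separated with a header row and empty
fields for missing values.  The thickness table is additionally supported
in a FreeSurfer ``aparcstats2table``-like tab-separated dialect, one file
per hemisphere, first column the participant id and then one
``<hemi>_<region>_thickness`` column per region.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .regions import HEMIS, region_columns
from .synthetic import (
    GeneratorConfig,
    HAIR_COLUMNS,
    ITEM_CATEGORIES,
    ITEM_BASE,
    ITEM_COLUMNS,
    SALIVA_COLUMNS,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_thickness",
    "write_thickness",
    "write_thickness_aparc",
    "read_qc_ledger",
    "config_from_yaml",
    "config_to_yaml",
]

MANDATORY_COHORT_COLUMNS = (
    ["participant_id", "age"] + list(ITEM_COLUMNS)
    + list(SALIVA_COLUMNS) + list(HAIR_COLUMNS)
)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; validates schema and value ranges.

    Unknown columns are preserved; empty fields become missing.  Raises on
    absent mandatory columns (listed by name), non-numeric hormone cells,
    non-positive hormone concentrations and out-of-range ordinal codes,
    naming the offending row and column.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks mandatory columns: {missing}")
    for c in list(SALIVA_COLUMNS) + list(HAIR_COLUMNS):
        try:
            vals = pd.to_numeric(df[c], errors="raise").to_numpy(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric hormone cell in column {c!r}") from exc
        bad = np.flatnonzero(~np.isnan(vals) & (vals <= 0))
        if bad.size:
            raise ValueError(
                f"non-positive concentration at row {bad[0]}, column {c!r}")
        df[c] = vals
    for item, k in ITEM_CATEGORIES.items():
        lo = ITEM_BASE[item]
        vals = df[item].to_numpy(float)
        ok = np.isnan(vals) | ((vals >= lo) & (vals <= lo + k - 1))
        if not ok.all():
            row = int(np.flatnonzero(~ok)[0])
            raise ValueError(
                f"ordinal value out of range at row {row}, column {item!r}: "
                f"{vals[row]!r} (expected {lo}..{lo + k - 1})")
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, na_rep="")


def read_thickness(path, dialect: str = "merged") -> pd.DataFrame:
    """Read a thickness table.

    ``dialect="merged"``: one CSV with ``participant_id`` and all 68
    canonical columns.  ``dialect="aparc"``: ``path`` is a pair of
    tab-separated per-hemisphere files (lh, rh) which are merged on the id
    column.  Region count must be 34 per hemisphere; duplicate ids raise.
    """
    if dialect == "merged":
        df = pd.read_csv(path)
        df = df.rename(columns={df.columns[0]: "participant_id"})
    elif dialect == "aparc":
        lh_path, rh_path = path
        parts = []
        for hemi, p in zip(HEMIS, (lh_path, rh_path)):
            t = pd.read_csv(p, sep="\t")
            t = t.rename(columns={t.columns[0]: "participant_id"})
            nreg = len(t.columns) - 1
            if nreg != 34:
                raise ValueError(
                    f"{hemi} file has {nreg} region columns, expected 34")
            bad = [c for c in t.columns[1:] if not c.startswith(f"{hemi}_")]
            if bad:
                raise ValueError(f"unexpected columns in {hemi} file: {bad}")
            parts.append(t)
        df = parts[0].merge(parts[1], on="participant_id", how="outer")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant id {dup!r}")
    missing = [c for c in region_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"missing region columns: {missing}")
    return df[["participant_id"] + region_columns()]


def write_thickness(thickness: pd.DataFrame, path: str | Path) -> None:
    thickness.to_csv(path, index=False, na_rep="")


def write_thickness_aparc(thickness: pd.DataFrame, lh_path, rh_path) -> None:
    """Write per-hemisphere tab-separated files in the aparc-stats dialect."""
    for hemi, p in zip(HEMIS, (lh_path, rh_path)):
        cols = [c for c in region_columns() if c.startswith(f"{hemi}_")]
        out = thickness[["participant_id"] + cols]
        out.to_csv(p, sep="\t", index=False, na_rep="")


def read_qc_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["participant_id", "opted_out", "raw_rating",
              "rating2_motion_excluded"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"QC ledger lacks columns: {missing}")
    return df


# ----------------------------------------------------------------------
# generator configuration files
# ----------------------------------------------------------------------
_TUPLE_FIELDS = {"hormone_marginals", "thickness_marginals", "age_range",
                 "item_thresholds"}


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from YAML; unspecified fields keep
    their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    base = GeneratorConfig()
    for key, val in raw.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown generator config field {key!r}")
        if key in _TUPLE_FIELDS and isinstance(val, dict):
            val = {k: tuple(v) for k, v in val.items()}
        elif key == "age_range":
            val = tuple(val)
        kw[key] = val
    return base.replace(**kw)


def config_to_yaml(config: GeneratorConfig, path: str | Path) -> None:
    raw = {}
    for key, val in vars(config).items():
        if isinstance(val, dict):
            raw[key] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in val.items()}
        elif isinstance(val, tuple):
            raw[key] = list(val)
        else:
            raw[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
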