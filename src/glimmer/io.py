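"""Cohort table I/O and schema validation.

The cohort CSV schema is one row per patient::

    patient_id,ohi,twi,nir,sto2,mgmt_mean_pct,mgmt_status,idh_status,
    who_grade,tert_status,codel_1p19q

Missing molecular fields are written as ``NA``.  When ``mgmt_status`` is
absent it is derived from ``mgmt_mean_pct`` via the 8% dichotomization rule.
Unknown extra columns are preserved on read but ignored by the analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError
from .score import METHYLATED, UNMETHYLATED, ScoreDefinition, dichotomize_mgmt
from .simulate import COHORT_COLUMNS

__all__ = ["read_cohort", "write_cohort", "validate_cohort"]

REQUIRED_NUMERIC = ["ohi", "twi", "nir", "sto2"]
OPTIONAL_MOLECULAR = ["idh_status", "who_grade", "tert_status", "codel_1p19q"]


def validate_cohort(
    df: pd.DataFrame, defn: ScoreDefinition = ScoreDefinition()
) -> pd.DataFrame:
    """Validate (and lightly normalize) a cohort table.

    Checks: required columns present, at least one row, numeric indices in
    [0, 1], methylation percentage in [0, 100], unique patient ids.  Derives
    ``mgmt_status`` from the percentage when the column is absent, and fills
    absent molecular columns with ``unknown``.  Returns a copy.
    """
    df = df.copy()
    if len(df) == 0:
        raise SchemaError("cohort table contains no rows")
    missing = [c for c in ["patient_id", *REQUIRED_NUMERIC, "mgmt_mean_pct"] if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort is missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id values: {dupes}")
    for col in REQUIRED_NUMERIC:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()].tolist()
        if bad:
            raise SchemaError(f"non-numeric {col} value in rows {bad}")
        out_of_range = df.index[(values < 0) | (values > 1)].tolist()
        if out_of_range:
            raise SchemaError(
                f"{col} outside [0, 1] in rows {out_of_range} "
                f"(patient_id {df.loc[out_of_range, 'patient_id'].tolist()})"
            )
        df[col] = values.astype(float)
    pct = pd.to_numeric(df["mgmt_mean_pct"], errors="coerce")
    bad = df.index[pct.isna() | (pct < 0) | (pct > 100)].tolist()
    if bad:
        raise SchemaError(f"mgmt_mean_pct missing or outside [0, 100] in rows {bad}")
    df["mgmt_mean_pct"] = pct.astype(float)
    if "mgmt_status" not in df.columns or df["mgmt_status"].isna().all():
        df["mgmt_status"] = [dichotomize_mgmt(v, defn) for v in df["mgmt_mean_pct"]]
    else:
        bad_status = set(df["mgmt_status"]) - {METHYLATED, UNMETHYLATED}
        if bad_status:
            raise SchemaError(f"unrecognized mgmt_status values: {sorted(bad_status)}")
    for col in OPTIONAL_MOLECULAR:
        if col not in df.columns:
            df[col] = "unknown"
        else:
            df[col] = df[col].fillna("unknown")
    return df


def read_cohort(path, defn: ScoreDefinition = ScoreDefinition()) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    try:
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"cohort file {path} is empty") from exc
    return validate_cohort(df, defn)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the documented schema, missing fields as NA."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False, na_rep="NA")
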