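"""Cohort schema, readers/writers and report serialisation.

The interchange format is a flat CSV/TSV (UTF-8, ``.`` decimal, header
row) with one patient per row: raw margin biomarkers, clinical covariates
from controlled vocabularies, and the two endpoints as (time in months,
event flag) pairs.  Derived scoring columns are optional on input and
appended by the scorer.  Floats are written at full precision; rounding is
applied only in human-readable report tables.
"""

from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

logger = logging.getLogger("mrix")

SCHEMA_VERSION = "1.0"

BIOMARKER_COLUMNS = (
    "tls_density",
    "panck_foci",
    "ki67_pct",
    "n_driver_mutations",
    "pdl1_fold",
    "cd8_foxp3_ratio",
    "gzmb_density",
    "margin_mm",
)

CLINICAL_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "age_group": ("<=55", ">55"),
    "sex": ("male", "female"),
    "primary_site": ("oral_oropharynx", "larynx_hypopharynx"),
    "cps": ("<1", ">=1"),
    "differentiation": ("well", "moderate", "poor"),
    "stage": ("III", "IV"),
    "radiologic_response": ("CR", "PR", "SD"),
    "pathologic_response": ("pCR", "mPR_not_pCR", "no_mPR"),
    "pni": ("no", "yes"),
    "lvi": ("no", "yes"),
    "ene": ("no", "yes"),
    "margin_class": ("close", "clear"),
}

CLINICAL_COLUMNS = tuple(CLINICAL_VOCABULARIES)

OUTCOME_COLUMNS = ("lrc_time_months", "lrc_event", "dmfs_time_months", "dmfs_event")

MANDATORY_COLUMNS = ("patient_id",) + BIOMARKER_COLUMNS + CLINICAL_COLUMNS + OUTCOME_COLUMNS

DERIVED_COLUMNS = (
    "histopathology_score",
    "tumor_burden_score",
    "molecular_score",
    "immune_score",
    "mrix_score",
    "mrix_category",
    "override_applied",
)

COLUMN_ORDER = MANDATORY_COLUMNS + DERIVED_COLUMNS


def percent_half_up(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded half-up, matching printed table formatting."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(10) ** -decimals
    ratio = Decimal(repr(float(count))) / Decimal(repr(float(total)))
    return float((ratio * 100).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def validate_cohort(df: pd.DataFrame, require_outcomes: bool = True) -> None:
    """Validate a cohort table against the schema.

    Raises :class:`SchemaError` naming the first missing mandatory column;
    vocabulary and range violations report the offending row index.
    """
    mandatory = list(MANDATORY_COLUMNS)
    if not require_outcomes:
        mandatory = [c for c in mandatory if c not in OUTCOME_COLUMNS]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col, vocab in CLINICAL_VOCABULARIES.items():
        bad = ~df[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"column {col!r} row {row}: value {df[col].iloc[row]!r} not in {vocab}"
            )
    if require_outcomes:
        for ep in ("lrc", "dmfs"):
            ev = df[f"{ep}_event"]
            if not ev.isin((0, 1)).all():
                row = int(np.flatnonzero(~ev.isin((0, 1)).to_numpy())[0])
                raise SchemaError(f"column '{ep}_event' row {row}: events must be 0 or 1")
            tm = df[f"{ep}_time_months"]
            if not (tm > 0).all():
                row = int(np.flatnonzero(~(tm > 0).to_numpy())[0])
                raise SchemaError(f"column '{ep}_time_months' row {row}: times must be > 0")
    unknown = [c for c in df.columns if c not in COLUMN_ORDER]
    if unknown:
        logger.warning("unknown columns preserved but ignored: %s", ", ".join(unknown))


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(path, require_outcomes: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV/TSV."""
    df = pd.read_csv(path, sep=_sep_for(path))
    validate_cohort(df, require_outcomes=require_outcomes)
    logger.info("read cohort %s: %d rows, %d columns (schema %s)",
                path, len(df), df.shape[1], SCHEMA_VERSION)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table with deterministic column order, full precision."""
    ordered = [c for c in COLUMN_ORDER if c in df.columns]
    extras = [c for c in df.columns if c not in ordered]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[ordered + extras].to_csv(path, sep=_sep_for(path), index=False)
    logger.info("wrote cohort %s: %d rows", path, len(df))


def write_report(report, outdir) -> dict:
    """Serialise a study report to CSV tables plus a JSON summary.

    Returns the manifest (section -> file name); empty sections are
    omitted from disk and noted in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str | None] = {}

    def emit_csv(name: str, df) -> None:
        if df is None or (hasattr(df, "empty") and df.empty):
            manifest[name] = None
            return
        fname = f"{name}.csv"
        df.to_csv(outdir / fname, index=df.index.name is not None or df.index.dtype == object)
        manifest[name] = fname

    emit_csv("baseline_table", getattr(report, "baseline_table", None))
    emit_csv("domain_analysis", getattr(report, "domain_km", None))
    table3 = getattr(report, "table3_analog", None) or {}
    for ep, fit in table3.items():
        emit_csv(f"adjusted_model_{ep}", fit.summary())
    table4 = getattr(report, "table4_analog", None) or {}
    for ep, cmpres in table4.items():
        emit_csv(f"model_comparison_{ep}", cmpres.to_frame())
    summary = getattr(report, "summary_dict", None)
    if callable(summary):
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary(), fh, indent=2, sort_keys=True)
        manifest["summary"] = "summary.json"
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
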