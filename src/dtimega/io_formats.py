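"""Reading, validating and writing the pipeline's tabular formats.

Two canonical CSV schemas:

* participants.csv — one row per subject with site, diagnosis, subgroup,
  sex, age and clinical covariates;
* roi_measures.csv — long format with columns
  ``subject_id, metric, roi, value``.

Missing values are written as empty cells; ``""``, ``"NA"`` and
``"NaN"`` are accepted on read.  A wide-format ROI reader (one column
per ROI) is provided for convenience and converted to long on ingest.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rois import METRICS, ROI_VOCABULARY

NA_TOKENS = ["", "NA", "NaN"]

PARTICIPANT_COLUMNS = [
    "subject_id", "site_id", "diagnosis", "subgroup", "sex", "age", "handedness",
    "panss_neg", "panss_pos", "age_onset", "duration", "cpz",
    "ap_user", "lithium_user", "ad_user", "ae_user",
]
MEASURE_COLUMNS = ["subject_id", "metric", "roi", "value"]

DIAGNOSES = ("CTR", "EOP")
SUBGROUP_LEVELS = ("CTR", "EOS", "AFP", "OTP")
SEX_LEVELS = ("F", "M")
HANDEDNESS_LEVELS = ("R", "L", "A")

# enough digits for exact float64 round-trips
FLOAT_FORMAT = "%.17g"


class SchemaError(ValueError):
    """A table violates its schema; message names the rule and rows."""


@dataclass
class SchemaReport:
    table: str
    n_rows: int
    failed_rules: list[tuple[str, list[int]]] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.failed_rules


def _check(report: SchemaReport, rule: str, bad_mask: pd.Series) -> None:
    if bad_mask.any():
        report.failed_rules.append((rule, bad_mask[bad_mask].index.tolist()))


def validate_participants(df: pd.DataFrame) -> SchemaReport:
    report = SchemaReport("participants", len(df))
    _check(report, "duplicate subject_id", df["subject_id"].duplicated(keep=False))
    _check(report, "unknown diagnosis level", ~df["diagnosis"].isin(DIAGNOSES))
    _check(report, "unknown subgroup level", ~df["subgroup"].isin(SUBGROUP_LEVELS))
    _check(
        report,
        "subgroup must be CTR exactly when diagnosis is CTR",
        (df["subgroup"] == "CTR") != (df["diagnosis"] == "CTR"),
    )
    _check(
        report, "unknown sex level", ~df["sex"].isin(SEX_LEVELS) & df["sex"].notna()
    )
    hand = df["handedness"]
    _check(
        report, "unknown handedness level",
        hand.notna() & ~hand.isin(HANDEDNESS_LEVELS),
    )
    both = df["age_onset"].notna() & df["duration"].notna()
    _check(
        report,
        "age_onset + duration exceeds age + 0.5",
        both & (df["age_onset"] + df["duration"] > df["age"] + 0.5),
    )
    clin = ["panss_neg", "panss_pos", "age_onset", "duration", "cpz",
            "ap_user", "lithium_user", "ad_user", "ae_user"]
    ctr = df["diagnosis"] == "CTR"
    _check(
        report,
        "clinical fields must be missing for controls",
        ctr & df[clin].notna().any(axis=1),
    )
    return report


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read and validate a participant CSV; raise SchemaError on violations."""
    df = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"participants: missing required columns {missing}")
    extra = [c for c in df.columns if c not in PARTICIPANT_COLUMNS]
    if extra:
        warnings.warn(f"participants: ignoring unknown columns {extra}", stacklevel=2)
        df = df.drop(columns=extra)
    df = df[PARTICIPANT_COLUMNS].copy()
    for c in ("subject_id", "site_id", "diagnosis", "subgroup", "sex", "handedness"):
        df[c] = df[c].astype("string").str.strip()
        df[c] = df[c].where(df[c] != "", other=pd.NA)
    for c in df.columns:
        if c not in ("subject_id", "site_id", "diagnosis", "subgroup", "sex", "handedness"):
            df[c] = pd.to_numeric(df[c], errors="raise")
    report = validate_participants(df)
    if not report.valid:
        lines = "; ".join(f"{rule} (rows {rows[:5]})" for rule, rows in report.failed_rules)
        raise SchemaError(f"participants: {lines}")
    return df


def validate_roi_measures(df: pd.DataFrame) -> SchemaReport:
    report = SchemaReport("roi_measures", len(df))
    unknown = ~df["roi"].isin(ROI_VOCABULARY)
    if unknown.any():
        bad = sorted(df.loc[unknown, "roi"].unique())
        hints = {
            b: (difflib.get_close_matches(str(b), ROI_VOCABULARY, n=1) or ["?"])[0]
            for b in bad
        }
        report.failed_rules.append(
            (f"unknown ROI labels {bad} (nearest valid: {hints})",
             df.index[unknown].tolist())
        )
    _check(report, "unknown metric", ~df["metric"].isin(METRICS))
    fa = df["metric"] == "FA"
    _check(report, "FA outside (0,1)", fa & ~df["value"].between(0, 1, inclusive="neither"))
    _check(report, "non-positive diffusivity", ~fa & (df["value"] <= 0))
    _check(report, "duplicated (subject, metric, roi)",
           df.duplicated(subset=["subject_id", "metric", "roi"], keep=False))
    return report


def read_roi_measures(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format ROI-measure CSV."""
    df = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False,
                     float_precision="round_trip")
    missing = [c for c in MEASURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"roi_measures: missing required columns {missing}")
    extra = [c for c in df.columns if c not in MEASURE_COLUMNS]
    if extra:
        warnings.warn(f"roi_measures: ignoring unknown columns {extra}", stacklevel=2)
    df = df[MEASURE_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype("string").str.strip()
    df["metric"] = df["metric"].astype("string").str.strip()
    df["roi"] = df["roi"].astype("string").str.strip()
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    report = validate_roi_measures(df)
    if not report.valid:
        lines = "; ".join(f"{rule} (rows {rows[:5]})" for rule, rows in report.failed_rules)
        raise SchemaError(f"roi_measures: {lines}")
    return df


def read_roi_measures_wide(path: str | Path, metric: str) -> pd.DataFrame:
    """Read a wide ROI table (subject_id + one column per ROI) as long format."""
    if metric not in METRICS:
        raise SchemaError(f"unknown metric {metric!r}")
    df = pd.read_csv(path, na_values=NA_TOKENS, keep_default_na=False,
                     float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError("wide roi table: missing subject_id column")
    long = df.melt(id_vars="subject_id", var_name="roi", value_name="value")
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    long.insert(1, "metric", metric)
    long["value"] = pd.to_numeric(long["value"], errors="raise")
    report = validate_roi_measures(long)
    if not report.valid:
        lines = "; ".join(rule for rule, _ in report.failed_rules)
        raise SchemaError(f"wide roi table: {lines}")
    return long


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def write_roi_measures(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  extra_manifest: dict | None = None) -> dict:
    """Write one CSV per named result table plus a checksum manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    Column order is preserved as given, so reruns on identical inputs
    produce identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")
        entries.append(
            {"name": name, "file": path.name, "rows": int(len(table)),
             "sha256": _sha256(path)}
        )
    manifest = {"tables": entries}
    if extra_manifest:
        manifest.update(extra_manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
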