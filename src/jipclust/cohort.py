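"""Patient cohort data model: CSV I/O, validation, complete-case filtering,
joint counts and 3-component disease activity scores.

A :class:`Cohort` wraps a pandas DataFrame with one row per patient. Baseline
columns are ``patient_id, age, sex, rf, acpa, hb, ht, leuko, thrombo, esr``
plus 88 binary joint-flag columns (``tender_<SIDE>_<SITE>`` and
``swollen_<SIDE>_<SITE>`` over the 44-joint atlas). Optional longitudinal
columns carry treatment, follow-up, serial DAS values and synovial Krenn
grades.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import JointAtlas, default_atlas

#: DAS44 remission cut-off (strict inequality: DAS44 < 1.6 is remission).
REMISSION_DAS44 = 1.6

MANDATORY_NUMERIC = ["age", "hb", "ht", "leuko", "thrombo", "esr"]
MANDATORY_BINARY = ["rf", "acpa"]
OPTIONAL_COLUMNS = [
    "physician_id", "symptom_duration", "drug", "switch_day",
    "followup_days", "event_mtx_failure",
    "krenn_lining", "krenn_stromal", "krenn_infiltrate",
    "true_label", "cluster_label",
]


class CohortSchemaError(ValueError):
    """A mandatory column is missing from a cohort table."""


class CohortValidationError(ValueError):
    """Row-level contents violate the cohort invariants."""


def joint_flag_columns(atlas: JointAtlas) -> list[str]:
    cols = [f"tender_{jid}" for jid in atlas.joint_ids]
    cols += [f"swollen_{jid}" for jid in atlas.joint_ids]
    return cols


def mandatory_columns(atlas: JointAtlas) -> list[str]:
    return (["patient_id", "age", "sex", "rf", "acpa",
             "hb", "ht", "leuko", "thrombo", "esr"]
            + joint_flag_columns(atlas))


@dataclass
class Cohort:
    """An ordered patient table sharing one joint atlas."""

    df: pd.DataFrame
    atlas: JointAtlas = field(default_factory=default_atlas)
    provenance: str = ""

    def __post_init__(self):
        ids = self.df["patient_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique().tolist())
            raise CohortValidationError(f"duplicate patient_id values: {dupes}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list:
        return self.df["patient_id"].tolist()

    def subset(self, mask) -> "Cohort":
        return Cohort(self.df.loc[mask].reset_index(drop=True), self.atlas,
                      self.provenance)


def _coerce_binary(value):
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if value in (0, 1):
        return int(value)
    if isinstance(value, float) and value in (0.0, 1.0):
        return int(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes"):
        return 1
    if s in ("0", "false", "no"):
        return 0
    raise ValueError(f"not a binary flag: {value!r}")


def load_cohort(path, atlas: JointAtlas | None = None,
                provenance: str | None = None) -> Cohort:
    """Read a cohort CSV, validating schema and row contents.

    Rows whose mandatory fields cannot be parsed (or violate range
    invariants) are rejected; their diagnostics are attached to the raised
    :class:`CohortValidationError` or, when only some rows fail, returned
    cohort's ``df.attrs['rejected_rows']``. Missing (empty) mandatory values
    are kept as NaN — they are the business of
    :func:`filter_complete_cases`, not the parser.
    """
    atlas = atlas or default_atlas()
    path = Path(path)
    raw = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in mandatory_columns(atlas) if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {missing}")

    diagnostics: list[str] = []
    keep = np.ones(len(raw), dtype=bool)

    for col in MANDATORY_NUMERIC:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        for i in raw.index[bad]:
            diagnostics.append(f"row {i}: unparseable {col}={raw.at[i, col]!r}")
        keep &= ~bad.to_numpy()
        raw[col] = vals
    # range invariants, checked only where a value is present
    checks = [
        ("esr", raw["esr"] < 0, "esr < 0"),
        ("age", (raw["age"] < 18) | (raw["age"] > 100), "age outside [18, 100]"),
    ]
    for lab in ("hb", "ht", "leuko", "thrombo"):
        checks.append((lab, raw[lab] <= 0, f"{lab} <= 0"))
    for col, bad, msg in checks:
        bad = bad.fillna(False)
        for i in raw.index[bad]:
            diagnostics.append(f"row {i}: {msg} ({raw.at[i, col]!r})")
        keep &= ~bad.to_numpy()

    flag_cols = [c for c in joint_flag_columns(atlas) + MANDATORY_BINARY]
    for col in flag_cols:
        parsed = []
        for i, v in raw[col].items():
            if pd.isna(v):
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(_coerce_binary(v)))
            except ValueError:
                diagnostics.append(f"row {i}: unparseable {col}={v!r}")
                keep[i] = False
                parsed.append(np.nan)
        raw[col] = parsed

    sex_ok = raw["sex"].isna() | raw["sex"].isin(["female", "male"])
    for i in raw.index[~sex_ok]:
        diagnostics.append(f"row {i}: unknown sex {raw.at[i, 'sex']!r}")
    keep &= sex_ok.to_numpy()

    df = raw.loc[keep].reset_index(drop=True)
    df["das_series"] = _collapse_das_columns(df)
    df = df.drop(columns=[c for c in df.columns
                          if c.startswith(("das_day_", "das_val_"))])
    cohort = Cohort(df, atlas, provenance or str(path))
    cohort.df.attrs["rejected_rows"] = diagnostics
    return cohort


def _collapse_das_columns(df: pd.DataFrame) -> list:
    day_cols = sorted((c for c in df.columns if c.startswith("das_day_")),
                      key=lambda c: int(c.split("_")[-1]))
    series = []
    for _, row in df.iterrows():
        pairs = []
        for dc in day_cols:
            vc = "das_val_" + dc.split("_")[-1]
            d, v = row.get(dc), row.get(vc)
            if pd.notna(d) and pd.notna(v):
                pairs.append((float(d), float(v)))
        series.append(pairs)
    return series


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (das_series expanded into das_day_k/das_val_k)."""
    df = cohort.df.copy()
    if "das_series" in df.columns:
        series = df.pop("das_series")
        max_len = max((len(s) for s in series), default=0)
        for k in range(max_len):
            df[f"das_day_{k + 1}"] = [s[k][0] if len(s) > k else np.nan
                                      for s in series]
            df[f"das_val_{k + 1}"] = [s[k][1] if len(s) > k else np.nan
                                      for s in series]
    df.to_csv(path, index=False)


def filter_complete_cases(cohort: Cohort) -> tuple[Cohort, dict]:
    """Drop patients missing any lab, ESR, serology, age, sex or joint flag.

    Returns the filtered cohort and a report counting dropped patients per
    missing field. Mirrors the complete-case analysis design: no imputation.
    """
    df = cohort.df
    required = (["age", "sex", "rf", "acpa", "hb", "ht", "leuko", "thrombo",
                 "esr"] + joint_flag_columns(cohort.atlas))
    report: dict[str, int] = {}
    keep = np.ones(len(df), dtype=bool)
    for col in required:
        miss = df[col].isna().to_numpy()
        n = int(miss.sum())
        if n:
            report[col] = n
        keep &= ~miss
    out = cohort.subset(keep)
    if len(out) == 0 and len(df) > 0:
        import warnings
        warnings.warn("complete-case filter removed every patient")
    return out, report


JointCounts = namedtuple(
    "JointCounts", ["tjc44", "sjc44", "tjc28", "sjc28", "hand", "foot"])


def joint_counts(record, atlas: JointAtlas | None = None) -> JointCounts:
    """Tender/swollen joint counts over the full atlas, the DAS28 subset,
    and involved-joint (tender OR swollen) counts per hand/foot region."""
    atlas = atlas or default_atlas()
    tjc44 = sjc44 = tjc28 = sjc28 = hand = foot = 0
    for j in atlas:
        t = bool(record[f"tender_{j.joint_id}"])
        s = bool(record[f"swollen_{j.joint_id}"])
        tjc44 += t
        sjc44 += s
        if j.das28_member:
            tjc28 += t
            sjc28 += s
        if t or s:
            if j.region == "hand":
                hand += 1
            elif j.region == "foot":
                foot += 1
    return JointCounts(tjc44, sjc44, tjc28, sjc28, hand, foot)


def compute_das(tjc: float, sjc: float, esr: float, scheme: str) -> float:
    """3-component disease activity score.

    das28_3 = 1.08*(0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln ESR) + 0.16
    das44_3 = 0.54*sqrt(RAI) + 0.065*SJC44 + 0.33*ln ESR + 0.22

    The Ritchie articular index (RAI) is approximated by TJC44 (one grade per
    tender joint) since only binary tenderness is recorded. ESR is clamped to
    >= 1 mm/hr (lab floor) before the log.
    """
    if tjc < 0 or sjc < 0:
        raise ValueError("joint counts must be non-negative")
    if scheme not in ("das28_3", "das44_3"):
        raise ValueError(f"unknown scheme {scheme!r}")
    limit = 28 if scheme == "das28_3" else 44
    if tjc > limit or sjc > limit:
        raise ValueError(f"count exceeds {scheme} range (0..{limit})")
    esr = max(float(esr), 1.0)
    if scheme == "das28_3":
        return 1.08 * (0.56 * math.sqrt(tjc) + 0.28 * math.sqrt(sjc)
                       + 0.70 * math.log(esr)) + 0.16
    return (0.54 * math.sqrt(tjc) + 0.065 * sjc
            + 0.33 * math.log(esr) + 0.22)


def is_remission(das44: float) -> bool:
    """DAS44-based remission: strict DAS44 < 1.6."""
    return das44 < REMISSION_DAS44
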