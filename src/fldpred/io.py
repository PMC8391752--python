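"""Cohort serialization: long-format CSV plus a JSON schema sidecar.

CSV columns: subject_id, gender, birth_year, visit_year, visit_month,
fld_label, then one column per feature in schema order; an empty cell is
a missing value.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cohort import (
    LABEL_CODES,
    LABEL_NAMES,
    Cohort,
    FeatureSchema,
    SubjectHistory,
    Visit,
)

META_COLUMNS = ["subject_id", "gender", "birth_year", "visit_year", "visit_month", "fld_label"]


class CohortFormatError(ValueError):
    """Raised for malformed cohort files (bad rows, duplicate or
    non-monotone visit dates)."""


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame: one row per visit, meta columns then features."""
    rows = []
    for s, v in cohort.iter_visits():
        row = {
            "subject_id": s.subject_id,
            "gender": s.gender,
            "birth_year": s.birth_year,
            "visit_year": v.year,
            "visit_month": v.month,
            "fld_label": LABEL_NAMES[v.fld_label] if v.fld_label is not None else "",
        }
        for f in cohort.schema:
            row[f.name] = v.value(f.name)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + cohort.schema.names)


def cohort_to_csv(cohort: Cohort, path: Union[str, os.PathLike], schema_path: Optional[Union[str, os.PathLike]] = None) -> None:
    frame = cohort_to_frame(cohort)
    frame.to_csv(path, index=False)
    if schema_path is not None:
        with open(schema_path, "w") as fh:
            fh.write(cohort.schema.to_json())


def frame_to_cohort(frame: pd.DataFrame, schema: FeatureSchema) -> Cohort:
    missing_meta = [c for c in META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise CohortFormatError(f"missing required columns {missing_meta}")
    unknown = [c for c in frame.columns if c not in META_COLUMNS and c not in schema.names]
    if unknown:
        raise CohortFormatError(f"columns not declared in schema: {unknown}")

    subjects: list[SubjectHistory] = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.reset_index(drop=True)
        months = grp["visit_year"].astype(int) * 12 + grp["visit_month"].astype(int)
        if months.duplicated().any():
            raise CohortFormatError(f"duplicate (subject, date) rows for subject {sid}")
        order = months.sort_values().index
        grp = grp.loc[order]
        visits = []
        for _, r in grp.iterrows():
            numeric: dict[str, float] = {}
            categorical: dict[str, int] = {}
            for f in schema:
                val = r.get(f.name)
                if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                    continue
                if f.kind == "numeric":
                    numeric[f.name] = float(val)
                else:
                    categorical[f.name] = int(val)
            raw_label = r["fld_label"]
            if isinstance(raw_label, str):
                label = LABEL_CODES.get(raw_label) if raw_label else None
            elif raw_label is None or (isinstance(raw_label, float) and np.isnan(raw_label)):
                label = None
            else:
                label = int(raw_label)
            visits.append(
                Visit(
                    subject_id=str(sid),
                    year=int(r["visit_year"]),
                    month=int(r["visit_month"]),
                    numeric=numeric,
                    categorical=categorical,
                    fld_label=label,
                )
            )
        subjects.append(
            SubjectHistory(
                subject_id=str(sid),
                gender=str(grp["gender"].iloc[0]),
                birth_year=int(grp["birth_year"].iloc[0]),
                visits=visits,
            )
        )
    return Cohort(schema=schema, subjects=subjects)


def csv_to_cohort(path: Union[str, os.PathLike], schema: FeatureSchema) -> Cohort:
    frame = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=True, float_precision="round_trip")
    if frame.empty and list(frame.columns) == []:
        raise CohortFormatError(f"{path} is empty")
    return frame_to_cohort(frame, schema)


def load_schema(path: Union[str, os.PathLike]) -> FeatureSchema:
    with open(path) as fh:
        return FeatureSchema.from_json(fh.read())


__all__ = [
    "CohortFormatError",
    "cohort_to_frame",
    "cohort_to_csv",
    "frame_to_cohort",
    "csv_to_cohort",
    "load_schema",
    "META_COLUMNS",
]
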