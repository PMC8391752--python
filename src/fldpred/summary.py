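"""Cohort descriptive statistics: per-year visit counts, per-gender and
per-year NFLD/FLD class-size ratios, per-feature missingness, and yearly
means of a named feature stratified by label and gender."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .cohort import FLD, NFLD, Cohort


def class_ratio(n_nfld: int, n_fld: int) -> float:
    """NFLD/FLD class-size ratio; infinity when the FLD count is zero."""
    if n_fld == 0:
        warnings.warn("FLD count is zero; class ratio reported as infinity")
        return math.inf
    return n_nfld / n_fld


@dataclass
class CohortSummary:
    n_subjects: int
    n_visits: int
    visits_per_year_by_gender: pd.DataFrame  # index year, columns male/female
    class_ratio_by_gender: dict[str, float]  # NFLD/FLD
    class_ratio_by_year: pd.DataFrame  # index year, columns gender
    missingness: pd.Series  # per-feature missing fraction
    feature_yearly_mean: Optional[pd.DataFrame] = None  # (year, label, gender) mean


def cohort_summary(cohort: Cohort, track_feature: Optional[str] = None) -> CohortSummary:
    if cohort.n_visits == 0:
        raise ValueError("cohort has no visits")
    rows = []
    for s, v in cohort.iter_visits():
        rows.append(
            {
                "gender": s.gender,
                "year": v.year,
                "label": v.fld_label,
                **{f.name: v.value(f.name) for f in cohort.schema},
            }
        )
    df = pd.DataFrame(rows)

    visits = df.pivot_table(index="year", columns="gender", values="label", aggfunc="size", fill_value=0)

    ratio_gender = {}
    for g, grp in df.groupby("gender"):
        ratio_gender[g] = class_ratio(int((grp["label"] == NFLD).sum()), int((grp["label"] == FLD).sum()))

    ratio_year = (
        df.groupby(["year", "gender"])["label"]
        .apply(lambda s: class_ratio(int((s == NFLD).sum()), int((s == FLD).sum())))
        .unstack("gender")
    )

    missing = df[cohort.schema.names].isna().mean()

    tracked = None
    if track_feature is not None:
        if track_feature not in cohort.schema.names:
            raise KeyError(f"unknown feature {track_feature!r}")
        tracked = df.groupby(["year", "label", "gender"])[track_feature].mean().unstack(["label", "gender"])

    return CohortSummary(
        n_subjects=cohort.n_subjects,
        n_visits=cohort.n_visits,
        visits_per_year_by_gender=visits,
        class_ratio_by_gender=ratio_gender,
        class_ratio_by_year=ratio_year,
        missingness=missing,
        feature_yearly_mean=tracked,
    )


__all__ = ["class_ratio", "CohortSummary", "cohort_summary"]
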