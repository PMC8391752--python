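"""Cleaning and normalization of cohorts into model-ready feature tables.

The canonical order is: drop (by name, by missingness) -> impute
(mean/mode) -> consolidate questionnaire items -> z-score.  Normalization
statistics are computed from a designated fitting subset only, so that
held-out rows never leak into the scaler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureSchema, SubjectHistory, Visit


@dataclass
class FeatureTable:
    """Cross-sectional visits-by-features matrix with labels and metadata.

    ``X`` holds one row per visit (categoricals coded as integers before
    normalization), ``y`` the binary FLD label (1 = FLD), ``meta`` the
    subject/date columns, and ``norm_stats`` the per-feature (mean, std)
    captured by :func:`zscore_fit_apply` from the fitting subset.
    """

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame  # subject_id, gender, birth_year, visit_year, visit_month
    schema: FeatureSchema
    norm_stats: Optional[pd.DataFrame] = None  # index features, columns mean/std

    def __post_init__(self) -> None:
        if not (len(self.X) == len(self.y) == len(self.meta)):
            raise ValueError("X, y and meta must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def is_imputed(self) -> bool:
        return not self.X.isna().any().any()

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.X.copy(), self.y.copy(), self.meta.copy(), self.schema,
            None if self.norm_stats is None else self.norm_stats.copy(),
        )

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "FeatureTable":
        xrows, yvals, mrows = [], [], []
        for s, v in cohort.iter_visits():
            xrows.append([v.value(f.name) for f in cohort.schema])
            yvals.append(v.fld_label)
            mrows.append((s.subject_id, s.gender, s.birth_year, v.year, v.month))
        X = pd.DataFrame(xrows, columns=cohort.schema.names, dtype=float)
        y = pd.Series(yvals, name="fld_label", dtype="Int64").astype(float)
        meta = pd.DataFrame(mrows, columns=["subject_id", "gender", "birth_year", "visit_year", "visit_month"])
        return cls(X, y.astype(int) if not y.isna().any() else y, meta, cohort.schema)

    def select_rows(self, mask: Union[np.ndarray, pd.Series, Sequence[bool]]) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            self.X.loc[mask].reset_index(drop=True),
            self.y.loc[mask].reset_index(drop=True),
            self.meta.loc[mask].reset_index(drop=True),
            self.schema,
            self.norm_stats,
        )

    def rows_in_years(self, years: Sequence[int]) -> "FeatureTable":
        return self.select_rows(self.meta["visit_year"].isin(list(years)).to_numpy())

    def to_histories(self) -> list[SubjectHistory]:
        """Re-assemble per-subject ordered visit histories (for the
        sequence-building stage). Requires an imputed table."""
        if not self.is_imputed:
            raise ValueError("impute before building sequences")
        kinds = {f.name: f.kind for f in self.schema if f.name in self.X.columns}
        out = []
        meta = self.meta
        for sid, idx in meta.groupby("subject_id", sort=False).groups.items():
            idx = list(idx)
            sub = meta.loc[idx]
            order = (sub["visit_year"] * 12 + sub["visit_month"]).sort_values().index
            visits = []
            for i in order:
                numeric, categorical = {}, {}
                for name, kind in kinds.items():
                    val = self.X.at[i, name]
                    if kind == "numeric":
                        numeric[name] = float(val)
                    else:
                        categorical[name] = int(round(val))
                visits.append(
                    Visit(
                        subject_id=str(sid),
                        year=int(meta.at[i, "visit_year"]),
                        month=int(meta.at[i, "visit_month"]),
                        numeric=numeric,
                        categorical=categorical,
                        fld_label=int(self.y.loc[i]),
                    )
                )
            out.append(
                SubjectHistory(
                    subject_id=str(sid),
                    gender=str(sub["gender"].iloc[0]),
                    birth_year=int(sub["birth_year"].iloc[0]),
                    visits=visits,
                )
            )
        return out


def drop_by_name(table: FeatureTable, names: Sequence[str]) -> FeatureTable:
    """Remove configured useless/redundant features; unknown or repeated
    names warn but do not fail (drop lists are configuration)."""
    seen: set[str] = set()
    to_drop: list[str] = []
    for name in names:
        if name in seen:
            warnings.warn(f"feature {name!r} listed twice in drop list")
            continue
        seen.add(name)
        if name not in table.X.columns:
            warnings.warn(f"feature {name!r} not present; nothing to drop")
            continue
        to_drop.append(name)
    out = table.copy()
    out.X = out.X.drop(columns=to_drop)
    out.schema = out.schema.drop(to_drop)
    return out


def drop_high_missing(table: FeatureTable, threshold: float) -> tuple[FeatureTable, list[str]]:
    """Drop features whose missing fraction is >= threshold (a feature
    exactly at the threshold is dropped)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    frac = table.X.isna().mean()
    dropped = [c for c in table.X.columns if frac[c] >= threshold]
    out = table.copy()
    out.X = out.X.drop(columns=dropped)
    out.schema = out.schema.drop(dropped)
    return out, dropped


def impute(table: FeatureTable, schema: Optional[FeatureSchema] = None) -> FeatureTable:
    """Mean-impute numeric features and mode-impute questionnaire
    features; ties on the mode go to the smallest level. Observed values
    are never altered."""
    schema = schema or table.schema
    kinds = schema.by_name()
    out = table.copy()
    for col in out.X.columns:
        s = out.X[col]
        if not s.isna().any():
            continue
        observed = s.dropna()
        if observed.empty:
            raise ValueError(f"feature {col!r} is entirely missing; cannot impute")
        kind = kinds[col].kind if col in kinds else "numeric"
        if kind == "numeric":
            fill = float(observed.mean())
        else:
            counts = observed.value_counts()
            top = counts.max()
            fill = float(min(level for level, c in counts.items() if c == top))
        out.X[col] = s.fillna(fill)
    return out


@dataclass(frozen=True)
class ConsolidationRule:
    """Derive one numeric feature as a gated weighted product of
    questionnaire items: gate_indicator * prod_i (value_i * coeff_i).

    The gate column (e.g. "drink or not") zeroes the result when 0; gate
    and source columns are removed after derivation.
    """

    name: str
    sources: tuple[tuple[str, float], ...]
    gate: Optional[str] = None


def consolidate(table: FeatureTable, rules: Sequence[ConsolidationRule]) -> FeatureTable:
    out = table.copy()
    for rule in rules:
        needed = [c for c, _ in rule.sources] + ([rule.gate] if rule.gate else [])
        absent = [c for c in needed if c not in out.X.columns]
        if absent:
            raise KeyError(f"consolidation rule {rule.name!r} references missing columns {absent}")
        value = np.ones(len(out), dtype=float)
        for col, coeff in rule.sources:
            value = value * out.X[col].to_numpy(dtype=float) * coeff
        if rule.gate is not None:
            value = value * (out.X[rule.gate].to_numpy(dtype=float) != 0.0)
        out.X = out.X.drop(columns=needed)
        out.schema = out.schema.drop(needed)
        out.X[rule.name] = value
        out.schema = out.schema.add_numeric(rule.name)
    return out


def zscore_fit_apply(table: FeatureTable, fit_rows: Union[np.ndarray, Sequence[bool], None] = None) -> FeatureTable:
    """Standardize every feature to zero mean and unit sample variance,
    with the mean and standard deviation computed from ``fit_rows`` only
    (default: all rows). Constant features map to 0 with a warning."""
    if not table.is_imputed:
        raise ValueError("z-score requires an imputed table; run impute() first")
    if fit_rows is None:
        mask = np.ones(len(table), dtype=bool)
    else:
        mask = np.asarray(fit_rows, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("fitting subset is empty")
    fit = table.X.loc[mask]
    mean = fit.mean()
    std = fit.std(ddof=1)
    out = table.copy()
    stats = pd.DataFrame({"mean": mean, "std": std})
    zero = std.index[(std == 0) | std.isna()]
    if len(zero):
        warnings.warn(f"constant features on the fitting subset mapped to 0: {list(zero)}")
    safe = std.replace(0.0, np.nan)
    out.X = (out.X - mean) / safe
    out.X[zero] = 0.0
    out.norm_stats = stats
    return out


__all__ = [
    "FeatureTable",
    "drop_by_name",
    "drop_high_missing",
    "impute",
    "ConsolidationRule",
    "consolidate",
    "zscore_fit_apply",
]
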