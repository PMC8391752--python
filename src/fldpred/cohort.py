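"""Domain model for longitudinal health-checkup cohorts.

A cohort is a set of subjects, each with an ordered history of checkup
visits.  Every visit carries numeric lab features, integer-coded
questionnaire features, and a binary fatty-liver-disease (FLD) label from
abdominal ultrasound.  Visit dates are calendar months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Optional, Sequence

NFLD = 0
FLD = 1

LABEL_NAMES = {NFLD: "NFLD", FLD: "FLD"}
LABEL_CODES = {"NFLD": NFLD, "FLD": FLD}


def month_index(year: int, month: int) -> int:
    """Map a (year, month) calendar date to a single monthly integer."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year * 12 + (month - 1)


def index_to_date(idx: int) -> tuple[int, int]:
    return idx // 12, idx % 12 + 1


@dataclass(frozen=True)
class FeatureDef:
    """One feature in the cohort schema."""

    name: str
    kind: str  # "numeric" | "categorical"
    levels: Optional[tuple[int, int]] = None  # inclusive level range for categoricals
    expert: bool = False  # flagged by the (synthetic) expert panel

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "categorical":
            if self.levels is None:
                raise ValueError(f"categorical feature {self.name!r} needs a level range")
            lo, hi = self.levels
            if hi < lo:
                raise ValueError(f"empty level range for {self.name!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature declarations; the column order used everywhere downstream."""

    features: tuple[FeatureDef, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")

    def __iter__(self) -> Iterator[FeatureDef]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name()

    def by_name(self) -> dict[str, FeatureDef]:
        return {f.name: f for f in self.features}

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def numeric_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "numeric"]

    @property
    def categorical_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "categorical"]

    @property
    def expert_set(self) -> frozenset[str]:
        return frozenset(f.name for f in self.features if f.expert)

    def kind_of(self, name: str) -> str:
        return self.by_name()[name].kind

    def subset(self, names: Sequence[str]) -> "FeatureSchema":
        keep = set(names)
        return FeatureSchema(tuple(f for f in self.features if f.name in keep))

    def drop(self, names: Sequence[str]) -> "FeatureSchema":
        gone = set(names)
        return FeatureSchema(tuple(f for f in self.features if f.name not in gone))

    def add_numeric(self, name: str, expert: bool = False) -> "FeatureSchema":
        return FeatureSchema(self.features + (FeatureDef(name, "numeric", expert=expert),))

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "levels": list(f.levels) if f.levels else None,
                    "expert": f.expert,
                }
                for f in self.features
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        raw = json.loads(text)
        return cls(
            tuple(
                FeatureDef(
                    d["name"],
                    d["kind"],
                    tuple(d["levels"]) if d.get("levels") else None,
                    bool(d.get("expert", False)),
                )
                for d in raw
            )
        )


@dataclass
class Visit:
    """A single checkup: features measured on one calendar month.

    Missing measurements are simply absent from the maps; the label may be
    None if the ultrasound result is unavailable.
    """

    subject_id: str
    year: int
    month: int
    numeric: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, int] = field(default_factory=dict)
    fld_label: Optional[int] = None

    @property
    def month_idx(self) -> int:
        return month_index(self.year, self.month)

    def value(self, name: str) -> Optional[float]:
        if name in self.numeric:
            return self.numeric[name]
        if name in self.categorical:
            return float(self.categorical[name])
        return None


@dataclass
class SubjectHistory:
    """One subject's ordered visit history."""

    subject_id: str
    gender: str  # "male" | "female"
    birth_year: int
    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise ValueError(f"gender must be male/female, got {self.gender!r}")
        idxs = [v.month_idx for v in self.visits]
        if any(b <= a for a, b in zip(idxs, idxs[1:])):
            raise ValueError(f"visit dates not strictly increasing for subject {self.subject_id}")

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def age_at(self, visit: Visit) -> int:
        # age at visit = visit year minus birth year; month ignored
        return visit.year - self.birth_year


@dataclass
class Cohort:
    """A schema, a list of subject histories, and (for synthetic cohorts)
    the ground-truth set of informative feature names."""

    schema: FeatureSchema
    subjects: list[SubjectHistory]
    ground_truth: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        declared = set(self.schema.names)
        for s in self.subjects:
            for v in s.visits:
                extra = (set(v.numeric) | set(v.categorical)) - declared
                if extra:
                    raise ValueError(
                        f"visit of subject {s.subject_id} has undeclared features {sorted(extra)}"
                    )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_visits(self) -> int:
        return sum(s.n_visits for s in self.subjects)

    def iter_visits(self) -> Iterator[tuple[SubjectHistory, Visit]]:
        for s in self.subjects:
            for v in s.visits:
                yield s, v


__all__ = [
    "NFLD",
    "FLD",
    "LABEL_NAMES",
    "LABEL_CODES",
    "month_index",
    "index_to_date",
    "FeatureDef",
    "FeatureSchema",
    "Visit",
    "SubjectHistory",
    "Cohort",
]
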