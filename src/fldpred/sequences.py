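"""Turning irregular visit histories into sequence-classification samples.

Two encodings of a subject's history for next-visit prediction:

* feature set 1 (fs1, fixed interval): the history is resampled to a
  monthly grid (shape-preserving piecewise-cubic interpolation for
  numeric features; linear interpolation with rounding for questionnaire
  features and the label), then 12-month input windows predict the label
  a fixed horizon (default 12 months) ahead, collected with a sliding
  window.
* feature set 2 (fs2, variable interval): the raw visits of each prefix
  are the steps, and each step vector is augmented with two timing
  inputs — months since the previous visit and months from the prefix's
  last visit to the prediction time — giving width d+2 for d features.

Subjects with a single visit are discarded for next-visit prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cohort import FeatureSchema, SubjectHistory, Visit


@dataclass
class MonthlySeries:
    """A subject's history resampled to consecutive calendar months."""

    subject_id: str
    months: np.ndarray  # consecutive month indices, first to last visit
    values: "np.ndarray"  # (n_months, n_features) in feature_names order
    labels: np.ndarray  # (n_months,) 0/1
    feature_names: list[str]
    visit_months: np.ndarray

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


@dataclass
class SequenceSample:
    """One training instance: an input sequence and the next-visit target."""

    encoding: str  # "fs1" | "fs2"
    inputs: np.ndarray  # (T, width)
    target: int  # 0/1 label at the prediction time
    subject_id: str
    anchor_month: int  # month index of the last input step
    horizon: int  # months from anchor to prediction time
    anchor_label: int  # label at the anchor (for the persistence baseline)
    step_months: tuple[int, ...] = ()  # month index of each input step (fs2)


def extract_prefix_pairs(history: SubjectHistory) -> list[tuple[list[Visit], Visit]]:
    """All (prefix, next visit) pairs: a history of N visits yields N-1
    pairs {v1..vi => v(i+1)}; single-visit histories yield none."""
    v = history.visits
    return [(v[:i], v[i]) for i in range(1, len(v))]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def interpolate_monthly(history: SubjectHistory, schema: FeatureSchema) -> MonthlySeries:
    """Resample a history to its full monthly grid.

    Numeric features use a shape-preserving piecewise-cubic (monotone
    Hermite) interpolant, which degenerates to linear between two visits
    and never overshoots monotone segments.  Categorical features and the
    label use linear interpolation rounded half-up to the nearest level,
    clamped to the declared level range.  Values at the original visit
    months are reproduced exactly.
    """
    if history.n_visits < 2:
        raise ValueError(f"subject {history.subject_id}: need >= 2 visits to interpolate")
    vm = np.array([v.month_idx for v in history.visits])
    grid = np.arange(vm[0], vm[-1] + 1)
    names = [f.name for f in schema if f.name in _present_features(history)]
    by_name = schema.by_name()
    cols = np.empty((len(grid), len(names)))
    for j, name in enumerate(names):
        obs = np.array([_require_value(v, name, history.subject_id) for v in history.visits], dtype=float)
        if by_name[name].kind == "numeric":
            col = PchipInterpolator(vm, obs)(grid)
        else:
            col = _round_half_up(np.interp(grid, vm, obs))
            lo, hi = by_name[name].levels
            col = np.clip(col, lo, hi)
        col[np.searchsorted(grid, vm)] = obs  # visit months exact
        cols[:, j] = col
    lab_obs = np.array([v.fld_label for v in history.visits], dtype=float)
    labels = np.clip(_round_half_up(np.interp(grid, vm, lab_obs)), 0, 1).astype(int)
    labels[np.searchsorted(grid, vm)] = lab_obs.astype(int)
    return MonthlySeries(
        subject_id=history.subject_id,
        months=grid,
        values=cols,
        labels=labels,
        feature_names=names,
        visit_months=vm,
    )


def _present_features(history: SubjectHistory) -> set[str]:
    first = history.visits[0]
    return set(first.numeric) | set(first.categorical)


def _require_value(v: Visit, name: str, sid: str) -> float:
    val = v.value(name)
    if val is None:
        raise ValueError(f"subject {sid}: missing {name!r}; run imputation first")
    return val


def build_fs1_samples(
    series: MonthlySeries,
    selected_features: Sequence[str],
    window: int = 12,
    horizon: int = 12,
    stride: int = 1,
    pad_left: bool = False,
) -> list[SequenceSample]:
    """Sliding fixed-interval windows over a monthly series.

    Default anchors require the full input window inside the observed
    span and the target month at or before the last visit month, so no
    sample trains on a wholly fabricated target.  With ``pad_left=True``
    anchors may start at the first month and the input is back-filled by
    duplicating the earliest month's values.
    """
    cols = [series.feature_names.index(f) for f in selected_features]
    first, last = int(series.months[0]), int(series.months[-1])
    lo = first if pad_left else first + window - 1
    hi = last - horizon
    samples: list[SequenceSample] = []
    for anchor in range(lo, hi + 1, stride):
        rows = np.arange(anchor - window + 1, anchor + 1)
        rows = np.maximum(rows, first)  # left duplication when pad_left
        idx = rows - first
        inputs = series.values[np.ix_(idx, cols)]
        samples.append(
            SequenceSample(
                encoding="fs1",
                inputs=inputs,
                target=int(series.labels[anchor + horizon - first]),
                subject_id=series.subject_id,
                anchor_month=anchor,
                horizon=horizon,
                anchor_label=int(series.labels[anchor - first]),
            )
        )
    return samples


def build_fs2_samples(
    history: SubjectHistory,
    selected_features: Sequence[str],
) -> list[SequenceSample]:
    """Variable-interval encoding: one sample per prefix pair; each step
    is [months since previous visit, months to the prediction time,
    d feature values] — width d+2.  The first step's elapsed time is 0."""
    samples: list[SequenceSample] = []
    for prefix, target in extract_prefix_pairs(history):
        t_target = target.month_idx
        t_anchor = prefix[-1].month_idx
        steps = []
        months = []
        for i, v in enumerate(prefix):
            dt = 0 if i == 0 else v.month_idx - prefix[i - 1].month_idx
            feats = [_require_value(v, f, history.subject_id) for f in selected_features]
            steps.append([float(dt), float(t_target - t_anchor)] + feats)
            months.append(v.month_idx)
        samples.append(
            SequenceSample(
                encoding="fs2",
                inputs=np.asarray(steps, dtype=float),
                target=int(target.fld_label),
                subject_id=history.subject_id,
                anchor_month=t_anchor,
                horizon=t_target - t_anchor,
                anchor_label=int(prefix[-1].fld_label),
                step_months=tuple(months),
            )
        )
    return samples


def build_fs2_cohort_samples(histories: Sequence[SubjectHistory], selected_features: Sequence[str]) -> list[SequenceSample]:
    out: list[SequenceSample] = []
    for h in histories:
        out.extend(build_fs2_samples(h, selected_features))
    return out


def split_samples(
    samples: Sequence[SequenceSample],
    train_frac: float = 0.7,
    val_frac_of_train: float = 0.1,
    stratify: bool = True,
    group_by_subject: bool = True,
    seed: int = 0,
) -> tuple[list[SequenceSample], list[SequenceSample], list[SequenceSample]]:
    """Stratified train/val/test partition of samples.

    With ``group_by_subject`` all samples of one subject land in the same
    split (stratification is then best-effort at the subject level);
    without grouping the split is exactly stratified on the target.
    """
    if not 0 < train_frac < 1 or not 0 < val_frac_of_train < 1:
        raise ValueError("fractions must be in (0, 1)")
    samples = list(samples)
    rng = np.random.default_rng(seed)
    y = np.array([s.target for s in samples])
    if stratify:
        for cls in np.unique(y):
            if (y == cls).sum() < 3:
                warnings.warn(f"stratum {cls} has < 3 samples; best-effort assignment")
    if not group_by_subject:
        trainval_idx, test_idx = _stratified_split(np.arange(len(samples)), y, train_frac, stratify, rng)
        tv_y = y[trainval_idx]
        train_idx, val_idx = _stratified_split(trainval_idx, tv_y, 1 - val_frac_of_train, stratify, rng)
        return ([samples[i] for i in train_idx], [samples[i] for i in val_idx], [samples[i] for i in test_idx])

    subjects: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        subjects.setdefault(s.subject_id, []).append(i)
    sids = list(subjects)
    rng.shuffle(sids)
    # greedy per-stratum filling toward the test fraction
    targets = {c: (1 - train_frac) * (y == c).sum() for c in np.unique(y)}
    got = {c: 0.0 for c in targets}
    test_idx: list[int] = []
    trainval_idx: list[int] = []
    for sid in sids:
        idxs = subjects[sid]
        cls_counts = {c: sum(1 for i in idxs if y[i] == c) for c in targets}
        need = sum(max(targets[c] - got[c], 0.0) for c in targets)
        if need > 0:
            test_idx.extend(idxs)
            for c in targets:
                got[c] += cls_counts[c]
        else:
            trainval_idx.extend(idxs)
    # carve validation subjects out of the trainval pool
    tv_subjects: dict[str, list[int]] = {}
    for i in trainval_idx:
        tv_subjects.setdefault(samples[i].subject_id, []).append(i)
    tv_sids = list(tv_subjects)
    rng.shuffle(tv_sids)
    n_val_target = val_frac_of_train * len(trainval_idx)
    val_idx: list[int] = []
    train_idx: list[int] = []
    for sid in tv_sids:
        if len(val_idx) < n_val_target:
            val_idx.extend(tv_subjects[sid])
        else:
            train_idx.extend(tv_subjects[sid])
    return ([samples[i] for i in train_idx], [samples[i] for i in val_idx], [samples[i] for i in test_idx])


def _stratified_split(idx: np.ndarray, y: np.ndarray, keep_frac: float, stratify: bool, rng: np.random.Generator):
    idx = np.asarray(idx)
    if not stratify:
        perm = rng.permutation(len(idx))
        cut = int(round(keep_frac * len(idx)))
        return idx[perm[:cut]], idx[perm[cut:]]
    keep, rest = [], []
    for c in np.unique(y):
        sub = idx[y == c]
        perm = rng.permutation(len(sub))
        cut = int(round(keep_frac * len(sub)))
        keep.extend(sub[perm[:cut]].tolist())
        rest.extend(sub[perm[cut:]].tolist())
    return np.array(keep, dtype=int), np.array(rest, dtype=int)


__all__ = [
    "MonthlySeries",
    "SequenceSample",
    "extract_prefix_pairs",
    "interpolate_monthly",
    "build_fs1_samples",
    "build_fs2_samples",
    "build_fs2_cohort_samples",
    "split_samples",
]
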