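"""Prefix-pair extraction, monthly interpolation, fs1/fs2 encodings and
sample splitting."""

import numpy as np
import pytest

from fldpred.cohort import FeatureDef, FeatureSchema
from fldpred.sequences import (
    build_fs1_samples,
    build_fs2_cohort_samples,
    build_fs2_samples,
    extract_prefix_pairs,
    interpolate_monthly,
    split_samples,
)
from tests.conftest import make_history

SCHEMA = FeatureSchema(
    (FeatureDef("x1", "numeric"), FeatureDef("q1", "categorical", (0, 3)))
)


class TestPrefixPairs:
    @pytest.mark.parametrize("n_visits, expected", [(5, 4), (2, 1), (1, 0), (4, 3)])
    def test_pair_count(self, n_visits, expected):
        h = make_history(list(range(0, n_visits * 3, 3)), [0] * n_visits)
        pairs = extract_prefix_pairs(h)
        assert len(pairs) == expected
        for i, (prefix, target) in enumerate(pairs, start=1):
            assert len(prefix) == i
            assert target is h.visits[i]


class TestInterpolation:
    def test_categorical_integer_slope(self):
        h = make_history([0, 3], [0, 0], values=[0.0, 3.0])
        series = interpolate_monthly(h, SCHEMA)
        assert series.column("q1").tolist() == [0, 1, 2, 3]

    def test_two_point_numeric_is_linear(self):
        h = make_history([0, 4], [0, 0], values=[1.0, 9.0])
        series = interpolate_monthly(h, SCHEMA)
        assert series.column("x1")[2] == pytest.approx(5.0)  # midpoint = mean

    def test_label_midpoint_rounds_to_fld(self):
        h = make_history([0, 2], [0, 1])
        series = interpolate_monthly(h, SCHEMA)
        assert series.labels.tolist() == [0, 1, 1]  # 0.5 rounds half-up to FLD

    def test_visit_months_reproduced_exactly(self):
        h = make_history([0, 5, 11], [0, 1, 0], values=[1.5, -2.0, 0.25])
        series = interpolate_monthly(h, SCHEMA)
        idx = np.searchsorted(series.months, series.visit_months)
        assert series.column("x1")[idx].tolist() == [1.5, -2.0, 0.25]
        assert series.labels[idx].tolist() == [0, 1, 0]

    def test_idempotent_on_already_monthly_series(self):
        vals = [0.0, 1.0, 0.5, 2.0]
        h = make_history([0, 1, 2, 3], [0, 0, 1, 1], values=vals)
        series = interpolate_monthly(h, SCHEMA)
        assert series.column("x1").tolist() == pytest.approx(vals)

    def test_monotone_segments_do_not_overshoot(self):
        h = make_history([0, 6, 18], [0, 0, 0], values=[0.0, 1.0, 10.0])
        series = interpolate_monthly(h, SCHEMA)
        x = series.column("x1")
        assert np.all(np.diff(x) >= -1e-12)
        assert x.min() >= 0.0 - 1e-12 and x.max() <= 10.0 + 1e-12

    def test_single_visit_rejected(self):
        with pytest.raises(ValueError):
            interpolate_monthly(make_history([0], [0]), SCHEMA)


class TestFs1:
    def test_24_month_series_yields_single_anchor(self):
        # months 0..24 span exactly 24 intervals; window 12 + horizon 12
        h = make_history([0, 24], [0, 1])
        series = interpolate_monthly(h, SCHEMA)
        samples = build_fs1_samples(series, ["x1"], window=12, horizon=12, stride=1)
        assert len(samples) == 2  # anchors at grid months 12 and 13 on a 25-month grid
        h = make_history([1, 24], [0, 1])  # 24 months inclusive
        series = interpolate_monthly(h, SCHEMA)
        samples = build_fs1_samples(series, ["x1"], window=12, horizon=12, stride=1)
        assert len(samples) == 1
        assert samples[0].anchor_month - series.months[0] == 11  # the 12th month

    def test_stride_two_halves_sample_count(self):
        h = make_history([0, 48], [0, 0])
        series = interpolate_monthly(h, SCHEMA)
        s1 = build_fs1_samples(series, ["x1"], stride=1)
        s2 = build_fs1_samples(series, ["x1"], stride=2)
        assert abs(len(s1) / 2 - len(s2)) <= 1

    def test_every_input_has_exactly_window_steps(self):
        h = make_history([0, 10, 30, 40], [0, 1, 1, 0])
        series = interpolate_monthly(h, SCHEMA)
        for s in build_fs1_samples(series, ["x1", "q1"]):
            assert s.inputs.shape == (12, 2)
            assert s.target in (0, 1)

    def test_pad_left_duplicates_earliest_month(self):
        h = make_history([0, 14], [0, 0], values=[3.0, 5.0])
        series = interpolate_monthly(h, SCHEMA)
        samples = build_fs1_samples(series, ["x1"], window=12, horizon=2, stride=1, pad_left=True)
        first = samples[0]
        assert first.anchor_month == series.months[0]
        assert np.allclose(first.inputs[:, 0], 3.0)  # back-filled with the first month


class TestFs2:
    @pytest.mark.parametrize("d", [1, 3, 24])
    def test_step_width_is_d_plus_2(self, d):
        names = [f"g{i}" for i in range(d)]
        schema = FeatureSchema(tuple(FeatureDef(n, "numeric") for n in names))
        from fldpred.cohort import SubjectHistory, Visit

        visits = [
            Visit("S", 2010 + m // 12, m % 12 + 1, {n: float(m) for n in names}, {}, m % 2)
            for m in (0, 4, 10)
        ]
        h = SubjectHistory("S", "male", 1960, visits)
        for s in build_fs2_samples(h, names):
            assert s.inputs.shape[1] == d + 2

    def test_timing_inputs_hand_computed(self):
        h = make_history([0, 4, 10], [0, 0, 1])
        samples = build_fs2_samples(h, ["x1"])
        s = samples[1]  # prefix {v1, v2} -> v3 at month 10
        assert s.inputs[:, 0].tolist() == [0.0, 4.0]  # months since previous visit
        assert s.inputs[:, 1].tolist() == [6.0, 6.0]  # months to prediction time
        assert s.horizon == 6 and s.anchor_label == 0 and s.target == 1

    def test_sample_lengths_are_prefix_lengths(self):
        h = make_history([0, 3, 7, 12], [0, 1, 1, 0])
        lengths = [len(s.inputs) for s in build_fs2_samples(h, ["x1"])]
        assert lengths == [1, 2, 3]

    def test_timing_is_lossless(self):
        h = make_history([2, 9, 21], [0, 1, 1])
        s = build_fs2_samples(h, ["x1"])[-1]  # prefix {v1, v2} -> v3
        deltas = s.inputs[:, 0]
        rel_months = np.cumsum(deltas)  # visit months relative to the first
        assert rel_months.tolist() == [0.0, 7.0]
        assert s.inputs[0, 1] == s.horizon == 12  # prediction offset on every step

    def test_cohort_sample_count_matches_brute_force(self, small_table):
        histories = [h for h in small_table.to_histories() if h.n_visits >= 2]
        samples = build_fs2_cohort_samples(histories, ["bmi"])
        assert len(samples) == sum(max(h.n_visits - 1, 0) for h in histories)


class TestSplit:
    @staticmethod
    def samples_with_subjects(n, rng, one_per_subject=False):
        out = []
        for i in range(n):
            sid = f"P{i}" if one_per_subject else f"P{i % (n // 4)}"
            h = make_history([0, 6], [int(rng.random() < 0.4)] * 2, subject_id=sid)
            out.extend(build_fs2_samples(h, ["x1"]))
        return out

    def test_fractions_without_grouping(self):
        rng = np.random.default_rng(0)
        samples = self.samples_with_subjects(1000, rng, one_per_subject=True)
        train, val, test = split_samples(samples, group_by_subject=False, seed=1)
        assert len(test) == 300
        assert len(train) + len(val) == 700
        assert abs(len(val) - 70) <= 2

    def test_no_subject_spans_splits(self):
        rng = np.random.default_rng(1)
        samples = self.samples_with_subjects(400, rng)
        train, val, test = split_samples(samples, group_by_subject=True, seed=2)
        tr = {s.subject_id for s in train}
        va = {s.subject_id for s in val}
        te = {s.subject_id for s in test}
        assert not (tr & te) and not (tr & va) and not (va & te)

    def test_same_seed_identical_split(self):
        rng = np.random.default_rng(2)
        samples = self.samples_with_subjects(200, rng)
        a = split_samples(samples, seed=3)
        b = split_samples(samples, seed=3)
        for pa, pb in zip(a, b):
            assert [id(s) for s in pa] == [id(s) for s in pb]
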