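"""Drop rules, mean/mode imputation, consolidation, z-score with
training-only statistics."""

import numpy as np
import pandas as pd
import pytest

from fldpred.cohort import FeatureDef, FeatureSchema
from fldpred.preprocessing import (
    ConsolidationRule,
    FeatureTable,
    consolidate,
    drop_by_name,
    drop_high_missing,
    impute,
    zscore_fit_apply,
)


def make_table(data: dict, kinds: dict, labels=None):
    X = pd.DataFrame(data, dtype=float)
    n = len(X)
    schema = FeatureSchema(
        tuple(
            FeatureDef(name, kinds.get(name, "numeric"), (0, 9) if kinds.get(name) == "categorical" else None)
            for name in X.columns
        )
    )
    y = pd.Series(labels if labels is not None else [0] * n)
    meta = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "gender": ["male"] * n,
            "birth_year": [1960] * n,
            "visit_year": [2015] * n,
            "visit_month": [1] * n,
        }
    )
    return FeatureTable(X, y, meta, schema)


class TestDrop:
    def test_empty_list_is_identity(self):
        t = make_table({"a": [1, 2], "b": [3, 4]}, {})
        out = drop_by_name(t, [])
        assert out.feature_names == ["a", "b"]

    def test_single_drop_preserves_order(self):
        t = make_table({c: [0.0] for c in "abcdefghij"}, {})
        out = drop_by_name(t, ["c"])
        assert out.feature_names == [c for c in "abdefghij"]
        assert "c" not in out.schema

    def test_duplicate_name_warns_and_drops_once(self):
        t = make_table({"a": [1], "b": [2]}, {})
        with pytest.warns(UserWarning):
            out = drop_by_name(t, ["a", "a"])
        assert out.feature_names == ["b"]

    def test_unknown_name_warns_not_raises(self):
        t = make_table({"a": [1]}, {})
        with pytest.warns(UserWarning):
            out = drop_by_name(t, ["zz"])
        assert out.feature_names == ["a"]


class TestDropHighMissing:
    def test_threshold_is_inclusive(self):
        # one feature at exactly 90% missing, one at 95%, one below
        col90 = [1.0] + [np.nan] * 9
        col95 = [1.0] + [np.nan] * 19
        t = make_table(
            {"at90": col90 * 2, "at95": col95, "ok": list(range(20))}, {}
        )
        out, dropped = drop_high_missing(t, 0.9)
        assert set(dropped) == {"at90", "at95"}
        assert out.feature_names == ["ok"]

    def test_fully_observed_table_untouched(self):
        t = make_table({"a": [1, 2, 3]}, {})
        out, dropped = drop_high_missing(t, 0.9)
        assert dropped == [] and out.feature_names == ["a"]


class TestImpute:
    def test_numeric_mean(self):
        t = make_table({"a": [1.0, np.nan, 3.0]}, {})
        assert impute(t).X["a"].tolist() == [1.0, 2.0, 3.0]

    def test_categorical_mode(self):
        t = make_table({"q": [2, 2, np.nan, 5]}, {"q": "categorical"})
        assert impute(t).X["q"].tolist() == [2, 2, 2, 5]

    def test_bimodal_tie_takes_smallest_level(self):
        # enumerate the tie: levels 1 and 2 both appear twice
        t = make_table({"q": [1, 1, 2, 2, np.nan]}, {"q": "categorical"})
        counts = pd.Series([1, 1, 2, 2]).value_counts()
        tied = sorted(level for level, c in counts.items() if c == counts.max())
        assert impute(t).X["q"].iloc[-1] == tied[0] == 1

    def test_observed_values_never_altered(self, small_cohort):
        t = FeatureTable.from_cohort(small_cohort)
        out = impute(t)
        observed = (~t.X.isna()).to_numpy()
        assert np.array_equal(out.X.to_numpy()[observed], t.X.to_numpy()[observed])
        assert out.is_imputed

    def test_entirely_missing_column_errors(self):
        t = make_table({"a": [np.nan, np.nan]}, {})
        with pytest.raises(ValueError, match="a"):
            impute(t)


class TestConsolidate:
    def test_gate_zeroes_result(self):
        t = make_table(
            {"drink_or_not": [0, 1], "amount": [10, 10], "dtype": [1, 1]}, {}
        )
        rule = ConsolidationRule("alcohol_g", (("amount", 0.4), ("dtype", 1.0)), gate="drink_or_not")
        out = consolidate(t, [rule])
        assert out.X["alcohol_g"].tolist() == [0.0, 4.0]
        assert set(out.feature_names) == {"alcohol_g"}

    def test_met_rule_product(self):
        t = make_table({"freq": [3.0], "dur": [0.5], "intensity": [6.0]}, {})
        rule = ConsolidationRule("met_week", (("freq", 1.0), ("dur", 1.0), ("intensity", 1.0)))
        out = consolidate(t, [rule])
        assert out.X["met_week"].iloc[0] == pytest.approx(9.0)

    def test_missing_source_column_errors(self):
        t = make_table({"a": [1.0]}, {})
        with pytest.raises(KeyError, match="ghost"):
            consolidate(t, [ConsolidationRule("d", (("ghost", 1.0),))])


class TestZScore:
    def test_closed_form(self):
        t = make_table({"a": [2.0, 4.0, 6.0]}, {})
        out = zscore_fit_apply(t)
        assert out.X["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert out.norm_stats.loc["a", "mean"] == 4.0
        assert out.norm_stats.loc["a", "std"] == 2.0

    def test_constant_column_maps_to_zero_with_warning(self):
        t = make_table({"a": [5.0, 5.0, 5.0]}, {})
        with pytest.warns(UserWarning):
            out = zscore_fit_apply(t)
        assert (out.X["a"] == 0).all()

    def test_held_out_row_at_fit_mean_maps_to_zero(self):
        t = make_table({"a": [2.0, 4.0, 6.0, 4.0]}, {})
        fit = np.array([True, True, True, False])
        out = zscore_fit_apply(t, fit)
        assert out.X["a"].iloc[3] == pytest.approx(0.0)

    def test_stats_come_only_from_fit_rows(self):
        t = make_table({"a": [0.0, 1.0, 2.0, 100.0]}, {})
        fit = np.array([True, True, True, False])
        out = zscore_fit_apply(t, fit)
        # recompute from the designated subset and compare
        assert out.norm_stats.loc["a", "mean"] == pytest.approx(1.0)
        assert out.norm_stats.loc["a", "std"] == pytest.approx(1.0)
        fitted = out.X["a"].iloc[:3]
        assert fitted.mean() == pytest.approx(0.0, abs=1e-9)
        assert fitted.var(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_zscore_before_impute_rejected(self):
        t = make_table({"a": [1.0, np.nan]}, {})
        with pytest.raises(ValueError, match="impute"):
            zscore_fit_apply(t)
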