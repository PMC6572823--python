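"""Depth-column aggregation: weights, weighted means, SOC stocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critdepth.soil_columns import (
    STUDY_COLUMNS,
    STUDY_INCREMENTS,
    AlignmentError,
    DepthColumn,
    DepthIncrement,
    MissingDataError,
    aggregate_column,
    build_column_table,
    column_weights,
    soc_stock_column,
    soc_stock_increments,
    validate_increment_table,
)
from .conftest import make_increment_table


class TestColumnWeights:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (20, [0.25, 0.25, 0.5, 0, 0, 0]),
            (5, [1, 0, 0, 0, 0, 0]),
            (50, [0.1, 0.1, 0.2, 0.2, 0.2, 0.2]),
        ],
    )
    def test_study_columns(self, column, expected):
        w = column_weights(STUDY_INCREMENTS, DepthColumn(column))
        assert np.allclose(w, expected)

    @pytest.mark.parametrize("column", STUDY_COLUMNS)
    def test_weights_sum_to_one(self, column):
        w = column_weights(STUDY_INCREMENTS, column)
        assert abs(w.sum() - 1) < 1e-12
        assert (w >= 0).all()

    def test_misaligned_column_rejected(self):
        with pytest.raises(AlignmentError):
            column_weights(STUDY_INCREMENTS, DepthColumn(17))

    def test_invalid_increment_geometry(self):
        with pytest.raises(ValueError):
            DepthIncrement(5, 5)
        with pytest.raises(ValueError):
            # gap between increments
            column_weights([DepthIncrement(0, 5), DepthIncrement(10, 20)], DepthColumn(20))


class TestAggregateColumn:
    def test_constant_profile_preserved(self):
        w = column_weights(STUDY_INCREMENTS, DepthColumn(50))
        assert aggregate_column([7.0] * 6, w) == pytest.approx(7.0)

    def test_hand_arithmetic(self):
        assert aggregate_column([4, 8, 2], [0.25, 0.25, 0.5]) == pytest.approx(4.0)

    def test_single_increment_identity(self):
        w = column_weights(STUDY_INCREMENTS, DepthColumn(5))
        assert aggregate_column([3.7, 9, 9, 9, 9, 9], w) == pytest.approx(3.7)

    def test_missing_weighted_value_raises(self):
        w = column_weights(STUDY_INCREMENTS, DepthColumn(10))
        with pytest.raises(MissingDataError):
            aggregate_column([1, np.nan, 2, 2, 2, 2], w)

    def test_missing_outside_column_ignored(self):
        w = column_weights(STUDY_INCREMENTS, DepthColumn(10))
        assert aggregate_column([1, 3, np.nan, np.nan, np.nan, np.nan], w) == pytest.approx(2.0)

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_convexity(self, values):
        """The weighted mean lies within [min, max] of contributing values."""
        for column in STUDY_COLUMNS:
            w = column_weights(STUDY_INCREMENTS, column)
            m = aggregate_column(values, w)
            active = [v for v, wi in zip(values, w) if wi > 0]
            assert min(active) - 1e-9 <= m <= max(active) + 1e-9

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    @settings(deadline=None)
    def test_nested_column_reweighting(self, values):
        """0-d2 mean equals the thickness-weighted mix of the 0-d1 mean and
        the d1-d2 increments (independent brute-force re-weighting)."""
        d1, d2 = 20.0, 50.0
        w1 = column_weights(STUDY_INCREMENTS, DepthColumn(d1))
        w2 = column_weights(STUDY_INCREMENTS, DepthColumn(d2))
        m1 = aggregate_column(values, w1)
        deep = [
            (inc.thickness, v)
            for inc, v in zip(STUDY_INCREMENTS, values)
            if inc.top >= d1 and inc.bottom <= d2
        ]
        brute = (d1 * m1 + sum(t * v for t, v in deep)) / d2
        assert aggregate_column(values, w2) == pytest.approx(brute, abs=1e-9)


class TestSocStocks:
    def test_zero_carbon(self):
        assert soc_stock_column(
            STUDY_INCREMENTS, [0] * 6, [1.2] * 6, [10] * 6, DepthColumn(50)
        ) == 0.0

    def test_all_coarse_material(self):
        assert soc_stock_column(
            STUDY_INCREMENTS, [2] * 6, [1.2] * 6, [100] * 6, DepthColumn(50)
        ) == pytest.approx(0.0)

    def test_single_increment_direct_evaluation(self):
        # 0.05 m * (1.0/10) * (1.0/1000) * 1 / 100
        terms = soc_stock_increments([DepthIncrement(0, 5)], [1.0], [1.0], [0.0])
        assert terms[0] == pytest.approx(5.0e-8, rel=1e-12)

    def test_additive_over_depth_split(self):
        rng = np.random.default_rng(7)
        ct, bd, cm = rng.uniform(0.5, 4, 6), rng.uniform(0.8, 1.5, 6), rng.uniform(0, 60, 6)
        total = soc_stock_column(STUDY_INCREMENTS, ct, bd, cm, DepthColumn(50))
        shallow = soc_stock_column(STUDY_INCREMENTS, ct, bd, cm, DepthColumn(20))
        deep_terms = soc_stock_increments(STUDY_INCREMENTS, ct, bd, cm)[3:]
        assert total == pytest.approx(shallow + deep_terms.sum(), rel=1e-12)

    def test_conventional_formula(self):
        # 5 cm * 1.2 g/cm3 * 2 mass-% * (1 - 0.1)
        terms = soc_stock_increments(
            [DepthIncrement(0, 5)], [2.0], [1.2], [10.0], formula="conventional"
        )
        assert terms[0] == pytest.approx(5 * 1.2 * 2.0 * 0.9)

    @pytest.mark.parametrize(
        "ct,bd,cm", [([-1] * 6, [1] * 6, [0] * 6), ([1] * 6, [1] * 6, [101] * 6),
                     ([1] * 6, [0] * 6, [0] * 6)]
    )
    def test_validation(self, ct, bd, cm):
        with pytest.raises(ValueError):
            soc_stock_column(STUDY_INCREMENTS, ct, bd, cm, DepthColumn(50))


class TestBuildColumnTable:
    def test_constant_property_constant_columns(self):
        table = make_increment_table({"pH": [6.1] * 6})
        out = build_column_table(table)
        assert np.allclose(out["value"], 6.1)
        assert len(out) == 6

    def test_soc_stocks_non_decreasing(self, rng):
        vals = {
            "Ct": rng.uniform(0.5, 4, (3, 6)),
            "BD": rng.uniform(0.8, 1.5, (3, 6)),
            "CM": rng.uniform(0, 60, (3, 6)),
            "SOCstocks": np.zeros((3, 6)),
        }
        table = make_increment_table(
            vals, plots=("P1", "P2", "P3"),
            cls={"Ct": "dynamic", "BD": "stable", "CM": "stable", "SOCstocks": "dynamic"},
        )
        out = build_column_table(table)
        for _, g in out[out["property"] == "SOCstocks"].groupby("plot_id"):
            stocks = g.sort_values("column_lower_cm")["value"].to_numpy()
            assert (np.diff(stocks) >= -1e-15).all()
            assert (stocks > 0).all()

    def test_output_shape_27_plots(self, rng):
        plots = tuple(f"P{i}" for i in range(27))
        table = make_increment_table({"x": rng.normal(size=(27, 6))}, plots=plots)
        out = build_column_table(table)
        assert len(out) == 27 * 6
        assert set(out["column_lower_cm"]) == {5, 10, 20, 30, 40, 50}

    def test_overlapping_increments_rejected(self):
        bad = pd.DataFrame({
            "plot_id": ["P1", "P1"], "property": ["x", "x"], "cls": ["dynamic"] * 2,
            "top_cm": [0, 4], "bottom_cm": [5, 10], "value": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="contiguous"):
            validate_increment_table(bad)

    def test_plots_must_share_increments(self):
        t1 = make_increment_table({"x": [1] * 6}, plots=("P1",))
        t2 = make_increment_table({"x": [1] * 6}, plots=("P2",)).iloc[:-1]
        with pytest.raises(ValueError, match="identical increment set"):
            validate_increment_table(pd.concat([t1, t2], ignore_index=True))
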