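"""Whole-tumor-area metrics, median splits, and stage comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from shapely.geometry import Polygon

from spatialtme import (DegenerateSplitError, Panel, RegionAnnotation,
                        UsageError, compute_wta_metrics, median_split,
                        stage_compare)
from conftest import make_cells


def _empty_cd8():
    return make_cells(np.empty((0, 2)), panel=Panel.CD8_GZMB)


class TestComputeWtaMetrics:
    def test_forced_arithmetic(self, unit_square_mm):
        tf = make_cells(np.tile([500.0, 500.0], (5, 1)),
                        markers={"FOXP3": [1] * 5, "CCR8": [1, 1, 0, 0, 0]})
        m = compute_wta_metrics(tf, _empty_cd8(), unit_square_mm)
        assert m.treg_density == pytest.approx(5.0)
        assert m.ccr8_treg_density == pytest.approx(2.0)
        assert m.pct_ccr8_in_treg == pytest.approx(40.0)

    def test_degenerate_denominators_are_missing_not_zero(self, unit_square_mm):
        tf = make_cells([[10, 10]], markers={"FOXP3": [0], "CCR8": [1]})
        m = compute_wta_metrics(tf, _empty_cd8(), unit_square_mm)
        assert m.treg_density == 0.0
        assert np.isnan(m.pct_ccr8_in_treg)
        assert np.isnan(m.ratio_cd8_over_treg)
        assert np.isnan(m.ratio_cd8_over_ccr8treg)

    def test_out_of_region_cells_excluded(self, unit_square_mm):
        tf = make_cells([[500, 500], [1500, 500]],
                        markers={"FOXP3": [1, 1], "CCR8": [1, 1]})
        m = compute_wta_metrics(tf, _empty_cd8(), unit_square_mm)
        assert m.ccr8_treg_density == pytest.approx(1.0)

    def test_simulated_case_matches_count_and_divide_oracle(self, rng):
        region = RegionAnnotation(
            [Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])])
        xy_t = rng.uniform(0, 2000, size=(250, 2))
        ccr8 = rng.uniform(size=250) < 0.4
        tf = make_cells(xy_t, markers={"FOXP3": np.ones(250, bool), "CCR8": ccr8})
        xy_c = rng.uniform(0, 2000, size=(250, 2))
        gzmb = rng.uniform(size=250) < 0.6
        cg = make_cells(xy_c, panel=Panel.CD8_GZMB,
                        markers={"CD8": np.ones(250, bool), "GZMB": gzmb})
        m = compute_wta_metrics(tf, cg, region)
        area = 4.0
        assert m.treg_density == pytest.approx(250 / area)
        assert m.ccr8_treg_density == pytest.approx(ccr8.sum() / area)
        assert m.cd8_density == pytest.approx(250 / area)
        assert m.gzmb_cd8_density == pytest.approx(gzmb.sum() / area)
        assert m.pct_ccr8_in_treg == pytest.approx(100 * ccr8.mean())
        assert m.pct_gzmb_in_cd8 == pytest.approx(100 * gzmb.mean())
        assert m.ratio_cd8_over_ccr8treg == pytest.approx(250 / ccr8.sum())

    def test_scale_invariance_of_percentages_and_ratios(self, rng):
        k = 3.0
        xy = rng.uniform(0, 1000, size=(100, 2))
        ccr8 = rng.uniform(size=100) < 0.5
        region = RegionAnnotation(
            [Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])])
        region_k = RegionAnnotation(
            [Polygon([(0, 0), (1000 * k, 0), (1000 * k, 1000 * k), (0, 1000 * k)])])
        tf = make_cells(xy, markers={"FOXP3": np.ones(100, bool), "CCR8": ccr8})
        tf_k = make_cells(xy * k, markers={"FOXP3": np.ones(100, bool), "CCR8": ccr8})
        m = compute_wta_metrics(tf, _empty_cd8(), region)
        mk = compute_wta_metrics(tf_k, _empty_cd8(), region_k)
        assert mk.treg_density == pytest.approx(m.treg_density / k ** 2)
        assert mk.ccr8_treg_density == pytest.approx(m.ccr8_treg_density / k ** 2)
        assert mk.pct_ccr8_in_treg == pytest.approx(m.pct_ccr8_in_treg)

    def test_zero_area_rejected(self):
        with pytest.raises(Exception):
            RegionAnnotation([Polygon([(0, 0), (1, 0), (2, 0)])])


class TestMedianSplit:
    def test_symmetric_split(self):
        labels = median_split({f"c{i}": float(i) for i in range(1, 9)})
        assert (labels == "HIGH").sum() == 4
        assert (labels == "LOW").sum() == 4

    def test_median_value_goes_low(self):
        labels = median_split({f"c{i}": float(i) for i in range(1, 8)})
        assert labels["c4"] == "LOW"  # the median itself
        assert (labels == "HIGH").sum() == 3
        assert (labels == "LOW").sum() == 4

    def test_eighty_distinct_values_split_forty_forty(self, rng):
        vals = {f"c{i}": v for i, v in enumerate(rng.permutation(80).astype(float))}
        labels = median_split(vals)
        assert (labels == "HIGH").sum() == 40
        assert (labels == "LOW").sum() == 40

    def test_missing_values_receive_no_label(self):
        labels = median_split({"a": 1.0, "b": 2.0, "c": np.nan, "d": 3.0})
        assert "c" not in labels.index

    def test_degenerate_and_underpowered_inputs(self):
        with pytest.raises(DegenerateSplitError):
            median_split({"a": 2.0, "b": 2.0, "c": 2.0})
        with pytest.raises(UsageError):
            median_split({"a": 1.0})

    @given(vals=hst.lists(hst.integers(min_value=0, max_value=30),
                          min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_split_properties(self, vals):
        """The split is exhaustive, ordered, and never HIGH-heavy."""
        if len(set(vals)) < 2:
            return
        series = {f"c{i}": float(v) for i, v in enumerate(vals)}
        labels = median_split(series)
        n_hi = (labels == "HIGH").sum()
        n_lo = (labels == "LOW").sum()
        assert n_hi + n_lo == len(vals)
        assert n_hi <= n_lo  # ties at the median go LOW
        hi_vals = [series[c] for c in labels.index[labels == "HIGH"]]
        lo_vals = [series[c] for c in labels.index[labels == "LOW"]]
        assert min(hi_vals, default=np.inf) > max(lo_vals)
        if len(vals) % 2 == 0 and len(set(vals)) == len(vals):
            assert n_hi == n_lo  # balanced split on even distinct values


class TestStageCompare:
    def _metrics(self, values):
        df = pd.DataFrame({"ccr8_treg_density": values},
                          index=[f"c{i}" for i in range(len(values))])
        return df

    def test_identical_distributions_give_p_one(self):
        metrics = self._metrics([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        stages = pd.Series(["I"] * 3 + ["II"] * 3, index=metrics.index)
        out = stage_compare(metrics, stages,
                            metric_columns=("ccr8_treg_density",))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_separated_stages_exact_enumeration(self):
        metrics = self._metrics([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        stages = pd.Series(["I"] * 3 + ["III"] * 3, index=metrics.index)
        out = stage_compare(metrics, stages,
                            metric_columns=("ccr8_treg_density",))
        # U = 0 and exact two-sided p = 2/C(6,3) = 0.1
        assert out["statistic"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_small_stage_skipped_with_warning(self):
        metrics = self._metrics([1.0, 2.0, 3.0, 4.0])
        stages = pd.Series(["I", "I", "I", "II"], index=metrics.index)
        with pytest.warns(UserWarning, match="skipped"):
            out = stage_compare(metrics, stages,
                                metric_columns=("ccr8_treg_density",))
        assert len(out) == 0

    def test_shifted_cohort_rejection_direction(self, rng):
        """Direction of the detected shift matches the simulated shift."""
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = r.normal(100, 10, size=20)
            b = r.normal(130, 10, size=20)  # stage III shifted upward
            metrics = self._metrics(np.concatenate([a, b]))
            stages = pd.Series(["I"] * 20 + ["III"] * 20, index=metrics.index)
            out = stage_compare(metrics, stages,
                                metric_columns=("ccr8_treg_density",))
            # U below its null mean means stage I ranks lower
            if out["p"].iloc[0] < 0.05 and out["statistic"].iloc[0] < 200:
                hits += 1
        assert hits >= 38  # ≥95% of seeds
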