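"""Distance binning, group comparisons, proliferation and re-entry tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cortexlayers as cl


def _chi2_yates_oracle(table):
    """Textbook 2x2 chi-square with Yates continuity correction."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    diff = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    return float(np.sum(diff ** 2 / expected))


class TestBinning:
    def test_boundary_assignments(self):
        bc = cl.bin_distances([0.0, 49.9, 50.0, 499.9, 500.0])
        assert bc.counts[0] == 2     # 0 and 49.9
        assert bc.counts[1] == 1     # 50.0 enters the second bin
        assert bc.counts[9] == 2     # 499.9 and the closed edge 500.0
        assert bc.overflow == 0

    def test_overflow_category(self):
        bc = cl.bin_distances([100.0, 500.0001, 720.0])
        assert bc.counts.sum() == 1
        assert bc.overflow == 2
        assert bc.total == 3

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0, 800), max_size=200), st.integers(0, 10**6))
    def test_conservation(self, distances, _seed):
        bc = cl.bin_distances(distances)
        assert bc.total == len(distances)

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError, match="non-negative"):
            cl.bin_distances([-1.0])


class TestGroupComparison:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=8), rng.normal(0.5, 1.0, size=8)
        cmp = cl.group_comparison({"a": a, "b": b})
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert cmp.f_statistic == pytest.approx(t ** 2, rel=1e-9)
        assert cmp.p_value == pytest.approx(p, rel=1e-9)

    def test_identical_groups_not_significant(self):
        vals = np.array([1.0, 2.0, 3.0])
        cmp = cl.group_comparison({"a": vals, "b": vals.copy()})
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_single_replicate_descriptive_only(self):
        cmp = cl.group_comparison({"a": [1.0], "b": [2.0, 3.0]})
        assert cmp.f_statistic is None and cmp.tukey is None
        assert cmp.means["b"] == 2.5

    def test_tukey_matches_studentized_range_oracle(self):
        """Tukey adjusted p's equal the textbook studentized-range formula."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            k, n = 4, 5
            groups = {f"g{i}": rng.normal(rng.normal(), 1.0, size=n)
                      for i in range(k)}
            cmp = cl.group_comparison(groups)
            df = k * n - k
            mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
            for _, row in cmp.tukey.iterrows():
                a, b = groups[row["group1"]], groups[row["group2"]]
                q = abs(a.mean() - b.mean()) / np.sqrt(mse / n)
                p = stats.studentized_range.sf(q, k, df)
                assert row["p_adj"] == pytest.approx(p, abs=1e-9)

    def test_oneway_anova_type_one_error_calibrated(self):
        """Rejection rate under the null ~ 5% over 1000 simulations."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = [rng.normal(size=3) for _ in range(4)]
            _, p = stats.f_oneway(*groups)
            rejections += p < 0.05
        rate = rejections / n_sim
        assert 0.03 < rate < 0.07


class TestMigrationSummary:
    def test_study_parameter_recovery(self, cells_data):
        """Tukey flags CTRL vs GB and CTRL vs GBL but not CTRL vs GL."""
        cells, rois = cells_data
        summary = cl.migration_summary(cells, rois)
        cmp = summary.distance_comparison
        assert cmp.pairwise_p("CTRL", "GB") < 0.05
        assert cmp.pairwise_p("CTRL", "GBL") < 0.05
        assert cmp.pairwise_p("CTRL", "GL") > 0.05
        assert summary.thickness_comparison.pairwise_p("CTRL", "GB") < 0.05
        assert summary.bin_anova is not None
        assert summary.bin_anova.loc["C(model)", "PR(>F)"] < 0.05

    def test_thickness_means_near_configured(self, cells_data):
        cells, rois = cells_data
        summary = cl.migration_summary(cells, rois)
        cfg = cl.CellSimConfig()
        for model, mean in summary.thickness_means.items():
            assert mean == pytest.approx(cfg.thickness_mean[model], abs=40)


class TestProliferation:
    def test_rate_arithmetic(self):
        assert cl.proliferation_rate(10, 500.0) == pytest.approx(2.0)
        assert cl.proliferation_rate(0, 123.0) == 0.0
        assert cl.proliferation_rate(20, 1000.0) == cl.proliferation_rate(10, 500.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive"):
            cl.proliferation_rate(10, 0.0)
        with pytest.raises(ValueError, match="non-negative"):
            cl.proliferation_rate(-1, 100.0)

    def test_summary_counts_marker_cells(self, cells_data):
        cells, rois = cells_data
        table, cmp = cl.proliferation_summary(cells, rois, "pHH3")
        roi = table.iloc[0]
        expected = cells[(cells["roi_id"] == roi["roi_id"]) & cells["pHH3"]].shape[0]
        assert roi["positive"] == expected
        assert cmp.means["GL"] > cmp.means["GB"]


class TestReentry:
    def test_proportional_table_is_null(self):
        res = cl.reentry_test((10, 90), (20, 180))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.fraction_ctrl == pytest.approx(res.fraction_model)

    def test_matches_textbook_yates_oracle(self):
        res = cl.reentry_test((10, 90), (20, 80))
        expected = _chi2_yates_oracle([[10, 20], [90, 80]])
        assert res.chi2 == pytest.approx(expected, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-9)

    @settings(deadline=None, max_examples=100)
    @given(st.tuples(st.integers(1, 80), st.integers(1, 80)),
           st.tuples(st.integers(1, 80), st.integers(1, 80)))
    def test_random_tables_match_oracle(self, ctrl, model):
        res = cl.reentry_test(ctrl, model)
        expected = _chi2_yates_oracle([[ctrl[0], model[0]], [ctrl[1], model[1]]])
        assert res.chi2 == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(st.tuples(st.integers(2, 60), st.integers(2, 60)),
           st.tuples(st.integers(2, 60), st.integers(2, 60)))
    def test_removing_correction_never_decreases_statistic(self, ctrl, model):
        with_c = cl.reentry_test(ctrl, model, continuity_correction=True)
        without = cl.reentry_test(ctrl, model, continuity_correction=False)
        assert without.chi2 >= with_c.chi2 - 1e-12

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="zero margin"):
            cl.reentry_test((0, 0), (5, 5))

    def test_planted_reentry_difference_detected(self, cells_data):
        cells, _ = cells_data
        res = cl.reentry_test(cl.reentry_counts(cells, "CTRL"),
                              cl.reentry_counts(cells, "GB"))
        assert res.p_value < 0.001
        assert res.fraction_model > res.fraction_ctrl


class TestPositiveCellBins:
    def test_single_replicate_means_equal_counts(self):
        cells = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"], "model": ["CTRL"] * 3,
            "timepoint": ["E14.5"] * 3, "roi_id": ["r1"] * 3,
            "distance_um": [10.0, 60.0, 110.0],
            "BrdU": [True] * 3, "Ki67": [True, True, False]})
        table = cl.bin_positive_cells(cells, "Ki67")
        assert table.loc["CTRL", "bin1"] == 1
        assert table.loc["CTRL", "bin2"] == 1
        assert table.loc["CTRL", "bin3"] == 0

    def test_scattering_spreads_counts_across_bins(self, cells_data):
        cells, _ = cells_data
        table = cl.bin_positive_cells(cells, "BrdU")
        occupied = (table > 0.5).sum(axis=1)
        assert occupied["CTRL"] >= occupied["GB"]

    def test_empty_marker_subset_gives_zero_row(self):
        cells = pd.DataFrame({
            "cell_id": ["c1"], "model": ["GB"], "timepoint": ["E14.5"],
            "roi_id": ["r1"], "distance_um": [10.0],
            "BrdU": [True], "Ki67": [False]})
        table = cl.bin_positive_cells(cells, "Ki67")
        assert (table.loc["GB"] == 0).all()
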