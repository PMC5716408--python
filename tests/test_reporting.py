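import numpy as np
import pytest

from mddiff import (
    Criteria,
    GammaOptions,
    MetricMap,
    PerturbationSpec,
    ValidationError,
    apply_perturbation,
    cohort_trend,
    criteria_sweep,
    format_report_table,
    imrt_like_field,
    make_grid,
    read_report,
    summarize_metric,
    write_report,
)

from conftest import random_imrt_pair


def small_pair(seed=41):
    rng = np.random.default_rng(seed)
    return random_imrt_pair(rng, extent=20.0)[:2]


class TestSummarizeMetric:
    def test_all_zero_mddiff_map(self, criteria):
        m = MetricMap(np.zeros((10, 10)), np.ones((10, 10), bool), "mddiff")
        s = summarize_metric(m, criteria)
        assert s.total_points == 100
        assert s.failing_points == 0 and s.failing_ratio == 0.0
        assert s.mean == s.mean_abs == s.max_abs == 0.0

    def test_enumerated_mddiff_values(self, criteria):
        vals = np.array([[3.0, -3.0], [0.0, 0.0]])
        s = summarize_metric(MetricMap(vals, np.ones((2, 2), bool), "mddiff"), criteria)
        assert s.failing_points == 2
        assert s.failing_ratio == pytest.approx(0.5)
        assert s.mean == pytest.approx(0.0)
        assert s.mean_abs == pytest.approx(1.5)
        assert s.max_abs == pytest.approx(3.0)

    def test_enumerated_gamma_values(self, criteria):
        vals = np.array([[0.5, 1.5]])
        s = summarize_metric(MetricMap(vals, np.ones((1, 2), bool), "gamma"), criteria)
        assert s.failing_points == 1
        assert s.failing_ratio == pytest.approx(0.5)
        assert s.mean == pytest.approx(1.0)
        assert s.max_abs == pytest.approx(1.5)

    def test_summary_invariants_on_random_maps(self, criteria):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vals = rng.normal(0, 3, (8, 8))
            mask = rng.random((8, 8)) < 0.9
            if not mask.any():
                continue
            s = summarize_metric(MetricMap(vals, mask, "mddiff"), criteria)
            assert 0 <= s.failing_points <= s.total_points
            assert s.failing_ratio == pytest.approx(s.failing_points / s.total_points)
            assert s.mean_abs >= abs(s.mean) - 1e-12
            assert s.max_abs >= s.mean_abs - 1e-12

    def test_empty_mask_raises(self, criteria):
        m = MetricMap(np.zeros((3, 3)), np.zeros((3, 3), bool), "mddiff")
        with pytest.raises(ValidationError):
            summarize_metric(m, criteria)


class TestCriteriaSweep:
    def test_identical_pair_all_zero(self):
        ref = imrt_like_field([((8, 8), (8, 8), 150.0)], 1.5, 1.0, 16.0)
        crits = [Criteria(v, 3.0, 200.0) for v in (3.0, 6.0, 9.0)]
        tab = criteria_sweep(ref, ref, crits, "dd",
                             gamma_options=GammaOptions(search_radius=5.0,
                                                        subsample_factor=1))
        assert (tab["gamma_failing"] == 0).all()
        assert (tab["mddiff_failing"] == 0).all()

    def test_counts_non_increasing_with_dose_criterion(self):
        ref, ev = small_pair()
        crits = [Criteria(v, 3.0, 200.0) for v in (2.0, 4.0, 6.0, 8.0)]
        tab = criteria_sweep(ev, ref, crits, "dd",
                             gamma_options=GammaOptions(subsample_factor=2))
        assert (tab["gamma_failing"].diff().dropna() <= 0).all()
        assert (tab["mddiff_failing"].diff().dropna() <= 0).all()

    def test_counts_non_increasing_with_dta_criterion(self):
        ref, ev = small_pair(seed=43)
        crits = [Criteria(6.0, v, 200.0) for v in (1.0, 2.0, 3.0, 4.0)]
        tab = criteria_sweep(ev, ref, crits, "dta",
                             gamma_options=GammaOptions(search_radius=8.0,
                                                        subsample_factor=2))
        assert (tab["gamma_failing"].diff().dropna() <= 0).all()
        assert (tab["mddiff_failing"].diff().dropna() <= 0).all()

    def test_flat_offset_gamma_count_drops_at_offset(self):
        """On a flat pair offset by 6 cGy, gamma = 6/dD0: everything fails
        up to 6 cGy (gamma >= 1 is inclusive) and nothing beyond it."""
        ref = make_grid(np.full((9, 9), 100.0), (1.0, 1.0))
        ev = make_grid(np.full((9, 9), 106.0), (1.0, 1.0))
        crits = [Criteria(v, 3.0, 200.0) for v in (4.0, 6.0, 6.5, 8.0)]
        tab = criteria_sweep(ev, ref, crits, "dd",
                             gamma_options=GammaOptions(search_radius=3.0,
                                                        subsample_factor=1))
        counts = tab["gamma_failing"].tolist()
        assert counts[0] == counts[1] > 0  # gamma = 1.0 at 6 cGy still fails
        assert counts[2] == counts[3] == 0

    def test_unsorted_sweep_rejected(self):
        ref, ev = small_pair()
        crits = [Criteria(v, 3.0, 200.0) for v in (6.0, 3.0)]
        with pytest.raises(ValidationError):
            criteria_sweep(ev, ref, crits, "dd")

    def test_non_fixed_other_criterion_rejected(self):
        ref, ev = small_pair()
        crits = [Criteria(3.0, 3.0, 200.0), Criteria(6.0, 4.0, 200.0)]
        with pytest.raises(ValidationError):
            criteria_sweep(ev, ref, crits, "dd")

    def test_unknown_sweep_axis_rejected(self):
        ref, ev = small_pair()
        with pytest.raises(ValidationError):
            criteria_sweep(ev, ref, [Criteria(6.0, 3.0, 200.0)], "prescribed")


class TestCohortTrend:
    def test_fewer_than_two_cases_rejected(self, criteria):
        with pytest.raises(ValidationError):
            cohort_trend([], criteria)

    def test_identical_pairs_have_undefined_correlation(self, criteria):
        ref = imrt_like_field([((8, 8), (8, 8), 150.0)], 1.5, 1.0, 16.0)
        df, rho = cohort_trend([(ref, ref), (ref, ref)], criteria,
                               gamma_options=GammaOptions(search_radius=5.0,
                                                          subsample_factor=1))
        assert (df["gamma_ratio"] == 0).all()
        assert (df["mddiff_ratio"] == 0).all()
        assert rho is None

    def test_gross_shift_ranks_worse_under_both_methods(self, criteria):
        ref = imrt_like_field([((12, 12), (12, 12), 200.0)], 2.0, 1.0, 24.0)
        bad = apply_perturbation(ref, PerturbationSpec(shift=(5.0, 0.0)))
        df, _ = cohort_trend([(ref, ref), (ref, bad)], criteria,
                             gamma_options=GammaOptions(search_radius=6.0,
                                                        subsample_factor=2))
        assert df["gamma_ratio"][1] > df["gamma_ratio"][0]
        assert df["mddiff_ratio"][1] > df["mddiff_ratio"][0]


class TestReportIO:
    def test_round_trip(self, criteria, tmp_path):
        ref, ev = small_pair(seed=47)
        from mddiff import compare_pair

        stats = compare_pair(ev, ref, criteria,
                             gamma_options=GammaOptions(subsample_factor=2))
        path = tmp_path / "report.json"
        table = write_report(stats, path, criteria, case_id="QA1")
        case_id, crit2, stats2 = read_report(path)
        assert case_id == "QA1"
        assert crit2.dose_diff_criterion == pytest.approx(criteria.dose_diff_criterion)
        assert stats2 == stats

    def test_table_mentions_both_methods(self, criteria):
        ref, ev = small_pair(seed=47)
        from mddiff import compare_pair

        stats = compare_pair(ev, ref, criteria,
                             gamma_options=GammaOptions(subsample_factor=2))
        table = format_report_table(stats, case_id="QA1")
        assert "gamma >= 1" in table
        assert "MDdiff" in table
        assert "(ratio)" in table
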