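import math

import numpy as np
import pytest

from neuroseg.evaluation import (
    bland_altman,
    cohort_summary,
    correlate_volumes,
    paired_two_tailed_t,
    stratified_median_dice,
    volume_dice_correlation,
    wmh_prevalence,
)
from neuroseg.metrics import MetricReport, RegionMetrics


def _report(case_id, dice_v, truth_vol, region="WMH", pred_vol=None):
    rep = MetricReport(case_id=case_id)
    rep.regions[region] = RegionMetrics(
        dice=dice_v, hausdorff95=0.0,
        predicted_volume_mm3=pred_vol if pred_vol is not None else truth_vol,
        truth_volume_mm3=truth_vol,
    )
    return rep


class TestCorrelateVolumes:
    def test_identical_lists_give_r_one(self):
        res = correlate_volumes([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r == pytest.approx(1.0)

    def test_negated_list_gives_r_minus_one(self):
        res = correlate_volumes([1, 2, 3], [-1, -2, -3])
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        """Pearson r recomputed from the raw product-moment formula."""
        a = [12.0, 5.0, 33.0, 8.0, 21.0, 14.0, 2.0, 27.0, 19.0, 7.0]
        b = [10.0, 9.0, 30.0, 11.0, 17.0, 18.0, 5.0, 22.0, 15.0, 12.0]
        am, bm = np.mean(a), np.mean(b)
        num = sum((x - am) * (y - bm) for x, y in zip(a, b))
        den = math.sqrt(
            sum((x - am) ** 2 for x in a) * sum((y - bm) ** 2 for y in b)
        )
        res = correlate_volumes(a, b, method="pearson")
        assert res.r == pytest.approx(num / den, abs=1e-12)
        assert res.n == 10

    def test_affine_invariance(self):
        a = [1.0, 4.0, 2.0, 9.0, 5.0]
        b = [2.0, 3.0, 7.0, 1.0, 6.0]
        r0 = correlate_volumes(a, b).r
        r1 = correlate_volumes([3 * x + 10 for x in a], b).r
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = correlate_volumes([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined

    def test_spearman_is_rank_based(self):
        a = [1.0, 10.0, 100.0, 1000.0]
        b = [2.0, 3.0, 5.0, 20.0]
        assert correlate_volumes(a, b, "spearman").r == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            correlate_volumes([1, 2, 3], [1, 2])


class TestBlandAltman:
    def test_identical_measurements(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert res.lower_limit == res.upper_limit == 0.0

    def test_constant_offset(self):
        res = bland_altman([6.0, 7.0, 8.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(5.0)
        assert res.lower_limit == pytest.approx(5.0)
        assert res.upper_limit == pytest.approx(5.0)

    def test_matches_bruteforce_mean_sd(self, rng):
        a = rng.normal(10, 2, size=20)
        b = rng.normal(9, 2, size=20)
        res = bland_altman(a, b)
        d = a - b
        sd = math.sqrt(sum((x - d.mean()) ** 2 for x in d) / (len(d) - 1))
        assert res.bias == pytest.approx(d.mean())
        assert res.upper_limit == pytest.approx(d.mean() + 1.96 * sd)
        assert res.lower_limit == pytest.approx(d.mean() - 1.96 * sd)

    def test_limits_cover_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, size=10_000)
        b = rng.normal(0, 1, size=10_000)
        res = bland_altman(a, b)
        d = a - b
        frac = np.mean((d >= res.lower_limit) & (d <= res.upper_limit))
        assert abs(frac - 0.95) < 0.01


class TestWmhPrevalence:
    def test_boundary_inclusive_counts(self):
        counts = wmh_prevalence([0, 50, 100, 2000], [100, 1000])
        assert counts == [2, 1]

    def test_empty_cohort(self):
        assert wmh_prevalence([], [100, 1000]) == [0, 0]

    def test_zero_threshold_counts_everything(self):
        assert wmh_prevalence([0.0, 5.0, 1.0], [0]) == [3]

    def test_monotone_and_order_invariant(self, rng):
        vols = rng.uniform(0, 15000, size=50)
        thresholds = [100, 1000, 5000, 10000]
        counts = wmh_prevalence(vols, thresholds)
        assert counts == sorted(counts, reverse=True)
        assert counts == wmh_prevalence(vols[::-1], thresholds)


class TestStratifiedMedianDice:
    def test_constant_dice_in_every_stratum(self):
        reports = [_report(f"c{i}", 0.5, v) for i, v in
                   enumerate([150, 1200, 5600, 11000])]
        summary = stratified_median_dice(reports, "WMH")
        for s in summary.strata:
            assert s.median_dice == pytest.approx(0.5)

    def test_nested_strata_counts_non_increasing(self):
        vols = [50, 150, 800, 1500, 6000, 12000]
        reports = [_report(f"c{i}", 0.4, v) for i, v in enumerate(vols)]
        summary = stratified_median_dice(reports, "WMH")
        ns = [s.n for s in summary.strata]
        assert ns == sorted(ns, reverse=True)
        assert ns == [5, 3, 2, 1]

    def test_dice_increasing_with_volume_gives_nondecreasing_medians(self):
        vols = [200.0 * (i + 1) ** 2 for i in range(12)]
        reports = [
            _report(f"c{i}", 0.1 + 0.07 * i, v) for i, v in enumerate(vols)
        ]
        summary = stratified_median_dice(reports, "WMH")
        meds = [s.median_dice for s in summary.strata if s.n]
        assert meds == sorted(meds)

    def test_empty_stratum_flagged(self):
        reports = [_report("a", 0.3, 500), _report("b", 0.6, 700)]
        summary = stratified_median_dice(reports, "WMH", [100, 99999])
        assert summary.strata[1].n == 0
        assert math.isnan(summary.strata[1].median_dice)

    def test_even_stratum_median_is_central_mean(self):
        reports = [_report("a", 0.2, 500), _report("b", 0.6, 700)]
        summary = stratified_median_dice(reports, "WMH", [100])
        assert summary.strata[0].median_dice == pytest.approx(0.4)


class TestVolumeDiceCorrelation:
    def test_log_transform_strengthens_log_linear_relation(self):
        """When Dice is a noisy linear function of log10 volume over a wide
        dynamic range, r on the log scale exceeds r on the raw scale."""
        rng = np.random.default_rng(5)
        vols = 10 ** rng.uniform(1.5, 4.5, size=60)
        dices = np.clip(
            0.2 * (np.log10(vols) - 1) + rng.normal(0, 0.03, 60), 0, 1
        )
        reports = [
            _report(f"c{i}", d, v) for i, (d, v) in enumerate(zip(dices, vols))
        ]
        raw = volume_dice_correlation(reports, "WMH", log10=False)
        logr = volume_dice_correlation(reports, "WMH", log10=True)
        assert logr.r > raw.r

    def test_zero_volume_cases_excluded_and_counted(self):
        reports = [_report(f"c{i}", 0.1 * i, 100.0 * i) for i in range(5)]
        res = volume_dice_correlation(reports, "WMH", log10=True)
        assert res.n_excluded == 1
        assert res.n == 4

    def test_constant_dice_flagged(self):
        reports = [_report(f"c{i}", 0.5, 100.0 + i) for i in range(5)]
        res = volume_dice_correlation(reports, "WMH")
        assert not res.defined

    def test_too_few_cases_raises(self):
        reports = [_report("a", 0.5, 100), _report("b", 0.7, 200)]
        with pytest.raises(ValueError):
            volume_dice_correlation(reports, "WMH")


class TestPairedT:
    def test_identical_lists(self):
        res = paired_two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_difference_flagged(self):
        res = paired_two_tailed_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert not res.defined

    def test_matches_textbook_t_and_p(self):
        """t recomputed from the mean/sd formula and the t CDF."""
        from scipy import stats

        a = [3.1, 2.8, 3.6, 3.0, 2.5, 3.3, 3.9, 2.7]
        b = [2.9, 2.9, 3.1, 2.6, 2.4, 3.0, 3.2, 2.8]
        d = np.subtract(a, b)
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_ref = 2 * stats.t.sf(abs(t_ref), df=len(d) - 1)
        res = paired_two_tailed_t(a, b)
        assert res.statistic == pytest.approx(t_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)
        assert res.n == 8

    def test_nan_pairs_dropped(self):
        res = paired_two_tailed_t(
            [1.0, float("nan"), 3.0, 5.0], [0.5, 2.0, 2.0, 4.8]
        )
        assert res.n == 3


class TestCohortSummary:
    def test_summary_recomputable_and_serialisable(self):
        import json

        rng = np.random.default_rng(2)
        reports = []
        for i in range(12):
            rep = MetricReport(case_id=f"c{i}")
            for region in ("WT", "TC", "ET", "WMH"):
                vol = float(rng.uniform(100, 10000))
                rep.regions[region] = RegionMetrics(
                    dice=float(rng.uniform(0.3, 1.0)),
                    hausdorff95=float(rng.uniform(0, 10)),
                    predicted_volume_mm3=vol * float(rng.uniform(0.8, 1.2)),
                    truth_volume_mm3=vol,
                )
            reports.append(rep)
        summary = cohort_summary(reports)
        json.dumps(summary)  # must be serialisable
        assert summary["n_cases"] == 12
        assert set(summary["wmh_prevalence"]) == {"100", "1000", "5000", "10000"}
        assert summary["regions"]["WT"]["median_dice"] is not None
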