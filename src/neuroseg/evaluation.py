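"""Cohort-level statistical analyses of segmentation performance.

Covers the analyses used to characterise a multi-disease segmentation
model: predicted-vs-reference volume correlation (Pearson or Spearman),
Bland-Altman agreement, lesion-burden prevalence counts at fixed volume
thresholds, volume-stratified median Dice, the volume-Dice relationship
(optionally on a log10 volume scale), and the paired two-tailed t-test
comparing per-case metrics between two models.

Conventions: threshold comparisons are inclusive ("at least X mm^3");
cases with undefined (NaN) metrics are excluded from aggregates and their
count is surfaced; the median of an even-sized group is the mean of the
two central order statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .metrics import MetricReport

#: the WMH-burden thresholds (mm^3) used for prevalence and stratification
DEFAULT_THRESHOLDS_MM3: tuple[float, ...] = (100.0, 1000.0, 5000.0, 10000.0)


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p_value: float
    n: int
    n_excluded: int = 0  # zero/NaN-volume cases dropped before log10

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    lower_limit: float
    upper_limit: float
    differences: tuple[float, ...]
    means: tuple[float, ...]


@dataclass(frozen=True)
class StratumSummary:
    threshold_mm3: float
    n: int
    median_dice: float  # NaN for an empty stratum


@dataclass(frozen=True)
class StratifiedDiceSummary:
    region: str
    strata: tuple[StratumSummary, ...]


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.statistic)


def correlate_volumes(
    a: Sequence[float], b: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two equal-length volume lists, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if a.std() == 0 or b.std() == 0:
        return CorrelationResult(method, float("nan"), float("nan"), len(a))
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r), float(p), len(a))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Agreement between paired measurements: bias = mean(a-b) and
    bias +/- 1.96 * sd(a-b) limits (sample sd, n-1 denominator)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        differences=tuple(diff),
        means=tuple((a + b) / 2.0),
    )


def wmh_prevalence(
    volumes: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_MM3,
) -> list[int]:
    """Count of cases with lesion volume >= each threshold (inclusive)."""
    v = np.asarray(volumes, dtype=float)
    return [int(np.count_nonzero(v >= t)) for t in thresholds]


def _region_values(
    reports: Iterable[MetricReport], region: str
) -> tuple[np.ndarray, np.ndarray]:
    dices, vols = [], []
    for rep in reports:
        m = rep.regions[region]
        dices.append(m.dice)
        vols.append(m.truth_volume_mm3)
    return np.asarray(dices, dtype=float), np.asarray(vols, dtype=float)


def stratified_median_dice(
    reports: Sequence[MetricReport],
    region: str,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_MM3,
) -> StratifiedDiceSummary:
    """Median Dice over cases whose reference volume meets each threshold.

    Cases with undefined Dice are excluded.  An empty stratum yields a NaN
    median with n = 0.
    """
    dices, vols = _region_values(reports, region)
    ok = ~np.isnan(dices)
    strata = []
    for t in thresholds:
        sel = ok & (vols >= t)
        n = int(sel.sum())
        med = float(np.median(dices[sel])) if n else float("nan")
        strata.append(StratumSummary(float(t), n, med))
    return StratifiedDiceSummary(region=region, strata=tuple(strata))


def volume_dice_correlation(
    reports: Sequence[MetricReport],
    region: str,
    log10: bool = False,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between reference lesion volume and Dice for a region.

    With ``log10=True``, zero-volume cases are excluded (their count is
    reported in ``n_excluded``) and volumes are log10-transformed.
    """
    dices, vols = _region_values(reports, region)
    ok = ~np.isnan(dices)
    n_excluded = 0
    if log10:
        pos = vols > 0
        n_excluded = int((ok & ~pos).sum())
        ok &= pos
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable cases")
    x = np.log10(vols[ok]) if log10 else vols[ok]
    res = correlate_volumes(x, dices[ok], method=method)
    return CorrelationResult(res.method, res.r, res.p_value, res.n, n_excluded)


def paired_two_tailed_t(
    a: Sequence[float], b: Sequence[float]
) -> PairedTestResult:
    """Paired two-tailed t-test (one-sample t on the differences vs 0).

    Pairs with a NaN in either list are dropped.  Zero-variance differences
    yield an undefined (NaN) result, except the all-zero case which is the
    degenerate "no difference" outcome (t = 0, p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(a) | np.isnan(b))
    diff = a[ok] - b[ok]
    if len(diff) < 2:
        raise ValueError("need at least 2 complete pairs")
    if diff.std(ddof=1) == 0:
        if np.all(diff == 0):
            return PairedTestResult(0.0, 1.0, len(diff))
        return PairedTestResult(float("nan"), float("nan"), len(diff))
    t, p = stats.ttest_1samp(diff, 0.0)
    return PairedTestResult(float(t), float(p), len(diff))


def cohort_summary(
    reports: Sequence[MetricReport],
    regions: Sequence[str] = ("WT", "TC", "ET", "WMH"),
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_MM3,
) -> dict:
    """JSON-serialisable summary of a cohort's per-case metric reports."""
    out: dict = {"n_cases": len(reports), "regions": {}}
    for region in regions:
        dices, vols = _region_values(reports, region)
        hd = np.asarray(
            [rep.regions[region].hausdorff95 for rep in reports], dtype=float
        )
        pred_vols = np.asarray(
            [rep.regions[region].predicted_volume_mm3 for rep in reports],
            dtype=float,
        )
        ok_d, ok_h = ~np.isnan(dices), ~np.isnan(hd)
        entry: dict = {
            "median_dice": float(np.median(dices[ok_d])) if ok_d.any() else None,
            "median_hd95": float(np.median(hd[ok_h])) if ok_h.any() else None,
            "n_undefined_dice": int((~ok_d).sum()),
            "n_undefined_hd95": int((~ok_h).sum()),
        }
        if ok_d.sum() >= 3 and np.std(vols[ok_d]) > 0:
            vol_r = correlate_volumes(vols[ok_d], pred_vols[ok_d])
            entry["volume_pearson_r"] = vol_r.r
            ba = bland_altman(pred_vols[ok_d], vols[ok_d])
            entry["bland_altman"] = {
                "bias": ba.bias,
                "lower_limit": ba.lower_limit,
                "upper_limit": ba.upper_limit,
            }
        out["regions"][region] = entry
    if "WMH" in regions:
        _, wmh_vols = _region_values(reports, "WMH")
        out["wmh_prevalence"] = {
            str(int(t)): c
            for t, c in zip(thresholds, wmh_prevalence(wmh_vols, thresholds))
        }
        strat = stratified_median_dice(reports, "WMH", thresholds)
        out["wmh_stratified_median_dice"] = {
            str(int(s.threshold_mm3)): (
                None if math.isnan(s.median_dice) else s.median_dice
            )
            for s in strat.strata
        }
    return out
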