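"""Segmentation metrics: confusion counts, Dice, 95th-percentile Hausdorff.

Metrics are computed per evaluation region.  The composite tumor regions
follow the challenge convention on on-disk label codes:

    WT (whole tumor)      = {1, 2, 4}   (NCR + ED + AT; WMH excluded)
    TC (tumor core)       = {1, 4}      (NCR + AT)
    ET (enhancing tumor)  = {4}
    WMH                   = {3}

Dice = 2*TP / (2*TP + FP + FN).  The Hausdorff95 distance extracts each
mask's surface (mask voxels with at least one face-adjacent background
neighbor, 6-connectivity), computes both directed sets of Euclidean
nearest-surface distances in mm, and reports the maximum of the two
directed 95th percentiles (linear interpolation between order statistics).
A pooled variant (95th percentile of the union of both directed sets) is
available via ``method="pooled"``.

Empty-mask policy: Dice of two empty masks and HD95 with any empty mask
are reported as undefined (NaN) and excluded from cohort aggregates;
Dice of an empty vs a nonempty mask is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: face-adjacency structuring element used for surface extraction
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RegionSpec:
    name: str
    label_codes: frozenset[int]


WT = RegionSpec("WT", frozenset({1, 2, 4}))
TC = RegionSpec("TC", frozenset({1, 4}))
ET = RegionSpec("ET", frozenset({4}))
ED_REGION = RegionSpec("ED", frozenset({2}))
NCR_REGION = RegionSpec("NCR", frozenset({1}))
WMH_REGION = RegionSpec("WMH", frozenset({3}))

DEFAULT_REGIONS: tuple[RegionSpec, ...] = (WT, TC, ET, WMH_REGION)

REGION_BY_NAME = {
    r.name: r for r in (WT, TC, ET, ED_REGION, NCR_REGION, WMH_REGION)
}


@dataclass
class RegionMetrics:
    dice: float  # NaN when undefined
    hausdorff95: float  # NaN when undefined
    predicted_volume_mm3: float
    truth_volume_mm3: float


@dataclass
class MetricReport:
    case_id: str
    regions: dict[str, RegionMetrics] = field(default_factory=dict)


def region_mask(labels: np.ndarray, region: RegionSpec) -> np.ndarray:
    """Binary mask of voxels whose on-disk code belongs to the region."""
    return np.isin(labels, sorted(region.label_codes))


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts, empty_value: float = float("nan")) -> float:
    """2TP/(2TP+FP+FN); ``empty_value`` is returned for the 0/0 case
    (two empty masks) — NaN by default, 1.0 for the portal-style convention."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return empty_value
    return 2.0 * c.tp / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n, 3) of mask voxels with a face-adjacent background
    neighbor; voxels on the array border count as surface."""
    mask = mask.astype(bool)
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff95(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    method: str = "max_directed",
) -> float:
    """Symmetric 95th-percentile surface distance in mm.

    ``method="max_directed"`` (default): max of the two directed 95th
    percentiles.  ``method="pooled"``: 95th percentile of the pooled
    directed distance set.  NaN when either mask is empty.
    """
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    if not pred.any() or not truth.any():
        return float("nan")
    sp = np.asarray(spacing, dtype=float)
    ps = surface_voxels(pred) * sp
    ts = surface_voxels(truth) * sp
    d_pt = cKDTree(ts).query(ps, k=1)[0]
    d_tp = cKDTree(ps).query(ts, k=1)[0]
    if method == "max_directed":
        return float(
            max(np.percentile(d_pt, 95), np.percentile(d_tp, 95))
        )
    if method == "pooled":
        return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))
    raise ValueError(f"unknown method {method!r}")


def evaluate_case(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    regions: Iterable[RegionSpec] = DEFAULT_REGIONS,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    case_id: str = "",
) -> MetricReport:
    """Per-region Dice, HD95 and volumes for one case (labels as codes)."""
    if pred_labels.shape != truth_labels.shape:
        raise ValueError("geometry mismatch between prediction and truth")
    voxel_mm3 = float(np.prod(spacing))
    report = MetricReport(case_id=case_id)
    for region in regions:
        pm = region_mask(pred_labels, region)
        tm = region_mask(truth_labels, region)
        c = confusion(pm, tm)
        report.regions[region.name] = RegionMetrics(
            dice=dice(c),
            hausdorff95=hausdorff95(pm, tm, spacing),
            predicted_volume_mm3=float(pm.sum()) * voxel_mm3,
            truth_volume_mm3=float(tm.sum()) * voxel_mm3,
        )
    return report


def reports_to_records(reports: Iterable[MetricReport]) -> list[dict]:
    """Flatten reports into rows suitable for a tidy CSV/DataFrame."""
    rows = []
    for rep in reports:
        for name, m in rep.regions.items():
            rows.append(
                {
                    "case_id": rep.case_id,
                    "region": name,
                    "dice": m.dice,
                    "hd95": m.hausdorff95,
                    "pred_vol_mm3": m.predicted_volume_mm3,
                    "truth_vol_mm3": m.truth_volume_mm3,
                }
            )
    return rows
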