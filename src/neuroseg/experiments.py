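"""Reproducible scaled-down phantom studies.

These are the package's built-in end-to-end experiments: they generate a
seeded phantom cohort, train compact U-Net variants on CPU, and evaluate
held-out performance.  Problem sizes (64- or 48-voxel grids, 2-level
networks with 8 base filters, tens of epochs) are chosen so a study runs
in minutes on a single core while still exercising every stage of the
pipeline — they are scaled-down counterparts of the full-resolution
protocol (240x240x155 grids, 4 levels, 32 filters, 600 epochs), not a
replication of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluation, io_brats, metrics, phantom, unet
from .patches import PatchSpec

#: training protocol shared by the scaled-down studies
STUDY_PATCH_EDGE = 32
STUDY_LEVELS = 2
STUDY_BASE_FILTERS = 8
STUDY_LR = 3e-3
STUDY_EPOCHS = 30
STUDY_PATCHES_PER_EPOCH = 16
#: the 4- vs 5-class comparison trains 2-member ensembles (prediction
#: averaging, as in the full-scale protocol) of smaller patches
COMPARISON_PATCH_EDGE = 24
COMPARISON_EPOCHS = 28
COMPARISON_PATCHES_PER_EPOCH = 24
COMPARISON_ENSEMBLE_SIZE = 2


def _cohort_64(n: int, master_seed: int) -> list[phantom.PhantomCase]:
    """Default study cohort: 64-cubes whose WMH burden spans the strata of
    the 100/1000/5000/10000 mm^3 analysis thresholds."""
    tmpl = phantom.PhantomSpec(
        wmh=phantom.WMHSpec(
            count_range=(1, 4), target_total_volume_mm3=(0.0, 12000.0)
        )
    )
    return phantom.generate_cohort(n, tmpl, master_seed)


def _train_and_eval(
    train_cases: list[io_brats.MpMRICase],
    test_cases: list[phantom.PhantomCase],
    n_classes: int,
    seed: int,
    patch_edge: int,
    epochs: int = STUDY_EPOCHS,
    patches_per_epoch: int = STUDY_PATCHES_PER_EPOCH,
    ensemble_size: int = 1,
) -> list[metrics.MetricReport]:
    if n_classes == 4:
        train_cases = [
            io_brats.with_labels(
                c, io_brats.remap_label_codes(c.labels, {3: 0})
            )
            for c in train_cases
        ]
    ucfg = unet.UNetConfig(
        n_classes=n_classes, levels=STUDY_LEVELS, base_filters=STUDY_BASE_FILTERS
    )
    tcfg = unet.TrainConfig(
        initial_lr=STUDY_LR,
        epochs=epochs,
        patches_per_epoch=patches_per_epoch,
        batch_size=2,
        ensemble_size=ensemble_size,
        seed=seed,
    )
    ensemble = unet.train_ensemble(
        train_cases, ucfg, tcfg, PatchSpec(edge=patch_edge)
    )
    reports = []
    for pc in test_cases:
        _, codes = unet.predict_case(ensemble, pc.case)
        reports.append(
            metrics.evaluate_case(
                codes,
                pc.case.labels,
                spacing=pc.case.spacing,
                case_id=pc.case_id,
            )
        )
    return reports


@dataclass
class EndToEndResult:
    reports: list[metrics.MetricReport]
    median_wt_dice: float
    median_wmh_dice: float
    median_wt_hd95: float
    wt_volume_pearson_r: float


def end_to_end_study(
    master_seed: int, n_cases: int = 20, n_test: int = 5
) -> EndToEndResult:
    """Train a 5-class model on a 64-cube phantom cohort and evaluate the
    held-out cases: the pipeline's basic learnability check."""
    cohort = _cohort_64(n_cases, master_seed)
    reports = _train_and_eval(
        [pc.case for pc in cohort[: n_cases - n_test]],
        cohort[n_cases - n_test :],
        n_classes=5,
        seed=master_seed + 1,
        patch_edge=STUDY_PATCH_EDGE,
    )
    wt = np.array([r.regions["WT"].dice for r in reports])
    wmh = np.array([r.regions["WMH"].dice for r in reports])
    hd = np.array([r.regions["WT"].hausdorff95 for r in reports])
    truth_v = [r.regions["WT"].truth_volume_mm3 for r in reports]
    pred_v = [r.regions["WT"].predicted_volume_mm3 for r in reports]
    corr = evaluation.correlate_volumes(truth_v, pred_v)
    return EndToEndResult(
        reports=reports,
        median_wt_dice=float(np.nanmedian(wt)),
        median_wmh_dice=float(np.nanmedian(wmh)),
        median_wt_hd95=float(np.nanmedian(hd)),
        wt_volume_pearson_r=corr.r,
    )


@dataclass
class ClassComparisonResult:
    median_wt_hd95_5class: float
    median_wt_hd95_4class: float
    per_case_hd95_5class: list[float]
    per_case_hd95_4class: list[float]

    @property
    def five_class_no_worse(self) -> bool:
        return self.median_wt_hd95_5class <= self.median_wt_hd95_4class


def class_comparison_study(
    master_seed: int,
    n_cases: int = 24,
    n_test: int = 10,
    epochs: int = COMPARISON_EPOCHS,
) -> ClassComparisonResult:
    """4- vs 5-class comparison on a WMH-rich cohort.

    Every case carries at least two distal WMH blobs.  The 4-class variant
    trains on the same cases with WMH relabelled to background (the label
    set the original tumor-only annotation provides).  Both variants share
    the training protocol — a 2-member ensemble with softmax averaging —
    and held-out whole-tumor HD95 medians are compared.
    """
    tmpl = phantom.PhantomSpec(
        grid_shape=(64, 64, 64),
        wmh=phantom.WMHSpec(
            count_range=(2, 4), target_total_volume_mm3=(1500.0, 9000.0)
        ),
    )
    cohort = phantom.generate_cohort(n_cases, tmpl, master_seed)
    train = [pc.case for pc in cohort[: n_cases - n_test]]
    test = cohort[n_cases - n_test :]
    hd = {}
    for n_classes in (5, 4):
        reports = _train_and_eval(
            train,
            test,
            n_classes=n_classes,
            seed=master_seed + n_classes,
            patch_edge=COMPARISON_PATCH_EDGE,
            epochs=epochs,
            patches_per_epoch=COMPARISON_PATCHES_PER_EPOCH,
            ensemble_size=COMPARISON_ENSEMBLE_SIZE,
        )
        hd[n_classes] = [r.regions["WT"].hausdorff95 for r in reports]
    return ClassComparisonResult(
        median_wt_hd95_5class=float(np.nanmedian(hd[5])),
        median_wt_hd95_4class=float(np.nanmedian(hd[4])),
        per_case_hd95_5class=hd[5],
        per_case_hd95_4class=hd[4],
    )
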