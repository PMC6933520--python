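"""Independent brute-force reference implementations used only by tests.

These deliberately avoid every vectorised shortcut used by the package:
surfaces come from an explicit 6-neighbour loop, distances from the full
all-pairs matrix, and confusion counts from a per-voxel Python tally.
"""

from __future__ import annotations

import numpy as np

_FACE_NEIGHBORS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
]


def brute_confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for idx in np.ndindex(pred.shape):
        p, t = bool(pred[idx]), bool(truth[idx])
        if p and t:
            tp += 1
        elif p:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    tp, fp, fn, _ = brute_confusion(pred, truth)
    denom = 2 * tp + fp + fn
    return float("nan") if denom == 0 else 2.0 * tp / denom


def brute_surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face-adjacent background (or out-of-grid) voxel."""
    coords = []
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for d in _FACE_NEIGHBORS:
            nb = tuple(i + o for i, o in zip(idx, d))
            if any(n < 0 or n >= s for n, s in zip(nb, shape)) or not mask[nb]:
                coords.append(idx)
                break
    return np.asarray(coords, dtype=float)


def brute_hd95(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    method: str = "max_directed",
) -> float:
    if not pred.any() or not truth.any():
        return float("nan")
    sp = np.asarray(spacing)
    ps = brute_surface(pred) * sp
    ts = brute_surface(truth) * sp
    dmat = np.sqrt(((ps[:, None, :] - ts[None, :, :]) ** 2).sum(axis=2))
    d_pt = dmat.min(axis=1)
    d_tp = dmat.min(axis=0)
    if method == "max_directed":
        return float(max(np.percentile(d_pt, 95), np.percentile(d_tp, 95)))
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


def random_mask_pair(
    rng: np.random.Generator, max_edge: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Random nonempty mask pair: blobby (thresholded smoothed noise) or sparse."""
    shape = tuple(rng.integers(3, max_edge + 1, size=3))
    while True:
        if rng.random() < 0.5:
            a = rng.random(shape) < rng.uniform(0.05, 0.5)
            b = rng.random(shape) < rng.uniform(0.05, 0.5)
        else:
            from scipy import ndimage

            a = ndimage.gaussian_filter(rng.normal(size=shape), 1.2) > rng.uniform(-0.2, 0.4)
            b = ndimage.gaussian_filter(rng.normal(size=shape), 1.2) > rng.uniform(-0.2, 0.4)
        if a.any() and b.any():
            return a, b
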