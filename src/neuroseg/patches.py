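"""Training-patch sampling and train-time augmentation.

Patch centerpoints follow the 90/10 rule: with probability
``lesion_fraction`` (default 0.9) a center is drawn uniformly from lesion
voxels, otherwise uniformly from the whole brain mask.  Extracted patches
are fixed-size cubes; regions falling outside the image grid are zero-filled
(background for labels), matching the zero-padded convolution convention.

Augmentation is a random left-right flip followed by a constrained affine
warp: rotation up to 45 degrees about each axis, per-axis scaling within
+/-25 %, shear coefficients within +/-0.1.  Images are resampled trilinearly,
labels nearest-neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .io_brats import MpMRICase


class Provenance(str, Enum):
    LESION = "lesion"
    BRAIN = "brain"


@dataclass(frozen=True)
class PatchSpec:
    edge: int = 80
    lesion_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.lesion_fraction <= 1.0):
            raise ValueError("lesion_fraction must be in [0, 1]")
        if self.edge < 8 or self.edge % 2:
            raise ValueError("edge must be even and >= 8")


@dataclass(frozen=True)
class AugmentSpec:
    flip_lr: bool = True
    max_rotation_deg: float = 45.0
    scale_low: float = 0.75
    scale_high: float = 1.25
    max_shear: float = 0.1

    def __post_init__(self) -> None:
        if not (self.scale_low <= 1.0 <= self.scale_high):
            raise ValueError("scale range must bracket 1")
        if self.max_rotation_deg < 0 or self.max_shear < 0:
            raise ValueError("maxima must be non-negative")


@dataclass(frozen=True)
class AugmentParams:
    """One realised draw of the augmentation transform."""

    flip: bool
    rotation_deg: tuple[float, float, float]
    scales: tuple[float, float, float]
    shears: tuple[float, float, float]

    @property
    def is_identity(self) -> bool:
        return (
            not self.flip
            and all(a == 0 for a in self.rotation_deg)
            and all(s == 1 for s in self.scales)
            and all(s == 0 for s in self.shears)
        )


@dataclass
class Patch:
    image: np.ndarray  # (4, edge, edge, edge) float32
    labels: np.ndarray  # (edge, edge, edge) integer class indices or codes
    center: tuple[int, int, int]
    provenance: Provenance


def sample_center(
    case: MpMRICase, spec: PatchSpec, rng: np.random.Generator
) -> tuple[tuple[int, int, int], Provenance]:
    """Draw a patch centerpoint per the lesion/brain sampling rule.

    Falls back to brain-uniform sampling when the case has no lesion voxels.
    """
    brain = case.brain_coords
    if len(brain) == 0:
        raise ValueError(f"{case.case_id}: empty brain mask")
    lesion = case.lesion_coords
    use_lesion = len(lesion) > 0 and rng.random() < spec.lesion_fraction
    pool, prov = (
        (lesion, Provenance.LESION) if use_lesion else (brain, Provenance.BRAIN)
    )
    idx = rng.integers(len(pool))
    return tuple(int(v) for v in pool[idx]), prov


def extract_patch(
    case: MpMRICase,
    center: tuple[int, int, int],
    spec: PatchSpec,
    provenance: Provenance = Provenance.BRAIN,
) -> Patch:
    """Cut the ``edge``-cube centred on ``center``; out-of-grid regions are
    zero-filled (images) / background (labels)."""
    e = spec.edge
    half = e // 2
    shape = case.shape
    image = np.zeros((4, e, e, e), dtype=np.float32)
    labels = np.zeros((e, e, e), dtype=np.uint8)
    src = []
    dst = []
    for ax in range(3):
        lo = center[ax] - half
        hi = lo + e
        s_lo, s_hi = max(lo, 0), min(hi, shape[ax])
        if s_lo >= s_hi:
            return Patch(image, labels, tuple(center), provenance)
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    image[(slice(None),) + tuple(dst)] = case.channels[(slice(None),) + tuple(src)]
    if case.labels is not None:
        labels[tuple(dst)] = case.labels[tuple(src)]
    return Patch(image, labels, tuple(center), provenance)


def draw_augment(rng: np.random.Generator, spec: AugmentSpec) -> AugmentParams:
    """Draw flip/rotation/scale/shear parameters within the spec's bounds."""
    flip = bool(rng.random() < 0.5) if spec.flip_lr else False
    rot = tuple(
        float(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
        for _ in range(3)
    )
    scales = tuple(
        float(rng.uniform(spec.scale_low, spec.scale_high)) for _ in range(3)
    )
    shears = tuple(
        float(rng.uniform(-spec.max_shear, spec.max_shear)) for _ in range(3)
    )
    return AugmentParams(flip, rot, scales, shears)


def _affine_matrix(params: AugmentParams) -> np.ndarray:
    """3x3 voxel-space matrix: rotation @ shear @ scale."""
    ax, ay, az = np.deg2rad(params.rotation_deg)
    rx = np.array(
        [[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]]
    )
    ry = np.array(
        [[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]]
    )
    rz = np.array(
        [[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]]
    )
    sxy, sxz, syz = params.shears
    shear = np.array([[1, sxy, sxz], [0, 1, syz], [0, 0, 1]])
    scale = np.diag(params.scales)
    return rz @ ry @ rx @ shear @ scale


def apply_augment(patch: Patch, params: AugmentParams) -> Patch:
    """Apply flip then affine warp about the patch center.

    Trilinear interpolation for image channels, nearest-neighbor for labels
    (never creates label values absent from the input).  Identity parameters
    return the patch bit-unchanged.
    """
    image, labels = patch.image, patch.labels
    if params.flip:
        image = np.flip(image, axis=1).copy()
        labels = np.flip(labels, axis=0).copy()
    affine_is_identity = (
        all(a == 0 for a in params.rotation_deg)
        and all(s == 1 for s in params.scales)
        and all(s == 0 for s in params.shears)
    )
    if not affine_is_identity:
        m = _affine_matrix(params)
        c = (np.array(labels.shape) - 1) / 2.0
        offset = c - m @ c
        warped = np.empty_like(image)
        for ch in range(image.shape[0]):
            warped[ch] = ndimage.affine_transform(
                image[ch], m, offset=offset, order=1, mode="constant", cval=0.0
            )
        image = warped
        labels = ndimage.affine_transform(
            labels, m, offset=offset, order=0, mode="constant", cval=0
        )
    return Patch(image, labels, patch.center, patch.provenance)
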