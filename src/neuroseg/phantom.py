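"""Synthetic multi-parametric MRI phantoms with glioma + WMH ground truth.

Each phantom emulates the layout of a preprocessed brain-tumor case: a
skull-stripped ellipsoidal brain at 1 mm isotropic spacing containing

* a contiguous tumor complex — a necrotic core (NCR, code 1) inside an
  enhancing active-tumor rim (AT, code 4) inside an edema envelope
  (ED, code 2), built from concentric jittered ellipsoids so the nesting
  NCR ⊂ AT ⊂ ED holds by construction;
* a small central "ventricle" with CSF-like intensities (labelled
  background) that provides a periventricular surface for lesion placement;
* zero or more distal white-matter-hyperintensity blobs (WMH, code 3),
  placed in deep white matter or along the ventricular surface, at a
  minimum distance from the tumor complex.

Channel intensities follow a per-class profile over (T1, T1PC, T2, FLAIR)
chosen to reproduce the radiological relationships the segmentation task
hinges on: AT enhances (brightest class on T1PC), NCR is dark on T1PC,
ED and WMH are both bright on T2/FLAIR and nearly iso-intense to each
other, while WMH shows no contrast enhancement.  Distinguishing WMH from
edema therefore requires multi-channel evidence plus spatial context —
the core difficulty of the multi-disease segmentation problem.
Additive Gaussian noise (single sd, all channels, brain voxels only)
controls task hardness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_brats import DEFAULT_AFFINE, MpMRICase, write_case

#: label codes
BG, NCR, ED, WMH, AT = 0, 1, 2, 3, 4

#: mean intensity per tissue class and channel (T1, T1PC, T2, FLAIR),
#: arbitrary units.  "brain" and "ventricle" are unlabelled (background)
#: tissue classes that only shape the images.
DEFAULT_INTENSITY_PROFILE: Mapping[str, tuple[float, float, float, float]] = {
    "brain": (70.0, 70.0, 40.0, 45.0),
    "ventricle": (25.0, 25.0, 95.0, 20.0),
    "ncr": (35.0, 25.0, 70.0, 55.0),
    "ed": (55.0, 60.0, 75.0, 80.0),
    "wmh": (50.0, 68.0, 75.0, 80.0),
    "at": (60.0, 95.0, 65.0, 65.0),
}

_CLASS_OF_CODE = {NCR: "ncr", ED: "ed", WMH: "wmh", AT: "at"}

#: hard-mode profile: WMH voxelwise indistinguishable from edema, so the
#: tumor/WMH decision rests entirely on spatial context — the regime in
#: which an explicit WMH class matters most.
AMBIGUOUS_WMH_PROFILE: Mapping[str, tuple[float, float, float, float]] = {
    **DEFAULT_INTENSITY_PROFILE,
    "wmh": DEFAULT_INTENSITY_PROFILE["ed"],
}


class InfeasibleSpecError(ValueError):
    """The requested lesion geometry cannot be realised inside the brain."""


@dataclass(frozen=True)
class TumorSpec:
    """Concentric tumor geometry in mm (radii of the nested ellipsoids)."""

    ncr_radius_mm: float = 4.0
    at_rim_mm: float = 2.5
    ed_margin_mm: float = 3.5
    #: tumor center is drawn inside this fraction of the brain semi-axes,
    #: offset into one hemisphere so WMH can sit contralaterally
    center_fraction: float = 0.45

    @property
    def outer_radius_mm(self) -> float:
        return self.ncr_radius_mm + self.at_rim_mm + self.ed_margin_mm


@dataclass(frozen=True)
class WMHSpec:
    """Distal WMH burden: blob count, size and placement constraints."""

    count_range: tuple[int, int] = (1, 4)
    radius_range_mm: tuple[float, float] = (2.0, 4.0)
    min_distance_from_tumor_mm: float = 6.0
    #: when set, total WMH volume is drawn from this range and blob radii are
    #: derived from it (overriding radius_range_mm)
    target_total_volume_mm3: tuple[float, float] | None = None


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    brain_radius_fraction: float = 0.42
    tumor: TumorSpec = field(default_factory=TumorSpec)
    wmh: WMHSpec = field(default_factory=WMHSpec)
    intensity_profile: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_PROFILE)
    )
    noise_sd: float = 3.0
    seed: int = 0


@dataclass
class PhantomCase:
    """A generated case together with its spec and realised class volumes."""

    case: MpMRICase
    spec: PhantomSpec
    volumes_mm3: dict[int, float]

    @property
    def case_id(self) -> str:
        return self.case.case_id


def _ellipsoid_mask(
    shape: Sequence[int], center: np.ndarray, semi_axes: np.ndarray
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return r2 <= 1.0


def _jitter(rng: np.random.Generator, lo: float = 0.85, hi: float = 1.15) -> np.ndarray:
    return rng.uniform(lo, hi, size=3)


def min_profile_gap(
    profile: Mapping[str, tuple[float, float, float, float]],
    classes: Sequence[str] | None = None,
) -> float:
    """Smallest Euclidean distance between two class intensity profiles."""
    names = list(classes) if classes is not None else list(profile)
    gaps = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            gaps.append(
                float(np.linalg.norm(np.subtract(profile[a], profile[b])))
            )
    return min(gaps)


def _place_tumor(
    spec: PhantomSpec,
    brain: np.ndarray,
    ventricle: np.ndarray,
    brain_center: np.ndarray,
    brain_semi: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (ncr, at, ed) masks; AT/ED returned as filled regions."""
    t = spec.tumor
    if t.outer_radius_mm >= brain_semi.min():
        raise InfeasibleSpecError("tumor outer radius exceeds brain semi-axis")
    for _ in range(300):
        # offset into the +x hemisphere; a tumor may displace the ventricle
        frac = rng.uniform(-t.center_fraction, t.center_fraction, size=3)
        frac[0] = abs(frac[0]) * 0.7 + 0.2
        center = brain_center + frac * brain_semi
        jit = _jitter(rng)
        ncr = _ellipsoid_mask(spec.grid_shape, center, t.ncr_radius_mm * jit)
        at = _ellipsoid_mask(
            spec.grid_shape, center, (t.ncr_radius_mm + t.at_rim_mm) * jit
        )
        ed = _ellipsoid_mask(spec.grid_shape, center, t.outer_radius_mm * jit)
        if not ncr.any():
            continue
        if (ed & ~brain).any():
            continue
        return ncr, at, ed
    raise InfeasibleSpecError("could not place tumor inside the brain")


def _wmh_blob_radii(spec: WMHSpec, rng: np.random.Generator) -> list[float]:
    lo, hi = spec.count_range
    if spec.target_total_volume_mm3 is not None:
        target = rng.uniform(*spec.target_total_volume_mm3)
        return _radii_for_target(target, spec, rng)
    count = int(rng.integers(lo, hi + 1))
    return [float(rng.uniform(*spec.radius_range_mm)) for _ in range(count)]


#: largest practical single-blob volume (radius ~6.5 mm) — bigger targets
#: are split across more blobs so they still fit the brain interior
_MAX_BLOB_VOLUME_MM3 = 1150.0


def _radii_for_target(
    target: float, spec: WMHSpec, rng: np.random.Generator
) -> list[float]:
    if target <= 0:
        return []
    lo, hi = spec.count_range
    count = max(1, lo, int(np.ceil(target / _MAX_BLOB_VOLUME_MM3)))
    if count <= hi:
        count = int(rng.integers(max(1, lo), hi + 1))
        count = max(count, int(np.ceil(target / _MAX_BLOB_VOLUME_MM3)))
    # inflate slightly: voxelisation and brain/ventricle clipping shave volume
    per_blob = 1.08 * target / count
    radii = []
    for _ in range(count):
        v = per_blob * rng.uniform(0.9, 1.1)
        radii.append((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0))
    return radii


def _place_wmh(
    spec: PhantomSpec,
    radii: list[float],
    brain: np.ndarray,
    ventricle: np.ndarray,
    tumor: np.ndarray,
    brain_center: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Union of WMH blobs: periventricular and deep-white-matter sites,
    disjoint from tumor (by the spec's minimum distance), ventricle and brain
    boundary."""
    wmh = np.zeros_like(brain)
    if not radii:
        return wmh
    # distances in mm (voxels are 1 mm isotropic)
    dist_tumor = ndimage.distance_transform_edt(~tumor)
    dist_outside = ndimage.distance_transform_edt(brain)
    periventricular = (
        ndimage.binary_dilation(ventricle, iterations=2) & ~ventricle & brain
    )
    pv_coords = np.argwhere(periventricular)
    allowed = brain & ~ventricle
    min_dist = spec.wmh.min_distance_from_tumor_mm
    for r in sorted(radii, reverse=True):
        placed = False
        for attempt in range(600):
            # progressively shrink the blob if placement keeps failing
            r_eff = r * (1.0 if attempt < 300 else 0.75 if attempt < 480 else 0.55)
            if rng.random() < 0.4 and len(pv_coords):
                center = pv_coords[rng.integers(len(pv_coords))].astype(float)
            else:
                center = np.array(
                    [rng.uniform(2, s - 3) for s in spec.grid_shape]
                )
            c = tuple(np.clip(np.round(center).astype(int), 0,
                              np.array(spec.grid_shape) - 1))
            if not allowed[c]:
                continue
            # most of the blob must lie inside the brain (clipped afterwards)
            if dist_outside[c] < max(2.0, 0.6 * r_eff):
                continue
            if dist_tumor[c] < 1.1 * r_eff + min_dist:
                continue
            blob = _ellipsoid_mask(
                spec.grid_shape, center, r_eff * _jitter(rng, 0.9, 1.1)
            )
            blob &= allowed
            if not blob.any():
                continue
            # keep blobs separated so each stays its own connected component
            near = ndimage.binary_dilation(
                blob, structure=np.ones((3, 3, 3), dtype=bool)
            )
            if (near & wmh).any():
                continue
            wmh |= blob
            placed = True
            break
        if not placed:
            raise InfeasibleSpecError(
                f"could not place WMH blob of radius {r:.1f} mm"
            )
    return wmh


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Deterministically synthesise one case from ``spec`` (seed included)."""
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.grid_shape)
    center = (shape - 1) / 2.0
    brain_semi = spec.brain_radius_fraction * shape
    brain = _ellipsoid_mask(spec.grid_shape, center, brain_semi)
    ventricle = _ellipsoid_mask(
        spec.grid_shape,
        center,
        brain_semi * np.array([0.22, 0.45, 0.30]),
    )

    ncr, at_core, ed_full = _place_tumor(
        spec, brain, ventricle, center, brain_semi, rng
    )
    tumor = ed_full
    radii = _wmh_blob_radii(spec.wmh, rng)
    wmh = _place_wmh(spec, radii, brain, ventricle, tumor, center, rng)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[ed_full] = ED
    labels[at_core] = AT
    labels[ncr] = NCR
    labels[wmh] = WMH

    profile = spec.intensity_profile
    channels = np.zeros((4,) + spec.grid_shape, dtype=np.float32)
    tissue = {
        "brain": brain & ~ventricle & (labels == BG),
        "ventricle": ventricle & (labels == BG),
        "ncr": labels == NCR,
        "ed": labels == ED,
        "wmh": labels == WMH,
        "at": labels == AT,
    }
    for name, mask in tissue.items():
        means = profile[name]
        for ch in range(4):
            channels[ch][mask] = means[ch]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=channels.shape).astype(
            np.float32
        )
        channels += noise * brain[None]
        # keep the skull-stripped-zero background convention exact
        channels[:, ~brain] = 0.0
        # brain voxels must stay nonzero so the mask survives the round trip
        low = brain[None] & (channels < 0.5)
        channels[low] = 0.5

    case = MpMRICase(
        case_id=f"phantom-{spec.seed:08d}",
        channels=channels,
        labels=labels,
        affine=DEFAULT_AFFINE.copy(),
    )
    voxel_mm3 = float(np.prod(case.spacing))
    volumes = {
        code: float((labels == code).sum()) * voxel_mm3
        for code in (NCR, ED, WMH, AT)
    }
    return PhantomCase(case=case, spec=spec, volumes_mm3=volumes)


def generate_cohort(
    n: int, spec_template: PhantomSpec, master_seed: int
) -> list[PhantomCase]:
    """Generate ``n`` cases with per-case seeds derived from ``master_seed``.

    When the template requests a target total WMH volume range, per-case
    targets are spread evenly (then shuffled) across that range so that
    volume-stratified analyses at the 100/1000/5000/10000 mm^3 thresholds
    are populated rather than left to sampling luck.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    targets: list[tuple[float, float] | None] = [None] * n
    if spec_template.wmh.target_total_volume_mm3 is not None:
        lo, hi = spec_template.wmh.target_total_volume_mm3
        grid = lo + (np.arange(n) + 0.5) * (hi - lo) / n
        rng.shuffle(grid)
        targets = [(float(v), float(v)) for v in grid]

    cohort = []
    for i in range(n):
        wmh = spec_template.wmh
        if targets[i] is not None:
            wmh = replace(wmh, target_total_volume_mm3=targets[i])
        spec = replace(spec_template, wmh=wmh, seed=int(seeds[i]))
        pc = generate_phantom(spec)
        pc.case.case_id = f"phantom-{master_seed:04d}-{i:03d}"
        cohort.append(pc)
    return cohort


def write_cohort(
    cohort: Sequence[PhantomCase], out_dir: Path | str
) -> Path:
    """Write BraTS-layout case directories plus a manifest CSV."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pc in cohort:
        write_case(pc.case, out / pc.case_id)
        rows.append(
            {
                "case_id": pc.case_id,
                "seed": pc.spec.seed,
                "ncr_mm3": pc.volumes_mm3[NCR],
                "ed_mm3": pc.volumes_mm3[ED],
                "wmh_mm3": pc.volumes_mm3[WMH],
                "at_mm3": pc.volumes_mm3[AT],
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
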