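"""Reading, writing and label handling for BraTS-style multi-parametric MRI cases.

A case is a directory of four co-registered, skull-stripped NIfTI channels
(``_t1``, ``_t1ce``, ``_t2``, ``_flair``) plus an optional integer label
volume (``_seg``).  On-disk label codes follow the BraTS convention with the
white-matter-hyperintensity (WMH) extension::

    0 background, 1 necrotic core (NCR), 2 edema (ED), 3 WMH, 4 active tumor (AT)

Networks operate on contiguous class indices; :class:`LabelCodec` maps
between the two representations for the 4-class (no WMH) and 5-class
variants.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

#: fixed channel order used throughout the package
CHANNEL_NAMES = ("t1", "t1ce", "t2", "flair")

#: data grid is stored in LPS axis order (x: left-right, y: anterior-posterior,
#: z: inferior-superior) at 1 mm isotropic spacing; nibabel affines are RAS
#: so the default affine negates the first two axes.
DEFAULT_AFFINE = np.diag([-1.0, -1.0, 1.0, 1.0])


class UnknownLabelCodeError(ValueError):
    """A label volume contains a code outside the codec's code set."""


class GeometryMismatchError(ValueError):
    """Two volumes of one case disagree in shape or spacing."""


class MissingChannelError(FileNotFoundError):
    """A required channel NIfTI file is absent from a case directory."""


@dataclass(frozen=True)
class LabelCodec:
    """Bijection between contiguous class indices and on-disk label codes.

    ``code_of_index[i]`` is the on-disk code of class index ``i``; index 0 is
    always background (code 0).  The 4-class variant drops WMH (code 3), so
    active tumor (code 4) becomes index 3 — the only non-trivial remap.
    """

    code_of_index: tuple[int, ...]

    def __post_init__(self) -> None:
        codes = self.code_of_index
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be distinct")
        if codes[0] != 0:
            raise ValueError("class index 0 must map to background code 0")

    @classmethod
    def four_class(cls) -> "LabelCodec":
        return cls(code_of_index=(0, 1, 2, 4))

    @classmethod
    def five_class(cls) -> "LabelCodec":
        return cls(code_of_index=(0, 1, 2, 3, 4))

    @property
    def n_classes(self) -> int:
        return len(self.code_of_index)

    @property
    def index_of_code(self) -> Mapping[int, int]:
        return {c: i for i, c in enumerate(self.code_of_index)}

    def validate_codes(self, raw: np.ndarray) -> None:
        present = np.unique(raw)
        unknown = set(int(v) for v in present) - set(self.code_of_index)
        if unknown:
            raise UnknownLabelCodeError(
                f"label codes {sorted(unknown)} not in codec set {self.code_of_index}"
            )

    def encode(self, raw: np.ndarray) -> np.ndarray:
        """On-disk codes -> contiguous class indices (vectorised LUT)."""
        self.validate_codes(raw)
        lut = np.zeros(max(self.code_of_index) + 1, dtype=np.uint8)
        for idx, code in enumerate(self.code_of_index):
            lut[code] = idx
        return lut[raw.astype(np.int64)]

    def decode(self, indices: np.ndarray) -> np.ndarray:
        """Contiguous class indices -> on-disk codes."""
        indices = np.asarray(indices)
        if indices.size and (indices.min() < 0 or indices.max() >= self.n_classes):
            raise ValueError(
                f"class index out of range for {self.n_classes}-class codec"
            )
        lut = np.asarray(self.code_of_index, dtype=np.uint8)
        return lut[indices.astype(np.int64)]


def encode_labels(raw: np.ndarray, codec: LabelCodec) -> np.ndarray:
    return codec.encode(raw)


def decode_labels(indices: np.ndarray, codec: LabelCodec) -> np.ndarray:
    return codec.decode(indices)


def remap_label_codes(labels: np.ndarray, mapping: Mapping[int, int]) -> np.ndarray:
    """Replace on-disk codes per ``mapping`` (codes not mentioned pass through).

    The common use is ``{3: 0}``: discard WMH annotations so a case can be
    used to train/evaluate the 4-class model, mirroring the original BraTS
    labels in which WMH is unannotated background.
    """
    out = labels.copy()
    for src, dst in mapping.items():
        out[labels == src] = dst
    return out


@dataclass(eq=False)
class MpMRICase:
    """One subject: four channel volumes, optional labels, shared geometry.

    ``channels`` is a ``(4, X, Y, Z)`` float array in the fixed order
    (T1, T1PC, T2, FLAIR); ``labels`` holds on-disk codes.  The brain mask is
    the union of nonzero voxels across channels (images are skull-stripped
    with exact-zero background).
    """

    case_id: str
    channels: np.ndarray
    labels: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: DEFAULT_AFFINE.copy())

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError("channels must have shape (4, X, Y, Z)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.shape:
                raise GeometryMismatchError(
                    f"labels shape {self.labels.shape} != channel shape {self.shape}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.channels.shape[1:])

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @cached_property
    def brain_mask(self) -> np.ndarray:
        return (self.channels != 0).any(axis=0)

    @cached_property
    def brain_coords(self) -> np.ndarray:
        return np.argwhere(self.brain_mask)

    @cached_property
    def lesion_coords(self) -> np.ndarray:
        if self.labels is None:
            return np.empty((0, 3), dtype=np.int64)
        return np.argwhere(self.labels != 0)


@dataclass(frozen=True)
class PaddingRecord:
    """Book-keeping for the zero-padding applied before patching/inference."""

    original_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]
    pad_before: tuple[int, int, int]
    pad_after: tuple[int, int, int]

    def __post_init__(self) -> None:
        for o, p, b, a in zip(
            self.original_shape, self.padded_shape, self.pad_before, self.pad_after
        ):
            if p != o + b + a:
                raise ValueError("padding arithmetic does not reconcile shapes")


def pad_case(case: MpMRICase, patch_edge: int) -> tuple[MpMRICase, PaddingRecord]:
    """Zero-pad each axis up to the next multiple of ``patch_edge``.

    All padding is appended at the high-index end of each axis so original
    voxel coordinates are preserved (e.g. the canonical 240x240x155 grid grows
    to 240x240x160 for an 80-voxel patch).  Added voxels are zero in every
    channel and background in the labels.
    """
    if patch_edge < 1:
        raise ValueError("patch_edge must be >= 1")
    shape = case.shape
    padded = tuple(-(-s // patch_edge) * patch_edge for s in shape)
    after = tuple(p - s for p, s in zip(padded, shape))
    rec = PaddingRecord(shape, padded, (0, 0, 0), after)
    pad_width = [(0, 0)] + [(0, a) for a in after]
    channels = np.pad(case.channels, pad_width)
    labels = None
    if case.labels is not None:
        labels = np.pad(case.labels, pad_width[1:])
    return MpMRICase(case.case_id, channels, labels, case.affine.copy()), rec


def crop_case(case: MpMRICase, record: PaddingRecord) -> MpMRICase:
    """Inverse of :func:`pad_case`."""
    sl = tuple(
        slice(b, b + o)
        for b, o in zip(record.pad_before, record.original_shape)
    )
    channels = case.channels[(slice(None),) + sl]
    labels = case.labels[sl] if case.labels is not None else None
    return MpMRICase(case.case_id, channels, labels, case.affine.copy())


def crop_volume(volume: np.ndarray, record: PaddingRecord) -> np.ndarray:
    """Crop a single padded 3-D grid back to the original extent."""
    sl = tuple(
        slice(b, b + o) for b, o in zip(record.pad_before, record.original_shape)
    )
    return volume[sl]


def _find_channel_file(directory: Path, suffix: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        hits = sorted(directory.glob(f"*_{suffix}{ext}"))
        if hits:
            return hits[0]
    return None


def read_case(directory_path: os.PathLike | str, codec: LabelCodec) -> MpMRICase:
    """Load a BraTS-layout case directory, validating geometry and label codes."""
    directory = Path(directory_path)
    imgs = []
    affine = None
    shape = None
    for suffix in CHANNEL_NAMES:
        path = _find_channel_file(directory, suffix)
        if path is None:
            raise MissingChannelError(f"no *_{suffix}.nii[.gz] in {directory}")
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        if shape is None:
            shape, affine = data.shape, img.affine
        else:
            if data.shape != shape:
                raise GeometryMismatchError(
                    f"{path.name}: shape {data.shape} != {shape}"
                )
            if not np.allclose(img.affine, affine, atol=1e-4):
                raise GeometryMismatchError(f"{path.name}: affine mismatch")
        imgs.append(data)

    labels = None
    seg_path = _find_channel_file(directory, "seg")
    if seg_path is not None:
        seg_img = nib.load(str(seg_path))
        labels = np.asarray(seg_img.dataobj).astype(np.uint8)
        if labels.shape != shape:
            raise GeometryMismatchError(
                f"{seg_path.name}: shape {labels.shape} != {shape}"
            )
        codec.validate_codes(labels)

    return MpMRICase(directory.name, np.stack(imgs), labels, np.asarray(affine))


def write_case(case: MpMRICase, directory_path: os.PathLike | str) -> Path:
    """Write a case as a BraTS-layout directory of NIfTI files."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    for name, vol in zip(CHANNEL_NAMES, case.channels):
        nib.save(
            nib.Nifti1Image(np.asarray(vol, dtype=np.float32), case.affine),
            str(directory / f"{case.case_id}_{name}.nii.gz"),
        )
    if case.labels is not None:
        nib.save(
            nib.Nifti1Image(case.labels.astype(np.uint8), case.affine),
            str(directory / f"{case.case_id}_seg.nii.gz"),
        )
    return directory


def write_label_volume(
    labels: np.ndarray,
    codec: LabelCodec,
    reference_affine: np.ndarray,
    path: os.PathLike | str,
) -> Path:
    """Decode class indices to on-disk codes and save as uint8 NIfTI."""
    codes = codec.decode(labels)
    nib.save(nib.Nifti1Image(codes.astype(np.uint8), reference_affine), str(path))
    return Path(path)


def with_labels(case: MpMRICase, labels: np.ndarray | None) -> MpMRICase:
    """Copy of ``case`` with its label grid replaced."""
    return MpMRICase(case.case_id, case.channels, labels, case.affine.copy())
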