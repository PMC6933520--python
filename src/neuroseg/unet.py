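"""3-D U-Net architecture, training loop and whole-volume inference.

The network is an encoder-decoder with skip connections.  Each level block
is two nodes of [3x3x3 convolution (stride 1, zero padded) -> ReLU -> batch
norm]; channel counts start at ``base_filters`` in the outermost level and
double at each deeper level.  Downsampling is 2x2x2 max pooling, upsampling
a 2x2x2 stride-2 transposed convolution; encoder outputs are concatenated
onto the matching decoder inputs.  A final 1x1x1 convolution maps to
per-voxel class scores for either 4 classes (background, NCR, ED, AT) or
5 classes (adding WMH).

Training follows the reference recipe: Xavier initialization, Adam with a
2nd-order polynomial learning-rate decay ``lr(e) = lr0 * (1 - e/E)^2``,
unweighted voxelwise cross-entropy, patches sampled 90 % within lesions /
10 % within brain, optional flip+affine augmentation.  Inference runs the
full (zero-padded) volume through each ensemble member, averages the
softmax probabilities, and takes the voxelwise argmax (ties broken toward
the lowest class index).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _nn
from .io_brats import LabelCodec, MpMRICase, crop_volume, pad_case
from .patches import (
    AugmentSpec,
    PatchSpec,
    apply_augment,
    draw_augment,
    extract_patch,
    sample_center,
)


@dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 4
    n_classes: int = 5
    levels: int = 4
    base_filters: int = 32

    def __post_init__(self) -> None:
        if self.levels < 1 or self.base_filters < 1:
            raise ValueError("levels and base_filters must be >= 1")
        if self.n_classes not in (4, 5):
            raise ValueError("n_classes must be 4 or 5")

    @property
    def divisor(self) -> int:
        """Input edges must be divisible by this (one halving per pooling)."""
        return 2 ** (self.levels - 1)

    def codec(self) -> LabelCodec:
        return (
            LabelCodec.four_class()
            if self.n_classes == 4
            else LabelCodec.five_class()
        )


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-4
    epochs: int = 600
    lr_decay_power: int = 2
    folds: int = 10
    ensemble_size: int = 10
    batch_size: int = 2
    patches_per_epoch: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.folds < 2:
            raise ValueError("epochs >= 1 and folds >= 2 required")
        if self.initial_lr <= 0 or self.batch_size < 1:
            raise ValueError("rates and sizes must be positive")


class LabelConfigMismatchError(ValueError):
    """A training label code is not representable under the model's classes."""


def channel_plan(cfg: UNetConfig) -> list[int]:
    """Per-level filter counts: base_filters doubling at each level."""
    return [cfg.base_filters * 2**level for level in range(cfg.levels)]


def _conv_node(c_in: int, c_out: int, rng) -> list:
    # node order as specified: convolution -> ReLU -> batch normalization
    return [_nn.Conv3d(c_in, c_out, 3, rng), _nn.ReLU(), _nn.BatchNorm3d(c_out)]


class UNet3D:
    """Functional 3-D U-Net over the numpy layer stack in :mod:`neuroseg._nn`."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = channel_plan(cfg)
        L = cfg.levels
        self.enc = []
        for i in range(L):
            c_in = cfg.in_channels if i == 0 else ch[i - 1]
            self.enc.append(
                _nn.Sequential(*_conv_node(c_in, ch[i], rng), *_conv_node(ch[i], ch[i], rng))
            )
        self.pools = [_nn.MaxPool3d() for _ in range(L - 1)]
        self.ups = [
            _nn.ConvTranspose3d(ch[i + 1], ch[i], rng) for i in range(L - 1)
        ]
        self.dec = [
            _nn.Sequential(
                *_conv_node(2 * ch[i], ch[i], rng), *_conv_node(ch[i], ch[i], rng)
            )
            for i in range(L - 1)
        ]
        self.final = _nn.Conv3d(ch[0], cfg.n_classes, 1, rng)
        self._skip_channels = ch

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        return [*self.enc, *self.pools, *self.ups, *self.dec, self.final]

    def params(self) -> list[_nn.Param]:
        return [p for m in self._modules() for p in m.params()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for m in self._modules() for p in m.params()]
        arrays += [b for m in self._modules() for b in m.buffers()]
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state array count mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("state array shape mismatch")
            dst[...] = src

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if any(s % self.cfg.divisor for s in x.shape[2:]):
            raise ValueError(
                f"spatial extents {x.shape[2:]} must be divisible by "
                f"{self.cfg.divisor} for {self.cfg.levels} levels"
            )
        L = self.cfg.levels
        skips = []
        h = x
        for i in range(L):
            h = self.enc[i].forward(h, train)
            if i < L - 1:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for i in reversed(range(L - 1)):
            h = self.ups[i].forward(h, train)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec[i].forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        L = self.cfg.levels
        dh = self.final.backward(dlogits)
        dskips = [None] * (L - 1)
        for i in range(L - 1):
            dh = self.dec[i].backward(dh)
            c = self._skip_channels[i]
            dskips[i] = dh[:, :c]
            dh = self.ups[i].backward(np.ascontiguousarray(dh[:, c:]))
        # dh now flows into the bottom encoder level
        for i in reversed(range(L)):
            if i < L - 1:
                dh = self.pools[i].backward(dh)
                dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)


@dataclass
class TrainedEnsemble:
    members: list[UNet3D]
    ucfg: UNetConfig
    tcfg: TrainConfig
    histories: list[list[float]] = field(default_factory=list)

    def save(self, directory: Path | str) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "ucfg": self.ucfg.__dict__,
            "tcfg": self.tcfg.__dict__,
            "n_members": len(self.members),
            "histories": self.histories,
        }
        (d / "ensemble.json").write_text(json.dumps(meta, indent=2))
        for i, m in enumerate(self.members):
            np.savez(
                d / f"member_{i:02d}.npz",
                **{f"a{j}": a for j, a in enumerate(m.state_arrays())},
            )
        return d

    @classmethod
    def load(cls, directory: Path | str) -> "TrainedEnsemble":
        d = Path(directory)
        meta = json.loads((d / "ensemble.json").read_text())
        ucfg = UNetConfig(**meta["ucfg"])
        tcfg = TrainConfig(**meta["tcfg"])
        members = []
        for i in range(meta["n_members"]):
            with np.load(d / f"member_{i:02d}.npz") as z:
                arrays = [z[f"a{j}"] for j in range(len(z.files))]
            m = UNet3D(ucfg, seed=0)
            m.load_state_arrays(arrays)
            members.append(m)
        return cls(members, ucfg, tcfg, meta.get("histories", []))


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet3D:
    return UNet3D(cfg, seed=seed)


def lr_at_epoch(e: int, cfg: TrainConfig) -> float:
    """Polynomial decay ``lr0 * (1 - e/E)^power`` (monotone non-increasing)."""
    if not (0 <= e <= cfg.epochs):
        raise ValueError(f"epoch {e} outside [0, {cfg.epochs}]")
    return cfg.initial_lr * (1.0 - e / cfg.epochs) ** cfg.lr_decay_power


def make_folds(case_ids: list[str], k: int, seed: int) -> dict[str, int]:
    """Random partition into k folds with sizes differing by at most one."""
    if k > len(case_ids):
        raise ValueError("more folds than cases")
    rng = np.random.default_rng(seed)
    order = list(case_ids)
    rng.shuffle(order)
    return {cid: i % k for i, cid in enumerate(order)}


def normalize_case(case: MpMRICase) -> MpMRICase:
    """Per-channel z-score over brain-mask voxels; background stays zero."""
    mask = case.brain_mask
    channels = case.channels.astype(np.float32).copy()
    for ch in range(channels.shape[0]):
        vals = channels[ch][mask]
        sd = vals.std()
        channels[ch] = (channels[ch] - vals.mean()) / (sd if sd > 0 else 1.0)
        channels[ch][~mask] = 0.0
    return MpMRICase(case.case_id, channels, case.labels, case.affine.copy())


def _prepare_cases(
    cases: list[MpMRICase], codec: LabelCodec
) -> list[MpMRICase]:
    from .io_brats import UnknownLabelCodeError

    prepared = []
    for case in cases:
        if case.labels is None:
            raise ValueError(f"{case.case_id}: training requires labels")
        try:
            codec.validate_codes(case.labels)
        except UnknownLabelCodeError as err:
            raise LabelConfigMismatchError(
                f"{case.case_id}: {err} — incompatible with a "
                f"{codec.n_classes}-class model"
            ) from err
        prepared.append(normalize_case(case))
    return prepared


def train_model(
    cases: list[MpMRICase],
    ucfg: UNetConfig,
    tcfg: TrainConfig,
    patch_spec: PatchSpec | None = None,
    augment: AugmentSpec | None = None,
) -> tuple[UNet3D, list[float]]:
    """Train one network; returns the model and per-epoch mean loss history.

    Fully deterministic for a fixed ``tcfg.seed`` on a single worker.
    """
    codec = ucfg.codec()
    prepared = _prepare_cases(cases, codec)
    patch_spec = patch_spec or PatchSpec()
    rng = np.random.default_rng(tcfg.seed)
    model = UNet3D(ucfg, seed=int(rng.integers(2**31 - 1)))
    opt = _nn.Adam(model.params())
    history: list[float] = []
    steps = max(1, math.ceil(tcfg.patches_per_epoch / tcfg.batch_size))
    for epoch in range(tcfg.epochs):
        lr = lr_at_epoch(epoch, tcfg)
        losses = []
        for _ in range(steps):
            imgs, labs = [], []
            for _ in range(tcfg.batch_size):
                case = prepared[rng.integers(len(prepared))]
                center, prov = sample_center(case, patch_spec, rng)
                patch = extract_patch(case, center, patch_spec, prov)
                if augment is not None:
                    patch = apply_augment(patch, draw_augment(rng, augment))
                imgs.append(patch.image)
                labs.append(codec.encode(patch.labels))
            x = np.stack(imgs)
            y = np.stack(labs)
            logits = model.forward(x, train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def train_ensemble(
    cases: list[MpMRICase],
    ucfg: UNetConfig,
    tcfg: TrainConfig,
    patch_spec: PatchSpec | None = None,
    augment: AugmentSpec | None = None,
) -> TrainedEnsemble:
    """Train ``tcfg.ensemble_size`` members with distinct derived seeds."""
    member_seeds = (
        np.random.SeedSequence(tcfg.seed).generate_state(tcfg.ensemble_size)
        % (2**31 - 1)
    )
    members, histories = [], []
    for s in member_seeds:
        model, hist = train_model(
            cases, ucfg, replace(tcfg, seed=int(s)), patch_spec, augment
        )
        members.append(model)
        histories.append(hist)
    return TrainedEnsemble(members, ucfg, tcfg, histories)


def predict_case(
    ensemble: TrainedEnsemble, case: MpMRICase, codec: LabelCodec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-volume ensemble inference.

    The case is z-score normalized, zero-padded to the network's divisibility
    requirement, run through every member, and the members' softmax
    probabilities are averaged before the voxelwise argmax.  Returns
    ``(probs, labels)`` where ``probs`` is (n_classes, X, Y, Z) on the
    original grid and ``labels`` holds on-disk codes.
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    codec = codec or ensemble.ucfg.codec()
    if codec.n_classes != ensemble.ucfg.n_classes:
        raise ValueError("codec class count does not match the model")
    norm = normalize_case(case)
    padded, rec = pad_case(norm, ensemble.ucfg.divisor)
    x = padded.channels[None]
    probs = None
    for m in ensemble.members:
        p = _nn.softmax(m.forward(x, train=False), axis=1)[0]
        probs = p if probs is None else probs + p
    probs /= len(ensemble.members)
    labels_idx = np.argmax(probs, axis=0)
    probs = np.stack([crop_volume(p, rec) for p in probs])
    labels_idx = crop_volume(labels_idx, rec)
    return probs, codec.decode(labels_idx)
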