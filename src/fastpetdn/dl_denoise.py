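"""U-Net denoising variants, training protocol and tri-planar inference.

Three network variants are supported:

``axial_3ch_2p5d``
    2-D U-Net whose input channels are each axial slice and its two
    neighbours (edge slices replicated), target the matching reference slice.
``triplanar_1ch_2p5d``
    One 2-D U-Net fed single slices from *any* of the three anatomical planes
    (axial, coronal, sagittal). At inference the network denoises all slices
    of each orientation, the three reassembled volumes are averaged
    voxel-wise.
``patch_3d``
    3-D U-Net on overlapping cubic patches, overlap-averaged at inference.

Training minimises voxel-wise MSE with Adam (starting learning rate 1e-3,
halved when the validation loss plateaus), He initialisation, average pooling
and no batch normalisation; the deployed checkpoint is the absolute
validation-loss minimum. Intensities are divided by a fixed SUV scale
(default 10) rather than per-volume statistics, so quantification is
preserved on inverse scaling. On-the-fly paired augmentation applies random
rotation, anisotropic scaling and translation to input and target alike.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .nn import Adam, UNet, mse_loss
from .volio import Volume, check_aligned

__all__ = [
    "VARIANTS",
    "UNetConfig",
    "AugmentParams",
    "TrainState",
    "DenoiserModel",
    "TrainingDivergedError",
    "make_training_pairs",
    "count_samples",
    "train",
    "denoise_volume",
    "save_model",
    "load_model",
]

VARIANTS = ("axial_3ch_2p5d", "triplanar_1ch_2p5d", "patch_3d")


class TrainingDivergedError(RuntimeError):
    pass


@dataclasses.dataclass
class UNetConfig:
    variant: str = "triplanar_1ch_2p5d"
    depth: int = 3
    base_channels: int = 8
    lr0: float = 1e-3
    epochs: int = 30
    seed: int = 0
    patch_size_vox: int = 16      # patch_3d only
    patch_stride_vox: int = 8     # patch_3d only
    suv_scale: float = 10.0       # fixed intensity normalisation
    samples_per_epoch: int = 160
    batch_size: int = 8
    val_samples: int = 48
    lr_patience: int = 50         # epochs without val improvement before halving
    residual: bool = True         # identity shortcut from input to output
    aggregate: str = "mean"       # triplanar fusion: "mean" or "median"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.depth < 2 or self.base_channels < 4:
            raise ValueError("need depth >= 2 and base_channels >= 4")
        if self.lr0 <= 0 or self.epochs < 1:
            raise ValueError("need lr0 > 0 and epochs >= 1")

    @property
    def in_channels(self) -> int:
        return 3 if self.variant == "axial_3ch_2p5d" else 1

    @property
    def ndim(self) -> int:
        return 3 if self.variant == "patch_3d" else 2


@dataclasses.dataclass
class AugmentParams:
    """Symmetric-about-identity paired geometric augmentation."""

    rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_vox: float = 5.0
    prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not np.isclose(lo * hi, 1.0, rtol=0.05) and not (lo <= 1.0 <= hi):
            raise ValueError("scale_range must bracket the identity")


@dataclasses.dataclass
class TrainState:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    model: "DenoiserModel"

    @property
    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


@dataclasses.dataclass
class DenoiserModel:
    """A trained network plus everything inference needs."""

    config: UNetConfig
    net: UNet
    voxel_size_mm: tuple[float, float, float] | None = None


# ---------------------------------------------------------------------------
# Sample bookkeeping


def _sample_keys(shape: tuple[int, int, int], variant: str, patch: int, stride: int):
    """Enumerate all (kind, index) sample keys for one volume."""
    if variant == "axial_3ch_2p5d":
        return [(2, z) for z in range(shape[2])]
    if variant == "triplanar_1ch_2p5d":
        return [(ax, i) for ax in range(3) for i in range(shape[ax])]
    # patch_3d: corners covering the volume, end-aligned final patch per axis
    starts = []
    for n in shape:
        if n < patch:
            raise ValueError(f"volume extent {n} smaller than patch size {patch}")
        s = list(range(0, n - patch + 1, stride))
        if s[-1] != n - patch:
            s.append(n - patch)
        starts.append(s)
    return [
        ("patch", (i, j, k)) for i in starts[0] for j in starts[1] for k in starts[2]
    ]


def _extract(
    fast: np.ndarray, ref: np.ndarray, variant: str, key, patch: int
) -> tuple[np.ndarray, np.ndarray]:
    if variant == "axial_3ch_2p5d":
        _, z = key
        zm = max(z - 1, 0)
        zp = min(z + 1, fast.shape[2] - 1)
        inp = np.stack([fast[:, :, zm], fast[:, :, z], fast[:, :, zp]])
        tgt = ref[:, :, z][None]
        return inp, tgt
    if variant == "triplanar_1ch_2p5d":
        ax, i = key
        return np.take(fast, i, axis=ax)[None], np.take(ref, i, axis=ax)[None]
    _, (i, j, k) = key
    sl = (slice(i, i + patch), slice(j, j + patch), slice(k, k + patch))
    return fast[sl][None], ref[sl][None]


def make_training_pairs(
    volume_pairs: Sequence[tuple[Volume, Volume]],
    variant: str,
    patch_size_vox: int = 16,
    patch_stride_vox: int = 8,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream every (input, target) sample the variant defines, unnormalised."""
    for fast, ref in volume_pairs:
        check_aligned(fast, ref)
        for key in _sample_keys(fast.shape, variant, patch_size_vox, patch_stride_vox):
            yield _extract(fast.data, ref.data, variant, key, patch_size_vox)


def count_samples(shape: tuple[int, int, int], variant: str, patch: int = 16, stride: int = 8) -> int:
    return len(_sample_keys(shape, variant, patch, stride))


# ---------------------------------------------------------------------------
# Augmentation


def _augment_pair(inp, tgt, aug: AugmentParams, rng: np.random.Generator):
    if rng.uniform() >= aug.prob:
        return inp, tgt
    nd = inp.ndim - 1  # spatial rank
    theta = np.deg2rad(rng.uniform(-aug.rotation_deg, aug.rotation_deg))
    scales = rng.uniform(aug.scale_range[0], aug.scale_range[1], size=nd)
    shift = rng.uniform(-aug.translation_vox, aug.translation_vox, size=nd)
    rot = np.eye(nd)
    c, s = np.cos(theta), np.sin(theta)
    rot[-2:, -2:] = [[c, -s], [s, c]]  # rotate in the trailing plane
    minv = rot.T @ np.diag(1.0 / scales)
    center = (np.asarray(inp.shape[1:], dtype=np.float64) - 1) / 2.0
    offset = center - minv @ (center + shift)

    def tx(arr):
        out = np.empty_like(arr)
        for ch in range(arr.shape[0]):
            out[ch] = ndimage.affine_transform(
                arr[ch], minv, offset=offset, order=1, mode="nearest"
            )
        return out

    return tx(inp), tx(tgt)


# ---------------------------------------------------------------------------
# Training


def _pad_to_multiple(arr2d: np.ndarray, div: int) -> tuple[np.ndarray, tuple]:
    spatial = arr2d.shape[1:]
    pads = [(0, 0)] + [(0, (-s) % div) for s in spatial]
    if any(p[1] for p in pads):
        return np.pad(arr2d, pads, mode="reflect"), spatial
    return arr2d, spatial


def _batched(keys, batch_size):
    """Group sample keys by resulting spatial shape, then chunk."""
    from collections import defaultdict

    groups = defaultdict(list)
    for item in keys:
        groups[item[0]].append(item)
    for shape_key in groups:
        g = groups[shape_key]
        for i in range(0, len(g), batch_size):
            yield g[i : i + batch_size]


def _eval_loss(net: UNet, samples, div: int) -> float:
    total, count = 0.0, 0
    for inp, tgt in samples:
        x, sp = _pad_to_multiple(inp, div)
        t, _ = _pad_to_multiple(tgt, div)
        pred = net.predict(x[None])
        diff = pred[0] - t
        total += float(np.sum(diff.astype(np.float64) ** 2))
        count += diff.size
    return total / count


def train(
    config: UNetConfig,
    train_pairs: Sequence[tuple[Volume, Volume]],
    val_pairs: Sequence[tuple[Volume, Volume]],
    augment: AugmentParams | None = None,
) -> TrainState:
    """Train a U-Net variant on (fast, reference) volume pairs.

    Per epoch, ``samples_per_epoch`` slices/patches are drawn at random across
    all training pairs, augmented, and optimised in shape-grouped mini
    batches. The validation loss is computed on a fixed random subset of
    validation samples; the returned model carries the weights of the epoch
    with the lowest validation loss. Fully deterministic given
    ``config.seed`` on a single device.
    """
    if not train_pairs or not val_pairs:
        raise ValueError("need at least one training and one validation pair")
    for fa, re_ in list(train_pairs) + list(val_pairs):
        check_aligned(fa, re_)
    rng = np.random.default_rng(config.seed)
    net = UNet(
        in_channels=config.in_channels,
        depth=config.depth,
        base_channels=config.base_channels,
        ndim=config.ndim,
        residual=config.residual,
        seed=np.random.default_rng(rng.integers(2**31 - 1)),
    )
    opt = Adam(net.params(), lr=config.lr0)
    div = 2 ** (config.depth - 1)
    scale = config.suv_scale

    def norm(v: Volume) -> np.ndarray:
        return (v.data / scale).astype(np.float32)

    tr = [(norm(f), norm(r)) for f, r in train_pairs]
    va = [(norm(f), norm(r)) for f, r in val_pairs]
    tr_index = [
        (pi, key)
        for pi, (f, _) in enumerate(tr)
        for key in _sample_keys(f.shape, config.variant, config.patch_size_vox, config.patch_stride_vox)
    ]
    va_index = [
        (pi, key)
        for pi, (f, _) in enumerate(va)
        for key in _sample_keys(f.shape, config.variant, config.patch_size_vox, config.patch_stride_vox)
    ]
    val_pick = rng.choice(len(va_index), size=min(config.val_samples, len(va_index)), replace=False)
    val_samples = [
        _extract(va[pi][0], va[pi][1], config.variant, key, config.patch_size_vox)
        for pi, key in (va_index[i] for i in val_pick)
    ]

    train_losses: list[float] = []
    val_losses: list[float] = [_eval_loss(net, val_samples, div)]  # epoch 0 = init
    best_epoch = 0
    best_weights = net.get_weights()
    stall = 0
    for epoch in range(1, config.epochs + 1):
        picks = rng.choice(len(tr_index), size=config.samples_per_epoch, replace=True)
        epoch_samples = []
        for i in picks:
            pi, key = tr_index[i]
            inp, tgt = _extract(tr[pi][0], tr[pi][1], config.variant, key, config.patch_size_vox)
            if augment is not None:
                inp, tgt = _augment_pair(inp, tgt, augment, rng)
            epoch_samples.append((inp.shape[1:], inp, tgt))
        ep_loss, ep_n = 0.0, 0
        for batch in _batched(epoch_samples, config.batch_size):
            x = np.stack([_pad_to_multiple(b[1], div)[0] for b in batch])
            t = np.stack([_pad_to_multiple(b[2], div)[0] for b in batch])
            net.zero_grad()
            pred = net.forward(x, train=True)
            loss, dpred = mse_loss(pred, t)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"NaN/inf loss at epoch {epoch} (lr {opt.lr:g})"
                )
            net.backward(dpred)
            opt.step()
            ep_loss += loss * pred.size
            ep_n += pred.size
        train_losses.append(ep_loss / max(ep_n, 1))
        vloss = _eval_loss(net, val_samples, div)
        val_losses.append(vloss)
        if vloss < val_losses[best_epoch]:
            best_epoch = epoch
            best_weights = net.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr *= 0.5
                stall = 0
    net.set_weights(best_weights)
    model = DenoiserModel(config=config, net=net, voxel_size_mm=train_pairs[0][0].voxel_size_mm)
    return TrainState(train_losses, val_losses, best_epoch, model)


# ---------------------------------------------------------------------------
# Inference


def _run_slices(net: UNet, stack: np.ndarray, div: int, batch: int = 16) -> np.ndarray:
    """Apply the net to a (N, C, H, W) stack, padding spatial dims to ``div``."""
    x, spatial = _pad_to_multiple(stack.reshape(-1, *stack.shape[2:]), div)
    x = x.reshape(stack.shape[0], stack.shape[1], *x.shape[1:])
    outs = []
    for i in range(0, x.shape[0], batch):
        outs.append(net.predict(x[i : i + batch]))
    out = np.concatenate(outs, axis=0)[:, 0]
    return out[(slice(None),) + tuple(slice(0, s) for s in spatial)]


def denoise_volume(model: DenoiserModel, vol: Volume) -> Volume:
    """Denoise one volume with a trained model; geometry is preserved.

    Tri-planar models reconstruct the volume three times (all axial, all
    coronal, all sagittal slices) and fuse voxel-wise (mean by default);
    3-channel axial models stack denoised axial slices; 3-D patch models
    overlap-average patch predictions with uniform weights. Output is scaled
    back to SUV and clipped at 0.
    """
    cfg = model.config
    if model.voxel_size_mm is not None and not np.allclose(
        model.voxel_size_mm, vol.voxel_size_mm, atol=1e-6
    ):
        warnings.warn(
            f"inference spacing {vol.voxel_size_mm} differs from training "
            f"spacing {model.voxel_size_mm}",
            stacklevel=2,
        )
    div = 2 ** (cfg.depth - 1)
    x = (vol.data / cfg.suv_scale).astype(np.float32)
    if cfg.variant == "triplanar_1ch_2p5d":
        recons = []
        for ax in range(3):
            stack = np.moveaxis(x, ax, 0)[:, None]
            out = _run_slices(model.net, stack, div)
            recons.append(np.moveaxis(out, 0, ax))
        fused = (
            np.median(recons, axis=0) if cfg.aggregate == "median" else np.mean(recons, axis=0)
        )
    elif cfg.variant == "axial_3ch_2p5d":
        z = x.shape[2]
        idx = np.arange(z)
        stack = np.stack(
            [
                np.moveaxis(x[:, :, np.maximum(idx - 1, 0)], 2, 0),
                np.moveaxis(x, 2, 0),
                np.moveaxis(x[:, :, np.minimum(idx + 1, z - 1)], 2, 0),
            ],
            axis=1,
        )
        out = _run_slices(model.net, stack, div)
        fused = np.moveaxis(out, 0, 2)
    else:  # patch_3d
        patch, stride = cfg.patch_size_vox, cfg.patch_stride_vox
        acc = np.zeros(x.shape, dtype=np.float64)
        cnt = np.zeros(x.shape, dtype=np.float64)
        for _, (i, j, k) in _sample_keys(x.shape, "patch_3d", patch, stride):
            sl = (slice(i, i + patch), slice(j, j + patch), slice(k, k + patch))
            pred = model.net.predict(x[sl][None, None])[0, 0]
            acc[sl] += pred
            cnt[sl] += 1.0
        fused = acc / cnt
    out = np.clip(fused * cfg.suv_scale, 0.0, None).astype(np.float32)
    return vol.copy(out, denoiser=f"dl:{cfg.variant}")


# ---------------------------------------------------------------------------
# Persistence


def save_model(state: TrainState, outdir) -> None:
    """Model directory: config.yaml, losses.csv, weights.npz."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = state.model
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                **dataclasses.asdict(model.config),
                "voxel_size_mm": list(model.voxel_size_mm or ()),
                "best_epoch": state.best_epoch,
            },
            fh,
            sort_keys=False,
        )
    import csv

    with open(out / "losses.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "val_loss"])
        w.writerow([0, "", f"{state.val_losses[0]:.6g}"])
        for e, (tl, vl) in enumerate(zip(state.train_losses, state.val_losses[1:]), start=1):
            w.writerow([e, f"{tl:.6g}", f"{vl:.6g}"])
    np.savez(
        out / "weights.npz",
        **{f"w{i:04d}": w for i, w in enumerate(model.net.get_weights())},
    )


def load_model(modeldir) -> DenoiserModel:
    mdir = Path(modeldir)
    with open(mdir / "config.yaml") as fh:
        doc = yaml.safe_load(fh)
    vsize = doc.pop("voxel_size_mm", None)
    doc.pop("best_epoch", None)
    cfg = UNetConfig(**doc)
    net = UNet(
        in_channels=cfg.in_channels,
        depth=cfg.depth,
        base_channels=cfg.base_channels,
        ndim=cfg.ndim,
        residual=cfg.residual,
        seed=cfg.seed,
    )
    with np.load(mdir / "weights.npz") as z:
        net.set_weights([z[k] for k in sorted(z.files)])
    return DenoiserModel(cfg, net, tuple(vsize) if vsize else None)
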