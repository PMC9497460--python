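"""Voxel classifier, weighted loss, augmentation, and the training loop.

The classifier is a 3D encoder-decoder ("U-Net style") network with skip
connections, mapping a multi-channel patch (CT, PET, organ channels) to a
per-voxel probability over the four classes. It is trained on patches
drawn from the loss-adaptive sample masks with a weighted categorical
cross-entropy: foreground voxels carry a 2.5x larger weight than
background, deliberately favouring sensitivity over precision. The loss is
optimised with Nadam (Adam with Nesterov momentum) at an initial learning
rate of 1e-3, halved whenever the validation loss has not decreased for
five consecutive epochs. Training runs in rounds; after each round the
sample masks of a random half of the training studies are refreshed from
the current per-voxel loss (hard-example mining).

Regularisation follows the same recipe: two dropout sites at rate 0.25
(after the bottleneck and after the deepest decoder block) and an l2
penalty of 1e-3 on the convolution kernels. Patches are augmented with a
random isotropic scaling of +/-10%, an in-plane rotation of +/-0.15 rad,
and intensity shifts of +/-0.5 SUV on the PET channel and +/-100 HU on
the CT channel, both applied as the equivalent shifts inside the
normalised intensity windows.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import _nn
from .errors import ConfigurationError, TrainingDivergedError, ValidationError
from .phantom import Cohort
from .sampler import (
    SampleMask,
    draw_patch_centres,
    extract_patch_arrays,
    init_sample_mask,
    refresh_masks,
)
from .volumes import stack_input_channels

logger = logging.getLogger(__name__)

N_CLASSES = 4
_EPS = 1e-7  # probability clamp inside the log


@dataclass
class ModelConfig:
    n_input_channels: int = 6
    n_classes: int = 4
    encoder_depth: int = 2
    base_filters: int = 8
    dropout_rate: float = 0.25
    l2_weight: float = 0.001

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ConfigurationError("n_classes must be 4")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.l2_weight < 0:
            raise ConfigurationError("l2_weight must be >= 0")
        if self.encoder_depth < 1 or self.base_filters < 1:
            raise ConfigurationError("depth and base_filters must be >= 1")


@dataclass
class AugmentationSpec:
    scale_range: tuple[float, float] = (-0.10, 0.10)
    rotation_range_rad: tuple[float, float] = (-0.15, 0.15)
    pet_intensity_shift_suv: tuple[float, float] = (-0.5, 0.5)  # native SUV
    ct_intensity_shift_hu: tuple[float, float] = (-100.0, 100.0)
    ct_window_width_hu: float = 1600.0  # width of the CT clamp window
    pet_window_width_suv: float = 25.0  # width of the PET clamp window

    def __post_init__(self) -> None:
        for name in ("scale_range", "rotation_range_rad", "pet_intensity_shift_suv",
                     "ct_intensity_shift_hu"):
            lo, hi = getattr(self, name)
            if not np.isclose(lo, -hi):
                raise ValidationError(f"{name} must be symmetric about 0")


@dataclass
class TrainConfig:
    fg_loss_weight: float = 2.5
    initial_lr: float = 0.001
    lr_halving_patience_epochs: int = 5
    samples_per_epoch_train: int = 20000
    samples_per_epoch_val: int = 10000
    epochs_per_round: int = 10
    n_rounds: int = 5
    refresh_fraction: float = 0.5
    batch_size: int = 8
    patch_size: tuple[int, int, int] = (64, 64, 32)
    seed: int = 0
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)

    def __post_init__(self) -> None:
        for name in ("lr_halving_patience_epochs", "samples_per_epoch_train",
                     "samples_per_epoch_val", "epochs_per_round", "n_rounds",
                     "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.fg_loss_weight <= 0:
            raise ConfigurationError("fg_loss_weight must be > 0")
        if not 0.0 <= self.refresh_fraction <= 1.0:
            raise ConfigurationError("refresh_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class VoxelClassifier:
    """3D encoder-decoder voxel classifier with skip connections.

    ``forward`` returns logits ``(N, 4, *spatial)``; ``predict_proba``
    returns softmax probabilities with dropout disabled. Exactly two
    dropout sites exist regardless of depth: after the bottleneck and
    after the deepest decoder block.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d = cfg.encoder_depth
        f = [cfg.base_filters * 2**i for i in range(d + 1)]
        self.enc: list[tuple[_nn.Conv3D, _nn.Conv3D]] = []
        cin = cfg.n_input_channels
        for i in range(d):
            self.enc.append((_nn.Conv3D(cin, f[i], rng), _nn.Conv3D(f[i], f[i], rng)))
            cin = f[i]
        self.bott = (_nn.Conv3D(f[d - 1], f[d], rng), _nn.Conv3D(f[d], f[d], rng))
        self.dec: list[tuple[_nn.Conv3D, _nn.Conv3D]] = []
        below = f[d]
        for i in reversed(range(d)):
            self.dec.append(
                (_nn.Conv3D(below + f[i], f[i], rng), _nn.Conv3D(f[i], f[i], rng))
            )
            below = f[i]
        self.head = _nn.Conv3D(f[0], cfg.n_classes, rng, k=1)
        self.n_dropout_sites = 2
        self._cache: dict = {}

    # -- parameter access ---------------------------------------------------

    def _convs(self) -> list[_nn.Conv3D]:
        layers: list[_nn.Conv3D] = []
        for c1, c2 in self.enc:
            layers += [c1, c2]
        layers += list(self.bott)
        for c1, c2 in self.dec:
            layers += [c1, c2]
        layers.append(self.head)
        return layers

    def param_grads(self) -> list[tuple[np.ndarray, np.ndarray, bool]]:
        """(param, grad, is_kernel) triples; kernels carry the l2 penalty."""
        out = []
        for c in self._convs():
            out.append((c.W, c.dW, True))
            out.append((c.b, c.db, False))
        return out

    def astype(self, dtype) -> "VoxelClassifier":
        for c in self._convs():
            c.astype(dtype)
        return self

    def check_patch_size(self, spatial: tuple[int, ...]) -> None:
        div = 2**self.cfg.encoder_depth
        if any(s % div != 0 or s < div for s in spatial):
            raise ConfigurationError(
                f"patch size {tuple(spatial)} must be divisible by 2^depth = {div}"
            )

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if train and rng is None:
            rng = np.random.default_rng(0)
        return self._forward_impl(x, train, rng)

    def _forward_impl(self, x, train, rng) -> np.ndarray:
        self.check_patch_size(x.shape[2:])
        rate = self.cfg.dropout_rate
        cache: dict = {"enc_relu": [], "pool": [], "skips": [], "dec_relu": [],
                       "drop": [None, None], "train": train, "x_dtype": x.dtype}
        h = x
        for c1, c2 in self.enc:
            h, m1 = _nn.relu_forward(c1.forward(h))
            h, m2 = _nn.relu_forward(c2.forward(h))
            cache["enc_relu"].append((m1, m2))
            cache["skips"].append(h)
            h, pc = _nn.maxpool2_forward(h)
            cache["pool"].append(pc)
        b1, b2 = self.bott
        h, mb1 = _nn.relu_forward(b1.forward(h))
        h, mb2 = _nn.relu_forward(b2.forward(h))
        cache["bott_relu"] = (mb1, mb2)
        if train and rate > 0:
            h, keep = _nn.dropout_forward(h, rate, rng)
            cache["drop"][0] = keep
        dec_concat_ch = []
        for j, (c1, c2) in enumerate(self.dec):
            h = _nn.upsample2_forward(h)
            skip = cache["skips"][len(self.enc) - 1 - j]
            dec_concat_ch.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h, m1 = _nn.relu_forward(c1.forward(h))
            h, m2 = _nn.relu_forward(c2.forward(h))
            cache["dec_relu"].append((m1, m2))
            if j == 0 and train and rate > 0:
                h, keep = _nn.dropout_forward(h, rate, rng)
                cache["drop"][1] = keep
        cache["dec_concat_ch"] = dec_concat_ch
        logits = self.head.forward(h)
        self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        cache = self._cache
        h = self.head.backward(dlogits)
        for j in reversed(range(len(self.dec))):
            c1, c2 = self.dec[j]
            if j == 0 and cache["drop"][1] is not None:
                h = h * cache["drop"][1]
            m1, m2 = cache["dec_relu"][j]
            h = c2.backward(_nn.relu_backward(h, m2))
            h = c1.backward(_nn.relu_backward(h, m1))
            up_ch, _skip_ch = cache["dec_concat_ch"][j]
            h, dskip = h[:, :up_ch], h[:, up_ch:]
            cache.setdefault("dskips", {})[len(self.enc) - 1 - j] = dskip
            h = _nn.upsample2_backward(h)
        if cache["drop"][0] is not None:
            h = h * cache["drop"][0]
        b1, b2 = self.bott
        mb1, mb2 = cache["bott_relu"]
        h = b2.backward(_nn.relu_backward(h, mb2))
        h = b1.backward(_nn.relu_backward(h, mb1))
        for i in reversed(range(len(self.enc))):
            c1, c2 = self.enc[i]
            h = _nn.maxpool2_backward(h, cache["pool"][i])
            if i in cache.get("dskips", {}):
                h = h + cache["dskips"][i]
            m1, m2 = cache["enc_relu"][i]
            h = c2.backward(_nn.relu_backward(h, m2))
            h = c1.backward(_nn.relu_backward(h, m1))
        self._cache = {}

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities, dropout disabled (deterministic)."""
        return _nn.softmax(self._forward_impl(x, train=False, rng=None), axis=1)


def build_model(cfg: ModelConfig, seed: int = 0) -> VoxelClassifier:
    """Construct the voxel classifier with seeded weight initialisation."""
    return VoxelClassifier(cfg, seed=seed)


# ---------------------------------------------------------------------------
# weighted categorical cross-entropy
# ---------------------------------------------------------------------------

def class_weights(targets: np.ndarray, fg_weight: float = 2.5) -> np.ndarray:
    """Per-voxel loss weight: ``fg_weight`` for classes 1-3, 1 for background."""
    return np.where(targets > 0, fg_weight, 1.0)


def weighted_cce(probabilities: np.ndarray, targets: np.ndarray,
                 fg_weight: float = 2.5) -> tuple[float, np.ndarray]:
    """Weighted categorical cross-entropy.

    ``probabilities`` has the class axis first after an optional batch axis
    (``(4, *spatial)`` or ``(N, 4, *spatial)``); ``targets`` are integer
    class codes of the matching spatial shape. The per-voxel loss is
    ``-w_c log p(true class)`` with ``w_c = fg_weight`` for foreground and
    1 for background; the scalar is the mean over all voxels. Returns
    ``(scalar, per-voxel loss array)``. Probabilities are clamped at 1e-7
    inside the log.
    """
    probs = np.asarray(probabilities)
    targets = np.asarray(targets)
    if probs.ndim == 4:       # (4, x, y, z)
        batched = False
        probs = probs[None]
        targets = targets[None]
    elif probs.ndim == 5:     # (n, 4, x, y, z)
        batched = True
    else:
        raise ValidationError("probabilities must be 4D or batched 5D")
    if probs.shape[1] != N_CLASSES:
        raise ValidationError(f"expected {N_CLASSES} class channels")
    p_true = np.take_along_axis(
        probs, targets[:, None].astype(np.int64), axis=1
    )[:, 0]
    n_clamped = int((p_true < _EPS).sum())
    if n_clamped:
        logger.warning("clamped %d zero probabilities at the true class", n_clamped)
    per_voxel = -class_weights(targets, fg_weight) * np.log(
        np.maximum(p_true, _EPS)
    )
    if not batched:
        per_voxel = per_voxel[0]
    return float(per_voxel.mean()), per_voxel


def weighted_cce_grad(probs: np.ndarray, targets: np.ndarray,
                      fg_weight: float = 2.5) -> np.ndarray:
    """Gradient of the scalar weighted CCE w.r.t. the logits.

    For softmax + cross-entropy the per-voxel logit gradient is
    ``w * (p - onehot)``, scaled by 1/n_voxels for the mean.
    """
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, targets[:, None].astype(np.int64), 1.0, axis=1)
    w = class_weights(targets, fg_weight)[:, None]
    n = targets.size
    return (w * (probs - onehot) / n).astype(probs.dtype)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_patch(p, spec: AugmentationSpec, seed: int = 0):
    """Apply one random draw of the training augmentation to a patch.

    A single isotropic scale and one in-plane (x-y) rotation are drawn
    uniformly from the configured ranges and applied about the patch
    centre: continuous channels (CT, PET) trilinearly, organ channels and
    the label target with nearest neighbour, so no new codes appear.
    Intensity shifts are then added to the PET channel (drawn in native
    SUV, applied as the equivalent normalised shift) and the CT channel
    (drawn in HU, likewise mapped through the normalisation window), and
    the continuous channels are clipped back to [0, 1]. Collapsed ranges
    make the operation the identity. Deterministic given ``seed``.
    """
    from .sampler import Patch  # local import to avoid a cycle at import time

    rng = np.random.default_rng(seed)
    scale = 1.0 + rng.uniform(*spec.scale_range)
    angle = rng.uniform(*spec.rotation_range_rad)
    pet_shift = rng.uniform(*spec.pet_intensity_shift_suv) / spec.pet_window_width_suv
    ct_shift = rng.uniform(*spec.ct_intensity_shift_hu) / spec.ct_window_width_hu

    channels = p.channels.astype(np.float32, copy=True)
    target = p.target.copy()
    if not (np.isclose(scale, 1.0) and np.isclose(angle, 0.0)):
        c, s = np.cos(angle), np.sin(angle)
        fwd = scale * np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        inv = np.linalg.inv(fwd)
        centre = (np.array(p.size) - 1) / 2.0
        offset = centre - inv @ centre
        new_channels = np.empty_like(channels)
        for ch in range(channels.shape[0]):
            order = 1 if ch < 2 else 0  # CT/PET trilinear, organ masks nearest
            new_channels[ch] = ndimage.affine_transform(
                channels[ch], inv, offset=offset, order=order, mode="nearest"
            )
        channels = new_channels
        target = ndimage.affine_transform(
            target, inv, offset=offset, order=0, mode="nearest"
        ).astype(target.dtype)
    channels[0] = np.clip(channels[0] + ct_shift, 0.0, 1.0)
    channels[1] = np.clip(channels[1] + pet_shift, 0.0, 1.0)
    return Patch(channels=channels, target=target, centre=p.centre, size=p.size)


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

class ValLossHalver:
    """Halve the learning rate after ``patience`` epochs without a
    validation-loss decrease (strict improvement resets the counter)."""

    def __init__(self, initial_lr: float, patience: int):
        self.lr = float(initial_lr)
        self.patience = int(patience)
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        """Record one epoch's validation loss; return the LR for the next
        epoch."""
        if val_loss < self.best:
            self.best = float(val_loss)
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= 0.5
                self.bad_epochs = 0
                logger.info("validation loss plateaued; lr halved to %.2e", self.lr)
        return self.lr


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _draw_epoch_patches(studies, caches, masks, n_samples, patch_size, rng,
                        augmentation: AugmentationSpec | None):
    """Yield (channels, targets) batches-of-one for an epoch's sample plan."""
    from .sampler import Patch

    study_choice = rng.integers(len(studies), size=n_samples)
    out_ch, out_tg = [], []
    for si in range(len(studies)):
        count = int((study_choice == si).sum())
        if count == 0:
            continue
        study = studies[si]
        centres = draw_patch_centres(masks[study.study_id], count,
                                     seed=int(rng.integers(2**31 - 1)))
        stacked, target = caches[study.study_id]
        for c in centres:
            ch, tg = extract_patch_arrays(stacked, target, c, patch_size)
            if augmentation is not None:
                patch = augment_patch(
                    Patch(ch, tg, tuple(int(v) for v in c), tuple(patch_size)),
                    augmentation, seed=int(rng.integers(2**31 - 1)),
                )
                ch, tg = patch.channels, patch.target
            out_ch.append(ch)
            out_tg.append(tg)
    order = rng.permutation(len(out_ch))
    return [out_ch[i] for i in order], [out_tg[i] for i in order]


def train(cohort: Cohort, model: VoxelClassifier, cfg: TrainConfig
          ) -> tuple[VoxelClassifier, pd.DataFrame]:
    """Run the full patch-based training regime on a preprocessed cohort.

    ``cfg.n_rounds`` rounds of ``cfg.epochs_per_round`` epochs; each epoch
    draws ``samples_per_epoch_train`` training patches through the sample
    masks and ``samples_per_epoch_val`` validation patches through masks
    frozen at initialisation. After every round the training masks of a
    random ``refresh_fraction`` of studies are updated from the current
    per-voxel loss. Returns the trained model and a history table
    (round, epoch, train_loss, val_loss, lr). Fully seeded; raises
    :class:`TrainingDivergedError` on non-finite loss, after dumping the
    history to a diagnostic file.
    """
    train_studies = cohort.train
    val_studies = cohort.val
    if not train_studies or not val_studies:
        raise ValidationError("cohort must contain training and validation studies")
    model.check_patch_size(cfg.patch_size)

    caches = {}
    for s in train_studies + val_studies:
        if s.labels is None:
            raise ValidationError(f"study {s.study_id} has no labels")
        caches[s.study_id] = (stack_input_channels(s), s.labels.data)
    train_masks = {s.study_id: init_sample_mask(s.labels, s.study_id)
                   for s in train_studies}
    # validation masks are frozen: never loss-refreshed
    val_masks = {s.study_id: init_sample_mask(s.labels, s.study_id)
                 for s in val_studies}

    rng = np.random.default_rng(cfg.seed)
    optimiser = _nn.Nadam()
    scheduler = ValLossHalver(cfg.initial_lr, cfg.lr_halving_patience_epochs)
    lr = scheduler.lr
    history: list[dict] = []
    epoch_no = 0

    def _diverged(stage: str) -> TrainingDivergedError:
        dump = Path(tempfile.gettempdir()) / f"psmaseg_diverged_{id(model)}.json"
        pd.DataFrame(history).to_json(dump, orient="records")
        return TrainingDivergedError(
            f"non-finite {stage} loss at epoch {epoch_no}; history dumped to {dump}",
            dump_path=str(dump),
        )

    for rnd in range(cfg.n_rounds):
        for _ in range(cfg.epochs_per_round):
            epoch_no += 1
            chs, tgs = _draw_epoch_patches(
                train_studies, caches, train_masks, cfg.samples_per_epoch_train,
                cfg.patch_size, rng, cfg.augmentation,
            )
            batch_losses = []
            drop_rng = np.random.default_rng(rng.integers(2**31 - 1))
            for b0 in range(0, len(chs), cfg.batch_size):
                x = np.stack(chs[b0:b0 + cfg.batch_size]).astype(np.float32)
                y = np.stack(tgs[b0:b0 + cfg.batch_size])
                logits = model._forward_impl(x, train=True, rng=drop_rng)
                probs = _nn.softmax(logits, axis=1)
                loss, _ = weighted_cce(probs, y, cfg.fg_loss_weight)
                model.backward(weighted_cce_grad(probs, y, cfg.fg_loss_weight))
                pgs = []
                l2 = model.cfg.l2_weight
                for p, g, is_kernel in model.param_grads():
                    if is_kernel and l2 > 0:
                        g = g + l2 * p
                    pgs.append((p, g))
                optimiser.step(pgs, lr)
                batch_losses.append(loss)
            train_loss = float(np.mean(batch_losses))
            if not np.isfinite(train_loss):
                raise _diverged("training")

            vchs, vtgs = _draw_epoch_patches(
                val_studies, caches, val_masks, cfg.samples_per_epoch_val,
                cfg.patch_size, rng, augmentation=None,
            )
            vloss_terms = []
            for b0 in range(0, len(vchs), cfg.batch_size):
                x = np.stack(vchs[b0:b0 + cfg.batch_size]).astype(np.float32)
                y = np.stack(vtgs[b0:b0 + cfg.batch_size])
                probs = model.predict_proba(x)
                loss, _ = weighted_cce(probs, y, cfg.fg_loss_weight)
                vloss_terms.append((loss, len(x)))
            val_loss = float(
                sum(l * n for l, n in vloss_terms) / sum(n for _, n in vloss_terms)
            )
            if not np.isfinite(val_loss):
                raise _diverged("validation")

            history.append({"round": rnd + 1, "epoch": epoch_no,
                            "train_loss": train_loss, "val_loss": val_loss,
                            "lr": lr})
            logger.info("round %d epoch %d: train %.4f val %.4f lr %.2e",
                        rnd + 1, epoch_no, train_loss, val_loss, lr)
            lr = scheduler.step(val_loss)

        refresh_masks(
            train_studies, train_masks, model,
            fraction=cfg.refresh_fraction,
            seed=int(rng.integers(2**31 - 1)),
            fg_loss_weight=cfg.fg_loss_weight,
        )

    return model, pd.DataFrame(history)
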