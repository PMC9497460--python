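"""Loss-adaptive patch sampling.

Most voxels of a whole-body PET-CT study are background, so training
patches cannot be drawn uniformly. Each study carries a *sample mask*: a
per-voxel weight ``w_p`` over the set of all voxels ``P``, encoding how
often a patch is centred at voxel ``p``. The mask is initialised so that
50% of patch centres fall on background and 50% on foreground, with each
foreground class present in the study equally likely. After each training
round, the masks of a random half of the training studies are pulled
toward the current per-voxel loss ``l_p``:

    w_p^(i+1) = 0.5 * w_p^(i) + 0.5 * (max_P w^(i) / max_P l) * l_p

which biases sampling toward regions the model currently gets wrong (hard
examples) while retaining half of the old mass. The update is covariant
under uniform rescaling of ``w``, so it can be applied directly to the
normalised stored weights and re-normalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError
from .volumes import FOREGROUND_CLASSES, LabelMap, PetCtStudy, stack_input_channels

logger = logging.getLogger(__name__)


@dataclass
class SampleMask:
    """Per-voxel patch-centre weights for one study, normalised to sum 1."""

    weights: np.ndarray
    study_id: str = "study"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 3:
            raise ValueError("sample mask must be 3D")
        if (w < 0).any():
            raise ValueError("sample-mask weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("sample mask needs at least one positive weight")
        self.weights = w / total


@dataclass
class LossMap:
    """Per-voxel training loss for one study."""

    values: np.ndarray
    study_id: str = "study"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("loss map must be 3D")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("loss map must be finite and non-negative")
        self.values = v


@dataclass
class Patch:
    """A training example: multi-channel input sub-grid plus label target."""

    channels: np.ndarray  # (C, *size)
    target: np.ndarray    # (*size,) integer class codes
    centre: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if tuple(self.channels.shape[1:]) != tuple(self.size):
            raise ValueError("channel grid does not match patch size")
        if tuple(self.target.shape) != tuple(self.size):
            raise ValueError("target grid does not match patch size")


# ---------------------------------------------------------------------------
# mask initialisation
# ---------------------------------------------------------------------------

def init_sample_mask(labels: LabelMap, study_id: str = "study") -> SampleMask:
    """Build the 50/50 background/foreground initial sample mask.

    Total background weight is 0.5; the remaining 0.5 is split equally
    among the foreground classes *present* in the map and uniformly within
    each class. A map without foreground falls back to a uniform mask.
    """
    data = labels.data
    if data.size == 0:
        raise ValueError("empty label map")
    w = np.zeros(data.shape, dtype=np.float64)
    present = [c for c in FOREGROUND_CLASSES if (data == c).any()]
    if not present:
        w[...] = 1.0 / data.size
        return SampleMask(w, study_id)
    bg = data == 0
    n_bg = int(bg.sum())
    if n_bg > 0:
        w[bg] = 0.5 / n_bg
        fg_mass = 0.5
    else:  # degenerate all-foreground map: give everything to foreground
        fg_mass = 1.0
    per_class = fg_mass / len(present)
    for c in present:
        sel = data == c
        w[sel] = per_class / sel.sum()
    return SampleMask(w, study_id)


def draw_patch_centres(mask: SampleMask, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` patch-centre voxel indices ~ Categorical(mask weights).

    Returns an ``(n, 3)`` integer array; deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    flat = mask.weights.ravel()
    idx = rng.choice(flat.size, size=n, p=flat)
    return np.stack(np.unravel_index(idx, mask.weights.shape), axis=1)


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def _mirror_indices(start: int, size: int, n: int) -> np.ndarray:
    """Window indices reflected about the array boundaries (no edge
    repetition; period 2n - 2)."""
    idx = np.arange(start, start + size)
    if n == 1:
        return np.zeros(size, dtype=int)
    period = 2 * n - 2
    idx = np.mod(idx, period)
    return np.where(idx < n, idx, period - idx)


def _extract_window(arr: np.ndarray, centre, size) -> np.ndarray:
    """Extract a window centred at ``centre``, mirror-padding past edges.

    The window spans ``[c - size//2, c - size//2 + size)`` per axis;
    out-of-volume positions are reflected about the boundary voxel
    without repeating it.
    """
    spatial = arr.shape[-3:]
    starts = [int(c) - s // 2 for c, s in zip(centre, size)]
    stops = [st + s for st, s in zip(starts, size)]
    if all(0 <= st and sp <= n for st, sp, n in zip(starts, stops, spatial)):
        sl = tuple(slice(st, sp) for st, sp in zip(starts, stops))
        return arr[(..., *sl)].copy()
    ix, iy, iz = (
        _mirror_indices(st, s, n) for st, s, n in zip(starts, size, spatial)
    )
    return arr[..., ix[:, None, None], iy[None, :, None], iz[None, None, :]]


def extract_patch(study: PetCtStudy, centre, size) -> Patch:
    """Extract a multi-channel input patch and its label target.

    The study must be preprocessed (validated by the channel stacker).
    Regions outside the volume are mirror-padded. ``size`` may not exceed
    twice the volume extent on any axis.
    """
    size = tuple(int(s) for s in size)
    shape = study.grid_shape
    if any(s > 2 * n for s, n in zip(size, shape)):
        raise ValueError(f"patch size {size} exceeds twice the volume extent {shape}")
    stacked = stack_input_channels(study)
    if study.labels is None:
        target = np.zeros(shape, dtype=np.int16)
    else:
        target = study.labels.data
    return Patch(
        channels=_extract_window(stacked, centre, size),
        target=_extract_window(target, centre, size),
        centre=tuple(int(c) for c in centre),
        size=size,
    )


def extract_patch_arrays(stacked: np.ndarray, target: np.ndarray, centre, size
                         ) -> tuple[np.ndarray, np.ndarray]:
    # fast path for the training loop: volume already stacked once
    return (
        _extract_window(stacked, centre, size),
        _extract_window(target, centre, size),
    )


# ---------------------------------------------------------------------------
# loss-adaptive mask update
# ---------------------------------------------------------------------------

def eq1_update(w: np.ndarray, l: np.ndarray) -> np.ndarray:
    """One hard-example mask update on raw (unnormalised) weights:

    ``w' = 0.5 w + 0.5 (max w / max l) l``.

    Order-preserving in ``l`` and covariant under uniform scaling of ``w``.
    """
    w = np.asarray(w, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    lmax = l.max()
    if lmax <= 0:
        raise ValueError("max loss must be positive for the mask update")
    return 0.5 * w + 0.5 * (w.max() / lmax) * l


def update_sample_mask(mask: SampleMask, loss: LossMap) -> SampleMask:
    """Pull a sample mask toward the per-voxel loss (hard-example mining).

    An all-zero loss map returns the mask unchanged (no hard examples; the
    update's ``max loss`` denominator would be undefined).
    """
    if mask.weights.shape != loss.values.shape:
        raise AlignmentError(
            f"mask grid {mask.weights.shape} != loss grid {loss.values.shape}"
        )
    if loss.values.max() <= 0:
        return mask  # no hard examples anywhere: nothing to adapt
    return SampleMask(eq1_update(mask.weights, loss.values), mask.study_id)


def refresh_masks(
    studies: list[PetCtStudy],
    masks: dict[str, SampleMask],
    model,
    *,
    fraction: float = 0.5,
    seed: int = 0,
    fg_loss_weight: float = 2.5,
    tiling=None,
) -> dict[str, SampleMask]:
    """Recompute per-voxel losses for a random half of the training studies
    and update their sample masks in place.

    Exactly ``round(fraction * n)`` studies are selected uniformly at
    random (deterministic given ``seed``). Only the selected studies'
    masks change. Returns the mask dict.
    """
    if not studies:
        raise ValueError("empty study list")
    # local imports: inference/model_train themselves import this module
    from .inference import TilingConfig, predict_proba_volume
    from .model_train import weighted_cce

    tiling = tiling or TilingConfig()
    n = len(studies)
    k = int(np.floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False) if k > 0 else []
    for i in sorted(int(c) for c in np.atleast_1d(chosen)):
        study = studies[i]
        if study.labels is None:
            logger.warning("study %s has no labels; skipping refresh", study.study_id)
            continue
        probs = predict_proba_volume(model, study, tiling)
        _, loss_map = weighted_cce(probs, study.labels.data, fg_loss_weight)
        new_mask = update_sample_mask(
            masks[study.study_id], LossMap(loss_map, study.study_id)
        )
        masks[study.study_id] = new_mask
        logger.info(
            "refreshed mask for %s: max weight %.3e", study.study_id,
            new_mask.weights.max(),
        )
    return masks
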