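"""Whole-volume prediction by sliding-window tiling.

The classifier operates on patches, so a whole study is predicted by
tiling it with overlapping windows, averaging the per-voxel class
probabilities over all windows covering a voxel, and taking the argmax.
Ties on equal averaged probabilities break toward the lower class code
(background first), making inference fully deterministic; dropout is
disabled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PsmasegError
from .volumes import LabelMap, PetCtStudy, stack_input_channels

logger = logging.getLogger(__name__)


@dataclass
class TilingConfig:
    tile_size: tuple[int, int, int] = (32, 32, 32)
    overlap_voxels: tuple[int, int, int] = (8, 8, 8)

    def __post_init__(self) -> None:
        if any(o < 0 for o in self.overlap_voxels):
            raise ConfigurationError("overlap must be >= 0")
        if any(o >= t for o, t in zip(self.overlap_voxels, self.tile_size)):
            raise ConfigurationError("overlap must be smaller than the tile size")


def _tile_starts(n: int, tile: int, overlap: int) -> list[int]:
    if n <= tile:
        return [0]
    stride = tile - overlap
    starts = list(range(0, n - tile + 1, stride))
    if starts[-1] != n - tile:
        starts.append(n - tile)
    return starts


def predict_proba_volume(model, study: PetCtStudy, cfg: TilingConfig | None = None
                         ) -> np.ndarray:
    """Averaged per-voxel class probabilities ``(4, nx, ny, nz)``."""
    cfg = cfg or TilingConfig()
    x = stack_input_channels(study)
    shape = x.shape[1:]
    tile = tuple(min(t, _next_mult(n, model.cfg.encoder_depth))
                 for t, n in zip(cfg.tile_size, shape))
    model.check_patch_size(tile)
    # volumes smaller than the tile take a single mirror-padded tile
    pad = [max(0, t - n) for t, n in zip(tile, shape)]
    if any(pad):
        x = np.pad(x, [(0, 0)] + [(0, p) for p in pad], mode="reflect")
    padded_shape = x.shape[1:]
    probs = np.zeros((model.cfg.n_classes, *padded_shape), dtype=np.float64)
    counts = np.zeros(padded_shape, dtype=np.float64)
    starts = [
        _tile_starts(n, t, o)
        for n, t, o in zip(padded_shape, tile, cfg.overlap_voxels)
    ]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = (slice(sx, sx + tile[0]), slice(sy, sy + tile[1]),
                      slice(sz, sz + tile[2]))
                p = model.predict_proba(x[(slice(None), *sl)][None])[0]
                probs[(slice(None), *sl)] += p
                counts[sl] += 1.0
    probs /= counts
    return probs[(slice(None),) + tuple(slice(0, n) for n in shape)]


def _next_mult(n: int, depth: int) -> int:
    div = 2**depth
    return max(div, (n // div) * div)


def predict_volume(model, study: PetCtStudy, cfg: TilingConfig | None = None
                   ) -> LabelMap:
    """Predict a whole-volume 4-class label map for a preprocessed study.

    Every voxel receives exactly one class; ties break toward the lower
    class code. Deterministic on repeated calls.
    """
    probs = predict_proba_volume(model, study, cfg)
    labels = np.argmax(probs, axis=0).astype(np.int16)  # first max wins ties
    return LabelMap(labels, study.spacing_mm, study.pet.origin_mm)


def predict_cohort(model, studies, cfg: TilingConfig | None = None
                   ) -> list[LabelMap | None]:
    """Map :func:`predict_volume` over studies, order-aligned.

    A study failing validation is logged, recorded as ``None`` in the
    output, and reported in a summary at the end; the rest proceed.
    """
    results: list[LabelMap | None] = []
    failures: list[tuple[str, str]] = []
    for study in studies:
        t0 = time.perf_counter()
        try:
            lm = predict_volume(model, study, cfg)
        except PsmasegError as exc:
            logger.error("study %s failed: %s", study.study_id, exc)
            failures.append((study.study_id, str(exc)))
            results.append(None)
            continue
        counts = np.bincount(lm.data.ravel(), minlength=4)
        logger.info(
            "predicted %s in %.2fs; voxel counts bg=%d prostate=%d node=%d bone=%d",
            study.study_id, time.perf_counter() - t0, *counts[:4],
        )
        results.append(lm)
    if failures:
        logger.warning("%d/%d studies failed prediction: %s",
                       len(failures), len(studies), [f[0] for f in failures])
    return results
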