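"""Volume containers and preprocessing for PET-CT studies.

A study bundles four co-registered grids: the PET image in standardised
uptake values (SUV), the CT image in Hounsfield units (HU), a multi-channel
binary organ mask, and (for training/evaluation) a voxel label map with the
classes ``0 = background``, ``1 = prostate tumour/recurrence``,
``2 = lymph-node metastasis`` and ``3 = bone metastasis``.

Preprocessing maps the raw intensities into the classifier's input
representation: the CT is clamped to [-800, 800] HU and the PET to
[0, 25] SUV, each affinely mapped to [0, 1], and all grids are resampled to
a common voxel spacing of 1.37 x 1.37 x 2.79 mm. Continuous images are
interpolated trilinearly, categorical grids (organ channels, labels) with
nearest neighbour so no new codes can appear.

Conventions: arrays are indexed (x, y, z) with 0-based voxel indices; the
world position of index ``i`` is ``origin + i * spacing``; multi-channel
grids are channel-first ``(c, x, y, z)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

LEGAL_CLASS_CODES = (0, 1, 2, 3)
CLASS_NAMES = {0: "background", 1: "prostate", 2: "node", 3: "bone"}
FOREGROUND_CLASSES = (1, 2, 3)
#: organ-mask channels synthesised by the phantom and expected by the model
ORGAN_CHANNELS = ("prostate_bed", "pelvic_nodes", "skeleton", "soft_tissue")


@dataclass
class Volume:
    """One scalar 3D grid (or channel-first 4D for organ masks)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    normalised: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValidationError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "Volume":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class LabelMap:
    """Integer voxel grid restricted to the legal class codes {0,1,2,3}."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("label map must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError("label map must have an integer dtype")
        codes = np.unique(self.data)
        if not np.isin(codes, LEGAL_CLASS_CODES).all():
            bad = sorted(set(codes.tolist()) - set(LEGAL_CLASS_CODES))
            raise ValidationError(f"illegal class codes present: {bad}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "LabelMap":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class PetCtStudy:
    """Aligned PET / CT / organ-mask (and optionally label) bundle."""

    pet: Volume
    ct: Volume
    organs: Volume
    labels: LabelMap | None = None
    study_id: str = "study"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate_alignment()

    def validate_alignment(self) -> None:
        ref_shape = self.pet.grid_shape
        ref_spacing = self.pet.spacing_mm
        members: list[tuple[str, tuple, tuple]] = [
            ("ct", self.ct.grid_shape, self.ct.spacing_mm),
            ("organs", self.organs.grid_shape, self.organs.spacing_mm),
        ]
        if self.labels is not None:
            members.append(("labels", self.labels.grid_shape, self.labels.spacing_mm))
        for name, shape, spacing in members:
            if shape != ref_shape:
                raise AlignmentError(
                    f"{name} grid {shape} does not match PET grid {ref_shape}"
                )
            if not np.allclose(spacing, ref_spacing):
                raise AlignmentError(
                    f"{name} spacing {spacing} does not match PET spacing {ref_spacing}"
                )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.pet.grid_shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.pet.spacing_mm


@dataclass
class PreprocessConfig:
    """Intensity windows and the common voxel grid of the input space."""

    ct_clamp: tuple[float, float] = (-800.0, 800.0)
    pet_clamp: tuple[float, float] = (0.0, 25.0)
    target_spacing_mm: tuple[float, float, float] = (1.37, 1.37, 2.79)

    def __post_init__(self) -> None:
        if self.ct_clamp[1] <= self.ct_clamp[0]:
            raise ValidationError("ct_clamp interval is degenerate")
        if self.pet_clamp[1] <= self.pet_clamp[0]:
            raise ValidationError("pet_clamp interval is degenerate")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValidationError("target spacing must be positive")


# ---------------------------------------------------------------------------
# clamping and normalisation
# ---------------------------------------------------------------------------

def _clamp_unit(data: np.ndarray, lo: float, hi: float, fill: float) -> np.ndarray:
    out = np.asarray(data, dtype=np.float32).copy()
    out[~np.isfinite(out)] = fill
    np.clip(out, lo, hi, out=out)
    out -= lo
    out /= hi - lo
    return out


def clamp_normalise_ct(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clamp CT to the HU window and map it affinely onto [0, 1].

    Missing (non-finite) values are treated as air, i.e. the lower clamp
    bound. Already-normalised volumes pass through unchanged, which makes
    the operator idempotent.
    """
    cfg = cfg or PreprocessConfig()
    if v.normalised:
        return v.copy()
    lo, hi = cfg.ct_clamp
    return dataclasses.replace(v, data=_clamp_unit(v.data, lo, hi, lo), normalised=True)


def clamp_normalise_pet(v: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Clamp PET SUV to [0, 25] and scale to [0, 1]; idempotent."""
    cfg = cfg or PreprocessConfig()
    if v.normalised:
        return v.copy()
    lo, hi = cfg.pet_clamp
    return dataclasses.replace(v, data=_clamp_unit(v.data, lo, hi, lo), normalised=True)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def _resample_grid(
    data: np.ndarray,
    spacing: tuple[float, float, float],
    target: tuple[float, float, float],
    order: int,
) -> np.ndarray:
    """Sample ``data`` on the target-spacing grid anchored at index 0.

    Output voxel ``i`` sits at ``i * target`` mm, i.e. input index
    ``i * target / spacing``. The output extent is the physical extent
    divided by the target spacing, rounded half-up.
    """
    in_shape = np.array(data.shape, dtype=float)
    out_shape = np.maximum(_round_half_up(in_shape * np.array(spacing) / np.array(target)), 1)
    axes = [
        np.arange(n_out) * t / s for n_out, t, s in zip(out_shape, target, spacing)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=np.float32 if order > 0 else data.dtype),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    return out


def resample_study(s: PetCtStudy, cfg: PreprocessConfig | None = None) -> PetCtStudy:
    """Resample every member of a study to the target voxel spacing.

    PET and CT are interpolated trilinearly; organ channels and labels use
    nearest neighbour. A study already on the target grid is returned as a
    voxel-identical copy.
    """
    cfg = cfg or PreprocessConfig()
    target = cfg.target_spacing_mm
    spacing = s.spacing_mm
    if np.allclose(spacing, target):
        return PetCtStudy(
            pet=s.pet.copy(),
            ct=s.ct.copy(),
            organs=s.organs.copy(),
            labels=None if s.labels is None else s.labels.copy(),
            study_id=s.study_id,
            meta=dict(s.meta),
        )
    pet = dataclasses.replace(
        s.pet, data=_resample_grid(s.pet.data, spacing, target, order=1),
        spacing_mm=target,
    )
    ct = dataclasses.replace(
        s.ct, data=_resample_grid(s.ct.data, spacing, target, order=1),
        spacing_mm=target,
    )
    organ_channels = [
        _resample_grid(ch, spacing, target, order=0) for ch in s.organs.data
    ]
    organs = dataclasses.replace(
        s.organs, data=np.stack(organ_channels), spacing_mm=target
    )
    labels = None
    if s.labels is not None:
        labels = LabelMap(
            data=_resample_grid(s.labels.data, spacing, target, order=0),
            spacing_mm=target,
            origin_mm=s.labels.origin_mm,
        )
    return PetCtStudy(pet=pet, ct=ct, organs=organs, labels=labels,
                      study_id=s.study_id, meta=dict(s.meta))


def preprocess_study(s: PetCtStudy, cfg: PreprocessConfig | None = None) -> PetCtStudy:
    """Clamp, normalise and resample a study into the model input space."""
    cfg = cfg or PreprocessConfig()
    s = resample_study(s, cfg)
    return PetCtStudy(
        pet=clamp_normalise_pet(s.pet, cfg),
        ct=clamp_normalise_ct(s.ct, cfg),
        organs=s.organs,
        labels=s.labels,
        study_id=s.study_id,
        meta=dict(s.meta),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, tuple(float(z) for z in zooms), origin


def write_labelmap(l: LabelMap, path: str | Path) -> None:
    """Write a label map as int16 NIfTI (lossless for the legal codes)."""
    img = nib.Nifti1Image(l.data.astype(np.int16), _affine(l.spacing_mm, l.origin_mm))
    nib.save(img, str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    data, spacing, origin = _load_nifti(Path(path))
    return LabelMap(data=np.asarray(data).astype(np.int16), spacing_mm=spacing,
                    origin_mm=origin)


def write_study(s: PetCtStudy, out_dir: str | Path) -> None:
    """Write pet/ct/organs(/labels) NIfTI files plus a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(s.spacing_mm, s.pet.origin_mm)
    nib.save(nib.Nifti1Image(np.asarray(s.pet.data, dtype=np.float32), aff),
             str(out / "pet.nii.gz"))
    nib.save(nib.Nifti1Image(np.asarray(s.ct.data, dtype=np.float32), aff),
             str(out / "ct.nii.gz"))
    # organ mask: channel-first in memory, channel-last (x,y,z,c) on disk
    organs_xyzc = np.moveaxis(np.asarray(s.organs.data, dtype=np.uint8), 0, -1)
    nib.save(nib.Nifti1Image(organs_xyzc, aff), str(out / "organs.nii.gz"))
    if s.labels is not None:
        write_labelmap(s.labels, out / "labels.nii.gz")
    sidecar = {
        "study_id": s.study_id,
        "spacing_mm": list(s.spacing_mm),
        "origin_mm": list(s.pet.origin_mm),
        "pet_normalised": s.pet.normalised,
        "ct_normalised": s.ct.normalised,
        "organ_channels": list(ORGAN_CHANNELS),
        "meta": s.meta,
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))


def read_study(path: str | Path) -> PetCtStudy:
    """Read a study directory written by :func:`write_study`.

    Raises :class:`ValidationError` if a required file is missing and
    :class:`AlignmentError` if member grids disagree.
    """
    root = Path(path)
    for fname in ("pet.nii.gz", "ct.nii.gz", "organs.nii.gz"):
        if not (root / fname).exists():
            raise ValidationError(f"missing required volume file: {fname} in {root}")
    pet_data, spacing, origin = _load_nifti(root / "pet.nii.gz")
    ct_data, ct_spacing, _ = _load_nifti(root / "ct.nii.gz")
    organs_data, org_spacing, _ = _load_nifti(root / "organs.nii.gz")
    if organs_data.ndim != 4:
        raise ValidationError("organs.nii.gz must be 4D (x, y, z, channel)")
    if pet_data.shape != ct_data.shape or pet_data.shape != organs_data.shape[:3]:
        raise AlignmentError(
            f"grid mismatch: pet {pet_data.shape}, ct {ct_data.shape}, "
            f"organs {organs_data.shape[:3]}"
        )
    if not (np.allclose(spacing, ct_spacing) and np.allclose(spacing, org_spacing)):
        raise AlignmentError("member spacings disagree")
    meta: dict = {}
    pet_norm = ct_norm = False
    study_id = root.name
    sidecar = root / "study.json"
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        study_id = info.get("study_id", study_id)
        meta = info.get("meta", {})
        pet_norm = bool(info.get("pet_normalised", False))
        ct_norm = bool(info.get("ct_normalised", False))
    labels = None
    if (root / "labels.nii.gz").exists():
        labels = read_labelmap(root / "labels.nii.gz")
        if labels.grid_shape != pet_data.shape:
            raise AlignmentError("labels grid does not match PET grid")
    return PetCtStudy(
        pet=Volume(np.asarray(pet_data, dtype=np.float32), spacing, origin,
                   normalised=pet_norm),
        ct=Volume(np.asarray(ct_data, dtype=np.float32), spacing, origin,
                  normalised=ct_norm),
        organs=Volume(np.moveaxis(organs_data, -1, 0).astype(np.uint8), spacing,
                      origin),
        labels=labels,
        study_id=study_id,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# model input assembly
# ---------------------------------------------------------------------------

def stack_input_channels(s: PetCtStudy) -> np.ndarray:
    """Stack a preprocessed study into the classifier input tensor.

    Channel order (fixed): ``[CT, PET, organ channels...]``, shape
    ``(2 + n_organ_channels, nx, ny, nz)``. The study must already be
    clamped and normalised: CT and PET values outside [0, 1] or non-binary
    organ channels raise :class:`ValidationError`.
    """
    ct = np.asarray(s.ct.data, dtype=np.float32)
    pet = np.asarray(s.pet.data, dtype=np.float32)
    for name, arr in (("ct", ct), ("pet", pet)):
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValidationError(
                f"{name} values outside [0, 1]; run preprocessing first "
                f"(range {arr.min():.3g}..{arr.max():.3g})"
            )
    organs = np.asarray(s.organs.data)
    if organs.ndim != 4:
        raise ValidationError("organ mask must be 4D channel-first")
    if not np.isin(np.unique(organs), (0, 1)).all():
        raise ValidationError("organ channels must be binary")
    return np.concatenate(
        [ct[None], pet[None], organs.astype(np.float32)], axis=0
    )
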