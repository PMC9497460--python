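"""Synthetic PET-CT phantom studies with known ground-truth lesions.

Every downstream stage (sampling, training, inference, lesion-level
evaluation, burden quantification) is exercised on these phantoms, since no
clinical studies ship with the package. A phantom emulates the structure of
a whole-body PSMA PET-CT study at desk scale:

* a body compartment with CT soft-tissue contrast inside air;
* a skeleton compartment with bone-level HU;
* a prostate-bed sphere and a surrounding pelvic-nodes shell;
* PET background uptake with Gaussian noise, and spherical lesions with
  Gaussian-smoothed edges (a crude stand-in for partial-volume blur) whose
  uptake lies well above background;
* optional "unspecific" bone foci: PET-avid spots inside the skeleton that
  are labelled background, mimicking the benign bone uptake that is a known
  false-positive source for the [18F]PSMA-1007 tracer.

Simulated alternative human readings are produced by perturbing the
ground-truth label map (lesion drop-out, boundary jitter, spurious finds),
so inter-reader comparison tables can be generated without real readers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PlacementError, ValidationError
from .volumes import LabelMap, PetCtStudy, Volume

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: class code -> organ-mask channel index a lesion of that class lives in
_CLASS_COMPARTMENT = {1: 0, 2: 1, 3: 2}

#: default train/validation/test proportions (420/120/120 of 660 studies)
DEFAULT_SPLIT = (420.0, 120.0, 120.0)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic study; defaults are the package's
    standard desk-scale test conditions."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (1.37, 1.37, 2.79)
    background_suv_mean: float = 1.0
    background_suv_sd: float = 0.25
    lesions_per_class: tuple[int, int, int] = (1, 2, 2)
    lesion_radius_range_mm: tuple[float, float] = (3.0, 6.0)
    lesion_suv_range: tuple[float, float] = (5.0, 15.0)
    n_unspecific_bone_foci: int = 2
    ct_tissue_hu: dict = field(
        default_factory=lambda: {"air": -1000.0, "soft": 40.0, "bone": 700.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_suv_range[0] <= self.background_suv_mean:
            raise ValidationError(
                "lesion_suv_range minimum must exceed background_suv_mean"
            )
        if any(n < 0 for n in self.lesions_per_class) or self.n_unspecific_bone_foci < 0:
            raise ValidationError("counts must be >= 0")
        if self.lesion_radius_range_mm[0] <= 0:
            raise ValidationError("lesion radii must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ValidationError("grid_shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValidationError("voxel spacing must be positive")


@dataclass
class ReaderPerturbation:
    """Stochastic model of an alternative human reading."""

    p_drop_lesion: float = 0.0
    p_add_spurious: float = 0.0  # expected spurious lesions per study
    boundary_jitter_voxels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_drop_lesion <= 1.0:
            raise ValidationError("p_drop_lesion must be in [0, 1]")
        if self.p_add_spurious < 0:
            raise ValidationError("p_add_spurious must be >= 0")
        if self.boundary_jitter_voxels < 0:
            raise ValidationError("boundary_jitter_voxels must be >= 0")


@dataclass
class Cohort:
    """Studies plus deterministic train/validation/test split indices."""

    studies: list[PetCtStudy]
    train_idx: list[int]
    val_idx: list[int]
    test_idx: list[int]
    seed: int = 0

    @property
    def train(self) -> list[PetCtStudy]:
        return [self.studies[i] for i in self.train_idx]

    @property
    def val(self) -> list[PetCtStudy]:
        return [self.studies[i] for i in self.val_idx]

    @property
    def test(self) -> list[PetCtStudy]:
        return [self.studies[i] for i in self.test_idx]


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _sphere_mask(shape, centre, radius_mm, spacing) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, spacing))
    return d2 <= radius_mm**2


def _build_anatomy(spec: PhantomSpec, rng: np.random.Generator):
    """Return (organ mask (4, *grid) uint8, CT volume float32, body mask)."""
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    extent = np.array(shape) * np.array(spacing)
    centre_mm = extent / 2.0
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    pos = [g * s for g, s in zip(grids, spacing)]

    # body: centred ellipsoid filling 90% of each axis
    body = sum(((p - c) / (0.45 * e)) ** 2 for p, c, e in zip(pos, centre_mm, extent)) <= 1.0

    # skeleton: two lateral columns plus a posterior "spine" column (along z)
    r_col = 0.10 * min(extent[0], extent[1])
    cols = []
    for cx, cy in (
        (0.28 * extent[0], 0.5 * extent[1]),
        (0.72 * extent[0], 0.5 * extent[1]),
        (0.5 * extent[0], 0.75 * extent[1]),
    ):
        cols.append((pos[0] - cx) ** 2 + (pos[1] - cy) ** 2 <= r_col**2)
    skeleton = (cols[0] | cols[1] | cols[2]) & body

    # prostate bed: small central sphere; pelvic nodes: surrounding shell
    r_pb = 0.14 * extent.min()
    prostate_bed = _sphere_mask(shape, np.array(shape) / 2.0 - 0.5, r_pb, spacing) & body
    nodes_shell = (
        _sphere_mask(shape, np.array(shape) / 2.0 - 0.5, 2.2 * r_pb, spacing)
        & body & ~prostate_bed & ~skeleton
    )
    prostate_bed &= ~skeleton
    soft = body & ~skeleton & ~prostate_bed & ~nodes_shell

    organs = np.stack([prostate_bed, nodes_shell, skeleton, soft]).astype(np.uint8)

    hu = spec.ct_tissue_hu
    ct = np.full(shape, hu["air"], dtype=np.float32)
    ct[body] = hu["soft"]
    ct[skeleton] = hu["bone"]
    ct += rng.normal(0.0, 15.0, shape).astype(np.float32)  # mild detector noise
    return organs, ct, body


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _place_lesion(
    rng: np.random.Generator,
    compartment: np.ndarray,
    occupied: np.ndarray,
    spec: PhantomSpec,
    require_inside: bool,
    radius_range: tuple[float, float] | None = None,
    max_tries: int = 200,
) -> tuple[np.ndarray, float, tuple[int, int, int]] | None:
    """Rejection-sample a sphere inside a compartment, avoiding overlap."""
    shape = spec.grid_shape
    spacing = spec.voxel_spacing_mm
    cand = np.argwhere(compartment & ~occupied)
    if len(cand) == 0:
        return None
    lo, hi = radius_range or spec.lesion_radius_range_mm
    for _ in range(max_tries):
        radius = float(rng.uniform(lo, hi))
        centre = cand[rng.integers(len(cand))]
        # sphere must fit inside the grid
        if any(
            c * s - radius < 0 or (n - 1 - c) * s - radius < 0
            for c, s, n in zip(centre, spacing, shape)
        ):
            continue
        mask = _sphere_mask(shape, centre, radius, spacing)
        if not mask.any() or (mask & occupied).any():
            continue
        if require_inside and not (mask <= compartment.astype(bool)).all():
            continue
        return mask, radius, tuple(int(c) for c in centre)
    return None


def generate_study(spec: PhantomSpec, study_id: str | None = None) -> PetCtStudy:
    """Generate one synthetic PET-CT study with ground-truth labels.

    Deterministic given ``spec.seed``. Lesions are non-overlapping spheres
    separated by at least one background voxel, so the per-class connected
    component count of the label map equals the requested count. Labelled
    voxels are guaranteed PET uptake strictly above
    ``background_suv_mean + background_suv_sd``.

    Raises :class:`PlacementError` when a lesion cannot be placed after
    bounded retries (grid too small / too many lesions).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    organs, ct, _body = _build_anatomy(spec, rng)

    pet = rng.normal(spec.background_suv_mean, spec.background_suv_sd, shape)
    np.clip(pet, 0.0, None, out=pet)
    pet = pet.astype(np.float32)

    labels = np.zeros(shape, dtype=np.int16)
    occupied = np.zeros(shape, dtype=bool)
    lesion_records: list[dict] = []

    def add_uptake(mask: np.ndarray, suv: float) -> None:
        g = ndimage.gaussian_filter(mask.astype(np.float32), sigma=1.0)
        peak = g.max()
        if peak > 0:
            pet[...] += (suv - spec.background_suv_mean) * (g / peak)

    for class_code, count in zip((1, 2, 3), spec.lesions_per_class):
        compartment = organs[_CLASS_COMPARTMENT[class_code]].astype(bool)
        for k in range(count):
            placed = _place_lesion(
                rng, compartment, occupied, spec, require_inside=(class_code == 3)
            )
            if placed is None:
                raise PlacementError(
                    f"could not place lesion {k + 1}/{count} of class "
                    f"{class_code} on grid {shape}"
                )
            mask, radius, centre = placed
            labels[mask] = class_code
            # dilated footprint keeps a >=1 voxel gap between lesions so
            # 26-connected components never merge
            occupied |= ndimage.binary_dilation(mask, structure=_STRUCT26)
            suv = float(rng.uniform(*spec.lesion_suv_range))
            add_uptake(mask, suv)
            lesion_records.append(
                {"class": class_code, "centre": list(centre),
                 "radius_mm": radius, "suv": suv}
            )

    foci_records: list[dict] = []
    skeleton = organs[2].astype(bool)
    for _ in range(spec.n_unspecific_bone_foci):
        placed = _place_lesion(rng, skeleton, occupied, spec, require_inside=True)
        if placed is None:
            logger.warning("unspecific bone focus could not be placed; skipping")
            continue
        mask, radius, centre = placed
        occupied |= ndimage.binary_dilation(mask, structure=_STRUCT26)
        suv = float(rng.uniform(*spec.lesion_suv_range))
        add_uptake(mask, suv)
        foci_records.append(
            {"centre": list(centre), "radius_mm": radius, "suv": suv}
        )

    # enforce the uptake invariant at labelled voxels (the smoothed edge of
    # a small sphere can otherwise dip toward background on an unlucky
    # noise draw)
    floor = spec.background_suv_mean + 2.0 * spec.background_suv_sd
    fg = labels > 0
    pet[fg] = np.maximum(pet[fg], floor)
    assert (pet[fg] > spec.background_suv_mean + spec.background_suv_sd).all()

    spacing = spec.voxel_spacing_mm
    sid = study_id or f"phantom-{spec.seed:08d}"
    return PetCtStudy(
        pet=Volume(pet, spacing),
        ct=Volume(ct, spacing),
        organs=Volume(organs, spacing),
        labels=LabelMap(labels, spacing),
        study_id=sid,
        meta={"seed": int(spec.seed), "lesions": lesion_records,
              "unspecific_foci": foci_records},
    )


def split_counts(n: int, proportions: tuple[float, float, float] = DEFAULT_SPLIT
                 ) -> tuple[int, int, int]:
    """Apportion ``n`` studies into (train, val, test) by largest remainder.

    Ties between fractional remainders are broken toward the earlier bucket
    (train before validation before test).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    props = np.asarray(proportions, dtype=float)
    quotas = n * props / props.sum()
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(remainders))  # argmax takes the first on ties
        counts[i] += 1
        remainders[i] = -1.0
    return tuple(int(c) for c in counts)


def generate_cohort(
    n: int,
    spec: PhantomSpec,
    proportions: tuple[float, float, float] = DEFAULT_SPLIT,
) -> Cohort:
    """Generate ``n`` studies with per-study seeds derived from ``spec.seed``
    and a deterministic train/validation/test split."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    studies = [
        generate_study(dataclasses.replace(spec, seed=int(seeds[i])),
                       study_id=f"study-{i:04d}")
        for i in range(n)
    ]
    n_train, n_val, n_test = split_counts(n, proportions)
    idx = list(range(n))
    return Cohort(
        studies=studies,
        train_idx=idx[:n_train],
        val_idx=idx[n_train:n_train + n_val],
        test_idx=idx[n_train + n_val:],
        seed=int(spec.seed),
    )


# ---------------------------------------------------------------------------
# simulated alternative readings
# ---------------------------------------------------------------------------

def perturb_reading(truth: LabelMap, pert: ReaderPerturbation) -> LabelMap:
    """Simulate an alternative human reading of a ground-truth label map.

    Each true lesion (26-connected component, per class) is independently
    dropped with probability ``p_drop_lesion``; survivors are dilated or
    eroded by up to ``boundary_jitter_voxels`` (erosion backs off rather
    than extinguishing a lesion); spurious lesions are added with expected
    count ``p_add_spurious``, placed on background of both truth and
    output. Deterministic given ``pert.seed``; the zero perturbation is the
    identity.
    """
    rng = np.random.default_rng(pert.seed)
    data = truth.data
    out = np.zeros_like(data)
    jmax = pert.boundary_jitter_voxels
    for class_code in (1, 2, 3):
        comp, n_comp = ndimage.label(data == class_code, structure=_STRUCT26)
        for ci in range(1, n_comp + 1):
            if rng.random() < pert.p_drop_lesion:
                continue
            mask = comp == ci
            if jmax > 0:
                j = int(rng.integers(-jmax, jmax + 1))
                if j > 0:
                    mask = ndimage.binary_dilation(mask, iterations=j)
                elif j < 0:
                    for it in range(-j, 0, -1):
                        eroded = ndimage.binary_erosion(mask, iterations=it)
                        if eroded.any():
                            mask = eroded
                            break
            out[mask] = class_code

    n_spurious = int(rng.poisson(pert.p_add_spurious))
    shape = data.shape
    for _ in range(n_spurious):
        placed = False
        for _try in range(20):
            centre = [int(rng.integers(n)) for n in shape]
            radius = int(rng.integers(1, 3))
            mask = _sphere_mask(shape, centre, radius + 0.01, (1.0, 1.0, 1.0))
            mask &= (out == 0) & (data == 0)
            if mask.any():
                out[mask] = int(rng.integers(1, 4))
                placed = True
                break
        if not placed:
            logger.warning("spurious lesion could not be placed; skipping")
    return LabelMap(out, truth.spacing_mm, truth.origin_mm)
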