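"""Lesion-level evaluation: extraction, overlap matching, reader tables.

A *lesion* is a maximal 26-connected component of one class in a label
map. Matching between a candidate segmentation (model output or a human
reading) and a reference reading follows the overlap criterion:

* a reference lesion with at least one candidate voxel of the same class
  overlapping it is *detected*; with no overlap it is a false negative;
* a candidate lesion overlapping at least one reference voxel is a true
  positive; with no overlap it is a false positive;
* sensitivity = detected reference lesions / all reference lesions;
* PPV = TP / (TP + FP).

Detected-reference and TP-candidate counts are tracked separately so a
single candidate spanning two reference lesions does not inflate PPV.
This makes the counts dual: the false positives of X against reference Y
are exactly the false negatives of Y against reference X.

Tumour-burden agreement between two sources is assessed with Spearman
rank correlation (average ranks on ties, two-sided p).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import AlignmentError, ValidationError
from .volumes import FOREGROUND_CLASSES, LabelMap, Volume

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Lesion:
    """One connected lesion with its volume and mean uptake."""

    class_code: int
    voxel_indices: np.ndarray  # (n, 3) int
    volume_ml: float
    suv_mean: float
    lesion_id: str

    def __post_init__(self) -> None:
        if self.class_code not in FOREGROUND_CLASSES:
            raise ValidationError(f"illegal lesion class {self.class_code}")
        if len(self.voxel_indices) == 0:
            raise ValidationError("a lesion must contain at least one voxel")


@dataclass
class LesionSet:
    lesions: list[Lesion]
    source_id: str = "source"
    study_id: str = "study"
    grid_shape: tuple[int, int, int] | None = None

    def of_class(self, class_code: int) -> list[Lesion]:
        return [l for l in self.lesions if l.class_code == class_code]


@dataclass
class MatchResult:
    """Lesion-level comparison of a candidate set against a reference."""

    tp: int
    fp: int
    fn: int
    n_detected_ref: int
    n_ref: int
    sensitivity: float
    ppv: float
    class_code: int
    candidate_id: str
    reference_id: str
    tp_ids: list[str] = field(default_factory=list)
    fp_ids: list[str] = field(default_factory=list)
    fn_ids: list[str] = field(default_factory=list)
    detected_ref_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_lesions(labels: LabelMap, pet: Volume, source_id: str = "source",
                    study_id: str = "study") -> LesionSet:
    """Extract per-class 26-connected components with volume and SUVmean.

    Components are computed independently per class, so touching lesions
    of different classes stay separate. Volume is voxel count times voxel
    volume (mL); SUVmean averages the PET volume over the lesion voxels.
    """
    if labels.grid_shape != pet.grid_shape:
        raise AlignmentError("label map and PET volume are not aligned")
    if not np.allclose(labels.spacing_mm, pet.spacing_mm):
        raise AlignmentError("label map and PET volume spacings differ")
    vox_ml = labels.voxel_volume_mm3 / 1000.0
    lesions: list[Lesion] = []
    for c in FOREGROUND_CLASSES:
        comp, n_comp = ndimage.label(labels.data == c, structure=_STRUCT26)
        for ci in range(1, n_comp + 1):
            idx = np.argwhere(comp == ci)
            suv = float(pet.data[tuple(idx.T)].mean())
            lesions.append(Lesion(
                class_code=c,
                voxel_indices=idx,
                volume_ml=len(idx) * vox_ml,
                suv_mean=suv,
                lesion_id=f"{study_id}:{source_id}:c{c}:l{ci}",
            ))
    return LesionSet(lesions, source_id=source_id, study_id=study_id,
                     grid_shape=labels.grid_shape)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _voxel_keys(lesion: Lesion, shape) -> set[int]:
    return set(np.ravel_multi_index(lesion.voxel_indices.T, shape).tolist())


def match_lesions(candidate: LesionSet, reference: LesionSet, class_code: int
                  ) -> MatchResult:
    """Match candidate lesions against a reference by voxel overlap.

    Any same-class overlap (one voxel suffices) counts: a reference lesion
    overlapped by any candidate is detected, a candidate overlapping any
    reference is TP. Sensitivity is NaN when the reference has no lesions
    of the class; PPV is NaN when the candidate has none.
    """
    if class_code not in FOREGROUND_CLASSES:
        raise ValueError(f"illegal class code {class_code}")
    if candidate.study_id != reference.study_id:
        raise ValueError("candidate and reference are from different studies")
    shape = candidate.grid_shape or reference.grid_shape
    if shape is None:
        shape = tuple(
            int(max(
                (l.voxel_indices[:, a].max() for l in
                 candidate.lesions + reference.lesions), default=0,
            )) + 1
            for a in range(3)
        )
    cand = candidate.of_class(class_code)
    ref = reference.of_class(class_code)
    cand_vox = [_voxel_keys(l, shape) for l in cand]
    ref_vox = [_voxel_keys(l, shape) for l in ref]

    detected_ids, fn_ids = [], []
    for lesion, vox in zip(ref, ref_vox):
        if any(vox & cv for cv in cand_vox):
            detected_ids.append(lesion.lesion_id)
        else:
            fn_ids.append(lesion.lesion_id)
    tp_ids, fp_ids = [], []
    for lesion, vox in zip(cand, cand_vox):
        if any(vox & rv for rv in ref_vox):
            tp_ids.append(lesion.lesion_id)
        else:
            fp_ids.append(lesion.lesion_id)

    n_ref = len(ref)
    tp, fp = len(tp_ids), len(fp_ids)
    sensitivity = len(detected_ids) / n_ref if n_ref else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return MatchResult(
        tp=tp, fp=fp, fn=len(fn_ids), n_detected_ref=len(detected_ids),
        n_ref=n_ref, sensitivity=sensitivity, ppv=ppv, class_code=class_code,
        candidate_id=candidate.source_id, reference_id=reference.source_id,
        tp_ids=tp_ids, fp_ids=fp_ids, fn_ids=fn_ids,
        detected_ref_ids=detected_ids,
    )


# ---------------------------------------------------------------------------
# pairwise reader/model comparison tables
# ---------------------------------------------------------------------------

def pairwise_report(
    sets_by_source: dict[str, dict[str, LesionSet]],
    class_code: int,
) -> pd.DataFrame:
    """Pairwise candidate-vs-reference table pooled over shared studies.

    ``sets_by_source`` maps source name (e.g. ``"AI"``, ``"A"``) to a
    per-study dict of lesion sets. For each ordered (candidate, reference)
    pair the studies present in both sources are pooled: TP/FP/FN totals,
    per-patient means (over all shared patients, including those without
    reference lesions), pooled sensitivity (detected references over all
    references) and pooled PPV. Summary rows (reference ``"mean-of-refs"``)
    average each candidate's per-reference pooled values — averages of
    ratios, not ratios of pooled sums.
    """
    sources = sorted(sets_by_source)
    if len(sources) < 2:
        raise ValueError("need at least two sources")
    rows = []
    any_shared = False
    for cand_src, ref_src in itertools.permutations(sources, 2):
        shared = sorted(
            set(sets_by_source[cand_src]) & set(sets_by_source[ref_src])
        )
        if not shared:
            continue
        any_shared = True
        tot = {"tp": 0, "fp": 0, "fn": 0, "detected": 0, "n_ref": 0}
        for sid in shared:
            m = match_lesions(
                sets_by_source[cand_src][sid], sets_by_source[ref_src][sid],
                class_code,
            )
            tot["tp"] += m.tp
            tot["fp"] += m.fp
            tot["fn"] += m.fn
            tot["detected"] += m.n_detected_ref
            tot["n_ref"] += m.n_ref
        n_pat = len(shared)
        rows.append({
            "candidate": cand_src, "reference": ref_src, "n_patients": n_pat,
            "tp": tot["tp"], "fp": tot["fp"], "fn": tot["fn"],
            "tp_per_patient": tot["tp"] / n_pat,
            "fp_per_patient": tot["fp"] / n_pat,
            "fn_per_patient": tot["fn"] / n_pat,
            "sensitivity": (tot["detected"] / tot["n_ref"]
                            if tot["n_ref"] else float("nan")),
            "ppv": (tot["tp"] / (tot["tp"] + tot["fp"])
                    if tot["tp"] + tot["fp"] else float("nan")),
            "class_code": class_code,
        })
    if not any_shared:
        raise ValueError("no two sources share any study")
    df = pd.DataFrame(rows)
    summaries = []
    for cand_src, grp in df.groupby("candidate"):
        summary = {
            "candidate": cand_src, "reference": "mean-of-refs",
            "n_patients": grp["n_patients"].mean(), "class_code": class_code,
        }
        for col in ("tp", "fp", "fn", "tp_per_patient", "fp_per_patient",
                    "fn_per_patient", "sensitivity", "ppv"):
            summary[col] = grp[col].mean()
            summary[f"{col}_min"] = grp[col].min()
            summary[f"{col}_max"] = grp[col].max()
        summaries.append(summary)
    return pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)


# ---------------------------------------------------------------------------
# burden correlation
# ---------------------------------------------------------------------------

def spearman_burden(burden_a, burden_b) -> tuple[float, float]:
    """Spearman rank correlation between two per-study burden vectors.

    Average ranks on ties, two-sided p-value. Requires paired vectors of
    length >= 3; a zero-variance vector yields NaN with a warning.
    """
    a = np.asarray(burden_a, dtype=float)
    b = np.asarray(burden_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("burden vectors must be paired (equal length)")
    if a.size < 3:
        raise ValueError("need at least 3 paired studies")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero variance in a burden vector; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
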