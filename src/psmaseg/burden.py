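"""Tumour-burden quantification: total lesion volume and uptake.

TLV (total lesion volume, mL) sums the volume of all segmented voxels of
a class. TLU (total lesion uptake, SUV*mL) is the analogue of total
lesion glycolysis: per lesion, SUVmean times lesion volume, summed over
the lesions of a class. Classes with no lesions report 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lesion_eval import Lesion, LesionSet
from .volumes import FOREGROUND_CLASSES


@dataclass
class BurdenSummary:
    """Per-class TLV (mL) and TLU (SUV*mL) for one study and source."""

    tlv_ml: dict[int, float] = field(default_factory=dict)
    tlu: dict[int, float] = field(default_factory=dict)
    study_id: str = "study"
    source_id: str = "source"


def lesion_tlv(lesion: Lesion, spacing_mm) -> float:
    """Lesion volume in mL: voxel count x voxel volume."""
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    vox_mm3 = spacing_mm[0] * spacing_mm[1] * spacing_mm[2]
    return len(lesion.voxel_indices) * vox_mm3 / 1000.0


def lesion_tlu(lesion: Lesion) -> float:
    """Lesion uptake in SUV*mL: SUVmean x lesion volume."""
    return lesion.suv_mean * lesion.volume_ml


def study_burden(lesions: LesionSet, spacing_mm) -> BurdenSummary:
    """Per-class TLV/TLU sums for one study; absent classes report 0."""
    tlv = {c: 0.0 for c in FOREGROUND_CLASSES}
    tlu = {c: 0.0 for c in FOREGROUND_CLASSES}
    for lesion in lesions.lesions:
        tlv[lesion.class_code] += lesion_tlv(lesion, spacing_mm)
        tlu[lesion.class_code] += lesion_tlu(lesion)
    return BurdenSummary(tlv_ml=tlv, tlu=tlu, study_id=lesions.study_id,
                         source_id=lesions.source_id)


def cohort_burden_table(summaries: list[BurdenSummary]):
    """Long-format burden table (study_id, source, class, tlv_ml, tlu)."""
    import pandas as pd

    rows = [
        {"study_id": s.study_id, "source": s.source_id, "class_code": c,
         "tlv_ml": s.tlv_ml.get(c, 0.0), "tlu": s.tlu.get(c, 0.0)}
        for s in summaries
        for c in FOREGROUND_CLASSES
    ]
    return pd.DataFrame(rows)
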