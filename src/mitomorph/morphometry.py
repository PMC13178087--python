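"""Mitochondrial ultrastructure morphometry from traced EM annotations.

Three quantities per patient:

* **TAIM** (total area of interfibrillar mitochondria, %): per 5000× scene,
  the summed mitochondrial cross-section area inside the interfibrillar space
  divided by that space's area, ×100; mitochondria partially outside are
  clipped to the region.  The interfibrillar space denominator includes the
  mitochondrial area itself (the organelles lie within the counted space).
* **OIMR** (outer-to-inner membrane length ratio, %): per 15,000×
  mitochondrion, outer contour length divided by the total traced
  inner-membrane length — the inner boundary plus every crista — ×100.
  Lower values mean denser cristae.
* **Total index**: patient TAIM% / patient OIMR%, dimensionless.  Higher
  values indicate dense mitochondrial packing with elaborate inner membranes.

The measurement protocol analyzes three micrographs per patient and, for
OIMR, three mitochondria per micrograph; the per-patient value is the
arithmetic mean over all measurements.  ``strict=True`` enforces the 3×3
design; by default deviations only raise a warning so the tool remains usable
on other designs.  For balanced designs the grand mean equals the mean of
per-scene means; for unbalanced input the grand mean (each mitochondrion
weighted equally) is used.

All quantities are ratios of areas or lengths, hence invariant to the pixel
scale, to rotation and to translation of the traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from shapely.ops import unary_union

from .annotation_io import AnnotationScene, MembraneSet, PatientRecord
from .geometry import clip_to_region, polygon_area, polyline_length

__all__ = [
    "MorphometryError",
    "ProtocolViolation",
    "MorphometryResult",
    "taim_for_scene",
    "oimr_for_mitochondrion",
    "patient_taim",
    "patient_oimr",
    "total_index",
    "compute_patient",
    "compute_cohort",
]

#: micrographs per patient and mitochondria per micrograph in the protocol
PROTOCOL_N_SCENES = 3
PROTOCOL_N_MITO = 3


class MorphometryError(ValueError):
    """Scene content insufficient or invalid for the requested measurement."""


class ProtocolViolation(MorphometryError):
    """Input departs from the 3 micrographs × 3 mitochondria protocol."""


@dataclass
class MorphometryResult:
    """Per-patient morphometry summary.

    Percentages are carried at full float precision; rounding is applied only
    for display (TAIM one decimal, OIMR one decimal, index two decimals).
    """

    patient_id: str
    group_label: int
    taim_pct: float
    oimr_pct: float
    total_index: float
    n_micrographs_5000x: int
    n_mitochondria_15000x: int

    def rounded(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "group_label": self.group_label,
            "taim_pct": round(self.taim_pct, 1),
            "oimr_pct": round(self.oimr_pct, 1),
            "total_index": round(self.total_index, 2),
        }


def taim_for_scene(scene: AnnotationScene) -> float:
    """Percentage of the interfibrillar space occupied by mitochondria.

    ``100 × Σ_i area(mito_i ∩ region-union) / Σ_j area(region_j)``.  A scene
    with regions but no mitochondria is an error, not 0 — it is
    indistinguishable from an unannotated micrograph.
    """
    if not scene.interfibrillar_regions:
        raise MorphometryError(
            f"scene {scene.micrograph_id!r}: no interfibrillar region traced"
        )
    if not scene.mitochondria:
        raise MorphometryError(
            f"scene {scene.micrograph_id!r}: no mitochondria traced "
            "(an empty scene is not a 0% measurement)"
        )
    denom = sum(polygon_area(r) for r in scene.interfibrillar_regions)
    if denom <= 0:
        raise MorphometryError(
            f"scene {scene.micrograph_id!r}: zero total region area"
        )
    region_union = unary_union(
        [r.to_shapely() for r in scene.interfibrillar_regions]
    )
    numer = sum(clip_to_region(m, region_union) for m in scene.mitochondria)
    return 100.0 * numer / denom


def oimr_for_mitochondrion(m: MembraneSet) -> float:
    """Outer-membrane length as a percentage of total inner-membrane length."""
    outer_len = polyline_length(m.outer)
    inner_len = sum(polyline_length(t) for t in m.inner_traces)
    if inner_len <= 0:
        raise MorphometryError(
            f"mitochondrion {m.mitochondrion_id!r}: zero inner-membrane length"
        )
    return 100.0 * outer_len / inner_len


def _check_protocol(counts: Sequence[int], what: str, per_scene: int | None,
                    strict: bool) -> None:
    ok = len(counts) == PROTOCOL_N_SCENES and (
        per_scene is None or all(c == per_scene for c in counts)
    )
    if ok:
        return
    msg = (
        f"{what}: expected {PROTOCOL_N_SCENES} micrographs"
        + (f" × {per_scene} mitochondria" if per_scene else "")
        + f", got counts {list(counts)}"
    )
    if strict:
        raise ProtocolViolation(msg)
    warnings.warn(msg, stacklevel=3)


def patient_taim(scenes: Iterable[AnnotationScene], strict: bool = False) -> float:
    """Arithmetic mean of per-scene TAIM values (the 5000× protocol)."""
    scenes = list(scenes)
    if not scenes:
        raise MorphometryError("patient_taim: no 5000x scenes")
    _check_protocol([1] * len(scenes), "patient_taim", None, strict)
    values = [taim_for_scene(s) for s in scenes]
    return sum(values) / len(values)


def patient_oimr(scenes: Iterable[AnnotationScene], strict: bool = False) -> float:
    """Grand mean of per-mitochondrion OIMR values across 15,000× scenes.

    Under the balanced 3 scenes × 3 mitochondria protocol this equals the
    mean of per-scene means; for unbalanced input every measured
    mitochondrion is weighted equally.
    """
    scenes = list(scenes)
    if not scenes:
        raise MorphometryError("patient_oimr: no 15000x scenes")
    counts = [len(s.membrane_sets) for s in scenes]
    if any(c == 0 for c in counts):
        empty = [s.micrograph_id for s in scenes if not s.membrane_sets]
        raise MorphometryError(f"scenes without membrane sets: {empty}")
    _check_protocol(counts, "patient_oimr", PROTOCOL_N_MITO, strict)
    values = [oimr_for_mitochondrion(m) for s in scenes for m in s.membrane_sets]
    return sum(values) / len(values)


def total_index(taim_pct: float, oimr_pct: float) -> float:
    """Total ultrastructure index: patient TAIM% divided by patient OIMR%.

    Both inputs are percentages; the index is computed from the two
    patient-level parameters (not per scene) and kept unrounded.
    """
    if not (taim_pct > 0 and oimr_pct > 0):
        raise MorphometryError(
            f"total_index requires positive percentages, got "
            f"taim={taim_pct!r}, oimr={oimr_pct!r}"
        )
    return taim_pct / oimr_pct


def compute_patient(record: PatientRecord, strict: bool = False) -> MorphometryResult:
    """Full per-patient pipeline: TAIM, OIMR and the total index."""
    taim = patient_taim(record.scenes_5000x, strict=strict)
    oimr = patient_oimr(record.scenes_15000x, strict=strict)
    return MorphometryResult(
        patient_id=record.patient_id,
        group_label=record.group_label,
        taim_pct=taim,
        oimr_pct=oimr,
        total_index=total_index(taim, oimr),
        n_micrographs_5000x=len(record.scenes_5000x),
        n_mitochondria_15000x=sum(
            len(s.membrane_sets) for s in record.scenes_15000x
        ),
    )


def compute_cohort(records: Iterable[PatientRecord],
                   strict: bool = False) -> list[MorphometryResult]:
    return [compute_patient(r, strict=strict) for r in records]
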