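"""Annotation containers and I/O: ImageJ ROI archives, GeoJSON scenes, CSV.

A scene is everything traced on one micrograph.  Each trace carries a role
from a closed vocabulary:

* ``interfibrillar`` — closed contour of the interfibrillar space (5000×),
* ``mitochondrion``  — closed mitochondrial cross-section inside it (5000×),
* ``outer_membrane`` — closed outer-membrane contour of one mitochondrion (15,000×),
* ``inner_membrane`` — inner-membrane / cristae trace, open or closed (15,000×).

Membrane traces are grouped per mitochondrion via a ``mitochondrion_id``.
Coordinates are pixel positions with the y axis pointing image-down, the
native convention of raster annotation tools; all derived quantities are
ratios, so no pixel-size calibration is stored.

ImageJ ROI files carry no role metadata, so roles come from an explicit
manifest table (``roi_name, role, mitochondrion_id``) rather than from name
parsing heuristics.  The GeoJSON dialect stores the same information in each
feature's ``properties``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from . import ijroi
from .geometry import Polygon, Polyline, polyline_length

__all__ = [
    "ROLES",
    "AnnotationError",
    "AnnotationScene",
    "MembraneSet",
    "PatientRecord",
    "read_imagej_rois",
    "write_imagej_rois",
    "read_geojson_scene",
    "write_geojson_scene",
    "write_results_csv",
    "read_results_csv",
    "RESULT_COLUMNS",
]

ROLES = ("interfibrillar", "mitochondrion", "outer_membrane", "inner_membrane")

RESULT_COLUMNS = [
    "patient_id",
    "group_label",
    "taim_pct",
    "oimr_pct",
    "total_index",
    "n_micrographs_5000x",
    "n_mitochondria_15000x",
]


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass
class MembraneSet:
    """Outer contour plus all inner-membrane traces of one mitochondrion.

    The inner traces comprise the inner boundary membrane (if traced) and
    every crista; their lengths are summed downstream.
    """

    mitochondrion_id: str
    outer: Polygon
    inner_traces: list[Union[Polyline, Polygon]]

    def __post_init__(self) -> None:
        if not self.inner_traces:
            raise AnnotationError(
                f"mitochondrion {self.mitochondrion_id!r}: no inner-membrane traces"
            )
        total = sum(polyline_length(t) for t in self.inner_traces)
        if total <= 0:
            raise AnnotationError(
                f"mitochondrion {self.mitochondrion_id!r}: zero total inner length"
            )


@dataclass
class AnnotationScene:
    """All labeled traces of one micrograph."""

    micrograph_id: str
    magnification: int
    interfibrillar_regions: list[Polygon] = field(default_factory=list)
    mitochondria: list[Polygon] = field(default_factory=list)
    membrane_sets: list[MembraneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.micrograph_id:
            raise AnnotationError("micrograph_id must be nonempty")


@dataclass
class PatientRecord:
    """One patient: binary outcome label plus scenes at both magnifications."""

    patient_id: str
    group_label: int
    scenes_5000x: list[AnnotationScene] = field(default_factory=list)
    scenes_15000x: list[AnnotationScene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group_label not in (0, 1):
            raise AnnotationError(
                f"patient {self.patient_id!r}: group_label must be 0 or 1, "
                f"got {self.group_label!r}"
            )


# ---------------------------------------------------------------------------
# ImageJ ROI archives


def _load_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest, dtype=str)
    manifest = pd.DataFrame(manifest)
    required = {"roi_name", "role"}
    missing = required - set(manifest.columns)
    if missing:
        raise AnnotationError(f"manifest lacks columns: {sorted(missing)}")
    if "mitochondrion_id" not in manifest.columns:
        manifest = manifest.assign(mitochondrion_id=None)
    bad = set(manifest["role"]) - set(ROLES)
    if bad:
        raise AnnotationError(
            f"manifest has unknown roles {sorted(bad)}; vocabulary is {list(ROLES)}"
        )
    return manifest.set_index("roi_name")


def _assemble_membrane_sets(
    outers: dict[str, Polygon],
    inners: dict[str, list[Union[Polyline, Polygon]]],
    context: str,
) -> list[MembraneSet]:
    sets = []
    for mid in sorted(set(outers) | set(inners)):
        if mid not in outers:
            raise AnnotationError(
                f"{context}: mitochondrion {mid!r} has inner traces but no outer contour"
            )
        if mid not in inners:
            raise AnnotationError(
                f"{context}: mitochondrion {mid!r} has an outer contour but no inner traces"
            )
        sets.append(MembraneSet(mid, outers[mid], inners[mid]))
    return sets


def read_imagej_rois(
    path: str | Path,
    manifest,
    micrograph_id: str | None = None,
    magnification: int = 5000,
) -> AnnotationScene:
    """Read a ``.roi`` file or ``.zip`` ROI archive into a scene.

    ``manifest`` maps each ROI name to a role (and, for membrane traces, a
    ``mitochondrion_id``); it may be a DataFrame, a list of dicts, or a path
    to a CSV with columns ``roi_name, role[, mitochondrion_id]``.
    """
    path = Path(path)
    table = _load_manifest(manifest)
    try:
        rois = ijroi.read_roi_archive(path)
    except ijroi.RoiFormatError as exc:
        raise AnnotationError(str(exc)) from exc

    regions: list[Polygon] = []
    mitochondria: list[Polygon] = []
    outers: dict[str, Polygon] = {}
    inners: dict[str, list[Union[Polyline, Polygon]]] = {}

    for roi in rois:
        if roi.name not in table.index:
            raise AnnotationError(
                f"ROI {roi.name!r} is absent from the role manifest"
            )
        row = table.loc[roi.name]
        role = row["role"]
        if role == "inner_membrane":
            shape: Union[Polyline, Polygon]
            shape = (Polygon if roi.closed else Polyline)(roi.coords, label=roi.name)
        else:
            if not roi.closed:
                raise AnnotationError(
                    f"ROI {roi.name!r}: role {role!r} requires a closed contour, "
                    "got an open trace"
                )
            shape = Polygon(roi.coords, label=roi.name)
        if role == "interfibrillar":
            regions.append(shape)
        elif role == "mitochondrion":
            mitochondria.append(shape)
        else:
            mid = row.get("mitochondrion_id")
            if mid is None or (isinstance(mid, float) and np.isnan(mid)) or mid == "":
                raise AnnotationError(
                    f"ROI {roi.name!r}: membrane role needs a mitochondrion_id"
                )
            mid = str(mid)
            if role == "outer_membrane":
                if mid in outers:
                    raise AnnotationError(
                        f"mitochondrion {mid!r} has more than one outer contour"
                    )
                outers[mid] = shape
            else:
                inners.setdefault(mid, []).append(shape)

    scene_id = micrograph_id or path.stem
    return AnnotationScene(
        micrograph_id=scene_id,
        magnification=magnification,
        interfibrillar_regions=regions,
        mitochondria=mitochondria,
        membrane_sets=_assemble_membrane_sets(outers, inners, scene_id),
    )


def write_imagej_rois(scene: AnnotationScene, path: str | Path) -> pd.DataFrame:
    """Write a scene to an ImageJ ``.zip`` ROI archive (fixture writer).

    Coordinates are rounded to integer pixels — the format stores int16
    offsets.  Returns the role manifest needed to read the archive back.
    """
    rois: list[ijroi.RoiRecord] = []
    rows: list[dict] = []

    def add(name: str, coords: np.ndarray, closed: bool, role: str, mid=None):
        rois.append(ijroi.RoiRecord(name, coords, closed))
        rows.append({"roi_name": name, "role": role, "mitochondrion_id": mid})

    for i, region in enumerate(scene.interfibrillar_regions):
        add(f"ifs_{i + 1}", region.coords, True, "interfibrillar")
    for i, mito in enumerate(scene.mitochondria):
        add(f"mito_{i + 1}", mito.coords, True, "mitochondrion")
    for ms in scene.membrane_sets:
        add(f"outer_{ms.mitochondrion_id}", ms.outer.coords, True,
            "outer_membrane", ms.mitochondrion_id)
        for j, trace in enumerate(ms.inner_traces):
            add(f"inner_{ms.mitochondrion_id}_{j + 1}", trace.coords,
                isinstance(trace, Polygon), "inner_membrane", ms.mitochondrion_id)

    ijroi.write_roi_archive(path, rois)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GeoJSON dialect


def _feature(geometry_obj, role: str, scene: AnnotationScene, mid: str | None = None):
    if isinstance(geometry_obj, Polygon):
        ring = geometry_obj.coords.tolist()
        ring.append(ring[0])
        geometry = {"type": "Polygon", "coordinates": [ring]}
    else:
        geometry = {"type": "LineString", "coordinates": geometry_obj.coords.tolist()}
    props = {
        "role": role,
        "micrograph_id": scene.micrograph_id,
        "magnification": scene.magnification,
    }
    if mid is not None:
        props["mitochondrion_id"] = mid
    return {"type": "Feature", "geometry": geometry, "properties": props}


def write_geojson_scene(scene: AnnotationScene, path: str | Path) -> None:
    """Write a scene as a GeoJSON FeatureCollection.

    Coordinates are pixel positions (y image-down); roles and the micrograph
    metadata live in feature properties, so the write→read roundtrip is
    lossless.
    """
    features = []
    for region in scene.interfibrillar_regions:
        features.append(_feature(region, "interfibrillar", scene))
    for mito in scene.mitochondria:
        features.append(_feature(mito, "mitochondrion", scene))
    for ms in scene.membrane_sets:
        features.append(_feature(ms.outer, "outer_membrane", scene, ms.mitochondrion_id))
        for trace in ms.inner_traces:
            features.append(_feature(trace, "inner_membrane", scene, ms.mitochondrion_id))
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_geojson_scene(path: str | Path) -> AnnotationScene:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: not a FeatureCollection")
    features = doc.get("features", [])
    if not features:
        raise AnnotationError(f"{path}: empty FeatureCollection")

    micrograph_ids = set()
    magnification = None
    regions: list[Polygon] = []
    mitochondria: list[Polygon] = []
    outers: dict[str, Polygon] = {}
    inners: dict[str, list[Union[Polyline, Polygon]]] = {}

    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        role = props.get("role")
        if role is None:
            raise AnnotationError(f"feature {i}: missing 'role' property")
        if role not in ROLES:
            raise AnnotationError(
                f"feature {i}: unknown role {role!r}; vocabulary is {list(ROLES)}"
            )
        micrograph_ids.add(props.get("micrograph_id"))
        if props.get("magnification") is not None:
            magnification = int(props["magnification"])
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        label = f"feature_{i}"
        if gtype == "Polygon":
            shape: Union[Polyline, Polygon]
            shape = Polygon(geom["coordinates"][0], label=label)
        elif gtype == "LineString":
            if role != "inner_membrane":
                raise AnnotationError(
                    f"feature {i}: role {role!r} requires a Polygon geometry"
                )
            shape = Polyline(geom["coordinates"], label=label)
        else:
            raise AnnotationError(f"feature {i}: unsupported geometry {gtype!r}")

        if role == "interfibrillar":
            regions.append(shape)
        elif role == "mitochondrion":
            mitochondria.append(shape)
        else:
            mid = props.get("mitochondrion_id")
            if mid is None:
                raise AnnotationError(
                    f"feature {i}: membrane role needs properties.mitochondrion_id"
                )
            mid = str(mid)
            if role == "outer_membrane":
                if mid in outers:
                    raise AnnotationError(
                        f"mitochondrion {mid!r} has more than one outer contour"
                    )
                outers[mid] = shape
            else:
                inners.setdefault(mid, []).append(shape)

    micrograph_ids.discard(None)
    if len(micrograph_ids) != 1:
        raise AnnotationError(
            f"{path}: expected exactly one micrograph_id, found {sorted(micrograph_ids)}"
        )
    scene_id = micrograph_ids.pop()
    return AnnotationScene(
        micrograph_id=scene_id,
        magnification=magnification or 0,
        interfibrillar_regions=regions,
        mitochondria=mitochondria,
        membrane_sets=_assemble_membrane_sets(outers, inners, scene_id),
    )


# ---------------------------------------------------------------------------
# Results CSV


def write_results_csv(rows: Sequence, path: str | Path) -> pd.DataFrame:
    """Write per-patient morphometry results to a tidy UTF-8 CSV.

    One row per patient with a stable column order; duplicate patient ids and
    empty inputs are rejected.
    """
    rows = list(rows)
    if not rows:
        raise AnnotationError("no results to write")
    frame = pd.DataFrame(
        [{c: getattr(r, c) for c in RESULT_COLUMNS} for r in rows],
        columns=RESULT_COLUMNS,
    )
    dup = frame["patient_id"][frame["patient_id"].duplicated()]
    if not dup.empty:
        raise AnnotationError(f"duplicate patient_id: {sorted(set(dup))}")
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.10g")
    return frame


def read_results_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(RESULT_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise AnnotationError(f"results CSV lacks columns: {sorted(missing)}")
    return frame
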