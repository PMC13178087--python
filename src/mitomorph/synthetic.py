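"""Synthetic annotation scenes and cohorts with known ground truth.

No deposited micrograph annotations exist for this kind of study, so every
downstream module is exercised against generated scenes whose true packing
fraction and membrane-length ratio are known by construction:

* :func:`generate_scene` packs non-overlapping convex mitochondrion polygons
  into a rectangular interfibrillar region until the summed area fraction
  hits the requested packing within 0.5 percentage points (the final polygon
  is scaled to close the gap exactly), so the measured TAIM recovers the
  realized fraction by construction.
* :func:`generate_membrane_set` builds an elliptical outer membrane plus an
  inner boundary trace and straight cristae chords whose total length is
  solved to make the OIMR hit its target to float precision.
* :func:`generate_cohort` draws per-patient parameters for a two-group
  cohort (a heart-failure cohort split by atrial fibrillation) and can
  materialize each patient as full annotation scenes following the
  3 micrographs × 3 mitochondria protocol.

Cohort defaults emulate the published group distributions.  Because for any
bivariate-normal draw the median of the ratio TAIM/OIMR equals the ratio of
the component medians, independent marginals cannot reproduce the reported
per-patient index separation between groups; the default mode therefore
draws OIMR and the total index from their group distributions and derives
TAIM = index × OIMR (see docs/methods.md).  ``couple_index=False`` restores
independent TAIM/OIMR marginals.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.affinity as saff
import shapely.geometry as sgeom
from scipy.spatial import ConvexHull

from .annotation_io import (
    AnnotationScene,
    MembraneSet,
    PatientRecord,
    write_geojson_scene,
    write_imagej_rois,
)
from .geometry import Polygon, Polyline, polygon_area, polyline_length
from .morphometry import MorphometryResult, total_index

__all__ = [
    "SceneSpec",
    "MembraneSpec",
    "CohortSpec",
    "SyntheticError",
    "generate_scene",
    "generate_membrane_set",
    "draw_cohort_parameters",
    "generate_cohort",
    "write_fixture_tree",
]

#: IQR of a normal distribution in units of its standard deviation
_IQR_TO_SD = 2 * 0.6744897501960817


def _sd(iqr: float) -> float:
    return iqr / _IQR_TO_SD


class SyntheticError(ValueError):
    """Generator spec infeasible (packing or cristae length unachievable)."""


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth recipe for one 5000×-style scene (TAIM role).

    ``target_packing`` is the desired mitochondrial area fraction of the
    rectangular interfibrillar region; feasible targets are < 0.8 (random
    placement of non-overlapping convex bodies jams well below disk packing).
    """

    region_size: tuple[float, float] = (1000.0, 700.0)
    target_packing: float = 0.437
    n_mitochondria: int = 500  # upper cap; packing normally stops earlier
    mito_size_range: tuple[float, float] = (25.0, 55.0)  # radius in px
    seed: int = 0
    max_attempts: int = 60000

    def __post_init__(self) -> None:
        if not (0 < self.target_packing < 0.8):
            raise SyntheticError(
                f"target_packing {self.target_packing} outside feasible (0, 0.8)"
            )


@dataclass(frozen=True)
class MembraneSpec:
    """Ground-truth recipe for one mitochondrion's membranes (OIMR role).

    The inner-membrane budget is sized so that total inner length equals
    ``100 · outer_perimeter / target_oimr``.
    """

    target_oimr: float = 31.0
    n_cristae: int | None = None  # None: sized from the required inner length
    outer_axes: tuple[float, float] = (170.0, 100.0)  # ellipse semi-axes, px
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5.0 < self.target_oimr <= 100.0):
            raise SyntheticError(
                f"target_oimr {self.target_oimr} outside (5, 100]"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort recipe; group 0 = without AF, group 1 = with AF.

    Locations are medians and scales are standard deviations of truncated
    normal draws; defaults match the published group medians and IQRs
    (scale = IQR / 1.349).  In the default ``couple_index`` mode the index
    and OIMR are drawn and TAIM is derived; otherwise TAIM and OIMR are
    drawn independently from ``taim_*``.
    """

    n_per_group: tuple[int, int] = (27, 12)
    taim_g0: tuple[float, float] = (49.0, _sd(64 - 36))
    taim_g1: tuple[float, float] = (42.0, _sd(49 - 33))
    oimr_g0: tuple[float, float] = (31.0, _sd(36 - 25))
    oimr_g1: tuple[float, float] = (35.0, _sd(45 - 30))
    index_g0: tuple[float, float] = (1.75, _sd(2.39 - 1.28))
    index_g1: tuple[float, float] = (0.96, _sd(1.54 - 0.89))
    couple_index: bool = True
    taim_range: tuple[float, float] = (1.0, 99.0)
    oimr_range: tuple[float, float] = (1.0, 99.0)
    index_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise SyntheticError("need at least 2 patients per group")

    @classmethod
    def null(cls, n_per_group=(27, 12), seed: int = 0) -> "CohortSpec":
        """Both groups drawn from the pooled-cohort distribution (no effect)."""
        taim = (43.7, _sd(54.3 - 35.9))
        oimr = (31.0, _sd(37 - 25))
        index = (1.4, _sd(2.00 - 0.95))
        return cls(
            n_per_group=tuple(n_per_group),
            taim_g0=taim, taim_g1=taim,
            oimr_g0=oimr, oimr_g1=oimr,
            index_g0=index, index_g1=index,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Scene generation (TAIM ground truth)


def _convex_blob(rng: np.random.Generator, radius: float) -> sgeom.Polygon:
    """Random convex polygon of roughly the given radius (ellipse-perturbed)."""
    k = int(rng.integers(10, 16))
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = radius * (1 + rng.uniform(-0.25, 0.25, k))
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    pts[:, 1] *= rng.uniform(0.6, 1.0)  # anisotropy
    hull = ConvexHull(pts)
    poly = sgeom.Polygon(pts[hull.vertices])
    return saff.rotate(poly, rng.uniform(0, 180), origin="centroid")


def generate_scene(
    spec: SceneSpec,
    rng: np.random.Generator | None = None,
    micrograph_id: str | None = None,
) -> AnnotationScene:
    """Pack convex mitochondria into a rectangular region at a known fraction.

    The realized area fraction lands within 0.5 percentage points of
    ``spec.target_packing`` (the last polygon is shrunk to close the deficit
    exactly); the measured TAIM of the returned scene equals the realized
    fraction by construction, since all polygons are disjoint and inside the
    region.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    w, h = spec.region_size
    region_area = w * h
    target_area = spec.target_packing * region_area
    tol_area = 0.005 * region_area

    placed: list[sgeom.Polygon] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    realized = 0.0
    attempts = 0
    fails = 0
    r_lo, r_hi = spec.mito_size_range
    while realized < target_area - tol_area and len(placed) < spec.n_mitochondria:
        if attempts >= spec.max_attempts:
            raise SyntheticError(
                f"packing infeasible: reached {realized / region_area:.3f} of "
                f"target {spec.target_packing} after {attempts} attempts; "
                "lower target_packing or enlarge the region"
            )
        attempts += 1
        # late in the packing only small bodies fit: shrink after stalls
        if fails and fails % 300 == 0:
            r_lo = max(0.85 * r_lo, 8.0)
            r_hi = max(0.85 * r_hi, 1.3 * r_lo)
            fails += 1  # avoid re-triggering until the next 300 failures
        radius = rng.uniform(r_lo, r_hi)
        blob = _convex_blob(rng, radius)
        deficit = target_area - realized
        if blob.area > deficit:
            blob = saff.scale(
                blob, *(2 * [float(np.sqrt(deficit / blob.area))]), origin="centroid"
            )
        minx, miny, maxx, maxy = blob.bounds
        bw, bh = maxx - minx, maxy - miny
        if bw >= w or bh >= h:
            continue
        dx = rng.uniform(-minx, w - maxx)
        dy = rng.uniform(-miny, h - maxy)
        cand = saff.translate(blob, dx, dy)
        c = np.asarray(cand.centroid.coords[0])
        cr = np.max(np.hypot(*(np.asarray(cand.exterior.coords) - c).T))
        near = np.nonzero(np.hypot(*(centers - c).T) < radii + cr)[0]
        if any(cand.intersects(placed[i]) for i in near):
            fails += 1
            continue
        placed.append(cand)
        centers = np.vstack([centers, c])
        radii = np.append(radii, cr)
        realized += cand.area

    if abs(realized - target_area) > tol_area:
        raise SyntheticError(
            f"packing stopped at fraction {realized / region_area:.4f}, "
            f"outside ±0.5 pp of target {spec.target_packing}"
        )

    region = Polygon([(0, 0), (w, 0), (w, h), (0, h)], label="region")
    mitochondria = [
        Polygon(np.asarray(p.exterior.coords)[:-1], label=f"mito_{i + 1}")
        for i, p in enumerate(placed)
    ]
    return AnnotationScene(
        micrograph_id=micrograph_id or f"sim5000_{spec.seed}",
        magnification=5000,
        interfibrillar_regions=[region],
        mitochondria=mitochondria,
    )


# ---------------------------------------------------------------------------
# Membrane generation (OIMR ground truth)


def _ellipse_polygon(a: float, b: float, n: int = 64) -> Polygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([a * np.cos(t), b * np.sin(t)]), label="outer")


def generate_membrane_set(
    spec: MembraneSpec,
    rng: np.random.Generator | None = None,
    mitochondrion_id: str = "m1",
) -> MembraneSet:
    """Build membranes whose OIMR equals ``spec.target_oimr`` exactly.

    The inner membrane is a shrunken copy of the outer boundary plus
    ``n_cristae`` horizontal chords; chord lengths are scaled so the total
    inner length is ``100 · P_outer / target`` to float precision.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    a, b = spec.outer_axes
    outer = _ellipse_polygon(a, b)
    perimeter = polyline_length(outer)
    required = 100.0 * perimeter / spec.target_oimr

    if required <= perimeter:  # target == 100 (or numerically at the boundary)
        s = required / perimeter
        inner = Polygon(outer.coords * s, label="inner_boundary")
        return MembraneSet(mitochondrion_id, outer, [inner])

    boundary_scale = 0.97
    boundary = Polygon(outer.coords * boundary_scale, label="inner_boundary")
    chord_budget = required - polyline_length(boundary)

    n_cristae = spec.n_cristae
    if n_cristae is None:
        # mean feasible chord length is ~1.2 a; leave headroom for bad draws
        n_cristae = max(6, int(np.ceil(chord_budget / (1.1 * a))))

    for _ in range(50):
        ys = rng.uniform(-0.75 * b, 0.75 * b, n_cristae)
        halfwidth = a * np.sqrt(1 - (ys / b) ** 2)
        capacity = 2 * 0.94 * boundary_scale * halfwidth
        init = 0.6 * capacity
        s = chord_budget / init.sum()
        if np.all(s * init <= capacity):
            lengths = s * init
            traces: list[Polyline | Polygon] = [boundary]
            for y, L in zip(ys, lengths):
                traces.append(
                    Polyline([(-L / 2, y), (L / 2, y)], label="crista")
                )
            return MembraneSet(mitochondrion_id, outer, traces)
    raise SyntheticError(
        f"cannot fit {chord_budget:.0f} px of cristae inside the ellipse with "
        f"{n_cristae} chords; raise n_cristae or target_oimr"
    )


def _membrane_scene(
    target_oimr: float,
    rng: np.random.Generator,
    micrograph_id: str,
    n_mito: int = 3,
) -> AnnotationScene:
    sets = []
    for j in range(n_mito):
        axes = (rng.uniform(130, 200), rng.uniform(80, 120))
        ms = generate_membrane_set(
            MembraneSpec(target_oimr=target_oimr, outer_axes=axes),
            rng=rng,
            mitochondrion_id=f"{micrograph_id}_m{j + 1}",
        )
        sets.append(ms)
    return AnnotationScene(
        micrograph_id=micrograph_id, magnification=15000, membrane_sets=sets
    )


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_patient(
    rng: np.random.Generator,
    spec: CohortSpec,
    group: int,
    taim_range: tuple[float, float],
    oimr_range: tuple[float, float],
) -> tuple[float, float, float]:
    """One patient's true (taim, oimr, index), rejection-truncated."""
    oimr_loc, oimr_sc = (spec.oimr_g0, spec.oimr_g1)[group]
    for _ in range(100_000):
        o = rng.normal(oimr_loc, oimr_sc)
        if not (oimr_range[0] < o < oimr_range[1]):
            continue
        if spec.couple_index:
            iloc, isc = (spec.index_g0, spec.index_g1)[group]
            i = rng.normal(iloc, isc)
            t = i * o
            if i > spec.index_min and taim_range[0] < t < taim_range[1]:
                return t, o, i
        else:
            tloc, tsc = (spec.taim_g0, spec.taim_g1)[group]
            t = rng.normal(tloc, tsc)
            if taim_range[0] < t < taim_range[1]:
                return t, o, t / o
    raise SyntheticError("truncated sampling failed; check distribution parameters")


def draw_cohort_parameters(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    taim_range: tuple[float, float] | None = None,
    oimr_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-patient true parameters for a two-group cohort (fast path).

    Columns: patient_id, group_label, taim_pct, oimr_pct, total_index.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    taim_range = taim_range or spec.taim_range
    oimr_range = oimr_range or spec.oimr_range
    rows = []
    k = 0
    for group, n in enumerate(spec.n_per_group):
        for _ in range(n):
            k += 1
            t, o, i = _draw_patient(rng, spec, group, taim_range, oimr_range)
            rows.append(
                {
                    "patient_id": f"P{k:03d}",
                    "group_label": group,
                    "taim_pct": t,
                    "oimr_pct": o,
                    "total_index": i,
                }
            )
    return pd.DataFrame(rows)


#: drawn parameters are restricted to these windows when scenes are
#: materialized — the rejection packer jams well before dense disk packings,
#: and extreme membrane ratios need unreasonable cristae budgets
MATERIALIZABLE_TAIM = (5.0, 55.0)
MATERIALIZABLE_OIMR = (8.0, 99.0)


def generate_cohort(
    spec: CohortSpec,
    materialize: bool = False,
    rng: np.random.Generator | None = None,
):
    """Generate a cohort; see :func:`draw_cohort_parameters` for the draws.

    With ``materialize=False`` returns per-patient
    :class:`~mitomorph.morphometry.MorphometryResult` rows carrying the drawn
    values.  With ``materialize=True`` returns ``(records, truth)`` where
    each :class:`PatientRecord` holds 3 generated 5000× scenes at the
    patient's TAIM and 3 × 15,000× scenes of 3 mitochondria at the patient's
    OIMR, so running the morphometry pipeline recovers the drawn values
    within the scene generator's 0.5 pp tolerance.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    truth = draw_cohort_parameters(
        spec,
        rng=rng,
        taim_range=MATERIALIZABLE_TAIM if materialize else None,
        oimr_range=MATERIALIZABLE_OIMR if materialize else None,
    )

    if not materialize:
        return [
            MorphometryResult(
                patient_id=r.patient_id,
                group_label=int(r.group_label),
                taim_pct=float(r.taim_pct),
                oimr_pct=float(r.oimr_pct),
                total_index=total_index(r.taim_pct, r.oimr_pct),
                n_micrographs_5000x=3,
                n_mitochondria_15000x=9,
            )
            for r in truth.itertuples()
        ]

    records = []
    for r in truth.itertuples():
        scenes_5000 = [
            generate_scene(
                replace(SceneSpec(), target_packing=float(r.taim_pct) / 100.0),
                rng=rng,
                micrograph_id=f"{r.patient_id}_5000x_{i + 1}",
            )
            for i in range(3)
        ]
        scenes_15000 = [
            _membrane_scene(
                float(r.oimr_pct), rng, f"{r.patient_id}_15000x_{i + 1}"
            )
            for i in range(3)
        ]
        records.append(
            PatientRecord(
                patient_id=r.patient_id,
                group_label=int(r.group_label),
                scenes_5000x=scenes_5000,
                scenes_15000x=scenes_15000,
            )
        )
    return records, truth


def write_fixture_tree(
    spec: CohortSpec,
    outdir: str | Path,
    fmt: str = "geojson",
) -> pd.DataFrame:
    """Materialize a cohort to disk: scenes + manifest.csv + truth.csv.

    The manifest lists one row per scene file (patient_id, group_label,
    micrograph_id, magnification, path); ImageJ output additionally writes a
    per-scene role manifest next to each ``.zip``.
    """
    if fmt not in ("geojson", "imagej-roi"):
        raise ValueError(f"unknown format {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = generate_cohort(spec, materialize=True)

    rows = []
    for rec in records:
        pdir = outdir / rec.patient_id
        pdir.mkdir(exist_ok=True)
        for scene in rec.scenes_5000x + rec.scenes_15000x:
            if fmt == "geojson":
                path = pdir / f"{scene.micrograph_id}.geojson"
                write_geojson_scene(scene, path)
            else:
                path = pdir / f"{scene.micrograph_id}.zip"
                roles = write_imagej_rois(scene, path)
                roles.to_csv(path.with_suffix(".roles.csv"), index=False)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "group_label": rec.group_label,
                    "micrograph_id": scene.micrograph_id,
                    "magnification": scene.magnification,
                    "path": str(path.relative_to(outdir)),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    return manifest
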