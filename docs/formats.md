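# Annotation file formats

## Coordinate convention

All formats carry pixel coordinates with the y axis pointing image-down, the
native convention of raster annotation tools. No physical calibration
(nm/pixel) is stored: every measured quantity is a ratio, so the pixel scale
cancels. Nominal magnification (5000 or 15,000) is metadata that routes a
scene to the TAIM or OIMR computation; it never rescales coordinates.

## Role vocabulary

Every trace carries exactly one role:

| role              | geometry             | meaning                                   |
|-------------------|----------------------|-------------------------------------------|
| `interfibrillar`  | closed polygon       | contour of the interfibrillar space (5000×) |
| `mitochondrion`   | closed polygon       | mitochondrial cross-section inside it (5000×) |
| `outer_membrane`  | closed polygon       | outer membrane of one mitochondrion (15,000×) |
| `inner_membrane`  | polyline or polygon  | inner boundary membrane or one crista (15,000×) |

Membrane traces are grouped per mitochondrion by a `mitochondrion_id`; each
group needs exactly one outer contour and at least one inner trace.

## GeoJSON dialect

A `FeatureCollection` per micrograph. Each feature:

- `geometry`: `Polygon` (single outer ring, closed) or `LineString`
  (only for `inner_membrane`);
- `properties.role`: one of the vocabulary above;
- `properties.micrograph_id`: identical across all features of one file;
- `properties.magnification`: integer, e.g. 5000 or 15000;
- `properties.mitochondrion_id`: required for membrane roles.

Read/write round trips are lossless on coordinates. Files mixing
`micrograph_id` values, or with features missing a role, are rejected.

## ImageJ ROI

Single `.roi` files or `RoiSet.zip` archives as written by ImageJ's ROI
manager. Supported ROI types: polygon, freehand, traced (closed) and
polyline, freeline (open). Point, line, oval and rectangle ROIs are
rejected by name. ROI names come from the zip entry name / file stem.

The ROI format stores no semantics, so roles come from a manifest CSV with
columns `roi_name, role[, mitochondrion_id]`; an ROI name absent from the
manifest is an error. The fixture writer emits `<scene>.zip` plus
`<scene>.roles.csv` side by side. Coordinates are stored by the format as
int16 pixel offsets, so fractional coordinates round to integers (≤0.5 px
per vertex; for typical scene scales this perturbs the ratios by far less
than a percentage point).

## Cohort manifest and results

A cohort directory holds one `manifest.csv` with columns
`patient_id, group_label, micrograph_id, magnification, path` (paths
relative to the directory), plus the scene files. `mitomorph compute` writes
a per-patient results CSV with the stable column order
`patient_id, group_label, taim_pct, oimr_pct, total_index,
n_micrographs_5000x, n_mitochondria_15000x` (UTF-8).
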