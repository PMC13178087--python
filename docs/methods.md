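# Methods

## Measurement model

All measurements operate on planar traces: simple polygons (interfibrillar
regions, mitochondrial cross-sections, outer membranes) and open polylines
(inner-membrane/cristae traces). Coordinates are continuous pixel positions,
y-axis image-down. Because every reported quantity is a ratio of areas or of
lengths, the pixel scale cancels; magnification (5000× for TAIM scenes,
15,000× for OIMR scenes) is metadata that routes a scene to the right
computation and never rescales coordinates.

Areas are absolute shoelace sums — annotators' winding direction is not
controlled, so orientation must not affect the result. Self-intersecting and
degenerate (collinear) contours are rejected with errors naming the trace;
they indicate tracing mistakes, not measurable biology. Polygon intersection
(clipping mitochondria to the interfibrillar region) is delegated to shapely.

**TAIM** for one scene is `100 · Σᵢ area(mitoᵢ ∩ U) / Σⱼ area(regionⱼ)`
where `U` is the union of the traced interfibrillar regions. Decisions
embedded here:

- A mitochondrion partially outside the region contributes its clipped
  (intersection) area. Counting whole-or-nothing would make the value jump
  discontinuously as a trace crosses the border.
- The denominator is the interfibrillar space itself, *including* the area
  the mitochondria occupy (they lie within the counted space). Observed
  values near 44% are only consistent with this reading; excluding the
  mitochondrial area would map the same scenes to ~78%.
- A scene with a region but no mitochondrion traces raises an error rather
  than returning 0%: an unannotated micrograph is indistinguishable from a
  truly empty one, and silently treating it as 0% would bias cohort means.
- Traced regions are expected to be disjoint; if they overlap, the
  sum-of-areas denominator exceeds the union and TAIM is underestimated —
  the reader does not attempt to repair overlapping region annotations.

**OIMR** for one mitochondrion is `100 · L(outer) / Σ L(inner traces)`. The
inner total sums *all* traces labeled `inner_membrane` for that
mitochondrion — the inner boundary membrane, if traced, plus every crista.
The ratio is typically well below 100% in healthy tissue (cristae make the
inner membrane much longer than the outer); cristae loss drives it toward
100%.

**Total index** = patient-level TAIM% / patient-level OIMR%, computed from
the two patient parameters (not per scene and then averaged). It is kept at
full float precision; display rounding is one decimal for the percentages
and two for the index.

## Averaging protocol

The protocol analyzes 3 micrographs per patient, and for OIMR 3 mitochondria
per micrograph; the patient value is the arithmetic mean. For OIMR the
per-patient value is the grand mean over all measured mitochondria, which
coincides with the mean of per-scene means under the balanced 3×3 design; for
unbalanced input the grand mean (equal weight per mitochondrion) is used and
documented behavior. By default departures from 3×3 raise a warning only, so
the tool remains usable on other designs; `strict=True` (CLI `--strict`)
turns them into errors with the offending counts listed.

## Statistics

- **Summaries** are Me [Q1; Q3]. Quartiles use Tukey's inclusive-median
  hinge rule (each half includes the median when n is odd): `{1,2,3,4,5}` →
  2 and 4. Software defaults differ here (SPSS's weighted-average rule gives
  other hinges); one rule is fixed and tested so summaries are reproducible.
- **Mann–Whitney U**, two-sided, midranks for ties. Mode `auto` uses the
  exact null when the pooled sample is ≤25 and tie-free, the normal
  approximation (tie-corrected, continuity-corrected) otherwise; `exact`
  with ties falls back to a seeded Monte-Carlo permutation null (default
  10⁵ draws). U is reported for group 0, so U + U′ = n₀·n₁.
- **ROC AUC** uses the rank formulation with midranks, which makes
  `AUC_raw · n₀ · n₁ = U` an exact identity (tested against enumeration and
  against an independent implementation). The reported AUC is oriented to
  ≥0.5 with an explicit direction flag, because the clinically relevant
  direction here is *lower* index → positive (AF) class. No AUC confidence
  interval is reported.
- Significance convention: p ≤ 0.05.
- No multiple-testing correction is applied across the three parameter
  comparisons; this mirrors the analysis the method is designed to
  reproduce, and is a deliberate non-feature.

## Synthetic ground truth

The generator emulates *annotation geometry and cohort-level parameter
distributions*, not electron-microscope images. What passing tests show is
that the measurement and statistics pipeline is correct on traces whose true
values are known; they cannot show anything about segmentation or tracing
quality on real micrographs, which is manual and upstream of this package.

- **Scenes** (TAIM): convex ellipse-perturbed polygons are packed into a
  rectangular region by seeded rejection sampling (non-overlapping,
  contained). Candidate sizes shrink as placements stall, and the final
  polygon is scaled so the realized fraction lands within 0.5 percentage
  points of target. Defaults: 1000×700 px region, radii 25–55 px. Random
  sequential packing of convex bodies jams well below dense packings, so
  targets ≥0.8 are rejected outright and ~0.6 is a practical ceiling.
  Mitochondrion shape realism is deliberately out of scope: every measured
  quantity depends only on areas and lengths.
- **Membrane sets** (OIMR): a 64-gon ellipse outer contour (default
  semi-axes 170×100 px), an inner boundary at 0.97 scale, and straight
  horizontal cristae chords whose common scale factor is solved so total
  inner length equals `100·P/target` to float precision. The chord count is
  auto-sized from the required budget (a fixed count may be requested and
  may then be infeasible, which raises). Chords for a target of 100% reduce
  to a single inner trace congruent to the outer contour.
- **Cohorts**: per-patient parameters are truncated-normal draws per group,
  scale = IQR/1.349, since only medians and IQRs are published —
  normal-with-matching-quartiles is the minimal assumption. The default
  *couples* the draws: OIMR and the total index are drawn from their group
  distributions and TAIM = index·OIMR (rejection-truncated to (1, 99)%).
  This choice is forced by an arithmetic fact: for any bivariate-normal
  (TAIM, OIMR) the median of the ratio equals the ratio of medians, so
  independent marginals matching the published component medians (49/31 vs
  42/35) could never reproduce the much stronger published per-patient index
  separation (1.75 vs 0.96) — the published group summaries are mutually
  inconsistent under independence. Coupling preserves the load-bearing
  quantity (the index distribution, and incidentally the no-AF TAIM median
  ≈49); the cost is that the AF-group TAIM marginal centers near 34 rather
  than the published 42. `couple_index=False` restores independent
  marginals for users who care about the component marginals instead.
- **Materialized cohorts** (3 scenes × 3 mitochondria per patient, written
  as GeoJSON or ImageJ ROI trees) restrict drawn TAIM to (5, 55)% and OIMR
  to (8, 99)% so every drawn patient is constructible by the packer and the
  chord solver; parameter-level draws keep the full (1, 99)% range. ImageJ
  serialization rounds coordinates to integer pixels (int16 format), which
  perturbs measured values by well under one percentage point at the default
  scene scale.

All generators are deterministic given (spec, seed); cohort materialization
threads a single `numpy` Generator through every scene.

## Numerical and degenerate-input choices

- Degenerate polygons: area ≤ 1e-12 × (bounding-box span)² is rejected.
- Similarity invariance (scale/rotation/translation) of all three
  measurements holds to 1e-9 relative tolerance and is property-tested.
- `total_index` with nonpositive inputs, empty scene lists, zero inner
  membrane length, single-class outcomes, and single-group cohorts all raise
  typed errors rather than returning sentinel values.
- Identical values across both comparison groups yield p = 1 with a warning
  (the test statistic is degenerate, not significant).

## Problem sizes used in the verification suite

The suite checks the geometry against a 10⁶-sample Monte-Carlo
rasterization oracle on 200 random convex polygons; exact Mann–Whitney
against full enumeration for every tie-free split with n₀+n₁ ≤ 12; the
AUC·n₀·n₁ = U identity on 1000 random instances; type-I error of the cohort
comparison on 2000 null replicates (0.05 ± 0.02) and power on 500
default-effect replicates (≥80% at n = 27/12); and end-to-end recovery of
drawn cohort parameters through scene materialization for small cohorts.

## Known limitations

- The tool measures what was traced; it has no notion of tracing quality,
  section obliquity, or sampling bias in which mitochondria an annotator
  chose. How the three mitochondria per micrograph are selected is not
  specified by the protocol; the generator selects with a seeded RNG.
- Planar (2-D) morphometry only: no stereological correction to 3-D
  surface/volume quantities.
- The published group summaries cannot all be matched simultaneously by any
  independent-marginal generator (see above); the AF-group TAIM marginal is
  the quantity sacrificed by the default coupling.
- Shape descriptors (circularity, aspect ratio), mitochondrial counts and
  size distributions, and cristae-damage grading schemes are out of scope.
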