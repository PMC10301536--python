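# Methods

## The measurement model

volceph quantifies how the soft-tissue volume of the lower two-thirds of a
face is distributed over four anatomical slabs.  The input is a watertight
triangle surface of the facial soft tissue (an STL in mm, typically derived
from CBCT) plus named cephalometric landmarks.  Six infinite planes are built
from the landmarks:

| plane | definition | orientation |
|---|---|---|
| Frankfort Horizontal (FH) | both porions + left orbitale (exact 3-point), or a least-squares fit when the right orbitale is supplied | normal superior |
| bi-porion coronal | contains both porions, parallel to the FH normal | normal anterior |
| palatal (bispinal) | contains ANS and PNS, completed with the head frame's lateral axis (no transverse roll) | normal superior |
| occlusal | exact plane through one anterior and two molar occlusal points | normal superior |
| mental foramina | FH-parallel through the midpoint of the two mental foramina | normal superior |
| mandibular base | exact plane through both gonions and menton | normal superior |

The lower two-thirds is the region below FH, anterior of the coronal plane
and above the mandibular base.  A fixed cut tree partitions it: the palatal
plane splits off the malar slab, the occlusal plane splits maxillary from
the rest, and the foramina plane separates mandibular from chin.  Because
each boundary is introduced by exactly one cut, the partition is exact by
construction: the four slab volumes sum to the lower-two-thirds volume to
machine precision (the suite asserts 1e-6 relative).

Each slab is a watertight solid; its volume is the signed-tetrahedron sum
V = (1/6) Σ det[a, b, c] over faces.  The core statistic is the percentage
share of each slab in the total, plus the maxillary/mandibular volume ratio.
Shares are reported with half-away-from-zero rounding at 1 decimal, ratios
at 2 decimals.  Soft tissue is measured as the full solid enclosed by the
skin surface inside each slab; internal cavities and bone are not
subtracted.

### Assumptions and deliberate simplifications

- The bispinal "plane" is genuinely a line (ANS-PNS); it is lifted to a
  plane with the head frame's lateral axis, i.e. a transversely level
  palatal plane.
- An FH-parallel plane cannot in general contain both mental foramina; the
  midpoint rule is used and each foramen's residual distance is logged.
- The neck cut is a single plane through both gonions and menton.
- All vertical orderings (FH ≥ palatal ≥ occlusal ≥ foramina along the
  vertical line through ANS, menton at or below the foramina plane, ANS
  below FH and anterior of the coronal plane) are *validated*, not assumed;
  segmentation refuses on violation unless forced.

## Geometry engine

`cut_mesh` splits a watertight mesh by a plane and caps both cross-sections:

- Vertices within a snap tolerance of the plane are treated as on-plane.
  The tolerance is max(1e-9 mm, 1e-8 x bounding-box extent); the relative
  floor matters because vertices can graze a plane by float round-off
  (e.g. sin(pi) ~ 1e-16 propagated through a power law), which would
  otherwise spawn coincident intersection points and degenerate caps.
- Straddling triangles are clipped per side; intersection points are cached
  per mesh edge, so both pieces share identical cut vertices and volume
  additivity holds to machine precision.
- Triangles lying exactly in the cutting plane are assigned to the side the
  solid occupies (opposite their outward normal).
- Open boundary edges are chained into loops and triangulated in-plane by
  ear clipping.  Nested loops are handled by the even-odd rule (a loop
  inside a loop is a hole, bridged to its shell by the shortest interior
  segment).  Collinear boundary vertices are removed before clipping and
  restored afterwards by splitting the cap edges they lie on, which keeps
  edge topology watertight without emitting zero-area triangles.
- Cap triangles are oriented by the plane normal (outward away from the
  kept solid).  Both outputs are verified watertight; a failure raises
  rather than returning a corrupt solid.

Orientation repair: meshes read from STL with negative signed volume are
flipped with a warning (exporters disagree on winding); a mesh with locally
inconsistent winding is rejected.  The STL reader merges duplicate vertices
on a 1e-6 mm grid, since STL stores a triangle soup.

### The voxel parity oracle

`voxel_volume_oracle` counts voxel centres inside the surface, deciding
inside/outside by the parity of surface crossings along the vertical ray
through each centre.  It shares no code path with the signed-tetrahedron
sum, so the two can cross-check each other; the error bound is
O(surface area x voxel size).  The grid gets a tiny deterministic jitter so
centres never sit exactly on projected edges; if a column still shows odd
crossing parity the grid is re-jittered (up to 4 attempts).  A configurable
cell budget guards against accidentally huge grids.

## Cohort statistics

- **Jury selection.** Aesthetic scores (1-10 attractiveness scale, 6 judges
  x 2 sessions by default) are pooled equally over all judges and sessions;
  a subject is selected when the mean reaches the cutoff (default 8.5,
  inclusive).
- **Judge repeatability.** Per-judge Pearson r (with two-sided p) between
  session-1 and session-2 scores over paired subjects; zero-variance judges
  are reported as undefined and excluded from the mean r with a warning.
- **Normality.** Shapiro-Wilk (Royston AS R94, via scipy) per gender and
  region.
- **Gender summary.** Arithmetic mean of each slab volume per stratum;
  percentage shares are computed *from the mean volumes*, not as means of
  per-subject shares — this is the only convention under which a stratum's
  printed shares are exactly the distribution of its printed mean volumes.
  The maxilla/mandible ratio likewise comes from the mean volumes.
- **Normative comparison.** A subject's shares minus the reference shares
  (percentage points) per region, plus the volume change that would equalize
  each region's share at constant total.  These per-region equalizing
  volumes are a first-order guide: applying one changes the other shares.

### Embedded normative references

The packaged reference file stores the reported gender distributions
verbatim: female (38.7, 29.0, 27.6, 4.7)%, male (37, 26, 30, 6)%.  The male
set sums to 99% and its malar/maxillary values are inconsistent with the
male mean volumes they accompany (which compute to 36.5% and 28.0%); these
entries carry explicit flags rather than silent corrections.  The reported
male ratio 0.87 equals 26/30 from that inconsistent share line; the
volume-derived value is 0.95.

## Synthetic data generator

Real CBCT-derived surfaces are unavailable, so the generator emulates the
*measurable structure* of the data, not facial realism:

- **Head.** A lofted stack of superellipse cross-sections (lateral semi-axis
  up to 70 mm, anterior 85 mm, posterior 60 mm at scale 1, exponent 2.5)
  closed at two poles, with a Gaussian chin bump; landmarks are placed
  analytically on or inside the surface at the plane heights of the spec.
  Default plane heights (palatal -20, occlusal -45, foramina -62, base
  -80 mm below FH) are in the range of adult cephalometry and produce a
  valid plane stack.  Loft resolution defaults to 48 vertices per ring x 40
  rings (~3 800 faces); tests use 36 x 28 where speed matters.
- **Calibration.** The three inner plane heights are solved by bracketed
  root finding (Brent, ≤ 50 iterations, 0.01 mm tolerance) on the cumulative
  share above a horizontal plane, computed with the real cutting pipeline;
  the result is verified by a full partition and must land within 0.5
  percentage points of the target shares.  The mesh shape deliberately does
  not depend on the calibrated heights, so the loop converges exactly.
- **Cohort.** Per-subject region volumes are independent normal draws
  around the gender preset (female: the reported female shares; male: the
  volume-consistent shares 36.5/28.0/29.5/6.0) with coefficient of
  variation 0.08, truncated at 3 sigma and at zero.  Only normality of the
  real volumes is reported upstream, so independence is the minimal
  assumption.  Each subject's head is globally scaled so the
  lower-two-thirds total matches the drawn total (cube-law scaling), then
  calibrated to the drawn shares.  Default strata: 26 females, 20 males.
- **Jury scores.** Latent attractiveness ~ N(8.0, 1.0) per subject, judge
  bias ~ N(0, 0.3), session noise with sd = score_sd * sqrt((1-r)/r) so the
  expected within-judge test-retest Pearson correlation equals the target
  (default 0.85); scores are rounded to half points and clipped to [1, 10].
  A target r of exactly 1 uses zero noise, so session 2 duplicates session
  1.  With the default latent mean 8.0 and cutoff 8.5, roughly a third of a
  cohort is selected, in line with the normative cohort design.

What passing tests on this generator do **not** show: behaviour on real
anatomy (concave ears, nostrils, open mouths), landmark placement error,
or scanner/segmentation noise.  The generator's heads are star-shaped and
smooth; the cutting engine itself is exercised on non-convex topology
(torus cuts with annular caps) separately.

## Numerical choices

- Snap tolerance: see above (max of 1e-9 mm and 1e-8 x extent).
- Cap triangulation epsilons are relative to the loop's bounding-box scale
  (1e-10 x scale² for collinearity, 1e-12 x scale² for ear areas).
- Rounding is half away from zero; binary-float edge cases near exact
  halves follow the usual caveat of decimal-on-binary rounding.
- Degenerate inputs: collinear plane points, coincident porions, zero
  mandibular volume, zero-variance score vectors and sub-minimal sample
  sizes all raise typed errors naming the offending landmarks/subjects.
- Empty slabs (a plane missing the solid) are permitted and flagged, with
  volume 0 and share 0.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run heads at 36 x 28 loft resolution; the acceptance
script uses the default 48 x 40.  The randomized-conservation check uses 20
heads with parameters drawn over wide ranges (base depth -90..-70 mm,
semi-axes 50..95 mm, exponent 2..3).  The cohort recovery check generates
the full 26 + 20 cohort, measures every subject through the complete
pipeline and requires gender mean shares within 1.5 percentage points of
the presets.  The voxel oracle runs at 0.5 mm on the lower two-thirds.

## Known limitations

- The cutting engine assumes valid watertight input; repair is limited to
  duplicate-vertex merging and global orientation flips.
- The foramina plane's midpoint rule and the transversely level palatal
  plane are conventions; other 3D cephalometry packages may orient these
  planes differently, shifting slab boundaries by a few millimetres.
- Per-region volumes are modelled independently in the generator; real
  facial regions are correlated, so cohort-level variance structure is not
  faithful.
- Interactive clinical mesh tools do not document their capping or volume
  algorithms; agreement with them is established through volume
  conservation and the independent voxel oracle, not bit-compatibility.
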