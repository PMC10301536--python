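# volceph — volumetric cephalometry of the lower face

volceph measures how the soft-tissue volume of the lower two-thirds of a
face is distributed over four anatomical slabs — **malar, maxillary,
mandibular and chin** — and compares that distribution to gender-specific
normative references.  It is aimed at craniofacial researchers and
orthognathic-surgery planners who work with CBCT-derived soft-tissue
surfaces (STL) and 3D cephalometric landmarks, and who want the volume
distribution of a face as a quantitative planning reference rather than
angles and distances alone.

## The model

Given a watertight skin surface *S* (mm) and landmarks, six planes are
constructed: the Frankfort Horizontal plane (porions + orbitale), a coronal
plane through both porions, the bispinal (palatal) plane ANS–PNS, the
occlusal plane, an FH-parallel plane through the mental foramina, and the
mandibular base plane Go–Go–Me.  The lower two-thirds

> L = { p ∈ S : below FH, anterior of the bi-porion plane, above Go–Me }

is partitioned by the palatal, occlusal and foramina planes into four
contiguous watertight solids.  Each volume is the signed-tetrahedron sum
V = (1/6) Σ_faces det[a b c], and the statistic of interest is the share
vector

> sᵢ = 100 · Vᵢ / Σⱼ Vⱼ  (percent),  plus the ratio V_max / V_mand.

The embedded normative references are the reported gender means: females
38.7 / 29.0 / 27.6 / 4.7 % (maxilla/mandible ratio 1.05) and males
37 / 26 / 30 / 6 % (stored verbatim, with flags where the printed male
values are inconsistent with their own mean volumes — see
`docs/methods.md`).

A synthetic generator produces watertight parametric heads with consistent
landmarks whose measured distribution can be calibrated to any target
shares, plus whole cohorts and jury-score tables, so the entire analysis
runs without clinical data.

## Worked example

Calibrate a synthetic head to a mandible-heavy distribution and compare it
against the female reference:

```python
from volceph import HeadSpec, calibrate_to_distribution, generate_head
from volceph.planes import build_plane_stack
from volceph.slabs import extract_lower_two_thirds, partition_slabs, slab_volumes
from volceph.cohort import load_references, compare_to_reference

spec = calibrate_to_distribution(HeadSpec(), (36.7, 29.0, 29.6, 4.7))
mesh, lm = generate_head(spec)
stack = build_plane_stack(lm)
lower = extract_lower_two_thirds(mesh, stack)
profile = slab_volumes(partition_slabs(lower, stack, lm=lm))
print("volumes (mm^3):", [round(v) for v in profile.volumes])
print("shares (%):    ", profile.rounded_shares())
report = compare_to_reference(profile, load_references()["female"])
print(report.round(1))
```

prints

```
volumes (mm^3): [257413, 203407, 207615, 32965]
shares (%):     (36.7, 29.0, 29.6, 4.7)
            subject_share  reference_share  deviation_pp  equalizing_volume_mm3
region
malar                36.7             38.7          -2.0                14028.3
maxillary            29.0             29.0           0.0                   -0.6
mandibular           29.6             27.6           2.0               -14028.3
chin                  4.7              4.7          -0.0                    0.6
```

Reading: this face carries 2 percentage points less malar and 2 points more
mandibular volume than the female reference; at its total of ~701 cm³·10⁻³,
equalizing the malar share at constant total would take about +14 000 mm³
of malar soft tissue.

The same pipeline is scriptable from the shell:

```sh
volceph simulate --n-female 26 --n-male 20 --seed 7 --out study/
volceph measure --mesh study/f001.stl --landmarks study/f001_landmarks.json \
                --reference female --out study/f001_report
volceph cohort  --manifest study/manifest.csv --scores study/scores.csv \
                --out study/summary
volceph select  --scores study/scores.csv --cutoff 8.5
```

## Layout

- `volceph.geometry` — planes, watertight plane cuts with capping, mesh
  volume, voxel parity oracle
- `volceph.landmarks` / `volceph.planes` — landmark files, head frame, the
  six anatomical planes, stack validation
- `volceph.slabs` — lower-two-thirds extraction and the four-slab partition
- `volceph.cohort` — shares, ratios, jury selection, Pearson repeatability,
  Shapiro–Wilk, gender summaries, normative comparison
- `volceph.synthetic` — parametric heads, share calibration, cohorts,
  jury scores
- `volceph.io` / `volceph.cli` — STL/landmark I/O, run configuration, the
  `volceph` command

`docs/methods.md` documents the model, conventions, numerical choices and
limitations in detail.
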