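# facesym

Quantitative analysis of facial asymmetry for orthodontic / orthognathic
research: **volumetric soft-tissue asymmetry** from 3D facial surface meshes
by mirror-superimposition, the **28 postero-anterior (PA) cephalometric
skeletal measurements** from 2D landmark coordinates, and the **statistics
that relate the two** (Pearson r / R² with Cohen effect-size classes,
Dahlberg TEM, reliability coefficient, ICC, exact power analysis for
correlations). A synthetic-data module generates faces with analytically
known injected asymmetry, schematic PA landmark sets, and calibrated
multivariate cohorts, so the entire chain runs and validates without any
clinical data.

## The method

**Volumetric asymmetry.** For a facial surface *S* with soft-tissue
landmarks, the midsagittal plane is constructed through sellion (Se) and
subnasale (Sn), perpendicular to the coronal plane of an anatomical head
frame (Frankfort-horizontal surrogate through both tragia and the
exocanthion midpoint). *S* is reflected across this plane and superimposed
back onto itself with a best-fit rigid registration (two-phase
point-to-surface ICP; the refinement phase excludes the 10% worst-fitting
correspondences so the asymmetry being measured cannot bias its own
reference alignment). The asymmetry score per region *R* is

&nbsp;&nbsp;&nbsp;&nbsp;V(R) = Σ<sub>f∈R</sub> |d(c<sub>f</sub>, S′)| · A<sub>f</sub> &nbsp;&nbsp;[mm³ → cm³]

the area-weighted absolute closest-point distance from original face
centroids c<sub>f</sub> to the aligned mirror S′. Regions are cut by planes
parallel to the Frankfort horizontal: **midface** (exocanthion level →
cheilion level), **lower face** (cheilion → menton), with the nasal box
excluded; the whole-face value is their sum. A unilateral deformation is
counted on both sides of the mirror pair, so a hemispherical bump of radius
r contributes ≈ 2·(2/3)πr³.

**PA cephalometrics.** From named 2D landmarks (CG, ANS, U1, Me and
bilateral Lo, J, Mo, Go, Ag, L6 tagged `_a` deviated / `_b` contralateral),
the midline (CG–ANS by default, CG–U1 optional), the Lo line and the two
facial-plane lines FP/FP′ are built, and all 28 linear (mm) and angular
(degrees) measurements are evaluated: side distances are unsigned, side
differences are signed (a − b), angles are acute in [0°, 90°].

**Statistics.** R² = r² with Cohen's classes (very weak < 0.02 ≤ weak
< 0.13 ≤ moderate < 0.26 ≤ substantial); Dahlberg TEM = √(Σd²/2n) and
reliability R = 1 − TEM²/σ²; single-measure absolute-agreement ICC(A,1)
with Landis–Koch labels; and exact sample-size computation for detecting a
correlation under bivariate normality, integrating the exact sampling
density of r (for ρ = 0.50, α = 0.05 two-tailed, power 0.80 this yields
n = 29, where the Fisher-z approximation would give 30).

## Worked example

```python
from facesym import (FaceSpec, Deformation, generate_face, run_asymmetry_pipeline,
                     PAAsymmetryParams, generate_pa_landmarks, measure_all,
                     correlation_sample_size, CohortSpec, generate_cohort, pearson)

# a synthetic face with a 5 mm chin deviation and a 6 mm cheek bump
face = generate_face(FaceSpec(
    target_faces=40_000,
    deformations=(Deformation("chin", "lateral_shift", 5.0),
                  Deformation("cheek_left", "bump", 6.0)),
))
result = run_asymmetry_pipeline(face.mesh, face.landmarks)
print(f"whole face : {result.volume_whole:.2f} cm^3")
print(f"midface    : {result.volume_mid:.2f} cm^3")
print(f"lower face : {result.volume_lower:.2f} cm^3")
```

```
whole face : 1.54 cm^3
midface    : 0.93 cm^3
lower face : 0.61 cm^3
```

The midface reading is the cheek bump counted on both sides of the mirror
pair, 2·(2/3)π·6³ = 0.905 cm³, recovered within 3%; the lower-face volume
comes from the chin shift. The matching skeletal picture and study-level
statistics:

```python
pa = generate_pa_landmarks(PAAsymmetryParams(menton_offset_mm=5.0,
                                             occlusal_cant_deg=2.0))
meas = measure_all(pa)
print(f"Midline-Me : {meas.midline_me:.2f} mm   angle Ocl: {meas.ang_ocl:.2f} deg")

print("required n :", correlation_sample_size(0.50, alpha=0.05, power=0.80))

cohort = generate_cohort(CohortSpec(n_subjects=33, seed=1))
s = pearson(cohort["midline_me"], cohort["volume_whole"])
print(f"cohort n=33: r={s.r:.3f}  R^2={s.r_squared:.3f}  [{s.effect_class}]")
```

```
Midline-Me : 5.00 mm   angle Ocl: 2.00 deg
required n : 29
cohort n=33: r=0.780  R^2=0.609  [substantial]
```

The menton offset is recovered exactly as the midline–Me distance; the
simulated 33-subject cohort is calibrated so that the menton-deviation ↔
whole-face-volume coefficient of determination is 0.630 in expectation, and
a single draw lands near it.

## Command line

```bash
facesym simulate face --spec spec.toml --seed 1 --out sim/   # PLY + landmarks
facesym asym --mesh sim/face.ply --landmarks sim/landmarks.json --out asym.csv
facesym ceph --landmarks pa.csv --convention cg_ans --out meas.csv
facesym corr --cohort cohort.csv --out table.csv
facesym study --n-subjects 33 --mode mesh --seed 1 --out report/
```

`facesym study` runs the whole chain on simulated subjects — skeletal menton
deviation drives both the 3D chin deformation and the PA menton offset —
and writes per-subject measurements, descriptive statistics (mean, t-based
95% CI, SD, min, max) and the R² matrix with effect-size flags.

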