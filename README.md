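# kneemorph

Multimodal CT/MRI assessment of knee bone and cartilage condition.

Knee osteoarthritis and traumatic cartilage injury are usually graded from
single-modality images with semi-quantitative scores (ICRS 0–4 defect
grades, Ahlbäck joint-space narrowing). `kneemorph` implements a combined
workflow that turns paired CT/MRI knee volumes plus human-graded
radiological observations into a quantitative per-knee profile and a
three-way classification of degenerative (D), traumatic (T) and control
(C) knees:

* **Articular cartilage thickness (ACT)** at 17 protocol sites. Femoral
  condyles: a cylinder with axis perpendicular to the sagittal plane is
  fitted to the cartilage; thickness is read radially at the centers of
  three 30° regions (anterior −15°, middle +15°, posterior +45°, with the
  0° ray at the most inferior point of the lateral condyle and 20°
  anterior to it for the medial condyle). Tibia: thirds of the
  anteroposterior cartilage line. Femoropatellar compartment: the axial
  slice where trochlear + patellar cartilage are jointly thickest, probed
  at 2 trochlear and 3 patellar points.
* **Cumulative bone-pathology index (CI)**, 0–6: the number of distinct
  pathology kinds (subchondral cysts, sclerosis, osteophytes, bone
  attrition, osteonecrosis, subchondral edema) present in a bone,
  regardless of compartment or observing modality.
* **3-D morphometry** per segmented part: radiodensity (HU), bone mineral
  density via the linear phantom calibration ρ_app = 0.000494·HU + 1.1
  g/cm³, cartilage density after a 1-voxel erosion and 0–300 HU window
  (suppressing the partial-volume rim), volume (mm³) and surface (mm²),
  after landmark-based rigid registration of the MRI frame into the CT
  frame.
* **A 96-feature per-knee table** (78 2-D = 52 MRI + 26 CT, plus 18 3-D
  features) with named subsets (Tot/2D/3D/CT/MRI/Bone/Cartilage),
* **group statistics** (ANOVA with Bonferroni post-hoc, Cohen's d with
  80%-power sample sizes, age-trend r²), and
* **classification**: random forest and gradient boosting with stratified
  10-fold cross-validation, pooled confusion metrics (accuracy, per-class
  precision/recall/F1) and permutation feature importance normalised to a
  100% budget.

Because real cohorts require clinical data, the package ships a
first-class synthetic-data module: paired CT/MRI **phantoms** with exact
geometric ground truth (condylar cylinder shells, tibial/patellar slabs,
known HU distributions, a known rigid misalignment with paired landmarks)
and synthetic **cohorts** whose group-conditional prevalences, grade and
thickness distributions match published per-group summaries.

## Worked example

```python
import kneemorph as km

# phantom -> registration -> morphometry + thickness
phantom = km.generate_phantom(km.PhantomConfig(noise_seed=0))
result = km.extract_phantom(phantom)
print(f"registration rmsd: {result['registration_rmsd_mm']:.2e} mm")
print(f"fusion audit passed: {result['fusion'].passed}")
femur = next(m for m in result["morphometry"] if m.part == "femur")
print(f"femur BMD: {femur.bmd_g_cm3:.3f} g/cm^3")
t = result["thickness"][("lateral", "femur", "middle")]
print(f"lateral femoral mid-region ACT: {t:.2f} mm "
      f"(truth {phantom.truth_thickness[('lateral', 'femur', 'middle')]} mm)")

# cohort -> features -> classification
records = km.generate_cohort(km.CohortConfig(seed=0))
frame = km.cohort_to_frame(records)
X = frame[km.build_default_schema().names].to_numpy(float)
counts, metrics, folds = km.crossval_classify(X, frame["group"].to_numpy(),
                                              km.ModelSpec(algorithm="RF", seed=0))
print(f"{len(records)} knees, RF 10-fold accuracy: {metrics.accuracy:.1f}%")
```

prints

```
registration rmsd: 2.44e-14 mm
fusion audit passed: True
femur BMD: 1.320 g/cm^3
lateral femoral mid-region ACT: 3.11 mm (truth 3.0 mm)
47 knees, RF 10-fold accuracy: 95.7%
```

The registration recovers the phantom's known MRI→CT misalignment to
numerical precision; the femoral BMD follows from the mean bone HU (~445)
through the linear calibration; the thickness read-out lands within half a
voxel (0.3 mm) of the constructed 3.0 mm shell; and the default 47-knee
synthetic cohort is classified well above the 33% three-class chance level
because the planted group effects (e.g. medial pathology prevalences and
medial ACT loss in degenerative knees) are strong.

A command-line interface mirrors the stages:

```bash
kneemorph phantom --seed 0 --out runs/phantom
kneemorph cohort  --seed 0 --out runs/features.csv
kneemorph stats    --features runs/features.csv --out runs/stats
kneemorph classify --features runs/features.csv --subset Tot --algo rf --seed 0 --out runs/clf
kneemorph run --seed 0 --out runs/full        # everything + manifest.json
```

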