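# Methods

## Scope and data model

`kneemorph` models one knee as: two co-registered intensity volumes (CT
and an MRI-derived volume on the same quantitative HU-like scale), binary
per-part segmentation masks (femur, tibia, patella, fibula bones; femoral,
medial-tibial, lateral-tibial, patellar cartilages), human-graded
radiological observations (binary bone-pathology flags per location and
modality, ICRS 0–4, Ahlbäck 0–3, meniscal pathology, synovitis–effusion),
and a group label D/T/C. The canonical orientation maps array axes
(i, j, k) to (medial→lateral, posterior→anterior, inferior→superior) with
world coordinates in mm at voxel centers; "inferior" is −z and a sagittal
slice is a fixed-i plane. All downstream conventions (the condylar 0° ray,
the anteroposterior tibial line, axial femoropatellar slices) refer to
this frame.

## Thickness protocol

Femoral condyles: the cylinder axis is fixed perpendicular to the sagittal
plane, so the fit reduces to a least-squares circle in-slice (algebraic
Kåsa initialisation, geometric Levenberg–Marquardt refinement; RMS radial
deviation reported as the residual). The circle is fitted to the
bone–cartilage interface (cartilage voxels face-adjacent to bone). The 0°
ray points at the most inferior point of the condylar bone; for the medial
compartment it is rotated exactly 20° anterior (the protocol's "about 20°"
is treated as exact and is configurable). Angular regions are anterior
[−30°, 0°), middle [0°, 30°), posterior [30°, 60°], probed at their
centers −15°, +15°, +45°; positive angles run posterior. Thickness along a
ray is the length of the longest cartilage crossing, with both boundary
crossings located by linear interpolation of the binary mask sampled at
0.05 mm steps. Compartment averages are arithmetic means of their points.

Tibia, patella and trochlea are probed perpendicular to the
anteroposterior line / subchondral boundary (the protocol does not state a
direction for these; the surface-normal convention of standard
morphometry is used, which for the slab geometries here is an axis-aligned
column). Tibial points sit at 1/6, 1/2, 5/6 of the cartilage's AP extent.
The femoropatellar slice is the axial slice maximising the sum of the
maximum trochlear and patellar column thicknesses, ties resolving to the
lowest index (the alternative reading — both cartilages individually
maximal in one slice — is unsatisfiable in general). The sagittal
measurement slice of each femorotibial compartment is the mid-condylar
slice of that compartment's cartilage; the operator's slice choice is not
otherwise modelled.

Thickness is measured in the MRI frame: the protocol is a 2-D measurement
on the MRI scan, and only the 3-D morphometry depends on the fused
volumes. A binary mask localises each boundary only to the midpoint
between the last inside and first outside voxel center, so a single
boundary carries up to half a voxel of quantisation error.

## Registration and fusion

Paired anatomical landmarks (default 6; at least 3 non-collinear required)
drive a closed-form least-squares rigid fit (SVD/Kabsch with reflection
correction, no scaling); MRI→CT is the canonical direction with CT as the
reference frame. Masks are resampled by nearest neighbor into the CT
lattice to stay binary (linear interpolation + 0.5 threshold is the
documented alternative). Nearest-neighbor resampling can push boundary
cartilage voxels into bone; the pipeline clips resampled cartilage against
the bone masks — the automated analog of the manual adjustment that the
workflow performs after visual fusion inspection — and then audits all
part pairs for overlap (pass iff every count is within a configurable
voxel tolerance, default 0).

## Morphometry

Radiodensity is the mean and population SD of HU under a mask (population
rather than sample SD is fixed for testability; the difference is
negligible at the voxel counts involved). BMD uses the linear phantom
calibration ρ_app = 0.000494·HU + 1.1 g/cm³, applied to the mean HU of the
whole bone mask; by linearity this equals the mean of per-voxel
conversions, and the BMD SD is 0.000494·SD(HU). A boundary-region variant
(bone voxels within k mm of cartilage) is available behind a flag, since
whole-bone averaging dilutes subchondral changes. Cartilage density is
computed on (erode 1 voxel) ∩ (HU ∈ [0, 300]) — erosion first, then the
window — so the partial-volume rim where cartilage blends into bone is
excluded. Erosion uses the 6-connected structuring element in 3-D
("pixel" read as "voxel"; the volumes are near-isotropic). Volumes come
from voxel counts × voxel volume and from the signed tetrahedron sum of
marching-cubes surfaces (zero-padded, so always closed); surfaces are
triangle-area sums. Smoothing is off for quantitative figures and
available for export meshes only.

## Cumulative index

For each bone, the index counts the pathology kinds (of six) present
anywhere in that bone — OR over locations and over CT/MRI. Osteophytes
are graded per compartment and attribute to every bone articulating in
it; the trochlea attributes to the femur. A compartment-restricted
variant uses only that compartment's locations. Note that osteonecrosis
is graded at the four femorotibial sites only, so the patellar index
structurally ranges 0–5 while femur and tibia realise the full 0–6.

## Feature schema

The shipped 96-feature schema (editable YAML; count invariants enforced at
load): Cartilage (26, MRI) = 6 ICRS + 2 meniscal flags + synovitis–
effusion + 17 thickness points; Bone (50) = 25 CT-observable flags
(cysts×6, sclerosis×6, osteophytes×3, attrition×6, osteonecrosis×4) + 25
MRI-observable flags (edema replacing sclerosis); the remaining CT slot is
the Ahlbäck grade and the remaining MRI slot a single ordinal for the
meniscal-pathology type (0 none, 1 degeneration, 2 rupture, 3 protrusion —
a flagged encoding convention); 3-D (18) = {volume, density mean, density
SD} for 4 cartilage parts + {BMD, BMD SD} for 3 bones. This realises the
published subset sizes 96/78/18/26/52/50/26; the exact identities of the
study's own 52 MRI and 26 CT features are not published beyond the subset
sizes and a dozen named features, so the schema is a reconstruction
consistent with those names.

## Synthetic data

**Phantom.** Geometry matches the measurement model so ground truth is
exact: condyles are cylinder segments (axis ⟂ sagittal plane) with
concentric cartilage shells over a [−60°, +75°] inferior arc; the tibial
plateau is a slab with a planar cartilage layer split medial/lateral; the
trochlea and patella are blocks with facing planar cartilage slabs,
uniform along z so the femoropatellar read-out does not depend on the
selected slice; the fibula is a small cylinder. Default spacing is 0.6 mm
isotropic (the MRI protocol's voxel size; CT's 0.5 mm slices can be
configured). Default thicknesses (femoral 3.0, tibial 2.4, patellar 2.4,
trochlear 1.8 mm) lie in the published ACT ranges and are whole-voxel
multiples of the default spacing: binary-mask boundary localisation is
quantised to inter-voxel midpoints, so voxel-commensurate slabs keep the
protocol's half-voxel recovery bound attainable by design rather than by
luck of the sampling phase. The femoral thickness may be a function of
angle. Tissue HU defaults: bone (445, 150) — giving BMD ≈ 1.32 g/cm³ —
cartilage (100, 10), soft-tissue background (30, 15), and an optional
1-voxel partial-volume rim at (400, 30) painted on the cartilage
boundary. Both volumes share the quantitative HU-like scale because the
fused dataset extracts radiodensity in HU. The "MRI" volume renders the
same analytic geometry in a frame rigidly misaligned by a known transform
(default ≈2–3° rotations about the volume center plus a few mm of
translation), with its own noise realisation; cartilage truth masks live
in the MRI frame, bone masks in the CT frame, and exact paired landmarks
(optionally noised) in both. The phantom emulates geometry, tissue
contrast, misalignment and partial volume; it does not emulate anatomy,
MRI physics, motion, or segmentation error — so passing tests demonstrate
correctness of the measurement pipeline, not robustness to real clinical
variability.

**Cohort.** Subjects are drawn independently: Bernoulli pathology flags
from the published per-group, per-location prevalences (a pathology
observable in both CT and MRI is mirrored to both modality flags);
rounded, clipped Gaussians for ICRS (per-site means/SDs) and thickness
points (compartment-average means/SDs applied per point); demographics
from the published per-group, per-sex age distributions and female
fractions; 3-D features from the published per-group morphometry
summaries. Choices where the source tables are silent: Ahlbäck grades use
clipped Gaussians D (2.0, 1.0), T (0.5, 0.7), C (0.2, 0.4); the meniscal
type is uniform over the three types when pathology is present; the
per-subject voxelwise density-SD features use (50, 10) HU for cartilage
and 0.000494×N(150, 30) for bone; and the between-subject BMD SD is 0.05
g/cm³, because the published per-group BMD SDs (~1.1 g/cm³) are
inconsistent with the HU→BMD mapping and would produce negative
densities. Pathologies are sampled independently within a subject — the
published summaries carry no intra-subject correlation structure — so the
synthetic cohort is easier to classify than a real one; classifier checks
against it are sanity floors, not reproductions of the published metrics,
which require the real cohort.

## Statistics and classification

Group comparisons: classical one-way ANOVA (degenerate all-constant input
follows the F = 0, p = 1 convention) with pooled-variance pairwise t-tests
and Bonferroni multiplication capped at 1. Cohen's d uses (n−1)-weighted
pooled SD. Sample sizes for 80% power at α = 0.05 use the normal
approximation n = 2(z₁₋α/₂ + z_power)²/d² (ceiled) by default, with an
exact noncentral-t search as the alternative; the published sample-size
table is not consistent with any single standard method, so exact
reproduction of every cell is not claimed. Age trends are OLS with
r² = 1 − SSres/SStot.

Classification: scikit-learn RandomForest (100 trees, entropy splits, max
depth 10, min samples per leaf 1) and GradientBoosting (100 trees, depth
4, learning rate 0.1). The original analysis used a proprietary
"Information Gain Ratio" split criterion; entropy is the closest standard
criterion and the discrepancy is accepted. Folds are stratified 10-fold
with a fixed seed (the source is silent on stratification); out-of-fold
predictions are pooled into one confusion matrix. Metrics follow the
printed formulas: accuracy (TP+TN)/total per one-vs-rest class collapses
to overall correct/total, precision TP/(TP+FP), recall TP/(TP+FN),
F1 = TP/(TP+(FP+FN)/2); zero denominators report 0 with a warning.
Feature importance is out-of-fold permutation importance (accuracy drop,
averaged over folds and repeats, negatives clipped) normalised so the
per-feature shares sum to exactly 100%; group shares are exact sums of
their members (the published group table sums to 99.2%, suggesting an
unnormalised residual that is deliberately not reproduced). With
imbalanced groups a shuffled-label null converges to the majority-class
rate, so the 33% three-class chance level is checked on balanced cohorts.

## Numerical choices and degenerate inputs

HU windows are inclusive on both bounds. Collinear landmark or circle
configurations raise rather than fit. Surface extraction requires a
non-empty mask; volume computation requires a watertight mesh (an
isolated voxel meshes to the octahedron through its face midpoints,
volume v/6 — mesh volume converges to mask volume only as spacing → 0).
Empty post-filter cartilage masks ("no voxels survive partial-volume
filtering"), cartilage absent along a probe ray, and sub-voxel configured
thicknesses ("unresolvable geometry") are hard errors. All generators and
analyses are deterministic under a fixed seed.

## Problem sizes

The shipped tests and the acceptance checks use: a ~145³-voxel phantom at
0.6 mm (one per session, plus one 0.3 mm phantom for the convergence
check), cohorts of 47 (default), 470 (classifier floor) and 10⁴ (prevalence
convergence) subjects, 10⁴ ANOVA null simulations, and a 240×96 planted-
signal importance matrix — sizes chosen so every property is measured with
comfortable statistical margin on a single CPU.
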