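"""Default cohort model: published per-group summary statistics.

These are the study-cohort summaries (degenerative D, traumatic T, control
C) that parameterize the synthetic cohort generator: group sizes and
demographics, per-location bone-pathology prevalences, ICRS grade and
articular-cartilage-thickness distributions, and per-part 3-D morphometry
distributions. Prevalences are probabilities in [0, 1]; distributions are
(mean, SD) pairs per group in D, T, C order.
"""

from __future__ import annotations

#: Subjects per group
GROUP_SIZES = {"D": 23, "T": 16, "C": 8}

#: Number of females per group (of GROUP_SIZES)
FEMALES = {"D": 12, "T": 9, "C": 3}

#: Age (mean, SD) in years per (group, sex)
AGE = {
    ("D", "F"): (66.0, 12.0),
    ("D", "M"): (66.0, 7.0),
    ("T", "F"): (39.0, 11.0),
    ("T", "M"): (29.0, 7.0),
    ("C", "F"): (29.0, 5.0),
    ("C", "M"): (37.0, 16.0),
}


def _g(d, t, c):
    return {"D": d, "T": t, "C": c}


#: Bone-pathology prevalence per (pathology, location): {group: probability}
PREVALENCE = {
    ("cysts", "medial/femur"): _g(0.3478, 0.1875, 0.0),
    ("cysts", "medial/tibia"): _g(0.6087, 0.0625, 0.0),
    ("cysts", "lateral/femur"): _g(0.1739, 0.0625, 0.0),
    ("cysts", "lateral/tibia"): _g(0.2609, 0.125, 0.0),
    ("cysts", "femoropatellar/trochlea"): _g(0.2609, 0.1875, 0.125),
    ("cysts", "femoropatellar/patella"): _g(0.3043, 0.0625, 0.125),
    ("osteophytes", "medial"): _g(0.913, 0.0625, 0.125),
    ("osteophytes", "lateral"): _g(0.9565, 0.0, 0.0),
    ("osteophytes", "femoropatellar"): _g(0.913, 0.25, 0.25),
    ("attrition", "medial/femur"): _g(0.3043, 0.0, 0.0),
    ("attrition", "medial/tibia"): _g(0.2609, 0.0, 0.0),
    ("attrition", "lateral/femur"): _g(0.0, 0.0, 0.0),
    ("attrition", "lateral/tibia"): _g(0.0, 0.0, 0.0),
    ("attrition", "femoropatellar/trochlea"): _g(0.0, 0.0, 0.0),
    ("attrition", "femoropatellar/patella"): _g(0.0, 0.0, 0.0),
    ("osteonecrosis", "medial/femur"): _g(0.0435, 0.25, 0.0),
    ("osteonecrosis", "medial/tibia"): _g(0.1739, 0.125, 0.0),
    ("osteonecrosis", "lateral/femur"): _g(0.2174, 0.375, 0.125),
    ("osteonecrosis", "lateral/tibia"): _g(0.2174, 0.25, 0.125),
    ("sclerosis", "medial/femur"): _g(0.8696, 0.375, 0.125),
    ("sclerosis", "medial/tibia"): _g(1.0, 0.9735, 0.875),
    ("sclerosis", "lateral/femur"): _g(0.3478, 0.3125, 0.25),
    ("sclerosis", "lateral/tibia"): _g(0.2174, 0.125, 0.0),
    ("sclerosis", "femoropatellar/trochlea"): _g(0.1304, 0.0625, 0.0),
    ("sclerosis", "femoropatellar/patella"): _g(0.6957, 0.9375, 0.75),
    ("edema", "medial/femur"): _g(0.5227, 0.3125, 0.25),
    ("edema", "medial/tibia"): _g(0.6522, 0.125, 0.0),
    ("edema", "lateral/femur"): _g(0.2609, 0.6875, 0.25),
    ("edema", "lateral/tibia"): _g(0.1304, 0.0625, 0.0),
    ("edema", "femoropatellar/trochlea"): _g(0.1739, 0.5, 0.0),
    ("edema", "femoropatellar/patella"): _g(0.0435, 0.5, 0.0),
}

#: Meniscal pathology prevalence per compartment
MENISCAL_PREVALENCE = {
    "medial": _g(1.0, 0.1875, 0.0),
    "lateral": _g(0.2609, 0.375, 0.0),
}

#: Synovitis-effusion prevalence
SYNOVITIS_PREVALENCE = _g(0.9565, 1.0, 0.75)

#: ICRS grade (mean, SD) per (compartment, bone-part) site per group
ICRS = {
    ("medial", "femur"): _g((3.26, 0.67), (1.0, 1.41), (0.63, 0.70)),
    ("medial", "tibia"): _g((3.17, 1.31), (1.13, 1.05), (0.0, 0.0)),
    ("lateral", "femur"): _g((1.96, 1.37), (1.63, 1.11), (1.38, 0.70)),
    ("lateral", "tibia"): _g((2.22, 1.41), (1.75, 1.25), (0.75, 0.83)),
    ("femoropatellar", "trochlea"): _g((2.36, 1.37), (0.94, 1.09), (0.75, 1.09)),
    ("femoropatellar", "patella"): _g((3.09, 0.79), (2.69, 0.58), (1.75, 0.66)),
}

#: Articular cartilage thickness (mean, SD) in mm per site per group
ACT = {
    ("medial", "femur"): _g((1.5, 0.71), (2.63, 0.56), (2.64, 0.67)),
    ("medial", "tibia"): _g((1.63, 0.76), (2.3, 0.45), (2.48, 0.42)),
    ("lateral", "femur"): _g((2.44, 0.63), (2.7, 0.54), (2.9, 0.38)),
    ("lateral", "tibia"): _g((2.4, 0.81), (2.9, 0.73), (3.06, 0.65)),
    ("femoropatellar", "trochlea"): _g((2.21, 0.77), (1.97, 0.77), (2.31, 0.29)),
    ("femoropatellar", "patella"): _g((2.29, 0.61), (2.78, 0.7), (2.7, 0.32)),
}

#: Ahlback grade (mean, SD) per group — chosen defaults; the source tables
#: report no per-group Ahlback distribution
AHLBACK = _g((2.0, 1.0), (0.5, 0.7), (0.2, 0.4))

#: Cartilage radiodensity (mean, between-subject SD) in HU per part per group
CART_DENSITY = {
    "FemCartDEN": _g((85.19, 57.47), (88.67, 49.90), (93.53, 54.37)),
    "TibCartLatDEN": _g((87.84, 51.10), (88.69, 44.97), (91.19, 49.21)),
    "TibCartMedDEN": _g((98.49, 55.92), (93.63, 44.14), (103.79, 52.82)),
    "PatCartDEN": _g((78.36, 50.68), (81.56, 44.97), (99.09, 55.45)),
}

#: Cartilage volume (mean, between-subject SD) in mm^3 per part per group
CART_VOLUME = {
    "FemCartVOL": _g((17303.0, 5530.0), (12460.0, 2710.0), (11276.0, 4505.0)),
    "TibCartLatVOL": _g((2851.0, 2336.0), (1100.0, 439.0), (1501.0, 1927.0)),
    "TibCartMedVOL": _g((1915.0, 1638.0), (907.0, 566.0), (552.0, 362.0)),
    "PatCartVOL": _g((2761.0, 830.0), (2589.0, 781.0), (2703.0, 705.0)),
}

#: Bone mineral density mean (g/cm^3) per bone per group; the between-subject
#: SD (0.05) is a chosen default — the printed per-group SDs are inconsistent
#: with the linear HU->BMD mapping
BMD_MEAN = {
    "FemBMD": _g(1.32, 1.33, 1.32),
    "TibBMD": _g(1.32, 1.35, 1.29),
    "PatBMD": _g(1.36, 1.40, 1.41),
}
BMD_BETWEEN_SD = 0.05

#: Per-subject voxelwise cartilage-density SD feature (mean, SD) in HU — chosen
CART_DENSITY_SD_FEATURE = (50.0, 10.0)
#: Per-subject voxelwise bone HU SD (mean, SD) feeding the BMD-SD feature — chosen
BONE_HU_SD_FEATURE = (150.0, 30.0)
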