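"""Synthetic cohort generator.

Draws subject records whose group-conditional distributions match the
published per-group summaries in :mod:`kneemorph.reference`: binary
pathology flags are Bernoulli draws from the per-location prevalences,
ordinal grades are rounded, clipped Gaussians from the per-site means and
SDs, thickness points are Gaussians around the compartment averages, and
the 18 3-D features are Gaussians around the per-group morphometry
summaries. Pathologies are sampled independently within a subject (the
published summaries carry no intra-subject correlation structure), and a
pathology observable in both CT and MRI is mirrored to both modality
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference as ref
from .features import (
    GradeSet,
    MORPHOMETRY_FEATURES,
    PATHOLOGY_LOCATIONS,
    PathologyFlags,
    SITES6,
    SubjectRecord,
    THICKNESS_SITES,
)
from .morphometry import BMD_SLOPE


@dataclass
class CohortConfig:
    """Study-condition parameters of the cohort generator.

    Defaults reproduce the published group sizes (23 D / 16 T / 8 C),
    demographics, prevalences and grade/thickness distributions.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(ref.GROUP_SIZES)
    )
    prevalence: dict = field(default_factory=lambda: dict(ref.PREVALENCE))
    meniscal_prevalence: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in ref.MENISCAL_PREVALENCE.items()}
    )
    synovitis_prevalence: dict = field(default_factory=lambda: dict(ref.SYNOVITIS_PREVALENCE))
    icrs_dist: dict = field(default_factory=lambda: dict(ref.ICRS))
    act_dist: dict = field(default_factory=lambda: dict(ref.ACT))
    ahlback_dist: dict = field(default_factory=lambda: dict(ref.AHLBACK))
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {g: ref.FEMALES[g] / ref.GROUP_SIZES[g] for g in ref.GROUP_SIZES}
    )
    age_dist: dict = field(default_factory=lambda: dict(ref.AGE))
    seed: int = 0

    def validate(self) -> None:
        for group, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative group size for {group!r}: {n}")
        for key, probs in self.prevalence.items():
            for group, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence out of [0,1] for {key}/{group}: {p}")
        for key, dists in self.icrs_dist.items():
            for group, (_, sd) in dists.items():
                if sd < 0:
                    raise ValueError(f"negative SD for ICRS {key}/{group}")


def _clipped_gaussian_grade(rng, mean: float, sd: float, lo: int, hi: int) -> int:
    return int(np.clip(np.rint(rng.normal(mean, sd)), lo, hi))


def _sample_flags(rng: np.random.Generator, config: CohortConfig, group: str) -> PathologyFlags:
    flags = PathologyFlags.none()
    for pathology in PATHOLOGY_LOCATIONS:
        for location in PATHOLOGY_LOCATIONS[pathology]:
            prob = config.prevalence.get((pathology, location), {}).get(group, 0.0)
            present = rng.random() < prob
            # concordant across the modalities able to show the pathology
            flags.set(pathology, location, int(present))
    return flags


def _sample_grades(rng: np.random.Generator, config: CohortConfig, group: str) -> GradeSet:
    icrs = {
        site: _clipped_gaussian_grade(rng, *config.icrs_dist[site][group], 0, 4)
        for site in SITES6
    }
    ahlback = _clipped_gaussian_grade(rng, *config.ahlback_dist[group], 0, 3)
    meniscal = {
        comp: int(rng.random() < config.meniscal_prevalence[comp][group])
        for comp in ("medial", "lateral")
    }
    mtype = int(rng.integers(1, 4)) if any(meniscal.values()) else 0
    synovitis = int(rng.random() < config.synovitis_prevalence[group])
    return GradeSet(icrs=icrs, ahlback=ahlback, meniscal=meniscal,
                    meniscal_type=mtype, synovitis_effusion=synovitis)


def _sample_thickness(rng, config: CohortConfig, group: str) -> dict:
    out = {}
    for site in THICKNESS_SITES:
        comp, bone, _ = site
        bone_key = "trochlea" if bone == "trochlea" else bone
        mean, sd = config.act_dist[(comp, bone_key)][group]
        out[site] = float(max(rng.normal(mean, sd), 0.1))
    return out


def _sample_morphometry(rng, group: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, dists in ref.CART_VOLUME.items():
        mean, sd = dists[group]
        out[name] = float(max(rng.normal(mean, sd), 50.0))
    for name, dists in ref.CART_DENSITY.items():
        mean, sd = dists[group]
        out[name] = float(rng.normal(mean, sd))
    for name, dists in ref.BMD_MEAN.items():
        out[name] = float(rng.normal(dists[group], ref.BMD_BETWEEN_SD))
    for cart in ("FemCart", "TibCartLat", "TibCartMed", "PatCart"):
        out[f"{cart}STD"] = float(max(rng.normal(*ref.CART_DENSITY_SD_FEATURE), 1.0))
    for bone in ("Fem", "Tib", "Pat"):
        hu_sd = max(rng.normal(*ref.BONE_HU_SD_FEATURE), 1.0)
        out[f"{bone}BMDSTD"] = float(BMD_SLOPE * hu_sd)
    assert set(out) == set(MORPHOMETRY_FEATURES)
    return out


def generate_cohort(config: CohortConfig | None = None) -> list[SubjectRecord]:
    """Draw a synthetic cohort; deterministic under a fixed config seed."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    counter = 0
    for group in ("D", "T", "C"):
        for _ in range(config.n_per_group.get(group, 0)):
            counter += 1
            sex = "F" if rng.random() < config.female_fraction.get(group, 0.5) else "M"
            mean_age, sd_age = config.age_dist[(group, sex)]
            age = float(np.clip(rng.normal(mean_age, sd_age), 18.0, 95.0))
            records.append(
                SubjectRecord(
                    subject_id=f"S{counter:04d}",
                    group=group,
                    sex=sex,
                    age=round(age, 1),
                    flags=_sample_flags(rng, config, group),
                    grades=_sample_grades(rng, config, group),
                    thickness=_sample_thickness(rng, config, group),
                    morphometry=_sample_morphometry(rng, group),
                )
            )
    return records
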