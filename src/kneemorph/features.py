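"""Graded observations, the cumulative bone-pathology index and the
96-feature schema.

Each knee carries human-graded radiological observations (binary bone
pathology flags per location and modality, ICRS 0-4 cartilage grades,
Ahlback 0-3 joint-space grade, meniscal pathology, synovitis-effusion),
measured cartilage thicknesses, and 3-D morphometry. These are arranged
into an ordered 96-feature row partitioned into 78 2-D features (52 MRI +
26 CT) and 18 3-D features, with class tags of 50 bone and 26 cartilage
features (the remainder tagged "other").

The cumulative index (CI) counts, from 0 to 6, how many of the six tracked
bone pathology kinds (subchondral cysts, subchondral sclerosis,
osteophytes, bone attrition, osteonecrosis, subchondral edema) are present
in a bone — a pathology counts once regardless of the compartment it was
seen in and of whether CT or MRI showed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("D", "T", "C")
BONES = ("femur", "tibia", "patella")
COMPARTMENTS = ("medial", "lateral", "femoropatellar")

#: (compartment, bone-part) sites used for site-level observations
SITES6 = (
    ("medial", "femur"),
    ("medial", "tibia"),
    ("lateral", "femur"),
    ("lateral", "tibia"),
    ("femoropatellar", "trochlea"),
    ("femoropatellar", "patella"),
)
SITES4 = SITES6[:4]

PATHOLOGIES = ("cysts", "sclerosis", "osteophytes", "attrition", "osteonecrosis", "edema")

_SITE = lambda s: f"{s[0]}/{s[1]}"

#: Observation locations per pathology (osteophytes are graded per compartment)
PATHOLOGY_LOCATIONS: dict[str, tuple[str, ...]] = {
    "cysts": tuple(_SITE(s) for s in SITES6),
    "sclerosis": tuple(_SITE(s) for s in SITES6),
    "osteophytes": COMPARTMENTS,
    "attrition": tuple(_SITE(s) for s in SITES6),
    "osteonecrosis": tuple(_SITE(s) for s in SITES4),
    "edema": tuple(_SITE(s) for s in SITES6),
}

#: Modalities able to show each pathology (sclerosis CT-only, edema MRI-only)
PATHOLOGY_MODALITIES: dict[str, tuple[str, ...]] = {
    "cysts": ("CT", "MRI"),
    "sclerosis": ("CT",),
    "osteophytes": ("CT", "MRI"),
    "attrition": ("CT", "MRI"),
    "osteonecrosis": ("CT", "MRI"),
    "edema": ("MRI",),
}

#: The 17 thickness measurement sites: (compartment, bone, point)
THICKNESS_SITES = tuple(
    [("medial", "femur", p) for p in ("anterior", "middle", "posterior")]
    + [("lateral", "femur", p) for p in ("anterior", "middle", "posterior")]
    + [("medial", "tibia", p) for p in ("anterior", "middle", "posterior")]
    + [("lateral", "tibia", p) for p in ("anterior", "middle", "posterior")]
    + [("femoropatellar", "trochlea", p) for p in ("medial", "lateral")]
    + [("femoropatellar", "patella", p) for p in ("medial", "center", "lateral")]
)

#: The 18 3-D feature names: volume / density mean / density SD per
#: cartilage part and BMD mean / SD per bone
MORPHOMETRY_FEATURES = (
    "FemCartVOL", "FemCartDEN", "FemCartSTD",
    "TibCartLatVOL", "TibCartLatDEN", "TibCartLatSTD",
    "TibCartMedVOL", "TibCartMedDEN", "TibCartMedSTD",
    "PatCartVOL", "PatCartDEN", "PatCartSTD",
    "FemBMD", "FemBMDSTD", "TibBMD", "TibBMDSTD", "PatBMD", "PatBMDSTD",
)


def _location_bone_parts(location: str) -> tuple[str, ...]:
    """Bone(s) a flag location refers to (trochlea belongs to the femur)."""
    if "/" in location:
        comp, part = location.split("/")
        return ({"femur": "femur", "tibia": "tibia", "trochlea": "femur",
                 "patella": "patella"}[part],)
    # compartment-level (osteophytes): all bones articulating in it
    return {
        "medial": ("femur", "tibia"),
        "lateral": ("femur", "tibia"),
        "femoropatellar": ("femur", "patella"),
    }[location]


def _location_compartment(location: str) -> str:
    return location.split("/")[0] if "/" in location else location


@dataclass
class PathologyFlags:
    """Binary pathology indicators keyed by (pathology, location, modality)."""

    flags: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @classmethod
    def none(cls) -> "PathologyFlags":
        return cls(
            {
                (p, loc, mod): 0
                for p in PATHOLOGIES
                for loc in PATHOLOGY_LOCATIONS[p]
                for mod in PATHOLOGY_MODALITIES[p]
            }
        )

    @classmethod
    def all_present(cls) -> "PathologyFlags":
        out = cls.none()
        for key in out.flags:
            out.flags[key] = 1
        return out

    def set(self, pathology: str, location: str, value: int,
            modality: str | None = None) -> None:
        mods = (modality,) if modality else PATHOLOGY_MODALITIES[pathology]
        for mod in mods:
            key = (pathology, location, mod)
            if key not in self.flags:
                raise KeyError(f"unknown pathology flag {key}")
            self.flags[key] = int(bool(value))

    def present(self, pathology: str, bone: str, compartment: str | None = None) -> bool:
        """OR of a pathology over the bone's locations and modalities."""
        for loc in PATHOLOGY_LOCATIONS[pathology]:
            if bone not in _location_bone_parts(loc):
                continue
            if compartment is not None and _location_compartment(loc) != compartment:
                continue
            for mod in PATHOLOGY_MODALITIES[pathology]:
                if self.flags.get((pathology, loc, mod), 0):
                    return True
        return False


def cumulative_index(flags: PathologyFlags, bone: str) -> int:
    """Cumulative index 0-6: number of distinct pathology kinds present in
    a bone, regardless of compartment or observing modality."""
    if bone not in BONES:
        raise ValueError(f"unknown bone {bone!r}; expected one of {BONES}")
    return sum(int(flags.present(p, bone)) for p in PATHOLOGIES)


def compartment_cumulative_index(flags: PathologyFlags, bone: str, compartment: str) -> int:
    """Cumulative index restricted to one compartment's locations."""
    if bone not in BONES:
        raise ValueError(f"unknown bone {bone!r}; expected one of {BONES}")
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}; expected one of {COMPARTMENTS}")
    return sum(int(flags.present(p, bone, compartment)) for p in PATHOLOGIES)


@dataclass
class GradeSet:
    """Ordinal / binary cartilage and joint-space observations."""

    icrs: dict[tuple[str, str], int]  # (compartment, bone-part) of SITES6 -> 0..4
    ahlback: int  # 0..3
    meniscal: dict[str, int]  # compartment ('medial'/'lateral') -> 0/1
    meniscal_type: int  # 0 none, 1 degeneration, 2 rupture, 3 protrusion
    synovitis_effusion: int  # 0/1

    @classmethod
    def clean(cls) -> "GradeSet":
        return cls(
            icrs={s: 0 for s in SITES6},
            ahlback=0,
            meniscal={"medial": 0, "lateral": 0},
            meniscal_type=0,
            synovitis_effusion=0,
        )


@dataclass
class SubjectRecord:
    """One knee's observations, thickness measurements and 3-D morphometry."""

    subject_id: str
    group: str  # D, T or C
    sex: str  # 'F' or 'M'
    age: float  # years
    flags: PathologyFlags
    grades: GradeSet
    thickness: dict[tuple[str, str, str], float]  # THICKNESS_SITES -> mm
    morphometry: dict[str, float]  # MORPHOMETRY_FEATURES -> native units

    def cumulative_indices(self) -> dict[str, int]:
        return {bone: cumulative_index(self.flags, bone) for bone in BONES}

    @staticmethod
    def morphometry_from_parts(parts) -> dict[str, float]:
        """Build the 18 3-D feature values from PartMorphometry records."""
        by_part = {p.part: p for p in parts}
        cart = {
            "FemCart": "femoral_cartilage",
            "TibCartLat": "lateral_tibial_cartilage",
            "TibCartMed": "medial_tibial_cartilage",
            "PatCart": "patellar_cartilage",
        }
        bone = {"Fem": "femur", "Tib": "tibia", "Pat": "patella"}
        out: dict[str, float] = {}
        for prefix, part in cart.items():
            rec = by_part[part]
            out[f"{prefix}VOL"] = rec.volume_mm3
            out[f"{prefix}DEN"] = rec.density.mean_hu
            out[f"{prefix}STD"] = rec.density.sd_hu
        for prefix, part in bone.items():
            rec = by_part[part]
            out[f"{prefix}BMD"] = rec.bmd_g_cm3
            out[f"{prefix}BMDSTD"] = rec.bmd_sd_g_cm3
        return out


@dataclass(frozen=True)
class FeatureDef:
    name: str
    source: str  # 'MRI', 'CT' or '3D'
    klass: str  # 'bone', 'cartilage' or 'other'


#: Expected subset sizes, enforced at schema construction
SUBSET_SIZES = {"Tot": 96, "2D": 78, "3D": 18, "CT": 26, "MRI": 52, "Bone": 50, "Cartilage": 26}


class FeatureSchema:
    """Ordered 96-feature definition with source and class tags.

    The partition invariants (MRI + CT = 2D, 2D + 3D = Tot, bone and
    cartilage tags disjoint, subset sizes per :data:`SUBSET_SIZES`) are
    validated at construction.
    """

    def __init__(self, features: list[FeatureDef]):
        self.features = list(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in schema")
        for subset, size in SUBSET_SIZES.items():
            got = len(self.subset_names(subset))
            if got != size:
                raise ValueError(f"schema subset {subset!r} has {got} features, expected {size}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def subset_names(self, subset: str) -> list[str]:
        if subset == "Tot":
            return self.names
        if subset == "2D":
            return [f.name for f in self.features if f.source in ("MRI", "CT")]
        if subset == "3D":
            return [f.name for f in self.features if f.source == "3D"]
        if subset in ("CT", "MRI"):
            return [f.name for f in self.features if f.source == subset]
        if subset == "Bone":
            return [f.name for f in self.features if f.klass == "bone"]
        if subset == "Cartilage":
            return [f.name for f in self.features if f.klass == "cartilage"]
        raise ValueError(f"unknown subset {subset!r}; expected one of {sorted(SUBSET_SIZES)}")

    def to_dict(self) -> list[dict]:
        return [{"name": f.name, "source": f.source, "class": f.klass} for f in self.features]

    @classmethod
    def from_dict(cls, entries: list[dict]) -> "FeatureSchema":
        return cls([FeatureDef(e["name"], e["source"], e["class"]) for e in entries])

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FeatureSchema":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def flag_feature_name(modality: str, pathology: str, location: str) -> str:
    return f"{modality} {location} {pathology}"


def thickness_feature_name(site: tuple[str, str, str]) -> str:
    comp, bone, point = site
    return f"MRI act {comp}/{bone} {point}"


def icrs_feature_name(site: tuple[str, str]) -> str:
    return f"MRI icrs {site[0]}/{site[1]}"


def build_default_schema() -> FeatureSchema:
    """The shipped 96-feature schema.

    Cartilage (26, MRI): 6 ICRS grades + 2 meniscal-pathology flags +
    synovitis-effusion + 17 thickness points. Bone (50): the CT-observable
    flags (cysts, sclerosis, osteophytes, attrition, osteonecrosis; 25) and
    the MRI-observable flags (cysts, edema, osteophytes, attrition,
    osteonecrosis; 25). The remaining CT slot is the Ahlback grade and the
    remaining MRI slot the meniscal-pathology type (single ordinal). 3-D
    (18): volume, density mean and density SD of the 4 cartilage parts plus
    BMD mean and SD of the 3 bones.
    """
    feats: list[FeatureDef] = []
    for mod in ("CT", "MRI"):
        for p in PATHOLOGIES:
            if mod not in PATHOLOGY_MODALITIES[p]:
                continue
            for loc in PATHOLOGY_LOCATIONS[p]:
                feats.append(FeatureDef(flag_feature_name(mod, p, loc), mod, "bone"))
    feats.append(FeatureDef("CT ahlback", "CT", "other"))
    for site in SITES6:
        feats.append(FeatureDef(icrs_feature_name(site), "MRI", "cartilage"))
    feats.append(FeatureDef("MRI meniscal medial", "MRI", "cartilage"))
    feats.append(FeatureDef("MRI meniscal lateral", "MRI", "cartilage"))
    feats.append(FeatureDef("MRI meniscal type", "MRI", "other"))
    feats.append(FeatureDef("MRI synovitis_effusion", "MRI", "cartilage"))
    for site in THICKNESS_SITES:
        feats.append(FeatureDef(thickness_feature_name(site), "MRI", "cartilage"))
    for name in MORPHOMETRY_FEATURES:
        feats.append(FeatureDef(name, "3D", "other"))
    return FeatureSchema(feats)


@dataclass
class FeatureRow:
    """One knee's realized feature values in schema order."""

    subject_id: str
    group: str
    values: np.ndarray


@dataclass
class ValidationReport:
    errors: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_record(record: SubjectRecord) -> ValidationReport:
    """Range and completeness checks on a subject record."""
    errors: list[str] = []
    warnings: list[str] = []
    if record.group not in GROUPS:
        errors.append(f"invalid group {record.group!r}")
    if not record.age > 0:
        errors.append(f"invalid age {record.age}")
    for key, value in record.flags.flags.items():
        if value not in (0, 1):
            errors.append(f"flag {key} not binary: {value}")
    for site in SITES6:
        grade = record.grades.icrs.get(site)
        if grade is None:
            errors.append(f"missing ICRS grade at {site}")
        elif not 0 <= grade <= 4:
            errors.append(f"ICRS grade at {site} out of range 0-4: {grade}")
    if not 0 <= record.grades.ahlback <= 3:
        errors.append(f"Ahlback grade out of range 0-3: {record.grades.ahlback}")
    for site in THICKNESS_SITES:
        t = record.thickness.get(site)
        if t is None:
            errors.append(f"missing thickness at site {site}")
        elif not t > 0:
            errors.append(f"non-positive thickness at site {site}: {t}")
    for name in MORPHOMETRY_FEATURES:
        if name not in record.morphometry:
            errors.append(f"missing 3-D feature {name}")
    return ValidationReport(errors, warnings)


def _feature_value(record: SubjectRecord, feat: FeatureDef) -> float:
    name = feat.name
    if feat.source == "3D":
        return float(record.morphometry[name])
    if name == "CT ahlback":
        return float(record.grades.ahlback)
    if name == "MRI meniscal type":
        return float(record.grades.meniscal_type)
    if name == "MRI synovitis_effusion":
        return float(record.grades.synovitis_effusion)
    if name.startswith("MRI meniscal "):
        return float(record.grades.meniscal[name.rsplit(" ", 1)[1]])
    if name.startswith("MRI icrs "):
        comp, bone = name[len("MRI icrs ") :].split("/")
        return float(record.grades.icrs[(comp, bone)])
    if name.startswith("MRI act "):
        loc, point = name[len("MRI act ") :].split(" ")
        comp, bone = loc.split("/")
        return float(record.thickness[(comp, bone, point)])
    # remaining 2-D features are pathology flags: "<MOD> <location> <pathology>"
    mod, rest = name.split(" ", 1)
    loc, pathology = rest.rsplit(" ", 1)
    return float(record.flags.flags[(pathology, loc, mod)])


def assemble_features(record: SubjectRecord, schema: FeatureSchema) -> FeatureRow:
    """Realize a subject's ordered numeric feature row.

    Raises KeyError naming the feature if any value is missing.
    """
    values = np.empty(len(schema.features))
    for i, feat in enumerate(schema.features):
        try:
            values[i] = _feature_value(record, feat)
        except KeyError as exc:
            raise KeyError(f"missing value for feature {feat.name!r}") from exc
    return FeatureRow(record.subject_id, record.group, values)


def cohort_to_frame(records: list[SubjectRecord], schema: FeatureSchema | None = None):
    """Feature table: one row per subject, columns = metadata + schema order."""
    import pandas as pd

    schema = schema or build_default_schema()
    rows = []
    for rec in records:
        fr = assemble_features(rec, schema)
        row = {"subject_id": rec.subject_id, "group": rec.group, "sex": rec.sex,
               "age": rec.age}
        row.update(dict(zip(schema.names, fr.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def select_subset(rows, subset: str, schema: FeatureSchema | None = None):
    """Reduce a feature table to one of the named subsets (metadata kept)."""
    schema = schema or build_default_schema()
    names = schema.subset_names(subset)
    meta = [c for c in ("subject_id", "group", "sex", "age") if c in rows.columns]
    missing = [n for n in names if n not in rows.columns]
    if missing:
        raise ValueError(f"feature table lacks subset columns: {missing[:5]}...")
    return rows[meta + names]
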