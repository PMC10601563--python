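"""End-to-end orchestration: phantom -> registration/extraction, cohort ->
features -> statistics -> classification, with a reproducibility manifest.

Every stage writes plain CSV/JSON artifacts into the run directory;
re-running with the same configuration reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ModelSpec, crossval_classify, feature_importance
from .cohort import CohortConfig, generate_cohort
from .features import (
    FeatureSchema,
    PATHOLOGY_LOCATIONS,
    PATHOLOGY_MODALITIES,
    PathologyFlags,
    build_default_schema,
    cohort_to_frame,
    flag_feature_name,
    select_subset,
    validate_record,
)
from .features import BONES, cumulative_index
from .grids import Mask
from .maskops import extract_surface
from .morphometry import morphometry_table, part_morphometry
from .phantom import (
    BONE_PART_NAMES,
    CARTILAGE_PART_NAMES,
    PhantomConfig,
    PhantomSet,
    generate_phantom,
)
from .register import apply_transform, fit_rigid, validate_fusion
from .stats import PowerSpec, bonferroni_pairwise, cohens_d, linear_trend, one_way_anova, sample_size_for_power
from .thickness import measure_all_sites

DEFAULT_SUBSETS = ("Tot", "2D", "3D", "CT", "MRI", "Bone", "Cartilage")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    run_phantom: bool = True
    run_cohort: bool = True
    run_stats: bool = True
    run_classify: bool = True
    n_per_group: dict[str, int] | None = None
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    algorithms: tuple[str, ...] = ("RF", "GB")
    schema_path: str | None = None
    importance_subset: str = "Tot"

    def load_schema(self) -> FeatureSchema:
        if self.schema_path is None:
            return build_default_schema()
        path = Path(self.schema_path)
        if not path.exists():
            raise FileNotFoundError(f"schema file not found: {path}")
        return FeatureSchema.load(path)


def extract_phantom(phantom: PhantomSet, out_dir: Path | None = None) -> dict:
    """Registration + 3-D measurement stage on one phantom.

    Fits the rigid MRI->CT transform from the paired landmarks, resamples
    the MRI cartilage masks into the CT lattice, audits part overlap, and
    computes per-part morphometry plus the 17-site thickness protocol.
    """
    transform, rmsd = fit_rigid(phantom.landmarks_mri, phantom.landmarks_ct)
    fused: dict[str, Mask] = {
        name: phantom.truth_masks_ct[name] for name in BONE_PART_NAMES
    }
    bone_union = np.zeros(phantom.ct.shape, dtype=bool)
    for name in BONE_PART_NAMES:
        bone_union |= fused[name].selection
    for name in CARTILAGE_PART_NAMES + ("trochlear_cartilage",):
        resampled = apply_transform(transform, phantom.truth_masks_mri[name], phantom.ct)
        # nearest-neighbor resampling can push boundary cartilage voxels into
        # bone; clip them away (the automated analog of the manual adjustment
        # that follows the visual fusion inspection)
        resampled.selection &= ~bone_union
        fused[name] = resampled
    # the trochlear mask is an auxiliary subset of the femoral cartilage;
    # keep it out of the overlap audit and the morphometry
    report = validate_fusion(
        {k: v for k, v in fused.items() if k != "trochlear_cartilage"},
        tolerance_voxels=0,
    )
    parts = {k: v for k, v in fused.items() if k != "trochlear_cartilage"}
    meshes = {name: extract_surface(mask) for name, mask in parts.items()}
    morpho = part_morphometry(phantom.ct, parts, meshes)
    # thickness is a 2-D measurement taken on the MRI scan itself; only the
    # 3-D morphometry above relies on the fused (resampled) masks
    thickness = measure_all_sites(
        {name: mask.selection for name, mask in phantom.truth_masks_mri.items()},
        phantom.mri.spacing,
        phantom.mri.origin,
    )
    result = {
        "transform": transform,
        "registration_rmsd_mm": rmsd,
        "fusion": report,
        "morphometry": morpho,
        "thickness": thickness,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        morphometry_table(morpho).to_csv(out_dir / "morphometry.csv", index=False)
        rows = [
            {"compartment": c, "bone": b, "point": p, "thickness_mm": t}
            for (c, b, p), t in sorted(thickness.items())
        ]
        pd.DataFrame(rows).to_csv(out_dir / "thickness.csv", index=False)
        with open(out_dir / "registration.json", "w") as fh:
            json.dump(
                {
                    "matrix": transform.matrix().tolist(),
                    "rmsd_mm": rmsd,
                    "fusion_passed": report.passed,
                    "overlaps": {f"{a}|{b}": n for (a, b), n in report.overlaps.items()},
                },
                fh,
                indent=2,
            )
    return result


def flags_from_feature_row(row: pd.Series) -> PathologyFlags:
    """Rebuild pathology flags from the binary flag columns of a feature row."""
    flags = PathologyFlags.none()
    for pathology, locations in PATHOLOGY_LOCATIONS.items():
        for loc in locations:
            for mod in PATHOLOGY_MODALITIES[pathology]:
                flags.flags[(pathology, loc, mod)] = int(
                    round(float(row[flag_feature_name(mod, pathology, loc)]))
                )
    return flags


def add_cumulative_indices(frame: pd.DataFrame) -> pd.DataFrame:
    """Append CI_femur / CI_tibia / CI_patella columns to a feature table."""
    frame = frame.copy()
    ci = {bone: [] for bone in BONES}
    for _, row in frame.iterrows():
        flags = flags_from_feature_row(row)
        for bone in BONES:
            ci[bone].append(cumulative_index(flags, bone))
    for bone in BONES:
        frame[f"CI_{bone}"] = ci[bone]
    return frame


#: variables summarised by the statistics stage
def _stats_variables(frame: pd.DataFrame) -> list[str]:
    names = [c for c in frame.columns if c.startswith("CI_") or c.startswith("MRI icrs ")]
    names += [c for c in frame.columns if c.startswith("MRI act ")]
    return names


def run_group_stats(frame: pd.DataFrame, out_dir: Path | None = None) -> dict[str, pd.DataFrame]:
    """ANOVA + Bonferroni post-hoc + power analysis + age trends per variable."""
    frame = add_cumulative_indices(frame)
    variables = _stats_variables(frame)
    groups = {g: frame[frame["group"] == g] for g in ("D", "T", "C")}
    anova_rows, power_rows = [], []
    for var in variables:
        samples = {g: df[var].to_numpy(float) for g, df in groups.items() if len(df) >= 2}
        if len(samples) < 2:
            continue
        f_stat, p = one_way_anova(list(samples.values()))
        row = {"variable": var, "test": "ANOVA-Bonferroni correction",
               "F": f_stat, "p_value": p}
        pairwise = bonferroni_pairwise(samples)
        for (a, b), adj in pairwise.items():
            row[f"p_{a}v{b}"] = adj
        anova_rows.append(row)
        for (a, b), adj in pairwise.items():
            try:
                d = cohens_d(samples[a], samples[b])
            except ValueError:
                continue
            if d > 0:
                n_req = sample_size_for_power(PowerSpec(effect_size=d))
                power_rows.append({"variable": var, "pair": f"{a} vs {b}",
                                   "effect_size": d, "sample_size": n_req})
    trend_rows = []
    d_group = groups.get("D", pd.DataFrame())
    if len(d_group) >= 3 and d_group["age"].nunique() > 1:
        for var in variables:
            res = linear_trend(d_group["age"].to_numpy(float), d_group[var].to_numpy(float))
            trend_rows.append({"variable": var, "slope": res.slope,
                               "intercept": res.intercept, "r_squared": res.r_squared})
    out = {
        "anova": pd.DataFrame(anova_rows),
        "power": pd.DataFrame(power_rows),
        "trends": pd.DataFrame(trend_rows),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
    return out


def run_classification(
    frame: pd.DataFrame,
    schema: FeatureSchema,
    subsets=DEFAULT_SUBSETS,
    algorithms=("RF", "GB"),
    seed: int = 0,
    importance_subset: str = "Tot",
    k: int = 10,
    out_dir: Path | None = None,
) -> dict:
    """Cross-validated metrics per subset/algorithm plus feature importance."""
    y = frame["group"].to_numpy()
    metric_rows = []
    results = {}
    for subset in subsets:
        cols = schema.subset_names(subset)
        X = frame[cols].to_numpy(float)
        for algo in algorithms:
            spec = ModelSpec(algorithm=algo, seed=seed)
            counts, metrics, _ = crossval_classify(X, y, spec, k=k)
            results[(subset, algo)] = (counts, metrics)
            row = {"subset": subset, "algorithm": algo, "accuracy": metrics.accuracy}
            for cls in counts.classes:
                for m in ("recall", "precision", "f1"):
                    row[f"{m}_{cls}"] = metrics.per_class[cls][m]
            metric_rows.append(row)
    metrics_df = pd.DataFrame(metric_rows)
    cols = schema.subset_names(importance_subset)
    report = feature_importance(
        frame[cols].to_numpy(float), y,
        ModelSpec(algorithm="RF", seed=seed),
        feature_names=cols, schema=schema, k=k,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_df.to_csv(out_dir / "metrics.csv", index=False)
        pd.DataFrame(
            [{"feature": n, "importance_pct": v} for n, v in report.ranked()]
        ).to_csv(out_dir / "importance.csv", index=False)
        pd.DataFrame(
            [{"group": g, "importance_pct": v} for g, v in report.per_group.items()]
        ).to_csv(out_dir / "group_importance.csv", index=False)
    return {"metrics": metrics_df, "importance": report, "results": results}


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir`` and write a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = config.load_schema()  # fails fast if a schema path is missing
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "version": __version__}

    def _timed(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        return result

    if config.run_phantom:
        phantom = _timed(
            "phantom", lambda: generate_phantom(PhantomConfig(noise_seed=config.seed))
        )
        extraction = _timed("extract", lambda: extract_phantom(phantom, out_dir / "phantom"))
        manifest["registration_rmsd_mm"] = extraction["registration_rmsd_mm"]
        manifest["fusion_passed"] = extraction["fusion"].passed

    frame = None
    if config.run_cohort:
        cohort_cfg = CohortConfig(seed=config.seed)
        if config.n_per_group is not None:
            cohort_cfg.n_per_group = dict(config.n_per_group)
        records = _timed("cohort", lambda: generate_cohort(cohort_cfg))
        bad = [r.subject_id for r in records if not validate_record(r).ok]
        if bad:
            raise RuntimeError(f"pipeline stage 'cohort' produced invalid records: {bad}")
        frame = cohort_to_frame(records, schema)
        frame.to_csv(out_dir / "features.csv", index=False)
        manifest["n_subjects"] = len(frame)

    if config.run_stats:
        if frame is None:
            raise RuntimeError("pipeline stage 'stats' requires the cohort stage")
        _timed("stats", lambda: run_group_stats(frame, out_dir / "stats"))

    if config.run_classify:
        if frame is None:
            raise RuntimeError("pipeline stage 'classify' requires the cohort stage")
        clf = _timed(
            "classify",
            lambda: run_classification(
                frame, schema, config.subsets, config.algorithms,
                seed=config.seed, importance_subset=config.importance_subset,
                out_dir=out_dir / "classification",
            ),
        )
        manifest["best_accuracy"] = float(clf["metrics"]["accuracy"].max())

    cfg_dict = asdict(config)
    manifest["config"] = cfg_dict
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["timings_s"] = timings
    try:
        import sklearn

        manifest["lib_versions"] = {"numpy": np.__version__, "pandas": pd.__version__,
                                    "sklearn": sklearn.__version__}
    except Exception:
        pass
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir
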