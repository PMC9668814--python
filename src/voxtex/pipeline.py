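"""End-to-end orchestration: phantoms/volumes → texture maps → nested-CV
classification → LRP heatmaps → positive-relevance clustering → external
validation.

Two classification schemas are supported: schema "a" discriminates FEP from
HC, schema "b" FEP from CHR_NT; in both, the CHR_T group is scored as an
external validation set by every stored outer model.  Features are analyzed
one at a time and never concatenated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, glcm, lrp, prep
from .cluster import affinity_propagation, cluster_report, similarities
from .core import RelevanceMap, Volume, load_volume, save_volume
from .synthetic import CohortSpec, SubjectRecord, iter_cohort, load_cohort

__all__ = [
    "SCHEMAS",
    "EXTERNAL_GROUP",
    "RunConfig",
    "RunReport",
    "plan_feature_maps",
    "build_design_matrices",
    "run_pipeline",
    "validate_inputs",
]

SCHEMAS = {"a": ("FEP", "HC"), "b": ("FEP", "CHR_NT")}
EXTERNAL_GROUP = "CHR_T"


@dataclass
class RunConfig:
    cohort: CohortSpec | str | Path
    n_bins: int = 16
    cube_size: int = 7
    features: tuple[str, ...] = glcm.FEATURE_NAMES
    schema: str = "a"
    cv: classify.CVConfig = field(default_factory=classify.CVConfig)
    lrp_rule: lrp.LRPRule = field(default_factory=lrp.LRPRule)
    ap_damping: float = 0.9
    ap_max_iter: int = 1000
    ap_stable_iter: int = 100
    out_dir: str | Path | None = None
    explain_features: str = "best"  # "best" | "all" | "none"
    smooth_maps: bool = True

    def __post_init__(self) -> None:
        if self.schema not in SCHEMAS:
            raise ValueError(f"schema must be one of {sorted(SCHEMAS)}")
        for f in self.features:
            if f not in glcm.FEATURE_NAMES:
                raise ValueError(f"unknown feature {f!r}")


@dataclass
class RunReport:
    metrics: pd.DataFrame                 # one row per feature, percent units
    cv_results: dict                      # feature → CVResult
    external: dict                        # feature → external validation dict
    clusters: dict                        # feature → (means, membership table)
    relevance: dict                       # feature → {subject_id: RelevanceMap}
    manifest: dict


def plan_feature_maps(records: list[SubjectRecord], features=glcm.FEATURE_NAMES) -> list[str]:
    """Dry-run enumeration of the texture stage's outputs (no computation)."""
    return [f"{rec.subject_id}_{feat}" for rec in records for feat in features]


def _load_cohort_volumes(cohort) -> list[tuple[SubjectRecord, Volume]]:
    if isinstance(cohort, CohortSpec):
        return list(iter_cohort(cohort))
    records = load_cohort(cohort)
    return [
        (rec, load_volume(rec.volume_path, rec.subject_id, rec.group))
        for rec in records
    ]


def compute_feature_maps(
    volumes: list[tuple[SubjectRecord, Volume]],
    n_bins: int,
    cube_size: int,
    features,
    smooth: bool = True,
):
    """Equalize, quantize and run the texture stage for every subject.

    Returns (per-subject feature-map dicts, shared foreground mask).
    """
    maps = []
    shared_fg = None
    for rec, vol in volumes:
        eq, _ = prep.equalize(vol)
        qv = prep.quantize(eq, n_bins)
        fmaps = glcm.texture_maps(qv, features, cube_size=cube_size)
        fg = qv.foreground
        if smooth:
            fmaps = {
                name: glcm.smooth_map(fm, support=cube_size, foreground=fg)
                for name, fm in fmaps.items()
            }
        maps.append((rec, fmaps))
        shared_fg = fg if shared_fg is None else (shared_fg & fg)
    return maps, shared_fg


def build_design_matrices(maps, shared_fg, features):
    """Flatten each subject's maps over the shared foreground voxels.

    Returns (feature → (n_subjects, n_voxels) matrix, column coords,
    subject table).
    """
    coords = np.array(np.nonzero(shared_fg)).T
    flat = np.flatnonzero(shared_fg.ravel())
    X = {f: [] for f in features}
    rows = []
    for rec, fmaps in maps:
        rows.append({"subject_id": rec.subject_id, "group": rec.group})
        for f in features:
            X[f].append(fmaps[f].data.ravel()[flat])
    table = pd.DataFrame(rows)
    return {f: np.array(v) for f, v in X.items()}, coords, table


def _schema_labels(table: pd.DataFrame, schema: str):
    pos, neg = SCHEMAS[schema]
    sel = table["group"].isin([pos, neg]).to_numpy()
    y = np.where(table.loc[sel, "group"] == pos, 1, -1)
    ext = (table["group"] == EXTERNAL_GROUP).to_numpy()
    return sel, y, ext


def _subject_relevance(
    result: classify.CVResult,
    X: np.ndarray,
    y: np.ndarray,
    subject_ids,
    coords: np.ndarray,
    grid_shape,
    voxel_size: float,
    rule: lrp.LRPRule,
) -> dict[str, RelevanceMap]:
    """Average LRP heatmap per correctly classified subject, across the outer
    models that held that subject out and predicted it correctly."""
    correct = result.subject_correctness(y)
    out: dict[str, RelevanceMap] = {}
    for s in np.flatnonzero(correct):
        acc = np.zeros(grid_shape)
        n_models = 0
        for model, pred in result.holdout_models_for(s):
            if pred != y[s]:
                continue
            rel = lrp.lrp(model, X[s, model.selected_features], rule)
            rmap = lrp.relevance_to_map(
                rel, model.selected_features, coords, grid_shape,
                subject_id=subject_ids[s], voxel_size=voxel_size,
            )
            acc += rmap.data
            n_models += 1
        if n_models:
            out[subject_ids[s]] = RelevanceMap(
                data=acc / n_models,
                subject_id=subject_ids[s],
                model_id=f"mean-of-{n_models}",
                voxel_size=voxel_size,
            )
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    volumes = _load_cohort_volumes(config.cohort)
    if not volumes:
        raise ValueError("empty cohort")
    grid_shape = volumes[0][1].data.shape
    voxel_size = volumes[0][1].voxel_size

    maps, shared_fg = compute_feature_maps(
        volumes, config.n_bins, config.cube_size, config.features,
        smooth=config.smooth_maps,
    )
    X_all, coords, table = build_design_matrices(maps, shared_fg, config.features)
    sel, y, ext = _schema_labels(table, config.schema)
    if not sel.any():
        raise ValueError(f"no subjects for schema {config.schema!r}")
    subject_ids = table.loc[sel, "subject_id"].to_numpy()

    metric_rows = []
    cv_results, external, clusters, relevance = {}, {}, {}, {}
    for feat in config.features:
        X = X_all[feat][sel]
        result = classify.nested_cv(X, y, config.cv)
        cv_results[feat] = result
        metric_rows.append(
            {
                "feature": feat,
                "balanced_accuracy_pct": 100.0 * result.balanced_accuracy,
                "sensitivity_pct": 100.0 * result.sensitivity,
                "specificity_pct": 100.0 * result.specificity,
            }
        )
        if ext.any():
            external[feat] = classify.external_validate(result, X_all[feat][ext])

    metrics = pd.DataFrame(metric_rows)

    if config.explain_features != "none":
        if config.explain_features == "best":
            best = metrics.sort_values(
                "balanced_accuracy_pct", ascending=False, kind="stable"
            ).iloc[0]["feature"]
            to_explain = [best]
        else:
            to_explain = list(config.features)
        for feat in to_explain:
            rmaps = _subject_relevance(
                cv_results[feat], X_all[feat][sel], y, subject_ids,
                coords, grid_shape, voxel_size, config.lrp_rule,
            )
            relevance[feat] = rmaps
            if len(rmaps) >= 2:
                pr = [lrp.positive_relevance(m) for m in rmaps.values()]
                S = similarities(pr)
                assign = affinity_propagation(
                    S,
                    damping=config.ap_damping,
                    max_iter=config.ap_max_iter,
                    stable_iter=config.ap_stable_iter,
                )
                clusters[feat] = cluster_report(pr, assign)

    manifest = {
        "schema": config.schema,
        "n_bins": config.n_bins,
        "cube_size": config.cube_size,
        "features": list(config.features),
        "n_subjects": len(table),
        "n_classified": int(sel.sum()),
        "n_external": int(ext.sum()),
        "cv": {
            "outer_folds": config.cv.outer_folds,
            "inner_folds": config.cv.inner_folds,
            "outer_reps": config.cv.outer_reps,
            "inner_reps": config.cv.inner_reps,
            "k_features": config.cv.k_features,
            "seed": config.cv.seed,
        },
    }

    report = RunReport(
        metrics=metrics,
        cv_results=cv_results,
        external=external,
        clusters=clusters,
        relevance=relevance,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_report(report, config)
    return report


def _write_report(report: RunReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    payload = {
        "manifest": report.manifest,
        "metrics": report.metrics.to_dict(orient="records"),
        "cv": {f: r.to_jsonable() for f, r in report.cv_results.items()},
        "external": {
            f: {"n_positive": e["n_positive"], "n_negative": e["n_negative"]}
            for f, e in report.external.items()
        },
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    for feat, (means, table) in report.clusters.items():
        table.to_csv(out / f"clusters_{feat}.tsv", sep="\t", index=False)
        for label, mean_map in means.items():
            save_volume(
                RelevanceMap(data=mean_map, subject_id=f"cluster{label}"),
                out / f"cluster_mean_{feat}_{label}.nii.gz",
            )
    for feat, rmaps in report.relevance.items():
        for sid, rmap in rmaps.items():
            save_volume(rmap, out / f"{sid}_{feat}_PR.nii.gz")


def validate_inputs(directory: str | Path) -> dict:
    """Check a cohort directory: readable NIfTIs, one shared grid, table sanity."""
    directory = Path(directory)
    failures: list[str] = []
    try:
        records = load_cohort(directory)
    except (FileNotFoundError, ValueError) as exc:
        return {"failures": [str(exc)], "n_subjects": 0}

    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        failures.append("duplicate subject_id entries in table")
    allowed = {"FEP", "CHR_NT", "CHR_T", "HC"}
    for r in records:
        if r.group not in allowed:
            failures.append(f"{r.subject_id}: group {r.group!r} not in {sorted(allowed)}")

    shape = None
    for r in records:
        try:
            vol = load_volume(r.volume_path, r.subject_id, r.group)
        except Exception as exc:  # unreadable file is a report entry, not a crash
            failures.append(f"{r.subject_id}: unreadable volume ({exc})")
            continue
        if shape is None:
            shape = vol.data.shape
        elif vol.data.shape != shape:
            failures.append(
                f"{r.subject_id}: grid {vol.data.shape} != cohort grid {shape}"
            )
    return {"failures": failures, "n_subjects": len(records)}
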