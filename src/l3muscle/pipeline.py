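"""End-to-end evaluation pipeline over a cohort manifest.

Pulls the stages together: read each subject's CT slice, reference mask and
raw model mask; post-process the model mask (central-cluster selection, HU
threshold — fixed or swept); compute per-subject agreement metrics; and run
the cohort-level summaries (median/IQR, Bland–Altman, subgroup battery,
lowest-quartile error review).  All tabular outputs are written with a
deterministic CSV/JSON dialect so that identical inputs and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as l3io
from .metrics import (
    PairMetrics,
    SegmentationPair,
    bland_altman,
    evaluate_pair,
    summarize_cohort,
)
from .phantom import (
    CovariateConfig,
    ErrorProfile,
    GeometryConfig,
    generate_cohort,
    generate_phantom,
    simulate_model_mask,
)
from .postprocess import (
    ClusterParams,
    NoClusterFoundError,
    postprocess,
    sweep_threshold,
)
from .subgroups import (
    attribute_errors,
    classify_glim,
    error_class_prevalence_test,
    lowest_quartile_review,
    run_subgroup_battery,
)

__all__ = ["simulate_bundle", "run_pipeline", "COVARIATE_COLUMNS"]

COVARIATE_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "cancer_type",
    "cancer_grade",
    "cci",
    "arm_position",
    "iv_contrast",
)


def simulate_bundle(
    n: int,
    out_dir: str | Path,
    *,
    seed: int = 0,
    covariates: CovariateConfig | None = None,
    geometry: GeometryConfig | None = None,
    profile: ErrorProfile | None = None,
    fmt: str = "nifti",
) -> Path:
    """Simulate a cohort and write it as a file bundle with a manifest.

    One CT slice, reference mask, region-label map and raw model mask per
    subject, plus ``manifest.csv`` holding relative file paths and the
    covariates.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profile = profile or ErrorProfile()
    rng = np.random.default_rng(seed)
    subjects = generate_cohort(n, covariates, seed=int(rng.integers(0, 2**31)))
    rows = []
    for subject in subjects:
        p_seed = int(rng.integers(0, 2**31))
        phantom = generate_phantom(subject, geometry, seed=p_seed)
        model = simulate_model_mask(phantom, profile, seed=int(rng.integers(0, 2**31)))
        paths = l3io.export_phantom(phantom, out_dir, model_mask=model, fmt=fmt)
        row = {
            "subject_id": subject.subject_id,
            "ct_path": paths["ct"].name,
            "reference_path": paths["reference"].name,
            "model_path": paths["model"].name,
            "labels_path": paths["labels"].name,
        }
        row.update({c: getattr(subject, c) for c in COVARIATE_COLUMNS})
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    l3io.write_table(manifest, pd.DataFrame(rows))
    return manifest


@dataclass
class PipelineResult:
    """In-memory view of one pipeline run."""

    metrics: pd.DataFrame
    subgroups: pd.DataFrame | None
    sweep: pd.DataFrame | None
    threshold: int
    summary: dict
    exclusions: pd.DataFrame


def _load_subject(row: pd.Series, base: Path):
    ct = l3io.read_ct(base / row["ct_path"])
    ref = l3io.read_mask(base / row["reference_path"], ct.hu.shape)
    raw = l3io.read_mask(base / row["model_path"], ct.hu.shape)
    labels = None
    if "labels_path" in row and isinstance(row["labels_path"], str) and row["labels_path"]:
        labels = l3io.read_labels(base / row["labels_path"], ct.hu.shape)
    return ct, ref, raw, labels


def run_pipeline(
    manifest: str | Path | pd.DataFrame,
    config: l3io.RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Evaluate a cohort manifest and (optionally) write the output bundle.

    Subjects that fail to load or whose raw mask contains no cluster are
    recorded in the exclusions table with a reason code and skipped; a run
    in which every subject fails aborts.  When ``config.threshold`` is None
    the HU threshold is derived by the median-DSC sweep over the loaded
    cohort before metrics are computed.
    """
    cfg = config or l3io.RunConfig()
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        manifest_df = pd.read_csv(manifest)
    else:
        base = Path(".")
        manifest_df = manifest
    params = ClusterParams(epsilon=cfg.epsilon, min_samples=cfg.min_samples)

    loaded, exclusions = [], []
    for _, row in manifest_df.iterrows():
        try:
            loaded.append((row, *_load_subject(row, base)))
        except (ValueError, OSError) as exc:
            exclusions.append({"subject_id": row.get("subject_id", "?"), "reason": "load_error", "detail": str(exc)})
    if not loaded:
        raise RuntimeError("all subjects failed to load")

    sweep_df = None
    if cfg.threshold is None:
        sweep = sweep_threshold(
            [(ref, raw, ct) for _, ct, ref, raw, _ in loaded],
            params,
            (cfg.sweep_low, cfg.sweep_high),
        )
        threshold = sweep.optimal_threshold
        sweep_df = pd.DataFrame(sweep.as_rows(), columns=["threshold", "median_dsc"])
    else:
        threshold = int(cfg.threshold)

    rows, breakdowns = [], {}
    for row, ct, ref, raw, labels in loaded:
        try:
            pred = postprocess(raw, ct, params, threshold)
        except NoClusterFoundError:
            exclusions.append({"subject_id": row["subject_id"], "reason": "no_cluster", "detail": "empty model mask after clustering"})
            continue
        pair = SegmentationPair(reference=ref, prediction=pred, pixel_area=ct.pixel_area_cm2)
        m = evaluate_pair(pair)
        rec = {
            "subject_id": row["subject_id"],
            "tp": m.tp,
            "fp": m.fp,
            "fn": m.fn,
            "dsc": m.dsc,
            "sse_cm2": m.sse,
            "ref_area_cm2": m.ref_area,
            "pred_area_cm2": m.pred_area,
        }
        for c in COVARIATE_COLUMNS:
            if c in row:
                rec[c] = row[c]
        rows.append(rec)
        if labels is not None:
            breakdowns[row["subject_id"]] = attribute_errors(pair, labels)
    if not rows:
        raise RuntimeError("no subject survived post-processing")
    metrics_df = pd.DataFrame(rows)

    pm = [
        PairMetrics(r.tp, r.fp, r.fn, r.dsc, r.sse_cm2, r.ref_area_cm2, r.pred_area_cm2)
        for r in metrics_df.itertuples()
    ]
    summary: dict = {
        "config": cfg.to_dict(),
        "threshold_used": int(threshold),
        "n_subjects": int(len(metrics_df)),
        "n_excluded": int(len(exclusions)),
        "metrics": summarize_cohort(pm),
    }
    if len(metrics_df) >= 2:
        ba = bland_altman(
            metrics_df["ref_area_cm2"], metrics_df["pred_area_cm2"], orientation=cfg.ba_orientation
        )
        summary["bland_altman"] = {
            "mean_difference_cm2": ba.mean_difference,
            "loa_upper_cm2": ba.loa_upper,
            "loa_lower_cm2": ba.loa_lower,
            "n_outside": ba.n_outside,
        }

    subgroups_df = None
    has_covariates = all(c in metrics_df.columns for c in COVARIATE_COLUMNS)
    if has_covariates and len(metrics_df) >= 4:
        battery_in = metrics_df.rename(columns={"sse_cm2": "sse"})
        subgroups_df = run_subgroup_battery(battery_in, alpha=cfg.alpha, holm=cfg.holm)

    review_df = None
    if breakdowns and len(metrics_df) >= 4:
        review = lowest_quartile_review(
            metrics_df, breakdowns, involvement_threshold=cfg.involvement_threshold
        )
        review_df = review.subjects
        summary["lowest_quartile"] = {
            "n_reviewed": int(len(review.subjects)),
            "dsc_cutoff": review.dsc_cutoff,
            "class_counts": review.class_counts,
            "group_involvement_pct": review.group_involvement,
        }
        if has_covariates and len(review.subjects) > 0:
            uw = {
                r.subject_id: classify_glim(r.bmi, r.age).underweight
                for r in metrics_df.itertuples()
            }
            f_nonmuscle, f_boundary = error_class_prevalence_test(review, uw)
            summary["fisher"] = {
                "nonmuscle_anatomy": {"p": f_nonmuscle.p_value, "degenerate": f_nonmuscle.degenerate},
                "ill_defined_boundary": {"p": f_boundary.p_value, "degenerate": f_boundary.degenerate},
            }

    exclusions_df = pd.DataFrame(exclusions, columns=["subject_id", "reason", "detail"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        l3io.write_table(out / "metrics.csv", metrics_df)
        l3io.write_table(out / "exclusions.csv", exclusions_df)
        if sweep_df is not None:
            l3io.write_table(out / "sweep.csv", sweep_df)
        if subgroups_df is not None:
            l3io.write_table(out / "subgroups.csv", subgroups_df)
        if review_df is not None:
            l3io.write_table(out / "review.csv", review_df)
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        metrics=metrics_df,
        subgroups=subgroups_df,
        sweep=sweep_df,
        threshold=int(threshold),
        summary=summary,
        exclusions=exclusions_df,
    )
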