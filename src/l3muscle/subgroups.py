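"""Subject-characteristic analysis of segmentation performance.

Given per-subject agreement metrics joined to covariates, this module runs
the nonparametric battery used in body-composition validation studies:
Spearman rank correlation for continuous factors (age, BMI), Mann–Whitney U
for binary factors (sex, IV contrast, arm position, underweight status),
and Kruskal–Wallis for multi-level factors (cancer type, cancer grade,
Charlson Comorbidity Index) with pairwise Mann–Whitney follow-up between
cancer types.  Underweight status follows the GLIM age-dependent BMI
cut-offs.  Correlation strength is banded (|rho| < 0.40 weak, 0.40–0.69
moderate, >= 0.70 strong) and significance is declared at p < 0.05.

It also automates the error review usually done by eye: on labeled
phantoms, disagreement pixels are attributed to muscle groups, and each
subject is flagged for the two recurring error classes — inclusion of
non-muscle anatomy, and ill-defined muscle boundaries — whose prevalence
between underweight and non-underweight subjects is compared with Fisher's
exact test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .metrics import SegmentationPair, confusion_counts
from .phantom import Region, TRUNK_MUSCLE_LABELS

__all__ = [
    "GlimStatus",
    "ErrorBreakdown",
    "ReviewTable",
    "classify_glim",
    "run_subgroup_battery",
    "attribute_errors",
    "lowest_quartile_review",
    "error_class_prevalence_test",
    "correlation_strength",
]

ALPHA = 0.05
MIN_GROUP_N = 3  # rank tests need at least this many subjects per level

MUSCLE_GROUP_NAMES = {r: r.name.lower() for r in TRUNK_MUSCLE_LABELS}


@dataclass(frozen=True)
class GlimStatus:
    underweight: bool


def classify_glim(bmi: float, age: float) -> GlimStatus:
    """GLIM underweight classification from BMI and age.

    Underweight when BMI < 20 kg/m^2 below age 70, or BMI < 22 kg/m^2 at
    age 70 and above (age exactly 70 uses the elder, more inclusive
    cut-off).
    """
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if age < 70:
        return GlimStatus(underweight=bmi < 20.0)
    return GlimStatus(underweight=bmi < 22.0)


def correlation_strength(rho: float) -> str:
    """Band a Spearman coefficient: weak < 0.40 <= moderate < 0.70 <= strong."""
    a = abs(rho)
    if a >= 0.70:
        return "strong"
    if a >= 0.40:
        return "moderate"
    return "weak"


# ---------------------------------------------------------------------------
# Statistical battery
# ---------------------------------------------------------------------------

_BINARY_FACTORS = ("glim", "sex", "arm_position", "iv_contrast")
_MULTI_FACTORS = ("cancer_grade", "cci", "cancer_type")
_CONTINUOUS_FACTORS = ("age", "bmi")
BATTERY_FACTORS = _CONTINUOUS_FACTORS + _BINARY_FACTORS + _MULTI_FACTORS


def _row(factor, metric, test, stat, p, n, note="", strength=""):
    return {
        "factor": factor,
        "metric": metric,
        "test": test,
        "statistic": float(stat) if stat == stat else np.nan,
        "p_value": float(p) if p == p else np.nan,
        "significant": bool(p < ALPHA) if p == p else False,
        "strength": strength,
        "n": int(n),
        "note": note,
    }


def run_subgroup_battery(
    results: pd.DataFrame,
    *,
    metrics: tuple[str, ...] = ("dsc", "sse"),
    alpha: float = ALPHA,
    holm: bool = False,
) -> pd.DataFrame:
    """Run the full factor battery on a cohort results table.

    ``results`` must hold one row per subject with the covariate columns
    (age, sex, bmi, cancer_type, cancer_grade, cci, arm_position,
    iv_contrast) and the metric columns.  Missing covariates are dropped
    per factor (complete-case analysis) and the per-factor n is reported.
    Raw p-values are compared to ``alpha``; pass ``holm=True`` to add a
    Holm-adjusted significance column.
    """
    if len(results) == 0:
        raise ValueError("empty cohort")
    if results["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id in cohort results")
    df = results.copy()
    df["glim"] = [
        classify_glim(b, a).underweight if b == b and a == a else np.nan
        for b, a in zip(df["bmi"], df["age"])
    ]

    rows: list[dict] = []
    for metric in metrics:
        for factor in _CONTINUOUS_FACTORS:
            sub = df[[factor, metric]].dropna()
            if len(sub) < MIN_GROUP_N:
                rows.append(_row(factor, metric, "spearman", np.nan, np.nan, len(sub), "insufficient"))
                continue
            if np.ptp(sub[factor]) == 0 or np.ptp(sub[metric]) == 0:
                # a constant input carries no rank information
                rows.append(_row(factor, metric, "spearman", 0.0, 1.0, len(sub), "constant", "weak"))
                continue
            rho, p = stats.spearmanr(sub[factor], sub[metric])
            rows.append(_row(factor, metric, "spearman", rho, p, len(sub), strength=correlation_strength(rho)))

        for factor in _BINARY_FACTORS:
            sub = df[[factor, metric]].dropna()
            levels = sorted(sub[factor].unique(), key=str)
            groups = [sub.loc[sub[factor] == lv, metric].to_numpy() for lv in levels]
            if len(groups) != 2 or min(len(g) for g in groups) < MIN_GROUP_N:
                rows.append(_row(factor, metric, "mann_whitney", np.nan, np.nan, len(sub), "insufficient"))
                continue
            if np.ptp(np.concatenate(groups)) == 0:
                # identical values in every subject: no evidence of difference
                rows.append(_row(factor, metric, "mann_whitney", len(groups[0]) * len(groups[1]) / 2, 1.0, len(sub)))
                continue
            u, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
            rows.append(_row(factor, metric, "mann_whitney", u, p, len(sub)))

        for factor in _MULTI_FACTORS:
            sub = df[[factor, metric]].dropna()
            levels = sorted(sub[factor].unique(), key=str)
            groups = [sub.loc[sub[factor] == lv, metric].to_numpy() for lv in levels]
            if len(groups) < 2 or min(len(g) for g in groups) < MIN_GROUP_N:
                rows.append(_row(factor, metric, "kruskal_wallis", np.nan, np.nan, len(sub), "insufficient"))
            elif np.ptp(np.concatenate(groups)) == 0:
                rows.append(_row(factor, metric, "kruskal_wallis", 0.0, 1.0, len(sub)))
            else:
                h, p = stats.kruskal(*groups)
                rows.append(_row(factor, metric, "kruskal_wallis", h, p, len(sub)))
            if factor == "cancer_type":
                # pairwise follow-up regardless of the omnibus outcome
                for a, b in itertools.combinations(levels, 2):
                    ga = sub.loc[sub[factor] == a, metric].to_numpy()
                    gb = sub.loc[sub[factor] == b, metric].to_numpy()
                    name = f"cancer_type:{a}_vs_{b}"
                    if min(len(ga), len(gb)) < MIN_GROUP_N:
                        rows.append(_row(name, metric, "mann_whitney", np.nan, np.nan, len(ga) + len(gb), "insufficient"))
                    elif np.ptp(np.concatenate([ga, gb])) == 0:
                        rows.append(_row(name, metric, "mann_whitney", len(ga) * len(gb) / 2, 1.0, len(ga) + len(gb)))
                    else:
                        u, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                        rows.append(_row(name, metric, "mann_whitney", u, p, len(ga) + len(gb)))

    report = pd.DataFrame(rows)
    report["significant"] = (report["p_value"] < alpha).fillna(False)
    if holm:
        ok = report["p_value"].notna()
        adj = np.full(len(report), np.nan)
        if ok.any():
            rej, p_adj, _, _ = multipletests(report.loc[ok, "p_value"], alpha=alpha, method="holm")
            adj[np.flatnonzero(ok)] = p_adj
        report["p_holm"] = adj
        report["significant_holm"] = (report["p_holm"] < alpha).fillna(False)
    return report


# ---------------------------------------------------------------------------
# Automated error review
# ---------------------------------------------------------------------------


@dataclass
class ErrorBreakdown:
    """Attribution of disagreement pixels to muscle groups and error classes."""

    group_fractions: dict[str, float]
    unattributed_fraction: float
    nonmuscle_anatomy: bool
    ill_defined_boundary: bool
    total_error_pixels: int


def attribute_errors(
    pair: SegmentationPair,
    region_labels: np.ndarray,
    *,
    distance_cap: float = 15.0,
    boundary_margin: float = 2.0,
) -> ErrorBreakdown:
    """Attribute each error pixel to a muscle group and flag error classes.

    False-negative pixels carry their own region label.  False-positive
    pixels are charged to the muscle group of the nearest reference pixel,
    unless that is farther than ``distance_cap`` px (then unattributed).
    The non-muscle-anatomy flag fires when any false positive lies on organ
    tissue; the ill-defined-boundary flag fires when at least half of all
    error pixels sit within ``boundary_margin`` px of the reference
    boundary.
    """
    ref, pred = pair.reference, pair.prediction
    region_labels = np.asarray(region_labels)
    if region_labels.shape != ref.shape:
        raise ValueError("region label grid does not match mask shape")
    fp = ~ref & pred
    fn = ref & ~pred
    total = int(fp.sum() + fn.sum())
    fractions = {name: 0.0 for name in MUSCLE_GROUP_NAMES.values()}
    if total == 0:
        return ErrorBreakdown(fractions, 0.0, False, False, 0)

    counts = {name: 0 for name in MUSCLE_GROUP_NAMES.values()}
    unattributed = 0

    for region, name in MUSCLE_GROUP_NAMES.items():
        counts[name] += int(np.count_nonzero(fn & (region_labels == region)))

    # nearest reference pixel (and its label) for every off-reference pixel
    d_to_ref, (iy, ix) = ndimage.distance_transform_edt(~ref, return_indices=True)
    fp_pts = np.argwhere(fp)
    for y, x in fp_pts:
        if d_to_ref[y, x] > distance_cap:
            unattributed += 1
            continue
        label = Region(int(region_labels[iy[y, x], ix[y, x]]))
        name = MUSCLE_GROUP_NAMES.get(label)
        if name is None:
            unattributed += 1
        else:
            counts[name] += 1

    d_in = ndimage.distance_transform_edt(ref)
    near_boundary = int(np.count_nonzero(fp & (d_to_ref <= boundary_margin))) + int(
        np.count_nonzero(fn & (d_in <= boundary_margin))
    )

    fractions = {name: c / total for name, c in counts.items()}
    return ErrorBreakdown(
        group_fractions=fractions,
        unattributed_fraction=unattributed / total,
        nonmuscle_anatomy=bool(np.any(fp & (region_labels == Region.OTHER_ORGAN))),
        ill_defined_boundary=near_boundary >= total / 2.0,
        total_error_pixels=total,
    )


@dataclass
class ReviewTable:
    """Per-subject review of the lowest DSC quartile."""

    subjects: pd.DataFrame  # one row per reviewed subject, incl. error-class flags
    class_counts: dict[str, int]
    group_involvement: dict[str, float]  # % of reviewed subjects involving each group
    dsc_cutoff: float


def lowest_quartile_review(
    results: pd.DataFrame,
    breakdowns: dict[str, ErrorBreakdown],
    *,
    involvement_threshold: float = 0.05,
) -> ReviewTable:
    """Review subjects whose DSC falls strictly below the 25th percentile.

    Tabulates the two error-class flags and, for each muscle group, the
    percentage of reviewed subjects in which that group accounts for at
    least ``involvement_threshold`` of the error pixels.
    """
    if len(results) < 4:
        raise ValueError("quartile review needs a cohort of at least 4 subjects")
    cutoff = float(np.percentile(results["dsc"].to_numpy(dtype=float), 25))
    reviewed = results.loc[results["dsc"] < cutoff].copy()
    rows = []
    for _, r in reviewed.iterrows():
        bd = breakdowns[r["subject_id"]]
        row = {
            "subject_id": r["subject_id"],
            "dsc": r["dsc"],
            "nonmuscle_anatomy": bd.nonmuscle_anatomy,
            "ill_defined_boundary": bd.ill_defined_boundary,
        }
        row.update({f"frac_{k}": v for k, v in bd.group_fractions.items()})
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "dsc", "nonmuscle_anatomy", "ill_defined_boundary"]
        + [f"frac_{k}" for k in MUSCLE_GROUP_NAMES.values()],
    )
    n = len(table)
    counts = {
        "nonmuscle_anatomy": int(table["nonmuscle_anatomy"].sum()) if n else 0,
        "ill_defined_boundary": int(table["ill_defined_boundary"].sum()) if n else 0,
        "both": int((table["nonmuscle_anatomy"] & table["ill_defined_boundary"]).sum()) if n else 0,
    }
    involvement = {
        name: (100.0 * float((table[f"frac_{name}"] >= involvement_threshold).mean()) if n else 0.0)
        for name in MUSCLE_GROUP_NAMES.values()
    }
    return ReviewTable(subjects=table, class_counts=counts, group_involvement=involvement, dsc_cutoff=cutoff)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool
    table: tuple[tuple[int, int], tuple[int, int]]


def error_class_prevalence_test(
    review: ReviewTable | pd.DataFrame,
    underweight: dict[str, bool] | pd.Series,
) -> tuple[FisherResult, FisherResult]:
    """Fisher exact tests of error-class prevalence by underweight status.

    Builds, for each error class, the 2x2 table (underweight vs not) x
    (class present vs absent) over the reviewed subjects and returns the
    two-sided Fisher exact results, non-muscle anatomy first.  A table with
    a zero margin carries no information; it is reported as p = 1 with the
    ``degenerate`` flag set.
    """
    table = review.subjects if isinstance(review, ReviewTable) else review
    uw = pd.Series(underweight)
    out = []
    for col in ("nonmuscle_anatomy", "ill_defined_boundary"):
        flags = table.set_index("subject_id")[col].astype(bool)
        grp = uw.reindex(flags.index).astype(bool)
        a = int((flags & grp).sum())
        b = int((~flags & grp).sum())
        c = int((flags & ~grp).sum())
        d = int((~flags & ~grp).sum())
        t = ((a, b), (c, d))
        degenerate = min(a + b, c + d) == 0 or min(a + c, b + d) == 0
        if degenerate:
            out.append(FisherResult(p_value=1.0, odds_ratio=np.nan, degenerate=True, table=t))
        else:
            odds, p = stats.fisher_exact(t, alternative="two-sided")
            out.append(FisherResult(p_value=float(p), odds_ratio=float(odds), degenerate=False, table=t))
    return out[0], out[1]
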