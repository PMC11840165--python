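"""Tissue segmentation, ROI aggregation and group statistics.

The statistical battery mirrors the study design for a 15-MS / 10-control
NOE cohort:

* whole-brain and GM contrasts: Welch two-sample t-tests between groups,
  plus age/sex-adjusted multiple linear regression with group as the
  primary predictor;
* control WM vs normal-appearing WM (NAWM) vs WM lesion: the three pairwise
  t-tests with Bonferroni correction (family size 3, adjusted p = min(1, 3p));
* within the MS group: simple linear regressions of each contrast on
  clinical disease duration and on in-slab lesion volume (slope β₁, t, p, R²);
* percent change between group means, reported as
  100 · (comparison − reference) / reference.

Segmentation assigns GM/WM/CSF by T1 ranges; lesion masks are pipeline
inputs (manual segmentations in the emulated study) and override the T1
labels.  "Whole brain" is GM ∪ WM within the slab, excluding CSF; lesions
are included for MS subjects.  α = 0.05 throughout; the Welch (unequal
variance) form is the default two-sample test and a pooled-variance switch
is provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .phantom import LABEL_CODES, SubjectRecord

__all__ = [
    "TissueMask",
    "StatResult",
    "segment_from_t1",
    "roi_mean",
    "two_sample_ttest",
    "adjusted_group_regression",
    "pairwise_bonferroni",
    "covariate_regression",
    "percent_change",
    "subject_roi_table",
    "cohort_stats",
    "CONTRASTS",
]

logger = logging.getLogger("noemri")

ALPHA = 0.05
CONTRASTS = ("DS", "MT", "amide", "amine", "rNOE", "T1", "NOE_MTR")

#: default T1 boundaries (ms): WM below, GM between, CSF above
T1_THRESHOLDS = (1450.0, 2600.0)


@dataclass
class TissueMask:
    """Integer label volume using the shared label codes."""

    labels: np.ndarray

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABEL_CODES[tissue]

    @property
    def whole_brain(self) -> np.ndarray:
        """GM ∪ WM ∪ lesion (CSF and background excluded)."""
        return (
            self.mask("GM") | self.mask("WM") | self.mask("lesion")
        )


@dataclass
class StatResult:
    """One statistical comparison in tidy form."""

    contrast: str
    comparison: str
    estimate: float
    t_value: float
    p_value: float
    adjusted_p: float | None = None
    r_squared: float | None = None
    slope: float | None = None
    mean_a: float | None = None
    sd_a: float | None = None
    mean_b: float | None = None
    sd_b: float | None = None
    percent_change: float | None = None
    n_a: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-15:
            raise ValueError("adjusted p must be >= raw p")


# ---------------------------------------------------------------------------
# segmentation and ROI aggregation

def segment_from_t1(
    t1: np.ndarray,
    thresholds: tuple[float, float] = T1_THRESHOLDS,
    brain_mask: np.ndarray | None = None,
    lesion_mask: np.ndarray | None = None,
) -> TissueMask:
    """Label voxels by T1 range: WM < t_low < GM < t_high < CSF.

    ``brain_mask`` restricts labelling (default: T1 > 0); a provided lesion
    mask overrides the T1-derived labels.  Empty tissue classes raise a
    warning, not an error.
    """
    t1 = np.asarray(t1, dtype=float)
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds must be increasing")
    brain = (t1 > 0) & np.isfinite(t1) if brain_mask is None else np.asarray(brain_mask, bool)
    labels = np.zeros(t1.shape, dtype=np.int16)
    labels[brain & (t1 < t_low)] = LABEL_CODES["WM"]
    labels[brain & (t1 >= t_low) & (t1 < t_high)] = LABEL_CODES["GM"]
    labels[brain & (t1 >= t_high)] = LABEL_CODES["CSF"]
    if lesion_mask is not None:
        lesion_mask = np.asarray(lesion_mask, dtype=bool)
        if lesion_mask.shape != t1.shape:
            raise ValueError(
                f"lesion mask shape {lesion_mask.shape} does not match T1 {t1.shape}"
            )
        labels[lesion_mask] = LABEL_CODES["lesion"]
    for tissue in ("WM", "GM", "CSF"):
        if not np.any(labels == LABEL_CODES[tissue]):
            warnings.warn(f"segmentation produced an empty {tissue} class", stacklevel=2)
    return TissueMask(labels)


def roi_mean(
    value_map: np.ndarray, roi: np.ndarray, qc_mask: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Mean, SD and count of a map over an ROI (QC-passing voxels only).

    Returns ``(nan, nan, 0)`` for an empty ROI (logged).  SD is the
    population SD over the ROI voxels (ddof 0): the subject is the
    statistical unit downstream, the voxel SD is descriptive.
    """
    roi = np.asarray(roi, dtype=bool)
    if qc_mask is not None:
        roi = roi & np.asarray(qc_mask, dtype=bool)
    vals = np.asarray(value_map, dtype=float)[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        logger.info("roi_mean: empty ROI")
        return float("nan"), float("nan"), 0
    return float(vals.mean()), float(vals.std()), int(vals.size)


# ---------------------------------------------------------------------------
# statistics

def two_sample_ttest(
    group_a, group_b, contrast: str = "", comparison: str = "", equal_var: bool = False
) -> StatResult:
    """Two-sample t-test (Welch by default) between two groups of subjects.

    Degenerate case: zero variance in both groups with equal means is
    reported as t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t_val, p_val = 0.0, 1.0
    else:
        t_val, p_val = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(
        contrast=contrast,
        comparison=comparison,
        estimate=float(a.mean() - b.mean()),
        t_value=float(t_val),
        p_value=float(p_val),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        percent_change=percent_change(a.mean(), b.mean()) if a.mean() != 0 else None,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def _design_matrix(group, age, sex) -> np.ndarray:
    g = np.asarray([1.0 if x in ("MS", 1, True) else 0.0 for x in group])
    a = np.asarray(age, dtype=float)
    s = np.asarray([1.0 if x in ("F", 1, True) else 0.0 for x in sex])
    X = np.column_stack([g, a, s])
    return X


def adjusted_group_regression(
    values, group, age, sex, contrast: str = "", comparison: str = ""
) -> StatResult:
    """Age/sex-adjusted group effect: OLS of contrast on {group, age, sex}.

    The group indicator (MS = 1) is the primary predictor; its coefficient,
    t and p are reported.  A rank-deficient design raises with the names of
    the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    if y.size <= 4:
        raise ValueError("need n > 4 subjects for the adjusted model")
    X = _design_matrix(group, age, sex)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        names = ["intercept", "group", "age", "sex"]
        bad = [
            names[j]
            for j in range(Xc.shape[1])
            if np.linalg.matrix_rank(np.delete(Xc, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, Xc).fit()
    return StatResult(
        contrast=contrast,
        comparison=comparison or "MS vs control (age/sex adjusted)",
        estimate=float(fit.params[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        n_a=int(y.size),
    )


def pairwise_bonferroni(
    groups: dict[str, np.ndarray], contrast: str = "", equal_var: bool = False
) -> list[StatResult]:
    """All pairwise t-tests among the given groups, Bonferroni-corrected.

    With the canonical three tissues (control WM, NAWM, lesion) the family
    size is 3 and adjusted p = min(1, 3p).
    """
    names = list(groups)
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    m = len(pairs)
    results = []
    for i, j in pairs:
        res = two_sample_ttest(
            groups[names[i]],
            groups[names[j]],
            contrast=contrast,
            comparison=f"{names[i]} vs {names[j]}",
            equal_var=equal_var,
        )
        res.adjusted_p = min(1.0, m * res.p_value)
        results.append(res)
    return results


def covariate_regression(
    values, covariate, contrast: str = "", covariate_name: str = ""
) -> StatResult:
    """Simple linear regression of an MS-group contrast on one covariate.

    Reports slope β₁, its t and p, and R².  A zero-variance covariate is an
    error (undefined slope).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size < 3:
        raise ValueError("need n >= 3 for a covariate regression")
    if np.var(x) == 0:
        raise ValueError(f"covariate {covariate_name or 'x'} has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant outcome: no variance to explain
    p = float(fit.pvalues[1])
    return StatResult(
        contrast=contrast,
        comparison=f"vs {covariate_name}" if covariate_name else "covariate regression",
        estimate=float(fit.params[1]),
        slope=float(fit.params[1]),
        t_value=float(fit.tvalues[1]),
        p_value=1.0 if not np.isfinite(p) else p,
        r_squared=r2,
        n_a=int(y.size),
    )


def percent_change(reference: float, comparison: float) -> float:
    """100 · (comparison − reference) / reference; sign carries direction."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (comparison - reference) / reference


# ---------------------------------------------------------------------------
# cohort-level assembly

def subject_roi_table(
    subject: SubjectRecord,
    contrast_maps: dict[str, np.ndarray],
    tissue_mask: TissueMask,
    qc_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject ROI means: one row per (tissue, contrast).

    Tissues: whole_brain (GM ∪ WM, plus lesions for MS), GM, WM, lesion.
    """
    rois = {
        "whole_brain": tissue_mask.whole_brain
        if subject.group == "MS"
        else (tissue_mask.mask("GM") | tissue_mask.mask("WM")),
        "GM": tissue_mask.mask("GM"),
        "WM": tissue_mask.mask("WM"),
        "lesion": tissue_mask.mask("lesion"),
    }
    rows = []
    for tissue, roi in rois.items():
        for contrast, cmap in contrast_maps.items():
            mean, sd, n = roi_mean(cmap, roi, qc_mask=qc_mask)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "age": subject.age,
                    "sex": subject.sex,
                    "disease_duration": subject.disease_duration,
                    "lesion_volume": subject.lesion_volume,
                    "tissue": tissue,
                    "contrast": contrast,
                    "mean": mean,
                    "sd": sd,
                    "n_voxels": n,
                }
            )
    return pd.DataFrame(rows)


def _result_rows(results: list[StatResult], tissue: str, kind: str) -> list[dict]:
    rows = []
    for r in results:
        rows.append(
            {
                "kind": kind,
                "tissue": tissue,
                "contrast": r.contrast,
                "comparison": r.comparison,
                "estimate": r.estimate,
                "t_value": r.t_value,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "r_squared": r.r_squared,
                "slope": r.slope,
                "mean_a": r.mean_a,
                "sd_a": r.sd_a,
                "mean_b": r.mean_b,
                "sd_b": r.sd_b,
                "percent_change": r.percent_change,
                "n_a": r.n_a,
                "n_b": r.n_b,
            }
        )
    return rows


def cohort_stats(roi_table: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Run the full statistical battery on a cohort ROI table.

    ``roi_table`` is the concatenation of :func:`subject_roi_table` outputs.
    Returns a tidy results frame; comparisons that lack data (e.g. no
    lesions in a tiny phantom) are skipped.
    """
    rows: list[dict] = []

    def _vals(tissue, contrast, group=None):
        sel = (roi_table["tissue"] == tissue) & (roi_table["contrast"] == contrast)
        if group is not None:
            sel &= roi_table["group"] == group
        sub = roi_table[sel].dropna(subset=["mean"])
        return sub

    for tissue in ("whole_brain", "GM"):
        for contrast in CONTRASTS:
            ctrl = _vals(tissue, contrast, "control")
            ms = _vals(tissue, contrast, "MS")
            if len(ctrl) < 2 or len(ms) < 2:
                continue
            t_res = two_sample_ttest(
                ctrl["mean"], ms["mean"], contrast=contrast,
                comparison="control vs MS", equal_var=equal_var,
            )
            rows += _result_rows([t_res], tissue, "two_sample_t")
            both = pd.concat([ctrl, ms])
            if len(both) > 4:
                adj = adjusted_group_regression(
                    both["mean"], both["group"], both["age"], both["sex"],
                    contrast=contrast,
                )
                rows += _result_rows([adj], tissue, "adjusted_regression")

    # three-way WM comparison: control WM vs NAWM vs lesion
    for contrast in CONTRASTS:
        groups = {}
        ctrl_wm = _vals("WM", contrast, "control")
        nawm = _vals("WM", contrast, "MS")
        lesion = _vals("lesion", contrast, "MS")
        if len(ctrl_wm) >= 2:
            groups["control WM"] = ctrl_wm["mean"].to_numpy()
        if len(nawm) >= 2:
            groups["NAWM"] = nawm["mean"].to_numpy()
        if len(lesion) >= 2:
            groups["lesion"] = lesion["mean"].to_numpy()
        if len(groups) >= 2:
            res = pairwise_bonferroni(groups, contrast=contrast, equal_var=equal_var)
            rows += _result_rows(res, "WM", "pairwise_bonferroni")

    # MS-only covariate regressions per tissue
    for tissue in ("GM", "WM", "lesion"):
        for contrast in CONTRASTS:
            ms = _vals(tissue, contrast, "MS")
            for covariate in ("disease_duration", "lesion_volume"):
                if len(ms) < 3 or np.var(ms[covariate]) == 0:
                    continue
                res = covariate_regression(
                    ms["mean"], ms[covariate], contrast=contrast, covariate_name=covariate
                )
                rows += _result_rows([res], tissue, "covariate_regression")

    return pd.DataFrame(rows)
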