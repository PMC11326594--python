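"""Evaluation statistics: confusion diagnostics, ROC/AUC, group comparisons
and segmentation agreement.

The positive class is PCOS throughout.  Alongside the usual accuracy /
precision / recall / specificity / F1, the report includes the false
discovery rate FDR = FP/(FP+TP) and the false omission rate
FOR = FN/(FN+TN), which quantify how often a positive (resp. negative)
call is wrong — clinically more actionable than raw error rate.  Ratios
with a zero denominator are reported as ``None`` (absent), never as 0.

Group comparisons summarize a feature per cohort as mean +/- SD, a percent
difference |mean_PCOS - mean_normal| / mean_normal x 100 (the denominator
convention is recorded on the result), and a Welch two-sample t-test
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "GroupComparison",
    "AgreementReport",
    "confusion",
    "metrics",
    "roc_auc",
    "percent_difference",
    "group_feature_stats",
    "segmentation_agreement",
]

POSITIVE = "PCOS"
NEGATIVE = "normal"


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with PCOS as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FN/FP/TN over paired label sequences."""
    yt = np.asarray(y_true).astype(str)
    yp = np.asarray(y_pred).astype(str)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    known = {POSITIVE, NEGATIVE}
    if not (set(yt) | set(yp)) <= known:
        raise ValueError(f"unknown labels: {sorted((set(yt) | set(yp)) - known)}")
    return ConfusionMatrix(
        tp=int(((yt == POSITIVE) & (yp == POSITIVE)).sum()),
        fn=int(((yt == POSITIVE) & (yp == NEGATIVE)).sum()),
        fp=int(((yt == NEGATIVE) & (yp == POSITIVE)).sum()),
        tn=int(((yt == NEGATIVE) & (yp == NEGATIVE)).sum()),
    )


@dataclass
class MetricsReport:
    """Derived diagnostics, as fractions in [0, 1]; ``None`` = undefined."""

    accuracy: float
    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    fdr: float | None
    npv: float | None
    fom: float | None  # false omission rate
    auc: float | None = None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in self.__dict__.items()
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All confusion-matrix diagnostics; zero-denominator ratios are absent."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    specificity = _ratio(cm.tn, cm.tn + cm.fp)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and precision + recall > 0
        else None
    )
    return MetricsReport(
        accuracy=cm.accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        fdr=_ratio(cm.fp, cm.fp + cm.tp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        fom=_ratio(cm.fn, cm.fn + cm.tn),
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC with midrank tie handling, plus the ROC curve points.

    ``scores`` orient toward PCOS (higher = more PCOS-like).  Returns
    (auc, fpr, tpr).  Equivalent to the normalized Mann-Whitney U
    statistic: ties contribute 1/2.
    """
    y = np.asarray(labels).astype(str)
    s = np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("ROC needs both classes present")
    pos = s[y == POSITIVE]
    neg = s[y == NEGATIVE]
    # midrank AUC via the rank-sum form
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    fpr, tpr, _ = roc_curve(y == POSITIVE, s)
    return float(auc), fpr, tpr


def percent_difference(mean_pcos: float, mean_normal: float) -> float:
    """|mean_PCOS - mean_normal| / mean_normal x 100."""
    if mean_normal == 0:
        raise ZeroDivisionError(
            "normal-group mean is zero under the default convention; "
            "use the PCOS mean or a pooled mean as denominator instead"
        )
    return abs(mean_pcos - mean_normal) / abs(mean_normal) * 100.0


@dataclass
class FeatureComparison:
    feature: str
    mean_pcos: float
    sd_pcos: float
    mean_normal: float
    sd_normal: float
    percent_difference: float
    p_value: float


@dataclass
class GroupComparison:
    """Per-feature cohort summary with percent differences and p-values."""

    rows: list[FeatureComparison]
    convention: str = "abs(pcos-normal)/normal*100"

    def row(self, feature: str) -> FeatureComparison:
        for r in self.rows:
            if r.feature == feature:
                return r
        raise KeyError(feature)


def group_feature_stats(
    features_pcos: dict[str, np.ndarray] | "pandas.DataFrame",
    features_normal: dict[str, np.ndarray] | "pandas.DataFrame",
) -> GroupComparison:
    """Mean +/- SD per group, percent difference, Welch t-test p-value.

    Accepts mappings (or DataFrames) feature name -> per-image values;
    feature names are taken from the PCOS group.
    """
    rows = []
    for name in list(features_pcos):
        a = np.asarray(features_pcos[name], dtype=float)
        b = np.asarray(features_normal[name], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 samples per group for feature {name!r}")
        if np.allclose(a, b[: len(a)]) and np.allclose(a.var() + b.var(), 0):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):  # identical constant groups
                p = 1.0
        rows.append(
            FeatureComparison(
                feature=name,
                mean_pcos=float(a.mean()),
                sd_pcos=float(a.std(ddof=1)),
                mean_normal=float(b.mean()),
                sd_normal=float(b.std(ddof=1)),
                percent_difference=percent_difference(a.mean(), b.mean()),
                p_value=p,
            )
        )
    return GroupComparison(rows=rows)


@dataclass
class AgreementReport:
    """Boundary-distance and area-correlation agreement between mask sets."""

    mean_distance_mm: float
    sd_distance_mm: float
    r: float | None  # Pearson r of paired per-image foreground areas
    n_pairs: int
    n_skipped: int


def _boundary(mask: np.ndarray) -> np.ndarray:
    m = mask.astype(bool)
    return m & ~ndimage.binary_erosion(m)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Distance from each boundary pixel of src to the nearest of dst."""
    dt = ndimage.distance_transform_edt(~_boundary(dst))
    return dt[_boundary(src)]


def segmentation_agreement(
    ai_masks: list[np.ndarray],
    gt_masks: list[np.ndarray],
    pixel_spacing: float,
) -> AgreementReport:
    """Mean symmetric boundary distance (mm) and Pearson r of paired areas.

    Per image, every boundary pixel of one mask contributes its distance
    to the nearest boundary pixel of the other mask, in both directions.
    Images where either mask has an empty boundary are skipped (counted).
    """
    if len(ai_masks) != len(gt_masks):
        raise ValueError("mask lists must be paired")
    dists: list[np.ndarray] = []
    areas_ai, areas_gt = [], []
    skipped = 0
    for ai, gt in zip(ai_masks, gt_masks):
        if ai.shape != gt.shape:
            raise ValueError("paired masks must share a shape")
        if not _boundary(ai).any() or not _boundary(gt).any():
            skipped += 1
            continue
        d = np.concatenate([_directed_distances(ai, gt), _directed_distances(gt, ai)])
        dists.append(d * pixel_spacing)
        areas_ai.append(ai.sum())
        areas_gt.append(gt.sum())
    if not dists:
        raise ValueError("no image pair had non-empty boundaries on both sides")
    all_d = np.concatenate(dists)
    if len(areas_ai) >= 2 and np.std(areas_ai) > 0 and np.std(areas_gt) > 0:
        r = float(np.corrcoef(areas_ai, areas_gt)[0, 1])
    else:
        r = None
    return AgreementReport(
        mean_distance_mm=float(all_d.mean()),
        sd_distance_mm=float(all_d.std()),
        r=r,
        n_pairs=len(dists),
        n_skipped=skipped,
    )
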