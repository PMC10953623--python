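"""Classification and segmentation-agreement metrics.

Covers confusion-matrix arithmetic (sensitivity, specificity, accuracy,
positive/negative likelihood ratios, miss rates), Dice overlap and
volumetric correlation between segmentations, Welch two-sample group
comparisons with Bonferroni correction, and the stratified
misclassification report contrasting correctly and incorrectly
classified subjects feature by feature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import GeometryError, LabelVolume, SchemaError


@dataclass
class ConfusionMatrix:
    """TP/FN/FP/TN counts; the positive class is 'compatible with bvFTD'."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(true_labels, predicted_labels, positive=1) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from paired label sequences (order-invariant)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise SchemaError("true and predicted labels must be equal-length 1D")
    tpos = t == positive
    ppos = p == positive
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: float          # sensitivity / (1 - specificity); inf when fp = 0
    lr_neg: float          # (1 - sensitivity) / specificity
    fn_rate: float
    fp_rate: float
    lr_pos_infinite: bool = False

    def formatted(self) -> str:
        """Human-readable report: percentages to the nearest integer,
        likelihood ratios to 2 decimals."""
        lrp = "inf" if self.lr_pos_infinite else f"{self.lr_pos:.2f}"
        return (
            f"sensitivity: {round(self.sensitivity * 100):d}%\n"
            f"specificity: {round(self.specificity * 100):d}%\n"
            f"accuracy:    {round(self.accuracy * 100):d}%\n"
            f"LR+:         {lrp}\n"
            f"LR-:         {self.lr_neg:.2f}\n"
            f"FN rate:     {round(self.fn_rate * 100):d}%\n"
            f"FP rate:     {round(self.fp_rate * 100):d}%\n"
        )


class UndefinedMetricError(ValueError):
    pass


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard binary diagnostic metrics from a confusion matrix."""
    if cm.n_positive == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if cm.n_negative == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    sens = cm.tp / cm.n_positive
    spec = cm.tn / cm.n_negative
    acc = (cm.tp + cm.tn) / cm.total
    if cm.fp == 0:
        lr_pos, lr_pos_inf = math.inf, True
    else:
        lr_pos, lr_pos_inf = sens / (1.0 - spec), False
    if spec == 0:
        raise UndefinedMetricError("lr_neg undefined: specificity is zero")
    lr_neg = (1.0 - sens) / spec
    return MetricsReport(
        sensitivity=sens, specificity=spec, accuracy=acc,
        lr_pos=lr_pos, lr_neg=lr_neg,
        fn_rate=1.0 - sens, fp_rate=1.0 - spec,
        lr_pos_infinite=lr_pos_inf,
    )


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity index 2|A∩B|/(|A|+|B|).

    Two empty masks are defined to agree perfectly (1.0), the
    agreement-on-absence convention.
    """
    if not a.same_grid(b):
        raise GeometryError("masks are not on the same grid")
    if not (a.is_binary and b.is_binary):
        raise ValueError("dice needs binary masks")
    am = a.data == 1
    bm = b.data == 1
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


def volume_correlation(vols_a, vols_b) -> float:
    """Pearson correlation between two paired volume lists."""
    a = np.asarray(vols_a, dtype=float)
    b = np.asarray(vols_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length 1D lists with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedMetricError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)


def group_compare(group_a, group_b, n_comparisons: int = 1,
                  pooled: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test with Bonferroni adjustment.

    Welch's unequal-variance form by default (``pooled=True`` for the
    classical pooled-variance Student test).  Returns (t, p_raw,
    p_bonferroni) with p_bonferroni = min(1, n_comparisons * p_raw).
    Degenerate case (both groups constant and equal) returns t = 0,
    p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if np.std(a) == 0 and np.std(b) == 0:
        if a.mean() == b.mean():
            warnings.warn("degenerate comparison: both groups constant "
                          "and equal; returning p = 1")
            return 0.0, 1.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, equal_var=pooled)
    t = float(res.statistic)
    p = float(res.pvalue)
    return t, p, min(1.0, n_comparisons * p)


def misclassification_report(features: pd.DataFrame, true_labels,
                             predictions, positive=1,
                             feature_columns=None) -> pd.DataFrame:
    """Feature-wise contrasts between correctly and incorrectly
    classified subjects.

    Two strata: TP vs FN (within true positives) and FP vs TN (within
    true negatives).  Each row gives group means ± sd and a Welch t-test
    Bonferroni-adjusted over the number of features compared.  Strata
    with fewer than 2 subjects in either cell are skipped with a warning.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predictions)
    if not (len(features) == t.size == p.size):
        raise SchemaError("features, labels and predictions disagree in length")
    if feature_columns is None:
        feature_columns = [c for c in features.columns
                           if pd.api.types.is_numeric_dtype(features[c])]
    n_comp = len(feature_columns)
    strata = {
        "TP_vs_FN": ((t == positive) & (p == positive),
                     (t == positive) & (p != positive)),
        "FP_vs_TN": ((t != positive) & (p == positive),
                     (t != positive) & (p != positive)),
    }
    rows = []
    for name, (mask_a, mask_b) in strata.items():
        ga_name, gb_name = name.split("_vs_")
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            warnings.warn(f"stratum {name} skipped: fewer than 2 subjects "
                          f"in a cell ({int(mask_a.sum())} {ga_name}, "
                          f"{int(mask_b.sum())} {gb_name})")
            continue
        for col in feature_columns:
            va = features.loc[mask_a, col].to_numpy(dtype=float)
            vb = features.loc[mask_b, col].to_numpy(dtype=float)
            va = va[np.isfinite(va)]
            vb = vb[np.isfinite(vb)]
            if va.size < 2 or vb.size < 2:
                continue
            tt, praw, pbonf = group_compare(va, vb, n_comparisons=n_comp)
            rows.append({
                "stratum": name, "feature": col,
                "group_a": ga_name, "n_a": va.size,
                "mean_a": va.mean(), "sd_a": va.std(ddof=1),
                "group_b": gb_name, "n_b": vb.size,
                "mean_b": vb.mean(), "sd_b": vb.std(ddof=1),
                "t": tt, "p_raw": praw, "p_bonferroni": pbonf,
            })
    return pd.DataFrame(rows)
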