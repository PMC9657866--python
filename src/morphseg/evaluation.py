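"""Segmentation quality metrics and the statistical test protocol.

Pixel-level precision/recall against a ground-truth foreground mask, plus
the two-sample testing procedure used to check edge quality: Levene's test
for equal variances gates the choice between the pooled-variance Student
t-test and Welch's unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .colorspace import ColorImage
from .errors import EmptySampleError, ShapeMismatchError
from .markers import histogram, otsu_threshold
from .morphology import connectivity_se

__all__ = [
    "SegmentationMetrics",
    "TTestResult",
    "confusion_counts",
    "levene_test",
    "two_sample_ttest",
    "one_sample_ttest",
    "edge_rgb_ttest",
    "classify_foreground",
]


@dataclass(frozen=True)
class SegmentationMetrics:
    """Pixel confusion counts and the derived precision/recall fractions.

    When a ratio is undefined (zero denominator) it is reported as 0.0 and
    the corresponding ``*_defined`` flag is False, so batch tables stay
    rectangular instead of raising.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    precision_defined: bool = True
    recall_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "precision_defined": self.precision_defined,
            "recall_defined": self.recall_defined,
        }


@dataclass(frozen=True)
class TTestResult:
    """A t-test outcome plus the variance-homogeneity gate that chose it."""

    t: float
    df: float
    p: float
    levene_p: float | None = None
    equal_variance_assumed: bool | None = None


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> SegmentationMetrics:
    """Pixel confusion between predicted and true foreground masks.

    precision = TP / (TP + FP); recall = TP / (TP + FN).
    """
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"prediction shape {p.shape} != truth shape {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    prec_def = (tp + fp) > 0
    rec_def = (tp + fn) > 0
    return SegmentationMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=tp / (tp + fp) if prec_def else 0.0,
        recall=tp / (tp + fn) if rec_def else 0.0,
        precision_defined=prec_def,
        recall_defined=rec_def,
    )


def _sample(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64).ravel()
    if a.size == 0:
        raise EmptySampleError("statistical test received an empty sample")
    return a


def levene_test(x, y) -> float:
    """Levene's test (absolute deviations from the group means) for equal
    variances of two samples; returns the p-value."""
    a, b = _sample(x), _sample(y)
    if a.size < 2 or b.size < 2:
        raise EmptySampleError("Levene's test needs at least two values per group")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        return 1.0  # both groups constant: no evidence against equal spread
    return float(stats.levene(a, b, center="mean").pvalue)


def two_sample_ttest(x, y, alpha_gate: float = 0.05) -> TTestResult:
    """Two-sided two-sample t-test with a Levene variance gate.

    If Levene's p < ``alpha_gate`` the variances are treated as unequal and
    Welch's t-test (Welch-Satterthwaite degrees of freedom) is used;
    otherwise the pooled-variance Student t-test.
    """
    a, b = _sample(x), _sample(y)
    if a.size < 2 or b.size < 2:
        raise EmptySampleError("t-test needs at least two values per group")
    lp = levene_test(a, b)
    equal_var = lp >= alpha_gate
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate constant samples: define t = 0, p = 1 when means agree
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0, lp, equal_var)
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        levene_p=lp,
        equal_variance_assumed=equal_var,
    )


def one_sample_ttest(x, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test of mean(x) against ``mu0``;
    t = (mean - mu0) / (s / sqrt(n)), df = n - 1."""
    a = _sample(x)
    if a.size < 2:
        raise EmptySampleError("one-sample t-test needs n >= 2")
    if a.var(ddof=1) == 0.0 and a.mean() == mu0:
        return TTestResult(0.0, float(a.size - 1), 1.0)
    res = stats.ttest_1samp(a, mu0)
    return TTestResult(t=float(res.statistic), df=float(a.size - 1), p=float(res.pvalue))


def edge_rgb_ttest(
    img: ColorImage, labels: np.ndarray, groups: np.ndarray, alpha_gate: float = 0.05
) -> TTestResult:
    """Compare mean RGB intensity along watershed lines between two groups.

    ``groups`` is a boolean mask splitting the image into two populations;
    each watershed-line pixel (label 0) contributes the mean of its three
    channel values to the sample of its group.
    """
    img.require("rgb")
    lab = np.asarray(labels)
    grp = np.asarray(groups, dtype=bool)
    if lab.shape != img.shape or grp.shape != img.shape:
        raise ShapeMismatchError("labels/groups shape differs from image shape")
    line = lab == 0
    if not line.any():
        raise EmptySampleError("label image has no watershed-line pixels")
    values = np.asarray(img.data, dtype=np.float64).mean(axis=-1)
    x = values[line & grp]
    y = values[line & ~grp]
    if x.size < 2 or y.size < 2:
        raise EmptySampleError("each group needs at least two line pixels")
    return two_sample_ttest(x, y, alpha_gate)


def classify_foreground(
    labels: np.ndarray,
    gray: np.ndarray,
    include_lines: bool = True,
    connectivity: int = 8,
) -> np.ndarray:
    """Binarize a label image into foreground by basin intensity.

    Each basin is called foreground when its mean gray level exceeds the
    Otsu threshold of the image histogram (bright objects on a darker
    background).  With ``include_lines`` a watershed-line pixel bounding a
    foreground basin joins the foreground when its own gray level is above
    the threshold; a 1-px contour line straddling the true edge is thereby
    split between object and background at sub-pixel fidelity instead of
    being attributed wholesale to either side.
    """
    lab = np.asarray(labels)
    g = np.asarray(gray, dtype=np.float64)
    if lab.shape != g.shape:
        raise ShapeMismatchError("labels shape differs from gray-image shape")
    n = int(lab.max())
    if n == 0:
        return np.zeros(lab.shape, dtype=bool)
    g8 = np.clip(np.floor(g + 0.5), 0, 255).astype(np.int64)
    thr = otsu_threshold(histogram(g8)).threshold
    means = ndimage.mean(g, labels=lab, index=np.arange(1, n + 1))
    is_fg = np.concatenate([[False], means > thr])  # index by label
    fg = is_fg[lab]
    if include_lines:
        structure = connectivity_se(connectivity).footprint
        halo = ndimage.binary_dilation(fg, structure=structure)
        fg = fg | (halo & (lab == 0) & (g > thr))
    return fg
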