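"""FULL-mode analytics: per-compound loss, region statistics, ROC/KDE curves.

Given a projected table carrying ground truth y in {0,1} and a predicted
probability of activity p in [0,1], the central per-compound quantity is the
binary cross-entropy

    Loss = -[y log(p) + (1 - y) log(1 - p)]

using the natural logarithm, with p clamped to [eps, 1-eps] so that a
confidently wrong prediction gets a large but finite loss.  High loss marks a
compound the model is confidently wrong about; painted on the 2D map, pockets
of high loss delimit regions outside the model's applicability domain.

Any rectangular or polygonal region of the map can then be summarized with the
standard binary-classification statistics (sensitivity, specificity, accuracy,
balanced accuracy, F1, Matthews correlation coefficient, AUC-ROC), the ROC
curve, per-class kernel-density curves of the predicted probabilities, and the
confusion matrix.  Degenerate selections (empty, single-class) yield explicit
undefined markers rather than NaNs or exceptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

PROB_CLAMP_EPS = 1e-7
DEFAULT_THRESHOLD = 0.5
KDE_GRID_SIZE = 512
_DEGENERATE_BANDWIDTH = 0.05  # kernel width for classes with <2 distinct values


@dataclass
class ValidationRecord:
    canonical_smiles: str
    x: float
    y_coord: float
    y: int
    p: float
    loss: float


@dataclass
class RegionSelection:
    """A picked map region: axis-aligned rectangle or simple polygon (boundary inclusive)."""

    shape: str  # "rectangle" | "polygon"
    bounds: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    vertices: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.shape == "rectangle":
            if self.bounds is None:
                raise ValueError("rectangle region needs bounds (xmin, xmax, ymin, ymax)")
        elif self.shape == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon region needs >= 3 vertices")
        else:
            raise ValueError(f"unknown region shape {self.shape!r}")

    @classmethod
    def rectangle(cls, xmin: float, xmax: float, ymin: float, ymax: float) -> "RegionSelection":
        return cls(shape="rectangle", bounds=(xmin, xmax, ymin, ymax))

    @classmethod
    def polygon(cls, vertices: Sequence[tuple[float, float]]) -> "RegionSelection":
        return cls(shape="polygon", vertices=[tuple(v) for v in vertices])

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSelection":
        if "bounds" in d or d.get("shape") == "rectangle":
            return cls.rectangle(*d["bounds"])
        return cls.polygon(d["vertices"])


@dataclass
class MetricsReport:
    """Confusion counts plus the seven region statistics; None marks undefined."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    f1: float | None
    mcc: float | None
    auc_roc: float | None
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "flags": list(self.flags),
        }


def binary_cross_entropy(y: int, p: float, eps: float = PROB_CLAMP_EPS) -> float:
    """Per-compound loss -[y ln p + (1-y) ln(1-p)] with p clamped to [eps, 1-eps].

    Zero for a perfectly confident correct prediction; the higher the value,
    the more confident the model is in a wrong prediction.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if y not in (0, 1):
        raise ValueError(f"ground truth {y} not in {{0, 1}}")
    pc = min(max(p, eps), 1.0 - eps)
    return -(y * math.log(pc) + (1 - y) * math.log(1.0 - pc))


def loss_vector(y: np.ndarray, p: np.ndarray, eps: float = PROB_CLAMP_EPS) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def select_region(xy: np.ndarray, region: RegionSelection) -> np.ndarray:
    """Indices of the points falling inside a region, boundary inclusive."""
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    if region.shape == "rectangle":
        xmin, xmax, ymin, ymax = region.bounds
        mask = (
            (xy[:, 0] >= xmin) & (xy[:, 0] <= xmax)
            & (xy[:, 1] >= ymin) & (xy[:, 1] <= ymax)
        )
    else:
        poly = prep(Polygon(region.vertices))
        mask = np.fromiter(
            (poly.covers(Point(px, py)) for px, py in xy), dtype=bool, count=len(xy)
        )
    return np.flatnonzero(mask)


def confusion_counts(
    y: np.ndarray, p: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at a decision threshold; p == threshold counts positive."""
    y = np.asarray(y)
    p = np.asarray(p)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    pred = p >= threshold
    pos = y == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def classification_metrics(
    counts: tuple[int, int, int, int], auc: float | None = None, auc_flag: str | None = None
) -> MetricsReport:
    """The seven statistics from a confusion table.

    Zero-denominator rates become None with an explanatory flag; MCC with a
    zero denominator is reported as 0.0 by convention, also flagged.
    """
    tp, fp, tn, fn = (int(c) for c in counts)
    n = tp + fp + tn + fn
    flags: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            flags.append(f"{name}_undefined")
            return None
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = ratio(tp + tn, n, "accuracy")
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None else None
    if bal is None and "balanced_accuracy_undefined" not in flags:
        flags.append("balanced_accuracy_undefined")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den == 0.0:
        mcc = 0.0
        flags.append("mcc_zero_denominator")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    if auc is None and auc_flag:
        flags.append(auc_flag)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc,
        balanced_accuracy=bal, f1=f1, mcc=mcc, auc_roc=auc, flags=flags,
    )


def roc_auc(y: np.ndarray, p: np.ndarray) -> tuple[pd.DataFrame, float | None]:
    """ROC curve by descending threshold sweep and its trapezoidal AUC.

    Equals the tie-corrected pairwise probability P(p_pos > p_neg) + P(tie)/2.
    A single-class label vector yields an empty curve and AUC None.
    """
    y = np.asarray(y, dtype=np.int64)
    p = np.asarray(p, dtype=np.float64)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return pd.DataFrame(columns=["threshold", "fpr", "tpr"]), None
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    # index of the last occurrence of each unique score
    last = np.flatnonzero(np.diff(ps) != 0)
    last = np.concatenate([last, [len(ps) - 1]])
    tps = np.cumsum(ys == 1)[last]
    fps = np.cumsum(ys == 0)[last]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], ps[last]])
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, auc


def kde_curves(
    p: np.ndarray, y: np.ndarray, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-class Gaussian kernel-density curves of the predicted probabilities.

    Bandwidth by Scott's rule; a class with fewer than two distinct values
    falls back to a fixed-width single kernel per point.  Curves are reported
    on ``grid`` (default: 512 points on [0, 1]); a class absent from the data
    yields a NaN column.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, KDE_GRID_SIZE)
    grid = np.asarray(grid, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    out = {"grid": grid}
    for cls in (0, 1):
        vals = p[y == cls]
        if vals.size == 0:
            out[f"density_class{cls}"] = np.full_like(grid, np.nan)
            continue
        if vals.size < 2 or np.ptp(vals) == 0.0:
            h = _DEGENERATE_BANDWIDTH
            dens = np.exp(
                -0.5 * ((grid[:, None] - vals[None, :]) / h) ** 2
            ).sum(axis=1) / (vals.size * h * math.sqrt(2 * math.pi))
        else:
            dens = gaussian_kde(vals, bw_method="scott")(grid)
        out[f"density_class{cls}"] = dens
    return pd.DataFrame(out)


def clip_color_range(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linear rescale of values onto [0, 1], clamped at both ends of [lo, hi]."""
    if not lo < hi:
        raise ValueError(f"invalid color range: lo={lo} must be < hi={hi}")
    v = np.asarray(values, dtype=np.float64)
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class RegionReport:
    indices: np.ndarray
    metrics: MetricsReport
    roc_curve: pd.DataFrame
    kde: pd.DataFrame | None
    mean_loss: float | None

    def to_dict(self) -> dict:
        d = self.metrics.to_dict()
        d["mean_loss"] = self.mean_loss
        return d


def region_report(
    xy: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    region: RegionSelection | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> RegionReport:
    """Full statistics for the compounds inside a map region.

    ``region=None`` (or any region covering every point) reproduces the global
    report exactly.  An empty selection returns an n=0 report with undefined
    markers, never an exception.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    p = np.asarray(p, dtype=np.float64)
    idx = np.arange(len(y)) if region is None else select_region(xy, region)
    ys, ps = y[idx], p[idx]
    if idx.size == 0:
        metrics = classification_metrics((0, 0, 0, 0), auc=None, auc_flag="auc_undefined")
        metrics.flags.append("empty_region")
        return RegionReport(
            indices=idx,
            metrics=metrics,
            roc_curve=pd.DataFrame(columns=["threshold", "fpr", "tpr"]),
            kde=None,
            mean_loss=None,
        )
    counts = confusion_counts(ys, ps, threshold=threshold)
    curve, auc = roc_auc(ys, ps)
    metrics = classification_metrics(
        counts, auc=auc, auc_flag=None if auc is not None else "auc_undefined_single_class"
    )
    return RegionReport(
        indices=idx,
        metrics=metrics,
        roc_curve=curve,
        kde=kde_curves(ps, ys),
        mean_loss=float(np.mean(loss_vector(ys, ps))),
    )
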