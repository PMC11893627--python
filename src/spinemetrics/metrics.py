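"""Evaluation statistics: Dice/F1, landmark MAD, ICC, success rates.

The reliability statistic is the intraclass correlation coefficient of
the two-way model with single measurement and absolute agreement
(McGraw & Wong's ICC(A,1), the "two-way mixed effects, single
measurement, absolute agreement" choice of clinical inter-rater
studies), computed from the two-way ANOVA decomposition with an
F-based 95% confidence interval.  ICC values map onto the standard
four-grade scale: excellent (0.9-1.0), good (0.75-0.9), moderate
(0.5-0.75), poor (< 0.5); boundary values take the higher grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .landmarks import LandmarkSet

__all__ = [
    "RatingsMatrix",
    "IccResult",
    "dice_f1",
    "landmark_mad",
    "icc_absolute_agreement",
    "grade_reliability",
    "success_report",
]

GRADE_BOUNDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))

THORACIC_LEVELS = frozenset(["C7"] + [f"T{i}" for i in range(1, 13)])
LUMBAR_LEVELS = frozenset(f"L{i}" for i in range(1, 6))


@dataclass
class RatingsMatrix:
    """n_subjects x k_raters measurements of one parameter."""

    values: np.ndarray
    rater_labels: tuple[str, ...] = ()
    parameter: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings matrix must be 2-D (subjects x raters)")
        if np.isnan(self.values).any():
            keep = ~np.isnan(self.values).any(axis=1)
            self.n_dropped = int((~keep).sum())
            self.values = self.values[keep]
        else:
            self.n_dropped = 0
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if not self.rater_labels:
            self.rater_labels = tuple(f"R{i + 1}" for i in range(k))


@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    grade: str
    msr: float
    msc: float
    mse: float
    degenerate: bool = False


def dice_f1(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice coefficient / F1 score of two binary masks,
    2|A n B| / (|A| + |B|); defined as 1.0 when both are empty."""
    a = np.asarray(pred_mask)
    b = np.asarray(true_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _region_filter(name: str, region: str | None) -> bool:
    if region is None or region == "total":
        return True
    level = name.split(".")[0]
    if region == "thoracic":
        return level in THORACIC_LEVELS
    if region == "lumbar":
        return level in LUMBAR_LEVELS
    if region in ("sacral", "femoral"):
        return name.startswith(region)
    raise ValueError(f"unknown region {region!r}")


def landmark_mad(
    pred: LandmarkSet,
    true: LandmarkSet,
    view: str = "frontal",
    region: str | None = None,
) -> tuple[float, float, int]:
    """Mean absolute distance (mm) between matched landmarks.

    Landmarks are matched by name (level + corner, sacral point,
    femoral center); unmatched ones are skipped.  Returns
    (MAD, SD, n_matched); SD is the sample standard deviation of the
    absolute distances.
    """
    if pred.pixel_spacing_mm != true.pixel_spacing_mm:
        raise ValueError("landmark sets have different pixel spacing")
    sp = true.pixel_spacing_mm
    t_named = dict(true.iter_named(view))
    dists = []
    for name, (px, py) in pred.iter_named(view):
        if name not in t_named or not _region_filter(name, region):
            continue
        tx, ty = t_named[name]
        dists.append(np.hypot(px - tx, py - ty) * sp)
    if not dists:
        raise ValueError("no matched landmarks")
    d = np.asarray(dists)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd, int(d.size)


def _anova_two_way(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way single-observation ANOVA:
    rows (subjects), columns (raters), residual."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(
    matrix: RatingsMatrix, alpha: float = 0.05
) -> IccResult:
    """ICC(A,1): two-way, single measurement, absolute agreement.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), with the
    F-based confidence interval of the absolute-agreement single-
    measure form.  A matrix with no between-subject variance and no
    residual variance (all raters identical on identical subjects) is
    degenerate; if the raters agree exactly the ICC is defined as 1.0
    and flagged.
    """
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _anova_two_way(x)
    if np.all(x == x[:, [0]]):  # raters agree exactly: ICC is exactly 1
        return IccResult(
            icc=1.0, ci95=(1.0, 1.0), grade="excellent",
            msr=msr, msc=0.0, mse=0.0, degenerate=True,
        )
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if np.isclose(denom, 0.0, atol=1e-30):
        perfect = np.allclose(x, x[:, [0]])
        icc = 1.0 if perfect else 0.0
        return IccResult(
            icc=icc, ci95=(icc, icc), grade=grade_reliability(icc),
            msr=msr, msc=msc, mse=mse, degenerate=True,
        )
    icc = (msr - mse) / denom
    degenerate = np.isclose(mse, 0.0, atol=1e-30) and np.isclose(
        msc, 0.0, atol=1e-30
    )
    if degenerate:
        lo = hi = icc
    else:
        # McGraw & Wong (1996) CI for ICC(A,1)
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f1 * mse)) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = (n * (f2 * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
        else:
            lo = hi = 1.0
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return IccResult(
        icc=float(icc), ci95=(lo, hi), grade=grade_reliability(float(icc)),
        msr=msr, msc=msc, mse=mse, degenerate=bool(degenerate),
    )


def grade_reliability(icc_value: float) -> str:
    """Four-grade scale; boundary values take the higher grade."""
    if not -1.0 <= icc_value <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    for bound, grade in GRADE_BOUNDS:
        if icc_value >= bound:
            return grade
    return "poor"


def success_report(results) -> dict:
    """Per-stage success bookkeeping over a cohort of pipeline runs.

    ``results`` is an iterable of :class:`~spinemetrics.pipeline.SubjectResult`.
    Counts correct preprocessing (landmark containment), per-ROI window
    success, reasonable segmentations (every ROI predicted and >= 18
    vertebral bodies) and complete parameter predictions.
    """
    results = list(results)
    n = len(results)
    roi_counts = {
        view: {roi: 0 for roi in ("neck", "spine", "sacrum", "femur")}
        for view in ("frontal", "lateral")
    }
    n_contained = n_reasonable = n_params = 0
    for r in results:
        if r.preprocess_contained:
            n_contained += 1
        for view, succ in r.preprocess_success.items():
            for roi, ok in succ.items():
                if ok:
                    roi_counts[view][roi] += 1
        if r.reasonable:
            n_reasonable += 1
        if r.parameters is not None:
            n_params += 1
    return {
        "n": n,
        "preprocess_correct": n_contained,
        "preprocess_rate": n_contained / n if n else float("nan"),
        "roi_window_success": roi_counts,
        "reasonable_segmentation": n_reasonable,
        "reasonable_rate": n_reasonable / n if n else float("nan"),
        "parameter_predictions": n_params,
    }
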