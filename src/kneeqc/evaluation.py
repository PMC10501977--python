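"""Detection and agreement metrics for landmark-based QC.

Detection quality is scored with object keypoint similarity (OKS): a
scale-normalized Gaussian similarity between predicted and ground-truth
landmarks, averaged over visible landmarks,

    OKS = sum_i exp(-d_i^2 / (2 s^2 k_i^2)) [v_i > 0] / sum_i [v_i > 0]

where ``d_i`` is the Euclidean prediction error, ``s^2`` the area of the
smallest axis-aligned box containing all visible ground-truth landmarks,
``v_i`` the visibility flag and ``k_i = 2 sigma_i`` a per-landmark falloff
constant.  The default sigma vector for landmarks A-I is
(0.083, 0.083, 0.029, 0.029, 0.029, 0.083, 0.083, 0.083, 0.083) — the three
fibular-head landmarks are held to a tighter standard than the shaft
landmarks, whose exact position along the diaphysis is not unique.
AP/AR follow the COCO convention: detections ranked by confidence, true
positive iff OKS >= threshold, AP by 101-point interpolated precision-recall
area, mAP/mAR averaged over thresholds 0.50:0.05:0.95.

Human-machine agreement uses ICC(2,1) — intraclass correlation with two-way
random effects, absolute agreement, single rater — with a McGraw-Wong
F-based 95% CI, plus absolute-deviation summaries (optionally normalized by
a range width, e.g. 180 degrees for flexion angles) and pooled-variance
two-sample t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import LABELS, KeypointSet

__all__ = [
    "OKSConfig",
    "DetectionMetrics",
    "AgreementReport",
    "DeviationStats",
    "oks",
    "keypoint_ap_ar",
    "icc_2_1",
    "deviation_stats",
    "two_sample_t",
    "agreement_report",
    "COCO_THRESHOLDS",
]

DEFAULT_SIGMAS: tuple[float, ...] = (0.083, 0.083, 0.029, 0.029, 0.029, 0.083, 0.083, 0.083, 0.083)
COCO_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class OKSConfig:
    """Per-landmark falloff constants; ``k = 2 * sigma`` per landmark."""

    sigma: tuple[float, ...] = DEFAULT_SIGMAS

    def __post_init__(self) -> None:
        if len(self.sigma) != len(LABELS) or min(self.sigma) <= 0:
            raise ValueError(f"sigma must hold {len(LABELS)} positive entries")

    @property
    def k(self) -> tuple[float, ...]:
        return tuple(2.0 * s for s in self.sigma)


@dataclass(frozen=True)
class DetectionMetrics:
    mAP: float
    AP50: float
    AP75: float
    mAR: float
    oks_per_case: tuple[float, ...]


@dataclass(frozen=True)
class DeviationStats:
    """Absolute-deviation summary between two raters."""

    mean: float
    sd: float
    max: float
    normalized: tuple[float, float, float] | None = None  # display-rounded (3 dp)


@dataclass(frozen=True)
class AgreementReport:
    icc: float
    ci95: tuple[float, float]
    deviations: DeviationStats
    t_stat: float
    p_value: float


def oks(pred: KeypointSet, gt: KeypointSet, cfg: OKSConfig | None = None) -> float:
    """Object keypoint similarity between a prediction and the ground truth.

    A visible ground-truth landmark with no (or an invisible) prediction
    contributes 0, the d = infinity convention.
    """
    cfg = cfg or OKSConfig()
    vis = [lab for lab in LABELS if lab in gt and gt.keypoints[lab].visible]
    if not vis:
        raise ValueError("ground truth has no visible keypoints")
    xs = [gt.keypoints[lab].position.x for lab in vis]
    ys = [gt.keypoints[lab].position.y for lab in vis]
    s2 = (max(xs) - min(xs)) * (max(ys) - min(ys))
    if s2 <= 0:
        raise ValueError("degenerate scale: ground-truth bounding box has zero area")
    total = 0.0
    for lab in vis:
        ki = cfg.k[LABELS.index(lab)]
        pkp = pred.keypoints.get(lab)
        if pkp is None or not pkp.visible:
            continue  # exp(-inf) = 0
        d2 = (pkp.position.x - gt.keypoints[lab].position.x) ** 2 + (
            pkp.position.y - gt.keypoints[lab].position.y
        ) ** 2
        total += math.exp(-d2 / (2.0 * s2 * ki**2))
    return total / len(vis)


def _interpolated_ap(oks_vals: np.ndarray, conf: np.ndarray, thr: float) -> float:
    """101-point interpolated AP for one OKS threshold.

    One ground-truth instance and at most one detection per image; ranking
    by confidence (ties broken by input order, stable sort).
    """
    order = np.argsort(-conf, kind="stable")
    tp = (oks_vals[order] >= thr).astype(np.float64)
    n_gt = len(oks_vals)
    cum_tp = np.cumsum(tp)
    ranks = np.arange(1, len(tp) + 1)
    precision = cum_tp / ranks
    recall = cum_tp / n_gt
    # precision envelope, then 101-point sampling
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += float(prec_env[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def keypoint_ap_ar(
    cases: list[tuple[KeypointSet, float, KeypointSet]],
    thresholds: tuple[float, ...] = COCO_THRESHOLDS,
    cfg: OKSConfig | None = None,
) -> DetectionMetrics:
    """AP/AR metrics over ``(prediction, confidence, ground_truth)`` cases."""
    if not cases:
        raise ValueError("empty case list")
    oks_vals = np.array([oks(p, g, cfg) for p, _, g in cases])
    conf = np.array([c for _, c, _ in cases], dtype=np.float64)
    aps = {t: _interpolated_ap(oks_vals, conf, t) for t in thresholds}
    ars = {t: float(np.mean(oks_vals >= t)) for t in thresholds}
    return DetectionMetrics(
        mAP=float(np.mean(list(aps.values()))),
        AP50=aps.get(0.50, _interpolated_ap(oks_vals, conf, 0.50)),
        AP75=aps.get(0.75, _interpolated_ap(oks_vals, conf, 0.75)),
        mAR=float(np.mean(list(ars.values()))),
        oks_per_case=tuple(oks_vals),
    )


def icc_2_1(ratings: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1) — two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n subjects x k raters) matrix without missing cells.
    Returns the estimate and the F-based (1 - alpha) confidence interval.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (n subjects, >=2 raters)")
    n, k = x.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("constant ratings: ICC undefined (zero variance)")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # raters
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse == 0.0 and msc == 0.0:  # perfect agreement: the interval degenerates
        return float(icc), (float(icc), float(icc))

    # McGraw & Wong F-based interval for ICC(A,1)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_low = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = (n * (msr - f_low * mse)) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = (n * (f_up * msr - mse)) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), (float(lower), float(upper))


def deviation_stats(
    pairs: list[tuple[float, float]] | np.ndarray,
    normalization_range: float | None = None,
) -> DeviationStats:
    """Mean / sample-SD / max of absolute rater deviations.

    With ``normalization_range`` (e.g. 180 for angles in degrees), each
    statistic is also reported divided by that width and rounded to three
    decimals for display.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no pairs given")
    dev = np.abs(arr[:, 0] - arr[:, 1])
    mean = float(dev.mean())
    sd = float(dev.std(ddof=1)) if len(dev) > 1 else 0.0
    mx = float(dev.max())
    norm = None
    if normalization_range is not None:
        norm = tuple(round(v / normalization_range, 3) for v in (mean, sd, mx))
    return DeviationStats(mean=mean, sd=sd, max=mx, normalized=norm)


def two_sample_t(x, y) -> tuple[float, float]:
    """Pooled-variance (Student) independent two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise ValueError("both samples constant and equal: t undefined")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    if np.isnan(t):  # identical samples with zero pooled variance handled above
        t, p = 0.0, 1.0
    return float(t), float(p)


def agreement_report(
    rater1, rater2, normalization_range: float | None = None
) -> AgreementReport:
    """Full two-rater agreement summary for one QC criterion."""
    r1 = np.asarray(rater1, dtype=np.float64)
    r2 = np.asarray(rater2, dtype=np.float64)
    icc, ci = icc_2_1(np.column_stack([r1, r2]))
    dev = deviation_stats(np.column_stack([r1, r2]), normalization_range)
    t, p = two_sample_t(r1, r2)
    return AgreementReport(icc=icc, ci95=ci, deviations=dev, t_stat=t, p_value=p)
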