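"""Diagnostic-accuracy evaluation of a screening score against a reference standard.

Covers the full validation pipeline for an ordinal risk score: 2x2 confusion
matrices, sensitivity/specificity/predictive values, the Youden index
(J = sensitivity + specificity - 1), Cohen's kappa, ROC points at
half-integer thresholds with trapezoidal AUC, maximum-Youden cut-off
selection, and the Pearson chi-squared test for group contrasts
(no continuity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, InputError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "ROCPoint",
    "ChiSquaredResult",
    "confusion_matrix",
    "diagnostic_metrics",
    "cohen_kappa",
    "roc_curve",
    "auc_trapezoid",
    "select_cutoff_max_youden",
    "pearson_chi_squared",
    "validation_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention behind printed tables)."""
    x = float(x)
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)
    return float(d.copy_negate() if x < 0 else d)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))
        if self.total == 0:
            raise InputError("confusion matrix must have at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(predicted_positive: Sequence[bool],
                     reference_positive: Sequence[bool]) -> ConfusionMatrix:
    """Cross-tabulate paired binary classifications into a 2x2 matrix."""
    pred = np.asarray(predicted_positive, dtype=bool)
    ref = np.asarray(reference_positive, dtype=bool)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise InputError(
            f"paired 1-d classifications required, got shapes "
            f"{pred.shape} and {ref.shape}"
        )
    if pred.size == 0:
        raise InputError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(pred & ref)),
        fp=int(np.sum(pred & ~ref)),
        fn=int(np.sum(~pred & ref)),
        tn=int(np.sum(~pred & ~ref)),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy metrics; ``None`` marks an undefined (0/0) quantity."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def diagnostic_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and Youden index of a 2x2 matrix."""
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    youden = sens + spec - 1.0 if sens is not None and spec is not None else None
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        youden=youden,
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between the two binary classifications.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement
    p_o = (tp + tn)/N and chance agreement p_e from the marginal products.
    """
    n = cm.total
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if p_e == 1.0:
        raise ComputationError("kappa undefined: chance agreement p_e = 1")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    false_positive_rate: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0
                and 0.0 <= self.false_positive_rate <= 1.0):
            raise InputError("sensitivity and FPR must lie in [0, 1]")

    @property
    def specificity(self) -> float:
        return 1.0 - self.false_positive_rate

    @property
    def youden(self) -> float:
        return self.sensitivity - self.false_positive_rate


def default_thresholds(scores: Sequence[float]) -> list[float]:
    """Half-integer candidate cut values spanning the observed score range."""
    smax = int(max(scores))
    return [s + 0.5 for s in range(0, smax + 1)]


def roc_curve(scores: Sequence[float],
              reference_positive: Sequence[bool],
              candidate_thresholds: Sequence[float] | None = None,
              ) -> list[ROCPoint]:
    """ROC points for "positive iff score >= t" over candidate thresholds.

    Thresholds default to the half-integers between observed integer scores.
    The degenerate endpoints (FPR, sens) = (1, 1) (threshold below every
    score) and (0, 0) (above every score) are appended, so the curve always
    spans the unit square.  Points are returned sorted by ascending
    threshold, i.e. non-increasing sensitivity and FPR.
    """
    s = np.asarray(scores, dtype=float)
    ref = np.asarray(reference_positive, dtype=bool)
    if s.shape != ref.shape or s.ndim != 1 or s.size == 0:
        raise InputError("scores and reference must be equal-length 1-d arrays")
    n_pos = int(ref.sum())
    n_neg = int((~ref).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("reference standard must contain both classes")
    if candidate_thresholds is None:
        candidate_thresholds = default_thresholds(s)

    points = [ROCPoint(threshold=float(s.min()) - 0.5,
                       sensitivity=1.0, false_positive_rate=1.0)]
    for t in sorted(candidate_thresholds):
        pred = s >= t
        points.append(ROCPoint(
            threshold=float(t),
            sensitivity=float(np.sum(pred & ref)) / n_pos,
            false_positive_rate=float(np.sum(pred & ~ref)) / n_neg,
        ))
    top = points[-1]
    if top.sensitivity > 0.0 or top.false_positive_rate > 0.0:
        points.append(ROCPoint(threshold=float(s.max()) + 0.5,
                               sensitivity=0.0, false_positive_rate=0.0))
    return points


def auc_trapezoid(points: Iterable[ROCPoint]) -> float:
    """Trapezoidal area under the (FPR, sensitivity) curve.

    Points are sorted by FPR; at tied FPR only the maximum sensitivity is
    kept (the upper envelope of the step curve).
    """
    by_fpr: dict[float, float] = {}
    for p in points:
        key = p.false_positive_rate
        by_fpr[key] = max(by_fpr.get(key, 0.0), p.sensitivity)
    by_fpr.setdefault(0.0, 0.0)
    by_fpr.setdefault(1.0, 1.0)
    xs = sorted(by_fpr)
    ys = [by_fpr[x] for x in xs]
    return float(np.trapezoid(ys, xs))


def select_cutoff_max_youden(points: Sequence[ROCPoint]) -> tuple[int, float]:
    """Choose the cut-off maximizing Youden's J = sensitivity - FPR.

    Only interior points (neither degenerate endpoint) compete.  Ties break
    toward higher specificity, then lower threshold.  The returned integer
    cut is the ceiling of the winning half-integer threshold ("positive iff
    score >= cut" on the integer scale).
    """
    interior = [
        p for p in points
        if not ((p.sensitivity == 1.0 and p.false_positive_rate == 1.0)
                or (p.sensitivity == 0.0 and p.false_positive_rate == 0.0))
    ]
    if not interior:
        raise InputError("no interior ROC point to select a cut-off from")
    # round J so sens/FPR float noise cannot mask a genuine tie
    best = max(interior,
               key=lambda p: (round(p.youden, 12), p.specificity, -p.threshold))
    return int(np.ceil(best.threshold)), best.youden


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


def pearson_chi_squared(table, yates: bool = False) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on an r x c count table.

    The statistic is sum((O - E)^2 / E) with expected counts from the row and
    column margins; no continuity correction unless ``yates`` (2x2 only).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise InputError("contingency table must hold non-negative integers")
    total = obs.sum()
    if total == 0:
        raise InputError("contingency table is empty")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    zero = np.argwhere(expected == 0)
    if zero.size:
        r, c = zero[0]
        raise ComputationError(
            f"expected count is zero in cell ({r}, {c}); "
            "drop the all-zero row/column"
        )
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise InputError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float(np.sum(diff * diff / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquaredResult(statistic=statistic, df=df, p_value=p,
                            expected=expected)


def validation_report(scores: Sequence[float],
                      reference_positive: Sequence[bool],
                      candidate_thresholds: Sequence[float] | None = None,
                      ) -> dict:
    """Full validation summary of a score against a reference standard.

    Returns a dict with the per-cut-off sensitivity/specificity/Youden table,
    the AUC, the selected (maximum-Youden) integer cut-off, and the confusion
    matrix, accuracy metrics and kappa at that cut-off.  Percentages are
    reported to one decimal and kappa/AUC to three, ties away from zero,
    alongside the unrounded values.
    """
    points = roc_curve(scores, reference_positive, candidate_thresholds)
    auc = auc_trapezoid(points)
    cutoff, youden = select_cutoff_max_youden(points)
    s = np.asarray(scores, dtype=float)
    cm = confusion_matrix(s >= cutoff, reference_positive)
    metrics = diagnostic_metrics(cm)
    kappa = cohen_kappa(cm)

    def pct(v: float | None) -> float | None:
        return None if v is None else round_half_away(100.0 * v, 1)

    # every candidate-threshold point (the artificial all-positive endpoint
    # is presentation noise; the all-negative row mirrors printed tables)
    table_points = [
        p for p in points
        if not (p.sensitivity == 1.0 and p.false_positive_rate == 1.0)
    ]
    cutoff_table = [
        {
            "cutoff": p.threshold,
            "sensitivity_pct": pct(p.sensitivity),
            "specificity_pct": pct(p.specificity),
            "youden_pct": pct(p.youden),
        }
        for p in table_points
    ]
    return {
        "n": int(s.size),
        "n_reference_positive": int(np.asarray(reference_positive, bool).sum()),
        "cutoff_table": cutoff_table,
        "auc": auc,
        "auc_rounded": round_half_away(auc, 3),
        "selected_cutoff": cutoff,
        "youden_at_cutoff": youden,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "sensitivity_pct": pct(metrics.sensitivity),
        "specificity_pct": pct(metrics.specificity),
        "ppv_pct": pct(metrics.ppv),
        "npv_pct": pct(metrics.npv),
        "youden_pct": pct(metrics.youden),
        "kappa": kappa,
        "kappa_rounded": round_half_away(kappa, 3),
    }
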