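"""Diagnostic-performance statistics for the DWI lesion pipeline.

Confusion-matrix metrics (exact rational arithmetic, rounded only for
display), univariate 2x2 odds ratios with Woolf confidence intervals,
empirical ROC curves whose AUC is the Mann-Whitney probability (ties
counted 1/2) with the Hanley-McNeil standard error

    SE(A)^2 = [A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)] / (n1 n2),
    Q1 = A/(2-A),  Q2 = 2A^2/(1+A),

maximum-Youden-index cutoff selection, the Hanley-McNeil z-test for two
independent AUCs, the DeLong test for two correlated AUCs, and
:func:`evaluate_pipeline`, which runs the five diagnostic readings
(qualitative DWI, quantitative DWI, DWI combination, DCE-MRI alone,
DCE-MRI + ADC) over a lesion cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from .combination import CombinationRuleConfig, combine_dce, combine_dwi
from .lesion_schema import (
    DescriptorRiskTable,
    LesionRecord,
    Pathology,
    split_visible,
)
from .qualitative_scoring import qual_positive, qual_score

__all__ = [
    "ConfusionMatrix", "confusion_metrics", "OddsRatioResult", "odds_ratio",
    "RocCurve", "empirical_roc", "hanley_mcneil_se", "YoudenResult",
    "youden_cutoff", "compare_auc_independent", "compare_auc_paired",
    "evaluate_pipeline", "proportions_chi2", "adc_rank_sum",
]

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

#: Normal quantile used for 95% Woolf intervals (two decimal places, the
#: convention of the clinical literature this reproduces).
WOOLF_Z = 1.96


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts of one binary diagnostic reading."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_calls(cls, labels: Sequence[bool],
                   calls: Sequence[bool]) -> "ConfusionMatrix":
        """Build from truth labels (True = diseased) and test calls."""
        if len(labels) != len(calls):
            raise ValueError("labels and calls must have equal length")
        tp = sum(1 for y, c in zip(labels, calls) if y and c)
        fp = sum(1 for y, c in zip(labels, calls) if not y and c)
        fn = sum(1 for y, c in zip(labels, calls) if y and not c)
        tn = sum(1 for y, c in zip(labels, calls) if not y and not c)
        return cls(tp, fp, fn, tn)


def _round2(x: Fraction) -> float:
    """Round an exact rational to 2 decimals, half away from zero."""
    q = x * 100
    return float(math.floor(q + Fraction(1, 2))) / 100


def confusion_metrics(cm: ConfusionMatrix, exact: bool = False) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy, as percentages.

    Computed in exact rational arithmetic; by default rounded to 2 decimals
    (half up).  With ``exact=True`` returns :class:`~fractions.Fraction`
    values.  A metric with a zero denominator is reported as ``None``
    (undefined), never as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pairs = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
        "accuracy": (cm.tp + cm.tn, cm.total),
    }
    out: dict = {}
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = None
        else:
            frac = Fraction(100 * num, den)
            out[name] = frac if exact else _round2(frac)
    return out


@dataclass(frozen=True)
class OddsRatioResult:
    """Univariate odds ratio with Woolf 95% CI.

    ``counts`` is the 2x2 table ``((ref_ctrl, ref_case), (exp_ctrl,
    exp_case))``; the odds ratio is oriented exposure-vs-reference for
    case status.  Tables with any zero cell yield an undefined result
    (``defined`` False, values ``None``) rather than an exception.
    """

    counts: tuple[tuple[int, int], tuple[int, int]]
    or_value: float | None
    ci_low: float | None
    ci_high: float | None

    @property
    def defined(self) -> bool:
        return self.or_value is not None


def odds_ratio(table: Sequence[Sequence[int]]) -> OddsRatioResult:
    """Odds ratio of a 2x2 table, reference level first.

    ``table[0] = (controls, cases)`` at the reference level and
    ``table[1] = (controls, cases)`` at the exposed level, so
    ``OR = (ref_ctrl * exp_case) / (ref_case * exp_ctrl)``.  The 95% CI is
    Woolf's log-variance interval ``exp(ln OR +/- 1.96 * sqrt(sum 1/n))``.
    """
    (a, b), (c, d) = ((int(table[0][0]), int(table[0][1])),
                      (int(table[1][0]), int(table[1][1])))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    counts = ((a, b), (c, d))
    if min(a, b, c, d) == 0:
        return OddsRatioResult(counts, None, None, None)
    or_value = (a * d) / (b * c)
    half_width = WOOLF_Z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    return OddsRatioResult(counts, or_value,
                           math.exp(log_or - half_width),
                           math.exp(log_or + half_width))


def _oriented_scores(scores: Sequence[float], direction: str) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if direction == "lower_is_positive":
        return -s
    if direction == "higher_is_positive":
        return s
    raise ValueError(f"unknown direction {direction!r}")


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(score_pos > score_neg) + 1/2 P(equal), by midranks (exact)."""
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    r_pos = ranks[: len(pos)].sum()
    n1, n2 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n2))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil closed-form standard error of an empirical AUC."""
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: operating points, AUC and its SE.

    ``points`` rows are ``(threshold, sensitivity, 1 - specificity)`` on the
    original score scale, with sensitivity and FPR non-decreasing.  ``auc``
    is the Mann-Whitney probability that a random diseased lesion outranks a
    random benign one (ties 1/2), which equals the trapezoidal area under
    the points.
    """

    points: np.ndarray
    auc: float
    se_auc: float
    n_pos: int
    n_neg: int

    def ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% CI for the AUC, clipped to [0, 1]."""
        lo = self.auc - WOOLF_Z * self.se_auc
        hi = self.auc + WOOLF_Z * self.se_auc
        return max(lo, 0.0), min(hi, 1.0)


def empirical_roc(scores: Sequence[float], labels: Sequence[bool],
                  direction: str = "higher_is_positive") -> RocCurve:
    """Empirical ROC curve of a continuous or ordinal marker.

    ``direction='lower_is_positive'`` handles markers like ADC where low
    values indicate disease.  AUC is tie-aware Mann-Whitney; SE is
    Hanley-McNeil.
    """
    y = np.asarray(labels, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    s = _oriented_scores(scores, direction)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    pos, neg = s[y], s[~y]
    auc = _mann_whitney_auc(pos, neg)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    if direction == "lower_is_positive":
        thr = -thr
    points = np.column_stack([thr, tpr, fpr])
    return RocCurve(points=points, auc=auc,
                    se_auc=hanley_mcneil_se(auc, len(pos), len(neg)),
                    n_pos=int(len(pos)), n_neg=int(len(neg)))


@dataclass(frozen=True)
class YoudenResult:
    """Maximum-Youden-index operating point of a marker.

    ``j = sensitivity + specificity - 1`` at ``cutoff``; sensitivity and
    specificity are proportions in [0, 1].  For ``lower_is_positive`` a
    lesion is called positive iff its score is strictly below the cutoff;
    for ``higher_is_positive``, strictly above.
    """

    cutoff: float
    j: float
    sensitivity: float
    specificity: float


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool],
                  direction: str = "lower_is_positive") -> YoudenResult:
    """Cutoff maximizing the Youden index over all observed score values.

    Ties in J are broken toward the cutoff with the higher sensitivity,
    then toward the smaller threshold value.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    best: YoudenResult | None = None
    for c in np.unique(s):
        if direction == "lower_is_positive":
            sens = np.mean(pos < c)
            spec = np.mean(neg >= c)
        elif direction == "higher_is_positive":
            sens = np.mean(pos > c)
            spec = np.mean(neg <= c)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        cand = YoudenResult(cutoff=float(c), j=float(sens + spec - 1),
                            sensitivity=float(sens), specificity=float(spec))
        if (best is None
                or cand.j > best.j + 1e-12
                or (abs(cand.j - best.j) <= 1e-12
                    and (cand.sensitivity > best.sensitivity + 1e-12
                         or (abs(cand.sensitivity - best.sensitivity) <= 1e-12
                             and cand.cutoff < best.cutoff)))):
            best = cand
    assert best is not None
    return best


def compare_auc_independent(roc1: RocCurve, roc2: RocCurve) -> dict:
    """Hanley-McNeil z-test for two AUCs from independent samples."""
    se = math.sqrt(roc1.se_auc ** 2 + roc2.se_auc ** 2)
    if se == 0:
        raise ValueError("combined standard error is zero")
    z = (roc1.auc - roc2.auc) / se
    return {"z": z, "p": 2 * sps.norm.sf(abs(z)),
            "auc1": roc1.auc, "auc2": roc2.auc}


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: per-positive and per-negative
    placement values of the Mann-Whitney kernel (ties 1/2)."""
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return psi.mean(axis=1), psi.mean(axis=0)


def compare_auc_paired(scores1: Sequence[float], scores2: Sequence[float],
                       labels: Sequence[bool],
                       direction1: str = "higher_is_positive",
                       direction2: str = "higher_is_positive") -> dict:
    """DeLong test for two correlated AUCs measured on the same lesions."""
    y = np.asarray(labels, dtype=bool)
    s1 = _oriented_scores(scores1, direction1)
    s2 = _oriented_scores(scores2, direction2)
    if not (len(s1) == len(s2) == len(y)):
        raise ValueError("scores and labels must have equal length")
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    v10 = np.empty((2, int(y.sum())))
    v01 = np.empty((2, int((~y).sum())))
    aucs = np.empty(2)
    for k, s in enumerate((s1, s2)):
        v10[k], v01[k] = _placements(s[y], s[~y])
        aucs[k] = v10[k].mean()
    m, n = v10.shape[1], v01.shape[1]
    if m < 2 or n < 2:
        raise ValueError("need at least two lesions in each class")
    s10 = np.cov(v10)  # 2x2, ddof=1
    s01 = np.cov(v01)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * np.sign(diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if not math.isfinite(z) and diff == 0 else 2 * sps.norm.sf(abs(z))
    return {"z": float(z), "p": float(p),
            "auc1": float(aucs[0]), "auc2": float(aucs[1])}


def proportions_chi2(table: Sequence[Sequence[int]]) -> dict:
    """Chi-square test of homogeneity of proportions (delegated to scipy)."""
    res = sps.chi2_contingency(np.asarray(table))
    return {"chi2": float(res.statistic), "p": float(res.pvalue),
            "dof": int(res.dof)}


def adc_rank_sum(values_benign: Sequence[float],
                 values_malignant: Sequence[float]) -> dict:
    """Wilcoxon rank-sum test of a continuous marker between classes
    (delegated to scipy's Mann-Whitney U)."""
    res = sps.mannwhitneyu(values_benign, values_malignant,
                           alternative="two-sided")
    return {"u": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Whole-pipeline evaluation


def _analysis(labels: Sequence[bool], calls: Sequence[bool],
              roc_scores: Sequence[float] | None = None,
              direction: str = "higher_is_positive") -> dict:
    """Confusion matrix, metrics and ROC of one diagnostic reading.

    The ROC defaults to the binary calls themselves (AUC = mean of
    sensitivity and specificity); single-class inputs yield ``roc=None``.
    """
    cm = ConfusionMatrix.from_calls(labels, calls)
    out = {"confusion": cm, "metrics": confusion_metrics(cm),
           "metrics_exact": confusion_metrics(cm, exact=True)}
    y = np.asarray(labels, dtype=bool)
    if y.any() and not y.all():
        scores = [float(c) for c in calls] if roc_scores is None else roc_scores
        out["roc"] = empirical_roc(scores, labels, direction)
    else:
        out["roc"] = None
    return out


def evaluate_pipeline(cohort: Sequence[LesionRecord],
                      cfg: CombinationRuleConfig | None = None,
                      risk_table: DescriptorRiskTable | None = None,
                      size_split_cm: float = 1.0) -> dict:
    """Run the five diagnostic readings over a lesion cohort.

    DWI readings (qualitative, quantitative, combination) use only lesions
    visible on DWI; DCE readings (BI-RADS alone, BI-RADS + ADC) use the
    full cohort, invisible lesions keeping their DCE-alone call.  The DWI
    combination reading is additionally stratified by lesion size at
    ``size_split_cm`` (boundary lesions go to the small stratum).

    The qualitative reading reports two ROC curves: ``roc`` on the 3-level
    confidence score and ``roc_binary`` on the dichotomized call, since a
    published AUC may refer to either.

    Returns a nested dict; metrics of empty or single-class strata are
    ``None`` rather than 0.
    """
    if not cohort:
        raise ValueError("empty cohort")
    cfg = cfg or CombinationRuleConfig()
    visible, _ = split_visible(cohort)
    y_vis = [r.pathology is Pathology.MALIGNANT for r in visible]
    y_all = [r.pathology is Pathology.MALIGNANT for r in cohort]

    scores = [qual_score(r, risk_table) for r in visible]
    adcs = [r.adc for r in visible]
    qual_calls = [qual_positive(s) for s in scores]
    adc_calls = [a < cfg.adc_cutoff for a in adcs]
    comb_calls = [combine_dwi(s, a, cfg) for s, a in zip(scores, adcs)]
    dce_calls = [r.birads >= 4 for r in cohort]
    dce_adc_calls = [combine_dce(r.birads, r.adc, cfg) for r in cohort]

    analyses = {
        "dwi_qualitative": _analysis(y_vis, qual_calls,
                                     roc_scores=[float(s) for s in scores]),
        "dwi_quantitative": _analysis(y_vis, adc_calls, roc_scores=adcs,
                                      direction="lower_is_positive"),
        "dwi_combination": _analysis(y_vis, comb_calls),
        "dce_only": _analysis(y_all, dce_calls,
                              roc_scores=[float(r.birads) for r in cohort]),
        "dce_plus_adc": _analysis(y_all, dce_adc_calls),
    }
    if any(y_vis) and not all(y_vis):
        analyses["dwi_qualitative"]["roc_binary"] = empirical_roc(
            [float(c) for c in qual_calls], y_vis)
    else:
        analyses["dwi_qualitative"]["roc_binary"] = None

    by_size = {}
    for name, keep in (("small", lambda r: r.size_cm <= size_split_cm),
                       ("large", lambda r: r.size_cm > size_split_cm)):
        idx = [i for i, r in enumerate(visible) if keep(r)]
        if idx:
            by_size[name] = _analysis([y_vis[i] for i in idx],
                                      [comb_calls[i] for i in idx])
            by_size[name]["n"] = len(idx)
        else:
            by_size[name] = {"confusion": None, "metrics": None,
                             "metrics_exact": None, "roc": None, "n": 0}
    roc_small = by_size["small"]["roc"]
    roc_large = by_size["large"]["roc"]
    size_comparison = (compare_auc_independent(roc_small, roc_large)
                       if roc_small is not None and roc_large is not None
                       else None)

    n_total, n_visible = len(cohort), len(visible)
    return {
        "n_total": n_total,
        "n_visible": n_visible,
        "detection_rate_pct": _round2(Fraction(100 * n_visible, n_total)),
        "analyses": analyses,
        "combination_by_size": by_size,
        "combination_size_auc_comparison": size_comparison,
        "adc_cutoff": cfg.adc_cutoff,
    }
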