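"""Benchmark scoring: peak-level precision/recall against a known sample
composition, formula-level ROC analysis, and the uniform support-distribution
treatment of list-style annotation outputs.

The peak-level scheme scores, for each peak, the summed support for
compounds known to be *present* (p_n) and the summed support for compounds
known to be *absent* (a_n).  At a threshold t, p_n values above t are true
positives, a_n values above t false positives, p_n below t false negatives
and a_n below t true negatives.  Zero-valued p_n/a_n are discarded — except
in multi-algorithm mode, where a value is discarded only if it is zero under
*every* algorithm, which keeps TP+FP+TN+FN identical across algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakScorePair",
    "CurvePoint",
    "support_distribution",
    "peak_score_pairs",
    "peak_pr_curve",
    "multi_algorithm_pr_curves",
    "formula_roc",
    "f1",
    "auc",
    "tpr_at_fpr",
]

DEFAULT_THRESHOLD_MARKS = (0.0, 0.5, 0.75, 0.95, 1.0)


@dataclass(frozen=True)
class PeakScorePair:
    """Summed support of one peak for present (p) and absent (a) compounds."""

    peak_id: str
    p: float
    a: float


@dataclass(frozen=True)
class CurvePoint:
    """Confusion counts at one threshold, with the derived rates."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def tpr(self) -> float:
        return self.recall

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d else 0.0

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; zero when both are zero."""
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def support_distribution(
    annotations: dict[str, list | dict],
) -> dict[str, dict[object, float]]:
    """Per-peak support over candidate compounds.

    List-style outputs (a list of candidate ids per peak) get the uniform
    1/|A| weight per candidate; probabilistic outputs (a dict candidate ->
    probability) pass through unchanged.  Peaks with no annotation map to an
    empty dict.
    """
    out: dict[str, dict[object, float]] = {}
    for pid, ann in annotations.items():
        if isinstance(ann, dict):
            out[pid] = dict(ann)
        else:
            n = len(ann)
            weights: dict[object, float] = {}
            for cand in ann:
                weights[cand] = weights.get(cand, 0.0) + (1.0 / n if n else 0.0)
            out[pid] = weights
    return out


def peak_score_pairs(
    support: dict[str, dict[object, float]], present: set
) -> list[PeakScorePair]:
    """Collapse per-peak support maps into (p_n, a_n) score pairs."""
    pairs = []
    for pid, weights in support.items():
        p = sum(w for c, w in weights.items() if c in present)
        a = sum(w for c, w in weights.items() if c not in present)
        pairs.append(PeakScorePair(pid, p, a))
    return pairs


def _above(value: float, threshold: float, strict: bool | None) -> bool:
    # default semantics: ">= t" for t > 0, "> t" at t = 0 (so that the zero
    # threshold marks the end of the useful 0 < t <= 1 output range)
    if strict is None:
        strict = threshold == 0.0
    return value > threshold if strict else value >= threshold


def _confusion(
    p_vals: list[float], a_vals: list[float], threshold: float, strict: bool | None
) -> CurvePoint:
    tp = sum(1 for v in p_vals if _above(v, threshold, strict))
    fp = sum(1 for v in a_vals if _above(v, threshold, strict))
    return CurvePoint(threshold, tp, fp, len(a_vals) - fp, len(p_vals) - tp)


def _default_thresholds(values: list[float]) -> list[float]:
    return sorted(set(values) | set(DEFAULT_THRESHOLD_MARKS))


def peak_pr_curve(
    pairs: list[PeakScorePair],
    thresholds: list[float] | None = None,
    strict: bool | None = None,
) -> list[CurvePoint]:
    """Precision-recall curve over the retained p_n/a_n values.

    Zero-valued p_n and a_n are discarded (single-algorithm mode).  ``strict``
    forces ">" (True) or ">=" (False) comparison at every threshold; the
    default uses ">=" except at threshold zero.
    """
    if not pairs:
        raise ValueError("empty score-pair list")
    p_vals = [q.p for q in pairs if q.p > 0.0]
    a_vals = [q.a for q in pairs if q.a > 0.0]
    if thresholds is None:
        thresholds = _default_thresholds(p_vals + a_vals)
    return [_confusion(p_vals, a_vals, t, strict) for t in sorted(thresholds)]


def multi_algorithm_pr_curves(
    pairs_by_algorithm: dict[str, list[PeakScorePair]],
    thresholds: list[float] | None = None,
    strict: bool | None = None,
) -> dict[str, list[CurvePoint]]:
    """Precision-recall curves for several algorithms on a shared item set.

    A peak's p_n (or a_n) is discarded only when it is zero under every
    algorithm, so TP+FP+TN+FN is the same for each algorithm.
    """
    by_peak_p: dict[str, dict[str, float]] = {}
    by_peak_a: dict[str, dict[str, float]] = {}
    for alg, pairs in pairs_by_algorithm.items():
        for q in pairs:
            by_peak_p.setdefault(q.peak_id, {})[alg] = q.p
            by_peak_a.setdefault(q.peak_id, {})[alg] = q.a
    keep_p = {pid for pid, d in by_peak_p.items() if any(v > 0 for v in d.values())}
    keep_a = {pid for pid, d in by_peak_a.items() if any(v > 0 for v in d.values())}
    if thresholds is None:
        all_vals = [
            v
            for d, keep in ((by_peak_p, keep_p), (by_peak_a, keep_a))
            for pid in keep
            for v in d[pid].values()
        ]
        thresholds = _default_thresholds(all_vals)
    out: dict[str, list[CurvePoint]] = {}
    for alg in pairs_by_algorithm:
        p_vals = [by_peak_p[pid].get(alg, 0.0) for pid in keep_p]
        a_vals = [by_peak_a[pid].get(alg, 0.0) for pid in keep_a]
        out[alg] = [_confusion(p_vals, a_vals, t, strict) for t in sorted(thresholds)]
    return out


def formula_roc(
    scores: dict[object, float],
    truth: dict[object, bool],
    thresholds: list[float] | None = None,
    strict: bool | None = None,
) -> list[CurvePoint]:
    """TPR/FPR curve for formula presence calls.

    ``scores`` maps formula to a presence score (a probability, or a vote
    total for list-style baselines, where a typical threshold is 1);
    ``truth`` must cover every scored formula.
    """
    missing = set(scores) - set(truth)
    if missing:
        raise ValueError(f"truth missing for formulas: {sorted(map(str, missing))[:5]}")
    pos = [s for f, s in scores.items() if truth[f]]
    neg = [s for f, s in scores.items() if not truth[f]]
    if thresholds is None:
        thresholds = _default_thresholds(list(scores.values()))
    return [_confusion(pos, neg, t, strict) for t in sorted(thresholds)]


def auc(curve: list[CurvePoint]) -> float:
    """Area under the ROC curve by trapezoidal integration over (FPR, TPR),
    with the (0,0) and (1,1) endpoints appended."""
    pts = sorted({(c.fpr, c.tpr) for c in curve} | {(0.0, 0.0), (1.0, 1.0)})
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.trapezoid(y, x))


def tpr_at_fpr(curve: list[CurvePoint], fpr: float = 0.05) -> float:
    """TPR at a given FPR operating point, linearly interpolated between
    adjacent curve points (with the (0,0) and (1,1) endpoints appended)."""
    pts = sorted({(c.fpr, c.tpr) for c in curve} | {(0.0, 0.0), (1.0, 1.0)})
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    return float(np.interp(fpr, x, y))
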