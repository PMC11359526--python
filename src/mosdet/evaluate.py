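"""Event-based scoring of predicted moments of stress (MOS).

Raw per-second predictions are first merged: predictions within an 8 s run
collapse to one MOS, represented by the earliest time.  A merged prediction
is a true positive when it falls within the asymmetric window [r - 2 s,
r + 6 s] of a reference stressor r (earliest-first greedy matching, one
prediction per reference).  An unmatched prediction with no reference
within 8 s is a false positive; every unmatched reference is a false
negative, so tp + fn always equals the number of references.  True
negatives are counted on non-overlapping 8 s slots tiling the session that
contain neither a prediction nor a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MOSPredictionStream",
    "EventEvaluation",
    "merge_predictions",
    "match_events",
    "score",
    "predictions_to_times",
    "pool_evaluations",
]

PRE_S = 2.0
POST_S = 6.0
NEG_WINDOW_S = 8.0


@dataclass
class MOSPredictionStream:
    """Per-second binary predictions (or probabilities with a threshold)."""

    subject_id: str
    times_s: np.ndarray  # times of positive predictions, seconds, sorted

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) < 0):
            raise ValueError("prediction times must be sorted")


@dataclass
class EventEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int
    matched_pairs: list[tuple[float, float]] = field(default_factory=list)
    merged_predictions: list[float] = field(default_factory=list)

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else None

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else None

    @property
    def f1(self) -> float | None:
        r, p = self.recall, self.precision
        if r is None or p is None or r + p == 0:
            return None
        return 2 * p * r / (p + r)


def predictions_to_times(
    window_start_s: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
    offset_s: float = 0.0,
) -> np.ndarray:
    """Window probabilities -> sorted raw MOS times (start + offset)."""
    window_start_s = np.asarray(window_start_s, dtype=float)
    probabilities = np.asarray(probabilities, dtype=float)
    times = window_start_s[probabilities >= threshold] + offset_s
    return np.sort(times)


def merge_predictions(
    raw_prediction_times,
    merge_window_s: float = NEG_WINDOW_S,
    representative: str = "first",
) -> list[float]:
    """Greedy left-to-right clustering within ``merge_window_s`` of the
    cluster's first element.

    ``representative`` picks the reported time per cluster: ``"first"``
    (earliest member, the default) or ``"median"``.  The median is the
    robust choice when a detector fires on a run of consecutive seconds
    straddling the stimulus.
    """
    times = [float(t) for t in raw_prediction_times]
    if times != sorted(times):
        raise ValueError("prediction times must be sorted")
    if representative not in ("first", "median"):
        raise ValueError("representative must be 'first' or 'median'")
    clusters: list[list[float]] = []
    for t in times:
        if clusters and t - clusters[-1][0] <= merge_window_s:
            clusters[-1].append(t)
        else:
            clusters.append([t])
    if representative == "median":
        return [float(np.median(c)) for c in clusters]
    return [c[0] for c in clusters]


def match_events(
    merged_predictions,
    reference_times,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
    neg_window_s: float = NEG_WINDOW_S,
    session_duration: float | None = None,
) -> EventEvaluation:
    """Greedy earliest-first matching of merged predictions to references."""
    preds = [float(t) for t in merged_predictions]
    refs = [float(t) for t in reference_times]
    if preds != sorted(preds) or refs != sorted(refs):
        raise ValueError("inputs must be sorted")

    matched_pairs: list[tuple[float, float]] = []
    ref_matched = [False] * len(refs)
    pred_matched = [False] * len(preds)
    for pi, p in enumerate(preds):
        for ri, r in enumerate(refs):
            if ref_matched[ri]:
                continue
            if r - pre_s <= p <= r + post_s:
                matched_pairs.append((p, r))
                ref_matched[ri] = True
                pred_matched[pi] = True
                break

    tp = len(matched_pairs)
    # unmatched prediction with no reference anywhere within neg_window_s -> FP;
    # an unmatched prediction that is near some reference is not counted.
    fp = sum(
        1
        for pi, p in enumerate(preds)
        if not pred_matched[pi]
        and not any(abs(p - r) <= neg_window_s for r in refs)
    )
    # every reference contributes to exactly one of {tp, fn}
    fn = sum(1 for ri in range(len(refs)) if not ref_matched[ri])

    tn = 0
    if session_duration is not None:
        n_slots = int(session_duration // neg_window_s)
        for k in range(n_slots):
            lo, hi = k * neg_window_s, (k + 1) * neg_window_s
            if any(lo <= p < hi for p in preds):
                continue
            if any(lo <= r < hi for r in refs):
                continue
            tn += 1

    return EventEvaluation(tp, fp, fn, tn, matched_pairs, preds)


def score(evaluation: EventEvaluation) -> dict:
    """Metric dict; undefined ratios are reported as None, not zero."""
    return {
        "tp": evaluation.tp,
        "fp": evaluation.fp,
        "fn": evaluation.fn,
        "tn": evaluation.tn,
        "recall": evaluation.recall,
        "precision": evaluation.precision,
        "accuracy": evaluation.accuracy,
        "f1": evaluation.f1,
    }


def pool_evaluations(evaluations) -> EventEvaluation:
    """Sum confusion counts across subjects into one pooled evaluation."""
    pooled = EventEvaluation(0, 0, 0, 0)
    for ev in evaluations:
        pooled.tp += ev.tp
        pooled.fp += ev.fp
        pooled.fn += ev.fn
        pooled.tn += ev.tn
        pooled.matched_pairs.extend(ev.matched_pairs)
        pooled.merged_predictions.extend(ev.merged_predictions)
    return pooled
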