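"""Metrics, speaker-level aggregation, significance testing, seed summaries,
and channel-occlusion attribution.

All macro metrics are computed from the 5x5 confusion matrix (rows = truth,
columns = prediction, class order Normal, Mild, Moderate, Severe,
Tremor-dominant).  The multi-class Matthews correlation coefficient uses the
covariance (generalized) form, which reduces to the familiar binary
TP/TN/FP/FN formula for two classes; a zero denominator yields MCC = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .synth import CLASS_ORDER

logger = logging.getLogger(__name__)


def confusion_matrix(truth: np.ndarray, pred: np.ndarray,
                     n_classes: int = 5) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(truth, pred):
        cm[t, p] += 1
    return cm


def multiclass_mcc(truth: np.ndarray, pred: np.ndarray,
                   n_classes: int = 5) -> float:
    """Covariance-form MCC; 0 when the denominator degenerates."""
    cm = confusion_matrix(truth, pred, n_classes).astype(float)
    s = cm.sum()
    c = np.trace(cm)
    t = cm.sum(axis=1)   # truth counts
    p = cm.sum(axis=0)   # prediction counts
    num = c * s - float(t @ p)
    den = math.sqrt(max(s * s - float(p @ p), 0.0)) * \
        math.sqrt(max(s * s - float(t @ t), 0.0))
    if den == 0:
        return 0.0
    return float(num / den)


def binary_mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """The textbook two-class formula."""
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


@dataclass
class MetricReport:
    accuracy: float            # percent
    macro_f1: float
    macro_recall: float
    macro_specificity: float
    mcc: float
    roc_auc_ovr_macro: float
    confusion: np.ndarray
    level: str = "segment"     # "segment" | "speaker"
    aggregation: str = "none"  # "none" | "majority" | "mean_prob"

    def as_dict(self) -> dict[str, float]:
        return dict(accuracy=self.accuracy, macro_f1=self.macro_f1,
                    macro_recall=self.macro_recall,
                    macro_specificity=self.macro_specificity, mcc=self.mcc,
                    roc_auc_ovr_macro=self.roc_auc_ovr_macro)


def metrics(truth: np.ndarray, pred: np.ndarray,
            probabilities: np.ndarray | None = None,
            n_classes: int = 5, level: str = "segment",
            aggregation: str = "none") -> MetricReport:
    """Macro-averaged one-vs-rest metrics over the classes present in truth.

    Classes absent from the truth vector are excluded from the macro
    averages with a warning (their per-class terms are undefined).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    cm = confusion_matrix(truth, pred, n_classes)
    total = cm.sum()
    present = np.flatnonzero(cm.sum(axis=1) > 0)
    absent = set(range(n_classes)) - set(present)
    if absent:
        logger.warning("classes %s absent from truth; excluded from macro "
                       "averages", sorted(absent))

    f1s, recalls, specs = [], [], []
    for k in present:
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        f1s.append(f1)
        recalls.append(recall)
        specs.append(spec)

    auc = math.nan
    if probabilities is not None:
        auc = _macro_ovr_auc(truth, np.asarray(probabilities), present)

    return MetricReport(
        accuracy=100.0 * np.trace(cm) / total if total else math.nan,
        macro_f1=float(np.mean(f1s)),
        macro_recall=float(np.mean(recalls)),
        macro_specificity=float(np.mean(specs)),
        mcc=multiclass_mcc(truth, pred, n_classes),
        roc_auc_ovr_macro=auc, confusion=cm,
        level=level, aggregation=aggregation)


def _macro_ovr_auc(truth, proba, present) -> float:
    from sklearn.metrics import roc_auc_score

    aucs = []
    for k in present:
        y = (truth == k).astype(int)
        if y.min() == y.max():
            continue
        aucs.append(roc_auc_score(y, proba[:, k]))
    return float(np.mean(aucs)) if aucs else math.nan


def aggregate_speaker(speakers, pred, proba, rule: str = "majority"):
    """Collapse segment predictions to one prediction per speaker.

    majority: modal predicted label; ties broken by the higher mean
    posterior among the tied classes.  mean_prob: argmax of the per-speaker
    mean probability vector.  Returns (speaker_ids, labels, mean_probas),
    order-invariant with respect to segment ordering.
    """
    speakers = np.asarray(speakers)
    pred = np.asarray(pred)
    proba = np.asarray(proba)
    sids = sorted(set(speakers.tolist()))
    out_labels, out_probas = [], []
    for sid in sids:
        sel = speakers == sid
        if not np.any(sel):
            logger.warning("speaker %s has no segments; excluded", sid)
            continue
        mean_p = proba[sel].mean(axis=0)
        if rule == "mean_prob":
            lab = int(np.argmax(mean_p))
        elif rule == "majority":
            votes = np.bincount(pred[sel], minlength=proba.shape[1])
            top = np.flatnonzero(votes == votes.max())
            lab = int(top[np.argmax(mean_p[top])])
        else:
            raise ValueError(f"unknown aggregation rule {rule!r}")
        out_labels.append(lab)
        out_probas.append(mean_p)
    return np.array(sids), np.array(out_labels), np.array(out_probas)


def paired_permutation_test(scores_a, scores_b, n_perm: int = 10000,
                            seed: int = 0):
    """Sign-flip permutation test on paired per-unit scores.

    Returns (p_value, mean_difference).  p = (1 + #{|perm mean| >=
    |observed|}) / (1 + n_perm).  All-zero differences give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 paired scores")
    d = a - b
    obs = float(np.mean(d))
    if np.all(d == 0):
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    perm_means = (signs * d[None, :]).mean(axis=1)
    p = (1 + int(np.sum(np.abs(perm_means) >= abs(obs)))) / (1 + n_perm)
    return float(p), obs


def bootstrap_ci(outcomes, statistic=np.mean, level: float = 0.95,
                 n_boot: int = 2000, seed: int = 0):
    """Percentile bootstrap CI over per-speaker outcomes."""
    x = np.asarray(outcomes, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 speakers for a bootstrap interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    stats = np.asarray([statistic(x[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    return (float(np.percentile(stats, 100 * alpha)),
            float(np.percentile(stats, 100 * (1 - alpha))))


def seed_summary(values) -> tuple[float, float]:
    """Mean +- sample SD over per-seed values, rounded half-up to 1 decimal.

    With fewer than 2 values the SD is missing (NaN).
    """
    x = np.asarray(values, dtype=float)

    def round1(v: float) -> float:
        return float(Decimal(repr(v)).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_UP))

    mean = round1(float(np.mean(x)))
    if len(x) < 2:
        return mean, math.nan
    return mean, round1(float(np.std(x, ddof=1)))


def channel_attribution(model, tensors: np.ndarray, truth: np.ndarray,
                        background: np.ndarray,
                        channel_names) -> dict[str, float]:
    """Occlusion importance per input channel.

    Each channel in turn is replaced by its mean plane over the background
    set; the importance is the average drop in the true-class probability.
    Deterministic given model and data.
    """
    if len(background) == 0:
        raise ValueError("background set is empty")
    base_planes = background.mean(axis=0)          # (C, S, S)
    p_ref = model.predict_proba(tensors)
    ref = p_ref[np.arange(len(truth)), truth]
    out = {}
    for c, name in enumerate(channel_names):
        occluded = tensors.copy()
        occluded[:, c] = base_planes[c]
        p = model.predict_proba(occluded)
        out[name] = float(np.mean(ref - p[np.arange(len(truth)), truth]))
    return out
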