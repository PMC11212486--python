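"""Evaluation protocols for balanced and extremely imbalanced test sets.

Balanced benchmarks report accuracy, sensitivity, specificity and MCC under
stratified k-fold cross-validation.  Imbalanced benchmarks are summarised by
the precision-recall curve and its area (AUPR — equal to class prevalence
for a random scorer, which makes it the metric of choice at 1:1000), plus
precision, F1 and false-positives-per-correct (FP/C = FP/TP, the expected
number of wasted wet-lab validations per genuine hit) at a decision
threshold adjusted to reach a target recall (0.6 / 0.7).

Conventions: a peptide is predicted positive iff ``score >= threshold``
(ties positive); AUPR uses interpolation-free step summation over distinct
thresholds (the average-precision convention); MCC with a zero denominator
factor is reported as 0 with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import LabeledDataset, POSITIVE, kfold_split
from .model import (ModelConfig, TrainConfig, VariantSpec, fit,
                    predict_scores)
from .hard_sampler import SamplerConfig


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class PRCurve:
    """(recall, precision) pairs over all distinct score thresholds."""

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class MetricsReport:
    acc: float = math.nan
    sn: float = math.nan
    sp: float = math.nan
    mcc: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    f1: float = math.nan
    fp_per_correct: float = math.nan
    aupr: float = math.nan
    threshold: float = math.nan
    n_pos: int = 0
    n_neg: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _align(scores: Mapping[str, float],
           labels: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    if set(scores) != set(labels):
        diff = set(scores) ^ set(labels)
        raise KeyError(f"score/label id mismatch, e.g. {sorted(diff)[:5]}")
    ids = sorted(scores)
    s = np.array([scores[i] for i in ids], dtype=np.float64)
    y = np.array([labels[i] for i in ids], dtype=np.int64)
    return s, y


def confusion_at(scores: Mapping[str, float], labels: Mapping[str, int],
                 threshold: float) -> ConfusionCounts:
    """Counts under the rule: predict positive iff score >= threshold."""
    s, y = _align(scores, labels)
    pred = s >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))), fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))), fn=int(np.sum(~pred & (y == 1))))


def balanced_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """Accuracy, sensitivity, specificity, MCC."""
    acc = (c.tp + c.tn) / c.total if c.total else math.nan
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp else math.nan
    denom2 = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom2 == 0:
        warnings.warn("MCC denominator zero; reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return acc, sn, sp, mcc


FPC_SENTINEL = math.inf


def imbalanced_metrics(c: ConfusionCounts
                       ) -> tuple[float, float, float, float]:
    """Precision, recall, F1, FP-per-correct (= FP/TP).

    FP/TP with tp == 0 is reported as ``inf`` with a warning; precision with
    no predicted positives is NaN.
    """
    if c.tp + c.fn < 1:
        raise ValueError("imbalanced metrics need at least one positive")
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else math.nan
    recall = c.tp / (c.tp + c.fn)
    if math.isnan(precision) or precision + recall == 0:
        f1 = math.nan if math.isnan(precision) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if c.tp == 0:
        warnings.warn("no true positives; FP/C reported as inf", stacklevel=2)
        fpc = FPC_SENTINEL
    else:
        fpc = c.fp / c.tp
    return precision, recall, f1, fpc


def threshold_for_recall(scores: Mapping[str, float],
                         labels: Mapping[str, int],
                         target_recall: float) -> float:
    """Largest threshold with recall >= target (maximises precision there).

    Candidate thresholds are the distinct positive scores: recall only
    changes when the threshold crosses one.
    """
    if not (0.0 < target_recall <= 1.0):
        raise ValueError("target_recall must be in (0, 1]")
    s, y = _align(scores, labels)
    pos_scores = np.sort(np.unique(s[y == 1]))[::-1]
    if pos_scores.size == 0:
        raise ValueError("no positives in labels")
    n_pos = int(np.sum(y == 1))
    for t in pos_scores:
        if np.sum((s >= t) & (y == 1)) / n_pos >= target_recall:
            return float(t)
    return float(pos_scores[-1])  # threshold at min positive score: recall 1


def pr_curve_and_aupr(scores: Mapping[str, float],
                      labels: Mapping[str, int]) -> PRCurve:
    """PR curve over all distinct thresholds; AUPR by step summation.

    AUPR = sum_i (R_i - R_{i-1}) * P_i walking thresholds from high to low
    (average-precision convention, no interpolation).
    """
    s, y = _align(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    boundaries = np.r_[distinct, s_sorted.size - 1]
    cum_tp = np.cumsum(y_sorted == 1)[boundaries]
    cum_fp = np.cumsum(y_sorted == 0)[boundaries]
    recalls = cum_tp / n_pos
    precisions = cum_tp / (cum_tp + cum_fp)
    auc = float(np.sum(np.diff(np.r_[0.0, recalls]) * precisions))
    return PRCurve(recalls=recalls, precisions=precisions,
                   thresholds=s_sorted[boundaries], auc=auc)


def report_at_recall(scores: Mapping[str, float], labels: Mapping[str, int],
                     target_recall: float) -> MetricsReport:
    """Full imbalanced report at the threshold adjusted for target recall."""
    t = threshold_for_recall(scores, labels, target_recall)
    c = confusion_at(scores, labels, t)
    acc, sn, sp, mcc = balanced_metrics(c)
    precision, recall, f1, fpc = imbalanced_metrics(c)
    curve = pr_curve_and_aupr(scores, labels)
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc, precision=precision,
                         recall=recall, f1=f1, fp_per_correct=fpc,
                         aupr=curve.auc, threshold=t,
                         n_pos=c.tp + c.fn, n_neg=c.fp + c.tn)


def report_at_threshold(scores: Mapping[str, float],
                        labels: Mapping[str, int],
                        threshold: float = 0.5) -> MetricsReport:
    """Balanced-style report at a fixed threshold (default 0.5)."""
    c = confusion_at(scores, labels, threshold)
    acc, sn, sp, mcc = balanced_metrics(c)
    precision, recall, f1, fpc = imbalanced_metrics(c)
    aupr = math.nan
    if c.fp + c.tn:
        aupr = pr_curve_and_aupr(scores, labels).auc
    return MetricsReport(acc=acc, sn=sn, sp=sp, mcc=mcc, precision=precision,
                         recall=recall, f1=f1, fp_per_correct=fpc, aupr=aupr,
                         threshold=threshold, n_pos=c.tp + c.fn,
                         n_neg=c.fp + c.tn)


def cross_validate(dataset: LabeledDataset, k: int = 10,
                   variant: VariantSpec | None = None,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   embedder=None,
                   seed: int = 0) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold CV; returns per-fold reports and their unweighted mean.

    On balanced data hard mining is unnecessary, so folds are trained with
    uniform 1:1 per-batch sampling (K = M = 1), which bypasses candidate
    scoring entirely.
    """
    variant = variant or VariantSpec(use_fp=True, use_esm=True,
                                     sampling="uniform")
    if variant.sampling != "uniform":
        variant = VariantSpec(use_fp=variant.use_fp, use_esm=variant.use_esm,
                              sampling="uniform")
    tags = kfold_split(dataset, k=k, seed=seed)
    ds = LabeledDataset(peptides=list(dataset.peptides),
                        labels=list(dataset.labels), split=list(tags))
    fold_reports: list[MetricsReport] = []
    for fold in range(k):
        test = ds.select_split(f"fold-{fold}")
        train = ds.subset([i for i, t in enumerate(tags)
                           if t != f"fold-{fold}"])
        if test.n_positive() == 0 or train.n_positive() == 0:
            raise ValueError(f"fold {fold} has no positives")
        sampler = SamplerConfig(K=1, M=1, seed=seed, mode="uniform")
        model = fit(train, variant, model_cfg=model_cfg, train_cfg=train_cfg,
                    sampler_cfg=sampler, embedder=embedder)
        scores = predict_scores(model, test)
        labels = dict(zip(test.ids, test.labels))
        fold_reports.append(report_at_threshold(scores, labels, 0.5))
    mean = MetricsReport(**{
        name: float(np.mean([getattr(r, name) for r in fold_reports]))
        for name in ("acc", "sn", "sp", "mcc", "precision", "recall", "f1",
                     "fp_per_correct", "aupr", "threshold")
    })
    mean.n_pos = sum(r.n_pos for r in fold_reports)
    mean.n_neg = sum(r.n_neg for r in fold_reports)
    return fold_reports, mean
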