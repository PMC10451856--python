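"""Model evaluation: ROC/AUC with bootstrap confidence intervals, operating
point metrics, and decision curve analysis (DCA).

AUC is the rank statistic (Mann-Whitney U / (n1*n0), ties counted half),
computed by scikit-learn.  The 95% CI comes from a stratified bootstrap
(resampling within each class, 2000 replicates by default); a DeLong-style
analytic CI is intentionally not implemented — the bootstrap is uniform with
the resampling used elsewhere.  The operating point defaults to the Youden
threshold (max sensitivity + specificity - 1) on the evaluated set, with a
fixed-0.5 alternative.

Net benefit at threshold probability p_t:

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t)

with "treat all" and "treat none" (identically zero) reference policies.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve


@dataclasses.dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float


@dataclasses.dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray  # model
    treat_all: np.ndarray
    treat_none: np.ndarray  # identically zero


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to evaluate")
    return scores, labels


def rank_auc_rows(pos_scores: np.ndarray, neg_scores: np.ndarray) -> np.ndarray:
    """Row-wise Mann-Whitney AUC (ties counted half) for stacked instances.

    ``pos_scores``: (B, n1); ``neg_scores``: (B, n0).
    """
    from scipy.stats import rankdata

    n1 = pos_scores.shape[1]
    n0 = neg_scores.shape[1]
    ranks = rankdata(np.concatenate([pos_scores, neg_scores], axis=1), axis=1)
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def bootstrap_auc_ci(
    scores: np.ndarray, labels: np.ndarray, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for AUC, stratified by class (vectorized)."""
    scores, labels = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    stats = rank_auc_rows(
        rng.choice(pos, size=(n_boot, len(pos))), rng.choice(neg, size=(n_boot, len(neg)))
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def roc_auc(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    threshold: float | str = "youden",
) -> RocResult:
    """Rank AUC, stratified-bootstrap 95% CI and operating-point metrics.

    ``threshold``: "youden" picks the Youden-optimal cutpoint on this set;
    a float fixes the cutpoint (scores >= threshold called positive).
    """
    scores, labels = _check_scores_labels(scores, labels)
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    if threshold == "youden":
        cut = float(thr[np.argmax(tpr - fpr)])
    else:
        cut = float(threshold)
    pred = scores >= cut
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    ci_low, ci_high = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return RocResult(
        auc=auc,
        ci_low=min(ci_low, auc),
        ci_high=max(ci_high, auc),
        fpr=fpr,
        tpr=tpr,
        threshold=cut,
        accuracy=(tp + tn) / len(labels),
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
    )


def net_benefit(scores, labels, thresholds: np.ndarray | None = None) -> DcaCurve:
    """Decision-curve net benefit of calling ``scores >= p_t`` positive."""
    scores, labels = _check_scores_labels(scores, labels)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.61, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("threshold probabilities must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = (labels == 1).mean()
    odds = thresholds / (1.0 - thresholds)
    nb = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = scores >= pt
        tp = np.sum(pred & (labels == 1)) / n
        fp = np.sum(pred & (labels == 0)) / n
        nb[i] = tp - fp * odds[i]
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DcaCurve(thresholds, nb, treat_all, np.zeros_like(thresholds))


def compare_models(
    model_scores: Mapping[str, Sequence[float]],
    labels,
    patient_ids: Sequence[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-model AUC (95% CI), accuracy, sensitivity and specificity table.

    All models must be scored on the identical patient set (same order).
    """
    labels = np.asarray(labels, dtype=int)
    lengths = {name: len(s) for name, s in model_scores.items()}
    if len(set(lengths.values()) | {len(labels)}) != 1:
        raise ValueError(f"models evaluated on mismatched patient sets: {lengths}")
    rows = []
    for name, scores in model_scores.items():
        r = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "model": name,
                "auc": round(r.auc, 3),
                "ci_low": round(r.ci_low, 3),
                "ci_high": round(r.ci_high, 3),
                "accuracy": round(r.accuracy, 3),
                "sensitivity": round(r.sensitivity, 3),
                "specificity": round(r.specificity, 3),
            }
        )
    return pd.DataFrame(rows)


def format_report(table: pd.DataFrame) -> str:
    lines = [f"{'Model':<14}{'AUC (95% CI)':<22}{'Acc':>6}{'Sens':>6}{'Spec':>6}"]
    for _, r in table.iterrows():
        ci = f"{r.auc:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
        lines.append(f"{r.model:<14}{ci:<22}{r.accuracy:>6.2f}{r.sensitivity:>6.2f}{r.specificity:>6.2f}")
    return "\n".join(lines)
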