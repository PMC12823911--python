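"""Metrics, uncertainty and report assembly.

Per-class precision/recall/F1 and macro-F1 are computed on predictions
pooled across LOGO folds (each fold holds a single individual and hence
usually a single true class, so per-fold per-class averages would be
degenerate); fold-level accuracy means and SDs are reported separately.

Uncertainty uses percentile bootstraps without bias correction and
nearest-rank percentiles: the population-level interval resamples
subjects (not calls) with replacement — respecting within-individual
correlation — while the per-subject interval resamples that subject's
call outcomes.  Threshold sweeps trade minority-class recall against
false positives on the pooled positive-class probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClassMetrics",
    "BootstrapCI",
    "ThresholdCurve",
    "RegressionReport",
    "confusion_metrics",
    "per_subject_accuracy",
    "subject_bootstrap_ci",
    "within_subject_bootstrap",
    "threshold_sweep",
    "aggregate_importance",
    "regression_metrics",
    "pooled_report",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    macro_f1: float
    per_class: dict  # class -> {precision, recall, f1, support}
    confusion: dict  # (true, pred) -> count

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class,
            "confusion": {f"{t}->{p}": c for (t, p), c in self.confusion.items()},
        }


@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    sd: float
    lower_95: float
    upper_95: float
    n_iterations: int
    level: str  # subject | call

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "lower_95": self.lower_95,
            "upper_95": self.upper_95,
            "n_iterations": self.n_iterations,
            "level": self.level,
        }


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray
    minority_recall: np.ndarray
    majority_recall: np.ndarray
    fpr: np.ndarray
    accuracy: np.ndarray
    minority_f1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "minority_recall": self.minority_recall,
                "majority_recall": self.majority_recall,
                "fpr": self.fpr,
                "accuracy": self.accuracy,
                "minority_f1": self.minority_f1,
            }
        )


@dataclass(frozen=True)
class RegressionReport:
    mae: float
    rmse: float
    r2: float
    per_subject_mae: dict

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "per_subject_mae": self.per_subject_mae,
        }


def confusion_metrics(y_true, y_pred) -> ClassMetrics:
    """Accuracy, per-class precision/recall/F1, macro-F1 and confusion counts.

    Classes never observed in ``y_true`` have undefined recall and are
    excluded from the macro average (logged).  Precision of a class never
    predicted is 0 by convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    if len(y_true) == 0:
        raise ValueError("empty input")
    classes = sorted(set(y_true) | set(y_pred))
    confusion = {
        (t, p): int(np.sum((y_true == t) & (y_pred == p)))
        for t in classes
        for p in classes
    }
    per_class = {}
    f1s = []
    for c in classes:
        tp = confusion[(c, c)]
        fp = sum(confusion[(t, c)] for t in classes if t != c)
        fn = sum(confusion[(c, p)] for p in classes if p != c)
        support = int(np.sum(y_true == c))
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        if support == 0:
            log.info("class %r absent from y_true: excluded from macro-F1", c)
            per_class[c] = {
                "precision": precision,
                "recall": float("nan"),
                "f1": float("nan"),
                "support": 0,
            }
            continue
        recall = tp / (tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0
            else 0.0
        )
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
        f1s.append(f1)
    accuracy = float(np.mean(y_true == y_pred))
    return ClassMetrics(
        accuracy=accuracy,
        macro_f1=float(np.mean(f1s)),
        per_class=per_class,
        confusion=confusion,
    )


def _nearest_rank_ci(samples: np.ndarray) -> tuple[float, float]:
    lo = np.percentile(samples, 2.5, method="inverted_cdf")
    hi = np.percentile(samples, 97.5, method="inverted_cdf")
    return float(lo), float(hi)


def per_subject_accuracy(fold_results) -> dict[str, float]:
    """Subject -> fraction of that subject's calls classified correctly."""
    return {
        fr.held_out_subject: float(np.mean(fr.y_true == fr.y_pred))
        for fr in fold_results
    }


def subject_bootstrap_ci(
    per_subject_acc: dict[str, float], n_iter: int = 10_000, seed: int = 0
) -> BootstrapCI:
    """Percentile CI of mean accuracy, resampling subjects with replacement."""
    accs = np.asarray(list(per_subject_acc.values()), dtype=float)
    if len(accs) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(accs), size=(n_iter, len(accs)))
    stats = accs[idx].mean(axis=1)
    lo, hi = _nearest_rank_ci(stats)
    return BootstrapCI(
        mean=float(stats.mean()),
        sd=float(stats.std(ddof=0)),
        lower_95=lo,
        upper_95=hi,
        n_iterations=n_iter,
        level="subject",
    )


def within_subject_bootstrap(
    call_outcomes, n_iter: int = 10_000, seed: int = 0
) -> BootstrapCI:
    """Percentile CI of one subject's accuracy, resampling its calls."""
    outcomes = np.asarray(call_outcomes, dtype=float)
    if len(outcomes) == 0:
        raise ValueError("empty call outcomes")
    if len(outcomes) == 1:
        log.info("single-call subject: degenerate bootstrap interval")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(outcomes), size=(n_iter, len(outcomes)))
    stats = outcomes[idx].mean(axis=1)
    lo, hi = _nearest_rank_ci(stats)
    return BootstrapCI(
        mean=float(stats.mean()),
        sd=float(stats.std(ddof=0)),
        lower_95=lo,
        upper_95=hi,
        n_iterations=n_iter,
        level="call",
    )


def threshold_sweep(
    prob_positive,
    y_true,
    positive_label,
    grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
) -> ThresholdCurve:
    """Metrics along a decision-threshold grid (positive iff prob >= t).

    The positive label is the minority class; FPR is the fraction of
    majority-class calls labelled positive.  Minority recall and FPR are
    both non-increasing in the threshold by construction.
    """
    prob = np.asarray(prob_positive, dtype=float)
    y_true = np.asarray(y_true)
    grid = np.asarray(grid, dtype=float)
    if np.any(prob < 0) or np.any(prob > 1):
        raise ValueError("probabilities must be in [0, 1]")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("threshold grid must lie inside (0, 1)")
    pos = y_true == positive_label
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    rec_m, rec_M, fpr, acc, f1 = [], [], [], [], []
    for t in grid:
        pred_pos = prob >= t
        tp = int((pred_pos & pos).sum())
        fp = int((pred_pos & ~pos).sum())
        fn = n_pos - tp
        tn = n_neg - fp
        rec_m.append(tp / n_pos if n_pos else float("nan"))
        rec_M.append(tn / n_neg if n_neg else float("nan"))
        fpr.append(fp / n_neg if n_neg else float("nan"))
        acc.append((tp + tn) / len(y_true))
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        r = tp / n_pos if n_pos else 0.0
        f1.append(2 * prec * r / (prec + r) if (prec + r) else 0.0)
    return ThresholdCurve(
        thresholds=grid,
        minority_recall=np.asarray(rec_m),
        majority_recall=np.asarray(rec_M),
        fpr=np.asarray(fpr),
        accuracy=np.asarray(acc),
        minority_f1=np.asarray(f1),
    )


def aggregate_importance(per_fold_importances) -> pd.DataFrame:
    """Mean per-feature importance across folds, renormalized to sum 1.

    Accepts a list of ``{feature: weight}`` dicts (tree-model folds);
    features missing from a fold count as 0 there.  Output is ranked
    descending with stable name tie-breaks, mirroring a
    feature/importance table.
    """
    if not per_fold_importances:
        raise ValueError("no fold importances supplied")
    names = sorted({n for d in per_fold_importances for n in d})
    M = np.array(
        [[d.get(n, 0.0) for n in names] for d in per_fold_importances], dtype=float
    )
    mean = M.mean(axis=0)
    total = mean.sum()
    if total > 0:
        mean = mean / total
    order = np.lexsort((names, -mean))
    return pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "importance": mean[order],
        }
    ).reset_index(drop=True)


def regression_metrics(y_true, y_pred, subjects) -> RegressionReport:
    """Call-level MAE/RMSE/R^2 plus per-subject MAE of subject-mean predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    subjects = np.asarray(subjects)
    if not (len(y_true) == len(y_pred) == len(subjects)):
        raise ValueError("length mismatch")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if len(np.unique(y_true)) < 2:
        raise ValueError("R^2 undefined: fewer than 2 distinct true values")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    per_subject = {}
    for s in np.unique(subjects):
        sel = subjects == s
        per_subject[str(s)] = float(
            abs(y_pred[sel].mean() - y_true[sel].mean())
        )
    return RegressionReport(mae=mae, rmse=rmse, r2=r2, per_subject_mae=per_subject)


def pooled_report(fold_results, cfg=None, bootstrap_seed: int = 0) -> dict:
    """Assemble the JSON-ready evaluation report for one configuration."""
    y_true = np.concatenate([fr.y_true for fr in fold_results])
    y_pred = np.concatenate([fr.y_pred for fr in fold_results])
    metrics = confusion_metrics(y_true, y_pred)
    acc_by_subject = per_subject_accuracy(fold_results)
    boot = subject_bootstrap_ci(acc_by_subject, seed=bootstrap_seed)
    fold_accs = np.asarray(list(acc_by_subject.values()))
    importances = [fr.importance for fr in fold_results if fr.importance]
    report = {
        "config": cfg.to_dict() if cfg is not None else None,
        "pooled_metrics": metrics.to_dict(),
        "fold_accuracy_mean": float(fold_accs.mean()),
        "fold_accuracy_sd": float(fold_accs.std(ddof=0)),
        "per_subject_accuracy": acc_by_subject,
        "bootstrap": boot.to_dict(),
        "n_folds": len(fold_results),
        "n_calls": int(len(y_true)),
    }
    if importances:
        report["importance"] = aggregate_importance(importances).to_dict("records")
    return report
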