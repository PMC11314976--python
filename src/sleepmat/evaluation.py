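"""Subject-grouped cross-validation with summed confusion matrices.

Folds partition *subjects* (never minutes), so every test subject is
unseen during training -- the honest protocol for person-independent
posture detection.  Each round runs all k splits, sums the k confusion
matrices into one, and computes accuracy, macro recall / precision / F1
and one-vs-rest ROC areas; rounds differ only in the fold shuffle and
training seed, and results are reported as mean +- SD across rounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from .s3cnn import PostureCNN

log = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    assignments: dict          # subject_id -> fold index
    k: int
    seed: int

    def fold_of(self, subject_ids) -> np.ndarray:
        return np.array([self.assignments[s] for s in subject_ids])


def grouped_kfold(subject_ids, k: int = 10, seed: int = 0) -> FoldPlan:
    """Balanced random partition of subjects into k folds."""
    uniq = np.unique(np.asarray(subject_ids))
    if uniq.size < k:
        raise ValueError(f"need at least {k} subjects for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    assignments = {s: i % k for i, s in enumerate(order)}
    return FoldPlan(assignments, k, seed)


def confusion_matrix_3(y_true_idx, y_pred_idx, n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true_idx, y_pred_idx), 1)
    return cm


def compute_metrics(confusion: np.ndarray, scores: np.ndarray | None = None,
                    y_true_idx: np.ndarray | None = None) -> dict:
    """Accuracy and macro recall / precision / F1 from a summed confusion
    matrix; one-vs-rest ROC areas when per-sample scores are supplied.

    A class absent from the evaluated samples has undefined recall; it is
    reported as 0 with a warning so macro averages stay defined.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    acc = confusion.trace() / total if total else 0.0
    recalls, precisions, f1s = [], [], []
    for i in range(confusion.shape[0]):
        row, col = confusion[i].sum(), confusion[:, i].sum()
        if row == 0:
            warnings.warn(f"class {i} has no evaluated samples; recall set to 0")
        rec = confusion[i, i] / row if row else 0.0
        pre = confusion[i, i] / col if col else 0.0
        recalls.append(rec)
        precisions.append(pre)
        f1s.append(2 * pre * rec / (pre + rec) if (pre + rec) else 0.0)
    out = {
        "accuracy": float(acc),
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "f1": float(np.mean(f1s)),
        "per_class_recall": [float(r) for r in recalls],
        "per_class_precision": [float(p) for p in precisions],
    }
    if scores is not None and y_true_idx is not None:
        aucs = []
        for i in range(confusion.shape[0]):
            y_bin = (np.asarray(y_true_idx) == i).astype(int)
            if 0 < y_bin.sum() < y_bin.size:
                aucs.append(float(roc_auc_score(y_bin, scores[:, i])))
            else:
                aucs.append(float("nan"))
        out["per_class_auc"] = aucs
        out["auc"] = float(np.nanmean(aucs))
    return out


@dataclass
class CVReport:
    classes: list
    round_confusions: list = field(default_factory=list)   # summed per round
    round_metrics: list = field(default_factory=list)

    def summary(self) -> dict:
        keys = ("accuracy", "recall", "precision", "f1", "auc")
        out = {}
        for key in keys:
            vals = [m[key] for m in self.round_metrics if key in m]
            if vals:
                out[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        return out

    @property
    def total_confusion(self) -> np.ndarray:
        return np.sum(self.round_confusions, axis=0)


def _default_factory(seed: int, **kw) -> PostureCNN:
    return PostureCNN(random_state=seed, **kw)


def run_cv(X, y, groups, k: int = 10, rounds: int = 3, seed: int = 0,
           estimator=None, estimator_kwargs=None, max_retries: int = 10) -> CVReport:
    """Three-round subject-grouped k-fold CV of the posture classifier.

    ``X`` is the packed feature matrix, ``y`` posture labels, ``groups``
    subject ids.  If a split's training set misses a class, the round's
    fold plan is reshuffled (logged) and the round restarts -- mirroring
    how degenerate splits have to be handled when subjects sleep in few
    postures.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    groups = np.asarray(groups)
    classes = np.unique(y)
    report = CVReport(classes=list(classes))
    cls_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([cls_idx[c] for c in y])

    for r in range(rounds):
        plan_seed = seed + 1000 * r
        for attempt in range(max_retries):
            plan = grouped_kfold(groups, k=k, seed=plan_seed + attempt)
            folds = plan.fold_of(groups)
            ok = all(len(np.unique(y[folds != f])) == len(classes)
                     for f in range(k))
            if ok:
                if attempt:
                    log.warning("round %d: reshuffled fold plan %d time(s) to "
                                "cover all classes", r, attempt)
                break
        else:
            raise RuntimeError("could not build a fold plan covering all classes")

        cm = np.zeros((len(classes), len(classes)), dtype=int)
        all_scores = np.zeros((len(y), len(classes)))
        for f in range(k):
            train, test = folds != f, folds == f
            if estimator is not None:
                est = clone(estimator)
                if hasattr(est, "random_state"):
                    est.random_state = seed + 97 * r + f
            else:
                est = _default_factory(seed + 97 * r + f,
                                       **(estimator_kwargs or {}))
            est.fit(X[train], y[train])
            probs = est.predict_proba(X[test])
            # align estimator class order with the report's class order
            order = [list(est.classes_).index(c) for c in classes]
            probs = probs[:, order]
            all_scores[test] = probs
            pred_idx = probs.argmax(axis=1)
            cm += confusion_matrix_3(y_idx[test], pred_idx, len(classes))
        report.round_confusions.append(cm)
        report.round_metrics.append(compute_metrics(cm, all_scores, y_idx))
    return report


ABLATION_VARIANTS = ("temporal", "spatial", "combined")


def run_ablation(X, y, groups, k: int = 10, rounds: int = 1, seed: int = 0,
                 estimator_kwargs=None) -> dict:
    """CV per branch variant: temporal-only, spatial-only, combined."""
    out = {}
    for variant in ABLATION_VARIANTS:
        kw = dict(estimator_kwargs or {})
        kw["branches"] = variant
        out[variant] = run_cv(X, y, groups, k=k, rounds=rounds, seed=seed,
                              estimator_kwargs=kw)
    return out
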