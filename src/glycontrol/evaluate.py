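"""Metrics, bootstrap confidence intervals, and the rolling-origin protocol.

ROC-AUC uses the Mann-Whitney formulation (probability that a random
positive outscores a random negative, ties counted half).  PR-AUC uses
step-wise interpolation over distinct thresholds (no linear interpolation,
which is optimistically biased for PR curves).  Both are implemented
directly so they can be checked against brute-force enumeration; the test
suite also cross-checks them against scikit-learn.

Rolling-origin evaluation slides a one-year test window forward: for each
test year y, the model is trained on instances referenced in year y-1 and
evaluated on instances referenced in year y, so every training input
precedes every test outcome window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone

from .preprocess import (
    LabeledInstance,
    build_instances,
    instances_to_xy,
    make_rolling_splits,
)

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "pr_auc",
    "accuracy_at",
    "f1_at",
    "bootstrap_ci",
    "evaluate_scores",
    "lightgbm_comparator",
    "audit_no_leakage",
    "run_rolling_origin",
    "history_length_sweep",
    "RollingOriginResult",
]


def _check_both_classes(labels):
    labels = np.asarray(labels).astype(int).ravel()
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("metric undefined: both classes must be present")
    return labels


def roc_auc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie), via average ranks."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = _check_both_classes(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under precision-recall with step interpolation:
    sum over thresholds of (recall step) * precision."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC undefined without positive labels")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied score block
    last_of_block = np.r_[s[1:] != s[:-1], True]
    precision = tp[last_of_block] / pred_pos[last_of_block]
    recall = tp[last_of_block] / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def accuracy_at(scores, labels, threshold: float) -> float:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    pred = (scores >= threshold).astype(int)
    return float((pred == labels).mean())


def f1_at(scores, labels, threshold: float) -> float:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    denom = int(pred.sum()) + int(labels.sum())
    return 2.0 * tp / denom if denom else 0.0


def bootstrap_ci(metric_fn, scores, labels, n_boot: int = 1000, seed: int = 0,
                 max_redraw: int = 100):
    """Percentile (2.5th, 97.5th) interval over record-level resamples.

    Resamples on which the metric is undefined (e.g. a single class) are
    redrawn; if more than half of the replicates fail even after redraws,
    the interval is refused.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    rng = np.random.default_rng(seed)
    stats = []
    n_failed = 0
    for _ in range(n_boot):
        for attempt in range(max_redraw):
            idx = rng.integers(0, len(scores), size=len(scores))
            try:
                stats.append(metric_fn(scores[idx], labels[idx]))
                break
            except ValueError:
                continue
        else:
            n_failed += 1
    if n_failed > 0.5 * n_boot:
        raise ValueError("metric undefined on more than half of the bootstrap resamples")
    if n_failed:
        warnings.warn(f"{n_failed} bootstrap resamples dropped (metric undefined)", stacklevel=2)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    roc_auc: float
    pr_auc: float
    accuracy: float
    f1: float
    ci95: dict = field(default_factory=dict)
    n_records: int = 0
    n_positive: int = 0
    test_year: int | None = None
    history_years: int | None = None
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_records": self.n_records,
            "n_positive": self.n_positive,
            "test_year": self.test_year,
            "history_years": self.history_years,
            "threshold": self.threshold,
        }


def evaluate_scores(scores, labels, threshold: float, n_boot: int = 1000, seed: int = 0,
                    test_year=None, history_years=None) -> EvaluationReport:
    """Point estimates and bootstrap 95% CIs for the four study metrics."""
    labels = _check_both_classes(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    metrics = {
        "roc_auc": roc_auc,
        "pr_auc": pr_auc,
        "accuracy": lambda s, l: accuracy_at(s, l, threshold),
        "f1": lambda s, l: f1_at(s, l, threshold),
    }
    ci = {
        name: bootstrap_ci(fn, scores, labels, n_boot=n_boot, seed=seed + i)
        for i, (name, fn) in enumerate(metrics.items())
    }
    return EvaluationReport(
        roc_auc=roc_auc(scores, labels),
        pr_auc=pr_auc(scores, labels),
        accuracy=accuracy_at(scores, labels, threshold),
        f1=f1_at(scores, labels, threshold),
        ci95=ci,
        n_records=len(labels),
        n_positive=int(labels.sum()),
        test_year=test_year,
        history_years=history_years,
        threshold=threshold,
    )


def lightgbm_comparator(X_train, y_train, X_test, seed: int = 0, n_estimators: int = 200):
    """Reference gradient-boosted tree on the same weekly grid.

    LightGBM consumes the grid as equally spaced features with NaN at
    missing weeks handled natively (its usual missing-value routing), which
    is the standard way such a model ingests these data.
    """
    import lightgbm as lgb

    clf = lgb.LGBMClassifier(
        n_estimators=n_estimators, random_state=seed, verbose=-1, n_jobs=1
    )
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train).astype(int))
    return clf.predict_proba(np.asarray(X_test, dtype=float))[:, 1]


def audit_no_leakage(train_instances: list[LabeledInstance], test_instances: list[LabeledInstance]) -> None:
    """Assert the temporal contract of a rolling-origin split: every
    training input window (which ends at its reference date) precedes every
    test outcome window."""
    max_train_ref = max(i.series.reference_date for i in train_instances)
    min_test_outcome_start = min(
        i.series.reference_date + timedelta(days=1) for i in test_instances
    )
    if not max_train_ref < min_test_outcome_start:
        raise ValueError(
            "temporal leakage: a training input window ends at "
            f"{max_train_ref}, after a test outcome window starting "
            f"{min_test_outcome_start}"
        )


@dataclass
class RollingOriginResult:
    reports: list
    pooled: EvaluationReport
    yearly_mean: dict


def run_rolling_origin(
    cohort: pd.DataFrame,
    estimator,
    history_years: int,
    first_test_year: int,
    last_test_year: int,
    seed: int = 0,
    n_boot: int = 200,
    comparator: bool = False,
) -> RollingOriginResult:
    """Train/test across sliding one-year windows.

    For each test year y: build instances (train refs in y-1, test refs in
    y), fit a clone of ``estimator``, select the F1 threshold on training
    scores, and report metrics with bootstrap CIs on year y.  Years whose
    test set contains a single class are skipped with a warning.  The
    pooled report concatenates per-year scores and decisions.
    """
    reports = []
    pooled_scores, pooled_labels, pooled_pred = [], [], []
    for k, split in enumerate(make_rolling_splits(first_test_year, last_test_year)):
        train = build_instances(cohort, split.train_reference_year, history_years)
        test = build_instances(cohort, split.test_reference_year, history_years)
        if not train or not test:
            warnings.warn(f"split {split}: no instances; skipped", stacklevel=2)
            continue
        Xtr, ytr = instances_to_xy(train)
        Xte, yte = instances_to_xy(test)
        if len(np.unique(yte)) < 2 or len(np.unique(ytr)) < 2:
            warnings.warn(
                f"test year {split.test_reference_year}: single-class data; skipped",
                stacklevel=2,
            )
            continue
        audit_no_leakage(train, test)
        est = clone(estimator)
        est.set_params(random_state=(seed + 13 * k) % (2**31))
        est.fit(Xtr, ytr)
        scores = est.predict_proba(Xte)[:, 1]
        thr = est.threshold_.value
        rep = evaluate_scores(
            scores, yte, thr, n_boot=n_boot, seed=seed + k,
            test_year=split.test_reference_year, history_years=history_years,
        )
        if comparator:
            comp_scores = lightgbm_comparator(Xtr, ytr, Xte, seed=seed + k)
            rep.ci95["comparator_roc_auc"] = bootstrap_ci(
                roc_auc, comp_scores, yte, n_boot=n_boot, seed=seed + 91 + k
            )
        reports.append(rep)
        pooled_scores.append(scores)
        pooled_labels.append(yte)
        pooled_pred.append((scores >= thr).astype(int))

    if not reports:
        raise ValueError("no evaluable splits in the requested year range")
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pred = np.concatenate(pooled_pred)
    pooled = EvaluationReport(
        roc_auc=roc_auc(scores, labels),
        pr_auc=pr_auc(scores, labels),
        accuracy=float((pred == labels).mean()),
        f1=f1_at(np.where(pred == 1, 1.0, 0.0), labels, 0.5),
        n_records=len(labels),
        n_positive=int(labels.sum()),
        history_years=history_years,
    )
    yearly_mean = {
        m: float(np.mean([getattr(r, m) for r in reports]))
        for m in ("roc_auc", "pr_auc", "accuracy", "f1")
    }
    return RollingOriginResult(reports, pooled, yearly_mean)


def history_length_sweep(
    cohort: pd.DataFrame,
    estimator,
    n_values,
    test_year: int,
    seed: int = 0,
    n_boot: int = 200,
) -> dict[int, EvaluationReport]:
    """One report per history length N, on the same test reference year."""
    cohort = cohort.copy()
    cohort["date"] = pd.to_datetime(cohort["date"])
    first = int(cohort["date"].dt.year.min())
    max_n = max(n_values)
    required_first = test_year - 1 - max_n
    if first > required_first:
        raise ValueError(
            f"cohort starts in {first}; history sweep to N={max_n} with test year "
            f"{test_year} requires data from {required_first}"
        )
    out = {}
    for n in n_values:
        res = run_rolling_origin(
            cohort, estimator, history_years=n,
            first_test_year=test_year, last_test_year=test_year,
            seed=seed, n_boot=n_boot,
        )
        out[n] = res.reports[0]
    return out
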