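"""SVM screening evaluation: leave-one-out cross-validation and subset search.

Each leave-one-out fold standardizes the features with training-fold
statistics only, fits an SVM (linear kernel, C = 1 by default) on the
remaining n-1 subjects and predicts the held-out one; accuracy,
sensitivity and specificity aggregate over all n held-out predictions with
the patient group (MD) as the positive class.

Two metric conventions are supported.  ``standard`` is the textbook one
(Sens = TP/(TP+FN), Spec = TN/(TN+FP)); ``predictive_value`` fills the
Sens/Spec slots with the predictive values (PPV = TP/(TP+FP),
NPV = TN/(TN+FN)), which is how some screening reports tabulate them.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .config import ClassifierConfig
from .features import FEATURE_NAMES
from .stats import SignificanceGroups

__all__ = [
    "EvalResult",
    "compute_metrics",
    "loocv_evaluate",
    "exhaustive_subset_search",
    "evaluate_significance_groups",
    "best_per_size_frame",
]

CONVENTIONS = ("standard", "predictive_value")


def compute_metrics(
    tp: int, fn: int, fp: int, tn: int, convention: str = "standard"
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity-slot, specificity-slot) in percent.

    Undefined ratios (zero denominator) come out as NaN.
    """
    if min(tp, fn, fp, tn) < 0 or tp + fn + fp + tn == 0:
        raise ValueError("invalid confusion counts")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown metric convention: {convention!r}")
    total = tp + fn + fp + tn
    acc = 100.0 * (tp + tn) / total
    if convention == "standard":
        sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    else:
        sens = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        spec = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
    return acc, sens, spec


@dataclass(frozen=True)
class EvalResult:
    """LOOCV outcome for one feature subset."""

    subset: Tuple[str, ...]
    tp: int
    fn: int
    fp: int
    tn: int
    predictions: Tuple[Tuple[str, str, str], ...]  # (subject_id, truth, predicted)
    convention: str = "standard"
    skipped_folds: int = 0

    def metrics(self, convention: Optional[str] = None) -> Tuple[float, float, float]:
        return compute_metrics(
            self.tp, self.fn, self.fp, self.tn, convention or self.convention
        )

    @property
    def accuracy(self) -> float:
        return self.metrics()[0]

    @property
    def sensitivity(self) -> float:
        return self.metrics()[1]

    @property
    def specificity(self) -> float:
        return self.metrics()[2]

    def to_dict(self) -> dict:
        acc, sens, spec = self.metrics()
        return {
            "subset": list(self.subset),
            "size": len(self.subset),
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
            "convention": self.convention,
            "confusion": {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn},
        }


def _validate_table(table: pd.DataFrame, subset: Sequence[str], positive: str):
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise ValueError(f"unknown feature(s): {missing}")
    X = table[list(subset)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite values in selected features")
    y = (table["label"] == positive).to_numpy()
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")
    ids = (
        table["subject_id"].astype(str).to_numpy()
        if "subject_id" in table.columns
        else np.array([str(i) for i in range(len(table))])
    )
    return X, y, ids


def loocv_evaluate(
    table: pd.DataFrame,
    subset: Sequence[str],
    config: Optional[ClassifierConfig] = None,
    convention: Optional[str] = None,
) -> EvalResult:
    """Leave-one-out SVM evaluation of one feature subset.

    ``table`` needs ``label`` (and optionally ``subject_id``) columns plus
    the feature columns.  Deterministic: fixed table + config give
    bit-identical results.
    """
    cfg = config or ClassifierConfig()
    X, y, ids = _validate_table(table, subset, cfg.positive_label)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    tp = fn = fp = tn = 0
    skipped = 0
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if ytr.all() or not ytr.any():
            skipped += 1
            warnings.warn("single-class training fold skipped", RuntimeWarning)
            continue
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma)
        clf.fit((Xtr - mu) / sd, ytr)
        pred = bool(clf.predict(((X[i] - mu) / sd).reshape(1, -1))[0])
        truth = bool(y[i])
        if truth and pred:
            tp += 1
        elif truth and not pred:
            fn += 1
        elif not truth and pred:
            fp += 1
        else:
            tn += 1
        preds.append(
            (
                ids[i],
                cfg.positive_label if truth else "non-" + cfg.positive_label,
                cfg.positive_label if pred else "non-" + cfg.positive_label,
            )
        )
    return EvalResult(
        subset=tuple(subset),
        tp=tp, fn=fn, fp=fp, tn=tn,
        predictions=tuple(preds),
        convention=convention or cfg.convention,
        skipped_folds=skipped,
    )


@dataclass(frozen=True)
class SearchResult:
    best_per_size: Tuple[EvalResult, ...]
    n_evaluated: int
    all_results: Optional[pd.DataFrame] = None


def exhaustive_subset_search(
    table: pd.DataFrame,
    config: Optional[ClassifierConfig] = None,
    features: Optional[Sequence[str]] = None,
    keep_all: bool = False,
) -> SearchResult:
    """Evaluate every non-empty feature subset; report the best per size.

    Ties at a size break toward the earliest subset in lexicographic
    feature order (the enumeration order).  Best-per-size accuracy is kept
    as measured, without any monotonicity adjustment across sizes.
    """
    cfg = config or ClassifierConfig()
    feats = list(features) if features is not None else [
        f for f in FEATURE_NAMES if f in table.columns
    ]
    if len(feats) > 20:
        raise ValueError("subset enumeration limited to 20 features")
    best: List[Optional[EvalResult]] = [None] * len(feats)
    rows = []
    n_eval = 0
    for size in range(1, len(feats) + 1):
        for combo in itertools.combinations(feats, size):
            res = loocv_evaluate(table, combo, cfg)
            n_eval += 1
            cur = best[size - 1]
            if cur is None or res.accuracy > cur.accuracy:
                best[size - 1] = res
            if keep_all:
                acc, sens, spec = res.metrics()
                rows.append(
                    {"subset": "-".join(combo), "size": size,
                     "accuracy": acc, "sensitivity": sens, "specificity": spec}
                )
    return SearchResult(
        best_per_size=tuple(r for r in best if r is not None),
        n_evaluated=n_eval,
        all_results=pd.DataFrame(rows) if keep_all else None,
    )


def best_per_size_frame(result: SearchResult, convention: Optional[str] = None) -> pd.DataFrame:
    rows = []
    for res in result.best_per_size:
        acc, sens, spec = res.metrics(convention)
        rows.append(
            {"size": len(res.subset), "subset": "-".join(res.subset),
             "accuracy": acc, "sensitivity": sens, "specificity": spec}
        )
    return pd.DataFrame(rows)


def evaluate_significance_groups(
    table: pd.DataFrame,
    groups: SignificanceGroups,
    config: Optional[ClassifierConfig] = None,
) -> Dict[str, Optional[EvalResult]]:
    """LOOCV for the seven tier combinations (SIG ... SIG-PSIG-NSIG).

    Combinations whose tier union is empty map to None.
    """
    out: Dict[str, Optional[EvalResult]] = {}
    for name, feats in groups.combos().items():
        out[name] = loocv_evaluate(table, feats, config) if feats else None
    return out
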