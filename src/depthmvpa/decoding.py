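"""Linear-SVM near/far decoding with leave-one-run-out cross-validation.

Training uses only patterns from the highest-signal condition (or a caller
supplied level); test patterns from the held-out run are evaluated at every
level.  The soft-margin penalty follows the convention
``C = n_folds / sum_i ||x_i||^2`` computed on the training patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .preprocess import PatternSet

__all__ = ["LinearDecisionRule", "DecodingResult", "svm_cost", "train_linear_svm", "run_locv"]

_SOLVER_TOL = 1e-6


@dataclass
class LinearDecisionRule:
    """Affine decision rule: predict classes[1] when w.x + b > 0."""

    weights: np.ndarray
    bias: float
    classes: np.ndarray  # sorted ascending; classes[0] is the tie-break winner

    def score(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        s = self.score(X)
        # exact zero resolves to the lexicographically first class
        return np.where(s > 0, self.classes[1], self.classes[0])


@dataclass
class DecodingResult:
    """Per-level accuracies from leave-one-run-out cross-validation."""

    accuracy_by_level: dict[float, float]
    per_fold: pd.DataFrame          # rows: folds (held-out run id), cols: levels
    n_train: int
    n_test_per_level: int
    costs: list[float]
    train_level: float
    cost_mode: str

    @property
    def cost(self) -> float:
        return float(np.mean(self.costs))

    def to_tsv(self, path: str | Path) -> None:
        df = self.per_fold.copy()
        df.loc["mean"] = df.mean(axis=0)
        df.index.name = "fold"
        df.to_csv(path, sep="\t", float_format="%.8g")

    def metadata(self) -> dict:
        return {
            "train_level": self.train_level,
            "n_folds": len(self.per_fold),
            "n_train": self.n_train,
            "n_test_per_level": self.n_test_per_level,
            "cost_mean": self.cost,
            "cost_mode": self.cost_mode,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=1))


def svm_cost(train_patterns, n_folds: int, mode: str = "folds_over_sumsq") -> float:
    """Penalty parameter from the training data.

    ``folds_over_sumsq`` (default): C = n_folds / sum of squared entries.
    ``inverse_product``: C = 1 / (sum of squares * n_folds).
    """
    X = np.asarray(train_patterns, dtype=float)
    if X.size == 0:
        raise ValueError("no training patterns")
    total = float(np.sum(X**2))
    if total == 0:
        raise ValueError("all-zero training data: cost parameter undefined")
    if mode == "folds_over_sumsq":
        return n_folds / total
    if mode == "inverse_product":
        return 1.0 / (total * n_folds)
    raise ValueError(f"unknown cost mode {mode!r}")


def train_linear_svm(patterns, labels, C: float) -> LinearDecisionRule:
    """Fit a soft-margin linear SVM and return its affine decision rule."""
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes in the training set, got {len(classes)}")
    svc = SVC(kernel="linear", C=C, tol=_SOLVER_TOL, shrinking=False)
    svc.fit(X, y)
    return LinearDecisionRule(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        classes=classes,
    )


def _check_locv_inputs(ps: PatternSet, train_level: float | None):
    levels = np.unique(ps.levels)
    runs = np.unique(ps.run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    if train_level is None:
        train_level = float(levels.max())
    for run in runs:
        in_run = ps.run_ids == run
        for lv in levels:
            if not np.any(in_run & (ps.levels == lv)):
                raise ValueError(f"run {run} is missing level {lv:g}")
        at_train = in_run & (ps.levels == train_level)
        if len(np.unique(ps.signs[at_train])) != 2:
            raise ValueError(f"run {run} lacks both signs at the training level")
    return float(train_level), levels, runs


def run_locv(
    ps: PatternSet,
    train_level: float | None = None,
    cost_mode: str = "folds_over_sumsq",
) -> DecodingResult:
    """Leave-one-run-out decoding: train at ``train_level`` (default: the
    highest level), test the held-out run at every level.

    Chance for the balanced near/far problem is 0.5.
    """
    train_level, levels, runs = _check_locv_inputs(ps, train_level)
    n_folds = len(runs)
    rows = []
    costs = []
    n_train = n_test = 0
    for run in runs:
        tr_mask = (ps.run_ids != run) & (ps.levels == train_level)
        X, y = ps.patterns[tr_mask], ps.signs[tr_mask]
        C = svm_cost(X, n_folds, mode=cost_mode)
        rule = train_linear_svm(X, y, C)
        costs.append(C)
        n_train = int(tr_mask.sum())
        accs = {}
        for lv in levels:
            te_mask = (ps.run_ids == run) & (ps.levels == lv)
            pred = rule.predict(ps.patterns[te_mask])
            accs[float(lv)] = float(np.mean(pred == ps.signs[te_mask]))
            n_test = int(te_mask.sum())
        rows.append(pd.Series(accs, name=int(run)))
    per_fold = pd.DataFrame(rows)
    per_fold.index.name = "fold"
    return DecodingResult(
        accuracy_by_level={float(lv): float(per_fold[lv].mean()) for lv in per_fold.columns},
        per_fold=per_fold,
        n_train=n_train,
        n_test_per_level=n_test,
        costs=costs,
        train_level=train_level,
        cost_mode=cost_mode,
    )
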