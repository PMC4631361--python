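"""Permutation null distributions for decoding accuracy.

Per iteration, the training labels inside each leave-one-run-out training
set are shuffled (test labels untouched), the full cross-validation runs,
and the mean accuracy at the training level is recorded.  Centiles use the
nearest-rank (ceiling) rule; the 32nd-68th centile interval serves as the
chance band anchoring fMR-metric lower asymptotes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .decoding import _SOLVER_TOL, svm_cost
from .preprocess import PatternSet

__all__ = ["NullDistribution", "permutation_null", "centile", "chance_band", "significance_threshold"]


@dataclass
class NullDistribution:
    """Mean cross-validated accuracies under shuffled training labels."""

    accuracies: np.ndarray
    n_iter: int
    seed: int
    train_level: float | None = None

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if len(self.accuracies) != self.n_iter:
            raise ValueError("length must equal n_iter")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.accuracies, fmt="%.8g", header="accuracy", comments="")
        meta = {"n_iter": self.n_iter, "seed": self.seed, "train_level": self.train_level}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def permutation_null(
    ps: PatternSet,
    train_level: float | None = None,
    n_iter: int = 999,
    seed: int = 0,
    cost_mode: str = "folds_over_sumsq",
    shuffle_test: bool = False,
) -> NullDistribution:
    """Null distribution of mean LORO accuracy at the training level.

    Only training labels are permuted by default; ``shuffle_test=True``
    additionally permutes the held-out run's labels (sensitivity variant).
    Label permutation preserves class counts, so every iteration trains on
    both classes.  Linear-kernel fits reuse a precomputed per-fold Gram
    matrix, which is exactly equivalent and much faster.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    levels = np.unique(ps.levels)
    if train_level is None:
        train_level = float(levels.max())
    runs = np.unique(ps.run_ids)
    if len(runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    n_folds = len(runs)

    folds = []
    for run in runs:
        tr = (ps.run_ids != run) & (ps.levels == train_level)
        te = (ps.run_ids == run) & (ps.levels == train_level)
        Xtr, ytr = ps.patterns[tr], ps.signs[tr]
        Xte, yte = ps.patterns[te], ps.signs[te]
        C = svm_cost(Xtr, n_folds, mode=cost_mode)
        folds.append((Xtr @ Xtr.T, ytr, Xte @ Xtr.T, yte, C))

    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        fold_acc = np.empty(n_folds)
        for i, (Ktr, ytr, Kte, yte, C) in enumerate(folds):
            yp = rng.permutation(ytr)
            svc = SVC(kernel="precomputed", C=C, tol=_SOLVER_TOL, shrinking=False)
            svc.fit(Ktr, yp)
            pred = svc.predict(Kte)
            yt = rng.permutation(yte) if shuffle_test else yte
            fold_acc[i] = np.mean(pred == yt)
        accs[it] = fold_acc.mean()
    return NullDistribution(accuracies=accs, n_iter=n_iter, seed=seed, train_level=train_level)


def centile(values, q: float) -> float:
    """Nearest-rank (ceiling-rule) percentile of a sample.

    The q-th centile is the ``ceil(q/100 * n)``-th order statistic (at least
    the 1st); q=100 gives the maximum.
    """
    if isinstance(values, NullDistribution):
        values = values.accuracies
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("empty distribution")
    if not 0 <= q <= 100:
        raise ValueError("q must lie in [0, 100]")
    rank = max(1, math.ceil(q / 100.0 * n))
    return float(values[rank - 1])


def chance_band(nd: NullDistribution | np.ndarray) -> tuple[float, float]:
    """32nd-68th centile interval (~ +/- one standard error) of the null."""
    values = nd.accuracies if isinstance(nd, NullDistribution) else np.asarray(nd)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a chance band")
    return centile(values, 32), centile(values, 68)


def significance_threshold(
    nd: NullDistribution | np.ndarray, alpha: float = 0.005
) -> float:
    """One-tailed criterion: the upper ``100*(1-alpha)`` nearest-rank centile.

    The default alpha of 0.005 reproduces a 99.5th-centile cut-off; divide
    alpha by the number of ROIs examined for a Bonferroni-corrected family.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return centile(nd, 100.0 * (1.0 - alpha))


def binomial_null_quantile(n_trials: int, q: float, p: float = 0.5) -> float:
    """Analytic binomial cross-check: accuracy at the q-th centile when each
    of ``n_trials`` test patterns is classified independently at chance."""
    from scipy import stats

    return float(stats.binom.ppf(q / 100.0, n_trials, p) / n_trials)
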