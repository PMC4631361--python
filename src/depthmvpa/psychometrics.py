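"""Cumulative-Gaussian psychometric functions: fitting, thresholds, simulation.

The model is ``psi(s) = guess + (1 - guess - lapse) * Phi((x - mu) / sigma)``
where ``x`` is the stimulus magnitude on a linear or log axis.  Fitting is
binomial maximum likelihood with a bounded quasi-Newton optimizer started
from a deterministic grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricFunction",
    "BehavioralData",
    "fit_psychometric",
    "threshold",
    "simulate_observer",
]


@dataclass
class PsychometricFunction:
    """Cumulative-Gaussian performance curve with guess and lapse asymptotes."""

    mu: float
    sigma: float
    guess: float = 0.5
    lapse: float = 0.0
    axis: str = "linear"
    loglike: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.guess < 1 and 0 <= self.lapse < 1):
            raise ValueError("guess and lapse must lie in [0, 1)")
        if self.guess + self.lapse >= 1:
            raise ValueError("guess + lapse must be < 1")
        if self.axis not in ("linear", "log"):
            raise ValueError("axis must be 'linear' or 'log'")

    def _x(self, levels) -> np.ndarray:
        levels = np.asarray(levels, dtype=float)
        if self.axis == "log":
            if np.any(levels <= 0):
                raise ValueError("log axis requires strictly positive levels")
            return np.log(levels)
        return levels

    def predict(self, levels) -> np.ndarray:
        """Probability correct at each stimulus magnitude."""
        z = (self._x(levels) - self.mu) / self.sigma
        return self.guess + (1.0 - self.guess - self.lapse) * ndtr(z)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mu": self.mu,
                    "sigma": self.sigma,
                    "guess": self.guess,
                    "lapse": self.lapse,
                    "axis": self.axis,
                    "loglike": self.loglike,
                    "degenerate": self.degenerate,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PsychometricFunction":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BehavioralData:
    """Per-level binomial counts of correct responses."""

    levels: np.ndarray
    n_correct: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        self.n_total = np.asarray(self.n_total, dtype=int)
        if not (len(self.levels) == len(self.n_correct) == len(self.n_total)):
            raise ValueError("levels, n_correct, n_total must have equal length")
        if len(np.unique(self.levels)) != len(self.levels):
            raise ValueError("levels must be distinct")
        if np.any(self.levels < 0):
            raise ValueError("levels must be non-negative")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_total):
            raise ValueError("need 0 <= n_correct <= n_total")

    @property
    def proportion(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_total > 0, self.n_correct / self.n_total, np.nan)

    @classmethod
    def from_trials(cls, trial_levels, trial_correct) -> "BehavioralData":
        """Aggregate per-trial (level, correct) pairs into per-level counts."""
        df = pd.DataFrame({"level": trial_levels, "correct": trial_correct})
        agg = df.groupby("level")["correct"].agg(["sum", "count"]).reset_index()
        return cls(agg["level"].to_numpy(), agg["sum"].to_numpy(), agg["count"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"level": self.levels, "n_correct": self.n_correct, "n_total": self.n_total}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BehavioralData":
        df = pd.read_csv(path, sep="\t")
        return cls(df["level"].to_numpy(), df["n_correct"].to_numpy(), df["n_total"].to_numpy())


def _nll(params, x, n_correct, n_total, guess):
    mu, sigma, lapse = params
    psi = guess + (1.0 - guess - lapse) * ndtr((x - mu) / sigma)
    psi = np.clip(psi, 1e-9, 1.0 - 1e-9)
    return -np.sum(n_correct * np.log(psi) + (n_total - n_correct) * np.log1p(-psi))


def fit_psychometric(
    data: BehavioralData,
    guess: float = 0.5,
    lapse_max: float = 0.06,
    fit_lapse: bool = True,
    axis: str = "linear",
    mu_bounds: tuple[float, float] | None = None,
    sigma_bounds: tuple[float, float] | None = None,
    n_starts: int = 5,
) -> PsychometricFunction:
    """Maximum-likelihood cumulative-Gaussian fit.

    The guess rate is fixed (0.5 by default, for a two-alternative judgment);
    the lapse rate is free in ``[0, lapse_max]`` unless ``fit_lapse`` is
    False.  Optimization is L-BFGS-B from an ``n_starts``-squared
    deterministic grid over (mu, sigma); the best likelihood wins.

    Returns the fitted function with ``loglike`` filled in and ``degenerate``
    set when mu or sigma lands on a bound (e.g. all-correct or all-chance
    data).
    """
    usable = data.n_total > 0
    if usable.sum() < 3:
        raise ValueError("need at least 3 levels with observations")
    levels = data.levels[usable]
    nc, nt = data.n_correct[usable], data.n_total[usable]
    if axis == "log":
        if np.any(levels <= 0):
            raise ValueError("log axis requires strictly positive levels")
        x = np.log(levels)
    else:
        x = levels.astype(float)

    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("levels must span a nonzero range")
    if mu_bounds is None:
        mu_bounds = (lo - span, hi + span)
    if sigma_bounds is None:
        sigma_bounds = (span * 1e-3, span * 10.0)
    lapse_hi = lapse_max if fit_lapse else 0.0
    bounds = [mu_bounds, sigma_bounds, (0.0, lapse_hi)]

    best = None
    for mu0 in np.linspace(mu_bounds[0], mu_bounds[1], n_starts):
        for sig0 in np.geomspace(sigma_bounds[0], sigma_bounds[1], n_starts):
            res = minimize(
                _nll,
                [mu0, sig0, min(0.005, lapse_hi)],
                args=(x, nc, nt, guess),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    mu, sigma, lapse = best.x
    eps = 1e-8
    degenerate = (
        mu <= mu_bounds[0] + eps
        or mu >= mu_bounds[1] - eps
        or sigma <= sigma_bounds[0] * (1 + 1e-6)
        or sigma >= sigma_bounds[1] * (1 - 1e-6)
    )
    return PsychometricFunction(
        mu=float(mu),
        sigma=float(sigma),
        guess=guess,
        lapse=float(lapse),
        axis=axis,
        loglike=-float(best.fun),
        degenerate=bool(degenerate),
    )


def threshold(pf: PsychometricFunction, criterion: float = 0.75) -> float:
    """Stimulus magnitude where the fitted curve crosses ``criterion``.

    Solved analytically through the inverse normal; requires
    ``guess < criterion < 1 - lapse``.
    """
    if not (pf.guess < criterion < 1.0 - pf.lapse):
        raise ValueError(
            f"criterion {criterion} outside the attainable range "
            f"({pf.guess}, {1.0 - pf.lapse})"
        )
    p_inner = (criterion - pf.guess) / (1.0 - pf.guess - pf.lapse)
    x = pf.mu + pf.sigma * ndtri(p_inner)
    return float(np.exp(x)) if pf.axis == "log" else float(x)


def simulate_observer(
    pf: PsychometricFunction,
    levels: Sequence[float],
    n_per_level: int,
    seed: int,
) -> BehavioralData:
    """Binomial responses from an observer whose accuracy follows ``pf``."""
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    rng = np.random.default_rng(seed)
    p = pf.predict(levels)
    n_correct = rng.binomial(n_per_level, p)
    return BehavioralData(
        np.asarray(levels, dtype=float),
        n_correct,
        np.full(len(p), n_per_level),
    )
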