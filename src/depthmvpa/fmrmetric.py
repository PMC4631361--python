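"""Fit fMR-metric functions to decoding accuracies and compare them with
behavior.

Two fits are provided: a free cumulative-Gaussian least-squares fit whose
lower asymptote is constrained to the permutation chance band, and a scaled
behavioral fit that carries over the behavioral location and slope and
adjusts only the asymptotes.  Agreement is quantified with the Pearson
correlation between observed accuracies and the scaled-fit predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares, lsq_linear
from scipy.special import ndtr

from .psychometrics import PsychometricFunction

__all__ = [
    "FMRMetricResult",
    "GoodnessOfFit",
    "SlopeEstimate",
    "fit_fmrmetric",
    "scaled_behavioral_fit",
    "goodness_of_fit",
    "saturation_regression",
]

_FLAT_SPAN = 1e-3  # upper - lower below this marks a degenerate (flat) fit


def _model(x, mu, sigma, lower, upper):
    return lower + (upper - lower) * ndtr((x - mu) / sigma)


def _axis_values(levels, axis):
    levels = np.asarray(levels, dtype=float)
    if axis == "log":
        if np.any(levels <= 0):
            raise ValueError("log axis requires strictly positive levels")
        return np.log(levels)
    return levels


def fit_fmrmetric(
    levels,
    accuracies,
    band: tuple[float, float],
    axis: str = "linear",
) -> PsychometricFunction:
    """Least-squares cumulative-Gaussian fit to decoding accuracies.

    The lower asymptote is constrained to the chance ``band``; the upper
    asymptote is free up to 1.  Returns a PsychometricFunction whose guess
    is the fitted lower asymptote and lapse is one minus the fitted upper
    asymptote, with ``degenerate`` set for flat (no-signal) fits.
    """
    y = np.asarray(accuracies, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 levels")
    if not np.all(np.isfinite(y)):
        raise ValueError("accuracies must be finite")
    lo_b, hi_b = float(band[0]), float(band[1])
    if not (0 <= lo_b <= hi_b <= 1):
        raise ValueError("band must satisfy 0 <= low <= high <= 1")
    x = _axis_values(levels, axis)
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError("levels must span a nonzero range")

    # parameters: mu, sigma, lower, span_up (upper = lower + span_up)
    # a degenerate band (lo == hi) still needs strictly ordered solver bounds
    bounds_lo = [x.min() - span, span * 1e-3, lo_b, 0.0]
    bounds_hi = [x.max() + span, span * 10.0, max(hi_b, lo_b + 1e-9), 1.0 - lo_b]

    def resid(p):
        mu, sigma, lower, span_up = p
        upper = min(lower + span_up, 1.0)
        return _model(x, mu, sigma, lower, upper) - y

    lower0 = np.clip(0.5 * (lo_b + hi_b), lo_b, hi_b)
    up0 = np.clip(float(y.max()) - lower0, 1e-3, 1.0 - lo_b)
    best = None
    for mu0 in np.linspace(x.min(), x.max(), 5):
        for sig0 in np.geomspace(span / 10, 2 * span, 4):
            res = least_squares(
                resid,
                [mu0, sig0, lower0, up0],
                bounds=(bounds_lo, bounds_hi),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            if best is None or res.cost < best.cost:
                best = res
    mu, sigma, lower, span_up = best.x
    upper = min(lower + span_up, 1.0)
    # keep guess + lapse strictly < 1 even for flat (degenerate) fits
    upper_pf = max(upper, lower + 1e-9)
    return PsychometricFunction(
        mu=float(mu),
        sigma=float(sigma),
        guess=float(lower),
        lapse=float(np.clip(1.0 - upper_pf, 0.0, 1.0 - lower - 1e-12)),
        axis=axis,
        degenerate=bool(span_up < _FLAT_SPAN),
    )


@dataclass
class GoodnessOfFit:
    r: float
    p: float
    r2: float
    df: int
    low_df: bool = False
    constant_prediction: bool = False


def goodness_of_fit(observed, predicted) -> GoodnessOfFit:
    """Pearson correlation between observed accuracies and model predictions.

    The two-sided p-value comes from the t transform with n-2 degrees of
    freedom.  Constant predictions leave the correlation undefined and are
    flagged instead of raising.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need at least 3 paired points")
    df = len(obs) - 2
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return GoodnessOfFit(np.nan, np.nan, np.nan, df, df < 3, True)
    r, p = stats.pearsonr(obs, pred)
    return GoodnessOfFit(float(r), float(p), float(r**2), df, df < 3, False)


@dataclass
class FMRMetricResult:
    """Free and behavior-scaled fMR-metric fits plus their agreement."""

    free_fit: PsychometricFunction
    scaled_fit: PsychometricFunction
    gof: GoodnessOfFit
    band: tuple[float, float]
    lower: float
    upper: float
    residual_scaled: float
    residual_free: float
    degenerate: bool


def _scaled_lsq(x, y, mu, sigma, band, lower):
    """Least-squares asymptotes given the fixed behavioral shape.

    With Phi fixed the model ``lower*(1-Phi) + upper*Phi`` is linear in the
    asymptotes: bounded linear least squares when the lower asymptote floats
    in the band, a closed-form projection when it is supplied.
    """
    phi = ndtr((x - mu) / sigma)
    if lower is None and band[1] - band[0] < 1e-9:
        lower = band[0]  # degenerate band: the lower asymptote is pinned
    if lower is None:
        A = np.column_stack([1.0 - phi, phi])
        sol = lsq_linear(A, y, bounds=([band[0], band[0]], [band[1], 1.0]))
        lo, up = sol.x
    else:
        lo = float(lower)
        denom = float(np.sum(phi**2))
        up = float(np.sum(phi * (y - lo * (1.0 - phi))) / denom) if denom else lo
        up = float(np.clip(up, lo, 1.0))
    up = max(up, lo)
    resid = _model(x, mu, sigma, lo, up) - y
    return float(lo), float(min(up, 1.0)), float(np.sum(resid**2))


def scaled_behavioral_fit(
    pf_behavior: PsychometricFunction,
    levels,
    accuracies,
    band: tuple[float, float],
    lower: float | None = None,
) -> FMRMetricResult:
    """Scale the behavioral curve onto the decoding accuracies.

    Location and slope are copied from ``pf_behavior``; the lower asymptote
    is constrained to the chance band (or fixed at ``lower`` when given, in
    which case the upper asymptote has a one-dimensional closed form) and the
    upper asymptote is fitted by least squares.
    """
    y = np.asarray(accuracies, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("accuracies must be finite")
    lo_b, hi_b = float(band[0]), float(band[1])
    if not (0 <= lo_b <= hi_b <= 1):
        raise ValueError("band must satisfy 0 <= low <= high <= 1")
    if lower is not None and not (lo_b <= lower <= hi_b):
        raise ValueError("fixed lower asymptote must lie inside the band")
    x = _axis_values(levels, pf_behavior.axis)

    lo, up, sse = _scaled_lsq(x, y, pf_behavior.mu, pf_behavior.sigma, (lo_b, hi_b), lower)
    degenerate = (up - lo) < _FLAT_SPAN
    up_pf = max(up, lo + 1e-9)
    scaled = PsychometricFunction(
        mu=pf_behavior.mu,
        sigma=pf_behavior.sigma,
        guess=lo,
        lapse=float(np.clip(1.0 - up_pf, 0.0, 1.0 - lo - 1e-12)),
        axis=pf_behavior.axis,
        degenerate=degenerate,
    )
    free = fit_fmrmetric(levels, y, (lo_b, hi_b), axis=pf_behavior.axis)
    free_resid = float(np.sum((free.predict(levels) - y) ** 2))
    gof = goodness_of_fit(y, scaled.predict(levels))
    return FMRMetricResult(
        free_fit=free,
        scaled_fit=scaled,
        gof=gof,
        band=(lo_b, hi_b),
        lower=lo,
        upper=up,
        residual_scaled=sse,
        residual_free=free_resid,
        degenerate=degenerate,
    )


@dataclass
class SlopeEstimate:
    slope: float
    ci_low: float
    ci_high: float
    saturated: bool
    exact_fit: bool


def saturation_regression(levels, accuracies, conf: float = 0.95) -> SlopeEstimate:
    """OLS slope of accuracy on stimulus magnitude with a t-based CI.

    The verdict is 'saturated' when the confidence interval covers zero.
    A numerically exact linear fit collapses the interval to a point and is
    flagged, since the usual t interval is undefined at zero residual.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("levels must vary")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    scale = max(np.ptp(y), 1.0)
    exact = bool(np.sum((y - fitted) ** 2) <= (1e-12 * scale) ** 2 * len(y))
    if exact:
        lo = hi = res.slope
    else:
        tcrit = stats.t.ppf(0.5 + conf / 2.0, len(x) - 2)
        lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    return SlopeEstimate(
        slope=float(res.slope),
        ci_low=float(lo),
        ci_high=float(hi),
        saturated=bool(lo <= 0.0 <= hi),
        exact_fit=exact,
    )
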