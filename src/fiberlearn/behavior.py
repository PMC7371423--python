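"""Outcome classification, d-prime learning curves and sigmoid thresholds."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from fiberlearn.io import TrialTable, ValidationError, expected_outcome

DEFAULT_BIN_SIZE = 50


def sigmoid(t, a, b, c):
    """S(t) = a / (1 + exp(-(t - b)/c)); ``a`` amplitude, ``b`` inflection
    trial, ``c`` steepness in trials.  S(b) = a/2."""
    t = np.asarray(t, dtype=float)
    # guard against overflow for extreme arguments
    z = np.clip((t - b) / c, -500.0, 500.0)
    return a / (1.0 + np.exp(-z))


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    rss: float
    converged: bool
    offset: float = 0.0

    def __call__(self, t) -> np.ndarray:
        return self.offset + sigmoid(t, self.a, self.b, self.c)


@dataclass
class LearningCurve:
    """Binned behavioral performance across the learning run."""

    bin_center_trial: np.ndarray
    dprime: np.ndarray
    hit_rate: np.ndarray
    cr_rate: np.ndarray
    bin_size: int = DEFAULT_BIN_SIZE


def classify_outcomes(table: TrialTable) -> np.ndarray:
    """Outcome per trial from stimulus class and lick evidence:
    go+lick -> hit, go+no-lick -> miss, no-go+lick -> FA, no-go+no-lick -> CR,
    where "lick" means a lick inside the response window (go trials also
    count stimulus-period licks; see :func:`fiberlearn.io.expected_outcome`).
    """
    return np.array(
        [
            expected_outcome(c, lt)
            for c, lt in zip(table.stimulus_class, table.lick_times)
        ]
    )


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Z(hit_rate) - Z(fa_rate) with extreme rates clipped to
    [1/(2n), 1 - 1/(2n)] so the statistic stays finite."""
    if n_go < 1 or n_nogo < 1:
        raise ValidationError("n_go and n_nogo must be >= 1")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValidationError("rates must lie in [0, 1]")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_go), 1.0 - 1.0 / (2 * n_go)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_nogo), 1.0 - 1.0 / (2 * n_nogo)))
    return float(norm.ppf(h) - norm.ppf(f))


def learning_curve(table: TrialTable, bin_size: int = DEFAULT_BIN_SIZE) -> LearningCurve:
    """Non-overlapping consecutive bins of ``bin_size`` trials; per-bin d'
    from bin-local hit/FA rates.  The last partial bin is dropped; a bin
    with zero go or zero no-go trials gets NaN d'."""
    n_bins = table.n_trials // bin_size
    if n_bins < 1:
        return LearningCurve(
            np.array([]), np.array([]), np.array([]), np.array([]), bin_size
        )
    idx = table.trial_index
    outcome = table.outcome
    is_go = np.isin(outcome, ("hit", "miss"))
    is_hit = outcome == "hit"
    is_cr = outcome == "CR"
    is_fa = outcome == "FA"

    centers = np.empty(n_bins)
    dp = np.full(n_bins, np.nan)
    hr = np.full(n_bins, np.nan)
    cr = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = slice(k * bin_size, (k + 1) * bin_size)
        centers[k] = idx[sel].mean()
        n_go = int(is_go[sel].sum())
        n_nogo = bin_size - n_go
        if n_go > 0:
            hr[k] = is_hit[sel].sum() / n_go
        if n_nogo > 0:
            cr[k] = is_cr[sel].sum() / n_nogo
        if n_go > 0 and n_nogo > 0:
            fa = is_fa[sel].sum() / n_nogo
            dp[k] = dprime(hr[k], fa, n_go, n_nogo)
    return LearningCurve(centers, dp, hr, cr, bin_size)


def fit_sigmoid(x, y, with_offset: bool = False) -> SigmoidFit:
    """Deterministic bounded least-squares fit of the learning sigmoid.

    Initialization: a0 = max(y) (signed span with offset), b0 = midpoint of
    x, c0 = span(x)/10.  Bounds: a in [0, 2 max(y)] (or signed span bounds
    with offset), b in [min(x)-span, max(x)+span], c in (0, span].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        raise ValidationError("non-finite y entries; drop them before fitting")
    if len(x) < 4:
        raise ValidationError("need at least 4 points to fit a sigmoid")
    span = float(x.max() - x.min()) or 1.0
    b_lo, b_hi = x.min() - span, x.max() + span
    b0, c0 = float(x.mean()), span / 10.0

    if with_offset:
        amp0 = float(y[-1] - y[0])
        lim = 2.0 * max(float(np.abs(y).max()), 1e-12)
        p0 = [amp0 if amp0 != 0 else 1e-6, b0, c0, float(y[0])]
        bounds = ([-lim, b_lo, 1e-9, -lim], [lim, b_hi, span, lim])
        model = lambda t, a, b, c, d: d + sigmoid(t, a, b, c)
    else:
        a_hi = 2.0 * max(float(y.max()), 1e-12)
        p0 = [min(max(float(y.max()), 1e-12), a_hi), b0, c0]
        bounds = ([0.0, b_lo, 1e-9], [a_hi, b_hi, span])
        model = sigmoid

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        converged = False
    resid = y - model(x, *popt)
    rss = float(np.sum(resid ** 2))
    offset = float(popt[3]) if with_offset else 0.0
    return SigmoidFit(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
        rss=rss, converged=converged, offset=offset,
    )


def learning_threshold(fit: SigmoidFit, criterion: float = 1.0) -> float | None:
    """Smallest t with S(t) >= criterion, in closed form:
    t = b - c * ln(a/criterion - 1) when a > criterion; None otherwise."""
    if fit.a <= criterion:
        return None
    return float(fit.b - fit.c * np.log(fit.a / criterion - 1.0))
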