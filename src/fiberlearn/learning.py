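"""Response curves across learning, their thresholds, and the per-timepoint
correlation between neural response curves and the behavioral learning curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, logit
from scipy.stats import pearsonr, spearmanr

from fiberlearn.behavior import (
    DEFAULT_BIN_SIZE,
    LearningCurve,
    SigmoidFit,
    fit_sigmoid,
)
from fiberlearn.io import PhotometrySession, TrialTable, ValidationError
from fiberlearn.photometry import trial_filter_mask, window_response

#: Late-trial response window (s) used for the canonical response curve.
LATE_WINDOW_S = (0.6, 1.0)
#: Early-trial window (s) used as the control comparison.
EARLY_WINDOW_S = (0.0, 0.3)

#: Fitted amplitudes smaller than this fraction of the data span are
#: treated as flat (threshold undefined).
FLAT_AMPLITUDE_FRACTION = 0.05


@dataclass
class ResponseCurve:
    """Windowed go-trial response per 50-trial bin, with its sigmoid fit."""

    bin_center_trial: np.ndarray
    response: np.ndarray  # NaN where a bin has no go trials
    window_s: tuple[float, float]
    fit: SigmoidFit | None
    normalized_fit: np.ndarray | None  # in [0, 1] over the observed bins
    trial_threshold: float | None  # trial where the normalized fit crosses 0.5


@dataclass
class CorrelationTimecourse:
    time_s: np.ndarray
    r: np.ndarray  # NaN where undefined (zero variance or < 3 aligned bins)


def binned_response(
    session: PhotometrySession,
    table: TrialTable,
    window_s: tuple[float, float],
    bin_size: int = DEFAULT_BIN_SIZE,
    trial_filter: str = "go",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean windowed response over filtered trials -> (centers, values)."""
    if session.n_trials != table.n_trials:
        raise ValidationError("session/table trial count mismatch")
    per_trial = window_response(session, window_s)
    keep = trial_filter_mask(table, trial_filter)
    n_bins = table.n_trials // bin_size
    centers = np.empty(n_bins)
    values = np.full(n_bins, np.nan)
    for k in range(n_bins):
        sel = slice(k * bin_size, (k + 1) * bin_size)
        centers[k] = table.trial_index[sel].mean()
        rows = keep[sel]
        if rows.any():
            values[k] = per_trial[sel][rows].mean()
    return centers, values


def normalized_threshold(fit: SigmoidFit, x0: float, x1: float) -> float | None:
    """Trial where the fit, normalized to [0, 1] over [x0, x1], crosses 0.5.

    For monotone sigmoids of either direction the normalized magnitude of
    change |S(t) - S(x0)| / |S(x1) - S(x0)| crosses 0.5 exactly where the
    bare logistic reaches the midpoint of its endpoint values, which has
    the closed form t = b + c * logit((l0 + l1)/2).
    """
    l0 = float(expit((x0 - fit.b) / fit.c))
    l1 = float(expit((x1 - fit.b) / fit.c))
    mid = 0.5 * (l0 + l1)
    if not (0.0 < mid < 1.0):
        return None
    return float(fit.b + fit.c * logit(mid))


def response_curve(
    session: PhotometrySession,
    table: TrialTable,
    window_s: tuple[float, float] = LATE_WINDOW_S,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> ResponseCurve:
    """Windowed go-trial response per bin, sigmoid-fitted (with an offset
    term so non-zero floors and decreasing curves are representable), with
    the normalized-fit 0.5-crossing trial threshold.

    Flat curves (fitted amplitude below ``FLAT_AMPLITUDE_FRACTION`` of the
    data span) yield an undefined threshold.
    """
    centers, values = binned_response(session, table, window_s, bin_size, "go")
    ok = np.isfinite(values)
    if ok.sum() < 4:
        return ResponseCurve(centers, values, window_s, None, None, None)
    fit = fit_sigmoid(centers[ok], values[ok], with_offset=True)
    x0, x1 = float(centers[ok][0]), float(centers[ok][-1])
    span = float(np.ptp(values[ok]))
    threshold = None
    normalized = None
    if fit.converged and span > 0 and abs(fit.a) >= FLAT_AMPLITUDE_FRACTION * span:
        s = fit(centers)
        s0, s1 = fit(x0), fit(x1)
        if s1 != s0:
            normalized = np.clip((s - s0) / (s1 - s0), 0.0, 1.0)
            threshold = normalized_threshold(fit, x0, x1)
    return ResponseCurve(centers, values, window_s, fit, normalized, threshold)


def correlation_timecourse(
    session: PhotometrySession,
    table: TrialTable,
    learning: LearningCurve,
    method: str = "pearson",
    trial_filter: str = "go",
) -> CorrelationTimecourse:
    """Per-frame correlation between the binned go-trial response at that
    frame and the binned d' curve (no smoothing; bins with missing values
    in either curve are pairwise-deleted; r is NaN with < 3 aligned bins or
    zero variance)."""
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    if session.n_trials != table.n_trials:
        raise ValidationError("session/table trial count mismatch")
    bin_size = learning.bin_size
    n_bins = table.n_trials // bin_size
    if n_bins != len(learning.dprime):
        raise ValidationError("learning curve binning does not match the table")
    keep = trial_filter_mask(table, trial_filter)
    # bin x frame matrix of mean responses over filtered trials
    m = np.full((n_bins, session.n_frames), np.nan)
    for k in range(n_bins):
        sel = np.zeros(table.n_trials, dtype=bool)
        sel[k * bin_size:(k + 1) * bin_size] = True
        rows = sel & keep
        if rows.any():
            m[k] = session.traces[rows].mean(axis=0)

    d = learning.dprime
    r = np.full(session.n_frames, np.nan)
    corr = pearsonr if method == "pearson" else spearmanr
    for j in range(session.n_frames):
        ok = np.isfinite(m[:, j]) & np.isfinite(d)
        if ok.sum() < 3:
            continue
        x, y = m[ok, j], d[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r[j] = corr(x, y)[0]
    return CorrelationTimecourse(session.time_s.copy(), r)


def threshold_concordance(response_thresholds, learning_thresholds) -> float:
    """Pearson r between per-mouse response-curve trial thresholds and
    behavioral learning thresholds (>= 3 defined pairs required)."""
    x = np.asarray(
        [np.nan if v is None else float(v) for v in response_thresholds], dtype=float
    )
    y = np.asarray(
        [np.nan if v is None else float(v) for v in learning_thresholds], dtype=float
    )
    if x.shape != y.shape:
        raise ValidationError("threshold vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValidationError("need >= 3 mice with both thresholds defined")
    return float(pearsonr(x[ok], y[ok])[0])


def gaussian_smooth(curve: np.ndarray, two_sigma: float = 9.0) -> np.ndarray:
    """Gaussian smoothing (2 sigma = 9 bins by default, reflected
    boundaries).  For visualization only — statistics paths never call it."""
    curve = np.asarray(curve, dtype=float)
    if curve.size < 2:
        return curve.copy()
    return gaussian_filter1d(curve, sigma=two_sigma / 2.0, mode="reflect")
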