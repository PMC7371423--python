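"""Time-resolved single-trial discrimination between trial types.

Rank-based ROC/AUC per time frame, a label-shuffle null band (mean ± 3 SD
over 100 shuffles by default), significance latency, and second-derivative
onset estimation for choice and lick-rate traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import rankdata

from fiberlearn.io import PhotometrySession, TrialTable, ValidationError
from fiberlearn.photometry import phase_mask

#: Trial-type pairs: first-named label is class A (AUC > 0.5 means A > B).
PAIRS = {
    "stim": ("hit", "FA"),
    "choice": ("hit", "miss"),
    "alt_stim": ("CR", "miss"),
    "alt_choice": ("FA", "CR"),
}

DEFAULT_N_SHUFFLES = 100
SIGNIFICANCE_SD = 3.0
NULL_SD_FLOOR = 1e-6
ONSET_SMOOTH_FRAMES = 3
#: Frames eligible for the discrimination latency: stimulus onset through
#: stimulus offset.  Restricting to the stimulus period keeps the
#: single-frame 3-SD rule's family-wise false-positive rate low enough that
#: a pure-noise session almost never acquires a spurious latency.
LATENCY_WINDOW_S = (0.0, 1.0)


@dataclass
class AUCTimecourse:
    time_s: np.ndarray
    auc: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_shuffles: int = 0
    significant: np.ndarray | None = None
    latency_s: float | None = None
    pair: str = "choice"
    phase: str = "expert"


def auc(samples_a, samples_b) -> float:
    """Probability that a draw from A exceeds a draw from B, ties counted
    as 1/2 — the rank-statistic identity U_A / (n_A n_B)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both sample sets must be nonempty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _frames_auc(values: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Per-column AUC of rows where is_a vs the rest (vectorized)."""
    ranks = rankdata(values, axis=0)
    n_a = int(is_a.sum())
    n_b = values.shape[0] - n_a
    u = ranks[is_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    return u / (n_a * n_b)


def _pair_selection(table: TrialTable, pair: str, phase: str):
    if pair not in PAIRS:
        raise ValidationError(f"unknown pair {pair!r}; one of {sorted(PAIRS)}")
    lab_a, lab_b = PAIRS[pair]
    pm = phase_mask(table.n_trials, phase)
    sel_a = pm & (table.outcome == lab_a)
    sel_b = pm & (table.outcome == lab_b)
    return sel_a, sel_b


def auc_timecourse(
    session: PhotometrySession, table: TrialTable, pair: str, phase: str
) -> AUCTimecourse:
    """Observed per-frame AUC for a trial-type pair within a phase (no null).

    Requires at least 2 trials per class; otherwise returns an all-NaN
    timecourse with a warning.
    """
    sel_a, sel_b = _pair_selection(table, pair, phase)
    tc = AUCTimecourse(time_s=session.time_s.copy(),
                      auc=np.full(session.n_frames, np.nan),
                      pair=pair, phase=phase)
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        warnings.warn(
            f"pair {pair!r} in phase {phase!r} has a class with < 2 trials; "
            "AUC undefined"
        )
        return tc
    rows = sel_a | sel_b
    values = session.traces[rows]
    is_a = sel_a[rows]
    tc.auc = _frames_auc(values, is_a)
    return tc


def shuffle_null(
    session: PhotometrySession,
    table: TrialTable,
    pair: str,
    phase: str,
    n: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean and SD of the AUC under label permutation.

    The two class labels of the compared pair are permuted among their
    pooled trials (n iterations, seeded); pooled per-frame ranks are
    computed once, so each shuffle only re-sums ranks.
    """
    if n < 2:
        raise ValidationError("need at least 2 shuffle iterations")
    sel_a, sel_b = _pair_selection(table, pair, phase)
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValidationError(f"pair {pair!r} in phase {phase!r}: class too small")
    rows = sel_a | sel_b
    values = session.traces[rows]
    n_a = int(sel_a.sum())
    n_tot = int(rows.sum())
    n_b = n_tot - n_a
    ranks = rankdata(values, axis=0)
    rng = np.random.default_rng(seed)
    nulls = np.empty((n, session.n_frames))
    for i in range(n):
        perm = rng.permutation(n_tot)
        u = ranks[perm[:n_a]].sum(axis=0) - n_a * (n_a + 1) / 2.0
        nulls[i] = u / (n_a * n_b)
    return nulls.mean(axis=0), nulls.std(axis=0)


def significance_latency(
    tc: AUCTimecourse,
    eligible_window_s: tuple[float, float] = LATENCY_WINDOW_S,
) -> float | None:
    """Earliest eligible time where |auc - null_mean| exceeds 3 x null SD
    (SD floored at 1e-6); None when never significant.

    The ``significant`` mask is filled for every frame; only frames inside
    ``eligible_window_s`` (the stimulus period by default — frames before
    stimulus onset are never eligible) can define the latency."""
    if tc.null_mean is None or tc.null_sd is None:
        raise ValidationError("timecourse has no shuffle null")
    sd = np.maximum(tc.null_sd, NULL_SD_FLOOR)
    with np.errstate(invalid="ignore"):
        sig = np.abs(tc.auc - tc.null_mean) > SIGNIFICANCE_SD * sd
    sig &= np.isfinite(tc.auc)
    tc.significant = sig
    lo, hi = eligible_window_s
    lo = max(lo, 0.0)
    eligible = sig & (tc.time_s >= lo) & (tc.time_s <= hi)
    if not eligible.any():
        return None
    return float(tc.time_s[np.argmax(eligible)])


def auc_analysis(
    session: PhotometrySession,
    table: TrialTable,
    pair: str,
    phase: str,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> AUCTimecourse:
    """Full pipeline: observed AUC + shuffle null + significance + latency."""
    tc = auc_timecourse(session, table, pair, phase)
    if np.isnan(tc.auc).all():
        return tc
    tc.null_mean, tc.null_sd = shuffle_null(
        session, table, pair, phase, n=n_shuffles, seed=seed
    )
    tc.n_shuffles = n_shuffles
    tc.latency_s = significance_latency(tc)
    return tc


def trace_onset(trace: np.ndarray, time_s: np.ndarray) -> float | None:
    """Onset = time of the peak of the discrete second derivative, after a
    light 3-frame moving-average smoothing; None for constant traces.

    Only curvature at or before the trace's peak is eligible — an onset
    must precede the response it starts; without this the flattening after
    a transient would masquerade as the onset.  Predominantly negative-going
    traces are sign-flipped first so the onset of a suppression is found
    the same way.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 5:
        raise ValidationError("trace too short for onset estimation")
    if not np.isfinite(trace).all():
        return None
    if np.ptp(trace) == 0.0:
        return None
    smooth = uniform_filter1d(trace, size=ONSET_SMOOTH_FRAMES, mode="nearest")
    dev = smooth - smooth[0]
    if -dev.min() > dev.max():
        smooth = -smooth
    peak = int(np.argmax(smooth))
    d2 = smooth[2:] - 2.0 * smooth[1:-1] + smooth[:-2]
    hi = max(peak - 1, 1)  # d2[j] sits at sample j+1
    seg = d2[:hi]
    # first frame reaching the maximal curvature (tiny tolerance so exact
    # plateaus of constant curvature resolve to their first frame)
    tol = 1e-8 * max(float(np.ptp(smooth)), 1.0)
    j = int(np.argmax(seg >= seg.max() - tol))
    return float(time_s[1:-1][j])


def lick_rate_trace(
    table: TrialTable,
    phase: str,
    time_s: np.ndarray,
    binwidth_s: float | None = None,
) -> np.ndarray:
    """Per-frame lick probability across go trials of a phase.

    Frame t counts trials with >= 1 lick in [t, t + binwidth); smoothed with
    the same 3-frame moving average used before onset estimation.  Returns
    zeros when there are no licks.
    """
    time_s = np.asarray(time_s, dtype=float)
    if binwidth_s is None:
        binwidth_s = float(time_s[1] - time_s[0]) if len(time_s) > 1 else 1.0
    pm = phase_mask(table.n_trials, phase)
    rows = pm & np.isin(table.stimulus_class, ["go"])
    licks = [lt for lt, r in zip(table.lick_times, rows) if r]
    rate = np.zeros(len(time_s))
    if not licks or all(len(lt) == 0 for lt in licks):
        return rate
    for lt in licks:
        if len(lt) == 0:
            continue
        hit = (lt[None, :] >= time_s[:, None]) & (lt[None, :] < time_s[:, None] + binwidth_s)
        rate += hit.any(axis=1)
    rate /= len(licks)
    return uniform_filter1d(rate, size=ONSET_SMOOTH_FRAMES, mode="nearest")
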