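"""Trial normalization, learning maps, phase averages and frequency tuning."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from fiberlearn.behavior import DEFAULT_BIN_SIZE
from fiberlearn.io import PhotometrySession, TrialTable, ValidationError
from fiberlearn.synthetic import PassiveSession

#: Number of trials in the novice (first) and expert (last) learning phases.
PHASE_N_TRIALS = 500

TRIAL_FILTERS = ("go", "no-go", "hit", "miss", "CR", "FA")


def trial_filter_mask(table: TrialTable, trial_filter: str) -> np.ndarray:
    if trial_filter in ("go", "no-go"):
        return table.stimulus_class == trial_filter
    if trial_filter in ("hit", "miss", "CR", "FA"):
        return table.outcome == trial_filter
    raise ValidationError(f"unknown trial filter {trial_filter!r}")


def phase_mask(n_trials: int, phase: str, n_phase: int = PHASE_N_TRIALS) -> np.ndarray:
    """Boolean mask of the novice (first ``n_phase``) or expert (last
    ``n_phase``) trials; warns and uses all trials when the run is shorter."""
    if phase not in ("novice", "expert"):
        raise ValidationError(f"unknown phase {phase!r}")
    if n_trials < n_phase:
        warnings.warn(
            f"run has {n_trials} trials < phase size {n_phase}; using all trials"
        )
        return np.ones(n_trials, dtype=bool)
    m = np.zeros(n_trials, dtype=bool)
    if phase == "novice":
        m[:n_phase] = True
    else:
        m[-n_phase:] = True
    return m


def normalize_trials(session: PhotometrySession, subtract_one: bool = True) -> PhotometrySession:
    """Per-trial baseline division: F0 = mean over the baseline window,
    output = F/F0 - 1 (default dF/F convention) or F/F0.

    Refuses to normalize an already-normalized session; raises when any
    trial has F0 <= 0.
    """
    if session.normalized:
        raise ValidationError("session is already normalized")
    lo, hi = session.baseline_window
    sel = (session.time_s >= lo) & (session.time_s < hi)
    if not sel.any():
        raise ValidationError("baseline window contains no frames")
    f0 = session.traces[:, sel].mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValidationError(f"non-positive baseline F0 at trials {bad.tolist()}")
    traces = session.traces / f0[:, None]
    if subtract_one:
        traces = traces - 1.0
    return replace(session, traces=traces, normalized=True)


@dataclass
class LearningMap:
    """Mean trace per 50-trial bin for one trial type, across learning."""

    values: np.ndarray  # [n_bins, n_frames]; NaN rows = no qualifying trials
    bin_center_trial: np.ndarray
    time_s: np.ndarray
    trial_filter: str


def learning_map(
    session: PhotometrySession,
    table: TrialTable,
    trial_filter: str = "go",
    bin_size: int = DEFAULT_BIN_SIZE,
) -> LearningMap:
    _check_aligned(session, table)
    keep = trial_filter_mask(table, trial_filter)
    n_bins = table.n_trials // bin_size
    values = np.full((n_bins, session.n_frames), np.nan)
    centers = np.empty(n_bins)
    for k in range(n_bins):
        sel = np.zeros(table.n_trials, dtype=bool)
        sel[k * bin_size:(k + 1) * bin_size] = True
        centers[k] = table.trial_index[sel].mean()
        rows = sel & keep
        if rows.any():
            values[k] = session.traces[rows].mean(axis=0)
    return LearningMap(values, centers, session.time_s.copy(), trial_filter)


def phase_average(
    session: PhotometrySession,
    table: TrialTable,
    phase: str,
    by_outcome: bool = True,
) -> dict[str, dict[str, np.ndarray]]:
    """Outcome-wise mean and SEM traces within a learning phase.

    Returns ``{outcome: {"mean": ..., "sem": ..., "n": ...}}``; with
    ``by_outcome=False`` a single entry keyed ``"all"``.
    """
    _check_aligned(session, table)
    pm = phase_mask(table.n_trials, phase)
    groups = ("hit", "miss", "CR", "FA") if by_outcome else ("all",)
    out: dict[str, dict[str, np.ndarray]] = {}
    for g in groups:
        rows = pm if g == "all" else pm & (table.outcome == g)
        n = int(rows.sum())
        if n == 0:
            out[g] = {"mean": np.full(session.n_frames, np.nan),
                      "sem": np.full(session.n_frames, np.nan), "n": 0}
            continue
        sub = session.traces[rows]
        sem = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(
            session.n_frames, np.nan
        )
        out[g] = {"mean": sub.mean(axis=0), "sem": sem, "n": n}
    return out


def window_response(session: PhotometrySession, window_s: tuple[float, float]) -> np.ndarray:
    """Per-trial mean over frames with time in [start, end)."""
    lo, hi = window_s
    sel = (session.time_s >= lo) & (session.time_s < hi)
    if not sel.any():
        raise ValidationError(f"window {window_s} contains no frames")
    return session.traces[:, sel].mean(axis=1)


def choice_trace(
    session: PhotometrySession, table: TrialTable, phase: str
) -> np.ndarray:
    """Hit-mean minus miss-mean trace within a phase (NaN with a warning
    when either class is empty)."""
    avg = phase_average(session, table, phase)
    if avg["hit"]["n"] == 0 or avg["miss"]["n"] == 0:
        warnings.warn(f"phase {phase!r} lacks hit or miss trials; choice trace undefined")
        return np.full(session.n_frames, np.nan)
    return avg["hit"]["mean"] - avg["miss"]["mean"]


@dataclass
class TuningResult:
    freqs_hz: np.ndarray
    attens_db: np.ndarray
    fra: np.ndarray  # [n_atten, n_freq] mean evoked dF/F; NaN = missing combo
    tuning_curve: np.ndarray  # at the lowest attenuation (loudest level)
    best_frequency_hz: float


EVOKED_WINDOW_S = (0.0, 0.1)  # (0, 100 ms] after stimulus onset


def tuning(passive: PassiveSession) -> TuningResult:
    """Frequency-response area from passive presentations.

    Evoked response = mean dF/F over (0, 0.1] s post-onset, averaged per
    (frequency, attenuation); the tuning curve is taken at the lowest
    attenuation and best frequency is its argmax.
    """
    session = passive.session
    if not session.normalized:
        session = normalize_trials(session)
    t = session.time_s
    sel = (t > EVOKED_WINDOW_S[0]) & (t <= EVOKED_WINDOW_S[1])
    if not sel.any():
        raise ValidationError("no frames in the evoked window (0, 0.1] s")
    evoked = session.traces[:, sel].mean(axis=1)
    freqs = np.unique(passive.freq_hz)
    attens = np.unique(passive.atten_db)
    fra = np.full((len(attens), len(freqs)), np.nan)
    for i, a in enumerate(attens):
        for j, f in enumerate(freqs):
            rows = (passive.atten_db == a) & (passive.freq_hz == f)
            if rows.any():
                fra[i, j] = evoked[rows].mean()
    curve = fra[0]  # lowest attenuation = loudest presented level
    best = float(freqs[np.nanargmax(curve)])
    return TuningResult(freqs, attens, fra, curve, best)


def _check_aligned(session: PhotometrySession, table: TrialTable) -> None:
    if session.n_trials != table.n_trials:
        raise ValidationError(
            f"session has {session.n_trials} trials but table has {table.n_trials}"
        )
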