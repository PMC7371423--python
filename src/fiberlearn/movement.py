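"""Video-derived motion energy, movement detection, and movement-free
truncation of photometry trials."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fiberlearn.behavior import DEFAULT_BIN_SIZE
from fiberlearn.io import (
    CUE_TIME_S,
    FrameStack,
    PhotometrySession,
    TrialTable,
    ValidationError,
)
from fiberlearn.photometry import trial_filter_mask

#: Movement onset is placed this long before the first threshold crossing.
ONSET_LEAD_S = 0.2
THRESHOLD_SD = 3.0
SD_FLOOR = 1e-9

#: Scalar summary windows, half-open (lo, hi].
SUMMARY_WINDOWS_S = {
    "pre_stimulus": (-1.0, 0.0),
    "stimulus": (0.0, 1.0),
    "late": (0.6, 1.0),
}


@dataclass
class MovementTrace:
    """Per-trial motion energy with its binary moving/quiet vector."""

    time_s: np.ndarray
    energy: np.ndarray
    binary: np.ndarray  # True = moving
    threshold: float
    onset_s: float | None  # first crossing - ONSET_LEAD_S, None when quiet
    roi: str


@dataclass
class MovementMap:
    probability: np.ndarray  # [n_bins, n_frames] fraction of trials moving
    bin_center_trial: np.ndarray
    time_s: np.ndarray
    window_probability: dict[str, np.ndarray] = field(default_factory=dict)


def motion_energy(frames: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """One minus the Pearson correlation of ROI pixels between consecutive
    frames.  The first frame's energy is 0; frames where either member of
    the pair has zero pixel variance get energy 0 (no information is not
    movement)."""
    frames = np.asarray(frames)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValidationError("need >= 2 frames of shape [n, H, W]")
    if roi_mask.shape != frames.shape[1:]:
        raise ValidationError("ROI mask does not match the frame shape")
    if not roi_mask.any():
        raise ValidationError("ROI mask is empty")
    x = frames[:, roi_mask].astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", x, x)
    dot = np.einsum("ij,ij->i", x[1:], x[:-1])
    denom = np.sqrt(ss[1:] * ss[:-1])
    energy = np.zeros(frames.shape[0])
    valid = denom > 0
    energy[1:][valid] = 1.0 - dot[valid] / denom[valid]
    return energy


def binarize(
    energy: np.ndarray, baseline_frames: np.ndarray
) -> tuple[np.ndarray, float]:
    """Binary moving/quiet vector by thresholding at baseline mean + 3 SD.

    ``baseline_frames`` is a boolean mask of pre-cue frames (or an index
    array); the SD gets a small floor so any positive excursion above a
    silent baseline still triggers."""
    energy = np.asarray(energy, dtype=float)
    base = energy[baseline_frames]
    if base.size < 3:
        raise ValidationError("need >= 3 baseline frames")
    threshold = float(base.mean() + THRESHOLD_SD * max(base.std(), SD_FLOOR))
    return energy > threshold, threshold


def movement_trace(
    energy: np.ndarray,
    time_s: np.ndarray,
    roi: str = "any",
    cue_time_s: float = CUE_TIME_S,
) -> MovementTrace:
    """Build a full MovementTrace for one trial: threshold from the pre-cue
    baseline, binary vector, and onset 0.2 s before the first crossing."""
    time_s = np.asarray(time_s, dtype=float)
    baseline = time_s < cue_time_s
    binary, threshold = binarize(energy, baseline)
    onset = None
    if binary.any():
        onset = float(time_s[np.argmax(binary)] - ONSET_LEAD_S)
    return MovementTrace(time_s, np.asarray(energy, float), binary, threshold, onset, roi)


def stack_motion_energy(stack: FrameStack, roi: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial motion-energy matrix [n_trials, n_frames] for one ROI of a
    frame stack, with the (shared) trial-relative time axis."""
    if roi not in stack.roi_masks:
        raise ValidationError(f"unknown ROI {roi!r}")
    trials = np.unique(stack.trial_index)
    rows = []
    tv = None
    for tr in trials:
        frames = stack.trial_frames(tr)
        t = stack.trial_times(tr)
        if tv is None:
            tv = t
        elif len(t) != len(tv):
            raise ValidationError("trials have differing frame counts")
        rows.append(motion_energy(frames, stack.roi_masks[roi]))
    return np.vstack(rows), tv


def combine_binary(traces: list[MovementTrace]) -> MovementTrace:
    """Strict any-ROI movement vector: moving wherever any ROI moves; the
    onset comes from the combined vector."""
    if not traces:
        raise ValidationError("no traces to combine")
    time_s = traces[0].time_s
    binary = np.zeros(len(time_s), dtype=bool)
    energy = np.zeros(len(time_s))
    for tr in traces:
        binary |= tr.binary
        energy = np.maximum(energy, tr.energy)
    onset = None
    if binary.any():
        onset = float(time_s[np.argmax(binary)] - ONSET_LEAD_S)
    return MovementTrace(time_s, energy, binary, max(t.threshold for t in traces),
                         onset, "any")


def per_trial_traces(
    energies: dict[str, np.ndarray],
    time_s: np.ndarray,
    rois: tuple[str, ...] | None = None,
) -> list[MovementTrace]:
    """Composite (any-ROI) MovementTrace per trial from per-ROI energy
    matrices, e.g. the output of ``simulate_movement_energy`` or stacked
    :func:`stack_motion_energy` calls."""
    if rois is None:
        rois = tuple(energies)
    n_trials = next(iter(energies.values())).shape[0]
    out = []
    for i in range(n_trials):
        parts = [movement_trace(energies[r][i], time_s, roi=r) for r in rois]
        out.append(combine_binary(parts))
    return out


def movement_map(
    traces: list[MovementTrace],
    table: TrialTable,
    bin_size: int = DEFAULT_BIN_SIZE,
    trial_filter: str = "go",
) -> MovementMap:
    """Per-bin, per-frame fraction of filtered trials that are moving, plus
    scalar probabilities over the standard summary windows."""
    if len(traces) != table.n_trials:
        raise ValidationError("one MovementTrace per trial required")
    keep = trial_filter_mask(table, trial_filter)
    time_s = traces[0].time_s
    binary = np.vstack([tr.binary for tr in traces])
    n_bins = table.n_trials // bin_size
    prob = np.full((n_bins, len(time_s)), np.nan)
    centers = np.empty(n_bins)
    for k in range(n_bins):
        sel = np.zeros(table.n_trials, dtype=bool)
        sel[k * bin_size:(k + 1) * bin_size] = True
        centers[k] = table.trial_index[sel].mean()
        rows = sel & keep
        if rows.any():
            prob[k] = binary[rows].mean(axis=0)
    windows = {}
    for name, (lo, hi) in SUMMARY_WINDOWS_S.items():
        sel = (time_s > lo) & (time_s <= hi)
        windows[name] = np.nanmean(prob[:, sel], axis=1) if sel.any() else np.full(
            n_bins, np.nan
        )
    return MovementMap(prob, centers, time_s, windows)


@dataclass
class TruncatedTrials:
    """Variable-length movement-free photometry trials."""

    time_s: np.ndarray  # full photometry time axis
    traces: list[np.ndarray]  # per-trial surviving prefix (bit-exact)
    n_kept: np.ndarray  # surviving samples per trial
    fully_truncated: np.ndarray  # True where nothing survives


def truncate_movement(
    session: PhotometrySession, traces: list[MovementTrace]
) -> TruncatedTrials:
    """Remove photometry samples from the movement onset onward, per trial.

    The onset is mapped to the nearest photometry frame at or before it
    (conservative when clocks differ); trials without movement are kept
    whole; an onset before the trial start leaves an empty, flagged trial.
    """
    if len(traces) != session.n_trials:
        raise ValidationError("one MovementTrace per photometry trial required")
    t = session.time_s
    kept: list[np.ndarray] = []
    n_kept = np.empty(session.n_trials, dtype=int)
    fully = np.zeros(session.n_trials, dtype=bool)
    for i, tr in enumerate(traces):
        if tr.onset_s is None:
            kept.append(session.traces[i].copy())
            n_kept[i] = session.n_frames
            continue
        j = int(np.searchsorted(t, tr.onset_s + 1e-12, side="right")) - 1
        cut = max(j, 0) if j >= 0 else 0
        if j < 0:
            cut = 0
            fully[i] = True
        kept.append(session.traces[i, :cut].copy())
        n_kept[i] = cut
        if cut == 0:
            fully[i] = True
    return TruncatedTrials(t.copy(), kept, n_kept, fully)


def movement_free_response(
    truncated: TruncatedTrials,
    window_s: tuple[float, float],
    min_samples: int = 1,
) -> np.ndarray:
    """Per-trial mean over surviving frames with time in [start, end);
    NaN when fewer than ``min_samples`` frames survive in the window."""
    lo, hi = window_s
    t = truncated.time_s
    sel = np.flatnonzero((t >= lo) & (t < hi))
    if sel.size == 0:
        raise ValidationError(f"window {window_s} contains no frames")
    out = np.full(len(truncated.traces), np.nan)
    for i, trace in enumerate(truncated.traces):
        surviving = sel[sel < len(trace)]
        if len(surviving) >= min_samples:
            out[i] = trace[surviving].mean()
    return out
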