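"""Data model, file formats and validation shared by all analysis stages.

Time convention
---------------
All trial-relative times are in seconds with 0 at auditory stimulus onset.
The visual start cue occurs at -2.0 s, the stimulus lasts 1.0 s, and licks
are counted in a response window (1.0 s, 4.0 s] after stimulus onset.

File formats
------------
Trial tables are CSV with columns exactly::

    mouse_id,trial_index,day,stimulus_freq_hz,stimulus_class,outcome,lick_times_s

where ``lick_times_s`` is a semicolon-joined list of seconds (empty cell =
no licks).  Photometry sessions and frame stacks are HDF5 (see
:func:`write_session` / :func:`write_frame_stack` for the layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

#: Time of the visual start cue relative to stimulus onset (s).
CUE_TIME_S = -2.0
#: Auditory stimulus duration (s); stimulus occupies (0, 1] s.
STIMULUS_DURATION_S = 1.0
#: Response window relative to stimulus onset, half-open (start, end].
RESPONSE_WINDOW_S = (1.0, 4.0)
#: Default per-trial baseline window (s), ending at the visual cue.
DEFAULT_BASELINE_WINDOW_S = (-2.5, -2.0)

TRIAL_TABLE_COLUMNS = (
    "mouse_id",
    "trial_index",
    "day",
    "stimulus_freq_hz",
    "stimulus_class",
    "outcome",
    "lick_times_s",
)

STIMULUS_CLASSES = ("go", "no-go")
OUTCOMES = ("hit", "miss", "CR", "FA")


class ValidationError(ValueError):
    """Raised when a file or bundle violates the data contract."""


def expected_outcome(stimulus_class: str, lick_times_s: np.ndarray) -> str:
    """Outcome implied by the stimulus class and the lick times.

    A lick "counts" when it falls in the response window
    ``(RESPONSE_WINDOW_S[0], RESPONSE_WINDOW_S[1]]``.  For go trials,
    licks during the stimulus period ``(0, RESPONSE_WINDOW_S[0]]`` also
    count toward a hit (licking before the response window is allowed and
    a licking animal collects the reward); no-go licks are only penalized
    inside the response window.
    """
    lick = np.asarray(lick_times_s, dtype=float)
    lo, hi = RESPONSE_WINDOW_S
    in_window = np.any((lick > lo) & (lick <= hi))
    if stimulus_class == "go":
        licked = in_window or np.any((lick > 0.0) & (lick <= lo))
        return "hit" if licked else "miss"
    if stimulus_class == "no-go":
        return "FA" if in_window else "CR"
    raise ValidationError(f"unknown stimulus_class {stimulus_class!r}")


@dataclass
class TrialTable:
    """Ordered per-trial behavioral records across a whole learning run.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; the
    ``lick_times_s`` column holds one float ndarray per trial.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        bad = set(self.df["stimulus_class"]) - set(STIMULUS_CLASSES)
        if bad:
            raise ValidationError(f"unknown stimulus_class values: {sorted(bad)}")

    # -- accessors ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.df)

    @property
    def trial_index(self) -> np.ndarray:
        return self.df["trial_index"].to_numpy()

    @property
    def stimulus_class(self) -> np.ndarray:
        return self.df["stimulus_class"].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.df["outcome"].to_numpy()

    @property
    def lick_times(self) -> list[np.ndarray]:
        return list(self.df["lick_times_s"])

    @property
    def first_lick_s(self) -> np.ndarray:
        """First lick time per trial (NaN when the trial has no licks)."""
        return np.array(
            [t[0] if len(t) else np.nan for t in self.df["lick_times_s"]], dtype=float
        )

    def validate_index(self) -> None:
        """Check trial_index is strictly increasing and gapless per mouse."""
        for mouse, sub in self.df.groupby("mouse_id", sort=False):
            idx = sub["trial_index"].to_numpy()
            if len(idx) and not np.array_equal(
                idx, np.arange(idx[0], idx[0] + len(idx))
            ):
                raise ValidationError(
                    f"trial_index not strictly increasing and gapless for mouse {mouse!r}"
                )

    def validate_outcomes(self) -> None:
        """Check every outcome against the lick evidence; raise listing offenders."""
        bad: list[int] = []
        for i, row in self.df.iterrows():
            if row["outcome"] != expected_outcome(row["stimulus_class"], row["lick_times_s"]):
                bad.append(int(row["trial_index"]))
        if bad:
            raise ValidationError(
                f"outcome inconsistent with lick evidence at trial_index {bad}"
            )

    def subset(self, mask: np.ndarray) -> "TrialTable":
        sub = self.df.loc[np.asarray(mask)].copy()
        sub["trial_index"] = np.arange(len(sub))
        return TrialTable(sub)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, TrialTable):
            return NotImplemented
        if self.df.shape != other.df.shape:
            return False
        for col in TRIAL_TABLE_COLUMNS:
            a, b = self.df[col], other.df[col]
            if col == "lick_times_s":
                if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                    return False
            elif not a.equals(b):
                return False
        return True


@dataclass
class PhotometrySession:
    """Trial-aligned fluorescence matrix with its time axis."""

    mouse_id: str
    traces: np.ndarray  # [n_trials, n_frames]
    time_s: np.ndarray  # [n_frames], 0 = stimulus onset
    sampling_rate: float
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW_S
    normalized: bool = False

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.traces.ndim != 2:
            raise ValidationError("traces must be 2-D [n_trials, n_frames]")
        if self.traces.shape[1] != self.time_s.shape[0]:
            raise ValidationError(
                f"traces width {self.traces.shape[1]} != time axis length "
                f"{self.time_s.shape[0]}"
            )
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6, atol=1e-9):
                raise ValidationError("time_s not uniformly spaced at 1/sampling_rate")
        if self.baseline_window[1] > CUE_TIME_S + 1e-9:
            raise ValidationError(
                f"baseline_window must end at or before the visual cue ({CUE_TIME_S} s)"
            )

    @property
    def n_trials(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def copy(self) -> "PhotometrySession":
        return replace(self, traces=self.traces.copy(), time_s=self.time_s.copy())


@dataclass
class FrameStack:
    """Contiguous grayscale video frames with a trial index map and ROI masks."""

    frames: np.ndarray  # [n_frames_total, H, W] uint8
    frame_rate: float
    trial_index: np.ndarray  # [n_frames_total] trial each frame belongs to
    time_s: np.ndarray  # [n_frames_total] trial-relative timestamps
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be 3-D [n_frames, H, W]")
        n = self.frames.shape[0]
        if len(self.trial_index) != n or len(self.time_s) != n:
            raise ValidationError("trial_index/time_s length must match frame count")
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.frames.shape[1:]:
                raise ValidationError(f"ROI {name!r} shape does not match frames")
            if not mask.any():
                raise ValidationError(f"ROI {name!r} is empty")
            self.roi_masks[name] = mask

    def trial_frames(self, trial: int) -> np.ndarray:
        sel = self.trial_index == trial
        return self.frames[sel]

    def trial_times(self, trial: int) -> np.ndarray:
        return self.time_s[self.trial_index == trial]


# ---------------------------------------------------------------------------
# CSV trial tables
# ---------------------------------------------------------------------------

def _format_licks(t: np.ndarray) -> str:
    return ";".join(repr(float(x)) for x in np.asarray(t, dtype=float))


def _parse_licks(cell) -> np.ndarray:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return np.array([], dtype=float)
    return np.array([float(x) for x in str(cell).split(";")], dtype=float)


def write_trial_table(table: TrialTable, path) -> None:
    out = table.df.copy()
    out["lick_times_s"] = [_format_licks(t) for t in out["lick_times_s"]]
    out.to_csv(path, index=False, columns=list(TRIAL_TABLE_COLUMNS))


def read_trial_table(path) -> TrialTable:
    """Read a trial-table CSV and re-validate outcomes against lick times."""
    df = pd.read_csv(path, dtype={"mouse_id": str}, keep_default_na=False,
                     na_values=[])
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table CSV missing columns: {missing}")
    df["lick_times_s"] = [_parse_licks(c) for c in df["lick_times_s"]]
    df["trial_index"] = df["trial_index"].astype(int)
    df["day"] = df["day"].astype(int)
    df["stimulus_freq_hz"] = df["stimulus_freq_hz"].astype(float)
    table = TrialTable(df[list(TRIAL_TABLE_COLUMNS)])
    table.validate_index()
    table.validate_outcomes()
    return table


# ---------------------------------------------------------------------------
# HDF5 photometry sessions
# ---------------------------------------------------------------------------

def write_session(session: PhotometrySession, path) -> None:
    """HDF5 layout: datasets /traces, /time_s; attributes sampling_rate,
    normalized, mouse_id, baseline_window."""
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces)
        f.create_dataset("time_s", data=session.time_s)
        f.attrs["sampling_rate"] = session.sampling_rate
        f.attrs["normalized"] = bool(session.normalized)
        f.attrs["mouse_id"] = session.mouse_id
        f.attrs["baseline_window"] = list(session.baseline_window)


def read_session(path) -> PhotometrySession:
    with h5py.File(path, "r") as f:
        for name in ("traces", "time_s"):
            if name not in f:
                raise ValidationError(f"missing dataset /{name}")
        for attr in ("sampling_rate", "normalized"):
            if attr not in f.attrs:
                raise ValidationError(f"missing attribute {attr!r}")
        bw = f.attrs.get("baseline_window", DEFAULT_BASELINE_WINDOW_S)
        return PhotometrySession(
            mouse_id=str(f.attrs.get("mouse_id", "")),
            traces=f["traces"][...],
            time_s=f["time_s"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            baseline_window=(float(bw[0]), float(bw[1])),
            normalized=bool(f.attrs["normalized"]),
        )


def write_frame_stack(stack: FrameStack, path) -> None:
    """HDF5 layout: /frames (uint8), /frame_time_s, /frame_trial_index,
    /roi/<name> (uint8 masks); attribute frame_rate."""
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=stack.frames.astype(np.uint8))
        f.create_dataset("frame_time_s", data=stack.time_s)
        f.create_dataset("frame_trial_index", data=stack.trial_index)
        f.attrs["frame_rate"] = stack.frame_rate
        grp = f.create_group("roi")
        for name, mask in stack.roi_masks.items():
            grp.create_dataset(name, data=mask.astype(np.uint8))


def read_frame_stack(path) -> FrameStack:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise ValidationError("missing dataset /frames")
        if "frame_rate" not in f.attrs:
            raise ValidationError("missing attribute 'frame_rate'")
        rois = {}
        if "roi" in f:
            for name in f["roi"]:
                rois[name] = f["roi"][name][...].astype(bool)
        return FrameStack(
            frames=f["frames"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            trial_index=f["frame_trial_index"][...].astype(int),
            time_s=f["frame_time_s"][...],
            roi_masks=rois,
        )


# ---------------------------------------------------------------------------
# Bundle validation
# ---------------------------------------------------------------------------

def validate_bundle(
    table: TrialTable,
    session: PhotometrySession | None = None,
    frames: FrameStack | None = None,
) -> list[dict]:
    """Cross-check a trial table against its photometry session and frames.

    Report-only: returns a machine-readable list of issues (empty when the
    bundle is consistent) and never mutates or raises.
    """
    issues: list[dict] = []
    idx = table.trial_index
    dup = idx[:-1][np.diff(idx) == 0] if len(idx) > 1 else np.array([], dtype=int)
    for d in np.unique(dup):
        issues.append({"kind": "duplicate_trial_index", "trial_index": int(d)})
    if len(idx) > 1 and not np.all(np.diff(idx) == 1):
        if len(dup) == 0:
            issues.append({"kind": "non_monotone_trial_index"})
    if session is not None and session.n_trials != table.n_trials:
        issues.append(
            {
                "kind": "trial count mismatch",
                "table_trials": int(table.n_trials),
                "session_trials": int(session.n_trials),
            }
        )
    if frames is not None:
        frame_trials = np.unique(frames.trial_index)
        unknown = np.setdiff1d(frame_trials, idx)
        if unknown.size:
            issues.append(
                {"kind": "frames_for_unknown_trials", "trial_index": unknown.tolist()}
            )
        if session is not None and len(frames.time_s):
            t0, t1 = session.time_s[0], session.time_s[-1]
            if frames.time_s.min() < t0 - 1e-6 or frames.time_s.max() > t1 + 1e-6:
                issues.append({"kind": "frame_timestamps_outside_trial_window"})
    return issues
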