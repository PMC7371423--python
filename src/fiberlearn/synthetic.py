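"""Synthetic behavioral, photometric and video sessions with known ground truth.

Every generator is deterministic given the :class:`~fiberlearn.config.SimConfig`
seed: independent numpy ``SeedSequence`` streams are derived per stage, so
behavior, fluorescence, movement intervals and frames can be regenerated
independently and still agree with each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import norm, truncnorm

from fiberlearn.config import SimConfig
from fiberlearn.io import (
    DEFAULT_BASELINE_WINDOW_S,
    RESPONSE_WINDOW_S,
    TRIAL_TABLE_COLUMNS,
    FrameStack,
    PhotometrySession,
    TrialTable,
    ValidationError,
    expected_outcome,
)

_STAGE_BEHAVIOR = 1
_STAGE_PHOTOMETRY = 2
_STAGE_MOVEMENT = 3
_STAGE_ENERGY = 4
_STAGE_FRAMES = 5
_STAGE_PASSIVE = 6

#: Default ROI names used by the movement generators.
ROI_NAMES = ("forelimbs", "neck", "jaw")

_LICK_TRAIN_RATE_HZ = 7.0
_LICK_TRAIN_DURATION_S = 0.5
_JAW_BOUT_DURATION_S = 0.8
_CHOICE_HOLD_END_S = 1.5


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


@dataclass(frozen=True)
class MovementInterval:
    start_s: float
    end_s: float
    roi: str


@dataclass
class GroundTruth:
    """Recovery targets for the downstream analyses."""

    learning_threshold_trial: float | None
    stim_onset_s: float
    choice_onset_s: float
    movement_intervals: list[list[MovementInterval]] = field(default_factory=list)
    choice_amplitude: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_json(self, path) -> None:
        obj = {
            "learning_threshold_trial": self.learning_threshold_trial,
            "stim_onset_s": self.stim_onset_s,
            "choice_onset_s": self.choice_onset_s,
            "movement_intervals": [
                [[iv.start_s, iv.end_s, iv.roi] for iv in trial]
                for trial in self.movement_intervals
            ],
            "choice_amplitude": np.asarray(self.choice_amplitude).tolist(),
        }
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            learning_threshold_trial=obj["learning_threshold_trial"],
            stim_onset_s=obj["stim_onset_s"],
            choice_onset_s=obj["choice_onset_s"],
            movement_intervals=[
                [MovementInterval(a, b, r) for a, b, r in trial]
                for trial in obj["movement_intervals"]
            ],
            choice_amplitude=np.asarray(obj["choice_amplitude"], dtype=float),
        )


def true_learning_threshold(config: SimConfig, criterion: float = 1.0) -> float | None:
    """Trial at which the configured rate curves imply d' = ``criterion``.

    Uses the noiseless d'(t) = Z(hit_rate(t)) - Z(fa_rate(t)) implied by the
    config; returns None when the curve never reaches the criterion.
    """
    t = np.linspace(0.0, float(config.n_trials), 4096)
    hr = np.clip(config.hit_rate(t), 1e-9, 1 - 1e-9)
    fa = np.clip(1.0 - config.cr_rate(t), 1e-9, 1 - 1e-9)
    d = norm.ppf(hr) - norm.ppf(fa)
    above = d >= criterion
    if not above.any() or above[0]:
        return None if not above.any() else float(t[0])
    i = int(np.argmax(above))
    # linear interpolation of the crossing
    t0, t1, d0, d1 = t[i - 1], t[i], d[i - 1], d[i]
    return float(t0 + (criterion - d0) * (t1 - t0) / (d1 - d0))


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(config: SimConfig) -> TrialTable:
    """Draw a full learning run of trials from the configured rate sigmoids.

    Stimulus class is i.i.d. with probability ``go_fraction``; the lick
    decision follows the trial-indexed hit-rate (go) or false-alarm-rate
    (1 - cr_rate, no-go) sigmoid; lick times form a short train whose first
    lick is drawn from the configured latency distribution truncated to the
    response window.  Outcomes obey the task contingency.
    """
    rng = _rng(config, _STAGE_BEHAVIOR)
    n = config.n_trials
    trial = np.arange(n)
    is_go = rng.random(n) < config.go_fraction
    p_lick = np.where(is_go, config.hit_rate(trial), 1.0 - config.cr_rate(trial))
    licked = rng.random(n) < p_lick

    lo, hi = RESPONSE_WINDOW_S
    first_hi = hi - _LICK_TRAIN_DURATION_S
    a = (lo + 1e-3 - config.lick_latency_mean_s) / config.lick_latency_sd_s
    b = (first_hi - config.lick_latency_mean_s) / config.lick_latency_sd_s
    first_lick = truncnorm.rvs(
        a, b, loc=config.lick_latency_mean_s, scale=config.lick_latency_sd_s,
        size=n, random_state=rng,
    )

    lick_times: list[np.ndarray] = []
    n_train = int(_LICK_TRAIN_DURATION_S * _LICK_TRAIN_RATE_HZ)
    offsets = np.arange(n_train + 1) / _LICK_TRAIN_RATE_HZ
    for i in range(n):
        if licked[i]:
            t = first_lick[i] + offsets
            lick_times.append(t[t <= hi])
        else:
            lick_times.append(np.array([], dtype=float))

    stim_class = np.where(is_go, "go", "no-go")
    outcome = [expected_outcome(c, lt) for c, lt in zip(stim_class, lick_times)]
    df = pd.DataFrame(
        {
            "mouse_id": config.mouse_id,
            "trial_index": trial,
            "day": trial // 400 + 1,
            "stimulus_freq_hz": np.where(is_go, config.go_freq_hz, config.nogo_freq_hz),
            "stimulus_class": stim_class,
            "outcome": outcome,
            "lick_times_s": lick_times,
        },
        columns=list(TRIAL_TABLE_COLUMNS),
    )
    return TrialTable(df)


# ---------------------------------------------------------------------------
# movement intervals (shared by photometry, energy and frame generators)
# ---------------------------------------------------------------------------

def draw_movement_intervals(
    trials: TrialTable, config: SimConfig
) -> list[list[MovementInterval]]:
    """Ground-truth movement intervals per trial.

    Licked trials receive a body burst (forelimbs) with the scheduled
    probability plus a jaw bout starting at the first lick; no-lick trials
    receive the burst with probability scaled by ``quiet_factor``.
    Deterministic for a given config seed.
    """
    rng = _rng(config, _STAGE_MOVEMENT)
    mv = config.movement
    t_end = config.trial_window[1]
    out: list[list[MovementInterval]] = []
    licked_all = np.isin(trials.outcome, ("hit", "FA"))
    first_lick = trials.first_lick_s
    p_all = mv.probability(trials.trial_index)
    p_all = np.where(licked_all, p_all, p_all * mv.quiet_factor)
    for i in range(trials.n_trials):
        ivs: list[MovementInterval] = []
        licked = bool(licked_all[i])
        p = float(p_all[i])
        u_p, u_start = rng.random(), rng.uniform(*mv.burst_start_range_s)
        if u_p < p:
            start = u_start
            ivs.append(
                MovementInterval(start, min(start + mv.burst_duration_s, t_end), "forelimbs")
            )
        if licked:
            ivs.append(
                MovementInterval(
                    float(first_lick[i]),
                    min(float(first_lick[i]) + _JAW_BOUT_DURATION_S, t_end),
                    "jaw",
                )
            )
        out.append(ivs)
    return out


def _interval_mask(time_s: np.ndarray, ivs: list[MovementInterval], roi=None) -> np.ndarray:
    m = np.zeros(time_s.shape, dtype=bool)
    for iv in ivs:
        if roi is not None and iv.roi != roi:
            continue
        m |= (time_s >= iv.start_s) & (time_s < iv.end_s)
    return m


# ---------------------------------------------------------------------------
# photometry
# ---------------------------------------------------------------------------

def calcium_kernel(config: SimConfig) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1."""
    dt = 1.0 / config.sampling_rate
    t = np.arange(0.0, 5.0 * config.calcium_decay_s, dt)
    k = np.exp(-t / config.calcium_decay_s) - np.exp(-t / config.calcium_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValidationError("degenerate calcium kernel")
    return k / peak


def simulate_photometry(
    trials: TrialTable, config: SimConfig
) -> tuple[PhotometrySession, GroundTruth]:
    """Raw fluorescence per trial: baseline x (1 + drive * kernel) + noise.

    The drive sums a frequency-tuned stimulus transient, a choice ramp on
    licked trials whose amplitude follows the configured schedule (scaled
    by the stimulus tuning gain and signed by ``choice_sign``), and an
    additive movement-coupling term during ground-truth movement intervals.
    """
    n_frames = config.n_frames
    if config.stim_onset_s + config.stim_duration_s > config.trial_window[1]:
        raise ValidationError("trial window too short to contain the stimulus period")
    t = config.time_axis()
    n = trials.n_trials
    drive = np.zeros((n, n_frames))

    is_go = trials.stimulus_class == "go"
    gain = np.where(is_go, 1.0, config.nogo_gain)

    # stimulus transient
    stim_mask = (t >= config.stim_onset_s) & (t < config.stim_onset_s + config.stim_duration_s)
    drive += config.stim_amplitude * gain[:, None] * stim_mask[None, :]

    # choice ramp on licked trials
    licked = np.isin(trials.outcome, ("hit", "FA"))
    amp = config.choice_amplitude_at(trials.trial_index) * licked
    ramp = np.clip(
        (t - config.choice_onset_s) / max(config.choice_ramp_end_s - config.choice_onset_s, 1e-9),
        0.0,
        1.0,
    )
    ramp = ramp * (t < _CHOICE_HOLD_END_S)
    drive += config.choice_sign * (amp * gain)[:, None] * ramp[None, :]

    # movement coupling
    intervals = draw_movement_intervals(trials, config)
    if config.movement.coupling_gain != 0.0:
        for i, ivs in enumerate(intervals):
            drive[i] += config.movement.coupling_gain * _interval_mask(t, ivs)

    kernel = calcium_kernel(config)
    smoothed = signal.fftconvolve(drive, kernel[None, :], axes=1)[:, :n_frames]

    rng = _rng(config, _STAGE_PHOTOMETRY)
    noise = rng.normal(0.0, config.noise_sd * config.baseline_f, size=(n, n_frames))
    traces = config.baseline_f * (1.0 + smoothed) + noise

    session = PhotometrySession(
        mouse_id=config.mouse_id,
        traces=traces,
        time_s=t,
        sampling_rate=config.sampling_rate,
        baseline_window=DEFAULT_BASELINE_WINDOW_S,
        normalized=False,
    )
    gt = GroundTruth(
        learning_threshold_trial=true_learning_threshold(config),
        stim_onset_s=config.stim_onset_s,
        choice_onset_s=config.choice_onset_s,
        movement_intervals=intervals,
        choice_amplitude=config.choice_sign * amp * gain,
    )
    return session, gt


# ---------------------------------------------------------------------------
# movement: per-ROI motion-energy traces (light-weight alternative to frames)
# ---------------------------------------------------------------------------

def simulate_movement_energy(
    trials: TrialTable, config: SimConfig, quiet_sd: float = 0.002,
    burst_level: float = 0.6,
) -> tuple[dict[str, np.ndarray], list[list[MovementInterval]]]:
    """Per-ROI motion-energy matrices [n_trials, n_video_frames] on the
    video clock, without rendering frames.

    Quiet frames get folded-normal sensor noise; frames inside a ground-truth
    interval of the ROI get ``burst_level`` plus noise.  Intervals are
    identical to those coupled into the fluorescence.
    """
    rng = _rng(config, _STAGE_ENERGY)
    tv = config.frame_time_axis()
    intervals = draw_movement_intervals(trials, config)
    energies = {}
    for roi in ROI_NAMES:
        e = np.abs(rng.normal(0.0, quiet_sd, size=(trials.n_trials, len(tv))))
        for i, ivs in enumerate(intervals):
            m = _interval_mask(tv, ivs, roi=roi)
            e[i, m] += burst_level
        e[:, 0] = 0.0  # first frame has no predecessor
        energies[roi] = e
    return energies, intervals


# ---------------------------------------------------------------------------
# movement: rendered frame stacks
# ---------------------------------------------------------------------------

def default_roi_masks(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Three rectangular ROIs (forelimbs, neck, jaw) scaled to the frame."""
    h, w = shape
    masks = {}
    boxes = {
        "forelimbs": (0.60, 0.95, 0.05, 0.45),
        "neck": (0.30, 0.55, 0.30, 0.70),
        "jaw": (0.05, 0.25, 0.55, 0.95),
    }
    for name, (r0, r1, c0, c1) in boxes.items():
        m = np.zeros(shape, dtype=bool)
        m[int(r0 * h):int(r1 * h), int(c0 * w):int(c1 * w)] = True
        masks[name] = m
    return masks


def simulate_movement_frames(
    trials: TrialTable,
    config: SimConfig,
    roi_masks: dict[str, np.ndarray] | None = None,
    intervals: list[list[MovementInterval]] | None = None,
) -> tuple[FrameStack, list[list[MovementInterval]]]:
    """Render small grayscale frames: a static textured background, with the
    texture inside an ROI re-shuffled frame-to-frame during that ROI's
    ground-truth movement intervals.

    Frames outside any interval are bit-identical to the background, so
    motion energy is exactly zero there.
    """
    if roi_masks is None:
        roi_masks = default_roi_masks(config.frame_shape)
    for name, mask in roi_masks.items():
        if not np.asarray(mask).any():
            raise ValidationError(f"ROI {name!r} is empty")
    if intervals is None:
        intervals = draw_movement_intervals(trials, config)
    rng = _rng(config, _STAGE_FRAMES)
    h, w = config.frame_shape
    background = rng.integers(20, 236, size=(h, w), dtype=np.uint8)
    tv = config.frame_time_axis()
    n_per_trial = len(tv)
    n_total = trials.n_trials * n_per_trial
    frames = np.broadcast_to(background, (n_total, h, w)).copy()
    trial_index = np.repeat(trials.trial_index, n_per_trial)
    time_s = np.tile(tv, trials.n_trials)

    for i, ivs in enumerate(intervals):
        base = i * n_per_trial
        for roi, mask in roi_masks.items():
            m = _interval_mask(tv, ivs, roi=roi)
            idx = np.flatnonzero(m)
            for j in idx:
                vals = frames[base + j][mask]
                frames[base + j][mask] = rng.permutation(vals)

    stack = FrameStack(
        frames=frames,
        frame_rate=config.frame_rate,
        trial_index=trial_index,
        time_s=time_s,
        roi_masks=dict(roi_masks),
    )
    return stack, intervals


# ---------------------------------------------------------------------------
# passive tuning sessions
# ---------------------------------------------------------------------------

DEFAULT_ATTENS_DB = (10, 20, 30, 40)


@dataclass
class PassiveSession:
    """Short passively-presented trials labeled by (frequency, attenuation)."""

    session: PhotometrySession
    freq_hz: np.ndarray
    atten_db: np.ndarray


def gaussian_tuning(best_freq_hz: float, bandwidth_oct: float = 0.8, amplitude: float = 0.3):
    """Log-frequency Gaussian tuning function (amplitude in dF/F units)."""

    def fn(f_hz):
        x = np.log2(np.asarray(f_hz, dtype=float) / best_freq_hz)
        return amplitude * np.exp(-(x ** 2) / (2.0 * bandwidth_oct ** 2))

    return fn


def simulate_passive_tuning(
    config: SimConfig,
    freqs_hz=None,
    attens_db=DEFAULT_ATTENS_DB,
    n_repeats: int = 10,
    tuning_fn=None,
) -> PassiveSession:
    """Passive presentations (0.1 s tones over frequency x attenuation).

    Evoked amplitude = ``tuning_fn(freq) * (50 - atten)/40`` so louder
    presentations (smaller attenuation) evoke monotonically larger responses.
    """
    if freqs_hz is None:
        freqs_hz = 4000.0 * 2.0 ** np.linspace(0.0, np.log2(10.0), 9)  # 4-40 kHz
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    attens_db = np.asarray(attens_db, dtype=float)
    if tuning_fn is None:
        tuning_fn = gaussian_tuning(config.go_freq_hz, amplitude=config.stim_amplitude)

    rng = _rng(config, _STAGE_PASSIVE)
    window = (-2.5, 0.7)
    n_frames = int(round((window[1] - window[0]) * config.sampling_rate))
    t = window[0] + np.arange(n_frames) / config.sampling_rate

    combos = [(f, a) for a in attens_db for f in freqs_hz] * n_repeats
    order = rng.permutation(len(combos))
    freq = np.array([combos[i][0] for i in order])
    atten = np.array([combos[i][1] for i in order])

    amp = tuning_fn(freq) * (50.0 - atten) / 40.0
    pulse = ((t > 0.0) & (t <= 0.1)).astype(float)
    kernel = calcium_kernel(config)
    evoked = signal.fftconvolve(
        amp[:, None] * pulse[None, :], kernel[None, :], axes=1
    )[:, :n_frames]
    noise = rng.normal(0.0, config.noise_sd * config.baseline_f, size=evoked.shape)
    traces = config.baseline_f * (1.0 + evoked) + noise
    session = PhotometrySession(
        mouse_id=config.mouse_id,
        traces=traces,
        time_s=t,
        sampling_rate=config.sampling_rate,
        baseline_window=DEFAULT_BASELINE_WINDOW_S,
        normalized=False,
    )
    return PassiveSession(session=session, freq_hz=freq, atten_db=atten)
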