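"""Simulation configuration for the synthetic session generator."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from fiberlearn.io import CUE_TIME_S, ValidationError


@dataclass(frozen=True)
class RateSigmoid:
    """Trial-indexed probability curve ``floor + a / (1 + exp(-(t - b)/c))``.

    ``a`` is the acquisition amplitude, ``b`` the inflection trial and ``c``
    the steepness in trials; ``floor`` sets the pre-learning rate.
    """

    a: float
    b: float
    c: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValidationError(f"rate amplitude a={self.a} must be in [0, 1]")
        if not (0.0 <= self.floor <= 1.0) or self.floor + self.a > 1.0 + 1e-12:
            raise ValidationError("rate floor and floor+a must lie in [0, 1]")
        if self.c <= 0:
            raise ValidationError("steepness c must be > 0")

    def __call__(self, trial) -> np.ndarray:
        t = np.asarray(trial, dtype=float)
        from scipy.special import expit

        return np.clip(self.floor + self.a * expit((t - self.b) / self.c), 0.0, 1.0)

    def logistic(self, trial) -> np.ndarray:
        """The bare logistic component in [0, 1] (no floor, unit amplitude)."""
        from scipy.special import expit

        return expit((np.asarray(trial, dtype=float) - self.b) / self.c)


@dataclass(frozen=True)
class MovementConfig:
    """Movement generation: probability schedule over learning, additive
    coupling gain into the fluorescence, and burst geometry."""

    probability: RateSigmoid = RateSigmoid(a=0.6, b=1400.0, c=120.0, floor=0.15)
    quiet_factor: float = 0.25  # multiplier on probability for no-lick trials
    coupling_gain: float = 0.0  # dF/F added while moving (0 disables)
    burst_duration_s: float = 1.0
    burst_start_range_s: tuple[float, float] = (0.2, 0.6)

    def __post_init__(self) -> None:
        if self.burst_duration_s <= 0:
            raise ValidationError("burst_duration_s must be > 0")
        if not (0.0 <= self.quiet_factor <= 1.0):
            raise ValidationError("quiet_factor must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one synthetic mouse.

    Defaults emulate a run that is acquired over ~1200-2000 trials: a fast
    frequency-tuned sensory transient shortly after stimulus onset, a later
    choice-dependent ramp whose amplitude grows with the behavioral
    sigmoid, movement bursts coupled (optionally) into the fluorescence,
    and a difference-of-exponentials calcium kernel.

    The photometry sampling rate and the trial window are artifact
    choices (30 Hz, -3..5 s); both are configurable.
    """

    mouse_id: str = "m0"
    n_trials: int = 1600
    go_fraction: float = 0.5
    sampling_rate: float = 30.0
    trial_window: tuple[float, float] = (-3.0, 5.0)

    # behavioral acquisition
    hit_rate: RateSigmoid = RateSigmoid(a=0.35, b=1400.0, c=120.0, floor=0.60)
    cr_rate: RateSigmoid = RateSigmoid(a=0.75, b=1400.0, c=120.0, floor=0.15)
    lick_latency_mean_s: float = 1.4
    lick_latency_sd_s: float = 0.15

    # fluorescence signal components (dF/F units before kernel smoothing)
    stim_onset_s: float = 0.05
    stim_duration_s: float = 0.15
    stim_amplitude: float = 0.3
    nogo_gain: float = 0.6  # tuning gain of the no-go frequency
    choice_onset_s: float = 0.2
    choice_ramp_end_s: float = 1.0
    choice_amplitude: float = 0.5
    choice_sign: int = 1
    choice_schedule: str = "hit_sigmoid"  # or "constant"
    calcium_rise_s: float = 0.05
    calcium_decay_s: float = 0.4
    baseline_f: float = 100.0
    noise_sd: float = 0.02  # per-frame, in units of baseline_f

    movement: MovementConfig = field(default_factory=MovementConfig)

    # video
    frame_rate: float = 30.0
    frame_shape: tuple[int, int] = (64, 64)

    # task frequencies (Hz)
    go_freq_hz: float = 10000.0
    nogo_freq_hz: float = 7071.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        if not (0.0 <= self.go_fraction <= 1.0):
            raise ValidationError("go_fraction must be in [0, 1]")
        if self.sampling_rate <= 0 or self.frame_rate <= 0:
            raise ValidationError("rates must be > 0")
        t0, t1 = self.trial_window
        if not (t0 < 0.0 < t1):
            raise ValidationError("trial_window must span stimulus onset (t=0)")
        if t0 > CUE_TIME_S:
            raise ValidationError(
                f"trial_window must include the visual cue at {CUE_TIME_S} s"
            )
        for name in ("stim_duration_s", "calcium_rise_s", "calcium_decay_s",
                     "lick_latency_sd_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.choice_sign not in (-1, 1):
            raise ValidationError("choice_sign must be +1 or -1")
        if self.choice_schedule not in ("hit_sigmoid", "constant"):
            raise ValidationError("choice_schedule must be 'hit_sigmoid' or 'constant'")
        if self.calcium_decay_s <= self.calcium_rise_s:
            raise ValidationError("calcium_decay_s must exceed calcium_rise_s")

    # -- derived -----------------------------------------------------------
    @property
    def n_frames(self) -> int:
        t0, t1 = self.trial_window
        return int(round((t1 - t0) * self.sampling_rate))

    def time_axis(self) -> np.ndarray:
        t0, _ = self.trial_window
        return t0 + np.arange(self.n_frames) / self.sampling_rate

    def frame_time_axis(self) -> np.ndarray:
        t0, t1 = self.trial_window
        n = int(round((t1 - t0) * self.frame_rate))
        return t0 + np.arange(n) / self.frame_rate

    def choice_amplitude_at(self, trial) -> np.ndarray:
        """Per-trial choice-ramp amplitude (before the lick gate)."""
        t = np.asarray(trial, dtype=float)
        if self.choice_schedule == "constant":
            return np.full(t.shape, self.choice_amplitude)
        return self.choice_amplitude * self.hit_rate.logistic(t)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _as_rate(v) -> RateSigmoid:
    if isinstance(v, RateSigmoid):
        return v
    if isinstance(v, dict):
        return RateSigmoid(**v)
    return RateSigmoid(*v)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for key in ("hit_rate", "cr_rate"):
        if key in d:
            d[key] = _as_rate(d[key])
    if "movement" in d and isinstance(d["movement"], dict):
        mv = dict(d["movement"])
        if "probability" in mv:
            mv["probability"] = _as_rate(mv["probability"])
        if "burst_start_range_s" in mv:
            mv["burst_start_range_s"] = tuple(mv["burst_start_range_s"])
        d["movement"] = MovementConfig(**mv)
    for key in ("trial_window", "frame_shape"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


def load_config(path) -> SimConfig:
    """Load a SimConfig from YAML (missing keys fall back to defaults)."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return config_from_dict(data)
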