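"""Shared containers and configuration objects for the fUS pipeline.

The pipeline operates on three levels of data:

* complex ultrafast frame blocks (one block of 300 slow-time samples at
  500 Hz per second of acquisition), from which power-Doppler images are
  computed after clutter filtering;
* power-Doppler / %CBV voxel time series at 1 Hz;
* trial-epoched response tensors with stimulus labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "TrialProtocol",
    "HemodynamicModel",
    "GroundTruthMap",
    "FrameBlock",
    "PowerDopplerSeries",
    "CBVSeries",
    "TrialTensor",
    "DEFAULT_FREQUENCIES_HZ",
]

#: Pure-tone frequencies (Hz), log-spaced over the ferret hearing range.
DEFAULT_FREQUENCIES_HZ = (602.0, 1430.0, 3400.0, 8087.0, 19234.0)


class InvalidConfigError(ValueError):
    """Raised when an acquisition or protocol configuration is inconsistent."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Ultrafast-Doppler acquisition parameters.

    One power-Doppler image is computed from ``frames_per_block`` compound
    frames acquired at ``frame_rate``; blocks repeat every ``block_period``.
    The transmit frequency and speed of sound set the Doppler scale
    ``f_D = 2 v f0 / c`` that converts axial blood velocity to slow-time
    frequency.
    """

    frame_rate: float = 500.0           # Hz
    frames_per_block: int = 300
    block_period: float = 1.0           # s
    transmit_frequency: float = 15e6    # Hz
    speed_of_sound: float = 1540.0      # m/s
    voxel_pitch: tuple[float, float, float] = (100.0, 100.0, 400.0)  # µm

    def __post_init__(self) -> None:
        scalars = (self.frame_rate, self.frames_per_block, self.block_period,
                   self.transmit_frequency, self.speed_of_sound)
        if any(s <= 0 for s in scalars) or any(p <= 0 for p in self.voxel_pitch):
            raise InvalidConfigError("all acquisition parameters must be strictly positive")
        if self.frames_per_block / self.frame_rate > self.block_period + 1e-12:
            raise InvalidConfigError(
                "frames_per_block / frame_rate exceeds block_period: the block "
                "must fit within one acquisition period"
            )

    def doppler_frequency(self, velocity_mm_s) -> np.ndarray | float:
        """Doppler frequency (Hz) of axial velocity in mm/s: ``2 v f0 / c``."""
        v = np.asarray(velocity_mm_s, dtype=float) * 1e-3  # m/s
        return 2.0 * v * self.transmit_frequency / self.speed_of_sound


@dataclass(frozen=True)
class TrialProtocol:
    """Stimulus presentation protocol.

    Each trial is ``baseline_s`` of silence, ``stim_s`` of sound, then
    ``post_s`` of silence; consecutive trials are separated by an extra
    uniform jitter drawn from ``jitter_range_s``.
    """

    baseline_s: float = 10.0
    stim_s: float = 3.0
    post_s: float = 8.0
    jitter_range_s: tuple[float, float] = (1.0, 3.0)
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES_HZ
    trials_per_frequency: int = 10

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0:
            raise InvalidConfigError("frequency list must not be empty")
        if not all(b > a for a, b in zip(self.frequencies, self.frequencies[1:])):
            raise InvalidConfigError("frequencies must be strictly increasing")
        if self.jitter_range_s[0] > self.jitter_range_s[1]:
            raise InvalidConfigError("jitter bounds must be ordered")
        if self.trials_per_frequency < 2:
            raise InvalidConfigError("need at least 2 trials per frequency")

    @property
    def trial_length_s(self) -> float:
        return self.baseline_s + self.stim_s + self.post_s

    @property
    def n_trials(self) -> int:
        return len(self.frequencies) * self.trials_per_frequency


@dataclass(frozen=True)
class HemodynamicModel:
    """Discrete hemodynamic impulse response at 1 Hz, normalized to unit peak."""

    kernel: np.ndarray
    peak_delay_s: float
    duration_s: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 1 or k.size == 0:
            raise InvalidConfigError("kernel must be a non-empty 1-D array")
        if np.any(k < 0):
            raise InvalidConfigError("kernel must be non-negative")
        if not np.isclose(k.max(), 1.0):
            raise InvalidConfigError("kernel must be normalized to unit peak")
        object.__setattr__(self, "kernel", k)

    @classmethod
    def gamma(cls, peak_delay_s: float = 2.0, shape: float = 3.0,
              duration_s: float = 8.0, dt: float = 1.0) -> "HemodynamicModel":
        """Gamma-shaped kernel ``t^(a-1) exp(-t/b)`` with peak at ``(a-1)b``.

        Defaults peak at 2 s and decay below 5% of peak by 8 s, so that
        windowed response means over 3-5 s post-onset sit near the peak of
        the convolved response to a 3 s stimulus.
        """
        b = peak_delay_s / (shape - 1.0)
        t = np.arange(0.0, duration_s + dt / 2, dt)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(t > 0, t ** (shape - 1.0) * np.exp(-t / b), 0.0)
        if peak_delay_s == 0:
            k[0] = 1.0
        k /= k.max()
        return cls(kernel=k, peak_delay_s=peak_delay_s, duration_s=duration_s)


@dataclass
class GroundTruthMap:
    """Per-voxel ground truth used by the synthetic generators.

    ``bf_index`` indexes the frequency list (0..K-1); ``tuning_width`` is the
    Gaussian tuning width in frequency-step units; ``amplitude`` the peak
    %CBV response at the best frequency; ``layer_index`` an optional cortical
    depth bin (0..9).
    """

    bf_index: np.ndarray
    tuning_width: np.ndarray
    amplitude: np.ndarray
    responsive: np.ndarray
    layer_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bf_index = np.asarray(self.bf_index)
        self.tuning_width = np.asarray(self.tuning_width, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.responsive = np.asarray(self.responsive, dtype=bool)
        if np.any(self.amplitude < 0):
            raise InvalidConfigError("amplitudes must be non-negative")
        if np.any(self.bf_index[self.responsive] < 0):
            raise InvalidConfigError("bf_index must be defined for responsive voxels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.amplitude.shape


@dataclass
class FrameBlock:
    """Complex slow-time block: ``data`` has shape (z, x, t) with t samples
    at ``config.frame_rate``."""

    data: np.ndarray
    config: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2:
            raise ValueError("frame block must have at least one spatial axis plus time")
        if self.data.shape[-1] != self.config.frames_per_block:
            raise ValueError(
                f"time axis has {self.data.shape[-1]} samples, expected "
                f"{self.config.frames_per_block}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("frame block contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]


@dataclass
class PowerDopplerSeries:
    """Non-negative power-Doppler values, one sample per block (1 Hz).

    ``values`` has spatial axes first and time (block index) last; ``band``
    records the axial-velocity cutoff (mm/s) applied before the power
    integral, or None for the full Doppler spectrum.
    """

    values: np.ndarray
    band: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("power-Doppler values must be non-negative")


@dataclass
class CBVSeries:
    """%CBV series relative to a baseline window; time axis last, 1 Hz.

    ``invalid`` flags voxels whose baseline was non-positive (values NaN).
    """

    values: np.ndarray
    baseline_window: tuple[int, int] | None = None
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-1]


@dataclass
class TrialTensor:
    """Trial-epoched responses: ``values`` (trial, peristimulus time, *spatial).

    ``times`` gives the peristimulus grid in seconds relative to stimulus
    onset; ``labels`` one stimulus label per trial.
    """

    values: np.ndarray
    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if self.values.shape[1] != len(self.times):
            raise ValueError("peristimulus grid must match the time axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[2:]
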