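"""Synthetic-data generators for the fUS pipeline.

Every generator here is seed-deterministic and produces the inputs the rest
of the pipeline consumes: complex frame blocks mixing tissue clutter, blood
signal and noise; trial-structured %CBV volumes with tonotopic ground truth;
sharp functional-transition patches for the resolution statistic; and a
layered-cortex geometry for depth analyses.

The tissue component of a frame block is exactly rank one (a single spatial
profile times a single slow temporal oscillation), so the behaviour of the
SVD clutter filter on it is analytically known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AcquisitionConfig,
    CBVSeries,
    FrameBlock,
    GroundTruthMap,
    HemodynamicModel,
    InvalidConfigError,
    TrialProtocol,
)

__all__ = [
    "make_frame_block",
    "make_trial_series",
    "make_transition_patch",
    "make_layered_cortex",
    "ResponsePatch",
    "tuning_curve",
]


def tuning_curve(bf_index, tuning_width, amplitude, n_freq: int = 5) -> np.ndarray:
    """Gaussian tuning over the log-spaced frequency grid.

    Response to frequency index i is ``amplitude * exp(-(i - bf)^2 / (2 w^2))``.
    Returns an array with a leading frequency axis of length ``n_freq``.
    """
    bf = np.asarray(bf_index, dtype=float)
    w = np.asarray(tuning_width, dtype=float)
    a = np.asarray(amplitude, dtype=float)
    i = np.arange(n_freq, dtype=float).reshape((n_freq,) + (1,) * bf.ndim)
    return a * np.exp(-((i - bf) ** 2) / (2.0 * w**2))


def make_frame_block(
    config: AcquisitionConfig,
    tissue_amplitude: float,
    blood_fraction,
    blood_velocity,
    seed: int,
    *,
    spatial_shape: tuple[int, int] | None = None,
    tissue_frequency: float = 2.0,
) -> FrameBlock:
    """Simulate one complex slow-time block of tissue + blood + noise.

    Per voxel the slow-time signal is the sum of

    * a spatially coherent, rank-1 tissue component: a shared complex
      oscillation at ``tissue_frequency`` (< 5 Hz) scaled by
      ``tissue_amplitude`` and a fixed smooth spatial profile;
    * a blood component ``sqrt(blood_fraction) * exp(i(2 pi f_D t + phi))``
      with Doppler frequency ``f_D = 2 v f0 / c`` and random initial phase;
    * complex white noise of unit variance.

    ``blood_fraction`` and ``blood_velocity`` (axial, mm/s) are per-voxel
    arrays (or scalars, in which case ``spatial_shape`` must be given).
    """
    if tissue_amplitude < 0:
        raise ValueError("tissue_amplitude must be non-negative")
    if not 0 < tissue_frequency < 5.0:
        raise ValueError("tissue oscillation must be slower than 5 Hz")
    bf = np.asarray(blood_fraction, dtype=float)
    v = np.asarray(blood_velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("blood velocities must be finite")
    if bf.ndim == 0 and v.ndim == 0:
        if spatial_shape is None:
            raise ValueError("spatial_shape required with scalar blood maps")
        bf = np.broadcast_to(bf, spatial_shape)
        v = np.broadcast_to(v, spatial_shape)
    else:
        shape = np.broadcast_shapes(bf.shape, v.shape)
        bf = np.broadcast_to(bf, shape)
        v = np.broadcast_to(v, shape)
    if np.any(bf < 0):
        raise ValueError("blood_fraction must be non-negative")

    rng = np.random.default_rng(seed)
    nt = config.frames_per_block
    t = np.arange(nt) / config.frame_rate

    # Rank-1 tissue clutter: fixed smooth spatial profile x slow oscillation.
    zz = np.linspace(0.0, 1.0, bf.shape[0])[:, None]
    xx = np.linspace(0.0, 1.0, bf.shape[1])[None, :]
    profile = 1.0 + 0.3 * np.cos(np.pi * zz) * np.cos(np.pi * xx)
    tissue_t = np.exp(2j * np.pi * tissue_frequency * t)
    data = tissue_amplitude * profile[..., None] * tissue_t

    f_d = config.doppler_frequency(v)
    phase0 = rng.uniform(0.0, 2.0 * np.pi, size=bf.shape)
    data = data + np.sqrt(bf)[..., None] * np.exp(
        1j * (2.0 * np.pi * f_d[..., None] * t + phase0[..., None])
    )
    noise = (rng.standard_normal(bf.shape + (nt,))
             + 1j * rng.standard_normal(bf.shape + (nt,))) / np.sqrt(2.0)
    data = data + noise
    return FrameBlock(data=data.astype(np.complex128), config=config)


def _trial_onsets(protocol: TrialProtocol, rng: np.random.Generator) -> np.ndarray:
    """Stimulus-onset times (s), on the 1 Hz grid.

    Trials follow each other after ``trial_length_s`` plus a uniform jitter;
    the acquisition is synchronized to each trial start, which at a 1 Hz
    sampling rate amounts to rounding each inter-trial gap to whole seconds.
    """
    n = protocol.n_trials
    jit = rng.uniform(*protocol.jitter_range_s, size=n - 1) if n > 1 else np.empty(0)
    gaps = np.round(protocol.trial_length_s + jit)
    starts = np.concatenate([[0.0], np.cumsum(gaps)])
    return np.round(starts + protocol.baseline_s)


def make_trial_series(
    protocol: TrialProtocol,
    truth: GroundTruthMap,
    hrf: HemodynamicModel,
    noise_sd: float,
    seed: int,
) -> tuple[CBVSeries, pd.DataFrame]:
    """Simulate a 1 Hz %CBV series with jittered, randomly ordered trials.

    Each responsive voxel responds to frequency i with a Gaussian tuning
    factor of its peak amplitude; the stimulus boxcar (``stim_s`` long) is
    convolved with the hemodynamic kernel and added at each onset.
    i.i.d. Gaussian noise of ``noise_sd`` %CBV is added per sample. Returns
    the series and an event table with columns ``onset_s`` and ``label``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    n_freq = len(protocol.frequencies)
    rng = np.random.default_rng(seed)

    labels = np.repeat(np.arange(n_freq), protocol.trials_per_frequency)
    rng.shuffle(labels)
    onsets = _trial_onsets(protocol, rng)

    boxcar = np.ones(int(round(protocol.stim_s)))
    resp_kernel = np.convolve(hrf.kernel, boxcar)
    n_samples = int(onsets[-1] + len(resp_kernel) + protocol.post_s + 1)

    gains = tuning_curve(truth.bf_index, truth.tuning_width, truth.amplitude, n_freq)
    gains = gains * truth.responsive  # non-responsive voxels stay silent

    values = np.zeros(truth.shape + (n_samples,))
    for onset, lab in zip(onsets.astype(int), labels):
        seg = resp_kernel[: n_samples - onset]
        values[..., onset : onset + len(seg)] += gains[lab][..., None] * seg
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)

    events = pd.DataFrame(
        {"onset_s": onsets, "label": [protocol.frequencies[l] for l in labels]}
    )
    return CBVSeries(values=values), events


@dataclass
class ResponsePatch:
    """Windowed trial responses on a small voxel grid.

    ``responses`` has shape (n_trials, n_voxels) with one windowed %CBV
    value per trial and voxel; ``labels`` gives the frequency index of each
    trial; ``coords`` the (row, col) grid position of each voxel in
    voxel-pitch units.
    """

    responses: np.ndarray
    labels: np.ndarray
    coords: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.labels = np.asarray(self.labels)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.responses.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if self.responses.shape[1] != len(self.coords):
            raise ValueError("one coordinate per voxel required")

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]


def make_transition_patch(
    n_rows: int,
    n_cols: int,
    mode: str,
    step_params: dict,
    noise_sd: float,
    protocol: TrialProtocol | None = None,
    seed: int = 0,
) -> tuple[ResponsePatch, GroundTruthMap]:
    """Simulate windowed responses on a grid holding a sharp functional edge.

    ``mode='responsiveness'``: every voxel responds equally to all
    frequencies, with a steep per-column peak amplitude gradient given by
    ``step_params['column_amplitudes']`` (%CBV, length ``n_cols``).

    ``mode='tuning'``: Gaussian tuning of constant amplitude
    (``step_params['amplitude']``) and width (``step_params['width']``,
    frequency steps) whose center starts at ``step_params.get('start', 0)``
    and advances by ``step_params['drift_per_column']`` frequency steps per
    column.

    i.i.d. Gaussian noise of sd ``noise_sd`` is added to every response
    value. Returns the trial responses and the ground truth.
    """
    protocol = protocol or TrialProtocol()
    if n_rows < 1 or n_cols < 1:
        raise InvalidConfigError("patch must have at least one row and column")
    n_freq = len(protocol.frequencies)
    n_per = protocol.trials_per_frequency
    rng = np.random.default_rng(seed)

    cols = np.tile(np.arange(n_cols), n_rows)
    rows = np.repeat(np.arange(n_rows), n_cols)
    coords = np.stack([rows, cols], axis=1)
    n_vox = n_rows * n_cols

    if mode == "responsiveness":
        amps = np.asarray(step_params["column_amplitudes"], dtype=float)
        if len(amps) != n_cols:
            raise InvalidConfigError("need one column amplitude per column")
        amplitude = amps[cols]
        # Flat tuning: identical mean response at every frequency.
        mean_resp = np.broadcast_to(amplitude, (n_freq, n_vox)).copy()
        bf = np.zeros(n_vox, dtype=int)
        width = np.full(n_vox, np.inf)
    elif mode == "tuning":
        amp = float(step_params["amplitude"])
        width_step = float(step_params["width"])
        drift = float(step_params["drift_per_column"])
        start = float(step_params.get("start", 0.0))
        centers = start + drift * cols
        mean_resp = tuning_curve(centers, np.full(n_vox, width_step), amp, n_freq)
        amplitude = np.full(n_vox, amp)
        bf = np.clip(np.round(centers), 0, n_freq - 1).astype(int)
        width = np.full(n_vox, width_step)
    else:
        raise InvalidConfigError(f"unknown transition mode {mode!r}")

    labels = np.repeat(np.arange(n_freq), n_per)
    responses = mean_resp[labels]
    if noise_sd > 0:
        responses = responses + rng.normal(0.0, noise_sd, size=responses.shape)

    truth = GroundTruthMap(
        bf_index=bf.reshape(n_rows, n_cols),
        tuning_width=width.reshape(n_rows, n_cols),
        amplitude=amplitude.reshape(n_rows, n_cols),
        responsive=np.ones((n_rows, n_cols), dtype=bool),
    )
    patch = ResponsePatch(responses=responses, labels=labels, coords=coords,
                          grid_shape=(n_rows, n_cols))
    return patch, truth


class GeometryError(ValueError):
    """Raised when cortical delineation curves are inconsistent."""


def _polyline_y(polyline: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation of a polyline given as (x, y) vertices."""
    p = np.asarray(polyline, dtype=float)
    return np.interp(x, p[:, 0], p[:, 1])


def make_layered_cortex(
    surface_curve,
    deep_curve,
    grid_shape: tuple[int, int],
    n_layers: int = 10,
) -> np.ndarray:
    """Assign each voxel of a (rows=depth axis, cols) grid to a depth layer.

    The cortex lies between two non-crossing polylines (lists of (col, row)
    vertices), surface above deep. Each voxel between them gets layer
    ``floor(n_layers * relative depth)`` along the local surface-to-deep
    segment, clipped to 0..n_layers-1; voxels outside get -1.
    """
    n_rows, n_cols = grid_shape
    x = np.arange(n_cols, dtype=float)
    ys = _polyline_y(surface_curve, x)
    yd = _polyline_y(deep_curve, x)
    if np.any(yd <= ys):
        raise GeometryError("curves cross or touch: surface must lie above deep everywhere")
    rows = np.arange(n_rows, dtype=float)[:, None]
    rel = (rows - ys[None, :]) / (yd - ys)[None, :]
    layer = np.floor(n_layers * rel).astype(int)
    layer = np.clip(layer, 0, n_layers - 1)
    layer[(rel < 0) | (rel > 1)] = -1
    return layer
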