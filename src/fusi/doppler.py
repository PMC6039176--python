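"""Power-Doppler processing: SVD clutter filtering, velocity-band selection,
power integral and %CBV normalization.

A frame block is reshaped into its Casorati matrix (voxels x slow time); the
largest singular components — dominated by spatially coherent tissue motion —
are removed, optionally followed by a low-pass Butterworth filter on the
slow-time (Doppler) axis to keep only slow axial blood velocities. The power
integral over the block yields one power-Doppler value per voxel per second,
which is normalized to a baseline window to give %CBV.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt

from .core import CBVSeries, FrameBlock, PowerDopplerSeries

__all__ = [
    "svd_clutter_filter",
    "velocity_band_filter",
    "power_doppler",
    "power_doppler_series",
    "percent_cbv",
    "InvalidRankError",
    "InvalidCutoffError",
]


class InvalidRankError(ValueError):
    pass


class InvalidCutoffError(ValueError):
    pass


def svd_clutter_filter(block: FrameBlock, n_remove: int,
                       energy_fraction: float | None = None) -> FrameBlock:
    """Remove the largest singular components of the Casorati matrix.

    With ``n_remove=k`` the k largest spatio-temporal singular components
    are zeroed before reconstruction. Alternatively ``energy_fraction=q``
    removes leading components until their cumulative energy (squared
    singular values) reaches a fraction q of the total.
    """
    nt = block.n_frames
    casorati = block.data.reshape(-1, nt)
    if energy_fraction is not None:
        if not 0.0 <= energy_fraction < 1.0:
            raise InvalidRankError("energy_fraction must lie in [0, 1)")
        u, s, vh = np.linalg.svd(casorati, full_matrices=False)
        cum = np.cumsum(s**2) / np.sum(s**2)
        n_remove = int(np.searchsorted(cum, energy_fraction) + 1)
    if not 0 <= n_remove < nt:
        raise InvalidRankError(f"n_remove must be in [0, {nt}), got {n_remove}")
    if n_remove == 0:
        return FrameBlock(data=block.data.copy(), config=block.config)
    u, s, vh = np.linalg.svd(casorati, full_matrices=False)
    s = s.copy()
    s[:n_remove] = 0.0
    filtered = (u * s) @ vh
    return FrameBlock(data=filtered.reshape(block.data.shape), config=block.config)


def velocity_band_filter(block: FrameBlock, vmax: float, order: int = 5) -> FrameBlock:
    """Keep Doppler components below the cutoff of an axial-velocity band.

    The cutoff frequency is ``f_c = 2 vmax f0 / c`` (``vmax`` in mm/s). A
    low-pass Butterworth of the given order is applied to the complex
    slow-time signal forward and backward (zero phase), so the magnitude
    response is squared and no temporal shift is introduced. The filter is
    symmetric in Doppler frequency; the sign of the axial velocity is not
    resolved.
    """
    if vmax <= 0:
        raise InvalidCutoffError("vmax must be positive")
    cfg = block.config
    f_c = float(cfg.doppler_frequency(vmax))
    nyquist = cfg.frame_rate / 2.0
    if f_c >= nyquist:
        raise InvalidCutoffError(
            f"cutoff {f_c:.1f} Hz is at or above Nyquist ({nyquist:.1f} Hz)"
        )
    b, a = butter(order, f_c, btype="low", fs=cfg.frame_rate)
    filtered = filtfilt(b, a, block.data, axis=-1)
    return FrameBlock(data=filtered, config=block.config)


def power_doppler(block: FrameBlock) -> np.ndarray:
    """Per-voxel mean of |s(t)|^2 over the block (the power integral)."""
    if block.data.size == 0:
        raise ValueError("empty frame block")
    return np.mean(np.abs(block.data) ** 2, axis=-1)


def power_doppler_series(blocks, band: float | None = None) -> PowerDopplerSeries:
    """Stack per-block power images into a 1 Hz series (time axis last)."""
    images = [power_doppler(b) for b in blocks]
    return PowerDopplerSeries(values=np.stack(images, axis=-1), band=band)


def percent_cbv(pd: PowerDopplerSeries | np.ndarray,
                baseline_window: tuple[int, int]) -> CBVSeries:
    """Normalize a power-Doppler series to a baseline window.

    Returns ``100 (PD(t) - B) / B`` per voxel with B the mean power over
    ``baseline_window`` (inclusive sample indices). Voxels with non-positive
    baseline are flagged invalid and set to NaN.
    """
    values = pd.values if isinstance(pd, PowerDopplerSeries) else np.asarray(pd, float)
    lo, hi = baseline_window
    n = values.shape[-1]
    if not (0 <= lo <= hi < n):
        raise ValueError(f"baseline window [{lo}, {hi}] outside series of length {n}")
    baseline = values[..., lo : hi + 1].mean(axis=-1)
    invalid = baseline <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cbv = 100.0 * (values - baseline[..., None]) / baseline[..., None]
    cbv[invalid] = np.nan
    return CBVSeries(values=cbv, baseline_window=(lo, hi), invalid=invalid)
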