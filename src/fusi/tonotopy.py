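"""Best-frequency map post-processing.

Display masking (minimum response + correlation with the mean hemodynamic
response), spatial smoothing of the BF map, projection onto the cortical
surface, and slice re-matching against a vascular reference stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "BFMap",
    "display_mask",
    "smooth_maps",
    "surface_view",
    "match_plane",
]


@dataclass
class BFMap:
    """Best-frequency map with its display mask.

    ``bf`` may hold interpolated (non-integer) values after smoothing;
    ``provenance`` records the thresholds that produced the mask.
    """

    bf: np.ndarray
    mask: np.ndarray
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.bf = np.asarray(self.bf, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bf.shape != self.mask.shape:
            raise ValueError("bf and mask shapes differ")


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t distribution."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isnan(t), 1.0, np.where(np.isinf(t), 0.0, p))


def display_mask(
    max_response: np.ndarray,
    bf_timecourse: np.ndarray,
    mean_hrf: np.ndarray,
    min_response: float = 15.0,
    corr_alpha: float = 1e-3,
) -> np.ndarray:
    """Voxels worth displaying on a tonotopic map.

    A voxel is kept iff (i) its maximal tuning-curve response
    (``max_response``, %CBV) reaches ``min_response`` and (ii) the Pearson
    correlation between its mean time course at its best frequency
    (``bf_timecourse``, time axis first) and the mean hemodynamic response
    is significant at ``corr_alpha``.
    """
    mean_hrf = np.asarray(mean_hrf, dtype=float)
    tc = np.asarray(bf_timecourse, dtype=float)
    if tc.shape[0] != len(mean_hrf):
        raise ValueError("time course grid does not match the mean hemodynamic response")
    n = len(mean_hrf)
    if n < 3:
        raise ValueError("need at least 3 time points for the correlation test")

    hrf_c = mean_hrf - mean_hrf.mean()
    tc_c = tc - tc.mean(axis=0)
    denom = np.sqrt((tc_c**2).sum(axis=0) * (hrf_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("t...,t->...", tc_c, hrf_c) / denom
    p = _pearson_p(r, n)
    return (np.asarray(max_response) >= min_response) & (p < corr_alpha)


def _gaussian_kernel_2d(sigma: float = 0.5, radius: int = 1) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def smooth_maps(bf: BFMap, sigma: float = 0.5) -> BFMap:
    """Smooth a BF map for display and clean its mask.

    BF values are smoothed in-plane with a 3 x 3 x 1 Gaussian (sigma in
    voxels) whose kernel is renormalized over the mask, treating the BF
    index as ordinal on the log-frequency grid; the mask is cleaned with a
    3 x 3 x 3 median filter to remove isolated voxels. Works on 3-D maps
    (2-D maps are treated as a single slice).
    """
    vol = bf.bf
    mask = bf.mask
    squeeze = vol.ndim == 2
    if squeeze:
        vol = vol[..., None]
        mask = mask[..., None]
    if vol.ndim != 3:
        raise ValueError("expected a 2-D or 3-D map")

    kern = _gaussian_kernel_2d(sigma)[:, :, None]
    filled = np.where(mask, vol, 0.0)
    num = ndimage.convolve(filled, kern, mode="constant")
    den = ndimage.convolve(mask.astype(float), kern, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = np.where(den > 0, num / den, np.nan)

    new_mask = ndimage.median_filter(mask.astype(np.uint8), size=(3, 3, 3),
                                     mode="constant") > 0
    if squeeze:
        smoothed = smoothed[..., 0]
        new_mask = new_mask[..., 0]
    prov = dict(bf.provenance or {})
    prov.update(smoothing_sigma=sigma, median_size=3)
    return BFMap(bf=smoothed, mask=new_mask, provenance=prov)


def surface_view(
    bf: BFMap,
    surface: np.ndarray,
    depth_range: tuple[int, int] = (5, 10),
) -> np.ndarray:
    """Project the BF map onto the cortical surface.

    ``surface`` gives, per lateral position (all axes except the first),
    the depth index (axis 0) of the cortical surface; the surface value at
    a position is the mean of masked BF values at depths ``surface + 5`` to
    ``surface + 10`` (inclusive) straight below it. Positions with no
    masked voxel in that range are NaN.
    """
    surface = np.asarray(surface)
    if surface.shape != bf.bf.shape[1:]:
        raise ValueError("surface delineation must match the lateral map shape")
    lo, hi = depth_range
    n_depth = bf.bf.shape[0]
    out = np.full(surface.shape, np.nan)
    it = np.ndindex(*surface.shape)
    for pos in it:
        depths = np.arange(surface[pos] + lo, surface[pos] + hi + 1)
        depths = depths[(depths >= 0) & (depths < n_depth)]
        col_idx = (depths,) + pos
        vals = bf.bf[col_idx]
        m = bf.mask[col_idx] & ~np.isnan(vals)
        if np.any(m):
            out[pos] = vals[m].mean()
    return out


def match_plane(image: np.ndarray, stack: np.ndarray) -> tuple[int, float, bool]:
    """Find the reference-stack slice best matching a power-Doppler image.

    Both the image and each slice of ``stack`` (slice axis first) are
    z-scored before computing the Pearson correlation; returns the argmax
    slice index, its correlation, and a flag set when the maximum is tied
    (lowest index returned).
    """
    stack = np.asarray(stack, dtype=float)
    image = np.asarray(image, dtype=float)
    if stack.ndim != image.ndim + 1 or stack.shape[1:] != image.shape:
        raise ValueError("image and stack slices are not commensurate")
    if stack.shape[0] == 0:
        raise ValueError("empty stack")

    def zscore(a):
        sd = a.std()
        return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)

    img_z = zscore(image).ravel()
    scores = np.array([np.mean(zscore(s).ravel() * img_z) for s in stack])
    best = int(np.argmax(scores))
    tie = bool(np.sum(np.isclose(scores, scores[best], rtol=0, atol=1e-12)) > 1)
    return best, float(scores[best]), tie
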