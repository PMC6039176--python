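"""Trial-level response analysis.

Epochs 1 Hz %CBV series into peristimulus trial tensors, computes windowed
response scalars and per-voxel frequency tuning statistics (one-way ANOVA
with Wilcoxon rank-sum post-hocs), estimates the mean hemodynamic response
over strongly responsive voxels, deconvolves per-frequency impulse
responses with an FIR general linear model, and quantifies stimulation-
evoked ROI responses.

Window endpoints are inclusive on the 1 Hz grid: a "3 to 5 s" window means
the samples at 3, 4 and 5 s after onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CBVSeries, TrialTensor

__all__ = [
    "epoch_trials",
    "windowed_response",
    "tuning_stats",
    "mean_hemodynamic_response",
    "glm_fir",
    "stim_roi_response",
    "TuningMap",
    "ImpulseResponseSet",
    "significance_stars",
]


@dataclass
class TuningMap:
    """Per-voxel tuning: mean and sem per label, best frequency, statistics.

    ``curve`` and ``sem`` have a leading label axis; ``posthoc_p`` has a
    leading label-pair axis ordered as ``pairs``. Post-hoc p-values are NaN
    where the ANOVA did not reach ``posthoc_alpha``, or where a label had
    fewer than two valid trials (``valid`` False).
    """

    curve: np.ndarray
    sem: np.ndarray
    bf_index: np.ndarray
    anova_p: np.ndarray
    posthoc_p: np.ndarray
    pairs: list[tuple[int, int]]
    valid: np.ndarray
    posthoc_alpha: float = 1e-3


@dataclass
class ImpulseResponseSet:
    """FIR-GLM kernels: ``kernels`` (lag, frequency, *spatial), 1 Hz lags."""

    kernels: np.ndarray
    lags: np.ndarray
    labels: np.ndarray
    intercept: np.ndarray


def epoch_trials(
    cbv: CBVSeries | np.ndarray,
    events: pd.DataFrame,
    window: tuple[float, float],
    baseline: tuple[float, float] = (-10.0, -1.0),
) -> TrialTensor:
    """Cut a 1 Hz series into peristimulus trials, baseline-corrected.

    ``window`` (inclusive, s relative to onset) defines the peristimulus
    grid; each trial is corrected by subtracting the mean of its own
    ``baseline`` window (pre-onset). Trials whose window or baseline falls
    outside the series are dropped with a warning.
    """
    values = cbv.values if isinstance(cbv, CBVSeries) else np.asarray(cbv, float)
    n = values.shape[-1]
    times = np.arange(int(round(window[0])), int(round(window[1])) + 1)
    base_t = np.arange(int(round(baseline[0])), int(round(baseline[1])) + 1)

    trials, labels = [], []
    for _, ev in events.iterrows():
        onset = int(round(ev["onset_s"]))
        idx = onset + times
        bidx = onset + base_t
        if idx.min() < 0 or idx.max() >= n or bidx.min() < 0 or bidx.max() >= n:
            continue
        epoch = values[..., idx]
        epoch = epoch - values[..., bidx].mean(axis=-1, keepdims=True)
        trials.append(np.moveaxis(epoch, -1, 0))  # time axis first, then spatial
        labels.append(ev["label"])
    n_dropped = len(events) - len(trials)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} truncated trial(s)", stacklevel=2)
    if not trials:
        raise ValueError("no complete trials inside the series")
    return TrialTensor(values=np.stack(trials), times=times.astype(float),
                       labels=np.asarray(labels))


def windowed_response(tensor: TrialTensor, window: tuple[float, float]) -> np.ndarray:
    """Mean response over peristimulus samples inside the closed window.

    Returns an array of shape (trial, *spatial).
    """
    sel = (tensor.times >= window[0]) & (tensor.times <= window[1])
    if not np.any(sel):
        raise ValueError(f"window {window} contains no peristimulus samples")
    return tensor.values[:, sel].mean(axis=1)


def _pairwise_ranksum(groups, pairs, out_shape):
    p = np.full((len(pairs),) + out_shape, np.nan)
    for k, (i, j) in enumerate(pairs):
        p[k] = stats.ranksums(groups[i], groups[j], axis=0).pvalue
    return p


def tuning_stats(
    responses: np.ndarray,
    labels: np.ndarray,
    posthoc_alpha: float = 1e-3,
) -> TuningMap:
    """Per-voxel frequency tuning from per-trial windowed responses.

    ``responses`` has shape (trial, *spatial). A one-way ANOVA across labels
    is computed per voxel; where it reaches ``posthoc_alpha``, pairwise
    Wilcoxon rank-sum tests compare every label pair. The best frequency is
    the argmax of the label means.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    groups = [responses[labels == c] for c in classes]
    counts = np.array([g.shape[0] for g in groups])
    if np.any(counts < 2):
        raise ValueError("every label needs at least 2 trials")
    spatial = responses.shape[1:]

    curve = np.stack([g.mean(axis=0) for g in groups])
    sem = np.stack([g.std(axis=0, ddof=1) / np.sqrt(g.shape[0]) for g in groups])
    bf_index = np.argmax(curve, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        anova = stats.f_oneway(*groups, axis=0)
    # Zero-variance voxels yield NaN F; treat as "no evidence of tuning".
    anova_p = np.nan_to_num(np.asarray(anova.pvalue, dtype=float), nan=1.0)
    anova_p = anova_p.reshape(spatial)

    pairs = [(i, j) for i in range(len(classes)) for j in range(i + 1, len(classes))]
    posthoc_p = np.full((len(pairs),) + spatial, np.nan)
    sig = anova_p < posthoc_alpha
    if np.any(sig):
        all_p = _pairwise_ranksum(groups, pairs, spatial)
        if spatial:
            posthoc_p[:, sig] = all_p[:, sig]
        else:
            posthoc_p = all_p
    valid = np.ones(spatial, dtype=bool)
    return TuningMap(curve=curve, sem=sem, bf_index=bf_index, anova_p=anova_p,
                     posthoc_p=posthoc_p, pairs=pairs, valid=valid,
                     posthoc_alpha=posthoc_alpha)


def mean_hemodynamic_response(
    tensor: TrialTensor,
    z_threshold: float = 3.0,
    response_window: tuple[float, float] = (3.0, 5.0),
) -> np.ndarray:
    """Average peristimulus time course of strongly responsive voxels.

    A voxel's z-score is the mean of its windowed responses divided by
    their standard error across trials; voxels with z above the threshold
    are averaged (over trials and voxels) and the result is normalized to
    unit peak.
    """
    resp = windowed_response(tensor, response_window)  # (trial, *spatial)
    mean = resp.mean(axis=0)
    sem = resp.std(axis=0, ddof=1) / np.sqrt(resp.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sem > 0, mean / sem, np.inf * np.sign(mean))
    passing = z > z_threshold
    if not np.any(passing):
        raise ValueError(
            f"no voxel exceeds z-score {z_threshold}; consider lowering the threshold"
        )
    course = tensor.values[..., passing].mean(axis=(0, 2))
    peak = np.abs(course).max()
    if peak == 0:
        return course
    return course / course.max()


def glm_fir(
    cbv: CBVSeries | np.ndarray,
    events: pd.DataFrame,
    lag_window: tuple[float, float] = (0.0, 8.0),
    max_condition: float = 1e8,
) -> ImpulseResponseSet:
    """Estimate per-frequency voxel impulse responses with an FIR GLM.

    The design matrix holds one indicator column per (label, lag) pair —
    X[t, (f,l)] = 1 when a label-f stimulus started l seconds before t —
    plus an intercept; the least-squares solution per voxel gives the
    impulse response at each lag without assuming a hemodynamic shape.
    Jittered inter-stimulus intervals make the design full rank.
    """
    values = cbv.values if isinstance(cbv, CBVSeries) else np.asarray(cbv, float)
    n = values.shape[-1]
    lags = np.arange(int(round(lag_window[0])), int(round(lag_window[1])) + 1)
    classes = np.unique(np.asarray(events["label"]))
    n_l, n_c = len(lags), len(classes)

    X = np.zeros((n, n_c * n_l + 1))
    X[:, -1] = 1.0
    for _, ev in events.iterrows():
        onset = int(round(ev["onset_s"]))
        c = int(np.searchsorted(classes, ev["label"]))
        t = onset + lags
        ok = (t >= 0) & (t < n)
        np.add.at(X, (t[ok], c * n_l + np.arange(n_l)[ok]), 1.0)

    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"FIR design is rank-deficient (condition number {cond:.3g}); "
            "jitter the inter-stimulus intervals"
        )
    y = values.reshape(-1, n).T  # (time, voxels)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    kernels = beta[:-1].reshape(n_c, n_l, -1).transpose(1, 0, 2)
    kernels = kernels.reshape((n_l, n_c) + values.shape[:-1])
    intercept = beta[-1].reshape(values.shape[:-1])
    return ImpulseResponseSet(kernels=kernels, lags=lags.astype(float),
                              labels=classes, intercept=intercept)


def significance_stars(p: float) -> str:
    """Significance tiers: *** p<1e-3, ** p<1e-2, * p<5e-2, 'ns' otherwise."""
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def stim_roi_response(
    tensor: TrialTensor,
    roi: np.ndarray,
    window: tuple[float, float] = (3.0, 6.0),
) -> pd.DataFrame:
    """ROI-averaged stimulation responses per condition.

    For each condition (trial label, e.g. electrode position) the windowed
    %CBV is averaged over the ROI per trial; the table reports the mean,
    the sem and mean +/- 2 sem over trials, a two-sided Wilcoxon signed-rank
    test of the per-trial values against zero, and its significance tier.
    """
    roi = np.asarray(roi, dtype=bool)
    if not np.any(roi):
        raise ValueError("ROI mask is empty")
    resp = windowed_response(tensor, window)  # (trial, *spatial)
    roi_resp = resp[:, roi].mean(axis=1)

    rows = []
    for cond in np.unique(tensor.labels):
        r = roi_resp[tensor.labels == cond]
        m = r.mean()
        sem = r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan
        if np.allclose(r, 0):
            p = 1.0  # signed-rank undefined when every difference is zero
        else:
            p = stats.wilcoxon(r, alternative="two-sided").pvalue
        rows.append({"condition": cond, "mean": m, "sem": sem,
                     "lo": m - 2 * sem, "hi": m + 2 * sem,
                     "p_value": p, "stars": significance_stars(p),
                     "n_trials": len(r)})
    return pd.DataFrame(rows)
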