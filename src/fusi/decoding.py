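"""Multivoxel decoding of stimulus frequency.

A five-class linear decoder with a leave-one-out strategy: every class pair
gets a linear boundary fitted on the training trials, and the held-out
trial is classified by majority vote over the pairwise boundaries. The
plain decoder uses the mean-difference (nearest-centroid) hyperplane
through the midpoint of the class means; the Fisher decoder normalizes the
mean difference by the pooled within-class covariance (with optional
shrinkage towards its diagonal) to account for noise correlations between
voxels. Statistical significance comes from a label-permutation null, and
pseudo-populations concatenate voxel responses across separately recorded
slices sharing the stimulus labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "DecodingDataset",
    "DecodingResult",
    "build_pseudopopulation",
    "loo_ovo_decode",
    "fisher_decode",
    "permutation_test",
    "depth_decoding",
    "rm_anova_1way",
]


@dataclass
class DecodingDataset:
    """Trial x voxel response matrix with one label per trial."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be (n_trials, n_voxels) with one label per row")
        classes, counts = np.unique(self.y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 trials")
        self.classes_ = classes

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]


@dataclass
class DecodingResult:
    """Leave-one-out decoding outcome.

    ``accuracy`` is the fraction of held-out trials classified correctly;
    ``null_distribution`` and ``p_value`` are filled by
    :func:`permutation_test`. ``p_value`` is floored at 1/n_permutations.
    """

    accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)
    predictions: np.ndarray | None = None
    null_distribution: np.ndarray | None = None
    p_value: float | None = None
    significant: bool | None = None
    n_permutations: int | None = None
    degenerate: bool = False


def _check_equal_classes(y: np.ndarray) -> tuple[np.ndarray, int]:
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts != counts[0]):
        raise ValueError("decoder expects equal trial counts per class")
    return classes, int(counts[0])


def _majority_vote(votes: np.ndarray, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Majority vote per trial; ties broken uniformly at random."""
    counts = np.zeros((votes.shape[0], n_classes), dtype=int)
    for k in range(votes.shape[1]):
        np.add.at(counts, (np.arange(votes.shape[0]), votes[:, k]), 1)
    best = counts.max(axis=1, keepdims=True)
    pred = np.empty(votes.shape[0], dtype=int)
    for t in range(votes.shape[0]):
        winners = np.flatnonzero(counts[t] == best[t])
        pred[t] = winners[0] if len(winners) == 1 else rng.choice(winners)
    return pred


def _result_from_predictions(pred: np.ndarray, y_idx: np.ndarray,
                             classes: np.ndarray) -> DecodingResult:
    acc = float(np.mean(pred == y_idx))
    per_class = {classes[c]: float(np.mean(pred[y_idx == c] == c))
                 for c in range(len(classes))}
    return DecodingResult(accuracy=acc, per_class_accuracy=per_class, predictions=pred)


def _class_trial_matrix(X: np.ndarray, y_idx: np.ndarray, K: int, n_per: int):
    """Trials reordered as (fold, class, voxel), keeping within-class order."""
    order = np.stack([np.flatnonzero(y_idx == c) for c in range(K)])  # (K, T)
    return X[order].transpose(1, 0, 2), order  # (T, K, p)


def loo_ovo_decode(ds: DecodingDataset, seed: int = 0) -> DecodingResult:
    """Leave-one-out one-vs-one nearest-centroid decoding.

    Cross-validation folds hold out one trial per class, so every pairwise
    boundary is trained on the same number of trials from each of its two
    classes (9 of 10 in the standard protocol). For each held-out trial and
    class pair (a, b), the boundary is the hyperplane normal to the
    difference of the training class means through their midpoint; the
    trial votes for the nearer mean, and the predicted class is the
    majority vote over all pairs (ties broken at random, seeded).
    """
    classes, n_per = _check_equal_classes(ds.y)
    K = len(classes)
    rng = np.random.default_rng(seed)
    y_idx = np.searchsorted(classes, ds.y)
    Xc, order = _class_trial_matrix(ds.X, y_idx, K, n_per)  # (T, K, p)

    sums = Xc.sum(axis=0)                      # (K, p)
    mu_fold = (sums[None] - Xc) / (n_per - 1)  # training means per fold

    pair_list = [(a, b) for a in range(K) for b in range(a + 1, K)]
    votes = np.empty((n_per, K, len(pair_list)), dtype=int)
    for k, (a, b) in enumerate(pair_list):
        w = mu_fold[:, a] - mu_fold[:, b]                      # (T, p)
        mid = 0.5 * (mu_fold[:, a] + mu_fold[:, b])            # (T, p)
        score = np.einsum("tcp,tp->tc", Xc - mid[:, None, :], w)
        votes[..., k] = np.where(score > 0, a, b)
    pred_fold = _majority_vote(votes.reshape(-1, len(pair_list)), K, rng)
    # Map fold-ordered predictions back to the original trial order.
    pred = np.empty(ds.X.shape[0], dtype=int)
    pred[order.T.ravel()] = pred_fold
    return _result_from_predictions(pred, y_idx, classes)


def fisher_decode(ds: DecodingDataset, shrinkage: float = 0.1,
                  seed: int = 0) -> DecodingResult:
    """Leave-one-out one-vs-one Fisher (covariance-normalized) decoding.

    The pairwise boundary direction is ``Sigma^-1 (mu_a - mu_b)`` with the
    pooled within-class covariance regularized as
    ``(1 - lambda) Sigma + lambda diag(Sigma)``; the threshold sits at the
    midpoint of the class means. With isotropic within-class covariance
    this reduces to the plain mean-difference decoder.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    classes, n_per = _check_equal_classes(ds.y)
    K = len(classes)
    rng = np.random.default_rng(seed)
    y_idx = np.searchsorted(classes, ds.y)
    Xc, order = _class_trial_matrix(ds.X, y_idx, K, n_per)  # (T, K, p)
    p = Xc.shape[2]
    pair_list = [(a, b) for a in range(K) for b in range(a + 1, K)]
    votes = np.empty((n_per, K, len(pair_list)), dtype=int)

    for t in range(n_per):
        train = np.delete(Xc, t, axis=0)            # (T-1, K, p)
        mu = train.mean(axis=0)                     # (K, p)
        resid = (train - mu[None]).reshape(-1, p)
        dof = resid.shape[0] - K
        sigma = resid.T @ resid / dof
        sigma_reg = (1.0 - shrinkage) * sigma + shrinkage * np.diag(np.diag(sigma))
        try:
            chol = cho_factor(sigma_reg)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular; increase shrinkage"
            ) from err
        for k, (a, b) in enumerate(pair_list):
            w = cho_solve(chol, mu[a] - mu[b])
            score = (Xc[t] - 0.5 * (mu[a] + mu[b])) @ w
            votes[t, :, k] = np.where(score > 0, a, b)
    pred_fold = _majority_vote(votes.reshape(-1, len(pair_list)), K, rng)
    pred = np.empty(ds.X.shape[0], dtype=int)
    pred[order.T.ravel()] = pred_fold
    return _result_from_predictions(pred, y_idx, classes)


def permutation_test(
    decoder,
    ds: DecodingDataset,
    n_perm: int = 100,
    alpha_quantile: float = 0.95,
    seed: int = 0,
) -> DecodingResult:
    """Label-permutation null for a decoder.

    ``decoder`` is a callable ``(ds, seed) -> DecodingResult``. Labels are
    shuffled across trials ``n_perm`` times; the observed accuracy is
    significant when above the ``alpha_quantile`` percentile of the null
    accuracies, and the reported p-value is the null exceedance fraction
    floored at 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    observed = decoder(ds, seed=int(rng.integers(2**31)))
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_shuf = rng.permutation(ds.y)
        ds_shuf = DecodingDataset(X=ds.X, y=y_shuf, groups=ds.groups)
        null[i] = decoder(ds_shuf, seed=int(rng.integers(2**31))).accuracy
    p = max(1.0 / n_perm, float(np.mean(null >= observed.accuracy)))
    observed.null_distribution = null
    observed.p_value = p
    observed.significant = bool(observed.accuracy > np.percentile(null, 100 * alpha_quantile))
    observed.n_permutations = n_perm
    observed.degenerate = n_perm < 20  # too few permutations for a stable tail
    if observed.degenerate:
        warnings.warn(f"null distribution from only {n_perm} permutation(s); "
                      "p-value resolution is degenerate", stacklevel=2)
    return observed


def build_pseudopopulation(datasets: list[DecodingDataset], seed: int = 0) -> DecodingDataset:
    """Group trials with identical labels across slices into pseudo-trials.

    Pseudo-trial t of class c concatenates the voxel vectors of one
    randomly drawn class-c trial (without replacement) from each slice. If
    slices disagree on trial counts per class, all are truncated to the
    minimum with a warning.
    """
    if not datasets:
        raise ValueError("need at least one slice dataset")
    rng = np.random.default_rng(seed)
    classes = datasets[0].classes_
    for ds in datasets[1:]:
        if not np.array_equal(ds.classes_, classes):
            raise ValueError("all slices must share the label set")

    counts = np.array([[np.sum(ds.y == c) for c in classes] for ds in datasets])
    m_per_class = counts.min(axis=0)
    if np.any(counts != m_per_class[None, :]):
        warnings.warn("unequal trials per class across slices; truncating to minimum",
                      stacklevel=2)

    X_parts, y_out = [], []
    for ci, c in enumerate(classes):
        m = m_per_class[ci]
        cols = []
        for ds in datasets:
            idx = np.flatnonzero(ds.y == c)
            take = rng.permutation(idx)[:m]
            cols.append(ds.X[take])
        X_parts.append(np.concatenate(cols, axis=1))
        y_out.extend([c] * m)
    return DecodingDataset(X=np.concatenate(X_parts, axis=0), y=np.asarray(y_out))


def rm_anova_1way(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Classical two-way (subject x condition) decomposition without
    sphericity correction: F = MS_condition / MS_(subject x condition).
    Returns (F, p).
    """
    a = np.asarray(data, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    s, d = a.shape
    grand = a.mean()
    cond_means = a.mean(axis=0)
    subj_means = a.mean(axis=1)
    ss_cond = s * np.sum((cond_means - grand) ** 2)
    ss_err = np.sum((a - cond_means[None, :] - subj_means[:, None] + grand) ** 2)
    df_cond = d - 1
    df_err = (s - 1) * (d - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err == 0:
        return np.inf if ms_cond > 0 else 0.0, 0.0 if ms_cond > 0 else 1.0
    f = ms_cond / ms_err
    return float(f), float(stats.f.sf(f, df_cond, df_err))


def depth_decoding(
    subject_data: list[tuple[DecodingDataset, np.ndarray]],
    seed: int = 0,
    decoder=loo_ovo_decode,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Depth-resolved decoding with voxel-count equalization.

    ``subject_data`` holds one (dataset, voxel layer index) pair per
    subject (craniotomy). Within each subject, depths with no voxels are
    excluded (warned); remaining depths are subsampled (seeded) to the
    minimum voxel count so every depth uses equally many voxels, and the
    decoder runs per depth. Returns (depths, accuracy matrix
    subjects x depths, F, p) with the repeated-measures ANOVA over depth.
    """
    if len(subject_data) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    all_layers = np.unique(np.concatenate(
        [np.unique(layers[layers >= 0]) for _, layers in subject_data]))

    acc = np.full((len(subject_data), len(all_layers)), np.nan)
    for si, (ds, layers) in enumerate(subject_data):
        layers = np.asarray(layers)
        present = [d for d in all_layers if np.sum(layers == d) > 0]
        missing = set(all_layers) - set(present)
        if missing:
            warnings.warn(f"subject {si}: no voxels at depth(s) {sorted(missing)}; excluded",
                          stacklevel=2)
        n_min = min(int(np.sum(layers == d)) for d in present)
        for di, d in enumerate(all_layers):
            if d not in present:
                continue
            vox = np.flatnonzero(layers == d)
            take = rng.permutation(vox)[:n_min]
            sub = DecodingDataset(X=ds.X[:, take], y=ds.y)
            acc[si, di] = decoder(sub, seed=int(rng.integers(2**31))).accuracy

    complete = ~np.any(np.isnan(acc), axis=0)
    if complete.sum() < 2:
        warnings.warn("fewer than 2 depths measured in every subject; "
                      "depth ANOVA undefined", stacklevel=2)
        return all_layers, acc, np.nan, np.nan
    f, p = rm_anova_1way(acc[:, complete])
    return all_layers, acc, f, p
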