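"""Linear and Fisher decoders, permutation nulls, pseudo-populations,
depth-resolved decoding with repeated-measures ANOVA."""

import numpy as np
import pytest

from fusi import decoding
from fusi.decoding import DecodingDataset


def gaussian_classes(n_classes=5, n_per=10, n_vox=100, sep=5.0, seed=0):
    """Class means `sep` noise-sds apart along random directions, unit noise."""
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_classes, n_vox))
    means *= sep / np.linalg.norm(means, axis=1, keepdims=True)
    y = np.repeat(np.arange(n_classes), n_per)
    X = means[y] + rng.standard_normal((n_classes * n_per, n_vox))
    return DecodingDataset(X=X, y=y)


class TestLooOvoDecode:
    def test_separable_data_perfect(self):
        ds = gaussian_classes(sep=50.0, seed=1)  # >=10x the within-class spread
        assert decoding.loo_ovo_decode(ds, seed=0).accuracy == 1.0

    def test_two_class_toy_enumeration(self):
        """{0,0,1,1}: every fold trains on one 0 and one 1; midpoint at 0.5
        classifies both held-out trials correctly -> accuracy 1.0."""
        ds = DecodingDataset(X=np.array([[0.0], [0.0], [1.0], [1.0]]),
                             y=np.array(["a", "a", "b", "b"]))
        assert decoding.loo_ovo_decode(ds, seed=0).accuracy == 1.0

    def test_chance_level_under_null_labels(self):
        accs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((50, 50))
            y = rng.permutation(np.repeat(np.arange(5), 10))
            accs.append(decoding.loo_ovo_decode(DecodingDataset(X=X, y=y),
                                                seed=seed).accuracy)
        m, sem = np.mean(accs), np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert m == pytest.approx(0.2, abs=3 * sem + 1e-9)

    def test_affine_invariance(self):
        ds = gaussian_classes(sep=2.0, n_vox=20, seed=2)
        shifted = DecodingDataset(X=3.5 * ds.X + 7.0, y=ds.y)
        a = decoding.loo_ovo_decode(ds, seed=3)
        b = decoding.loo_ovo_decode(shifted, seed=3)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_per_class_accuracy_bookkeeping(self):
        ds = gaussian_classes(sep=50.0, seed=4)
        res = decoding.loo_ovo_decode(ds, seed=0)
        assert set(res.per_class_accuracy) == set(range(5))
        assert all(v == 1.0 for v in res.per_class_accuracy.values())

    def test_unequal_classes_rejected(self):
        with pytest.raises(ValueError):
            decoding.loo_ovo_decode(DecodingDataset(
                X=np.zeros((5, 2)), y=np.array([0, 0, 0, 1, 1])))


class TestFisherDecode:
    def test_matches_plain_decoder_when_isotropic(self):
        """With isotropic noise the covariance normalization is immaterial."""
        ds = gaussian_classes(sep=3.0, n_vox=10, n_per=20, seed=5)
        plain = decoding.loo_ovo_decode(ds, seed=6)
        fisher = decoding.fisher_decode(ds, shrinkage=0.1, seed=6)
        agree = np.mean(plain.predictions == fisher.predictions)
        assert agree > 0.9

    def test_correlated_noise_advantage(self):
        """Noise elongated obliquely to the mean difference: normalizing by
        the covariance recovers accuracy the plain decoder loses."""
        rng = np.random.default_rng(7)
        n_per = 30
        theta = np.pi / 4
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        cov = R @ np.diag([25.0, 0.05]) @ R.T
        mean_diff = np.array([2.0, 0.0])
        y = np.repeat([0, 1], n_per)
        noise = rng.multivariate_normal([0, 0], cov, size=2 * n_per)
        X = np.outer(y, mean_diff) + noise
        ds = DecodingDataset(X=X, y=y)
        plain = decoding.loo_ovo_decode(ds, seed=8).accuracy
        fisher = decoding.fisher_decode(ds, shrinkage=0.0, seed=8).accuracy
        assert fisher > plain

    def test_full_shrinkage_equals_diagonal_decoder(self):
        ds = gaussian_classes(sep=2.0, n_vox=5, n_per=10, seed=9)
        res = decoding.fisher_decode(ds, shrinkage=1.0, seed=10)

        # independent diagonal-covariance reference, same fold structure
        classes = ds.classes_
        K, T = len(classes), 10
        y_idx = np.searchsorted(classes, ds.y)
        order = np.stack([np.flatnonzero(y_idx == c) for c in range(K)])
        Xc = ds.X[order].transpose(1, 0, 2)
        preds = np.empty_like(y_idx)
        for t in range(T):
            train = np.delete(Xc, t, axis=0)
            mu = train.mean(axis=0)
            var = ((train - mu[None]) ** 2).reshape(-1, ds.X.shape[1]).sum(axis=0) \
                / (train.shape[0] * K - K)
            for c in range(K):
                votes = np.zeros(K, int)
                for a in range(K):
                    for b in range(a + 1, K):
                        w = (mu[a] - mu[b]) / var
                        s = (Xc[t, c] - 0.5 * (mu[a] + mu[b])) @ w
                        votes[a if s > 0 else b] += 1
                preds[order[c, t]] = np.argmax(votes)  # no ties in this data
        np.testing.assert_array_equal(res.predictions, preds)

    def test_invariance_under_invertible_linear_map(self):
        ds = gaussian_classes(sep=3.0, n_vox=5, n_per=20, seed=11)
        rng = np.random.default_rng(12)
        A = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        mapped = DecodingDataset(X=ds.X @ A, y=ds.y)
        a = decoding.fisher_decode(ds, shrinkage=0.0, seed=13)
        b = decoding.fisher_decode(mapped, shrinkage=0.0, seed=13)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_singular_covariance_without_shrinkage_raises(self):
        ds = gaussian_classes(n_vox=200, n_per=3, seed=14)  # p >> n
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            decoding.fisher_decode(ds, shrinkage=0.0)


class TestPermutationTest:
    def test_separable_data_significant(self):
        ds = gaussian_classes(sep=5.0, seed=7)
        res = decoding.permutation_test(decoding.loo_ovo_decode, ds,
                                        n_perm=100, seed=11)
        assert res.significant
        assert res.p_value <= 0.01  # floored at 1/n_perm
        assert res.null_distribution.shape == (100,)

    def test_null_distribution_mean_near_chance(self):
        ds = gaussian_classes(sep=0.0, n_per=4, n_vox=10, seed=15)
        res = decoding.permutation_test(decoding.loo_ovo_decode, ds,
                                        n_perm=1000, seed=16)
        null = res.null_distribution
        sem = null.std(ddof=1) / np.sqrt(len(null))
        assert null.mean() == pytest.approx(0.2, abs=3 * sem + 1e-9)

    def test_false_positive_calibration(self):
        """Null data is flagged significant in about 5% of runs."""
        hits = 0
        n_meta = 200
        for seed in range(n_meta):
            rng = np.random.default_rng(10_000 + seed)
            X = rng.standard_normal((20, 10))
            y = np.repeat(np.arange(5), 4)
            res = decoding.permutation_test(decoding.loo_ovo_decode,
                                            DecodingDataset(X=X, y=y),
                                            n_perm=60, seed=seed)
            hits += int(res.significant)
        rate = hits / n_meta
        assert 0.005 <= rate <= 0.12  # ~5% with meta-run noise

    def test_single_permutation_degenerate(self):
        ds = gaussian_classes(n_per=3, n_vox=5, seed=17)
        with pytest.warns(UserWarning, match="degenerate"):
            res = decoding.permutation_test(decoding.loo_ovo_decode, ds,
                                            n_perm=1, seed=18)
        assert res.degenerate
        assert res.p_value >= 1.0


class TestPseudopopulation:
    def test_single_slice_identity_up_to_order(self):
        ds = gaussian_classes(n_per=6, n_vox=8, seed=19)
        out = decoding.build_pseudopopulation([ds], seed=20)
        assert out.X.shape == ds.X.shape
        for c in np.unique(ds.y):
            a = np.sort(ds.X[ds.y == c], axis=0)
            b = np.sort(out.X[out.y == c], axis=0)
            np.testing.assert_array_equal(a, b)

    def test_two_slices_concatenate_voxels(self):
        d1 = gaussian_classes(n_per=10, n_vox=8, seed=21)
        d2 = gaussian_classes(n_per=10, n_vox=5, seed=22)
        out = decoding.build_pseudopopulation([d1, d2], seed=23)
        assert out.X.shape == (50, 13)
        assert all(np.sum(out.y == c) == 10 for c in np.unique(out.y))

    @pytest.mark.parametrize("seed", range(5))
    def test_class_means_preserved(self, seed):
        d1 = gaussian_classes(n_per=10, n_vox=4, seed=24)
        d2 = gaussian_classes(n_per=10, n_vox=3, seed=25)
        out = decoding.build_pseudopopulation([d1, d2], seed=seed)
        for c in np.unique(d1.y):
            np.testing.assert_allclose(out.X[out.y == c][:, :4].mean(axis=0),
                                       d1.X[d1.y == c].mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(out.X[out.y == c][:, 4:].mean(axis=0),
                                       d2.X[d2.y == c].mean(axis=0), atol=1e-12)

    def test_unequal_counts_truncated_with_warning(self):
        d1 = gaussian_classes(n_per=10, n_vox=4, seed=26)
        d2 = gaussian_classes(n_per=6, n_vox=4, seed=27)
        with pytest.warns(UserWarning, match="truncating"):
            out = decoding.build_pseudopopulation([d1, d2], seed=28)
        assert all(np.sum(out.y == c) == 6 for c in np.unique(out.y))


class TestRMAnova:
    def test_hand_computed_toy_table(self):
        """3 subjects x 2 depths; F computed by hand from the sums of squares."""
        data = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 4.0]])
        f, p = decoding.rm_anova_1way(data)
        assert f == pytest.approx(25.0, abs=1e-9)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(29)
        data = rng.standard_normal((6, 4)) + np.array([0.0, 0.3, 0.6, 0.1])
        f, p = decoding.rm_anova_1way(data)

        import pandas as pd
        from statsmodels.stats.anova import AnovaRM
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(6), 4),
            "depth": np.tile(np.arange(4), 6),
            "acc": data.ravel(),
        })
        table = AnovaRM(long, "acc", "subject", within=["depth"]).fit().anova_table
        assert f == pytest.approx(table["F Value"].iloc[0], abs=1e-9)
        assert p == pytest.approx(table["Pr > F"].iloc[0], abs=1e-9)


class TestDepthDecoding:
    def make_subject(self, snr_by_depth, n_vox_per_depth=12, n_per=6, seed=0):
        rng = np.random.default_rng(seed)
        layers = np.repeat(np.arange(len(snr_by_depth)), n_vox_per_depth)
        n_vox = len(layers)
        y = np.repeat(np.arange(5), n_per)
        means = rng.standard_normal((5, n_vox)) * np.array(
            [snr_by_depth[d] for d in layers])
        X = means[y] + rng.standard_normal((len(y), n_vox))
        return DecodingDataset(X=X, y=y), layers

    def test_flat_profile_not_significant(self):
        subjects = [self.make_subject([0.3, 0.3, 0.3], seed=s) for s in range(4)]
        depths, acc, f, p = decoding.depth_decoding(subjects, seed=30)
        assert acc.shape == (4, 3)
        assert p > 0.05

    def test_planted_depth_effect_detected(self):
        subjects = [self.make_subject([0.1, 1.5, 0.1], seed=100 + s)
                    for s in range(4)]
        depths, acc, f, p = decoding.depth_decoding(subjects, seed=31)
        assert np.nanargmax(acc.mean(axis=0)) == 1
        assert p < 0.05

    def test_empty_depth_excluded_with_warning(self):
        ds, layers = self.make_subject([0.5, 0.5], seed=32)
        layers2 = layers.copy()
        layers2[layers2 == 1] = 0  # subject 2 has no depth-1 voxels
        with pytest.warns(UserWarning, match="excluded"):
            depths, acc, f, p = decoding.depth_decoding(
                [(ds, layers), (self.make_subject([0.5, 0.5], seed=33)[0], layers2)],
                seed=34)
        assert np.isnan(acc[1, 1])
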