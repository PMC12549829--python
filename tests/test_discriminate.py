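"""SVD/LDA oracles and the repeated-split evaluation protocol."""

import numpy as np
import pytest

import lfpbeta as lb
from lfpbeta.errors import InsufficientDataError, InvalidParameterError


def gaussian_classes(rng, means, n_per=100, dim=2, scale=1.0):
    X = np.vstack([m + scale * rng.standard_normal((n_per, dim)) for m in means])
    y = np.concatenate([[f"s{i}"] * n_per for i in range(len(means))])
    return X, y


class TestBuildEpochs:
    def test_shape_arithmetic(self):
        env = np.arange(4000, dtype=float)
        m = lb.build_epochs(env, 400.0, 1.0, "A")
        assert m.X.shape == (10, 400)
        assert list(m.labels) == ["A"] * 10

    def test_trailing_partial_window_dropped(self):
        env = np.ones(4200)
        m = lb.build_epochs(env, 400.0, 1.0, "A")
        assert m.X.shape == (10, 400)

    def test_constant_envelope_identical_rows(self):
        m = lb.build_epochs(np.full(2000, 3.0), 400.0, 1.0, "A")
        assert np.all(m.X == m.X[0])

    def test_too_short_epoch_raises(self):
        with pytest.raises(InvalidParameterError):
            lb.build_epochs(np.ones(100), 400.0, 0.001, "A")


class TestSvdProject:
    def test_rank_one_second_component_vanishes(self, rng):
        v = rng.standard_normal(10)
        X = np.outer(rng.standard_normal(8), v)
        scores, proj = lb.svd_project(X, k=2)
        assert proj.singular_values[1] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(scores[:, 1], 0.0, atol=1e-8)

    def test_eckart_young_reconstruction_error(self, rng):
        """Frobenius error of the rank-k reconstruction equals the energy in
        the discarded singular values."""
        X = rng.standard_normal((12, 7))
        scores, proj = lb.svd_project(X, k=2)
        Xc = X - proj.mean
        recon = scores @ proj.components
        err = np.linalg.norm(Xc - recon, "fro")
        s_full = np.linalg.svd(Xc, compute_uv=False)
        assert err == pytest.approx(np.sqrt(np.sum(s_full[2:] ** 2)), rel=1e-9)

    def test_singular_values_vs_gram_eigenvalue_oracle(self, rng):
        """Independent oracle: sqrt of the Gram-matrix eigenvalues."""
        for n, p in [(5, 5), (8, 4), (6, 8)]:
            X = rng.standard_normal((n, p))
            k = min(n, p, 3)
            _, proj = lb.svd_project(X, k=k)
            Xc = X - X.mean(axis=0)
            eig = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
            np.testing.assert_allclose(
                proj.singular_values, np.sqrt(np.maximum(eig[:k], 0)), atol=1e-8
            )

    def test_projection_reusable_on_heldout(self, rng):
        X = rng.standard_normal((20, 6))
        scores, proj = lb.svd_project(X, k=2)
        np.testing.assert_allclose(proj.transform(X), scores, atol=1e-12)

    def test_k_exceeding_dims_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            lb.svd_project(rng.standard_normal((3, 5)), k=4)


class TestLda:
    def test_well_separated_classes_near_perfect(self, rng):
        X, y = gaussian_classes(rng, [(-5.0, 0.0), (5.0, 0.0)], n_per=100)
        model = lb.lda_fit(X, y)
        acc = np.mean(lb.lda_predict(model, X) == y)
        assert acc >= 0.99

    def test_identical_distributions_near_chance(self, rng):
        X, y = gaussian_classes(rng, [(0.0, 0.0), (0.0, 0.0)], n_per=400)
        model = lb.lda_fit(X[::2], y[::2])
        acc = np.mean(lb.lda_predict(model, X[1::2]) == y[1::2])
        assert acc == pytest.approx(0.5, abs=0.07)

    def test_1d_boundary_is_class_mean_midpoint(self, rng):
        """Equal priors in 1-D: the decision boundary is (mu1+mu2)/2."""
        X = np.concatenate([rng.normal(0.0, 1.0, 200), rng.normal(4.0, 1.0, 200)])
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = lb.lda_fit(X[:, None], y)
        mid = (model.class_means[0, 0] + model.class_means[1, 0]) / 2
        eps = 1e-6
        below = lb.lda_predict(model, np.array([[mid - eps]]))[0]
        above = lb.lda_predict(model, np.array([[mid + eps]]))[0]
        assert below == "a" and above == "b"

    def test_matches_sklearn_on_random_data(self, rng):
        """Cross-check predictions against an independent LDA implementation."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X, y = gaussian_classes(
            rng, [(0.0, 0.0), (2.0, 1.0), (-1.0, 2.0)], n_per=60
        )
        ours = lb.lda_predict(lb.lda_fit(X, y), X)
        ref = sklearn_lda(solver="lsqr").fit(X, y).predict(X)
        assert np.mean(ours == ref) > 0.98

    def test_single_epoch_class_raises(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(InsufficientDataError):
            lb.lda_fit(X, np.array(["a", "a", "b"]))

    def test_degenerate_covariance_regularized(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        model = lb.lda_fit(X, y)  # zero within-class scatter
        assert np.all(np.isfinite(model._coef))


class TestEvaluate:
    def _epochs(self, rng, sep, n_per=60, dim=20):
        means = [np.full(dim, i * sep) for i in range(3)]
        X, y = gaussian_classes(rng, means, n_per=n_per, dim=dim)
        return lb.EpochMatrix(X, y, 1.0)

    def test_seed_determinism(self, rng):
        epochs = self._epochs(rng, 1.0)
        a = lb.evaluate(epochs, repetitions=5, seed=3)
        b = lb.evaluate(epochs, repetitions=5, seed=3)
        np.testing.assert_array_equal(
            a.per_repetition_accuracy, b.per_repetition_accuracy
        )
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_separable_classes_high_accuracy(self, rng):
        res = lb.evaluate(self._epochs(rng, 3.0), repetitions=10, seed=1)
        assert res.mean_accuracy >= 0.95
        assert res.p_vs_chance < 1e-10

    def test_label_permutation_destroys_accuracy(self, rng):
        """No leakage: shuffled labels give chance-level accuracy."""
        epochs = self._epochs(rng, 3.0, n_per=80)
        perm = rng.permutation(epochs.labels.size)
        shuffled = lb.EpochMatrix(epochs.X, epochs.labels[perm], 1.0)
        res = lb.evaluate(shuffled, repetitions=30, seed=2)
        assert res.mean_accuracy == pytest.approx(1 / 3, abs=0.05)

    def test_monotone_separability(self, rng):
        accs = [
            lb.evaluate(self._epochs(np.random.default_rng(99), sep),
                        repetitions=5, seed=4).mean_accuracy
            for sep in (0.0, 0.5, 1.0, 2.0)
        ]
        assert accs == sorted(accs)

    def test_confusion_row_sums_equal_test_counts(self, rng):
        res = lb.evaluate(self._epochs(rng, 1.0, n_per=60), repetitions=6, seed=0)
        # stratified 60/40 of 60 epochs/class -> 24 test epochs/class/rep
        assert np.all(res.confusion.sum(axis=1) == 24 * 6)

    def test_class_too_small_raises(self, rng):
        X, y = gaussian_classes(rng, [(0, 0), (1, 1)], n_per=8)
        with pytest.raises(InsufficientDataError):
            lb.evaluate(lb.EpochMatrix(X, y, 1.0), folds=10)


class TestSignificance:
    def _result(self, correct, total):
        return lb.DiscriminationResult(
            per_repetition_accuracy=np.array([correct / total]),
            mean_accuracy=correct / total,
            confusion=np.zeros((3, 3), int),
            cv_accuracy=0.0,
            classes=np.array(["a", "b", "c"]),
            n_test_total=total,
            n_correct_total=correct,
        )

    def test_chance_accuracy_gives_half(self):
        p = lb.significance_vs_chance(self._result(1000, 3000), chance=1 / 3)
        assert p == pytest.approx(0.5, abs=0.02)

    def test_perfect_accuracy_closed_form(self):
        p = lb.significance_vs_chance(self._result(40, 40), chance=1 / 3)
        assert p == pytest.approx((1 / 3) ** 40, rel=1e-9)

    def test_below_chance_gives_large_p(self):
        p = lb.significance_vs_chance(self._result(200, 900), chance=1 / 3)
        assert p > 0.5

    def test_bonferroni_factor(self):
        p1 = lb.significance_vs_chance(self._result(30, 40))
        p8 = lb.significance_vs_chance(self._result(30, 40), n_channels_tested=8)
        assert p8 == pytest.approx(min(1.0, 8 * p1))

    def test_invalid_chance_raises(self):
        with pytest.raises(InvalidParameterError):
            lb.significance_vs_chance(self._result(10, 40), chance=1.5)


class TestChannelCorrelation:
    def test_duplicated_and_negated_channels(self, rng):
        x = rng.standard_normal(5000)
        rec = lb.Recording(np.vstack([x, x, -x]), 400.0, ["a", "b", "c"])
        r = lb.channel_correlation(rec)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_independent_channels_uncorrelated(self, rng):
        rec = lb.Recording(rng.standard_normal((4, 120_000)), 400.0,
                           ["a", "b", "c", "d"])
        r = lb.channel_correlation(rec)
        off = r[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_zero_variance_channel_flagged(self, rng):
        rec = lb.Recording(
            np.vstack([rng.standard_normal(1000), np.zeros(1000)]),
            400.0, ["a", "b"],
        )
        r = lb.channel_correlation(rec)
        assert np.isnan(r[0, 1]) and np.isnan(r[1, 0])

    def test_single_channel_raises(self, rng):
        rec = lb.Recording(rng.standard_normal((1, 100)), 400.0, ["a"])
        with pytest.raises(InvalidParameterError):
            lb.channel_correlation(rec)


def test_select_epoch_length_returns_candidate(rng):
    envs = {
        lab: np.abs(rng.standard_normal(24000)) + (3.0 * i)
        for i, lab in enumerate(["A", "B", "C"])
    }
    best, cv = lb.select_epoch_length(envs, fs=400.0, candidates=(0.5, 1.0), folds=5)
    assert best in (0.5, 1.0)
    assert set(cv) == {0.5, 1.0}
    assert all(0.0 <= v <= 1.0 for v in cv.values())


def test_combine_channels_concatenates_features(rng):
    a = lb.EpochMatrix(rng.standard_normal((6, 4)), ["x"] * 6, 1.0, "ch1")
    b = lb.EpochMatrix(rng.standard_normal((6, 4)), ["x"] * 6, 1.0, "ch2")
    combined = lb.combine_channels([a, b])
    assert combined.X.shape == (6, 8)
    assert combined.channel == "ch1+ch2"
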