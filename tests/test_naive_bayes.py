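"""Gaussian naive Bayes: fitting, likelihood/evidence/posterior math."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fallfusion as ff
from fallfusion.naive_bayes import log_gaussian_likelihood

STILL, FALL = ff.MotionClass.STILL, ff.MotionClass.FALL


def _stats(classes, priors, means, sds):
    return ff.ClassStats(
        classes=tuple(classes),
        priors=np.asarray(priors, dtype=float),
        means=np.asarray(means, dtype=float),
        sds=np.asarray(sds, dtype=float),
        sigma_floor=np.full(6, 1e-12),
    )


def _random_stats(rng, n_classes=3):
    classes = tuple(ff.MotionClass)[:n_classes]
    priors = rng.dirichlet(np.ones(n_classes))
    means = rng.normal(0, 5, (n_classes, 6))
    sds = rng.uniform(0.2, 4.0, (n_classes, 6))
    return _stats(classes, priors, means, sds)


def longdouble_posterior(f, stats, scale=1.0):
    """Independent oracle: raw prior x product-of-densities pipeline in
    extended precision, optionally scaled by a common positive constant."""
    f = np.asarray(f, dtype=np.longdouble)
    joints = []
    for k in range(stats.n_classes):
        dens = np.longdouble(scale)
        for i in range(6):
            mu = np.longdouble(stats.means[k, i])
            sd = np.longdouble(stats.sds[k, i])
            z = (f[i] - mu) / sd
            dens *= np.exp(-z * z / 2) / (sd * np.sqrt(2 * np.pi, dtype=np.longdouble))
        joints.append(np.longdouble(stats.priors[k]) * dens)
    joints = np.array(joints, dtype=np.longdouble)
    return joints / joints.sum()


class TestFit:
    def test_balanced_corpus_has_uniform_priors(self, train_set):
        stats = ff.fit_gaussian_nb(train_set)
        assert np.allclose(stats.priors, 1 / 6)
        assert stats.classes == tuple(ff.MotionClass)

    def test_matches_pandas_column_statistics(self, train_set, small_corpus):
        import pandas as pd

        stats = ff.fit_gaussian_nb(train_set)
        df = pd.DataFrame(train_set.X)
        df["y"] = [c.value for c in train_set.y]
        for k, c in enumerate(stats.classes):
            grp = df[df["y"] == c.value].drop(columns="y")
            assert np.allclose(stats.means[k], grp.mean().to_numpy(), atol=1e-10)
            assert np.allclose(stats.sds[k], grp.std(ddof=1).to_numpy(), atol=1e-10)

    def test_zero_variance_features_hit_the_floor(self):
        X = np.tile(np.arange(6.0), (4, 1))  # identical rows per class
        y = (STILL, STILL, FALL, FALL)
        stats = ff.fit_gaussian_nb(ff.TrainingSet(X, y))
        assert np.array_equal(stats.means, np.tile(np.arange(6.0), (2, 1)))
        assert np.array_equal(stats.sds, np.tile(stats.sigma_floor, (2, 1)))
        assert (stats.sds > 0).all()

    def test_class_with_single_point_is_named_in_error(self):
        X = np.random.default_rng(0).uniform(size=(3, 6))
        y = (STILL, STILL, FALL)
        with pytest.raises(ff.FittingError, match="fall"):
            ff.fit_gaussian_nb(ff.TrainingSet(X, y))


class TestGaussianLikelihood:
    def test_peak_and_one_sigma_values(self):
        assert ff.gaussian_likelihood(0.0, 0.0, 1.0) == pytest.approx(
            1 / math.sqrt(2 * math.pi), abs=1e-12
        )
        assert ff.gaussian_likelihood(1.0, 0.0, 1.0) == pytest.approx(
            math.exp(-0.5) / math.sqrt(2 * math.pi), abs=1e-12
        )

    def test_matches_scipy_norm_pdf(self):
        from scipy.stats import norm

        rng = np.random.default_rng(1)
        for _ in range(100):
            x, mu = rng.normal(0, 5, 2)
            sd = rng.uniform(0.1, 5)
            assert ff.gaussian_likelihood(x, mu, sd) == pytest.approx(
                norm.pdf(x, mu, sd), abs=1e-12
            )

    def test_rejects_non_positive_sigma(self):
        for sd in (0.0, -1.0):
            with pytest.raises(ff.ParameterError):
                ff.gaussian_likelihood(0.0, 0.0, sd)


class TestEvidence:
    def test_single_class_equals_prior_times_joint(self):
        rng = np.random.default_rng(2)
        stats = _stats([STILL], [1.0], rng.normal(size=(1, 6)),
                       rng.uniform(0.5, 2, (1, 6)))
        f = rng.normal(size=6)
        joint = math.exp(float(
            log_gaussian_likelihood(f, stats.means[0], stats.sds[0]).sum()
        ))
        assert ff.evidence(f, stats) == pytest.approx(joint, rel=1e-12)

    def test_two_identical_classes_collapse_by_symmetry(self):
        rng = np.random.default_rng(3)
        mu, sd = rng.normal(size=6), rng.uniform(0.5, 2, 6)
        one = _stats([STILL], [1.0], [mu], [sd])
        two = _stats([STILL, FALL], [0.5, 0.5], [mu, mu], [sd, sd])
        f = rng.normal(size=6)
        assert ff.evidence(f, two) == pytest.approx(ff.evidence(f, one), rel=1e-12)

    def test_matches_term_by_term_longdouble_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            stats = _random_stats(rng)
            f = rng.normal(0, 5, 6)
            terms = longdouble_posterior(f, stats)  # normalised joints
            # Recompute the unnormalised sum directly.
            total = np.longdouble(0)
            for k in range(stats.n_classes):
                dens = np.longdouble(stats.priors[k])
                for i in range(6):
                    dens *= np.longdouble(
                        ff.gaussian_likelihood(f[i], stats.means[k, i], stats.sds[k, i])
                    )
                total += dens
            assert ff.evidence(f, stats) == pytest.approx(float(total), rel=1e-9)


class TestPosterior:
    def test_identical_classes_split_evenly(self):
        rng = np.random.default_rng(5)
        mu, sd = rng.normal(size=6), rng.uniform(0.5, 2, 6)
        stats = _stats([STILL, FALL], [0.5, 0.5], [mu, mu], [sd, sd])
        post = ff.posterior(rng.normal(size=6), stats)
        assert np.allclose(post.probs, [0.5, 0.5], atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_posterior_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        stats = _random_stats(rng, n_classes=4)
        post = ff.posterior(rng.normal(0, 10, 6), stats)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (post.probs >= 0).all()

    def test_two_gaussian_closed_form(self):
        # Five features identical across classes cancel; the remaining one
        # has mu 0 vs 2 with sd 1, observed at 0: posterior = 1/(1+e^-2).
        means = np.zeros((2, 6))
        means[1, 0] = 2.0
        stats = _stats([STILL, FALL], [0.5, 0.5], means, np.ones((2, 6)))
        post = ff.posterior(np.zeros(6), stats)
        assert post[STILL] == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-12)

    def test_invariant_to_common_likelihood_scaling(self):
        # Scaling every likelihood by one positive constant (here pushed
        # through an extended-precision oracle) must not move the posterior.
        rng = np.random.default_rng(6)
        stats = _random_stats(rng)
        f = rng.normal(0, 5, 6)
        base = ff.posterior(f, stats).probs
        for scale in (1e-200, 1.0, 1e200):
            oracle = longdouble_posterior(f, stats, scale=scale)
            assert np.allclose(base, oracle.astype(float), atol=1e-9)

    def test_survives_underflow_regimes(self):
        # Joint densities far in the tails underflow float64; the log-space
        # posterior must still normalise.
        stats = _stats([STILL, FALL], [0.5, 0.5],
                       np.zeros((2, 6)) + [[0.0], [1.0]],
                       np.full((2, 6), 1e-3))
        post = ff.posterior(np.full(6, 0.4), stats)
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert post.top() is STILL


class TestNbClassify:
    def test_dominant_likelihood_wins(self, train_set):
        stats = ff.fit_gaussian_nb(train_set)
        for k, c in enumerate(stats.classes):
            assert ff.nb_classify(stats.means[k], stats) is c

    def test_symmetric_tie_goes_to_earlier_class(self):
        mu = np.zeros((2, 6))
        stats = _stats([ff.MotionClass.SITTING_UP, FALL], [0.5, 0.5], mu,
                       np.ones((2, 6)))
        assert ff.nb_classify(np.zeros(6), stats) is ff.MotionClass.SITTING_UP

    def test_prior_breaks_identical_likelihoods(self):
        mu = np.zeros((2, 6))
        stats = _stats([STILL, FALL], [0.3, 0.7], mu, np.ones((2, 6)))
        assert ff.nb_classify(np.zeros(6), stats) is FALL
        stats = _stats([STILL, FALL], [0.7, 0.3], mu, np.ones((2, 6)))
        assert ff.nb_classify(np.zeros(6), stats) is STILL

    def test_matches_extended_precision_pipeline(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            stats = _random_stats(rng)
            f = rng.normal(0, 5, 6)
            oracle = stats.classes[int(np.argmax(longdouble_posterior(f, stats)))]
            assert ff.nb_classify(f, stats) is oracle

    def test_training_set_fall_accuracy_on_separable_corpus(self):
        corpus = ff.generate_corpus(20, ff.MotionModelParams(seed=3))
        ts = ff.TrainingSet.from_corpus(corpus)
        stats = ff.fit_gaussian_nb(ts)
        correct = sum(
            ff.nb_classify(x, stats).fall_flag == y.fall_flag
            for x, y in zip(ts.X, ts.y)
        )
        assert correct / len(ts) >= 0.95
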