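"""Gaussian mixture: densities, supervised fitting, EM, responsibilities."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

import choroidseg as cs
from choroidseg.mixture import GaussianComponent, LabelMask, MixtureModel
from choroidseg.wavelet import FeatureStack


def naive_density(x, mean, cov):
    """Textbook multivariate normal density with explicit det and inverse."""
    n = mean.size
    diff = x - mean
    return float(
        np.exp(-0.5 * diff @ np.linalg.inv(cov) @ diff)
        / ((2 * np.pi) ** (n / 2) * np.sqrt(np.linalg.det(cov)))
    )


def random_spd(rng, n=5):
    A = rng.normal(size=(n, n))
    return A @ A.T + n * np.eye(n)


def make_feature_stack(X, shape):
    """Pack an (N, n) descriptor matrix into a FeatureStack of given image shape."""
    n = X.shape[1]
    return FeatureStack(X.reshape(*shape, n).transpose(2, 0, 1))


def model_loglik(model, X):
    lj = np.stack(
        [
            np.log(c.weight) + multivariate_normal(c.mean, c.covariance).logpdf(X)
            for c in model.components
        ],
        axis=1,
    )
    return float(logsumexp(lj, axis=1).sum())


class TestGaussianDensity:
    def test_at_mean_identity_covariance(self):
        comp = GaussianComponent(weight=1.0, mean=np.zeros(5), covariance=np.eye(5))
        assert cs.gaussian_density(np.zeros(5), comp) == pytest.approx(
            (2 * np.pi) ** (-2.5)
        )

    def test_at_mahalanobis_distance_two(self):
        comp = GaussianComponent(weight=1.0, mean=np.zeros(5), covariance=np.eye(5))
        x = np.zeros(5)
        x[0] = 2.0
        assert cs.gaussian_density(x, comp) == pytest.approx(
            (2 * np.pi) ** (-2.5) * np.exp(-2.0)
        )

    def test_matches_naive_formula(self, rng):
        for _ in range(10):
            cov = random_spd(rng)
            mean = rng.normal(size=5)
            x = rng.normal(size=5)
            comp = GaussianComponent(weight=1.0, mean=mean, covariance=cov)
            assert cs.gaussian_density(x, comp) == pytest.approx(
                naive_density(x, mean, cov), rel=1e-10
            )

    def test_rejects_non_spd_covariance(self):
        cov = np.eye(5)
        cov[0, 0] = -1.0
        comp = GaussianComponent(weight=1.0, mean=np.zeros(5), covariance=cov)
        with pytest.raises(ValueError, match="positive-definite"):
            cs.gaussian_density(np.zeros(5), comp)


def _draw_labeled(rng, n_per_class, means, cov_scales):
    X, labels = [], []
    for k, (m, s) in enumerate(zip(means, cov_scales), start=1):
        X.append(np.abs(rng.normal(loc=m, scale=s, size=(n_per_class[k - 1], 5))))
        labels.append(np.full(n_per_class[k - 1], k))
    return np.concatenate(X), np.concatenate(labels)


class TestFitFromMasks:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(99)
        counts = (15000, 9000, 6000)  # true weights 0.5 / 0.3 / 0.2
        means = (50.0, 100.0, 150.0)
        scales = (1.5, 2.0, 2.5)
        X, labels = _draw_labeled(rng, counts, means, scales)
        fs = make_feature_stack(X, (200, 150))
        mask = LabelMask(labels.reshape(200, 150))
        model = cs.fit_from_masks(fs, mask)
        for k, comp in enumerate(model.components):
            se = np.sqrt(np.diag(comp.covariance) / counts[k])
            assert np.all(np.abs(comp.mean - means[k]) <= 3 * se)
            assert abs(comp.weight - counts[k] / sum(counts)) <= 0.02
            assert np.allclose(
                np.diag(comp.covariance), scales[k] ** 2, rtol=0.1
            )

    def test_pooling_invariance(self, rng):
        X, labels = _draw_labeled(rng, (40, 40, 40), (1.0, 5.0, 9.0), (1, 1, 1))
        perm = rng.permutation(120)
        X, labels = X[perm], labels[perm]
        joint = cs.fit_from_masks(
            make_feature_stack(X, (12, 10)), LabelMask(labels.reshape(12, 10))
        )
        split = cs.fit_from_masks(
            [make_feature_stack(X[:60], (6, 10)), make_feature_stack(X[60:], (6, 10))],
            [LabelMask(labels[:60].reshape(6, 10)), LabelMask(labels[60:].reshape(6, 10))],
        )
        for a, b in zip(joint.components, split.components):
            assert np.allclose(a.mean, b.mean)
            assert np.allclose(a.covariance, b.covariance)
            assert a.weight == pytest.approx(b.weight)

    def test_missing_class_rejected(self, rng):
        X = np.abs(rng.normal(size=(60, 5)))
        labels = np.repeat([1, 2], 30)  # class 3 absent
        with pytest.raises(ValueError, match="class 3"):
            cs.fit_from_masks(
                make_feature_stack(X, (6, 10)), LabelMask(labels.reshape(6, 10))
            )

    def test_identical_descriptors_rejected(self, rng):
        X, labels = _draw_labeled(rng, (30, 30, 30), (1.0, 5.0, 9.0), (1, 1, 1))
        X[labels == 2] = 5.0  # class 2 collapses to a point
        with pytest.raises(ValueError, match="zero rank"):
            cs.fit_from_masks(
                make_feature_stack(X, (9, 10)), LabelMask(labels.reshape(9, 10))
            )

    def test_unlabeled_pixels_excluded(self, rng):
        X, labels = _draw_labeled(rng, (40, 40, 40), (1.0, 5.0, 9.0), (1, 1, 1))
        base = cs.fit_from_masks(
            make_feature_stack(X, (12, 10)), LabelMask(labels.reshape(12, 10))
        )
        # append junk pixels labeled 0: the fit must not change
        X2 = np.concatenate([X, np.full((10, 5), 1e3)])
        labels2 = np.concatenate([labels, np.zeros(10, dtype=int)])
        extended = cs.fit_from_masks(
            make_feature_stack(X2, (13, 10)), LabelMask(labels2.reshape(13, 10))
        )
        for a, b in zip(base.components, extended.components):
            assert np.allclose(a.mean, b.mean)


def _three_component_model(means=(0.0, 8.0, 20.0), weights=(0.5, 0.3, 0.2), scale=4.0):
    return MixtureModel(
        components=[
            GaussianComponent(weight=w, mean=np.full(5, m), covariance=np.eye(5) * scale)
            for m, w in zip(means, weights)
        ]
    )


class TestEmRefine:
    def test_loglik_monotone_over_iterations(self, rng):
        X = np.vstack(
            [rng.normal(1, 1, (300, 5)) ** 2, rng.normal(4, 1, (200, 5)) ** 2]
        )
        fs = make_feature_stack(X, (25, 20))
        model = _three_component_model()
        lls = [
            model_loglik(cs.em_refine(fs, model, max_iter=k, tol=0), fs.descriptors())
            for k in (1, 2, 4, 8)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_final_loglik_not_below_initial(self, rng):
        X = np.vstack(
            [rng.normal(1, 1, (900, 5)) ** 2, rng.normal(4, 1.5, (600, 5)) ** 2]
        )
        fs = make_feature_stack(X, (50, 30))
        model = _three_component_model(means=(1.0, 8.0, 20.0))
        refined = cs.em_refine(fs, model, max_iter=50)
        assert model_loglik(refined, X) >= model_loglik(model, X) - 1e-9

    def test_near_fixed_point_on_model_data(self):
        rng = np.random.default_rng(3)
        model = _three_component_model(means=(12.0, 40.0, 80.0), scale=2.0)
        parts = []
        for comp, n in zip(model.components, (10000, 6000, 4000)):
            parts.append(
                rng.multivariate_normal(comp.mean, comp.covariance, size=n)
            )
        X = np.concatenate(parts)
        rng.shuffle(X)
        fs = make_feature_stack(X, (200, 100))
        refined = cs.em_refine(fs, model, max_iter=1, tol=0)
        for a, b in zip(model.components, refined.components):
            assert np.allclose(a.mean, b.mean, atol=0.15)
            assert abs(a.weight - b.weight) < 0.02

    def test_matches_reference_em_implementation(self, rng):
        from sklearn.mixture import GaussianMixture

        X = np.vstack(
            [rng.normal(1, 1, (900, 5)) ** 2, rng.normal(4, 1.5, (600, 5)) ** 2]
        )
        fs = make_feature_stack(X, (50, 30))
        init = _three_component_model(means=(1.0, 8.0, 20.0))
        ours = cs.em_refine(fs, init, max_iter=300, tol=1e-10)
        ref = GaussianMixture(
            n_components=3,
            covariance_type="full",
            weights_init=[c.weight for c in init.components],
            means_init=[c.mean for c in init.components],
            precisions_init=[np.linalg.inv(c.covariance) for c in init.components],
            reg_covar=0,
            tol=1e-10,
            max_iter=300,
        ).fit(fs.descriptors())
        ll_ours = model_loglik(ours, fs.descriptors()) / X.shape[0]
        ll_ref = ref.score(fs.descriptors())
        assert abs(ll_ours - ll_ref) <= 1e-4 * abs(ll_ref)


class TestResponsibilities:
    def test_identical_components_give_uniform_posterior(self, rng):
        model = MixtureModel(
            components=[
                GaussianComponent(
                    weight=1 / 3, mean=np.full(5, 2.0), covariance=np.eye(5)
                )
                for _ in range(3)
            ]
        )
        fs = make_feature_stack(np.abs(rng.normal(2, 1, (60, 5))), (6, 10))
        maps = cs.responsibilities(model, fs)
        assert np.allclose(maps.probs, 1 / 3)

    def test_dominant_component_at_its_mean(self):
        model = _three_component_model(means=(0.0, 50.0, 100.0), scale=1.0)
        X = np.full((1, 5), 50.0)
        maps = cs.responsibilities(model, make_feature_stack(X, (1, 1)))
        assert maps.probs[1, 0, 0] > 0.99

    def test_matches_naive_posterior_formula(self, rng):
        model = _three_component_model(means=(1.0, 4.0, 8.0), scale=3.0)
        X = np.abs(rng.normal(4, 2, size=(50, 5)))
        maps = cs.responsibilities(model, make_feature_stack(X, (5, 10)))
        for j in range(50):
            dens = np.array(
                [
                    c.weight * naive_density(X[j], c.mean, c.covariance)
                    for c in model.components
                ]
            )
            expected = dens / dens.sum()
            assert np.allclose(maps.probs[:, j // 10, j % 10], expected, atol=1e-9)

    def test_rows_sum_to_one(self, rng):
        model = _three_component_model()
        fs = make_feature_stack(np.abs(rng.normal(5, 3, (200, 5))), (20, 10))
        maps = cs.responsibilities(model, fs)
        assert np.allclose(maps.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = _three_component_model()
        fs = FeatureStack(np.abs(rng.normal(size=(4, 6, 6))))
        with pytest.raises(ValueError, match="dimensions"):
            cs.responsibilities(model, fs)


class TestSerialization:
    def test_json_round_trip(self, rng):
        model = _three_component_model()
        restored = MixtureModel.from_json(model.to_json())
        for a, b in zip(model.components, restored.components):
            assert a.weight == b.weight
            assert np.array_equal(a.mean, b.mean)
            assert np.array_equal(a.covariance, b.covariance)
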