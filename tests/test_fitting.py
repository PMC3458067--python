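"""Local Gaussian intensity model: statistics, densities, costs and forces."""

import numpy as np
import pytest
from scipy import ndimage

from longiseg4d.fitting import (
    AtlasPrior,
    MultiModalImage,
    class_cost_fields,
    data_fitting_energy_and_force,
    multivariate_log_density,
    update_local_statistics,
)
from longiseg4d.geometry import (
    LevelSetField,
    LevelSetTriple,
    RegionIndicators,
    region_indicators,
)

from conftest import circle_sdf


def hard_indicators_from(tri):
    from longiseg4d.geometry import extract_labels, LABEL_WM, LABEL_GM, LABEL_CSF, LABEL_BG

    lab = extract_labels(tri)
    return RegionIndicators(
        wm=(lab == LABEL_WM).astype(float),
        gm=(lab == LABEL_GM).astype(float),
        csf=(lab == LABEL_CSF).astype(float),
        bg=(lab == LABEL_BG).astype(float),
    )


class TestLocalStatistics:
    def test_piecewise_constant_image_recovers_class_means(self, nested_triple):
        ind = hard_indicators_from(nested_triple)
        img_data = 0.2 * ind.wm + 0.5 * ind.gm + 0.8 * ind.csf + 0.05 * ind.bg
        img = MultiModalImage(img_data[None], 1.0)
        stats = update_local_statistics(img, ind, kernel_sigma=3.0)
        for k, val in (("wm", 0.2), ("gm", 0.5), ("csf", 0.8)):
            support = getattr(ind, k) > 0
            np.testing.assert_allclose(stats.mean[k][0][support], val, atol=1e-6)
            # zero within-class variance: covariance is just the reg floor
            assert stats.cov[k][0, 0][support].max() < 1e-3

    def test_1d_brute_force_kernel_oracle(self, rng):
        """Local means match an explicit kernel-weighted average on a tiny grid."""
        n = 5
        I = rng.random((1, n, 1))
        u = rng.random((n, 1))
        ind = RegionIndicators(wm=u, gm=1 - u, csf=np.zeros((n, 1)), bg=np.zeros((n, 1)))
        sigma = 1.0
        stats = update_local_statistics(
            MultiModalImage(I, 1.0), ind, kernel_sigma=sigma, mass_floor=1e-12
        )
        # oracle: materialize the smoother as an explicit matrix (column j =
        # response to a unit impulse at j), then take the weighted average by
        # direct summation
        K = np.zeros((n, n))
        for j in range(n):
            impulse = np.zeros((n, 1))
            impulse[j] = 1.0
            K[:, j] = ndimage.gaussian_filter(
                impulse, (sigma, sigma), mode="nearest", truncate=3.0
            )[:, 0]
        num = K @ (u[:, 0] * I[0, :, 0])
        den = K @ u[:, 0]
        np.testing.assert_allclose(stats.mean["wm"][0][:, 0], num / den, rtol=1e-10)

    def test_single_channel_reduces_to_scalar_local_model(self, rng, nested_triple):
        """m=1 equals an independently coded scalar local mean/variance."""
        ind = hard_indicators_from(nested_triple)
        I = rng.random(nested_triple.shape)
        stats = update_local_statistics(
            MultiModalImage(I[None], 1.0), ind, kernel_sigma=2.0, mass_floor=1e-12
        )
        # independent scalar implementation (kernel truncated at 3 sigma)
        def smooth(a):
            return ndimage.gaussian_filter(a, (2.0, 2.0), mode="nearest", truncate=3.0)

        mass = np.maximum(smooth(ind.wm), 1e-12)
        mean = smooth(ind.wm * I) / mass
        var = smooth(ind.wm * I * I) / mass - mean**2
        ok = mass > 1e-3
        np.testing.assert_allclose(stats.mean["wm"][0][ok], mean[ok], rtol=1e-8)
        np.testing.assert_allclose(
            stats.cov["wm"][0, 0][ok], var[ok] + 1e-4 * np.maximum(I.var(), 1e-12), rtol=1e-6
        )

    def test_empty_class_falls_back_globally_with_warning(self, nested_triple):
        ind = hard_indicators_from(nested_triple)
        ind.csf[:] = 0.0
        img = MultiModalImage(np.random.default_rng(0).random((1, *nested_triple.shape)), 1.0)
        with pytest.warns(UserWarning, match="csf"):
            update_local_statistics(img, ind, kernel_sigma=3.0)


class TestMultivariateLogDensity:
    def test_at_mean_identity_covariance(self):
        assert multivariate_log_density([1.0, 2.0], [1.0, 2.0], np.eye(2)) == pytest.approx(
            -np.log(2 * np.pi)
        )

    def test_diagonal_factorizes(self):
        v, mu = np.array([0.3, -1.2]), np.array([0.1, 0.4])
        var = np.array([0.5, 2.0])
        joint = multivariate_log_density(v, mu, np.diag(var))
        parts = sum(
            multivariate_log_density([v[i]], [mu[i]], [[var[i]]]) for i in range(2)
        )
        assert joint == pytest.approx(parts, rel=1e-12)

    def test_matches_explicit_inverse_and_determinant(self, rng):
        A = rng.standard_normal((3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        v, mu = rng.standard_normal(3), rng.standard_normal(3)
        expected = (
            -1.5 * np.log(2 * np.pi)
            - 0.5 * np.log(np.linalg.det(cov))
            - 0.5 * (v - mu) @ np.linalg.inv(cov) @ (v - mu)
        )
        assert multivariate_log_density(v, mu, cov) == pytest.approx(expected, rel=1e-10)

    def test_non_positive_definite_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            multivariate_log_density([0.0], [0.0], [[-1.0]])


class TestAtlasPrior:
    def test_validation(self):
        with pytest.raises(ValueError):
            AtlasPrior(np.full((4, 3, 3), 0.3))  # sums to 1.2
        with pytest.raises(ValueError):
            AtlasPrior(np.full((3, 3, 3), 1 / 3))  # only 3 classes
        uni = AtlasPrior.uniform((3, 3))
        np.testing.assert_allclose(uni.prob.sum(axis=0), 1.0)


class TestDataFittingForce:
    def test_equal_costs_give_zero_force(self, nested_triple):
        grid = nested_triple.shape
        img = MultiModalImage(np.full((1, *grid), 0.5), 1.0)
        stats = update_local_statistics(
            img, region_indicators(nested_triple, 1.0), kernel_sigma=3.0
        )
        costs = {k: np.ones(grid) for k in ("wm", "gm", "csf", "bg")}
        _, forces = data_fitting_energy_and_force(
            img, nested_triple, stats, None, 1.0, costs=costs
        )
        for f in forces:
            np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_informative_prior_lowers_truth_energy(self, nested_triple, rng):
        from longiseg4d.phantom import make_atlas
        from longiseg4d.geometry import extract_labels

        ind = hard_indicators_from(nested_triple)
        data = 0.2 * ind.wm + 0.5 * ind.gm + 0.8 * ind.csf + 0.05 * ind.bg
        data = data + 0.02 * rng.standard_normal(data.shape)
        img = MultiModalImage(data[None], 1.0)
        stats = update_local_statistics(img, ind, kernel_sigma=3.0)
        atlas = make_atlas(extract_labels(nested_triple), (1.0, 1.0), blur_sigma_mm=2.0)
        e_prior, _ = data_fitting_energy_and_force(img, nested_triple, stats, atlas, 1.0)
        e_unif, _ = data_fitting_energy_and_force(img, nested_triple, stats, None, 1.0)
        # uniform prior costs -log(1/4) everywhere; a correct prior is cheaper
        assert e_prior < e_unif

    def test_force_sign_points_to_cheaper_class(self, nested_triple):
        grid = nested_triple.shape
        img = MultiModalImage(np.zeros((1, *grid)), 1.0)
        stats = update_local_statistics(
            img, region_indicators(nested_triple, 1.0), kernel_sigma=3.0
        )
        costs = {
            "wm": np.zeros(grid),
            "gm": np.ones(grid),
            "csf": np.ones(grid),
            "bg": np.ones(grid),
        }
        _, (f1, _, _) = data_fitting_energy_and_force(
            img, nested_triple, stats, None, 1.0, costs=costs
        )
        band = np.abs(nested_triple.phi1.values) < 0.5
        # WM strictly cheaper: gradient negative => descent grows phi1 (WM expands)
        assert np.all(f1[band] < 0)
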