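"""PCA compression and Mahalanobis distance against independent oracles."""

import numpy as np
import pytest

from nirscreen.chemometrics import (
    ReferenceScores,
    ScoreMatrix,
    build_reference,
    fit_pca,
    ledoit_wolf_intensity,
    mahalanobis_distance,
    project,
    select_n_components,
)
from nirscreen.preprocess import mean_center

from conftest import make_set


def centered_set(matrix, **kw):
    sset = make_set(matrix, **kw)
    out, model = mean_center(sset)
    return out, model


class TestFitPca:
    def test_identical_rows_give_zero_scores(self):
        out, _ = centered_set(np.tile(np.linspace(0, 1, 30), (5, 1)))
        model, scores = fit_pca(out)
        np.testing.assert_allclose(scores.scores, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.explained_variance, 0.0, atol=1e-12)

    def test_rank_one_set_explained_by_first_component(self):
        rng = np.random.default_rng(1)
        basis = rng.random(40)
        coeffs = rng.random(6)
        out, _ = centered_set(np.outer(coeffs, basis))
        model, _ = fit_pca(out)
        assert model.explained_variance_ratio[0] >= 1 - 1e-9

    def test_variances_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        out, _ = centered_set(rng.random((6, 20)))
        model, scores = fit_pca(out)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(out.absorbance, rowvar=False)))[::-1]
        np.testing.assert_allclose(model.explained_variance, eigvals[:5], atol=1e-8)
        # score column variance equals the explained variance
        np.testing.assert_allclose(
            scores.scores.var(axis=0, ddof=1), model.explained_variance, rtol=1e-8
        )

    def test_full_reconstruction(self):
        rng = np.random.default_rng(8)
        out, _ = centered_set(rng.random((7, 25)))
        model, scores = fit_pca(out)
        recon = scores.scores @ model.loadings
        np.testing.assert_allclose(recon, out.absorbance, atol=1e-8)

    def test_reconstruction_error_non_increasing_in_k(self):
        rng = np.random.default_rng(9)
        out, _ = centered_set(rng.random((8, 30)))
        model, scores = fit_pca(out)
        errs = [
            np.linalg.norm(out.absorbance - scores.scores[:, :k] @ model.loadings[:k])
            for k in range(1, model.n_components + 1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestSelectComponents:
    @pytest.mark.parametrize(
        "ratios, target, expected",
        [((0.6, 0.3, 0.1), 0.9, 2), ((1.0,), 0.9, 1), ((0.5, 0.3, 0.2), 0.99, 3)],
    )
    def test_cumulative_rule(self, ratios, target, expected):
        model, _ = _model_with_ratios(ratios)
        assert select_n_components(model, target) == expected

    def test_low_rank_simulated_population_bounds_k(self):
        rng = np.random.default_rng(2)
        basis = rng.random((10, 120))
        coeffs = rng.random((60, 10))
        noise = 1e-4 * rng.standard_normal((60, 120))
        out, _ = centered_set(coeffs @ basis + noise)
        model, _ = fit_pca(out)
        assert select_n_components(model, 0.90) <= 12


def _model_with_ratios(ratios):
    from nirscreen.chemometrics import PCAModel

    ratios = np.asarray(ratios, float)
    model = PCAModel(
        loadings=np.zeros((ratios.size, 5)),
        explained_variance=ratios,
        explained_variance_ratio=ratios,
        n_samples_fit=ratios.size + 1,
    )
    return model, None


class TestProject:
    def test_fitting_set_projects_to_fit_scores(self):
        rng = np.random.default_rng(3)
        raw = make_set(rng.random((6, 30)))
        out, centering = mean_center(raw)
        model, scores = fit_pca(out, centering)
        reproj = project(model, out)  # already centered: used as-is
        np.testing.assert_allclose(reproj.scores, scores.scores, atol=1e-10)
        # uncentered set goes through the stored centering and agrees too
        reproj_raw = project(model, raw)
        np.testing.assert_allclose(reproj_raw.scores, scores.scores, atol=1e-10)

    def test_mean_spectrum_projects_to_zero(self):
        rng = np.random.default_rng(4)
        raw = make_set(rng.random((6, 30)))
        out, centering = mean_center(raw)
        model, _ = fit_pca(out, centering)
        query = make_set(centering.mean_spectrum[None, :], grid=raw.grid)
        np.testing.assert_allclose(project(model, query).scores, 0.0, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        out, centering = centered_set(rng.random((5, 20)))
        model, _ = fit_pca(out, centering)
        other = make_set(rng.random((2, 20)), grid=5000 + 8.0 * np.arange(20))
        with pytest.raises(ValueError, match="grid"):
            project(model, other)


class TestBuildReference:
    def _scores(self, n, k, seed=0):
        rng = np.random.default_rng(seed)
        return ScoreMatrix(rng.random((n, k)), [f"r{i}" for i in range(n)])

    def test_five_scans_four_components_valid(self):
        ref = build_reference(self._scores(5, 6), [f"r{i}" for i in range(5)], 4)
        assert ref.n_components == 4
        assert ref.covariance.shape == (4, 4)
        np.testing.assert_allclose(ref.covariance, ref.covariance.T)

    def test_two_observations_one_component_valid(self):
        ref = build_reference(self._scores(2, 3), ["r0", "r1"], 1)
        assert ref.n_components == 1

    def test_components_equal_observations_rejected(self):
        with pytest.raises(ValueError, match="strictly fewer"):
            build_reference(self._scores(5, 6), [f"r{i}" for i in range(5)], 5)

    def test_unbiased_covariance(self):
        sm = self._scores(6, 2, seed=7)
        ref = build_reference(sm, sm.sample_ids, 2)
        np.testing.assert_allclose(
            ref.covariance, np.cov(sm.scores, rowvar=False, ddof=1), atol=1e-12
        )


class TestMahalanobis:
    def test_query_at_mean_is_zero(self):
        rng = np.random.default_rng(11)
        sm = ScoreMatrix(rng.random((6, 3)), [f"r{i}" for i in range(6)])
        ref = build_reference(sm, sm.sample_ids, 2)
        assert mahalanobis_distance(ref, ref.mean[None, :])[0] == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_euclidean(self):
        ref = ReferenceScores(
            scores=np.zeros((5, 2)), mean=np.zeros(2), covariance=np.eye(2)
        )
        q = np.array([[3.0, 4.0]])
        assert mahalanobis_distance(ref, q)[0] == pytest.approx(5.0)

    def test_hand_computed_toy(self):
        # S = diag(4, 1), u = (2, 1): d^2 = 4/4 + 1/1 = 2
        ref = ReferenceScores(
            scores=np.zeros((5, 2)), mean=np.zeros(2), covariance=np.diag([4.0, 1.0])
        )
        assert mahalanobis_distance(ref, np.array([[2.0, 1.0]]))[0] == pytest.approx(
            np.sqrt(2.0)
        )

    def test_one_dimension_matches_z_score(self):
        rng = np.random.default_rng(12)
        obs = rng.normal(3.0, 2.0, size=(8, 1))
        sm = ScoreMatrix(obs, [f"r{i}" for i in range(8)])
        ref = build_reference(sm, sm.sample_ids, 1)
        q = np.array([[5.5]])
        expected = abs(5.5 - obs.mean()) / obs.std(ddof=1)
        assert mahalanobis_distance(ref, q)[0] == pytest.approx(expected, rel=1e-10)

    def test_invariance_under_joint_linear_transform(self):
        rng = np.random.default_rng(13)
        obs = rng.random((8, 3))
        queries = rng.random((4, 3))
        sm = ScoreMatrix(obs, [f"r{i}" for i in range(8)])
        d0 = mahalanobis_distance(build_reference(sm, sm.sample_ids, 3), queries)
        for trial in range(5):
            A = rng.random((3, 3)) + np.eye(3)  # invertible w.h.p.
            smT = ScoreMatrix(obs @ A.T, sm.sample_ids)
            dT = mahalanobis_distance(
                build_reference(smT, sm.sample_ids, 3), queries @ A.T
            )
            np.testing.assert_allclose(dT, d0, rtol=1e-6)

    def test_brute_force_inverse_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            p = int(rng.integers(2, 5))
            n = int(rng.integers(p + 1, 11))
            obs = rng.normal(size=(n, p))
            sm = ScoreMatrix(obs, [f"r{i}" for i in range(n)])
            ref = build_reference(sm, sm.sample_ids, p)
            q = rng.normal(size=(3, p))
            d = mahalanobis_distance(ref, q)
            Sinv = np.linalg.inv(np.cov(obs, rowvar=False, ddof=1))
            for j in range(3):
                diff = q[j] - obs.mean(axis=0)
                np.testing.assert_allclose(
                    d[j], np.sqrt(diff @ Sinv @ diff), atol=1e-8, rtol=1e-8
                )

    def test_shrinkage_one_is_scaled_euclidean(self):
        rng = np.random.default_rng(15)
        obs = rng.random((5, 3))
        sm = ScoreMatrix(obs, [f"r{i}" for i in range(5)])
        ref = build_reference(sm, sm.sample_ids, 3)
        q = rng.random((4, 3))
        d = mahalanobis_distance(ref, q, shrinkage=1.0)
        mu = np.trace(ref.covariance) / 3
        expected = np.linalg.norm(q - ref.mean, axis=1) / np.sqrt(mu)
        np.testing.assert_allclose(d, expected, rtol=1e-10)

    def test_ledoit_wolf_intensity_bounds(self):
        rng = np.random.default_rng(16)
        small = rng.normal(size=(5, 4))
        big = rng.normal(size=(500, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
        assert 0.0 <= ledoit_wolf_intensity(small) <= 1.0
        # with many observations of a clearly anisotropic covariance the
        # estimated shrinkage is small
        assert ledoit_wolf_intensity(big) < 0.2
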