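"""Gaussian mixtures, DPMM stick-breaking, consensus configurations, Rand index."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgwr.clustering import (
    canonical_relabel,
    dahl_configuration,
    dpmm_fit,
    gmm_em_fit,
    gmm_select_K,
    mode_configuration,
    rand_index,
    stick_breaking_weights,
    two_stage_configuration,
)


def two_blobs(seed=0, n=200, sep=10.0, dim=1):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n // 2, dim))
    b = rng.normal(sep, 1, size=(n - n // 2, dim))
    return np.vstack([a, b])


class TestGmm:
    def test_single_component_is_sample_moments(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 2))
        fit = gmm_em_fit(pts, K=1)
        assert fit.means[0] == pytest.approx(pts.mean(axis=0), abs=1e-8)
        assert fit.covariances[0] == pytest.approx(
            np.cov(pts.T, bias=True) + 1e-6 * np.eye(2), abs=1e-6
        )
        assert np.all(fit.responsibilities == 1.0)

    def test_two_separated_clusters_recovered(self):
        pts = two_blobs(seed=1)
        fit = gmm_em_fit(pts, K=2, seed=1)
        means = np.sort(fit.means.ravel())
        assert means == pytest.approx([0.0, 10.0], abs=0.5)

    def test_matches_sklearn_oracle(self):
        """Cross-check converged log-likelihood against scikit-learn's EM."""
        from sklearn.mixture import GaussianMixture

        pts = two_blobs(seed=2, dim=2)
        ours = gmm_em_fit(pts, K=2, seed=2, restarts=5)
        ref = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0,
                              reg_covar=1e-6).fit(pts)
        assert ours.log_likelihood / len(pts) == pytest.approx(
            ref.score(pts), abs=0.01
        )

    def test_loglik_path_nondecreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(80, 3))
        fit = gmm_em_fit(pts, K=3, seed=3, restarts=1)
        assert np.all(np.diff(fit.log_likelihood_path) > -1e-6)

    def test_responsibilities_rows_sum_to_one(self):
        fit = gmm_em_fit(two_blobs(seed=4), K=2, seed=4)
        assert fit.responsibilities.sum(axis=1) == pytest.approx(
            np.ones(200), abs=1e-8
        )

    def test_invalid_K(self):
        pts = two_blobs()
        with pytest.raises(ValueError):
            gmm_em_fit(pts, K=0)
        with pytest.raises(ValueError):
            gmm_em_fit(pts, K=len(pts))

    def test_identical_points_single_component_warning(self):
        pts = np.ones((20, 2))
        with pytest.warns(RuntimeWarning, match="identical"):
            fit = gmm_em_fit(pts, K=3)
        assert fit.K == 1

    def test_bic_selects_two_for_separated_blobs(self):
        pts = two_blobs(seed=5, dim=2)
        fit = gmm_select_K(pts, range(1, 7), seed=5, restarts=3)
        assert fit.K == 2

    def test_bic_selects_one_for_single_blob(self):
        rng = np.random.default_rng(6)
        fit = gmm_select_K(rng.normal(size=(200, 2)), range(1, 7), seed=6, restarts=3)
        assert fit.K == 1

    def test_singleton_range(self):
        fit = gmm_select_K(two_blobs(seed=7), [3], seed=7, restarts=2)
        assert fit.K == 3

    def test_selected_bic_is_minimal(self):
        pts = two_blobs(seed=8, dim=2)
        fits = [gmm_em_fit(pts, k, seed=8, restarts=2) for k in range(1, 5)]
        best = gmm_select_K(pts, range(1, 5), seed=8, restarts=2)
        assert best.bic == min(f.bic for f in fits)


class TestDpmm:
    def test_stick_identity(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0.01, 0.99, size=(5, 8))
        C = stick_breaking_weights(V)
        assert C[:, 0] == pytest.approx(V[:, 0])
        for k in range(1, 8):
            assert C[:, k] == pytest.approx(
                V[:, k] * np.prod(1 - V[:, :k], axis=1)
            )
        deficit = 1 - C.sum(axis=1)
        assert deficit == pytest.approx(np.prod(1 - V, axis=1), abs=1e-12)

    def test_emitted_states_satisfy_stick_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(30, 1))
        d = dpmm_fit(pts, iterations=50, burn_in=10, seed=1, truncation=6)
        assert d.C == pytest.approx(stick_breaking_weights(d.V))
        assert np.all(d.C.sum(axis=1) <= 1 + 1e-12)

    def test_tight_cluster_occupies_one_component(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 0.01, size=(100, 1))
        d = dpmm_fit(pts, alpha=1.0, iterations=400, burn_in=100, seed=2)
        n_occ = [len(np.unique(z)) for z in d.z]
        counts = np.bincount(n_occ)
        assert counts.argmax() == 1  # modal occupied-cluster count is 1

    def test_prior_cluster_count_grows_with_alpha(self):
        """Partitions sampled from the stick-breaking prior match the
        Chinese-restaurant expectation E[K] = sum_i alpha/(alpha+i-1)."""
        rng = np.random.default_rng(3)
        S, H, reps = 100, 80, 300
        means = {}
        for alpha in (0.1, 1.0, 10.0):
            ks = []
            for _ in range(reps):
                V = rng.beta(1.0, alpha, size=H)
                C = stick_breaking_weights(V)
                z = rng.choice(H, size=S, p=C / C.sum())
                ks.append(len(np.unique(z)))
            means[alpha] = np.mean(ks)
            crp = sum(alpha / (alpha + i) for i in range(S))
            assert means[alpha] == pytest.approx(crp, rel=0.15)
        assert means[0.1] < means[1.0] < means[10.0]

    def test_truncation_validation(self):
        with pytest.raises(ValueError):
            dpmm_fit(np.zeros((10, 1)), truncation=1)
        with pytest.raises(ValueError):
            dpmm_fit(np.zeros((10, 1)), alpha=-1.0)


class TestConfigurations:
    def test_dahl_degenerate_consensus(self):
        z = np.tile([1, 1, 2, 2], (5, 1))
        config, summary = dahl_configuration(z)
        assert list(config.assignment) == [1, 1, 2, 2]
        assert np.all(np.isin(summary.mean_matrix, [0.0, 1.0]))
        assert np.all(np.diag(summary.mean_matrix) == 1.0)

    def test_dahl_single_draw(self):
        config, _ = dahl_configuration(np.array([[3, 3, 7]]))
        assert list(config.assignment) == [1, 1, 2]

    def test_dahl_matches_brute_force(self):
        draws = np.array([[1, 1, 2, 2], [1, 2, 2, 2], [1, 1, 1, 2]])
        config, summary = dahl_configuration(draws)
        B = np.array([[r[:, None] == r[None, :] for r in draws]]).squeeze(0)
        Bbar = B.mean(axis=0)
        dists = [((b - Bbar) ** 2).sum() for b in B]
        assert summary.chosen_iteration == int(np.argmin(dists))
        assert summary.mean_matrix == pytest.approx(Bbar)

    def test_dahl_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        draws = rng.integers(1, 4, size=(20, 8))
        config1, _ = dahl_configuration(draws)
        permuted = np.vectorize({1: 7, 2: 5, 3: 9}.get)(draws)
        config2, _ = dahl_configuration(permuted)
        assert np.array_equal(config1.assignment, config2.assignment)

    def test_mode_identical_draws(self):
        config = mode_configuration(np.tile([2, 1, 1], (4, 1)))
        assert list(config.assignment) == [1, 2, 2]
        assert np.all(config.probabilities.to_numpy().max(axis=1) == 1.0)

    def test_mode_majority_probability(self):
        config = mode_configuration(np.array([[1.0], [1.0], [2.0]]))
        assert config.assignment[0] == 1
        probs = config.probabilities.iloc[0]
        assert probs[1] == pytest.approx(2 / 3)
        assert probs[2] == pytest.approx(1 / 3)

    def test_mode_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        draws = rng.integers(1, 5, size=(40, 6)).astype(float)
        config = mode_configuration(draws)
        for s in range(6):
            labs, counts = np.unique(draws[:, s], return_counts=True)
            winner = labs[counts.argmax()]
            # winner after relabeling still groups identically
            same = draws[:, s] == winner
            assert (
                config.probabilities.iloc[s].max()
                == pytest.approx(counts.max() / 40)
            )

    def test_mode_missing_handling(self):
        draws = np.array([[1.0, np.nan], [1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="region index 1"):
            mode_configuration(draws)
        ok = mode_configuration(np.array([[1.0, np.nan], [1.0, 2.0]]))
        assert ok.assignment[1] == ok.assignment[1]  # resolves from one valid draw

    def test_canonical_relabel_first_appearance(self):
        assert list(canonical_relabel(np.array([5, 5, 2, 7, 2]))) == [1, 1, 2, 3, 2]


class TestRandIndex:
    def test_perfect_agreement(self):
        assert rand_index([1, 1, 2, 3], [9, 9, 4, 5]) == 1.0

    def test_single_pair_disagreement(self):
        assert rand_index([1, 1], [1, 2]) == 0.0

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.integers(0, 4, size=10)
            b = rng.integers(0, 3, size=10)
            agree = sum(
                (a[i] == a[j]) == (b[i] == b[j])
                for i, j in itertools.combinations(range(10), 2)
            )
            assert rand_index(a, b) == pytest.approx(agree / 45)

    def test_matches_sklearn(self):
        from sklearn.metrics import rand_score

        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, size=50)
        b = rng.integers(0, 5, size=50)
        assert rand_index(a, b) == pytest.approx(rand_score(a, b))

    @settings(deadline=None, max_examples=50)
    @given(
        labels=st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=30
        )
    )
    def test_symmetry_and_relabel_invariance(self, labels):
        a = np.array([x for x, _ in labels])
        b = np.array([y for _, y in labels])
        assert rand_index(a, b) == pytest.approx(rand_index(b, a))
        assert rand_index(a + 10, b) == pytest.approx(rand_index(a, b))

    def test_validation(self):
        with pytest.raises(ValueError):
            rand_index([1], [1])
        with pytest.raises(ValueError):
            rand_index([1, 2], [1, 2, 3])


class TestTwoStage:
    def _draws_from_beta(self, beta):
        from bgwr.geo import KernelSpec
        from bgwr.sampler import BgwrDraws, McmcSettings, PriorSpec

        T, S, p = beta.shape
        return BgwrDraws(
            beta=beta,
            sigma2=np.ones((T, S)),
            sigma_beta2=np.ones(T),
            bandwidth=np.ones(T),
            acceptance_rate=0.3,
            region_ids=list(range(S)),
            covariate_names=[f"x{j}" for j in range(p)],
            settings=McmcSettings(iterations=T + 1, burn_in=0, seed=0),
            priors=PriorSpec(),
            kernel=KernelSpec("exponential", 1.0),
        )

    def test_identical_partitions_pass_through(self):
        """Clearly separated, draw-invariant structure yields that partition."""
        rng = np.random.default_rng(8)
        centers = np.array([[0.0], [50.0], [100.0]])
        truth = np.repeat([1, 2, 3], 10)
        beta = centers[truth - 1][None, :, :] + 0.01 * rng.normal(size=(12, 30, 1))
        draws = self._draws_from_beta(beta)
        config = two_stage_configuration(
            draws, n_samples=8, clusterer="gmm", seed=1, K_range=range(1, 5),
            gmm_restarts=3,
        )
        assert rand_index(config.assignment, truth) == 1.0

    def test_label_permutation_across_samples_is_resolved(self):
        rng = np.random.default_rng(12)
        vals = np.repeat([0.0, 50.0, 100.0], 4)
        beta = np.tile(vals[:, None], (10, 1, 1)) + 0.01 * rng.normal(
            size=(10, 12, 1)
        )
        draws = self._draws_from_beta(beta)
        config = two_stage_configuration(
            draws, n_samples=6, clusterer="gmm", seed=2, K_range=range(1, 5),
            gmm_restarts=2,
        )
        assert config.n_clusters == 3

    def test_n_samples_validation(self):
        draws = self._draws_from_beta(np.zeros((5, 4, 1)))
        with pytest.raises(ValueError, match="exceeds"):
            two_stage_configuration(draws, n_samples=10)
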