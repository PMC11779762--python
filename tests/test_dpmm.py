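import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from funcest.dpmm import (
    DirichletProcessGMM,
    NIWPrior,
    Partition,
    count_clusters,
    crp_prior,
    default_prior,
    gibbs_sweep,
    niw_update,
    predictive_loglik,
    predictive_moments,
    run_dpmm,
)
from funcest.exceptions import InvalidArgumentError


def three_blob_data(seed, separation=15.0, n_per=20):
    rng = np.random.default_rng(seed)
    means = np.array([[0, 0, 0], [separation, 0, 0], [0, separation, 0]], float)
    truth = np.repeat([0, 1, 2], n_per)
    return means[truth] + rng.normal(0, 1, (3 * n_per, 3)), truth


class TestCRPPrior:
    @pytest.mark.parametrize(
        "sizes,alpha,expected",
        [
            ([2, 1], 1.0, [0.5, 0.25, 0.25]),
            ([3], 1.5, [2 / 3, 1 / 3]),
        ],
    )
    def test_forced_examples(self, sizes, alpha, expected):
        np.testing.assert_allclose(crp_prior(sizes, alpha), expected, atol=1e-12)

    def test_sums_to_one_and_vanishing_alpha_limit(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sizes = rng.integers(1, 30, size=rng.integers(1, 6))
            p = crp_prior(sizes, rng.uniform(0.01, 10))
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)
        assert crp_prior([4, 2], 1e-12)[-1] < 1e-12

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(InvalidArgumentError):
            crp_prior([1], 0.0)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exchangeability_by_exhaustive_enumeration(self, n):
        # The sequential product probability of a labeled partition must not
        # depend on the order items are seated in.
        alpha = 1.3
        rng = np.random.default_rng(n)
        partition = rng.integers(0, 2, size=n)

        def seq_prob(order):
            seen: dict[int, int] = {}
            prob = 1.0
            for step, i in enumerate(order):
                g = partition[i]
                denom = step + alpha
                prob *= (seen[g] if g in seen else alpha) / denom
                seen[g] = seen.get(g, 0) + 1
            return prob

        probs = {seq_prob(order) for order in itertools.permutations(range(n))}
        assert max(probs) - min(probs) < 1e-15


class TestNIW:
    prior = NIWPrior(np.zeros(3), 1.0, 5.0, np.eye(3))

    def test_empty_members_returns_prior(self):
        assert niw_update(self.prior, np.empty((0, 3))) is self.prior

    def test_single_member_update(self):
        v = np.array([2.0, -1.0, 0.5])
        post = niw_update(self.prior, [v])
        np.testing.assert_allclose(post.mu0, v / 2.0)
        assert post.kappa0 == 2.0 and post.nu0 == 6.0

    def test_many_members_match_direct_conjugate_formulas(self):
        rng = np.random.default_rng(1)
        members = rng.normal(1.0, 2.0, (50, 3))
        post = niw_update(self.prior, members)
        m = 50
        xbar = members.mean(axis=0)
        S = (members - xbar).T @ (members - xbar)
        dev = xbar - self.prior.mu0
        np.testing.assert_allclose(
            post.mu0, (self.prior.mu0 + m * xbar) / (1 + m), atol=1e-10
        )
        np.testing.assert_allclose(
            post.lambda0,
            self.prior.lambda0 + S + (m / (1 + m)) * np.outer(dev, dev),
            atol=1e-10,
        )

    def test_prior_predictive_symmetric_about_mean(self):
        d = np.array([0.3, -0.2, 0.9])
        empty = np.empty((0, 3))
        up = predictive_loglik(self.prior.mu0 + d, empty, self.prior)
        down = predictive_loglik(self.prior.mu0 - d, empty, self.prior)
        assert up == pytest.approx(down, abs=1e-12)

    def test_moment_match_equals_student_t_moments(self):
        rng = np.random.default_rng(2)
        members = rng.normal(0, 1, (8, 3))
        mean, cov = predictive_moments(self.prior, members)
        post = niw_update(self.prior, members)
        d = 3
        t_dof = post.nu0 - d + 1
        t_scale = post.lambda0 * (post.kappa0 + 1) / (post.kappa0 * t_dof)
        np.testing.assert_allclose(mean, post.mu0, atol=1e-10)
        np.testing.assert_allclose(cov, t_scale * t_dof / (t_dof - 2), atol=1e-10)

    def test_predictive_approaches_sample_moments_at_large_n(self):
        rng = np.random.default_rng(3)
        members = rng.multivariate_normal([1, 2, 3], np.diag([1.0, 2.0, 0.5]), 500)
        mean, cov = predictive_moments(self.prior, members)
        np.testing.assert_allclose(mean, members.mean(axis=0), rtol=0.05)
        np.testing.assert_allclose(
            np.diag(cov), np.diag(np.cov(members, rowvar=False)), rtol=0.05
        )


class TestGibbsSweep:
    def test_single_item_always_singleton(self):
        data = np.array([[0.0, 0.0, 0.0]])
        prior = NIWPrior(np.zeros(3), 1.0, 5.0, np.eye(3))
        part = gibbs_sweep(Partition([0]), data, 1.0, prior, np.random.default_rng(0))
        assert part.n_clusters == 1 and part.sizes.sum() == 1

    def test_item_count_conserved_over_sweeps(self):
        X, _ = three_blob_data(0)
        prior = default_prior(X)
        part = Partition(np.arange(60))
        rng = np.random.default_rng(5)
        for _ in range(100):
            part = gibbs_sweep(part, X, 1.0, prior, rng)
            assert part.sizes.sum() == 60
            assert part.n_clusters == np.count_nonzero(part.sizes)

    def test_two_tight_blobs_modal_k_over_chains(self):
        ks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            means = np.array([[0, 0, 0], [20, 0, 0]], float)
            truth = np.repeat([0, 1], 20)
            X = means[truth] + rng.normal(0, 0.1, (40, 3))
            part, _ = run_dpmm(X, n_sweeps=200, burn_in=100, seed=100 + seed)
            ks.append(part.n_clusters)
        values, counts = np.unique(ks, return_counts=True)
        assert values[np.argmax(counts)] == 2


class TestRunDPMM:
    def test_identical_data_collapse_to_one_cluster(self):
        X = np.tile([1.0, 2.0, 3.0], (12, 1))
        part, summary = run_dpmm(X, n_sweeps=50, burn_in=10, seed=0)
        assert part.n_clusters == 1
        np.testing.assert_allclose(summary.geometric_mean[0], np.exp([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(summary.multiplicative_sd[0], 1.0)

    def test_three_blob_recovery_across_seeds(self):
        # reduced-size smoke check (8 chains, 300 sweeps); the full battery
        # at 20 chains x 1000 sweeps is exercised in the acceptance tests
        ks, aris = [], []
        for seed in range(8):
            X, truth = three_blob_data(seed)
            part, _ = run_dpmm(X, n_sweeps=300, burn_in=150, seed=seed)
            ks.append(part.n_clusters)
            aris.append(adjusted_rand_score(truth, part.assignments))
        values, counts = np.unique(ks, return_counts=True)
        assert values[np.argmax(counts)] == 3
        assert np.median(aris) > 0.9

    def test_seeded_determinism(self):
        X, _ = three_blob_data(1)
        p1, _ = run_dpmm(X, n_sweeps=60, burn_in=30, seed=11)
        p2, _ = run_dpmm(X, n_sweeps=60, burn_in=30, seed=11)
        np.testing.assert_array_equal(p1.assignments, p2.assignments)

    def test_summary_counts_reconcile_with_assignments(self):
        X, _ = three_blob_data(2)
        part, summary = run_dpmm(X, n_sweeps=100, burn_in=50, seed=3)
        np.testing.assert_array_equal(summary.counts, part.sizes[: part.n_clusters])
        assert np.all(np.diff(part.sizes) <= 0)  # canonical order: decreasing size

    def test_estimator_front_end(self):
        X, truth = three_blob_data(4)
        est = DirichletProcessGMM(n_sweeps=200, burn_in=100, random_state=0).fit(X)
        assert est.labels_.shape == (60,)
        assert est.n_clusters_ == len(est.summary_.counts)
        assert adjusted_rand_score(truth, est.labels_) > 0.9


class TestCountClusters:
    def test_reported_partition_examples(self):
        # membership-count rows from the reference study's cluster table
        sizes_a = [128, 43, 5, 1]
        part_a = Partition(np.repeat(np.arange(4), sizes_a))
        assert count_clusters(part_a) == 4
        sizes_b = [99, 78]
        part_b = Partition(np.repeat(np.arange(2), sizes_b))
        assert count_clusters(part_b) == 2

    def test_min_size_filter_and_single_group(self):
        part = Partition(np.repeat([0, 1, 2], [30, 12, 1]))
        assert count_clusters(part) == 3
        assert count_clusters(part, min_size=11) == 2
        assert count_clusters(Partition(np.zeros(7, dtype=int))) == 1
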