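import numpy as np
import pytest
from scipy.integrate import quad
from hypothesis import given, settings
from hypothesis import strategies as st

import colormotif as cm
from colormotif.model import (
    BBDPConfig,
    compute_elbo,
    hard_assignments,
    init_state,
    update_emissions,
    update_responsibilities,
    update_sticks,
)


def random_binary(rng, n, d):
    return rng.integers(0, 2, size=(n, d)).astype(float)


class TestDensities:
    @pytest.mark.parametrize(
        "x,theta,expected",
        [
            ((1, 1, 1), (0.5, 0.5, 0.5), 0.125),
            ((1, 0), (0.9, 0.2), 0.72),
            ((1,), (0.0,), 0.0),
            ((0,), (0.0,), 1.0),  # 0^0 -> 1
        ],
    )
    def test_bernoulli_density(self, x, theta, expected):
        assert cm.bernoulli_density(x, theta) == pytest.approx(expected)

    def test_bernoulli_density_length_mismatch(self):
        with pytest.raises(ValueError):
            cm.bernoulli_density([1, 0], [0.5])

    def test_marginal_single_one_equals_prior_mean(self):
        assert cm.log_beta_bernoulli_marginal([[1]], 0.9, 0.9) == pytest.approx(
            np.log(0.5)
        )

    def test_marginal_empty_block_is_zero(self):
        assert cm.log_beta_bernoulli_marginal(np.zeros((0, 3)), 0.9, 0.9) == 0.0

    def test_marginal_two_ones_uniform_prior(self):
        # integral of theta^2 over Beta(1,1) = 1/3
        assert cm.log_beta_bernoulli_marginal([[1], [1]], 1.0, 1.0) == pytest.approx(
            np.log(1 / 3)
        )

    def test_marginal_matches_numeric_integration(self):
        b1, b2 = 0.7, 0.4
        X = np.array([[1], [1], [0]])
        from scipy.stats import beta as beta_dist

        val, _ = quad(
            lambda t: t**2 * (1 - t) * beta_dist.pdf(t, b1, b2), 0, 1
        )
        assert cm.log_beta_bernoulli_marginal(X, b1, b2) == pytest.approx(
            np.log(val), abs=1e-8
        )


class TestExactOracles:
    def test_single_row_reduces_to_marginal(self):
        X = np.array([[1.0, 0.0]])
        for alpha in (0.5, 7.0):
            assert cm.crp_exact_log_evidence(X, alpha, 0.9, 0.9) == pytest.approx(
                cm.log_beta_bernoulli_marginal(X, 0.9, 0.9)
            )

    def test_small_alpha_limit_approaches_one_block(self):
        X = np.array([[1.0], [1.0]])
        v = cm.crp_exact_log_evidence(X, 1e-10, 0.9, 0.9)
        assert v == pytest.approx(cm.log_beta_bernoulli_marginal(X, 0.9, 0.9), abs=1e-8)

    def test_three_point_evidence_matches_hand_enumeration(self):
        # the 5 partitions of {0,1,2}, CRP prior alpha=1, beta=0.9
        X = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        alpha, b = 1.0, 0.9
        m = lambda rows: cm.log_beta_bernoulli_marginal(X[list(rows)], b, b)
        partitions = [
            [(0, 1, 2)],
            [(0, 1), (2,)],
            [(0, 2), (1,)],
            [(1, 2), (0,)],
            [(0,), (1,), (2,)],
        ]
        from scipy.special import gammaln

        norm = np.log(alpha) + np.log(alpha + 1) + np.log(alpha + 2)
        terms = []
        for blocks in partitions:
            lp = len(blocks) * np.log(alpha) - norm
            lp += sum(gammaln(len(bk)) + m(bk) for bk in blocks)
            terms.append(lp)
        expected = np.log(np.sum(np.exp(terms)))
        assert cm.crp_exact_log_evidence(X, alpha, b, b) == pytest.approx(expected)

    def test_refuses_large_instances(self):
        with pytest.raises(ValueError):
            cm.crp_exact_log_evidence(np.zeros((9, 1)), 1.0, 0.9, 0.9)

    def test_truncated_evidence_approaches_crp_for_large_K(self):
        # with K >> N and alpha small, nearly all stick mass is on the
        # first sticks and the truncated model approximates the full DP
        rng = np.random.default_rng(1)
        X = random_binary(rng, 3, 2)
        crp = cm.crp_exact_log_evidence(X, 0.5, 0.9, 0.9)
        trunc = cm.truncated_exact_log_evidence(X, 0.5, 0.9, 0.9, K=8)
        assert trunc == pytest.approx(crp, abs=0.02)


class TestUpdates:
    def test_init_is_deterministic(self):
        X = random_binary(np.random.default_rng(0), 5, 3)
        cfg = BBDPConfig(K=4, seed=11)
        s1, s2 = init_state(X, cfg), init_state(X, cfg)
        assert (s1.R == s2.R).all() and (s1.a == s2.a).all()

    def test_K1_forces_unit_responsibility(self):
        X = random_binary(np.random.default_rng(0), 6, 2)
        cfg = BBDPConfig(K=1)
        state = init_state(X, cfg)
        update_responsibilities(state, X, cfg)
        assert np.allclose(state.R, 1.0)

    def test_symmetric_clusters_share_responsibility(self):
        X = np.array([[1.0, 0.0]])
        cfg = BBDPConfig(alpha=1.0, K=2)
        state = init_state(X, cfg, seed=0)
        # hand-set identical stick and emission expectations
        state.gamma1 = np.array([1.0, 1.0])
        state.gamma2 = np.array([1.0, 1.0])
        state.a = np.full((2, 2), 2.0)
        state.b = np.full((2, 2), 3.0)
        # make expected log pi identical by construction: K=2 has
        # E[log pi_1] = E[log v_1], E[log pi_2] = E[log(1-v_1)] (v_2 = 1),
        # equal for the symmetric Beta(1,1) stick
        update_responsibilities(state, X, cfg)
        assert np.allclose(state.R, 0.5)

    def test_responsibility_matches_hand_arithmetic(self):
        from scipy.special import digamma

        X = np.array([[1.0, 0.0]])
        cfg = BBDPConfig(alpha=2.0, K=2)
        state = init_state(X, cfg, seed=0)
        state.gamma1 = np.array([3.0, 1.0])
        state.gamma2 = np.array([2.0, 4.0])
        state.a = np.array([[2.0, 1.0], [1.0, 3.0]])
        state.b = np.array([[1.0, 2.0], [2.0, 1.0]])
        elog_v1 = digamma(3) - digamma(5)
        elog_1mv1 = digamma(2) - digamma(5)
        elog_pi = np.array([elog_v1, elog_1mv1])  # last stick is 1
        ll = np.empty(2)
        for k in range(2):
            a, b = state.a[k], state.b[k]
            elog_t = digamma(a) - digamma(a + b)
            elog_1mt = digamma(b) - digamma(a + b)
            ll[k] = elog_t[0] + elog_1mt[1]  # x = (1, 0)
        logits = elog_pi + ll
        expected = np.exp(logits - np.logaddexp(*logits))
        update_responsibilities(state, X, cfg)
        assert np.allclose(state.R[0], expected)

    def test_stick_updates(self):
        cfg = BBDPConfig(alpha=5.0, K=2)
        X = np.zeros((2, 1))
        state = init_state(X, cfg, seed=0)
        state.R = np.array([[1.0, 0.0], [1.0, 0.0]])
        update_sticks(state, cfg)
        assert state.gamma1[0] == pytest.approx(3.0)  # 1 + 2
        assert state.gamma2[0] == pytest.approx(5.0)  # alpha + 0 downstream

    def test_empty_cluster_reverts_to_priors(self):
        cfg = BBDPConfig(alpha=4.0, beta1=0.9, beta2=0.9, K=3)
        X = np.array([[1.0], [0.0]])
        state = init_state(X, cfg, seed=0)
        state.R = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        update_sticks(state, cfg)
        update_emissions(state, X, cfg)
        assert (state.gamma1[1], state.gamma2[1]) == (1.0, 4.0)
        assert state.a[1, 0] == pytest.approx(0.9)
        assert state.b[1, 0] == pytest.approx(0.9)

    def test_emission_update_and_conservation(self):
        cfg = BBDPConfig(beta1=0.9, beta2=0.9, K=1)
        X = np.array([[1.0], [0.0]])
        state = init_state(X, cfg, seed=0)
        state.R = np.ones((2, 1))
        update_emissions(state, X, cfg)
        assert state.a[0, 0] == pytest.approx(1.9)
        assert state.b[0, 0] == pytest.approx(1.9)
        # a + b = beta1 + beta2 + sum_i r_ik for every dimension
        assert np.allclose(state.a + state.b, 0.9 + 0.9 + state.R.sum(0)[:, None])


class TestElbo:
    def test_single_cluster_conjugate_case_is_exact(self):
        X = np.array([[1.0]])
        cfg = BBDPConfig(alpha=1.0, beta1=0.9, beta2=0.9, K=1, n_restarts=1)
        state, _ = cm.fit(X, cfg)
        assert state.elbo_trace[-1] == pytest.approx(np.log(0.5), abs=1e-9)

    def test_elbo_never_exceeds_truncated_exact_evidence(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            n, d = rng.integers(2, 6), rng.integers(1, 4)
            X = random_binary(rng, n, d)
            alpha = float(rng.choice([0.5, 1.0, 1000.0]))
            beta = float(rng.choice([0.5, 0.9]))
            cfg = BBDPConfig(
                alpha=alpha, beta1=beta, beta2=beta, K=3, n_restarts=3,
                seed=int(rng.integers(1000)),
            )
            state, _ = cm.fit(X, cfg)
            exact = cm.truncated_exact_log_evidence(X, alpha, beta, beta, K=3)
            assert state.elbo_trace[-1] <= exact + 1e-9

    def test_elbo_trace_nondecreasing(self):
        rng = np.random.default_rng(3)
        X = random_binary(rng, 30, 10)
        cfg = BBDPConfig(alpha=2.0, K=8, n_restarts=1, seed=5)
        state, _ = cm.fit(X, cfg)
        diffs = np.diff(state.elbo_trace)
        assert (diffs >= -1e-8 * np.abs(state.elbo_trace[:-1])).all()

    def test_duplicating_rows_lowers_log_probability(self):
        rng = np.random.default_rng(4)
        X = random_binary(rng, 6, 4)
        cfg = BBDPConfig(alpha=1.0, K=4, n_restarts=3, seed=2)
        s1, _ = cm.fit(X, cfg)
        s2, _ = cm.fit(np.vstack([X, X]), cfg)
        assert s2.elbo_trace[-1] < s1.elbo_trace[-1]


class TestFit:
    def test_identical_rows_collapse_to_one_cluster(self):
        X = np.tile(np.array([[1.0, 0.0, 1.0]]), (20, 1))
        cfg = BBDPConfig(alpha=1.0, K=10, n_restarts=2, seed=0)
        _, result = cm.fit(X, cfg)
        assert result.effective_K == 1

    def test_two_separable_blocks_recovered(self):
        X = np.vstack([np.ones((20, 30)), np.zeros((20, 30))])
        cfg = BBDPConfig(alpha=1.0, K=10, n_restarts=3, seed=0)
        _, result = cm.fit(X, cfg)
        assert result.effective_K == 2
        z = result.assignments
        assert len(set(z[:20])) == 1 and len(set(z[20:])) == 1
        assert z[0] != z[20]

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(0)
        X = random_binary(rng, 15, 8)
        cfg = BBDPConfig(alpha=2.0, K=5, n_restarts=2, seed=42)
        _, r1 = cm.fit(X, cfg)
        _, r2 = cm.fit(X, cfg)
        assert (r1.assignments == r2.assignments).all()
        assert r1.final_elbo == r2.final_elbo
        assert (r1.centroids == r2.centroids).all()

    def test_row_permutation_equivariance(self):
        # observations are exchangeable: permuting data rows (with the
        # matching initial responsibilities) permutes the trajectory row-wise
        # and leaves the ELBO and the induced partition unchanged.  Component
        # labels, by contrast, are NOT exchangeable under stick-breaking: the
        # prior is size-biased in the component index.
        rng = np.random.default_rng(6)
        X = random_binary(rng, 12, 6)
        cfg = BBDPConfig(alpha=1.0, K=4, n_restarts=1, seed=9)
        perm = rng.permutation(12)

        def run(Xrun, row_perm):
            state = init_state(X, cfg, seed=9)
            state.R = state.R[row_perm]
            update_sticks(state, cfg)
            update_emissions(state, Xrun, cfg)
            for _ in range(60):
                update_responsibilities(state, Xrun, cfg)
                update_sticks(state, cfg)
                update_emissions(state, Xrun, cfg)
            return compute_elbo(state, Xrun, cfg), hard_assignments(state)

        base_elbo, base_z = run(X, np.arange(12))
        perm_elbo, perm_z = run(X[perm], perm)
        assert perm_elbo == pytest.approx(base_elbo, rel=1e-9)
        assert (perm_z == base_z[perm]).all()

    def test_expected_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        X = random_binary(rng, 10, 5)
        cfg = BBDPConfig(alpha=3.0, K=6, n_restarts=1, seed=1)
        state, result = cm.fit(X, cfg)
        assert result.expected_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (state.R.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-12))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            cm.fit(np.zeros((0, 3)), BBDPConfig(K=2))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            BBDPConfig(beta1=1.5)
        with pytest.raises(ValueError):
            BBDPConfig(alpha=-1.0)
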