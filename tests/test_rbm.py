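"""RBM energy/partition-function/sampling machinery against independent
oracles (brute-force enumeration, closed forms, Monte-Carlo checks)."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from conftest import make_rbm
from moldvae.autograd import Tensor
from moldvae.rbm import (RBM, AnnealerStub, PCDState, PosteriorHead,
                         ais_log_partition, bernoulli_entropy,
                         enumerate_states, exact_distribution,
                         gaussian_latent, kl_term, pcd_sample, prior_sample,
                         spike_exp_reparam, spike_exp_sample)


class TestEnergy:
    def test_all_zero_state_has_zero_energy(self):
        rbm = make_rbm(3, 3, seed=0)
        assert rbm.energy(np.zeros(6)) == 0.0

    def test_zero_parameters_give_zero_energy(self):
        rbm = RBM(3, 3, np.random.default_rng(0), init_scale=0.0)
        states = enumerate_states(6)
        assert np.allclose(rbm.energy(states), 0.0)

    def test_hand_case_two_units(self):
        rbm = RBM(1, 1, np.random.default_rng(0))
        rbm.h.data = np.array([1.0, -2.0])
        rbm.W.data = np.array([[3.0]])
        assert rbm.energy(np.array([1.0, 1.0])) == pytest.approx(2.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_rbm(2, 2, seed=0).energy(np.zeros(5))

    def test_layer_swap_symmetry(self):
        rbm = make_rbm(3, 2, seed=1)
        swapped = RBM(2, 3, np.random.default_rng(0))
        swapped.h.data = np.concatenate([rbm.h.data[3:], rbm.h.data[:3]])
        swapped.W.data = rbm.W.data.T
        states = enumerate_states(5)
        for z in states:
            zs = np.concatenate([z[3:], z[:3]])
            assert rbm.energy(z) == pytest.approx(swapped.energy(zs))

    def test_differentiable_energy_matches_numpy(self):
        rbm = make_rbm(3, 3, seed=2)
        z = (np.random.default_rng(0).random((5, 6)) < 0.5).astype(float)
        assert np.allclose(rbm.energy_t(Tensor(z)).data, rbm.energy(z))


class TestExactPartition:
    def test_zero_parameters_give_n_log2(self):
        rbm = RBM(4, 3, np.random.default_rng(0), init_scale=0.0)
        assert rbm.log_partition_exact() == pytest.approx(7 * np.log(2))

    def test_single_biased_unit_closed_form(self):
        rbm = RBM(1, 1, np.random.default_rng(0), init_scale=0.0)
        rbm.h.data = np.array([1.7, 0.0])
        # Z = (1 + e^-1.7) * 2 because the second unit is free
        expected = np.log(1 + np.exp(-1.7)) + np.log(2)
        assert rbm.log_partition_exact() == pytest.approx(expected)

    def test_matches_independent_brute_force_loop(self):
        rbm = make_rbm(3, 3, seed=3)
        acc = 0.0
        for idx in range(2 ** 6):
            z = np.array([(idx >> k) & 1 for k in range(6)], dtype=float)
            acc += np.exp(-rbm.energy(z))
        assert rbm.log_partition_exact() == pytest.approx(np.log(acc))

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="AIS|ais|enumerat"):
            RBM(13, 13, np.random.default_rng(0)).log_partition_exact()


class TestBlockGibbs:
    def test_zero_parameters_sample_uniformly(self):
        rbm = RBM(3, 3, np.random.default_rng(0), init_scale=0.0)
        rng = np.random.default_rng(1)
        z = (rng.random((4000, 6)) < 0.5).astype(float)
        z = rbm.gibbs_block_update(z, rng)
        assert np.allclose(z.mean(axis=0), 0.5, atol=0.03)

    def test_strong_positive_bias_switches_unit_off(self):
        rbm = RBM(2, 2, np.random.default_rng(0), init_scale=0.0)
        rbm.h.data[0] = 20.0   # high energy when on -> never on
        rng = np.random.default_rng(2)
        z = (rng.random((2000, 4)) < 0.5).astype(float)
        z = rbm.gibbs_block_update(z, rng)
        assert z[:, 0].mean() < 1e-3

    def test_detailed_balance_matrix_check(self):
        """The block-Gibbs kernel leaves the exact Boltzmann distribution
        invariant: pi @ T == pi, with T built by enumeration."""
        rbm = make_rbm(2, 2, seed=4)
        states, pi = exact_distribution(rbm)
        ha, hb = rbm.h.data[:2], rbm.h.data[2:]

        def sigmoid(x):
            return 1 / (1 + np.exp(-x))

        n = len(states)
        T = np.zeros((n, n))
        for i, z in enumerate(states):
            pa = sigmoid(-(ha + z[2:] @ rbm.W.data.T))
            for j, znew in enumerate(states):
                p_a = np.prod(np.where(znew[:2] == 1, pa, 1 - pa))
                pb = sigmoid(-(hb + znew[:2] @ rbm.W.data))
                p_b = np.prod(np.where(znew[2:] == 1, pb, 1 - pb))
                T[i, j] = p_a * p_b
        assert np.allclose(T.sum(axis=1), 1.0)
        assert np.allclose(pi @ T, pi, atol=1e-12)

    def test_empirical_distribution_matches_enumeration(self):
        rbm = make_rbm(2, 2, seed=5, scale=0.6)
        states, probs = exact_distribution(rbm)
        rng = np.random.default_rng(6)
        z = (rng.random((1, 4)) < 0.5).astype(float)
        for _ in range(200):
            z = rbm.gibbs_block_update(z, rng)
        counts = np.zeros(16)
        weights = 2 ** np.arange(4)
        for _ in range(20000):
            for _ in range(3):
                z = rbm.gibbs_block_update(z, rng)
            counts[int(z[0] @ weights)] += 1
        _, p = chisquare(counts, probs @ np.eye(16) * counts.sum()
                         if False else probs * counts.sum())
        assert p > 0.01


class TestPCD:
    def test_zero_steps_returns_chains_unchanged(self):
        rbm = make_rbm(2, 2, seed=7)
        state = PCDState.initialize(rbm, 8, np.random.default_rng(0))
        before = state.chains.copy()
        out = pcd_sample(state, rbm, k=0)
        assert np.array_equal(out, before)

    def test_two_half_advances_equal_one_full(self):
        rbm = make_rbm(2, 2, seed=8)
        s1 = PCDState.initialize(rbm, 8, np.random.default_rng(42))
        s2 = PCDState.initialize(rbm, 8, np.random.default_rng(42))
        pcd_sample(s1, rbm, k=15)
        a = pcd_sample(s1, rbm, k=15)
        b = pcd_sample(s2, rbm, k=30)
        assert np.array_equal(a, b)

    def test_long_run_marginals_match_enumeration(self):
        rbm = make_rbm(2, 2, seed=9, scale=0.5)
        states, probs = exact_distribution(rbm)
        exact_marg = states.T @ probs
        state = PCDState.initialize(rbm, 200, np.random.default_rng(1))
        acc = np.zeros(4)
        n_draws = 50
        for _ in range(n_draws):
            acc += pcd_sample(state, rbm, k=30).mean(axis=0)
        est = acc / n_draws
        se = np.sqrt(exact_marg * (1 - exact_marg) / (200 * n_draws)) * 3
        # chains are correlated over draws; triple the binomial allowance
        assert np.all(np.abs(est - exact_marg) < 3 * se + 0.01)


class TestAIS:
    def test_zero_parameters_exact_with_zero_variance(self):
        rbm = RBM(4, 4, np.random.default_rng(0), init_scale=0.0)
        res = ais_log_partition(rbm, np.random.default_rng(1))
        assert res.log_z == pytest.approx(8 * np.log(2))
        assert res.std_err == pytest.approx(0.0)
        assert np.allclose(res.log_weights, 0.0)

    def test_random_rbm_within_three_standard_errors(self):
        rbm = make_rbm(4, 4, seed=10)
        res = ais_log_partition(rbm, np.random.default_rng(2))
        assert abs(res.log_z - rbm.log_partition_exact()) <= 3 * res.std_err

    def test_more_samples_do_not_increase_standard_error(self):
        rbm = make_rbm(3, 3, seed=11)
        wins = 0
        for s in range(20):
            small = ais_log_partition(rbm, np.random.default_rng(s),
                                      n_samples=500)
            big = ais_log_partition(rbm, np.random.default_rng(1000 + s),
                                    n_samples=5000)
            wins += big.std_err <= small.std_err
        assert wins >= 15  # monotone in probability, not surely


class TestSpikeExponential:
    def test_pure_spike_at_q_zero(self, rng):
        zeta = spike_exp_sample(np.zeros(1000), 8.0, rng)
        assert np.all(zeta == 0.0)

    def test_exponential_branch_cdf_at_q_one(self, rng):
        beta = 8.0
        zeta = spike_exp_sample(np.ones(100_000), beta, rng)
        cdf = lambda x: np.expm1(beta * np.clip(x, 0, 1)) / np.expm1(beta)
        assert kstest(zeta, cdf).pvalue > 0.01

    @pytest.mark.parametrize("q", [0.25, 0.5, 0.9])
    def test_spike_mass_matches_one_minus_q(self, q, rng):
        n = 100_000
        zeta = spike_exp_sample(np.full(n, q), 8.0, rng)
        p0 = (zeta == 0).mean()
        se = np.sqrt(q * (1 - q) / n)
        assert abs(p0 - (1 - q)) < 3 * se

    def test_sharpness_limit_approaches_binary(self, rng):
        q = np.full(50_000, 0.7)
        zeta = spike_exp_sample(q, 200.0, rng)
        on = zeta > 0
        assert np.quantile(zeta[on], 0.001) > 0.95  # mass piles up at 1
        assert abs(on.mean() - 0.7) < 0.01

    def test_reparam_gradient_matches_finite_difference(self):
        q0 = np.array([[0.3, 0.7, 0.95]])
        rho = np.array([[0.9, 0.5, 0.2]])
        q = Tensor(q0, requires_grad=True)
        spike_exp_reparam(q, rho, 8.0).sum().backward()
        eps = 1e-7
        for i in range(3):
            qp, qm = q0.copy(), q0.copy()
            qp[0, i] += eps
            qm[0, i] -= eps
            num = (spike_exp_reparam(Tensor(qp), rho, 8.0).data.sum()
                   - spike_exp_reparam(Tensor(qm), rho, 8.0).data.sum()) / (2 * eps)
            assert q.grad[0, i] == pytest.approx(num, rel=1e-5, abs=1e-9)


class TestPosteriorHead:
    def test_zero_weights_give_half(self):
        head = PosteriorHead(8, 4, np.random.default_rng(0))
        head.proj.weight.data[:] = 0.0
        q = head(Tensor(np.random.default_rng(1).normal(size=(3, 8))))
        assert np.allclose(q.data, 0.5)

    def test_large_bias_saturates(self):
        head = PosteriorHead(8, 4, np.random.default_rng(0))
        head.proj.bias.data[0] = 20.0
        q = head(Tensor(np.random.default_rng(1).normal(size=(5, 8)) * 0.01))
        assert np.all(q.data[:, 0] > 0.999)

    def test_gain_preserves_initial_output(self):
        x = Tensor(np.random.default_rng(2).normal(size=(2, 8)))
        plain = PosteriorHead(8, 4, np.random.default_rng(3), gain=1.0)
        gained = PosteriorHead(8, 4, np.random.default_rng(3), gain=4.0)
        assert np.allclose(plain(x).data, gained(x).data)


class TestKLTerm:
    def test_factorized_posterior_equals_factorized_prior(self):
        rbm = RBM(2, 2, np.random.default_rng(0), init_scale=0.0)
        rbm.h.data = np.random.default_rng(1).normal(size=4)
        qv = 1 / (1 + np.exp(rbm.h.data))   # sigma(-h)
        q = Tensor(qv[None, :], requires_grad=True)
        # mean-field positive phase: E_q[E] is exact when W = 0
        klt = kl_term(q, Tensor(qv[None, :]), rbm,
                      np.zeros((1, 4)), log_z=rbm.log_partition_exact())
        assert klt.value == pytest.approx(0.0, abs=1e-9)

    def test_uniform_everything_gives_zero(self):
        rbm = RBM(2, 2, np.random.default_rng(0), init_scale=0.0)
        q = Tensor(np.full((1, 4), 0.5))
        klt = kl_term(q, Tensor(np.full((1, 4), 0.5)), rbm,
                      np.zeros((1, 4)), log_z=4 * np.log(2))
        assert klt.value == pytest.approx(0.0, abs=1e-9)

    def test_entropy_closed_form(self):
        q = Tensor(np.array([[0.5, 0.25]]))
        expected = (np.log(2)
                    + (-0.25 * np.log(0.25) - 0.75 * np.log(0.75)))
        assert bernoulli_entropy(q).data[0] == pytest.approx(expected)

    def test_rbm_gradient_matches_enumeration(self):
        """Sampled positive-minus-negative phase RBM gradient vs the exact
        expectation difference computed by enumeration."""
        rbm = make_rbm(2, 2, seed=12, scale=0.5)
        qv = np.array([0.8, 0.3, 0.6, 0.45])
        states, probs = exact_distribution(rbm)
        # exact gradients of E_q[E] - E_p[E] w.r.t. h and W
        marg_q = qv
        marg_p = states.T @ probs
        gh_exact = marg_q - marg_p
        gW_exact = (np.outer(qv[:2], qv[2:])
                    - np.einsum("s,si,sj->ij", probs, states[:, :2],
                                states[:, 2:]))
        rng = np.random.default_rng(13)
        n = 20000
        z_pos = (rng.random((n, 4)) < qv).astype(float)  # independent q
        z_neg = states[rng.choice(len(states), size=n, p=probs)]
        rbm.zero_grad()
        obj = (rbm.energy_t(Tensor(z_pos)).mean()
               - rbm.energy_t(Tensor(z_neg)).mean())
        obj.backward()
        se_h = np.sqrt(2.0 / n) * 3    # generous 3-sigma for +/- phases
        assert np.all(np.abs(rbm.h.grad - gh_exact) < se_h + 0.02)
        assert np.all(np.abs(rbm.W.grad - gW_exact) < se_h + 0.02)


class TestPriorSampleBackends:
    def test_unknown_backend_rejected(self):
        rbm = make_rbm(2, 2, seed=0)
        with pytest.raises(KeyError, match="unknown"):
            prior_sample(rbm, 5, np.random.default_rng(0), backend="dwave")

    def test_annealer_stub_returns_primed_samples(self):
        rbm = make_rbm(2, 2, seed=0)
        primed = (np.random.default_rng(1).random((7, 4)) < 0.5).astype(float)
        stub = AnnealerStub().prime(primed)
        out = stub(rbm, 5, np.random.default_rng(0))
        assert np.array_equal(out, primed[:5])

    def test_unprimed_stub_raises(self):
        rbm = make_rbm(2, 2, seed=0)
        with pytest.raises(RuntimeError, match="primed"):
            AnnealerStub()(rbm, 3, np.random.default_rng(0))

    def test_gibbs_backend_matches_enumeration(self):
        rbm = make_rbm(2, 2, seed=14, scale=0.5)
        states, probs = exact_distribution(rbm)
        samples = prior_sample(rbm, 4000, np.random.default_rng(3),
                               backend="gibbs", burn_in=200, thin=3)
        counts = np.zeros(16)
        weights = 2 ** np.arange(4)
        for z in samples:
            counts[int(z @ weights)] += 1
        _, p = chisquare(counts, probs * counts.sum())
        assert p > 0.01


class TestGaussianLatent:
    def test_standard_normal_has_zero_kl(self):
        mu = Tensor(np.zeros((1, 3)))
        logvar = Tensor(np.zeros((1, 3)))
        _, kl = gaussian_latent(mu, logvar, np.random.default_rng(0))
        assert kl.data[0] == pytest.approx(0.0)

    def test_unit_mean_shift_gives_half(self):
        mu = Tensor(np.ones((1, 1)))
        logvar = Tensor(np.zeros((1, 1)))
        _, kl = gaussian_latent(mu, logvar, np.random.default_rng(0))
        assert kl.data[0] == pytest.approx(0.5)

    def test_sample_moments(self):
        n = 100_000
        mu = Tensor(np.full((n, 1), 0.7))
        logvar = Tensor(np.full((n, 1), np.log(2.25)))
        zeta, _ = gaussian_latent(mu, logvar, np.random.default_rng(1))
        assert zeta.data.mean() == pytest.approx(0.7, abs=3 * 1.5 / np.sqrt(n))
        assert zeta.data.var() == pytest.approx(2.25, rel=0.05)
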