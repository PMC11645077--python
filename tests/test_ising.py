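"""Pairwise MEM: energies, Boltzmann probabilities, sampling, fitting.

The independent oracles are (a) a direct per-state summation of the energy
quadratic form and exp(-E)/Z, written with explicit loops, and (b) a
generic L-BFGS maximization of the explicit log-likelihood for the fit.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from statescape import (
    FitDiagnostics,
    MEMParameters,
    PairwiseMaxEnt,
    StateDistribution,
    boltzmann_distribution,
    decode_state,
    empirical_distribution,
    energy,
    energies,
    fit_diagnostics,
    fit_mem,
    fit_many,
    sample_ising,
)
from conftest import random_params


def brute_force_distribution(h, J):
    """Independent oracle: enumerate states with explicit loops."""
    n = len(h)
    es = []
    for k in range(2 ** n):
        sigma = 2 * decode_state(k, n).astype(float) - 1
        e = -sum(h[i] * sigma[i] for i in range(n))
        e -= 0.5 * sum(J[i][j] * sigma[i] * sigma[j]
                       for i in range(n) for j in range(n) if i != j)
        es.append(e)
    es = np.array(es)
    w = np.exp(-es)
    return es, w / w.sum()


def lbfgs_mle(dist: StateDistribution):
    """Independent oracle: generic numerical maximization of the likelihood."""
    n = dist.n_rois
    iu, ju = np.triu_indices(n, 1)

    def unpack(theta):
        h = theta[:n]
        J = np.zeros((n, n))
        J[iu, ju] = theta[n:]
        return h, J + J.T

    def negll(theta):
        h, J = unpack(theta)
        es, probs = brute_force_distribution(h, J)
        nz = dist.probs > 0
        return -float(dist.probs[nz] @ np.log(probs[nz]))

    res = minimize(negll, np.zeros(n + iu.size), method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000})
    return unpack(res.x)


class TestEnergy:
    def test_zero_parameters_zero_energy(self):
        p = MEMParameters(np.zeros(4), np.zeros((4, 4)))
        assert np.allclose(energies(p), 0.0)

    def test_two_roi_arithmetic(self):
        # state (+1, +1): E = -(1*1 + (-1)*1) - 0.5*(2*0.5*1*1) = -0.5
        J = np.array([[0.0, 0.5], [0.5, 0.0]])
        p = MEMParameters(np.array([1.0, -1.0]), J)
        assert energy(p, 3) == pytest.approx(-0.5)

    def test_global_flip_symmetry_without_fields(self, rng):
        p = random_params(4, rng)
        p = MEMParameters(np.zeros(4), p.J)
        e = energies(p)
        flipped = (1 << 4) - 1 - np.arange(1 << 4)
        assert np.allclose(e, e[flipped])

    def test_index_out_of_range(self, params3):
        with pytest.raises(ValueError):
            energy(params3, 8)

    def test_asymmetric_J_rejected(self):
        J = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            MEMParameters(np.zeros(2), J)


class TestBoltzmann:
    def test_uniform_at_zero_parameters(self):
        p = MEMParameters(np.zeros(8), np.zeros((8, 8)))
        probs = boltzmann_distribution(p).probs
        assert probs.size == 256
        assert np.allclose(probs, 1 / 256)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            p = random_params(3, rng)
            es, probs = brute_force_distribution(p.h, p.J)
            assert np.allclose(energies(p), es, atol=1e-12)
            assert np.allclose(boltzmann_distribution(p).probs, probs, atol=1e-12)

    def test_argmin_energy_is_argmax_probability(self, rng):
        p = random_params(5, rng)
        assert np.argmin(energies(p)) == np.argmax(boltzmann_distribution(p).probs)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    @settings(max_examples=25, deadline=None)
    def test_normalization_and_rank_inversion(self, seed, n):
        p = random_params(n, np.random.default_rng(seed))
        dist = boltzmann_distribution(p)
        assert abs(dist.probs.sum() - 1.0) < 1e-12
        # probability order is exactly the reverse of energy order
        assert np.array_equal(np.argsort(dist.probs), np.argsort(-energies(p)))

    def test_overflow_safety_at_large_couplings(self):
        J = np.zeros((6, 6))
        J[0, 1] = J[1, 0] = 400.0
        p = MEMParameters(np.full(6, 50.0), J)
        probs = boltzmann_distribution(p).probs
        assert np.isfinite(probs).all() and abs(probs.sum() - 1) < 1e-12


class TestSampler:
    def test_uniform_when_parameters_zero(self):
        p = MEMParameters(np.zeros(3), np.zeros((3, 3)))
        seq = sample_ising(p, 30000, seed=0)
        freq = np.bincount(seq.state_index, minlength=8) / 30000
        bound = 3 * np.sqrt(0.125 * 0.875 / 30000)
        assert np.abs(freq - 0.125).max() < bound

    def test_strong_coupling_concentrates_on_aligned_states(self):
        J = np.array([[0.0, 3.0], [3.0, 0.0]])
        p = MEMParameters(np.zeros(2), J)
        seq = sample_ising(p, 20000, seed=1)
        freq = np.bincount(seq.state_index, minlength=4) / 20000
        assert freq[0] + freq[3] > 0.99
        assert abs(freq[0] - freq[3]) < 0.03

    def test_exact_sampler_moments_match_enumeration(self, rng):
        h = np.array([0.5, -0.2, 0.1])
        p = random_params(3, rng)
        p = MEMParameters(h, p.J)
        n_samp = 50000
        seq = sample_ising(p, n_samp, seed=2, method="exact")
        _, probs = brute_force_distribution(p.h, p.J)
        S = np.stack([2 * decode_state(k, 3).astype(float) - 1 for k in range(8)])
        m_true = probs @ S
        c_true = S.T @ (probs[:, None] * S)
        spins = seq.spins.astype(float)
        m_emp = spins.mean(axis=0)
        c_emp = spins.T @ spins / n_samp
        se_m = np.sqrt((1 - m_true ** 2) / n_samp)
        assert np.all(np.abs(m_emp - m_true) < 3 * se_m + 1e-12)
        assert np.abs(c_emp - c_true).max() < 3 / np.sqrt(n_samp) + 1e-12

    def test_gibbs_agrees_with_exact_in_moments(self, params3):
        ex = sample_ising(params3, 20000, seed=3, method="exact").spins.astype(float)
        gb = sample_ising(params3, 20000, seed=4, method="gibbs").spins.astype(float)
        mc_err = 4 / np.sqrt(20000)
        assert np.abs(ex.mean(0) - gb.mean(0)).max() < mc_err
        assert np.abs(ex.T @ ex / 20000 - gb.T @ gb / 20000).max() < mc_err

    def test_invalid_requests_rejected(self, params3):
        with pytest.raises(ValueError):
            sample_ising(params3, 0)
        with pytest.raises(ValueError):
            sample_ising(params3, 10, method="quantum")


class TestFit:
    def test_uniform_distribution_gives_zero_parameters(self):
        dist = StateDistribution(np.full(8, 1 / 8))
        params, diag = fit_mem(dist)
        assert np.allclose(params.h, 0, atol=1e-9)
        assert np.allclose(params.J, 0, atol=1e-9)
        assert diag.converged

    def test_factorized_distribution_closed_form(self):
        """Independent spins with <sigma> = tanh(0.5) imply h = 0.5, J = 0."""
        p_up = (1 + np.tanh(0.5)) / 2
        probs = np.array([
            np.prod([p_up if decode_state(k, 3)[i] else 1 - p_up for i in range(3)])
            for k in range(8)
        ])
        params, diag = fit_mem(StateDistribution(probs / probs.sum()), tol=1e-10)
        assert np.allclose(params.h, 0.5, atol=1e-7)
        assert np.allclose(params.J, 0.0, atol=1e-7)

    def test_recovers_exact_boltzmann_input(self, rng):
        """Self-consistency at N=3, cross-checked against an L-BFGS oracle."""
        truth = random_params(3, rng)
        dist = boltzmann_distribution(truth)
        params, diag = fit_mem(dist, tol=1e-10)
        assert diag.converged
        assert np.abs(params.h - truth.h).max() < 1e-6
        assert np.abs(params.J - truth.J).max() < 1e-6
        h_o, J_o = lbfgs_mle(dist)
        assert np.abs(params.h - h_o).max() < 1e-4
        assert np.abs(params.J - J_o).max() < 1e-4

    def test_moment_matching_at_convergence(self, rng):
        seq = sample_ising(random_params(4, rng), 5000, seed=5)
        model = PairwiseMaxEnt(tol=1e-9).fit(seq)
        assert model.diagnostics_.max_moment_residual <= 1e-9

    def test_nonconvergence_is_flagged_not_silent(self, params3):
        dist = boltzmann_distribution(params3)
        params, diag = fit_mem(dist, max_iter=2)
        assert not diag.converged
        assert diag.n_iterations == 2

    def test_log_likelihood_nondecreasing_over_iterations(self, params3):
        """Zero-init determinism: longer runs are likelihood prefixes."""
        seq = sample_ising(params3, 2000, seed=6)
        dist = empirical_distribution(seq)
        lls = []
        for iters in (1, 3, 10, 30, 100, 300):
            params, _ = fit_mem(dist, max_iter=iters)
            lls.append(fit_diagnostics(params, dist).log_likelihood_per_sample)
        assert np.all(np.diff(lls) >= -1e-12)

    def test_batch_fit_matches_single_fits(self, rng):
        dists = [empirical_distribution(sample_ising(random_params(3, rng), 1000, seed=s))
                 for s in range(4)]
        batch = fit_many(dists, tol=1e-9)
        for d, b in zip(dists, batch):
            single, _ = fit_mem(d, tol=1e-9)
            assert np.abs(single.h - b.h).max() < 1e-7
            assert np.abs(single.J - b.J).max() < 1e-7


class TestDiagnostics:
    def test_fitted_model_has_tiny_kl(self, params3):
        dist = boltzmann_distribution(params3)
        params, _ = fit_mem(dist, tol=1e-10)
        assert fit_diagnostics(params, dist).kl_empirical_vs_model < 1e-12

    def test_uniform_closed_form(self):
        n = 4
        p = MEMParameters(np.zeros(n), np.zeros((n, n)))
        diag = fit_diagnostics(p, StateDistribution(np.full(1 << n, 2.0 ** -n)))
        assert diag.kl_empirical_vs_model == pytest.approx(0.0, abs=1e-14)
        assert diag.log_likelihood_per_sample == pytest.approx(-n * np.log(2))

    def test_perturbation_increases_kl(self, rng):
        """The fitted parameters are the KL optimum among tested neighbours."""
        truth = random_params(3, rng)
        dist = boltzmann_distribution(truth)
        fitted, _ = fit_mem(dist, tol=1e-10)
        base_kl = fit_diagnostics(fitted, dist).kl_empirical_vs_model
        for _ in range(5):
            pert = MEMParameters(
                fitted.h + rng.normal(0, 0.05, 3),
                fitted.J + (lambda u: u + u.T)(np.triu(rng.normal(0, 0.05, (3, 3)), 1)),
            )
            assert fit_diagnostics(pert, dist).kl_empirical_vs_model > base_kl


class TestEstimatorInterface:
    def test_sklearn_params_and_fitted_attrs(self, rng):
        model = PairwiseMaxEnt(learning_rate=0.2, tol=1e-7)
        assert model.get_params()["learning_rate"] == 0.2
        model.set_params(learning_rate=0.1)
        seq = sample_ising(random_params(3, rng), 1000, seed=7)
        model.fit(seq)
        assert model.h_.shape == (3,)
        assert model.J_.shape == (3, 3)
        assert model.energies_.size == 8
        assert model.converged_

    def test_score_is_mean_log_likelihood(self, rng):
        seq = sample_ising(random_params(3, rng), 2000, seed=8)
        model = PairwiseMaxEnt().fit(seq)
        logp = np.log(model.state_probabilities().probs)
        expected = logp[seq.state_index].mean()
        assert model.score(seq) == pytest.approx(expected)

    def test_accepts_binary_01_matrix(self, rng):
        X01 = rng.integers(0, 2, size=(500, 3))
        m1 = PairwiseMaxEnt().fit(X01)
        m2 = PairwiseMaxEnt().fit(2 * X01 - 1)
        assert np.allclose(m1.h_, m2.h_)
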