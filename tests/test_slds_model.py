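import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainstates import (decode, emission_mean, log_joint,
                         one_step_latent_mean, transition_probabilities)
from brainstates.slds_model import SldsParameters, kalman_smooth, viterbi

from conftest import random_params


class TestTransitionProbabilities:
    def test_zero_recurrence_reduces_to_markov_row(self, rng):
        p = random_params(rng, K=3)
        out = transition_probabilities(p.Q, np.zeros((3, 2)),
                                       rng.normal(size=2), 1)
        np.testing.assert_allclose(out, p.Q[1], atol=1e-12)

    def test_zero_latent_reduces_to_markov_row(self, rng):
        p = random_params(rng, K=3)
        out = transition_probabilities(p.Q, rng.normal(size=(3, 2)),
                                       np.zeros(2), 2)
        np.testing.assert_allclose(out, p.Q[2], atol=1e-12)

    def test_hand_evaluated_softmax(self):
        Q = np.full((2, 2), 0.5)
        r = np.array([[1.0, 0.0], [0.0, 0.0]])
        x = np.array([np.log(3.0), 0.0])
        out = transition_probabilities(Q, r, x, 0)
        np.testing.assert_allclose(out, [0.75, 0.25], atol=1e-12)

    def test_structural_zero_stays_zero(self):
        Q = np.array([[0.0, 1.0], [0.5, 0.5]])
        out = transition_probabilities(Q, np.ones((2, 2)), np.ones(2), 0)
        assert out[0] == 0.0 and out[1] == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_always_a_simplex(self, seed):
        rng = np.random.default_rng(seed)
        K, D = int(rng.integers(2, 5)), int(rng.integers(1, 4))
        Q = rng.dirichlet(np.ones(K), size=K)
        r = rng.normal(0, 2, size=(K, D))
        out = transition_probabilities(Q, r, rng.normal(0, 3, size=D),
                                       int(rng.integers(K)))
        assert np.all(out >= 0)
        assert abs(out.sum() - 1.0) < 1e-12


class TestOneStepEquations:
    def test_identity_dynamics_returns_previous(self, rng):
        p = random_params(rng)
        p.A[0] = np.eye(2)
        p.V[0] = 0.0
        p.b[0] = 0.0
        x = rng.normal(size=2)
        np.testing.assert_allclose(
            one_step_latent_mean(p, 0, x, np.zeros(4)), x, atol=1e-15)

    def test_bias_only(self, rng):
        p = random_params(rng)
        np.testing.assert_allclose(
            one_step_latent_mean(p, 1, np.zeros(2), np.zeros(4)), p.b[1])

    def test_matches_matrix_product_oracle(self, rng):
        p = random_params(rng)
        x, u = rng.normal(size=2), rng.normal(size=4)
        exp = p.A[1] @ x + p.V[1] @ u + p.b[1]
        np.testing.assert_allclose(one_step_latent_mean(p, 1, x, u), exp,
                                   atol=1e-12)
        np.testing.assert_allclose(emission_mean(p, x), p.C @ x + p.d,
                                   atol=1e-12)

    def test_emission_at_origin_is_bias(self, rng):
        p = random_params(rng)
        np.testing.assert_allclose(emission_mean(p, np.zeros(2)), p.d)

    def test_dimension_mismatch_errors(self, rng):
        p = random_params(rng)
        with pytest.raises(ValueError):
            one_step_latent_mean(p, 0, np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError):
            emission_mean(p, np.zeros(5))


def _scalar_params():
    """D = 1, N = 2 scalar-dynamics model with unit variances."""
    return SldsParameters(
        C=np.array([[1.0], [0.0]]), d=np.zeros(2), Sigma_v=np.eye(2),
        A=np.array([[[0.5]]]), V=np.zeros((1, 1, 1)), b=np.array([[0.2]]),
        Sigma_h=np.array([[[1.0]]]), Q=np.array([[1.0]]),
        r=np.zeros((1, 1)))


class TestLogJoint:
    def test_matches_hand_computed_gaussians(self):
        p = _scalar_params()
        X = np.array([[0.3], [0.6]])
        Y = np.array([[0.1, 0.0], [0.7, 0.0]])
        U = np.zeros((2, 1))
        Z = np.array([0, 0])
        got = log_joint(p, X, Z, Y, U)
        logN = lambda x, m, v: -0.5 * (np.log(2 * np.pi * v) + (x - m) ** 2 / v)
        exp = (logN(0.1, 0.3, 1) + logN(0.0, 0.0, 1)      # emission t=0
               + logN(0.7, 0.6, 1) + logN(0.0, 0.0, 1)    # emission t=1
               + logN(0.6, 0.5 * 0.3 + 0.2, 1))           # dynamics t=1
        # switching term is log 1 = 0 for K = 1
        np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_translation_invariance(self, rng):
        p = random_params(rng)
        T = 10
        X = rng.normal(size=(T, 2))
        Y = rng.normal(size=(T, 6))
        U = np.zeros((T, 4))
        U[:, 0] = 1
        Z = rng.integers(0, 2, size=T)
        base = log_joint(p, X, Z, Y, U)
        shift = rng.normal(size=6)
        p2 = random_params(rng)
        for name in ("C", "Sigma_v", "A", "V", "b", "Sigma_h", "Q", "r"):
            setattr(p2, name, getattr(p, name))
        p2.d = p.d + shift
        np.testing.assert_allclose(log_joint(p2, X, Z, Y + shift, U), base,
                                   rtol=1e-10)

    def test_switching_term_maximized_by_most_probable_label(self, rng):
        p = random_params(rng, K=3)
        T = 6
        X = rng.normal(size=(T, 2))
        Y = X @ p.C.T + p.d
        U = np.zeros((T, 4))
        U[:, 0] = 1
        Z = rng.integers(0, 3, size=T)
        probs = transition_probabilities(p.Q, p.r, X[2], Z[2])
        best = int(np.argmax(probs))
        scores = {}
        for j in range(3):
            Zj = Z.copy()
            Zj[3] = j
            # isolate the switching contribution by zeroing dynamics variation
            scores[j] = log_joint(p, X, Zj, Y, U)
        # moving to a lower-transition-probability label cannot beat the
        # dynamics-plus-switching optimum by the switching term alone; check
        # the switching ordering directly on equal-dynamics instances
        pbest = probs[best]
        for j in range(3):
            if probs[j] < pbest:
                ll_best = np.log(pbest)
                assert np.log(probs[j]) <= ll_best

    def test_singular_covariance_named(self, rng):
        p = random_params(rng)
        p.Sigma_v = np.zeros((6, 6))
        X = rng.normal(size=(3, 2))
        with pytest.raises(np.linalg.LinAlgError, match="Sigma_v"):
            log_joint(p, X, np.zeros(3, int), rng.normal(size=(3, 6)),
                      np.zeros((3, 4)))


def _dense_gaussian_smoother(p, Y, U):
    """Independent K=1 smoother: solve the full joint Gaussian system.

    Stacks all latents into one vector and maximises the joint log
    density by solving the (block tridiagonal) normal equations densely.
    """
    T, D = Y.shape[0], p.D
    A, b, V = p.A[0], p.b[0], p.V[0]
    Sh_inv = np.linalg.inv(p.Sigma_h[0])
    Sv_inv = np.linalg.inv(p.Sigma_v)
    H = np.zeros((T * D, T * D))
    g = np.zeros(T * D)
    CtSi = p.C.T @ Sv_inv
    for t in range(T):
        sl = slice(t * D, (t + 1) * D)
        H[sl, sl] += CtSi @ p.C
        g[sl] += CtSi @ (Y[t] - p.d)
        if t == 0:
            H[sl, sl] += np.eye(D) / 1e4        # diffuse prior on X_0
    for t in range(1, T):
        sl, slp = slice(t * D, (t + 1) * D), slice((t - 1) * D, t * D)
        c = V @ U[t] + b
        H[sl, sl] += Sh_inv
        H[slp, slp] += A.T @ Sh_inv @ A
        H[sl, slp] -= Sh_inv @ A
        H[slp, sl] -= A.T @ Sh_inv
        g[sl] += Sh_inv @ c
        g[slp] -= A.T @ Sh_inv @ c
    return np.linalg.solve(H, g).reshape(T, D)


class TestDecode:
    def test_single_state_matches_dense_gaussian_oracle(self, rng):
        p = random_params(rng, K=1, D=2, N=6, M=3)
        T = 40
        U = np.zeros((T, 3))
        U[:, 0] = 1
        Y = rng.normal(size=(T, 6))
        res = decode(p, Y, U)
        assert np.all(res.Z == 0)
        X_oracle = _dense_gaussian_smoother(p, Y, U)
        np.testing.assert_allclose(res.X, X_oracle, atol=1e-6)

    def test_decode_is_idempotent_on_reconstruction(self, quiet_study):
        p = quiet_study.true_params
        Y, U = quiet_study.y_list()[0], quiet_study.u_list()[0]
        res = decode(p, Y, U)
        recon = res.X @ p.C.T + p.d
        res2 = decode(p, recon, U)
        assert np.array_equal(res.Z, res2.Z)

    def test_planted_logjoint_beats_permuted_labels(self, quiet_study):
        p = quiet_study.true_params
        rng = np.random.default_rng(0)
        X = quiet_study.x_list()[0]
        Z = quiet_study.z_list()[0]
        Y, U = quiet_study.y_list()[0], quiet_study.u_list()[0]
        base = log_joint(p, X, Z, Y, U)
        for _ in range(5):
            assert base >= log_joint(p, X, rng.permutation(Z), Y, U)

    def test_moderate_noise_accuracy(self, small_study):
        p = small_study.true_params
        correct = total = 0
        for Y, U, Z in zip(small_study.y_list(), small_study.u_list(),
                           small_study.z_list()):
            res = decode(p, Y, U)
            correct += int((res.Z == Z).sum())
            total += Z.size
        assert correct / total >= 0.85
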