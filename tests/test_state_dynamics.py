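import numpy as np
import pytest

from brainstates import (attractor_map, average_trajectory, fixed_point,
                         spectral_radius, stability_test, state_geometry,
                         vector_field_2d)

from conftest import random_params


def _random_stable(rng, D=2, rho=None):
    rho = rho or rng.uniform(0.3, 0.95)
    Q, R = np.linalg.qr(rng.normal(size=(D, D)))
    return rho * Q * np.sign(np.diag(R))


class TestFixedPoint:
    def test_scalar_contraction(self):
        np.testing.assert_allclose(
            fixed_point(0.5 * np.eye(2), np.array([1.0, 1.0])), [2.0, 2.0])

    def test_zero_bias_zero_fixed_point(self, rng):
        A = _random_stable(rng)
        np.testing.assert_allclose(fixed_point(A, np.zeros(2)), 0.0,
                                   atol=1e-14)

    def test_iteration_oracle(self, rng):
        for _ in range(10):
            A = _random_stable(rng, D=3)
            b = rng.normal(size=3)
            xbar = fixed_point(A, b)
            x = rng.normal(0, 5, size=3)
            for _ in range(10_000):
                x = A @ x + b
            np.testing.assert_allclose(x, xbar, atol=1e-8)
            assert np.linalg.norm(xbar - (A @ xbar + b)) < 1e-8

    def test_marginally_stable_rejected(self):
        with pytest.raises(np.linalg.LinAlgError, match="marginal"):
            fixed_point(np.eye(2), np.ones(2))

    def test_radius_below_one_iff_convergent(self, rng):
        for rho in (0.8, 1.15):
            A = _random_stable(rng, D=2, rho=rho)
            b = rng.normal(size=2)
            converged = True
            for _ in range(10):
                x = rng.normal(0, 3, size=2)
                for _ in range(3000):
                    x = A @ x + b
                    if np.abs(x).max() > 1e6:
                        break
                if np.abs(x).max() > 1e6:
                    converged = False
                    break
            assert converged == (spectral_radius(A) < 1)


class TestStabilityTest:
    def test_expanding_matrices_unstable(self):
        stacks = np.tile(1.1 * np.eye(2), (30, 1, 1, 1))
        out = stability_test(stacks, K=1)
        assert out[0]["p"] == 1.0 and not out[0]["stable"]

    def test_contracting_rotations_stable(self, rng):
        th = 0.3
        R = 0.99 * np.array([[np.cos(th), -np.sin(th)],
                             [np.sin(th), np.cos(th)]])
        stacks = np.tile(R, (30, 1, 1, 1))
        out = stability_test(stacks, K=1)
        assert out[0]["p"] == 0.0 and out[0]["stable"]

    def test_p_equals_exceedance_fraction(self):
        B = 500
        stacks = np.tile(0.5 * np.eye(2), (B, 1, 1, 1))
        stacks[:10, 0] = 1.2 * np.eye(2)
        out = stability_test(stacks, K=1)
        assert out[0]["p"] == 10 / 500


class TestAttractorMap:
    def _identity_padded_params(self, rng, xbar):
        p = random_params(rng, K=1, D=2, N=6, M=2)
        p.C = np.zeros((6, 2))
        p.C[0, 0] = p.C[1, 1] = 1.0
        p.d = np.zeros(6)
        p.A[0] = 0.5 * np.eye(2)
        p.b[0] = 0.5 * np.asarray(xbar)
        return p

    def test_identity_padded_emission_copies_fixed_point(self, rng):
        p = self._identity_padded_params(rng, [2.0, 2.0])
        res = attractor_map([p] * 25, k=0)
        np.testing.assert_allclose(res.roi_projection[:2], [2.0, 2.0])
        np.testing.assert_allclose(res.roi_projection[2:], 0.0, atol=1e-12)

    def test_bias_only_model_maps_to_bias(self, rng):
        p = random_params(rng, K=1, D=2, N=6, M=2)
        p.A[0] = np.zeros((2, 2))
        p.b[0] = np.zeros(2)
        samples = []
        for _ in range(30):
            q = random_params(rng, K=1, D=2, N=6, M=2)
            q.C, q.A, q.b = p.C, p.A.copy(), p.b.copy()
            q.d = p.d + rng.normal(0, 1e-6, size=6)
            samples.append(q)
        res = attractor_map(samples, k=0)
        np.testing.assert_allclose(res.roi_projection, p.d, atol=1e-5)
        assert res.roi_mask[np.abs(p.d) > 0.1].all()


class TestStateGeometry:
    def test_hand_example(self):
        X = [np.array([[0.0, 0.0], [2.0, 2.0], [9.0, 9.0]])]
        Z = [np.array([0, 0, 1])]
        g = state_geometry(X, Z, 0)
        np.testing.assert_allclose(g.centroid, [1.0, 1.0])
        assert g.mean_lifetime == 2.0 and g.occupancy == 2

    def test_alternating_states_lifetime_one(self):
        Z = [np.array([0, 1] * 10)]
        X = [np.zeros((20, 2))]
        assert state_geometry(X, Z, 0).mean_lifetime == 1.0

    def test_matches_run_length_encoding_oracle(self, rng):
        Z = [rng.integers(0, 3, 200), rng.integers(0, 3, 150)]
        X = [rng.normal(size=(200, 2)), rng.normal(size=(150, 2))]
        g = state_geometry(X, Z, 1)
        # oracle via itertools.groupby
        from itertools import groupby
        lengths = [len(list(grp)) for z in Z
                   for lab, grp in groupby(z) if lab == 1]
        pts = np.concatenate([x[z == 1] for x, z in zip(X, Z)])
        np.testing.assert_allclose(g.centroid, pts.mean(axis=0))
        assert g.mean_lifetime == pytest.approx(np.mean(lengths))

    def test_never_occupied_state_rejected(self):
        with pytest.raises(ValueError):
            state_geometry([np.zeros((5, 2))], [np.zeros(5, int)], 2)


class TestAverageTrajectory:
    def test_single_window_is_the_window(self, rng):
        X = [rng.normal(size=(12, 2))]
        Z = [np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])]
        path, modal, split = average_trajectory(X, Z, k=1, horizon=10)
        np.testing.assert_allclose(path, X[0][:10])
        assert split == 1

    def test_all_windows_stay_in_state(self):
        X = [np.zeros((15, 2))]
        Z = [np.full(15, 2)]
        _, modal, split = average_trajectory(X, Z, k=2, horizon=10)
        assert split == 10 and np.all(modal == 2)

    def test_majority_switch_index(self):
        # three windows: two switch to state 1 at step 6, one stays
        Z = []
        X = []
        for stays in (False, False, True):
            z = np.zeros(10, int)
            if not stays:
                z[6:] = 1
            Z.append(z)
            X.append(np.zeros((10, 2)))
        path, modal, split = average_trajectory(X, Z, k=0, horizon=10)
        assert split == 6
        assert modal[:6].tolist() == [0] * 6 and modal[6:].tolist() == [1] * 4

    def test_no_windows_rejected(self):
        with pytest.raises(ValueError):
            average_trajectory([np.zeros((5, 2))], [np.zeros(5, int)], k=1,
                               horizon=10)


class TestVectorField:
    def test_zero_vector_at_fixed_point(self, rng):
        A = _random_stable(rng, D=2)
        b = rng.normal(size=2)
        path = rng.normal(size=(10, 2))
        field = vector_field_2d(A, b, path)
        # lift the attractor's in-plane coordinates and advance
        g = field["attractor_2d"]
        lifted = field["center"] + field["basis"] @ g
        adv = A @ lifted + b
        vec = field["basis"].T @ (adv - field["center"]) - g
        np.testing.assert_allclose(vec, 0.0, atol=1e-10)

    def test_pure_contraction_points_at_attractor(self, rng):
        A = 0.5 * np.eye(2)
        b = np.array([1.0, -0.5])
        path = rng.normal(size=(10, 2))
        field = vector_field_2d(A, b, path)
        attr = field["attractor_2d"]
        for g, v in zip(field["grid"], field["vectors"]):
            np.testing.assert_allclose(v, 0.5 * (attr - g), atol=1e-10)

    def test_matches_lift_advance_project_oracle(self, rng):
        A = _random_stable(rng, D=4)
        b = rng.normal(size=4)
        path = rng.normal(size=(10, 4))
        field = vector_field_2d(A, b, path)
        basis, center = field["basis"], field["center"]
        for g, v in zip(field["grid"][:20], field["vectors"][:20]):
            lifted = center + basis @ g
            adv = A @ lifted + b
            exp = basis.T @ (adv - center) - g
            np.testing.assert_allclose(v, exp, atol=1e-10)

    def test_degenerate_path_rejected(self):
        path = np.outer(np.arange(10.0), [1.0, 0.0])   # rank-1 path
        with pytest.raises(ValueError, match="rank"):
            vector_field_2d(0.5 * np.eye(2), np.zeros(2), path)
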