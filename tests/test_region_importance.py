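import numpy as np
import pytest

from brainstates import (importance, importance_activity_correlation,
                         normalize_importance, project_dynamics,
                         state_locked_importance)
from brainstates.region_importance import DataSpaceDynamics, ImportanceSeries

from conftest import random_params


def _onehot(cats, M):
    U = np.zeros((len(cats), M))
    U[np.arange(len(cats)), cats] = 1
    return U


class TestProjectDynamics:
    def test_square_invertible_emission_is_similarity_transform(self, rng):
        p = random_params(rng, K=1, D=2, N=6, M=2)
        # square C embedded: use D=2, N=3 for an easy full-rank case
        p = random_params(rng, K=1, D=2, N=3, M=2)
        p.d = np.zeros(3)
        dsd = project_dynamics(p)
        Ahat_direct = p.C @ p.A[0] @ np.linalg.pinv(p.C)
        np.testing.assert_allclose(dsd.A_hat[0], Ahat_direct, atol=1e-12)

    def test_in_subspace_prediction_matches_latent_one_step(self, rng):
        p = random_params(rng, K=2, D=3, N=8, M=4)
        dsd = project_dynamics(p)
        for _ in range(100):
            x = rng.normal(size=3)
            u = np.zeros(4)
            u[rng.integers(4)] = 1
            y_prev = p.C @ x + p.d
            for k in range(2):
                lat = p.A[k] @ x + p.V[k] @ u + p.b[k]
                y_lat = p.C @ lat + p.d
                y_data = dsd.A_hat[k] @ y_prev + dsd.V_hat[k] @ u + dsd.b_hat[k]
                np.testing.assert_allclose(y_data, y_lat, atol=1e-8)

    def test_identity_dynamics_bias_structure(self, rng):
        p = random_params(rng, K=1, D=2, N=5, M=2)
        p.A[0] = np.eye(2)
        p.V[0] = 0.0
        p.b[0] = 0.0
        dsd = project_dynamics(p)
        P = p.C @ np.linalg.pinv(p.C)
        np.testing.assert_allclose(dsd.b_hat[0], (np.eye(5) - P) @ p.d,
                                   atol=1e-10)

    def test_rank_deficient_emission_rejected(self, rng):
        p = random_params(rng, K=1, D=2, N=5, M=2)
        p.C[:, 1] = p.C[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            project_dynamics(p)


class TestImportance:
    def test_hand_example(self):
        A_hat = np.array([[[0.5, 0.2], [0.1, 0.4]]])
        dsd = DataSpaceDynamics(A_hat=A_hat, V_hat=np.zeros((1, 2, 1)),
                                b_hat=np.zeros((1, 2)),
                                C_pinv=np.zeros((1, 2)))
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        Z = np.zeros(2, int)
        U = np.zeros((2, 1))
        q = importance(Y, Z, U, dsd).q
        assert q[1, 0] == pytest.approx(np.sqrt(0.26))
        assert q[1, 1] == pytest.approx(0.0)

    def test_matches_brute_force_lesion_oracle(self, rng):
        p = random_params(rng, K=3, D=3, N=7, M=4)
        dsd = project_dynamics(p)
        T = 40
        Y = rng.normal(size=(T, 7))
        Z = rng.integers(0, 3, T)
        U = _onehot(rng.integers(0, 4, T), 4)
        q = importance(Y, Z, U, dsd).q
        for t in range(1, T):
            k = Z[t]
            intact = dsd.A_hat[k] @ Y[t - 1] + dsd.V_hat[k] @ U[t] + dsd.b_hat[k]
            for i in range(7):
                A_l = dsd.A_hat[k].copy()
                A_l[:, i] = 0
                V_l = dsd.V_hat[k].copy()
                V_l[i, :] = 0
                b_l = dsd.b_hat[k].copy()
                b_l[i] = 0
                lesioned = A_l @ Y[t - 1] + V_l @ U[t] + b_l
                assert abs(q[t, i] - np.linalg.norm(intact - lesioned)) < 1e-10

    def test_silent_region_scores_zero(self, rng):
        p = random_params(rng, K=1, D=2, N=5, M=2)
        dsd = project_dynamics(p)
        dsd.A_hat[0][:, 2] = 0.0
        dsd.V_hat[0][2, :] = 0.0
        dsd.b_hat[0][2] = 0.0
        Y = rng.normal(size=(10, 5))
        Y[:, 2] = 0.0
        q = importance(Y, np.zeros(10, int), np.zeros((10, 2)), dsd).q
        np.testing.assert_allclose(q[1:, 2], 0.0, atol=1e-14)

    def test_region_permutation_permutes_scores(self, rng):
        p = random_params(rng, K=1, D=2, N=5, M=2)
        dsd = project_dynamics(p)
        T = 20
        Y = rng.normal(size=(T, 5))
        Z = np.zeros(T, int)
        U = _onehot(rng.integers(0, 2, T), 2)
        q = importance(Y, Z, U, dsd).q
        perm = rng.permutation(5)
        dsd_p = DataSpaceDynamics(
            A_hat=dsd.A_hat[:, perm][:, :, perm],
            V_hat=dsd.V_hat[:, perm], b_hat=dsd.b_hat[:, perm],
            C_pinv=dsd.C_pinv[:, perm])
        q_p = importance(Y[:, perm], Z, U, dsd_p).q
        np.testing.assert_allclose(q_p[1:], q[1:][:, perm], atol=1e-12)

    def test_triangle_inequality_bound(self, rng):
        p = random_params(rng, K=1, D=2, N=5, M=3)
        dsd = project_dynamics(p)
        T = 30
        Y = rng.normal(size=(T, 5))
        Z = np.zeros(T, int)
        U = _onehot(rng.integers(0, 3, T), 3)
        q = importance(Y, Z, U, dsd).q
        colnorm = np.linalg.norm(dsd.A_hat[0], axis=0)
        for t in range(1, T):
            s = dsd.V_hat[0] @ U[t] + dsd.b_hat[0]
            bound = np.abs(Y[t - 1]) * colnorm + np.abs(s)
            assert np.all(q[t] <= bound + 1e-10)


class TestNormalization:
    def _series(self, q):
        return ImportanceSeries(q=q, roi_names=[f"r{i}" for i in
                                                range(q.shape[1])],
                                Z=np.zeros(q.shape[0], int))

    def test_constant_column_flagged_zero(self, rng):
        q = rng.uniform(1, 2, size=(20, 3))
        q[:, 1] = 5.0
        out = normalize_importance(self._series(q))
        assert out.zero_variance[1]
        np.testing.assert_allclose(out.q[:, 1], 0.0)

    def test_mean_zero_unit_variance(self, rng):
        q = rng.uniform(0, 3, size=(50, 4))
        out = normalize_importance(self._series(q))
        np.testing.assert_allclose(out.q.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.q.std(axis=0), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        q = rng.uniform(0, 3, size=(30, 3))
        a, c = 2.5, 7.0
        out1 = normalize_importance(self._series(q))
        out2 = normalize_importance(self._series(a * q + c))
        np.testing.assert_allclose(out1.q, out2.q, atol=1e-10)


class TestStateLocked:
    def _series(self, q, Z):
        return ImportanceSeries(q=q, Z=np.asarray(Z, dtype=int))

    def test_single_entry_equals_slice(self, rng):
        q = rng.normal(size=(12, 3))
        Z = np.zeros(12, int)
        Z[4:9] = 1
        locked, counts = state_locked_importance(
            [self._series(q, Z)], k=1)
        L = locked.shape[0]
        np.testing.assert_allclose(locked, q[4:4 + L])

    def test_matches_gather_oracle(self, rng):
        runs = []
        for _ in range(4):
            q = rng.normal(size=(60, 2))
            Z = rng.integers(0, 2, 60)
            runs.append(self._series(q, Z))
        locked, counts = state_locked_importance(runs, k=1)
        # oracle: explicit per-onset gather
        from itertools import groupby
        lengths = []
        for s in runs:
            lengths += [len(list(g)) for lab, g in groupby(s.Z) if lab == 1]
        steps = max(int(round(np.mean(lengths))), 1)
        acc = np.zeros((steps, 2))
        cnt = np.zeros(steps)
        for s in runs:
            Z = s.Z
            for t0 in range(60):
                if Z[t0] == 1 and (t0 == 0 or Z[t0 - 1] != 1):
                    for w in range(steps):
                        t = t0 + w
                        if t >= 60 or Z[t] != 1:
                            break
                        if np.all(np.isfinite(s.q[t])):
                            acc[w] += s.q[t]
                            cnt[w] += 1
        np.testing.assert_allclose(locked, acc / cnt[:, None])

    def test_never_entered_state_rejected(self, rng):
        s = self._series(rng.normal(size=(10, 2)), np.zeros(10, int))
        with pytest.raises(ValueError):
            state_locked_importance([s], k=3)


class TestCorrelation:
    def test_monotone_transform_gives_one(self, rng):
        bold = rng.normal(size=(1, 8))
        imp = np.exp(bold)       # strictly monotone
        rho = importance_activity_correlation(imp, bold)
        assert rho[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        bold = np.arange(8.0)[None, :]
        imp = bold[:, ::-1]
        rho = importance_activity_correlation(imp, bold)
        assert rho[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata
        imp = rng.normal(size=(5, 10))
        bold = rng.normal(size=(5, 10))
        rho = importance_activity_correlation(imp, bold)
        for s in range(5):
            ra, rb = rankdata(imp[s]), rankdata(bold[s])
            exp = np.corrcoef(ra, rb)[0, 1]
            assert rho[s] == pytest.approx(exp, abs=1e-12)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            importance_activity_correlation(np.zeros((2, 2)),
                                            np.zeros((2, 2)))
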