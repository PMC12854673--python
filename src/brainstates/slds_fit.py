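"""Group-level estimation of recurrent SLDS parameters.

Fitting alternates a hard E-step over the discrete states with exact
M-steps over the continuous parameters: given the current labels Z, the
RTS smoother yields the Gaussian posterior over the latents (means,
marginal covariances, lag-one cross-covariances); the M-steps for the
per-state dynamics {A_k, V_k, b_k, Sigma_h_k} and the shared emission
{C, d, Sigma_v} are closed-form weighted least squares on those
posterior moments — using the full second moments rather than the
smoothed means alone removes the errors-in-variables attenuation that
would otherwise bias the dynamics toward zero.  Q is re-estimated from
label bigrams (add-one smoothed) and the recurrence weights r by
quasi-Newton ascent on the switching log-likelihood.  Labels are then
refreshed by Viterbi.  Multi-run data are handled without any temporal
coupling across run boundaries.

The objective in ``FitResult.objective_trace`` is the complete-data log
joint of the hard assignments (latents at their posterior means) summed
over runs — a deterministic surrogate for the marginal likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .slds_model import SldsParameters, kalman_smooth, log_joint, viterbi

__all__ = ["FitConfig", "FitResult", "initialize", "fit", "fit_group"]

_COV_FLOOR = 1e-6


@dataclass
class FitConfig:
    max_iter: int = 50
    tol: float = 1e-6           # relative objective change declaring convergence
    n_restarts: int = 3
    seed: int = 0
    fit_recurrence: bool = True
    full_emission_cov: bool = False


@dataclass
class FitResult:
    params: SldsParameters
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    n_restarts_used: int = 1
    seed: int = 0


# ---------------------------------------------------------------------------
# sufficient statistics and closed-form M-steps
# ---------------------------------------------------------------------------

def _dynamics_mstep(X_list, U_list, Z_list, P_list, L_list, K, D, M):
    """Per-state regression of X_t on [X_{t-1}, U_t, 1] using posterior
    moments.  P_list/L_list may be None (means treated as exact).

    One-hot input rows sum to 1, making the intercept collinear with the
    input columns: only ``V u + b`` is identified.  The gauge is fixed by
    shifting each V row's category mean into b (matching the convention
    of the synthetic generator), so attractors ``(I - A)^{-1} b`` are
    well-defined.
    """
    onehot = all(np.allclose(U.sum(axis=1), 1.0) for U in U_list)
    dim = D + M + 1
    G_k = np.zeros((K, dim, dim))
    B_k = np.zeros((K, D, dim))
    Stt_k = np.zeros((K, D, D))
    n_k = np.zeros(K)
    for ridx, (X, U, Z) in enumerate(zip(X_list, U_list, Z_list)):
        P = P_list[ridx] if P_list is not None else None
        L = L_list[ridx] if L_list is not None else None
        for k in range(K):
            idx = np.nonzero(Z[1:] == k)[0] + 1
            if idx.size == 0:
                continue
            mu_t, mu_p, u = X[idx], X[idx - 1], U[idx]
            S_pp = mu_p.T @ mu_p
            S_tp = mu_t.T @ mu_p
            S_tt = mu_t.T @ mu_t
            if P is not None:
                S_pp = S_pp + P[idx - 1].sum(axis=0)
                S_tt = S_tt + P[idx].sum(axis=0)
                S_tp = S_tp + L[idx - 1].transpose(0, 2, 1).sum(axis=0)
            G = np.zeros((dim, dim))
            G[:D, :D] = S_pp
            G[:D, D:D + M] = mu_p.T @ u
            G[D:D + M, :D] = G[:D, D:D + M].T
            G[D:D + M, D:D + M] = u.T @ u
            G[:D, -1] = mu_p.sum(axis=0)
            G[-1, :D] = G[:D, -1]
            G[D:D + M, -1] = u.sum(axis=0)
            G[-1, D:D + M] = G[D:D + M, -1]
            G[-1, -1] = idx.size
            B = np.zeros((D, dim))
            B[:, :D] = S_tp
            B[:, D:D + M] = mu_t.T @ u
            B[:, -1] = mu_t.sum(axis=0)
            G_k[k] += G
            B_k[k] += B
            Stt_k[k] += S_tt
            n_k[k] += idx.size

    pooled_G = G_k.sum(axis=0)
    pooled_B = B_k.sum(axis=0)
    pooled_Stt = Stt_k.sum(axis=0)
    pooled_n = n_k.sum()

    A = np.zeros((K, D, D))
    V = np.zeros((K, D, M))
    b = np.zeros((K, D))
    Sigma_h = np.zeros((K, D, D))
    for k in range(K):
        if n_k[k] < D + M + 1:     # starved state: fall back to pooled fit
            G, B, Stt, n = pooled_G, pooled_B, pooled_Stt, pooled_n
        else:
            G, B, Stt, n = G_k[k], B_k[k], Stt_k[k], n_k[k]
        Greg = G + 1e-8 * np.trace(G) / dim * np.eye(dim)
        W = np.linalg.solve(Greg, B.T).T
        A[k] = W[:, :D]
        V[k] = W[:, D:D + M]
        b[k] = W[:, -1]
        if onehot:
            shift = V[k].mean(axis=1)
            V[k] -= shift[:, None]
            b[k] += shift
        S = (Stt - W @ B.T - B @ W.T + W @ G @ W.T) / n
        Sigma_h[k] = 0.5 * (S + S.T) + _COV_FLOOR * np.eye(D)
    return A, V, b, Sigma_h


def _emission_mstep(Y_list, X_list, P_list, full=False):
    D = X_list[0].shape[1]
    N = Y_list[0].shape[1]
    dim = D + 1
    G = np.zeros((dim, dim))
    B = np.zeros((N, dim))
    S_yy = np.zeros((N, N)) if full else np.zeros(N)
    n = 0
    for ridx, (Y, X) in enumerate(zip(Y_list, X_list)):
        S_xx = X.T @ X
        if P_list is not None:
            S_xx = S_xx + P_list[ridx].sum(axis=0)
        G[:D, :D] += S_xx
        G[:D, -1] += X.sum(axis=0)
        G[-1, :D] = G[:D, -1]
        G[-1, -1] += X.shape[0]
        B[:, :D] += Y.T @ X
        B[:, -1] += Y.sum(axis=0)
        if full:
            S_yy += Y.T @ Y
        else:
            S_yy += (Y ** 2).sum(axis=0)
        n += X.shape[0]
    Greg = G + 1e-8 * np.trace(G) / dim * np.eye(dim)
    W = np.linalg.solve(Greg, B.T).T
    C, d = W[:, :D], W[:, -1]
    if full:
        S = (S_yy - W @ B.T - B @ W.T + W @ G @ W.T) / n
        Sigma_v = 0.5 * (S + S.T) + _COV_FLOOR * np.eye(N)
    else:
        var = (S_yy - 2 * np.einsum("ij,ij->i", W, B)
               + np.einsum("ij,jk,ik->i", W, G, W)) / n
        Sigma_v = np.diag(np.maximum(var, _COV_FLOOR))
    return C, d, Sigma_v


def _estimate_Q(Z_list, K):
    counts = np.ones((K, K))  # add-one smoothing
    for Z in Z_list:
        np.add.at(counts, (Z[:-1], Z[1:]), 1)
    return counts / counts.sum(axis=1, keepdims=True)


def _fit_recurrence(X_list, Z_list, Q, r0):
    """Maximise the switching log-likelihood over r with Q held fixed."""
    K, D = r0.shape
    with np.errstate(divide="ignore"):
        logQ = np.log(Q)
    Xp = np.concatenate([X[:-1] for X in X_list], axis=0)
    Zp = np.concatenate([Z[:-1] for Z in Z_list])
    Zc = np.concatenate([Z[1:] for Z in Z_list])

    n = Zc.size

    def negloglik(rflat):
        r = rflat.reshape(K, D)
        logits = logQ[Zp] + Xp @ r.T
        lognorm = logsumexp(logits, axis=1)
        ll = np.sum(logits[np.arange(n), Zc] - lognorm)
        p = np.exp(logits - lognorm[:, None])
        ind = np.zeros_like(p)
        ind[np.arange(n), Zc] = 1.0
        grad = (ind - p).T @ Xp  # (K, D)
        # per-sample scale: invariant to duplicating the dataset
        return -ll / n, -grad.ravel() / n

    res = minimize(negloglik, r0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 50})
    return res.x.reshape(K, D)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def initialize(Y_list, U_list, K: int, D: int, seed: int = 0,
               restart: int = 0) -> SldsParameters:
    """Spectral + clustering initialisation.

    Emission from the top-D principal directions of the pooled data
    (bias = pooled mean); latents by orthogonal projection; initial
    states by k-means on (position, one-step displacement) features;
    per-state dynamics by least squares within the initial segments.
    """
    Y_list = [np.atleast_2d(Y) for Y in Y_list]
    U_list = [np.atleast_2d(U) for U in U_list]
    M = U_list[0].shape[1]
    pooled = np.concatenate(Y_list, axis=0)
    if pooled.shape[0] < 10 * (D * D + D * M):
        raise ValueError("insufficient pooled time steps for the requested K, D")
    d = pooled.mean(axis=0)
    _, _, Vt = np.linalg.svd(pooled - d, full_matrices=False)
    C = Vt[:D].T
    X_list = [(Y - d) @ C for Y in Y_list]

    # short-window trajectory summaries: a centred 5-step rolling mean
    # suppresses the within-dwell excursions so clusters track the region a
    # state occupies rather than single noisy samples
    w = 5
    kern = np.ones(w) / w
    feats = np.concatenate(
        [np.column_stack([np.convolve(X[:, dd], kern, mode="same")
                          for dd in range(D)]) for X in X_list], axis=0)
    # cluster a canonically sorted copy so the initialisation is invariant
    # to participant/run ordering (and to duplicating the data); restarts
    # beyond the first cluster an 80% subsample for diversity
    sorted_feats = feats[np.lexsort(feats.T)]
    if restart == 0:
        sub = sorted_feats
    else:
        sub_rng = np.random.default_rng(seed)
        n_sub = max(int(0.8 * sorted_feats.shape[0]), K)
        sub = sorted_feats[np.sort(sub_rng.choice(sorted_feats.shape[0],
                                                  n_sub, replace=False))]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    km.fit(sub)
    labels = km.predict(feats)
    if np.unique(labels).size < K:
        raise ValueError(f"k-means could not separate {K} state clusters; "
                         "try a smaller K")
    Z_list = []
    pos = 0
    for X in X_list:
        Z_list.append(labels[pos: pos + X.shape[0]])
        pos += X.shape[0]

    A, V, b, Sigma_h = _dynamics_mstep(X_list, U_list, Z_list, None, None, K, D, M)
    Q = _estimate_Q(Z_list, K)
    _, _, Sigma_v = _emission_mstep(Y_list, X_list, None)
    return SldsParameters(C=C, d=d, Sigma_v=Sigma_v, A=A, V=V, b=b,
                          Sigma_h=Sigma_h, Q=Q, r=np.zeros((K, D)))


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _reseed_collapsed(params, Y_list, X_list, Z_list, rng):
    """Give starved states a contiguous chunk of the worst-fit time steps."""
    K = params.K
    need = params.D + params.M + 1
    counts = np.bincount(np.concatenate(Z_list), minlength=K)
    starved = np.nonzero(counts < need)[0]
    if starved.size == 0:
        return False
    for k in starved:
        run = int(rng.integers(len(Y_list)))
        resid = np.linalg.norm(
            Y_list[run] - X_list[run] @ params.C.T - params.d, axis=1)
        t0 = int(np.argmax(np.convolve(resid, np.ones(need), mode="valid")))
        Z_list[run][t0: t0 + need] = k
    return True


def _run_em(Y_list, U_list, K, D, cfg, seed, restart=0):
    params = initialize(Y_list, U_list, K, D, seed=seed, restart=restart)
    M = params.M
    Z_list = [viterbi(params, (Y - params.d) @ np.linalg.pinv(params.C).T, U)
              for Y, U in zip(Y_list, U_list)]
    rng = np.random.default_rng(seed)
    trace = []
    best = None
    collapse_count = 0
    converged = False
    for _ in range(cfg.max_iter):
        moments = [kalman_smooth(params, Z, Y, U, return_moments=True)
                   for Z, Y, U in zip(Z_list, Y_list, U_list)]
        X_list = [m[0] for m in moments]
        P_list = [m[1] for m in moments]
        L_list = [m[2] for m in moments]
        Z_list = [viterbi(params, X, U) for X, U in zip(X_list, U_list)]
        if _reseed_collapsed(params, Y_list, X_list, Z_list, rng):
            collapse_count += 1
            if collapse_count > 3:
                warnings.warn("state collapse persisted after 3 re-seeds; "
                              "returning best iterate", RuntimeWarning)
                break
        A, V, b, Sigma_h = _dynamics_mstep(
            X_list, U_list, Z_list, P_list, L_list, K, D, M)
        C, d, Sigma_v = _emission_mstep(
            Y_list, X_list, P_list, full=cfg.full_emission_cov)
        Q = _estimate_Q(Z_list, K)
        r = _fit_recurrence(X_list, Z_list, Q, params.r) \
            if cfg.fit_recurrence else params.r
        params = SldsParameters(C=C, d=d, Sigma_v=Sigma_v, A=A, V=V, b=b,
                                Sigma_h=Sigma_h, Q=Q, r=r)
        obj = sum(log_joint(params, X, Z, Y, U)
                  for X, Z, Y, U in zip(X_list, Z_list, Y_list, U_list))
        trace.append(obj)
        if best is None or obj > best[0]:
            best = (obj, params)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol * max(
                1.0, abs(trace[-2])):
            converged = True
            break
    return FitResult(params=best[1], objective_trace=trace,
                     converged=converged, seed=seed)


def fit(Y_list, U_list, K: int, D: int, config: FitConfig = None) -> FitResult:
    """Estimate parameters from one or more runs (best of restarts).

    ``Y_list``/``U_list`` are per-run arrays; temporal terms never
    bridge two list entries.  Restarts differ only in the clustering
    seed of the initialiser; the result with the highest final
    objective wins.
    """
    cfg = config or FitConfig()
    Y_list = [np.atleast_2d(Y) for Y in Y_list]
    U_list = [np.atleast_2d(U) for U in U_list]
    if len({Y.shape[1] for Y in Y_list}) != 1:
        raise ValueError("all runs must share the number of observed channels")
    results = []
    for i in range(max(cfg.n_restarts, 1)):
        results.append(_run_em(Y_list, U_list, K, D, cfg, seed=cfg.seed + i,
                               restart=i))
    best = max(results, key=lambda fr: fr.objective_trace[-1]
               if fr.objective_trace else -np.inf)
    best.n_restarts_used = len(results)
    return best


def fit_group(study, K: int = None, D: int = None,
              config: FitConfig = None) -> FitResult:
    """Fit one shared model to all participants' runs.

    Accepts a ``SyntheticStudy`` or any object exposing ``y_list()`` and
    ``u_list()``; runs are concatenated as independent segments (no
    dynamics or switching term crosses a run boundary).
    """
    Y_list, U_list = study.y_list(), study.u_list()
    if K is None:
        K = study.true_params.K if hasattr(study, "true_params") else 6
    if D is None:
        D = study.true_params.D if hasattr(study, "true_params") else 10
    return fit(Y_list, U_list, K, D, config)
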