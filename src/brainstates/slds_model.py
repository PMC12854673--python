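"""Recurrent switching linear dynamical system: model, likelihood, decoding.

The generative model has three parts.  Observations ``Y_t`` (N channels,
one per region of interest) are an affine Gaussian map of a
low-dimensional latent ``X_t`` (D < N)::

    Y_t | X_t               ~  N(C X_t + d, Sigma_v)          (observation)
    X_t | X_{t-1}, Z_t, U_t ~  N(A_k X_{t-1} + V_k U_t + b_k, Sigma_h_k),
                               k = Z_t                        (dynamics)
    P(Z_t = j | Z_{t-1} = i, X_{t-1})
        ∝ exp(log Q_ij + r_j^T X_{t-1})                       (switching)

The discrete state ``Z_t`` selects which of K linear systems is active;
the ``r_j`` recurrence weights let the switch probability depend on the
latent position, which is what makes the model *recurrent*.  With
``r = 0`` the switching step reduces to a plain Markov chain with
transition matrix Q.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import LinAlgError
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.special import logsumexp

__all__ = [
    "SldsParameters",
    "LatentTrajectory",
    "StateSequence",
    "RoiTimeSeries",
    "DecodeResult",
    "transition_probabilities",
    "one_step_latent_mean",
    "emission_mean",
    "log_joint",
    "decode",
    "kalman_smooth",
    "viterbi",
]

# Diffuse prior variance on X_0 (no informative initial distribution is
# modelled; the first latent is pinned down by the data).
_DIFFUSE_VAR = 1e4


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class SldsParameters:
    """All model matrices of the observation / dynamics / switching steps.

    Shapes: ``C`` (N, D), ``d`` (N,), ``Sigma_v`` (N, N); per state
    ``A`` (K, D, D), ``V`` (K, D, M), ``b`` (K, D), ``Sigma_h`` (K, D, D);
    ``Q`` (K, K) row-stochastic; ``r`` (K, D) recurrence weights.
    """

    C: np.ndarray
    d: np.ndarray
    Sigma_v: np.ndarray
    A: np.ndarray
    V: np.ndarray
    b: np.ndarray
    Sigma_h: np.ndarray
    Q: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        for name in ("C", "d", "Sigma_v", "A", "V", "b", "Sigma_h", "Q", "r"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- dimensions ---------------------------------------------------------
    @property
    def N(self) -> int:
        return self.C.shape[0]

    @property
    def D(self) -> int:
        return self.C.shape[1]

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    @property
    def M(self) -> int:
        return self.V.shape[2]

    def validate(self) -> None:
        N, D = self.C.shape
        K = self.Q.shape[0]
        M = self.V.shape[2]
        if D >= N:
            raise ValueError(f"latent dimension D={D} must be < N={N}")
        expected = {
            "d": (N,),
            "Sigma_v": (N, N),
            "A": (K, D, D),
            "V": (K, D, M),
            "b": (K, D),
            "Sigma_h": (K, D, D),
            "Q": (K, K),
            "r": (K, D),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"{name} has shape {got}, expected {shape}")
        if np.any(self.Q < 0) or not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must be nonnegative and sum to 1")
        for name in ("Sigma_v",):
            S = getattr(self, name)
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
        for k in range(K):
            S = self.Sigma_h[k]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"Sigma_h[{k}] must be symmetric")

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {"format_version": 1}
        for name in ("C", "d", "Sigma_v", "A", "V", "b", "Sigma_h", "Q", "r"):
            arr = getattr(self, name)
            payload[name] = arr.tolist()
            payload[name + "_shape"] = list(arr.shape)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SldsParameters":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {}
        for name in ("C", "d", "Sigma_v", "A", "V", "b", "Sigma_h", "Q", "r"):
            arr = np.asarray(payload[name], dtype=float)
            kwargs[name] = arr.reshape(payload[name + "_shape"])
        return cls(**kwargs)


@dataclass
class LatentTrajectory:
    """Continuous latent path X (T, D) for one run."""

    X: np.ndarray
    run_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("latent trajectory contains non-finite entries")


@dataclass
class StateSequence:
    """Discrete state labels Z in 0..K-1 (length T) for one run."""

    Z: np.ndarray
    K: int = 0
    run_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=int)
        if self.K and (self.Z.min() < 0 or self.Z.max() >= self.K):
            raise ValueError(f"state labels must lie in 0..{self.K - 1}")


@dataclass
class RoiTimeSeries:
    """Observed multi-region series Y (T, N) with region names."""

    Y: np.ndarray
    roi_names: list = field(default_factory=list)
    run_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if not self.roi_names:
            self.roi_names = [f"roi{i:03d}" for i in range(self.Y.shape[1])]
        if len(self.roi_names) != self.Y.shape[1]:
            raise ValueError("roi_names length must match number of columns")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("observed series contains missing/non-finite values")


@dataclass
class DecodeResult:
    X: np.ndarray
    Z: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# one-step equations
# ---------------------------------------------------------------------------

def transition_probabilities(Q: np.ndarray, r: np.ndarray, x_prev: np.ndarray,
                             z_prev: int) -> np.ndarray:
    """Switch distribution P(Z_t = . | Z_{t-1} = z_prev, X_{t-1} = x_prev).

    ``P(j) ∝ exp(log Q[z_prev, j] + r_j · x_prev)``.  A structural zero in
    Q stays an exact zero: no finite recurrence term can revive it.
    """
    Q = np.asarray(Q, dtype=float)
    r = np.asarray(r, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    with np.errstate(divide="ignore"):
        logits = np.log(Q[z_prev]) + r @ x_prev
    if np.all(np.isneginf(logits)):
        raise ValueError("transition row has no admissible successor state")
    p = np.exp(logits - logsumexp(logits))
    return p / p.sum()


def one_step_latent_mean(params: SldsParameters, k: int, x_prev: np.ndarray,
                         u_t: np.ndarray) -> np.ndarray:
    """Mean of the dynamics step: ``A_k x_prev + V_k u_t + b_k``."""
    x_prev = np.asarray(x_prev, dtype=float)
    u_t = np.asarray(u_t, dtype=float)
    if x_prev.shape != (params.D,) or u_t.shape != (params.M,):
        raise ValueError("x_prev/u_t dimension mismatch")
    return params.A[k] @ x_prev + params.V[k] @ u_t + params.b[k]


def emission_mean(params: SldsParameters, x: np.ndarray) -> np.ndarray:
    """Mean of the observation step: ``C x + d``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.D,):
        raise ValueError("latent dimension mismatch")
    return params.C @ x + params.d


# ---------------------------------------------------------------------------
# joint log density
# ---------------------------------------------------------------------------

def _chol_or_raise(S: np.ndarray, name: str):
    try:
        return cho_factor(S, lower=True)
    except LinAlgError as exc:
        raise LinAlgError(f"covariance {name} is singular or not positive definite") from exc


def _gauss_logpdf_stack(resid: np.ndarray, chol) -> np.ndarray:
    """Log N(resid; 0, S) for rows of resid, given cho_factor(S)."""
    dim = resid.shape[1]
    half = cho_solve(chol, resid.T)
    quad = np.einsum("ij,ji->i", resid, half)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return -0.5 * (quad + logdet + dim * np.log(2.0 * np.pi))


def log_joint(params: SldsParameters, X: np.ndarray, Z: np.ndarray,
              Y: np.ndarray, U: np.ndarray) -> float:
    """Complete-data log density of one run under the three model steps.

    Sums emission, dynamics (t >= 1) and switching (t >= 1) log terms;
    X_0 and Z_0 carry flat (constant) priors that are omitted.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    U = np.atleast_2d(U)
    Z = np.asarray(Z, dtype=int)
    T = X.shape[0]
    if not (Y.shape[0] == T and U.shape[0] == T and Z.shape[0] == T):
        raise ValueError("X, Z, Y, U must share the time dimension")

    chol_v = _chol_or_raise(params.Sigma_v, "Sigma_v")
    total = float(np.sum(_gauss_logpdf_stack(Y - X @ params.C.T - params.d, chol_v)))

    with np.errstate(divide="ignore"):
        logQ = np.log(params.Q)
    for k in range(params.K):
        idx = np.nonzero(Z[1:] == k)[0] + 1
        if idx.size == 0:
            continue
        chol_h = _chol_or_raise(params.Sigma_h[k], f"Sigma_h[{k}]")
        pred = X[idx - 1] @ params.A[k].T + U[idx] @ params.V[k].T + params.b[k]
        total += float(np.sum(_gauss_logpdf_stack(X[idx] - pred, chol_h)))

    rx = X[:-1] @ params.r.T                      # (T-1, K), r_j . x_{t-1}
    logits = logQ[Z[:-1]] + rx                    # (T-1, K)
    lognorm = logsumexp(logits, axis=1)
    total += float(np.sum(logits[np.arange(T - 1), Z[1:]] - lognorm))
    return total


# ---------------------------------------------------------------------------
# decoding: alternating Kalman smoothing and Viterbi
# ---------------------------------------------------------------------------

def kalman_smooth(params: SldsParameters, Z: np.ndarray, Y: np.ndarray,
                  U: np.ndarray, return_moments: bool = False):
    """RTS smoother for the continuous latents with Z held fixed.

    The discrete sequence selects time-varying (A, V, b, Sigma_h); the
    recurrence term is dropped from the continuous step (it only tilts
    the discrete potentials, which the Viterbi pass handles).  X_0 has a
    diffuse N(0, 1e4 I) prior.

    With ``return_moments=True`` also returns the smoothed marginal
    covariances P_t and the lag-one cross-covariances Cov(X_t, X_{t+1}),
    the sufficient statistics for exact M-steps.
    """
    Y = np.atleast_2d(Y)
    U = np.atleast_2d(U)
    Z = np.asarray(Z, dtype=int)
    T = Y.shape[0]
    D = params.D
    C, dvec = params.C, params.d
    chol_v = _chol_or_raise(params.Sigma_v, "Sigma_v")
    # information-form emission update pieces (constant over time)
    CtSi = cho_solve(chol_v, C).T                 # C^T Sigma_v^{-1}, (D, N)
    J_obs = CtSi @ C                              # (D, D)

    mu_f = np.zeros((T, D))
    P_f = np.zeros((T, D, D))
    mu_p = np.zeros((T, D))
    P_p = np.zeros((T, D, D))
    Pp_inv = np.zeros((T, D, D))

    # t = 0: diffuse prior
    mu_p[0] = 0.0
    P_p[0] = _DIFFUSE_VAR * np.eye(D)
    inv = np.linalg.inv
    for t in range(T):
        if t > 0:
            k = Z[t]
            Ak = params.A[k]
            mu_p[t] = Ak @ mu_f[t - 1] + params.V[k] @ U[t] + params.b[k]
            P_p[t] = Ak @ P_f[t - 1] @ Ak.T + params.Sigma_h[k]
        # measurement update in information form
        Pp_inv[t] = inv(P_p[t])
        J = Pp_inv[t] + J_obs
        Pf = inv(J)
        P_f[t] = 0.5 * (Pf + Pf.T)
        mu_f[t] = P_f[t] @ (Pp_inv[t] @ mu_p[t] + CtSi @ (Y[t] - dvec))

    # backward RTS pass
    mu_s = mu_f.copy()
    P_s = P_f.copy()
    C_lag = np.zeros((T - 1, D, D))               # Cov(X_t, X_{t+1})
    for t in range(T - 2, -1, -1):
        Ak = params.A[Z[t + 1]]
        G = P_f[t] @ Ak.T @ Pp_inv[t + 1]
        mu_s[t] = mu_f[t] + G @ (mu_s[t + 1] - mu_p[t + 1])
        P_s[t] = P_f[t] + G @ (P_s[t + 1] - P_p[t + 1]) @ G.T
        C_lag[t] = G @ P_s[t + 1]
    if return_moments:
        return mu_s, P_s, C_lag
    return mu_s


def _dynamics_loglik(params: SldsParameters, X: np.ndarray,
                     U: np.ndarray) -> np.ndarray:
    """L[t, j] = log N(X_t ; A_j X_{t-1} + V_j U_t + b_j, Sigma_h_j), t>=1."""
    T = X.shape[0]
    L = np.zeros((T, params.K))
    for k in range(params.K):
        chol_h = _chol_or_raise(params.Sigma_h[k], f"Sigma_h[{k}]")
        pred = X[:-1] @ params.A[k].T + U[1:] @ params.V[k].T + params.b[k]
        L[1:, k] = _gauss_logpdf_stack(X[1:] - pred, chol_h)
    return L


def viterbi(params: SldsParameters, X: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Most likely state path given the latent trajectory.

    Potentials: switching log-probabilities (with the recurrence tilt)
    plus the state-conditional dynamics log densities; Z_0 has a uniform
    prior.  Ties resolve to the lowest state label.
    """
    X = np.atleast_2d(X)
    U = np.atleast_2d(U)
    T = X.shape[0]
    K = params.K
    L = _dynamics_loglik(params, X, U)
    with np.errstate(divide="ignore"):
        logQ = np.log(params.Q)
    rx = X[:-1] @ params.r.T                      # (T-1, K)
    delta = np.full(K, -np.log(K))
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        logits = logQ + rx[t - 1][None, :]        # (K, K) over (i, j)
        logits = logits - logsumexp(logits, axis=1, keepdims=True)
        score = delta[:, None] + logits           # (i, j)
        back[t] = np.argmax(score, axis=0)
        delta = score[back[t], np.arange(K)] + L[t]
    Z = np.zeros(T, dtype=int)
    Z[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        Z[t - 1] = back[t, Z[t]]
    return Z


def decode(params: SldsParameters, Y: np.ndarray, U: np.ndarray,
           max_iter: int = 25) -> DecodeResult:
    """Approximate MAP decoding of (X, Z) under fixed parameters.

    Coordinate ascent: initialise X by pseudo-inverse projection of the
    observations, then alternate Viterbi over Z with RTS smoothing of X
    until the label sequence stops changing.  Deterministic: no random
    initialisation is used.
    """
    Y = np.atleast_2d(Y)
    U = np.atleast_2d(U)
    X = (Y - params.d) @ np.linalg.pinv(params.C).T
    Z = viterbi(params, X, U)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        X = kalman_smooth(params, Z, Y, U)
        Z_new = viterbi(params, X, U)
        if np.array_equal(Z_new, Z):
            converged = True
            Z = Z_new
            break
        Z = Z_new
    return DecodeResult(X=X, Z=Z, converged=converged, n_iter=it)
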