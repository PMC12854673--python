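"""Lesion-based region importance in data space.

The latent dynamics are projected onto the observed channels through
the emission map and its Moore-Penrose pseudoinverse::

    Â_k = C A_k C†,   V̂_k = C V_k,   b̂_k = C b_k + (I - C A_k C†) d

so that (for latents in the emission column space) the one-step
prediction reads ``Y_t ≈ Â Y_{t-1} + V̂ U_t + b̂``.  Lesioning region i
zeroes column i of Â, row i of V̂ and element i of b̂; the importance
``q_t^i`` is the Euclidean norm of the change in the one-step
prediction, which collapses to the closed form::

    q_t^i = || Y_{t-1}^i · Â^{(:,i)} + (V̂^{(i,:)} U_t) e_i + b̂^{(i)} e_i ||_2

with the state-k matrices chosen by k = Z_t.  Raw importance series are
z-scored per region within each run before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "DataSpaceDynamics",
    "ImportanceSeries",
    "project_dynamics",
    "importance",
    "normalize_importance",
    "state_locked_importance",
    "importance_activity_correlation",
]


@dataclass
class DataSpaceDynamics:
    A_hat: np.ndarray         # (K, N, N)
    V_hat: np.ndarray         # (K, N, M)
    b_hat: np.ndarray         # (K, N)
    C_pinv: np.ndarray        # (D, N)


@dataclass
class ImportanceSeries:
    q: np.ndarray             # (T, N); row 0 is NaN (needs Y_{t-1})
    roi_names: list = field(default_factory=list)
    Z: np.ndarray = None
    normalized: bool = False
    zero_variance: np.ndarray = None   # flagged all-zero regions after z-scoring


def project_dynamics(params) -> DataSpaceDynamics:
    """Map the latent dynamics matrices to the observed-channel space."""
    C = params.C
    N, D = C.shape
    rank = np.linalg.matrix_rank(C)
    if rank < D:
        raise np.linalg.LinAlgError(
            f"emission matrix has numerical rank {rank} < D={D}; "
            "data-space projection undefined")
    C_pinv = np.linalg.pinv(C)
    K = params.K
    A_hat = np.zeros((K, N, N))
    V_hat = np.zeros((K, N, params.M))
    b_hat = np.zeros((K, N))
    I = np.eye(N)
    for k in range(K):
        A_hat[k] = C @ params.A[k] @ C_pinv
        V_hat[k] = C @ params.V[k]
        b_hat[k] = C @ params.b[k] + (I - A_hat[k]) @ params.d
    return DataSpaceDynamics(A_hat=A_hat, V_hat=V_hat, b_hat=b_hat,
                             C_pinv=C_pinv)


def importance(Y: np.ndarray, Z: np.ndarray, U: np.ndarray,
               dsd: DataSpaceDynamics, roi_names=None) -> ImportanceSeries:
    """Raw per-region importance q (T, N); q[0] is NaN.

    Exactly equals the norm of intact-minus-lesioned one-step
    predictions; computed in closed form per state.
    """
    Y = np.atleast_2d(Y)
    Z = np.asarray(Z, dtype=int)
    U = np.atleast_2d(U)
    T, N = Y.shape
    if Z.shape[0] != T or U.shape[0] != T:
        raise ValueError("Y, Z, U must be aligned")
    q = np.full((T, N), np.nan)
    for k in np.unique(Z[1:]):
        idx = np.nonzero(Z[1:] == k)[0] + 1
        Yp = Y[idx - 1]                                   # (n, N)
        s = U[idx] @ dsd.V_hat[k].T + dsd.b_hat[k]        # (n, N)
        colnorm2 = (dsd.A_hat[k] ** 2).sum(axis=0)        # (N,)
        diag = np.diag(dsd.A_hat[k])                      # (N,)
        q2 = Yp ** 2 * colnorm2 + 2.0 * Yp * diag * s + s ** 2
        q[idx] = np.sqrt(np.maximum(q2, 0.0))
    names = list(roi_names) if roi_names else [f"roi{i:03d}" for i in range(N)]
    return ImportanceSeries(q=q, roi_names=names, Z=Z)


def normalize_importance(series: ImportanceSeries) -> ImportanceSeries:
    """Z-score each region's importance within the run (NaN rows ignored).

    Zero-variance regions become all-zero and are flagged.
    """
    q = series.q
    if np.sum(np.any(np.isfinite(q), axis=1)) < 2:
        raise ValueError("run too short to normalize")
    mean = np.nanmean(q, axis=0)
    sd = np.nanstd(q, axis=0)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    qn = (q - mean) / sd_safe
    qn[:, zero_var] = 0.0
    qn[np.isnan(q)] = np.nan
    return ImportanceSeries(q=qn, roi_names=series.roi_names, Z=series.Z,
                            normalized=True, zero_variance=zero_var)


def state_locked_importance(series_list, k: int, mean_lifetime: float = None):
    """Average importance locked to entries into state k.

    Collects every onset of state k across runs and averages q over
    steps since onset, truncated at the rounded mean lifetime of the
    state; shorter entries contribute only their available steps.
    Returns ``(locked (steps, N), counts (steps,))``.
    """
    series_list = list(series_list)
    if mean_lifetime is None:
        from .state_dynamics import _run_lengths
        lengths = [L for s in series_list for L in _run_lengths(s.Z, k)]
        if not lengths:
            raise ValueError(f"state {k} never entered")
        mean_lifetime = float(np.mean(lengths))
    steps = max(int(round(mean_lifetime)), 1)
    N = series_list[0].q.shape[1]
    acc = np.zeros((steps, N))
    counts = np.zeros(steps)
    n_entries = 0
    for s in series_list:
        Z = s.Z
        T = Z.shape[0]
        onsets = [t for t in range(T)
                  if Z[t] == k and (t == 0 or Z[t - 1] != k)]
        n_entries += len(onsets)
        for t0 in onsets:
            for w in range(steps):
                t = t0 + w
                if t >= T or Z[t] != k:
                    break
                if np.all(np.isfinite(s.q[t])):
                    acc[w] += s.q[t]
                    counts[w] += 1
    if n_entries == 0:
        raise ValueError(f"state {k} never entered")
    with np.errstate(invalid="ignore", divide="ignore"):
        locked = acc / counts[:, None]
    return locked, counts


def importance_activity_correlation(locked_importance: np.ndarray,
                                    locked_bold: np.ndarray) -> np.ndarray:
    """Spearman rank correlation across regions, per locked step."""
    imp = np.atleast_2d(locked_importance)
    bold = np.atleast_2d(locked_bold)
    if imp.shape != bold.shape:
        raise ValueError("importance and activity matrices must match")
    if imp.shape[1] < 3:
        raise ValueError("need at least 3 regions for a rank correlation")
    return np.array([spearmanr(imp[s], bold[s]).statistic
                     for s in range(imp.shape[0])])
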