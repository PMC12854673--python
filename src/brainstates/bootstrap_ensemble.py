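"""Participant-level bootstrap with state-label alignment.

State labels of independently fitted SLDS models are arbitrary up to
permutation.  To compare parameters across bootstrap refits, each
state's dynamics parameters (A_k, b_k, Sigma_h_k) are flattened into a
'theta' vector, all B*K vectors are pooled and k-means clustered into K
clusters, and each sample's K thetas are assigned to the K centroids by
the Hungarian algorithm, yielding a per-sample relabeling.  Components
are z-scored across the pooled ensemble before clustering so covariance
entries cannot dominate the Euclidean metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .slds_model import SldsParameters

__all__ = [
    "BootstrapEnsemble",
    "resample_participants",
    "theta_vector",
    "align_ensemble",
    "centroid_stability",
    "permute_states",
    "match_states",
    "bootstrap_fit",
]


@dataclass
class BootstrapEnsemble:
    samples: list                       # {"params": SldsParameters, "relabeling": ndarray}
    centroids: np.ndarray               # (K, len(theta)) in raw (unstandardised) units
    B: int = 0
    seed: int = 0

    def aligned_params(self) -> list:
        return [permute_states(s["params"], s["relabeling"]) for s in self.samples]


def resample_participants(study, B: int, seed: int = 0) -> list:
    """B multisets of participant indices, drawn with replacement."""
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(study.participants) if hasattr(study, "participants") else int(study)
    if n == 0:
        raise ValueError("empty study")
    rng = np.random.default_rng(seed)
    return [rng.integers(0, n, size=n) for _ in range(B)]


def theta_vector(params: SldsParameters, k: int) -> np.ndarray:
    """Flat descriptor of state k's intrinsic dynamics: vec(A_k), b_k, vec(Sigma_h_k)."""
    return np.concatenate([params.A[k].ravel(), params.b[k],
                           params.Sigma_h[k].ravel()])


def permute_states(params: SldsParameters, perm) -> SldsParameters:
    """Relabel states: new state j is old state perm^{-1}(j).

    ``perm[i] = j`` sends old label i to new label j; Q permutes on both
    axes, r per state.
    """
    perm = np.asarray(perm, dtype=int)
    K = params.K
    inv = np.empty(K, dtype=int)
    inv[perm] = np.arange(K)
    return SldsParameters(
        C=params.C, d=params.d, Sigma_v=params.Sigma_v,
        A=params.A[inv], V=params.V[inv], b=params.b[inv],
        Sigma_h=params.Sigma_h[inv],
        Q=params.Q[np.ix_(inv, inv)], r=params.r[inv])


def match_states(Z_ref, Z_other, K: int) -> np.ndarray:
    """Permutation sending labels of Z_other onto Z_ref by maximal overlap.

    Both arguments may be single label arrays or lists of per-run
    arrays.  Returns ``perm`` with ``perm[label_in_other] =
    label_in_ref`` (Hungarian on the co-occurrence matrix).
    """
    Zr = np.concatenate([np.asarray(z) for z in
                         (Z_ref if isinstance(Z_ref, (list, tuple)) else [Z_ref])])
    Zo = np.concatenate([np.asarray(z) for z in
                         (Z_other if isinstance(Z_other, (list, tuple)) else [Z_other])])
    conf = np.zeros((K, K))
    np.add.at(conf, (Zo, Zr), 1)
    ri, ci = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=int)
    perm[ri] = ci
    return perm


def _pooled_thetas(params_list) -> np.ndarray:
    K = params_list[0].K
    return np.array([theta_vector(p, k) for p in params_list for k in range(K)])


def align_ensemble(params_list, seed: int = 0) -> BootstrapEnsemble:
    """Cluster pooled theta vectors and Hungarian-assign each sample's states.

    All samples must share K and D.  k-means runs on z-scored theta
    components with 10 restarts; an empty cluster triggers a re-run with
    a fresh seed (up to 10 attempts).
    """
    K = params_list[0].K
    if any(p.K != K or p.D != params_list[0].D for p in params_list):
        raise ValueError("all ensemble samples must share K and D")
    thetas = _pooled_thetas(params_list)                 # (B*K, L)
    mu = thetas.mean(axis=0)
    sd = thetas.std(axis=0)
    sd[sd == 0] = 1.0
    zs = (thetas - mu) / sd
    labels = centers = None
    for attempt in range(10):
        km = KMeans(n_clusters=K, n_init=10, random_state=seed + attempt).fit(zs)
        if np.unique(km.labels_).size == K:
            labels, centers = km.labels_, km.cluster_centers_
            break
    if labels is None:
        raise RuntimeError("k-means repeatedly produced an empty cluster")

    samples = []
    for b, p in enumerate(params_list):
        block = zs[b * K:(b + 1) * K]                    # this sample's K thetas
        cost = np.linalg.norm(block[:, None, :] - centers[None, :, :], axis=2)
        ri, ci = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[ri] = ci                                    # old state i -> centroid ci
        samples.append({"params": p, "relabeling": perm})
    centroids = centers * sd + mu
    return BootstrapEnsemble(samples=samples, centroids=centroids,
                             B=len(params_list), seed=seed)


def centroid_stability(params_list, step: int = 100, tol: float = 1e-5,
                       seed: int = 0):
    """First ensemble size at which centroids stop moving.

    Aligns the first m, m+step, ... samples; centroids of consecutive
    increments are matched by the Hungarian algorithm and compared
    element-wise.  Stable when every element changes by less than
    ``tol``.  Returns ``(stable, B_used)``; ``(False, B)`` if the budget
    is exhausted.
    """
    B = len(params_list)
    prev = None
    for m in range(step, B + 1, step):
        ens = align_ensemble(params_list[:m], seed=seed)
        cent = ens.centroids
        if prev is not None:
            cost = np.linalg.norm(prev[:, None, :] - cent[None, :, :], axis=2)
            ri, ci = linear_sum_assignment(cost)
            if np.max(np.abs(prev[ri] - cent[ci])) < tol:
                return True, m
        prev = cent
    return False, B


def bootstrap_fit(study, B: int, K: int, D: int, fit_config=None,
                  seed: int = 0, progress: bool = False) -> list:
    """Refit the model on B participant-bootstrap resamples of a study.

    Returns the list of fitted ``SldsParameters`` (unaligned); pass the
    list to :func:`align_ensemble`.
    """
    from .slds_fit import FitConfig, fit

    cfg = fit_config or FitConfig(n_restarts=1)
    multisets = resample_participants(study, B, seed=seed)
    out = []
    for b, idx in enumerate(multisets):
        Y_list = [run["roi"].Y for i in idx for run in study.participants[i]]
        U_list = [run["stimuli"].U for i in idx for run in study.participants[i]]
        cfg_b = FitConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * b})
        fr = fit(Y_list, U_list, K, D, cfg_b)
        if not fr.converged and progress:
            warnings.warn(f"bootstrap sample {b} did not converge", RuntimeWarning)
        out.append(fr.params)
    return out
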