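"""Intrinsic state dynamics: fixed points, stability, trajectories.

With the input held at zero, each state's latent dynamics
``X_t = A_k X_{t-1} + b_k`` approaches the fixed point
``x̄_k = (I - A_k)^{-1} b_k`` whenever every eigenvalue of A_k lies
inside the unit circle.  Stability is tested across bootstrap refits:
the p-value of a state is the fraction of samples whose spectral radius
is >= 1, Bonferroni-corrected over states.  Attractors are visualised
in region space through the emission map, ``C x̄ + d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

__all__ = [
    "AttractorResult",
    "StateGeometry",
    "fixed_point",
    "spectral_radius",
    "stability_test",
    "attractor_map",
    "state_geometry",
    "average_trajectory",
    "vector_field_2d",
]

_COND_LIMIT = 1e10


@dataclass
class AttractorResult:
    state: int
    fixed_point: np.ndarray
    spectral_radii: np.ndarray = None     # per bootstrap sample
    stability_p: float = np.nan
    stable: bool = False
    roi_projection: np.ndarray = None     # mean C x̄ + d across samples
    roi_mask: np.ndarray = None
    roi_pvals: np.ndarray = None


@dataclass
class StateGeometry:
    state: int
    centroid: np.ndarray
    mean_lifetime: float
    occupancy: int


def fixed_point(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Equilibrium ``(I - A)^{-1} b`` of the endogenous dynamics."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    ImA = np.eye(A.shape[0]) - A
    if np.linalg.cond(ImA) > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            "I - A is near-singular (eigenvalue of A at 1): marginally "
            "stable dynamics have no well-defined fixed point")
    return np.linalg.solve(ImA, b)


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def stability_test(A_stacks, alpha: float = 0.05, K: int = None) -> list:
    """Bootstrap stability test per state.

    ``A_stacks``: array (B, K, D, D) of aligned bootstrap dynamics
    matrices.  p = fraction of samples with spectral radius >= 1; a
    state is stable when p < alpha / K (Bonferroni over states).
    """
    A_stacks = np.asarray(A_stacks, dtype=float)
    B, K_ = A_stacks.shape[0], A_stacks.shape[1]
    K = K or K_
    out = []
    for k in range(K_):
        radii = np.array([spectral_radius(A_stacks[b, k]) for b in range(B)])
        p = float(np.mean(radii >= 1.0))
        out.append({"state": k, "radii": radii, "p": p,
                    "stable": p < alpha / K})
    return out


def attractor_map(aligned_params: list, k: int, alpha: float = 0.05,
                  n_comparisons: int = None) -> AttractorResult:
    """Region-space attractor of state k across an aligned ensemble.

    Per sample computes ``C x̄_k + d``; reports the mean pattern and a
    per-region Wilcoxon signed-rank test against zero, Bonferroni
    over K x N comparisons by default.
    """
    K = aligned_params[0].K
    N = aligned_params[0].N
    n_comp = n_comparisons if n_comparisons else K * N
    maps = []
    radii = []
    for p in aligned_params:
        xb = fixed_point(p.A[k], p.b[k])
        maps.append(p.C @ xb + p.d)
        radii.append(spectral_radius(p.A[k]))
    maps = np.array(maps)
    radii = np.array(radii)
    mean_map = maps.mean(axis=0)
    pvals = np.full(N, np.nan)
    mask = np.zeros(N, dtype=bool)
    for i in range(N):
        col = maps[:, i]
        if np.all(col == 0):
            pvals[i] = 1.0
            continue
        pvals[i] = wilcoxon(col, alternative="two-sided").pvalue
        mask[i] = pvals[i] < alpha / n_comp
    p_unstable = float(np.mean(radii >= 1.0))
    return AttractorResult(
        state=k, fixed_point=fixed_point(aligned_params[0].A[k],
                                         aligned_params[0].b[k]),
        spectral_radii=radii, stability_p=p_unstable,
        stable=p_unstable < alpha / K, roi_projection=mean_map,
        roi_mask=mask, roi_pvals=pvals)


def _run_lengths(Z: np.ndarray, k: int) -> list:
    lengths = []
    count = 0
    for z in Z:
        if z == k:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def state_geometry(X_list, Z_list, k: int) -> StateGeometry:
    """Centroid of visited latent positions and mean dwell time of state k."""
    Xs = [np.atleast_2d(X) for X in X_list]
    Zs = [np.asarray(Z, dtype=int) for Z in Z_list]
    pts = np.concatenate([X[Z == k] for X, Z in zip(Xs, Zs)], axis=0)
    if pts.shape[0] == 0:
        raise ValueError(f"state {k} is never occupied")
    lengths = [L for Z in Zs for L in _run_lengths(Z, k)]
    return StateGeometry(state=k, centroid=pts.mean(axis=0),
                         mean_lifetime=float(np.mean(lengths)),
                         occupancy=int(pts.shape[0]))


def average_trajectory(X_list, Z_list, k: int, horizon: int = 10):
    """Mean latent path over all windows starting in state k.

    Windows are ``horizon`` steps long, start at every t with Z_t = k
    and ``horizon`` steps remaining in the run (no window crosses a run
    boundary).  Returns ``(mean_path, modal_labels, split_index)`` where
    ``split_index`` is the first step whose modal state differs from k
    (ties resolve to the lowest label).
    """
    paths = []
    labels = []
    for X, Z in zip(X_list, Z_list):
        X = np.atleast_2d(X)
        Z = np.asarray(Z, dtype=int)
        starts = np.nonzero(Z[: max(Z.shape[0] - horizon + 1, 0)] == k)[0]
        for t in starts:
            paths.append(X[t: t + horizon])
            labels.append(Z[t: t + horizon])
    if not paths:
        raise ValueError(f"no windows of length {horizon} start in state {k}")
    mean_path = np.mean(paths, axis=0)
    labels = np.array(labels)                      # (W, horizon)
    K = int(labels.max()) + 1
    modal = np.zeros(horizon, dtype=int)
    for s in range(horizon):
        counts = np.bincount(labels[:, s], minlength=K)
        modal[s] = int(np.argmax(counts))          # argmax -> lowest label on ties
    off = np.nonzero(modal != k)[0]
    split_index = int(off[0]) if off.size else horizon
    return mean_path, modal, split_index


def vector_field_2d(A: np.ndarray, b: np.ndarray, mean_path: np.ndarray,
                    grid_spec: dict = None):
    """One-step endogenous flow field in the plane of a mean trajectory.

    The plane is spanned by the top two principal directions of the
    mean path, anchored at the path mean.  Each in-plane grid point g is
    lifted to latent space (``x = center + basis @ g``), advanced one
    endogenous step (``A x + b``), and the resulting displacement is
    projected back onto the plane.  The attractor is projected likewise.
    """
    mean_path = np.atleast_2d(mean_path)
    if mean_path.shape[0] < 3:
        raise ValueError("need at least 3 path points to fit the plane")
    center = mean_path.mean(axis=0)
    Uc, s, Vt = np.linalg.svd(mean_path - center, full_matrices=False)
    if (s > 1e-12 * s[0]).sum() < 2:
        raise ValueError("mean path is degenerate (rank < 2); no plane")
    basis = Vt[:2].T                               # (D, 2), orthonormal

    spec = {"xlim": None, "ylim": None, "n": 12}
    if grid_spec:
        spec.update(grid_spec)
    path2d = (mean_path - center) @ basis
    attractor = fixed_point(A, b)
    attr2d = (attractor - center) @ basis
    lo = np.minimum(path2d.min(axis=0), attr2d) - 1.0
    hi = np.maximum(path2d.max(axis=0), attr2d) + 1.0
    xlim = spec["xlim"] or (lo[0], hi[0])
    ylim = spec["ylim"] or (lo[1], hi[1])
    gx, gy = np.meshgrid(np.linspace(*xlim, spec["n"]),
                         np.linspace(*ylim, spec["n"]))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    lifted = center + grid @ basis.T
    advanced = lifted @ A.T + b
    vectors = (advanced - center) @ basis - grid
    return {"basis": basis, "center": center, "grid": grid,
            "vectors": vectors, "attractor_2d": attr2d, "path_2d": path2d}
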