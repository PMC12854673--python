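"""Exogenous steering of latent trajectories (l_eff).

The input term V_k U_t is a displacement vector in latent space.  Its
effective contribution toward a target position c (a state centroid) is
the projection of that displacement onto the unit vector from the
current trajectory point to the target::

    l_eff = <c - x, V u> / ||c - x||

Positive values push the trajectory toward the target, negative away.
For state maintenance the target is the occupied state's own centroid;
for a transition i -> j the target is state j's centroid while V and
the visited points are state i's.  The trajectory point at time t is
X_{t-1} and the input is U_t, matching the one-step dynamics update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wilcoxon

__all__ = [
    "SteeringTable",
    "l_eff",
    "maintenance_table",
    "transition_table",
    "steering_significance",
]


@dataclass
class SteeringTable:
    values: np.ndarray                 # rows x M mean l_eff
    row_labels: list
    column_labels: list
    evaluated: np.ndarray = None       # restriction mask (cells measured)
    boot_stack: np.ndarray = None
    mask: np.ndarray = None
    alpha: float = 0.05


def l_eff(x_t: np.ndarray, target_centroid: np.ndarray, V: np.ndarray,
          u_t: np.ndarray, normalize: bool = False) -> float:
    """Projection of the input push V u onto the direction toward the target.

    With ``normalize=True`` returns the cosine of the angle instead of
    the projection length.
    """
    x_t = np.asarray(x_t, dtype=float)
    c = np.asarray(target_centroid, dtype=float)
    push = np.asarray(V, dtype=float) @ np.asarray(u_t, dtype=float)
    diff = c - x_t
    nrm = np.linalg.norm(diff)
    if nrm == 0:
        raise ValueError("trajectory point coincides with the target "
                         "centroid: direction undefined")
    val = float(diff @ push / nrm)
    if normalize:
        pn = np.linalg.norm(push)
        val = val / pn if pn > 0 else 0.0
    return val


def _steering_cells(X, Z, U, V_by_state, targets, pairs):
    """Accumulate l_eff sums per (row, stimulus) cell for one run.

    ``pairs``: list of (row_index, occupied_state, target_vector).
    """
    X = np.atleast_2d(X)
    Z = np.asarray(Z, dtype=int)
    U = np.atleast_2d(U)
    M = U.shape[1]
    R = len(pairs)
    sums = np.zeros((R, M))
    counts = np.zeros((R, M))
    cats = np.argmax(U, axis=1)
    for ridx, (occ, target) in enumerate(pairs):
        idx = np.nonzero(Z[1:] == occ)[0] + 1
        Vk = V_by_state[occ]
        for t in idx:
            diff = target - X[t - 1]
            nrm = np.linalg.norm(diff)
            if nrm == 0:
                continue
            push = Vk @ U[t]
            sums[ridx, cats[t]] += diff @ push / nrm
            counts[ridx, cats[t]] += 1
    return sums, counts


def maintenance_table(X_list, Z_list, U_list, centroids, params,
                      restriction: np.ndarray = None,
                      column_labels=None) -> SteeringTable:
    """Mean l_eff toward each state's own centroid, per stimulus.

    ``centroids``: (K, D) state centroids from the group decode.
    ``restriction``: boolean (K, M) of cells to evaluate (typically the
    association-significant state-stimulus pairs); unevaluated or
    never-occurring cells are NaN.
    """
    K, M = params.K, params.M
    pairs = [(k, np.asarray(centroids[k], dtype=float)) for k in range(K)]
    sums = np.zeros((K, M))
    counts = np.zeros((K, M))
    for X, Z, U in zip(X_list, Z_list, U_list):
        s, c = _steering_cells(X, Z, U, params.V, centroids, pairs)
        sums += s
        counts += c
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts
    evaluated = np.ones((K, M), dtype=bool) if restriction is None \
        else np.asarray(restriction, dtype=bool)
    values[~evaluated] = np.nan
    rows = [f"state{k}" for k in range(K)]
    cols = list(column_labels) if column_labels is not None \
        else [f"u{j}" for j in range(M)]
    return SteeringTable(values=values, row_labels=rows, column_labels=cols,
                         evaluated=evaluated & (counts > 0))


def transition_table(X_list, Z_list, U_list, centroids, params,
                     transitions, column_labels=None) -> SteeringTable:
    """Mean l_eff from state i's visited points toward state j's centroid.

    Uses state i's input map V_i; rows follow ``transitions``.
    """
    if not transitions:
        raise ValueError("transitions list must be non-empty")
    M = params.M
    pairs = [(i, np.asarray(centroids[j], dtype=float)) for (i, j) in transitions]
    R = len(pairs)
    sums = np.zeros((R, M))
    counts = np.zeros((R, M))
    for X, Z, U in zip(X_list, Z_list, U_list):
        s, c = _steering_cells(X, Z, U, params.V, centroids, pairs)
        sums += s
        counts += c
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts
    rows = [f"{i}->{j}" for (i, j) in transitions]
    cols = list(column_labels) if column_labels is not None \
        else [f"u{j}" for j in range(M)]
    return SteeringTable(values=values, row_labels=rows, column_labels=cols,
                         evaluated=counts > 0)


def steering_significance(boot_stack, alpha: float = 0.05,
                          n_comparisons: int = None):
    """Wilcoxon signed-rank of per-bootstrap mean l_eff against zero.

    ``boot_stack``: (B, rows, M); all-NaN cells are excluded from the
    Bonferroni comparison count.  A cell is flagged when the Wilcoxon
    p-value clears the corrected level AND zero is extreme relative to
    the cell's bootstrap distribution at the same corrected level — the
    bootstrap-percentile gate supplies calibration, since
    replicate-consistency alone would flag any fixed finite-sample
    offset.  Standardised bootstrap deviates are pooled across cells so
    the percentile p-value has enough resolution for the correction.
    Returns ``(mask, pvals)``.
    """
    stack = np.asarray(boot_stack, dtype=float)
    if stack.shape[0] < 20:
        raise ValueError("need at least 20 bootstrap samples")
    rows, M = stack.shape[1], stack.shape[2]
    cell_ok = np.zeros((rows, M), dtype=bool)
    for i in range(rows):
        for j in range(M):
            cell_ok[i, j] = np.isfinite(stack[:, i, j]).sum() >= 20
    n_comp = n_comparisons if n_comparisons else max(int(cell_ok.sum()), 1)
    mask = np.zeros((rows, M), dtype=bool)
    pvals = np.full((rows, M), np.nan)
    # pooled standardised bootstrap deviates across cells
    means = np.full((rows, M), np.nan)
    sds = np.full((rows, M), np.nan)
    pool = []
    for i in range(rows):
        for j in range(M):
            if not cell_ok[i, j]:
                continue
            col = stack[:, i, j]
            col = col[np.isfinite(col)]
            means[i, j] = col.mean()
            sds[i, j] = max(col.std(ddof=1), 1e-12)
            pool.append((col - means[i, j]) / sds[i, j])
    pool = np.abs(np.concatenate(pool)) if pool else np.zeros(1)
    for i in range(rows):
        for j in range(M):
            if not cell_ok[i, j]:
                continue
            col = stack[:, i, j]
            col = col[np.isfinite(col)]
            if np.all(col == 0):
                pvals[i, j] = 1.0
                continue
            pvals[i, j] = wilcoxon(col, alternative="two-sided").pvalue
            z0 = abs(means[i, j]) / sds[i, j]     # how extreme is zero
            p_pct = (1 + np.sum(pool >= z0)) / (pool.size + 1)
            mask[i, j] = (pvals[i, j] < alpha / n_comp
                          and p_pct < alpha / n_comp)
    return mask, pvals
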