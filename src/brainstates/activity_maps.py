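"""State activity maps and transition-window responses at region level.

Each region's series is regressed on the K state indicator columns
(optionally plus confounds, no separate intercept — the indicators
partition time), giving one activity coefficient per state; contrasts
are coefficient differences.  Chance maps come from randomly permuted
state sequences; significance is a paired t-test between bootstrap and
null map stacks, Bonferroni-corrected over states x regions.

Transition responses average the observed signal over 8-step windows
whose first half is entirely state i and second half entirely state j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StateRegressionResult",
    "TransitionResponse",
    "state_regression",
    "state_contrast",
    "map_significance",
    "transition_responses",
    "find_transition_windows",
    "network_average",
    "permuted_state_null",
]


@dataclass
class StateRegressionResult:
    beta: np.ndarray                   # (K, N), NaN rows for starved states
    K: int = 0
    confound_beta: np.ndarray = None
    roi_names: list = field(default_factory=list)


@dataclass
class TransitionResponse:
    transition: tuple
    window: int
    mean: np.ndarray                   # (window, N) or (window, n_networks)
    se: np.ndarray = None
    band: tuple = None                 # (lower, upper) 95% normal band
    n_windows: int = 0
    labels: list = field(default_factory=list)


def state_regression(Y: np.ndarray, Z: np.ndarray, K: int = None,
                     confounds: np.ndarray = None,
                     roi_names=None) -> StateRegressionResult:
    """OLS of each region on state indicators (+ confound columns).

    States occupied fewer than 2 steps get NaN coefficients.  A
    confound collinear with the indicator block raises with the
    offending column index.
    """
    Y = np.atleast_2d(Y)
    Z = np.asarray(Z, dtype=int)
    if K is None:
        K = int(Z.max()) + 1
    T = Y.shape[0]
    ind = np.zeros((T, K))
    ind[np.arange(T), Z] = 1.0
    occupied = ind.sum(axis=0) >= 2
    design = ind[:, occupied]
    P = 0
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != T:
            confounds = confounds.T
        P = confounds.shape[1]
        for j in range(P):
            c = confounds[:, j]
            # residual of c after projecting on the indicators
            coefs = np.array([c[Z == k].mean() if np.any(Z == k) else 0.0
                              for k in range(K)])
            resid = c - coefs[Z]
            if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(c), 1.0):
                raise ValueError(f"confound column {j} is collinear with the "
                                 "state indicators")
        design = np.hstack([design, confounds])
    W, *_ = np.linalg.lstsq(design, Y, rcond=None)
    beta = np.full((K, Y.shape[1]), np.nan)
    beta[occupied] = W[: int(occupied.sum())]
    cbeta = W[int(occupied.sum()):] if P else None
    return StateRegressionResult(beta=beta, K=K, confound_beta=cbeta,
                                 roi_names=list(roi_names) if roi_names else [])


def state_contrast(result: StateRegressionResult, i: int, j: int) -> np.ndarray:
    """Per-region contrast beta_i - beta_j (NaN propagates)."""
    return result.beta[i] - result.beta[j]


def permuted_state_null(Z_list, seed: int = 0) -> list:
    """Fully permute each run's state labels in time (chance maps)."""
    rng = np.random.default_rng(seed)
    return [rng.permutation(np.asarray(Z)) for Z in Z_list]


def map_significance(real_stack, null_stack, alpha: float = 0.05,
                     n_comparisons: int = None):
    """Paired t-test of bootstrap maps against permuted-state null maps.

    Stacks are (B, N); Bonferroni over ``n_comparisons`` (default the
    map length; pass K*N when testing all states' maps).  A region is
    flagged when the paired t-test clears the corrected level AND the
    real mean is extreme relative to the null-map distribution at the
    same corrected level (two-sided exceedance gate).  The gate
    calibrates the procedure against fixed finite-sample quirks shared
    by all bootstrap replicates; standardised null deviates are pooled
    across regions so the exceedance p-value has enough resolution for
    the correction.  Returns ``(mask, pvals)``.
    """
    real = np.atleast_2d(np.asarray(real_stack, dtype=float))
    null = np.atleast_2d(np.asarray(null_stack, dtype=float))
    if real.shape != null.shape:
        raise ValueError("real and null stacks must match")
    if real.shape[0] < 3:
        raise ValueError("need at least 3 paired maps")
    N = real.shape[1]
    n_comp = n_comparisons if n_comparisons else N
    pvals = np.full(N, np.nan)
    mask = np.zeros(N, dtype=bool)
    null_mean = np.full(N, np.nan)
    null_sd = np.full(N, np.nan)
    pool = []
    for i in range(N):
        b = null[:, i]
        b = b[np.isfinite(b)]
        if b.size >= 3:
            null_mean[i] = b.mean()
            null_sd[i] = max(b.std(ddof=1), 1e-12)
            pool.append((b - null_mean[i]) / null_sd[i])
    pool = np.abs(np.concatenate(pool)) if pool else np.zeros(1)
    for i in range(N):
        a, b = real[:, i], null[:, i]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            continue
        if np.allclose(a[ok], b[ok]):
            pvals[i] = 1.0
            continue
        pvals[i] = stats.ttest_rel(a[ok], b[ok]).pvalue
        z_real = abs(a[ok].mean() - null_mean[i]) / null_sd[i]
        p_exc = (1 + np.sum(pool >= z_real)) / (pool.size + 1)
        mask[i] = pvals[i] < alpha / n_comp and p_exc < alpha / n_comp
    return mask, pvals


def find_transition_windows(Z: np.ndarray, i: int, j: int,
                            window: int = 8) -> list:
    """Start indices t where Z[t:t+w/2] == i and Z[t+w/2:t+w] == j."""
    Z = np.asarray(Z, dtype=int)
    half = window // 2
    out = []
    for t in range(Z.shape[0] - window + 1):
        if np.all(Z[t:t + half] == i) and np.all(Z[t + half:t + window] == j):
            out.append(t)
    return out


def transition_responses(Y_list, Z_list, transition, window: int = 8,
                         participant_ids=None, roi_names=None) -> TransitionResponse:
    """Average signal in windows straddling an i -> j switch.

    Windows never cross run boundaries.  Responses are averaged within
    participant first (``participant_ids`` gives one id per run; by
    default each run is its own participant), then across participants;
    the band is the 95% normal interval from the between-participant
    standard error.
    """
    i, j = transition
    if participant_ids is None:
        participant_ids = list(range(len(Y_list)))
    per_part = {}
    counts = {}
    n_windows = 0
    for Y, Z, pid in zip(Y_list, Z_list, participant_ids):
        Y = np.atleast_2d(Y)
        for t in find_transition_windows(Z, i, j, window):
            per_part.setdefault(pid, 0)
            per_part[pid] = per_part[pid] + Y[t:t + window]
            counts[pid] = counts.get(pid, 0) + 1
            n_windows += 1
    if n_windows == 0:
        raise ValueError(f"no qualifying windows for transition {i}->{j} "
                         f"(window={window})")
    stack = np.array([per_part[p] / counts[p] for p in sorted(per_part)])
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    else:
        se = np.zeros_like(mean)
    band = (mean - 1.96 * se, mean + 1.96 * se)
    return TransitionResponse(transition=(i, j), window=window, mean=mean,
                              se=se, band=band, n_windows=n_windows,
                              labels=list(roi_names) if roi_names else [])


def network_average(Y: np.ndarray, roi_names, roi_to_network: dict):
    """Unweighted mean series per named network.

    ``roi_to_network`` maps ROI name -> network name; every referenced
    ROI must exist.  Returns ``(series (T, n_networks), network_names)``.
    """
    Y = np.atleast_2d(Y)
    name_ix = {n: i for i, n in enumerate(roi_names)}
    unknown = [r for r in roi_to_network if r not in name_ix]
    if unknown:
        raise ValueError(f"unknown ROI labels: {unknown}")
    networks = sorted(set(roi_to_network.values()))
    cols = []
    for net in networks:
        members = [name_ix[r] for r, n in roi_to_network.items() if n == net]
        cols.append(Y[:, members].mean(axis=1))
    return np.column_stack(cols), networks
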