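"""State-stimulus association tables with surrogate nulls.

P(state | stimulus) is a counting table over lag-aligned (stimulus,
state) pairs pooled across runs: the stimulus at time t is paired with
the decoded state at t + lag (default 3 steps, the hemodynamic delay).
P(transition | stimulus) counts state bigrams the same way.  Chance
levels come from surrogate state sequences obtained by circularly
shifting each run's labels by a random offset — this destroys the
alignment with the stimulus stream while preserving occupancy and dwell
structure.  Each cell is tested with a paired Wilcoxon signed-rank test
across bootstrap samples (real vs surrogate), Bonferroni-corrected over
the full table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

from .stimulus_encoding import apply_lag

__all__ = [
    "AssociationTable",
    "state_given_stimulus",
    "transition_given_stimulus",
    "surrogate_null",
    "significance",
    "select_transitions",
]


@dataclass
class AssociationTable:
    values: np.ndarray                  # rows x M
    row_labels: list
    column_labels: list
    boot_stack: np.ndarray = None       # (B, rows, M)
    null_stack: np.ndarray = None
    mask: np.ndarray = None
    alpha: float = 0.05
    correction_factor: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.column_labels)


def _as_lists(Z_list, U_list):
    Zs = [np.asarray(Z, dtype=int) for Z in Z_list]
    Us = [np.atleast_2d(np.asarray(U, dtype=float)) for U in U_list]
    for Z, U in zip(Zs, Us):
        if Z.shape[0] != U.shape[0]:
            raise ValueError("Z and U must be aligned per run")
    return Zs, Us


def state_given_stimulus(Z_list, U_list, lag: int = 3, K: int = None) -> np.ndarray:
    """K x M table of P(state z at t+lag | stimulus u at t), pooled over runs.

    Columns of stimuli that never occur are NaN (no 0/0).
    """
    Zs, Us = _as_lists(Z_list, U_list)
    if K is None:
        K = max(int(Z.max()) for Z in Zs) + 1
    M = Us[0].shape[1]
    num = np.zeros((K, M))
    den = np.zeros(M)
    for Z, U in zip(Zs, Us):
        s_idx, z_idx = apply_lag(Z.shape[0], lag)
        cats = np.argmax(U[s_idx], axis=1)
        np.add.at(num, (Z[z_idx], cats), 1.0)
        np.add.at(den, cats, 1.0)
    empty = den == 0
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} stimulus categories never occur; "
                      "columns set to NaN", RuntimeWarning)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = num / den
    table[:, empty] = np.nan
    return table


def transition_given_stimulus(Z_list, U_list, lag: int = 3,
                              transitions=None) -> np.ndarray:
    """|transitions| x M table of P(Z_t = i, Z_{t+1} = j | stimulus u).

    The stimulus at time s is aligned with the bigram starting at
    s + lag; the denominator counts aligned stimulus occurrences.
    """
    if not transitions:
        raise ValueError("transitions list must be non-empty")
    for (i, j) in transitions:
        if i == j:
            raise ValueError("self-transitions are not of interest")
    Zs, Us = _as_lists(Z_list, U_list)
    M = Us[0].shape[1]
    R = len(transitions)
    num = np.zeros((R, M))
    den = np.zeros(M)
    tmap = {t: ix for ix, t in enumerate(transitions)}
    for Z, U in zip(Zs, Us):
        T = Z.shape[0]
        s_idx, z_idx = apply_lag(T, lag)
        keep = z_idx <= T - 2          # bigram needs Z_{t+1}
        s_idx, z_idx = s_idx[keep], z_idx[keep]
        cats = np.argmax(U[s_idx], axis=1)
        np.add.at(den, cats, 1.0)
        for (a, c), u in zip(zip(Z[z_idx], Z[z_idx + 1]), cats):
            ix = tmap.get((int(a), int(c)))
            if ix is not None:
                num[ix, u] += 1.0
    empty = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        table = num / den
    table[:, empty] = np.nan
    return table


def surrogate_null(Z_list, n_surrogates: int = 1, seed: int = 0) -> list:
    """Circularly shift each run's labels by an independent random offset.

    Offsets are uniform on [1, T-1], so a surrogate is never identical
    to the original; occupancy is preserved exactly and the dwell-time
    multiset up to the single wrapped run.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        shifted = []
        for Z in Z_list:
            Z = np.asarray(Z)
            T = Z.shape[0]
            if T < 2:
                raise ValueError("runs must have at least 2 steps to shift")
            off = int(rng.integers(1, T))
            shifted.append(np.roll(Z, off))
        out.append(shifted)
    return out


def significance(boot_tables, null_tables, alpha: float = 0.05,
                 correction: str = "bonferroni", n_comparisons: int = None):
    """Per-cell paired Wilcoxon of real vs surrogate tables.

    ``boot_tables``/``null_tables`` are matched stacks (B, rows, M): one
    real and one surrogate table per bootstrap sample.  A cell is
    flagged when (i) the two-sided Wilcoxon p-value clears the
    Bonferroni-corrected level, (ii) the real mean exceeds the null mean
    (enrichment direction), and (iii) the real mean exceeds the pooled
    surrogate distribution at the same corrected level (exceedance
    test).  The exceedance gate is what calibrates the procedure:
    bootstrap replicates share the dataset's chance alignments, so
    consistency across replicates alone would flag finite-sample
    quirks; the surrogate values estimate the chance distribution of
    exactly those quirks.  Standardised null deviates are pooled across
    cells so the exceedance p-value has enough resolution to be
    Bonferroni-corrected.  Returns ``(mask, pvals)`` with the Wilcoxon
    p-values.
    """
    real = np.asarray(boot_tables, dtype=float)
    null = np.asarray(null_tables, dtype=float)
    if real.shape != null.shape:
        raise ValueError("real and null stacks must have equal shapes")
    B = real.shape[0]
    if B < 6:
        raise ValueError("need at least 6 paired samples for the signed-rank test")
    rows, M = real.shape[1], real.shape[2]
    if correction == "bonferroni":
        n_comp = n_comparisons if n_comparisons else rows * M
    elif correction == "none":
        n_comp = 1
    else:
        raise ValueError(f"unknown correction '{correction}'")
    mask = np.zeros((rows, M), dtype=bool)
    pvals = np.full((rows, M), np.nan)
    # pooled standardised null deviates (chance-alignment distribution)
    null_mean = np.full((rows, M), np.nan)
    null_sd = np.full((rows, M), np.nan)
    pool = []
    for i in range(rows):
        for j in range(M):
            b = null[:, i, j]
            b = b[np.isfinite(b)]
            if b.size >= 6:
                null_mean[i, j] = b.mean()
                null_sd[i, j] = max(b.std(ddof=1), 1e-12)
                pool.append((b - null_mean[i, j]) / null_sd[i, j])
    pool = np.concatenate(pool) if pool else np.zeros(1)
    for i in range(rows):
        for j in range(M):
            a, b = real[:, i, j], null[:, i, j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 6:
                continue
            diff = a[ok] - b[ok]
            if np.all(diff == 0):
                pvals[i, j] = 1.0
                continue
            pvals[i, j] = wilcoxon(diff, zero_method="wilcox",
                                   alternative="two-sided").pvalue
            real_mean = np.mean(a[ok])
            z_real = (real_mean - null_mean[i, j]) / null_sd[i, j]
            p_exc = (1 + np.sum(pool >= z_real)) / (pool.size + 1)
            mask[i, j] = (pvals[i, j] < alpha / n_comp
                          and real_mean > np.mean(b[ok])
                          and p_exc < alpha / n_comp)
    return mask, pvals


def select_transitions(Z_list, top_n: int = 8) -> list:
    """Most frequent off-diagonal state bigrams, ties broken lexicographically."""
    counts = {}
    for Z in Z_list:
        Z = np.asarray(Z, dtype=int)
        for a, b in zip(Z[:-1], Z[1:]):
            if a != b:
                counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < top_n:
        warnings.warn(f"only {len(ranked)} distinct transitions observed "
                      f"(requested {top_n}); returning all", RuntimeWarning)
    return [t for t, _ in ranked[:top_n]]
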