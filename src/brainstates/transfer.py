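"""Transfer of a fitted model to a second dataset.

A model estimated on one paradigm can be applied, parameters frozen, to
decode states in another experiment on the same regions.  States are
then summarised around a behavioural event (e.g. crossing into safety):
``P(state | window step)`` counts the decoded state at each step of an
event-anchored window (default -6.25 s to +5.0 s at a 1.25 s sampling
interval, i.e. 10 steps).  Chance tables come from circularly shifted
state sequences; each cell is tested with a paired Wilcoxon signed-rank
test, Bonferroni-corrected over states x window steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association_stats import significance, surrogate_null
from .slds_model import decode

__all__ = [
    "TransferTable",
    "decode_transfer",
    "event_steps",
    "state_by_timestep",
    "transition_by_timestep",
    "transfer_significance",
]


@dataclass
class TransferTable:
    values: np.ndarray                  # K x W
    window_steps: np.ndarray            # step offsets relative to the event
    n_windows: int = 0
    n_dropped: int = 0
    mask: np.ndarray = None
    pvals: np.ndarray = None


def decode_transfer(params, Y_new_list, U_new_list=None, roi_names=None,
                    expected_names=None):
    """Decode runs of a second dataset under frozen parameters.

    Channel count (and, if names are provided, their order) must match
    the fitting data.  When the second paradigm has no input mapping,
    U defaults to all-zeros.  Returns ``(Z_list, X_list)``.
    """
    if roi_names is not None and expected_names is not None:
        mism = [(a, b) for a, b in zip(roi_names, expected_names) if a != b] \
            + [(a, None) for a in roi_names[len(expected_names):]] \
            + [(None, b) for b in expected_names[len(roi_names):]]
        if mism:
            raise ValueError(f"ROI mismatch between datasets: {mism[:5]}")
    Z_list, X_list = [], []
    for ridx, Y in enumerate(Y_new_list):
        Y = np.atleast_2d(Y)
        if Y.shape[1] != params.N:
            raise ValueError(f"run {ridx} has {Y.shape[1]} channels, "
                             f"model expects {params.N}")
        U = np.zeros((Y.shape[0], params.M)) if U_new_list is None \
            else np.atleast_2d(U_new_list[ridx])
        res = decode(params, Y, U)
        Z_list.append(res.Z)
        X_list.append(res.X)
    return Z_list, X_list


def event_steps(event_times_s, tr_s: float = 1.25):
    """Event times in seconds -> nearest sample indices."""
    return [np.asarray(np.round(np.asarray(t) / tr_s), dtype=int)
            for t in event_times_s]


def _window_offsets(pre_s: float = 6.25, post_s: float = 5.0,
                    tr_s: float = 1.25) -> np.ndarray:
    pre = int(round(pre_s / tr_s))
    post = int(round(post_s / tr_s))
    return np.arange(-pre, post)       # 10 steps for the defaults


def state_by_timestep(Z_list, events_list, K: int = None,
                      pre_s: float = 6.25, post_s: float = 5.0,
                      tr_s: float = 1.25) -> TransferTable:
    """P(state | window step) over event-anchored windows.

    ``events_list``: per run, sample indices of the anchoring event.
    Windows not fully inside their run are dropped (counted).
    """
    Zs = [np.asarray(Z, dtype=int) for Z in Z_list]
    if K is None:
        K = max(int(Z.max()) for Z in Zs) + 1
    offs = _window_offsets(pre_s, post_s, tr_s)
    W = offs.size
    counts = np.zeros((K, W))
    n_win = 0
    n_drop = 0
    for Z, events in zip(Zs, events_list):
        T = Z.shape[0]
        for e in np.atleast_1d(events):
            t = e + offs
            if t[0] < 0 or t[-1] >= T:
                n_drop += 1
                continue
            counts[Z[t], np.arange(W)] += 1
            n_win += 1
    if n_win == 0:
        raise ValueError("no complete event windows inside the runs")
    return TransferTable(values=counts / n_win, window_steps=offs,
                         n_windows=n_win, n_dropped=n_drop)


def transition_by_timestep(Z_list, events_list, transition, K: int = None,
                           pre_s: float = 6.25, post_s: float = 5.0,
                           tr_s: float = 1.25) -> TransferTable:
    """P(transition i->j starting at window step | step) over windows."""
    i, j = transition
    Zs = [np.asarray(Z, dtype=int) for Z in Z_list]
    offs = _window_offsets(pre_s, post_s, tr_s)
    W = offs.size
    counts = np.zeros(W)
    n_win = 0
    n_drop = 0
    for Z, events in zip(Zs, events_list):
        T = Z.shape[0]
        for e in np.atleast_1d(events):
            t = e + offs
            if t[0] < 0 or t[-1] + 1 >= T:
                n_drop += 1
                continue
            hit = (Z[t] == i) & (Z[t + 1] == j)
            counts += hit
            n_win += 1
    if n_win == 0:
        raise ValueError("no complete event windows inside the runs")
    return TransferTable(values=(counts / n_win)[None, :], window_steps=offs,
                         n_windows=n_win, n_dropped=n_drop)


def transfer_significance(Z_list, events_list, K: int = None, n_null: int = 50,
                          seed: int = 0, alpha: float = 0.05,
                          transition=None, pre_s: float = 6.25,
                          post_s: float = 5.0, tr_s: float = 1.25) -> TransferTable:
    """Event-window table with circular-shift null and paired Wilcoxon.

    Builds ``n_null`` paired replicates: each resamples runs with
    replacement, computes the real table, and a null table from the
    same resample with circularly shifted labels.  Cells are flagged at
    ``alpha`` / (states x steps) when enriched above the null.  With
    ``transition=(i, j)`` the same machinery tests the per-step
    probability of that transition.
    """
    if n_null < 20:
        raise ValueError("need at least 20 null replicates")
    Zs = [np.asarray(Z, dtype=int) for Z in Z_list]
    if K is None:
        K = max(int(Z.max()) for Z in Zs) + 1
    builder = (lambda zl, ev: state_by_timestep(zl, ev, K, pre_s, post_s, tr_s)) \
        if transition is None else \
        (lambda zl, ev: transition_by_timestep(zl, ev, transition, K,
                                               pre_s, post_s, tr_s))
    table = builder(Zs, events_list)
    rng = np.random.default_rng(seed)
    reals, nulls = [], []
    n_runs = len(Zs)
    for b in range(n_null):
        pick = rng.integers(0, n_runs, size=n_runs)
        zl = [Zs[i] for i in pick]
        ev = [events_list[i] for i in pick]
        reals.append(builder(zl, ev).values)
        zl_null = surrogate_null(zl, 1, seed=int(rng.integers(2**31)))[0]
        nulls.append(builder(zl_null, ev).values)
    mask, pvals = significance(np.array(reals), np.array(nulls), alpha=alpha,
                               n_comparisons=table.values.size)
    table.mask = mask
    table.pvals = pvals
    return table
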