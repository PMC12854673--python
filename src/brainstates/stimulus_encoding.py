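"""Stimulus categories: proximity binning, direction, hemodynamic lag.

Threat proximity (0 = farthest, 1 = circles touching) is quantised into
10 equal bins per movement direction, giving 20 one-hot categories
A1..A10 (approach) and R1..R10 (retreat).  A10 is collision.  Because
the BOLD response lags the stimulus by several seconds, association
analyses pair the stimulus at time t with the decoded state at
t + lag_steps (default 3 steps = 3.75 s at a 1.25 s repetition time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEncoding",
    "compute_direction",
    "encode_stimuli",
    "apply_lag",
    "category_labels",
]


@dataclass
class StimulusEncoding:
    """One-hot input matrix U (T, M) with M = 2 * n_bins categories."""

    U: np.ndarray
    category_labels: list = field(default_factory=list)
    lag_steps: int = 3

    def __post_init__(self) -> None:
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if not self.category_labels:
            self.category_labels = category_labels(self.U.shape[1] // 2)
        rowsums = self.U.sum(axis=1)
        if self.U.size and not np.all(rowsums == 1):
            raise ValueError("each row of U must be one-hot")

    @property
    def categories(self) -> np.ndarray:
        """Integer category index per time step."""
        return np.argmax(self.U, axis=1)


def category_labels(n_bins: int = 10) -> list:
    """A1..A<n> (approach) followed by R1..R<n> (retreat)."""
    return [f"A{i + 1}" for i in range(n_bins)] + [f"R{i + 1}" for i in range(n_bins)]


def compute_direction(proximity: np.ndarray) -> np.ndarray:
    """Movement direction from the discrete difference of proximity.

    +1 where proximity increases (approach), -1 where it decreases
    (retreat).  Zero differences inherit the previous nonzero direction;
    a leading plateau inherits the next nonzero one.  The first sample
    takes the direction of the first difference.
    """
    p = np.asarray(proximity, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two samples to compute direction")
    diff = np.diff(p)
    sign = np.sign(diff)
    if np.all(sign == 0):
        raise ValueError("constant proximity series: direction undefined")
    # direction at t is the sign of the step leading into t; t=0 uses the
    # first step out of it
    direction = np.concatenate([[sign[0]], sign])
    # forward-fill zeros with the previous nonzero sign
    nz = direction != 0
    idx = np.where(nz, np.arange(direction.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = direction[idx]
    # a leading run of zeros has no previous sign: backfill from the next
    if direction[0] == 0:
        first_nz = np.argmax(nz)
        filled[:first_nz] = direction[first_nz]
    return filled.astype(int)


def encode_stimuli(proximity: np.ndarray, direction: np.ndarray,
                   n_bins: int = 10, lag_steps: int = 3) -> StimulusEncoding:
    """One-hot encode (proximity bin, direction) pairs.

    Bins are half-open [0.0, 0.1), ..., with the top bin [0.9, 1.0]
    closed so that collision lands in A10.
    """
    p = np.asarray(proximity, dtype=float)
    direction = np.asarray(direction)
    if p.shape != direction.shape:
        raise ValueError("proximity and direction must have equal length")
    bad = np.nonzero((p < 0) | (p > 1))[0]
    if bad.size:
        raise ValueError(f"proximity outside [0, 1] at index {int(bad[0])}: {p[bad[0]]}")
    bins = np.minimum((p * n_bins).astype(int), n_bins - 1)
    cat = np.where(direction > 0, bins, n_bins + bins)
    U = np.zeros((p.size, 2 * n_bins))
    U[np.arange(p.size), cat] = 1.0
    return StimulusEncoding(U=U, category_labels=category_labels(n_bins),
                            lag_steps=lag_steps)


def decode_categories(enc: StimulusEncoding) -> list:
    """Category label per time step (inverse of the one-hot map)."""
    return [enc.category_labels[i] for i in enc.categories]


def apply_lag(T: int, lag_steps: int):
    """Index alignment pairing the stimulus at t with the signal at t+lag.

    Returns ``(stim_idx, signal_idx)`` arrays of equal length T - lag;
    pairs that would fall outside the run are dropped (no wrap-around).
    """
    if lag_steps < 0:
        raise ValueError("lag_steps must be nonnegative")
    if lag_steps >= T:
        raise ValueError(f"lag {lag_steps} >= run length {T}")
    stim_idx = np.arange(0, T - lag_steps)
    return stim_idx, stim_idx + lag_steps
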