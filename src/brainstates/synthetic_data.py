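"""Synthetic moving-circles paradigm and ground-truth SLDS studies.

The paradigm generator emulates the threat task: two circles approach
and retreat in alternating segments of 2-9 s (most longer than 6 s);
per 8-minute run there are a handful of collisions (proximity hits 1,
shock delivered) and 'near misses' where proximity peaks just below
collision before receding.  Proximity between turning points follows a
smooth cosine ramp sampled on the scanner's repetition-time grid.

`make_ground_truth` plants a known recurrent SLDS (stable dynamics per
state, separated fixed points) and samples multi-participant
observations from it, so that every downstream analysis stage can be
validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .slds_model import (LatentTrajectory, RoiTimeSeries, SldsParameters,
                         StateSequence)
from .stimulus_encoding import StimulusEncoding, compute_direction, encode_stimuli

__all__ = [
    "ParadigmTimeSeries",
    "ParadigmConfig",
    "StudyConfig",
    "SyntheticStudy",
    "simulate_paradigm",
    "sample_slds",
    "make_ground_truth",
    "draw_parameters",
]


# ---------------------------------------------------------------------------
# paradigm
# ---------------------------------------------------------------------------

@dataclass
class ParadigmConfig:
    """Moving-circles run layout.

    Defaults follow the task design: 480 s runs sampled at a 1.25 s
    repetition time, approach/retreat segments of 2-9 s with about 60%
    longer than 6 s, 4 collisions and 7 near misses per run, near-miss
    peak proximity 0.85 (the screen-to-proximity normalisation of the
    1.5-diameter closest approach is a free parameter).
    """

    run_length_s: float = 480.0
    tr_s: float = 1.25
    segment_bounds_s: tuple = (2.0, 9.0)
    long_segment_s: float = 6.0
    p_long: float = 0.6
    n_collisions: int = 4
    n_near_misses: int = 7
    near_miss_proximity: float = 0.85


@dataclass
class ParadigmTimeSeries:
    time: np.ndarray          # seconds, uniform grid
    proximity: np.ndarray     # in [0, 1]
    direction: np.ndarray     # +1 approach, -1 retreat
    shock: np.ndarray         # {0, 1}
    run_id: str = ""
    block_id: np.ndarray = None

    def __post_init__(self) -> None:
        if self.block_id is None:
            half = self.time[-1] / 2 if self.time.size else 0.0
            self.block_id = (self.time >= half).astype(int)


def _draw_segment_steps(rng, cfg: ParadigmConfig, total_steps: int):
    """Segment durations in TR steps, each within bounds, summing exactly."""
    lo = int(np.ceil(cfg.segment_bounds_s[0] / cfg.tr_s))
    hi = int(np.floor(cfg.segment_bounds_s[1] / cfg.tr_s))
    if lo < 1 or hi < lo:
        raise ValueError("segment_bounds_s incompatible with tr_s")
    long_lo = int(np.floor(cfg.long_segment_s / cfg.tr_s)) + 1
    short_choices = np.arange(lo, min(long_lo, hi + 1))
    long_choices = np.arange(long_lo, hi + 1)
    for _ in range(200):
        durs = []
        remaining = total_steps
        while remaining > 2 * hi:
            if long_choices.size and rng.random() < cfg.p_long:
                d = int(rng.choice(long_choices))
            else:
                d = int(rng.choice(short_choices))
            durs.append(d)
            remaining -= d
        if lo <= remaining <= hi:
            durs.append(remaining)
        elif remaining >= 2 * lo:
            d1 = max(lo, remaining - hi)
            durs.extend([d1, remaining - d1])
        else:
            continue  # awkward remainder; redraw
        if len(durs) % 2 == 1:
            continue  # need an even count (trough -> peak -> ... -> trough)
        return durs
    raise ValueError(
        "could not partition the run into alternating segments within "
        f"bounds {cfg.segment_bounds_s} at tr={cfg.tr_s}; adjust run length")


def simulate_paradigm(config: ParadigmConfig = None, seed: int = 0,
                      run_id: str = "run0") -> ParadigmTimeSeries:
    """Simulate one run of the moving-circles proximity trace.

    Turning points snap to the sampling grid, so collision peaks attain
    proximity exactly 1 (shock delivered there) and near-miss peaks
    attain exactly the configured level.  Raises ``ValueError`` when the
    requested event counts cannot fit into the run.
    """
    cfg = config or ParadigmConfig()
    if cfg.run_length_s <= 0 or cfg.tr_s <= 0:
        raise ValueError("run_length_s and tr_s must be positive")
    if not (0 < cfg.near_miss_proximity < 1):
        raise ValueError("near_miss_proximity must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    total_steps = int(round(cfg.run_length_s / cfg.tr_s))
    durs = _draw_segment_steps(rng, cfg, total_steps)
    n_peaks = len(durs) // 2
    n_events = cfg.n_collisions + cfg.n_near_misses
    if n_events > n_peaks:
        raise ValueError(
            f"requested {cfg.n_collisions} collisions + {cfg.n_near_misses} "
            f"near misses but the run only accommodates {n_peaks} "
            "approach/retreat cycles; shorten segments or the event list")

    # assign event identities to peaks
    peak_kind = np.array(["far"] * n_peaks, dtype=object)
    event_idx = rng.choice(n_peaks, size=n_events, replace=False)
    peak_kind[event_idx[:cfg.n_collisions]] = "collision"
    peak_kind[event_idx[cfg.n_collisions:]] = "near_miss"

    # turning-point values: troughs low, peaks by kind (kept clear of the
    # near-miss level so event counts are exact)
    far_hi = min(0.7, cfg.near_miss_proximity - 0.1)
    knots = [rng.uniform(0.0, 0.25)]
    for i in range(n_peaks):
        if peak_kind[i] == "collision":
            knots.append(1.0)
        elif peak_kind[i] == "near_miss":
            knots.append(cfg.near_miss_proximity)
        else:
            knots.append(rng.uniform(0.3, far_hi))
        knots.append(rng.uniform(0.0, 0.25))

    # cosine ramps between knots, sampled on the grid
    prox = np.empty(total_steps + 1)
    pos = 0
    prox[0] = knots[0]
    for seg, d in enumerate(durs):
        a, bval = knots[seg], knots[seg + 1]
        s = (1 - np.cos(np.pi * np.arange(1, d + 1) / d)) / 2
        prox[pos + 1: pos + d + 1] = a + (bval - a) * s
        prox[pos + d] = bval  # pin the turning point exactly (event counts)
        pos += d
    prox = prox[:total_steps]
    time = np.arange(total_steps) * cfg.tr_s
    direction = compute_direction(prox)
    shock = (prox >= 1.0).astype(int)
    return ParadigmTimeSeries(time=time, proximity=prox, direction=direction,
                              shock=shock, run_id=run_id)


# ---------------------------------------------------------------------------
# sampling from the generative model
# ---------------------------------------------------------------------------

def _sqrt_psd(S: np.ndarray, name: str) -> np.ndarray:
    """Matrix square root of a PSD covariance; errors if indefinite."""
    S = np.asarray(S, dtype=float)
    w, Vv = np.linalg.eigh(0.5 * (S + S.T))
    if w.min() < -1e-10 * max(1.0, abs(w.max())):
        raise ValueError(f"covariance {name} is not positive semi-definite")
    return Vv @ np.diag(np.sqrt(np.clip(w, 0, None))) @ Vv.T


def sample_slds(params: SldsParameters, inputs: StimulusEncoding, T: int,
                seed: int = 0, run_id: str = "", participant_id: str = ""):
    """Forward-sample (X, Z, Y) from the generative model.

    Z_0 is uniform; X_0 is drawn from the dynamics step applied to a
    zero previous latent, so the noise-free limit is the deterministic
    iteration of the dynamics rule started at the origin.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    U = np.atleast_2d(inputs.U)[:T]
    if U.shape[0] < T:
        raise ValueError("inputs shorter than requested T")
    rng = np.random.default_rng(seed)
    K, D, N = params.K, params.D, params.N
    sq_h = [_sqrt_psd(params.Sigma_h[k], f"Sigma_h[{k}]") for k in range(K)]
    sq_v = _sqrt_psd(params.Sigma_v, "Sigma_v")

    Z = np.zeros(T, dtype=int)
    X = np.zeros((T, D))
    Z[0] = rng.integers(K)
    x_prev = np.zeros(D)
    X[0] = params.A[Z[0]] @ x_prev + params.V[Z[0]] @ U[0] + params.b[Z[0]] \
        + sq_h[Z[0]] @ rng.standard_normal(D)
    from .slds_model import transition_probabilities
    for t in range(1, T):
        p = transition_probabilities(params.Q, params.r, X[t - 1], Z[t - 1])
        Z[t] = rng.choice(K, p=p)
        k = Z[t]
        X[t] = params.A[k] @ X[t - 1] + params.V[k] @ U[t] + params.b[k] \
            + sq_h[k] @ rng.standard_normal(D)
    Y = X @ params.C.T + params.d + rng.standard_normal((T, N)) @ sq_v.T
    lat = LatentTrajectory(X=X, run_id=run_id, participant_id=participant_id)
    states = StateSequence(Z=Z, K=K, run_id=run_id, participant_id=participant_id)
    obs = RoiTimeSeries(Y=Y, run_id=run_id, participant_id=participant_id)
    return lat, states, obs


# ---------------------------------------------------------------------------
# planted studies
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Ground-truth study layout.

    The compact default (3 states, 2 latent dimensions, 15 regions, 4
    input categories, 20 participants with one 500-step run each at an
    emission SNR of about 4) keeps every recovery experiment tractable
    on one CPU while exercising all pipeline stages.
    """

    n_participants: int = 20
    runs_per_participant: int = 1
    K: int = 3
    D: int = 2
    N: int = 15
    M: int = 4
    T: int = 500
    tr_s: float = 1.25
    emission_snr: float = 4.0
    dynamics_noise: float = 0.15
    input_scale: float = 0.4
    recurrence_scale: float = 0.1
    stay_prob: float = 0.94
    spectral_bound: float = 0.95
    fixed_point_radius: float = 4.0


@dataclass
class SyntheticStudy:
    true_params: SldsParameters
    participants: list          # list of lists of run dicts
    seed: int = 0
    config: StudyConfig = field(default_factory=StudyConfig)

    def y_list(self):
        return [run["roi"].Y for part in self.participants for run in part]

    def u_list(self):
        return [run["stimuli"].U for part in self.participants for run in part]

    def z_list(self):
        return [run["states"].Z for part in self.participants for run in part]

    def x_list(self):
        return [run["latents"].X for part in self.participants for run in part]


def _random_orthogonal(rng, D: int) -> np.ndarray:
    Qm, R = np.linalg.qr(rng.standard_normal((D, D)))
    return Qm * np.sign(np.diag(R))


def draw_parameters(cfg: StudyConfig, rng) -> SldsParameters:
    """Draw a stable, well-separated ground-truth parameter set.

    Each ``A_k`` is a random orthogonal rotation scaled by a contraction
    factor below the configured spectral bound, so stability holds by
    construction.  Fixed points are placed on a circle of configurable
    radius so states are geometrically distinct; ``b_k`` follows from
    ``(I - A_k) x̄_k``.
    """
    K, D, N, M = cfg.K, cfg.D, cfg.N, cfg.M
    C = np.linalg.qr(rng.standard_normal((N, D)))[0]
    d = rng.normal(0.0, 0.5, size=N)
    A = np.zeros((K, D, D))
    b = np.zeros((K, D))
    # zero row-mean over categories: with one-hot inputs only V u + b is
    # identifiable, so the planted model fixes the gauge by putting the
    # category-mean input effect into b
    V = rng.normal(0.0, cfg.input_scale, size=(K, D, M))
    V -= V.mean(axis=2, keepdims=True)
    Sigma_h = np.zeros((K, D, D))
    # fixed points spread on a circle in the first two latent coordinates
    angles = 2 * np.pi * np.arange(K) / K + rng.uniform(0, 2 * np.pi)
    for k in range(K):
        rho = rng.uniform(0.6, cfg.spectral_bound)
        A[k] = rho * _random_orthogonal(rng, D)
        xbar = np.zeros(D)
        xbar[0] = cfg.fixed_point_radius * np.cos(angles[k])
        xbar[min(1, D - 1)] = cfg.fixed_point_radius * np.sin(angles[k])
        if D > 2:
            xbar[2:] = rng.normal(0, 0.5, size=D - 2)
        b[k] = (np.eye(D) - A[k]) @ xbar
        Sigma_h[k] = max(cfg.dynamics_noise, 1e-6) ** 2 * np.eye(D)
    Q = np.full((K, K), (1 - cfg.stay_prob) / max(K - 1, 1))
    np.fill_diagonal(Q, cfg.stay_prob if K > 1 else 1.0)
    r = rng.normal(0.0, cfg.recurrence_scale, size=(K, D))
    # emission noise from the latent signal scale: var(CX) per channel is
    # bounded by the fixed-point spread; calibrated after a pilot sample
    Sigma_v = np.eye(N)  # placeholder, rescaled by the caller
    return SldsParameters(C=C, d=d, Sigma_v=Sigma_v, A=A, V=V, b=b,
                          Sigma_h=Sigma_h, Q=Q, r=r)


def make_ground_truth(config: StudyConfig = None, seed: int = 0) -> SyntheticStudy:
    """Plant a ground-truth model and sample a full multi-participant study.

    All participants share the planted parameters; noise realisations
    differ per run.  The emission covariance is calibrated on a pilot
    noise-free run so that the per-channel signal-to-noise ratio matches
    ``config.emission_snr``.
    """
    cfg = config or StudyConfig()
    for name in ("K", "D", "N", "M"):
        if getattr(cfg, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    if cfg.D >= cfg.N:
        raise ValueError("D must be smaller than N")
    if cfg.M % 2:
        raise ValueError("M must be even (approach/retreat pairs of bins)")
    rng = np.random.default_rng(seed)
    params = draw_parameters(cfg, rng)

    run_length_s = cfg.T * cfg.tr_s
    scale = run_length_s / 480.0
    base = ParadigmConfig(run_length_s=run_length_s, tr_s=cfg.tr_s,
                          n_collisions=max(1, int(round(4 * scale))),
                          n_near_misses=max(1, int(round(7 * scale))))

    # pilot: calibrate emission noise to the requested SNR
    pilot_par = simulate_paradigm(base, seed=int(rng.integers(2**31)))
    pilot_enc = encode_stimuli(pilot_par.proximity, pilot_par.direction,
                               n_bins=cfg.M // 2)
    lat, _, _ = sample_slds(params, pilot_enc, cfg.T, seed=int(rng.integers(2**31)))
    signal = lat.X @ params.C.T
    sd = signal.std(axis=0)
    noise_sd = np.maximum(sd / max(cfg.emission_snr, 1e-12), 1e-6)
    params.Sigma_v = np.diag(noise_sd ** 2)

    participants = []
    for p in range(cfg.n_participants):
        runs = []
        for rix in range(cfg.runs_per_participant):
            par = simulate_paradigm(base, seed=int(rng.integers(2**31)),
                                    run_id=f"run{rix}")
            enc = encode_stimuli(par.proximity, par.direction, n_bins=cfg.M // 2)
            lat, states, obs = sample_slds(
                params, enc, cfg.T, seed=int(rng.integers(2**31)),
                run_id=f"run{rix}", participant_id=f"sub{p:03d}")
            runs.append({"paradigm": par, "stimuli": enc, "latents": lat,
                         "states": states, "roi": obs})
        participants.append(runs)
    return SyntheticStudy(true_params=params, participants=participants,
                          seed=seed, config=cfg)
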