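# Methods

## Model

`brainstates` analyses multi-region fMRI time series with a recurrent
switching linear dynamical system (rSLDS).  Observed activity
`Y_t ∈ R^N` (one channel per region of interest) is an affine Gaussian
map of a low-dimensional latent trajectory `X_t ∈ R^D`, whose dynamics
switch between K linear regimes selected by a discrete state `Z_t`:

    Y_t | X_t                ~  N(C X_t + d, Σ_v)
    X_t | X_{t-1}, Z_t, U_t  ~  N(A_k X_{t-1} + V_k U_t + b_k, Σ_h_k),  k = Z_t
    P(Z_t = j | Z_{t-1} = i, X_{t-1})  ∝  exp(log Q_ij + r_j · X_{t-1})

`U_t` is a one-hot encoding of the experimental stimulus (20 categories:
10 threat-proximity bins × approach/retreat direction).  The recurrence
weights `r_j` let switch probabilities depend on where the latent
trajectory currently is; with `r = 0` switching is a plain Markov chain.

Each stable state has a fixed-point attractor `x̄_k = (I − A_k)^{-1} b_k`
(visualised in region space as `C x̄_k + d`), and the input term
`V_k U_t` is interpreted as a push whose projection onto the direction
toward a state centroid (`l_eff`) quantifies input steering.

## Identifiability conventions

Two gauge freedoms are fixed explicitly:

* **Input/bias split.**  One-hot input rows sum to 1, so the intercept
  is exactly collinear with the input columns and only `V_k u + b_k` is
  identified.  Both the synthetic generator and the estimator adopt the
  zero-row-mean gauge for `V_k` (each row's mean over categories is
  shifted into `b_k`).  Without this convention the attractor
  `(I − A)^{-1} b` is undefined up to an arbitrary constant; with it,
  attractor recovery is well-posed.  The gauge is applied only when the
  input rows are detected to be one-hot.
* **State labels.**  Labels are arbitrary up to permutation.  All
  cross-model comparisons go through alignment: k-means on pooled
  per-state parameter vectors θ_k = (vec A_k, b_k, vec Σ_h_k), z-scored
  componentwise, followed by a Hungarian assignment of each model's K
  states to the K centroids.  θ components are z-scored because the
  covariance entries would otherwise dominate the Euclidean metric.

The latent basis itself (C → C R, X → R⁻¹ X) is left free; all
recovery comparisons are made in observation space.

## Estimation

Parameters are fitted by hard-assignment EM, deliberately chosen over a
structured variational scheme for determinism and testability:

1. **E-step.**  Given labels Z, the RTS smoother returns the Gaussian
   posterior of X (means, marginal covariances, lag-one
   cross-covariances); given X, Viterbi over the switching-plus-dynamics
   potentials refreshes Z.  Dynamics and switching terms never bridge
   run boundaries, and X_0 carries a diffuse N(0, 10⁴ I) prior.  The
   recurrence term is omitted from the continuous smoothing step (it
   only tilts the discrete potentials, which Viterbi handles).
2. **M-step.**  Closed-form weighted least squares on the posterior
   moments for {A_k, V_k, b_k, Σ_h_k} and {C, d, Σ_v}.  Using the full
   second moments (not just smoothed means) removes the
   errors-in-variables attenuation that would otherwise bias dynamics
   toward zero — on the default planted study this is the difference
   between ~25% and ~0.5% attractor error.  Q comes from label bigrams
   with add-one smoothing; r from L-BFGS ascent on the per-sample
   switching log-likelihood.  Σ_v is diagonal by default (full
   optional); all covariances carry a 1e-6 floor.
3. **Initialisation.**  Emission from the top-D principal directions of
   the pooled data; latents by projection; initial states by k-means on
   5-step rolling means of the latent trajectory (short-window
   summaries suppress within-dwell excursions, which single-step
   features do not — pointwise features produced persistent label-split
   local optima).  The k-means runs on a canonically sorted copy of the
   features, making fits invariant to participant order and data
   duplication; restarts beyond the first cluster an 80% subsample for
   diversity.  Best of `n_restarts` by final objective.

The reported objective is the complete-data log joint of the hard
assignments — a surrogate for the marginal likelihood; the marginal
ELBO of a variational treatment is not computed.

## Decoding

`decode` is deterministic coordinate ascent: pseudo-inverse projection
of the observations initialises X, then Viterbi and smoothing alternate
until the label sequence is fixed (typically 2–4 sweeps).  Viterbi ties
resolve to the lowest state label.  Transfer decoding applies the same
procedure with frozen parameters; when the second paradigm has no input
mapping, U defaults to zeros.

## Statistical testing

All association machinery pairs the stimulus at time t with the decoded
state at t + 3 steps (3.75 s at the 1.25 s repetition time),
approximating the hemodynamic delay.  Chance references are built by
circularly shifting each run's label sequence by a uniform random
offset in [1, T−1], which preserves occupancy exactly and dwell
structure up to one wrapped run.

Each table cell is tested with the paired Wilcoxon signed-rank across
bootstrap replicates (real vs surrogate), Bonferroni-corrected over the
full table, with an enrichment-direction gate (two-sided p, real mean
above null mean).  Because bootstrap replicates share the dataset's
chance alignments, replicate-consistency alone would flag finite-sample
quirks with √B amplification; measured on null data this flags ~23% of
cells.  The tests therefore add a calibrated exceedance gate at the
same Bonferroni level:

* **Association / transfer:** the real cell mean must be extreme
  relative to the surrogate-value distribution.
* **Activity maps:** the real map value must be extreme relative to the
  permuted-state null-map distribution (two-sided).
* **Steering:** zero must be extreme relative to the cell's bootstrap
  distribution (percentile-bootstrap, two-sided).

In every case the null/bootstrap deviates are standardised per cell and
pooled across cells, giving the empirical p-value a resolution of about
1/(B·m) so it can be gated at α/m — the same pooled-null logic the
voxel-cluster calibration of the original analysis relies on.  Measured
on null synthetic data the flagged-cell fraction is 0–0.004 with power
0.95–1.0 at the planted effect sizes used in the acceptance checks.

The Wilcoxon's sidedness is not fully determined in the source
analysis; the implementation uses the two-sided p with a direction
gate.  Steering tables are evaluated only on cells passing the
association mask (the restriction the analysis prescribes); all-NaN
cells are excluded from the correction count.

## Synthetic paradigm and planted studies

The paradigm generator emulates the moving-circles threat task on the
scanner grid: 480 s runs at a 1.25 s repetition time, alternating
approach/retreat segments of 2–9 s with ~60% longer than 6 s, exactly 4
collisions (proximity 1, shock) and 7 near misses per run.  Turning
points snap to the sampling grid so event counts are exact; proximity
follows cosine ramps between turning points (any smooth interpolant
would do; cosine is chosen for testability).  The near-miss peak level
is a free parameter (default 0.85) because the screen-geometry
normalisation of "1.5 circle diameters" onto [0, 1] proximity is not
defined by the task description.  Segment-level direction is +1/−1 by
the sign of the proximity difference; plateaus inherit the previous
nonzero sign.

`make_ground_truth` plants a stable rSLDS: each `A_k` is a random
orthogonal rotation scaled by a contraction in [0.6, 0.95] (stability
by construction), fixed points sit on a circle of radius 4 in the
first two latent coordinates, `V_k` ~ N(0, 0.4) in the zero-row-mean
gauge, sticky transitions (diagonal 0.94), recurrence weights
~ N(0, 0.1), and dynamics noise 0.15.  Emission noise is calibrated on
a noise-free pilot run so each channel's signal-to-noise ratio matches
the configured value (default 4).  The compact default study — 3
states, 2 latent dimensions, 15 regions, 4 input categories, 20
participants × 500 steps — keeps every recovery experiment tractable
on one CPU while exercising all pipeline stages; these sizes are the
package's reference conditions for the recovery checks.

What the generator does **not** emulate: hemodynamic convolution,
scanner noise spectra, head motion, physiological confounds, or
between-participant parameter heterogeneity (all participants share the
planted parameters).  Passing recovery tests therefore demonstrate
correctness of the estimation and analysis machinery under the model's
own assumptions, not robustness to fMRI artefacts.

## Numerical choices

* Covariance floors 1e-6; normal-equation ridge 1e-8 · tr(G)/dim.
* Fixed points require cond(I − A) < 1e10; marginal stability raises.
* Pseudoinverses use `numpy.linalg.pinv` (SVD with the standard
  rank tolerance).
* Proximity bins are half-open with a closed top bin, so collision
  (proximity 1.0) lands in the top approach bin.
* Lag alignment drops pairs falling outside a run; nothing wraps.
* Modal-state ties along trajectories resolve to the lowest label.
* The 2-D vector-field lift anchors the trajectory plane at the mean of
  the averaged path and lifts grid points through the orthonormal plane
  basis; the grid vector at an in-plane attractor is exactly zero when
  the attractor lies in the plane (always true at D = 2).
* Importance scores are z-scored per region per run; the first sample
  of each run is undefined (no previous observation) and carried as
  NaN.
* State collapse during EM (a state owning fewer than D + M + 1 steps)
  is repaired up to three times by reassigning the worst-reconstructed
  contiguous segment; persistent collapse returns the best iterate with
  `converged=False`.

## Defaults

| parameter | default | meaning |
|---|---|---|
| K | 6 | discrete states (config input; no model selection) |
| D | 10 | latent dimensions (config input) |
| n_bins | 10 | proximity bins per direction (20 categories) |
| lag_steps | 3 | analysis-time hemodynamic shift (3.75 s) |
| tr_s | 1.25 | repetition time, seconds |
| B | 500 | bootstrap samples, grown in steps of 100 |
| boot_tol | 1e-5 | centroid-stability tolerance |
| alpha | 0.05 | significance level, Bonferroni-corrected |
| window | 8 | transition-response window, steps |
| horizon | 10 | trajectory-average window, steps |
| transfer window | −6.25 s … +5.0 s | event-anchored decode window |

## Known limitations

* Hard-assignment EM underestimates posterior uncertainty relative to a
  structured variational treatment; bootstrap refits are the package's
  only source of parameter uncertainty.
* The eight "transitions of interest" are chosen by observed frequency
  (ties broken lexicographically); the original selection rule is not
  public.
* Voxel-level maps and cluster-size correction are out of scope; maps
  are region-level with Bonferroni correction.
* The percentile/exceedance gates make the significance machinery
  conservative at very small B (below ~20/α·m pooled null values no
  cell can reach the corrected level).
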