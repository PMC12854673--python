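# brainstates

Recurrent switching linear dynamical systems (rSLDS) for brain-state
dynamics during continuous threat processing.

Sustained threat paradigms — e.g. two circles drifting toward and away
from each other on screen, with a shock on collision — evoke brain
dynamics that are not well described by event-locked averages.  This
package models multi-region fMRI time series as a small set of discrete
brain states, each with its own linear latent dynamics, and then asks
the questions that matter for threat processing: which states go with
which stimulus conditions, where each state's dynamics settle
(fixed-point attractors), how external inputs steer the latent
trajectory, which regions matter most for the dynamics, and whether the
states generalise to a second threat paradigm.

It is written for computational/cognitive neuroscientists who have
region-of-interest time series plus a per-run stimulus trace and want a
reproducible, testable pipeline — and it ships a synthetic paradigm and
ground-truth generator so every stage can be validated end to end
without any data download.

## Model

Observed activity `Y_t ∈ R^N` from N regions is tied to a latent
trajectory `X_t ∈ R^D` (D < N) with state-switching linear dynamics:

    Y_t | X_t                ~  N(C X_t + d, Σᵛ)                 (observation)
    X_t | X_{t−1}, Z_t, U_t  ~  N(A_k X_{t−1} + V_k U_t + b_k, Σʰ_k)   (dynamics)
    P(Z_t = j | Z_{t−1} = i, X_{t−1}) ∝ exp(log Q_ij + r_jᵀ X_{t−1})   (switching)

`U_t` one-hot encodes the stimulus into 20 categories (10 proximity
bins × approach/retreat).  Downstream analyses include
`P(state | stimulus)` and `P(transition | stimulus)` tables with
circular-shift surrogate nulls, fixed points `x̄_k = (I − A_k)⁻¹ b_k`
with bootstrap stability tests on the spectral radius, input steering
`l_eff = ⟨x̄c − x, V u⟩ / ‖x̄c − x‖`, a data-space lesion measure of
region importance via the emission pseudoinverse, state activity maps,
and transfer decoding onto a second dataset.  See `docs/methods.md`
for the full account.

## Worked example

Plant a ground-truth study, fit the model, and inspect recovery:

```python
import numpy as np
from brainstates import (StudyConfig, FitConfig, make_ground_truth,
                         fit_group, decode, match_states, fixed_point,
                         state_given_stimulus)

study = make_ground_truth(StudyConfig(n_participants=6, T=300), seed=8)
fit = fit_group(study, config=FitConfig(n_restarts=2, max_iter=30, seed=0))

Zs = [decode(fit.params, Y, U).Z
      for Y, U in zip(study.y_list(), study.u_list())]
perm = match_states(study.z_list(), Zs, K=3)
acc = np.mean(np.concatenate(
    [perm[z] == zt for z, zt in zip(Zs, study.z_list())]))
print(f"state recovery accuracy: {acc:.3f}")

est, tru = fit.params, study.true_params
for k in range(3):
    y_est = est.C @ fixed_point(est.A[k], est.b[k]) + est.d
    y_tru = tru.C @ fixed_point(tru.A[perm[k]], tru.b[perm[k]]) + tru.d
    rel = np.linalg.norm(y_est - y_tru) / np.linalg.norm(y_tru)
    print(f"state {k}: spectral radius "
          f"{np.abs(np.linalg.eigvals(est.A[k])).max():.3f}, "
          f"attractor rel. error {rel:.3f}")
```

Output:

```
state recovery accuracy: 0.999
state 0: spectral radius 0.863, attractor rel. error 0.015
state 1: spectral radius 0.671, attractor rel. error 0.009
state 2: spectral radius 0.818, attractor rel. error 0.007
```

The decoded state sequences recover the planted labels almost
perfectly (after the label permutation that any mixture-style model
needs), every fitted state is dynamically stable (spectral radius
below 1), and the region-space attractors `C x̄ + d` land within ~1–2%
of the planted ones.  From the same decode,
`state_given_stimulus(Zs, study.u_list(), lag=3)` gives the K × M
association table whose columns each sum to 1 over states.

The same stages run from the shell:

```
brainstates simulate --seed 1 --out paradigm.tsv
brainstates pipeline --config analysis.yaml --seed 7 --out results/
```

`pipeline` executes simulate/ingest → encode → fit → bootstrap →
association → dynamics → steering → importance → maps → transfer,
writing TSV/JSON outputs and a manifest; identical config + seed gives
byte-identical outputs.

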