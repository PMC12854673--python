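"""End-to-end pipeline: simulate/ingest -> fit -> bootstrap -> analyses.

Stages run in dependency order; every stochastic stage consumes an
explicit seed derived from the config seed, all numeric outputs are
written at full precision, and a JSON manifest records the config hash,
stage seeds and outcomes — two runs with identical config produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np

from . import association_stats as assoc
from . import input_steering as steering
from . import region_importance as rimp
from . import state_dynamics as dyn
from .activity_maps import (map_significance, permuted_state_null,
                            state_regression, transition_responses)
from .bootstrap_ensemble import align_ensemble, centroid_stability, \
    resample_participants
from .config import AnalysisConfig
from .io_utils import read_paradigm, read_roi_table, write_matrix, \
    write_paradigm
from .slds_fit import FitConfig, fit, fit_group
from .slds_model import decode
from .stimulus_encoding import category_labels, encode_stimuli
from .synthetic_data import StudyConfig, SyntheticStudy, make_ground_truth
from .transfer import decode_transfer, state_by_timestep, transfer_significance

__all__ = ["run_pipeline", "PipelineLogger"]


class PipelineLogger:
    """JSON-lines event log; every stochastic stage logs its seed."""

    def __init__(self, path, level: str = "info"):
        self.path = Path(path)
        self.levels = {"debug": 0, "info": 1, "warning": 2, "error": 3}
        self.min_level = self.levels.get(level, 1)

    def event(self, stage: str, level: str, message: str, **context) -> None:
        if self.levels.get(level, 1) < self.min_level:
            return
        rec = {"stage": stage, "level": level, "message": message,
               "context": context}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _config_hash(cfg: AnalysisConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _ingest(cfg: AnalysisConfig) -> SyntheticStudy:
    runs_spec = cfg.paths["runs"]
    participants = {}
    for spec in runs_spec:
        roi = read_roi_table(spec["roi"])
        par = read_paradigm(spec["paradigm"])
        enc = encode_stimuli(par.proximity, par.direction, n_bins=cfg.n_bins,
                             lag_steps=cfg.lag_steps)
        pid = spec.get("participant", "sub000")
        participants.setdefault(pid, []).append(
            {"paradigm": par, "stimuli": enc, "roi": roi,
             "latents": None, "states": None})
    study = SyntheticStudy(true_params=None, participants=list(
        participants.values()), seed=cfg.seed)
    return study


def _decode_runs(params, Y_list, U_list):
    Zs, Xs = [], []
    for Y, U in zip(Y_list, U_list):
        res = decode(params, Y, U)
        Zs.append(res.Z)
        Xs.append(res.X)
    return Zs, Xs


def run_pipeline(config: AnalysisConfig, out_dir, log_level: str = "info") -> Path:
    """Execute the enabled stages, writing results and a manifest.

    Returns the output directory.  Any stage error halts the pipeline,
    persists the partial manifest, and re-raises with the stage name.
    """
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = PipelineLogger(out / "pipeline.log.jsonl", level=log_level)
    (out / "pipeline.log.jsonl").write_text("")
    manifest = {"config_hash": _config_hash(cfg), "config": cfg.to_dict(),
                "stages": {}, "version": 1}
    ctx = {}
    stage = None
    try:
        for stage in ("simulate", "fit", "bootstrap", "assoc", "dynamics",
                      "steering", "importance", "maps", "transfer"):
            if stage not in cfg.stages:
                manifest["stages"][stage] = {"status": "skipped"}
                log.event(stage, "info", "stage skipped")
                continue
            seed = _stage_seed(cfg.seed, stage)
            log.event(stage, "info", "stage start", seed=seed,
                      K=cfg.K, D=cfg.D)
            _STAGE_FUNCS[stage](cfg, ctx, out, seed, log)
            manifest["stages"][stage] = {"status": "ok", "seed": seed}
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        manifest["status"] = f"failed at {stage}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        log.event(stage or "pipeline", "error", str(exc))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _st_simulate(cfg, ctx, out, seed, log):
    if cfg.paths.get("runs"):
        study = _ingest(cfg)
        log.event("simulate", "info", "ingested user data",
                  n_participants=len(study.participants))
    else:
        sc = StudyConfig(**cfg.study) if cfg.study else StudyConfig()
        study = make_ground_truth(sc, seed=seed)
        write_paradigm(study.participants[0][0]["paradigm"],
                       out / "paradigm_run0.tsv")
        log.event("simulate", "info", "synthetic study generated",
                  n_participants=len(study.participants), T=sc.T)
    ctx["study"] = study
    ctx["Y_list"] = study.y_list()
    ctx["U_list"] = study.u_list()
    ctx["n_per_part"] = [len(p) for p in study.participants]


def _st_fit(cfg, ctx, out, seed, log):
    fc = FitConfig(max_iter=cfg.max_iter, tol=cfg.fit_tol,
                   n_restarts=cfg.n_restarts, seed=seed)
    fr = fit(ctx["Y_list"], ctx["U_list"], cfg.K, cfg.D, fc)
    ctx["fit"] = fr
    fr.params.to_json(out / "model.json")
    write_matrix(out / "objective_trace.tsv",
                 np.asarray(fr.objective_trace)[:, None],
                 col_labels=["objective"])
    Zs, Xs = _decode_runs(fr.params, ctx["Y_list"], ctx["U_list"])
    ctx["Z_group"], ctx["X_group"] = Zs, Xs
    log.event("fit", "info", "group fit done", converged=fr.converged,
              iters=len(fr.objective_trace))


def _st_bootstrap(cfg, ctx, out, seed, log):
    study = ctx["study"]
    multisets = resample_participants(study, cfg.B, seed=seed)
    params_list = []
    boot_runs = []
    fc = FitConfig(max_iter=cfg.max_iter, tol=cfg.fit_tol, n_restarts=1)
    for b, idx in enumerate(multisets):
        Y = [r["roi"].Y for i in idx for r in study.participants[i]]
        U = [r["stimuli"].U for i in idx for r in study.participants[i]]
        fc_b = FitConfig(**{**fc.__dict__, "seed": seed + 1000 * b})
        params_list.append(fit(Y, U, cfg.K, cfg.D, fc_b).params)
        boot_runs.append((Y, U))
    ens = align_ensemble(params_list, seed=seed)
    stable, b_used = centroid_stability(params_list, step=cfg.boot_step,
                                        tol=cfg.boot_tol, seed=seed)
    aligned = ens.aligned_params()
    # per-sample decodes under the aligned parameters
    boot_dec = []
    for p, (Y, U) in zip(aligned, boot_runs):
        Zs, Xs = _decode_runs(p, Y, U)
        boot_dec.append({"params": p, "Y": Y, "U": U, "Z": Zs, "X": Xs})
    ctx["ensemble"] = ens
    ctx["boot"] = boot_dec
    with open(out / "bootstrap_manifest.json", "w") as fh:
        json.dump({"B": cfg.B, "seed": seed,
                   "multisets": [m.tolist() for m in multisets],
                   "relabelings": [s["relabeling"].tolist()
                                   for s in ens.samples],
                   "centroid_stable": bool(stable), "B_stable": int(b_used)},
                  fh, indent=2, sort_keys=True)
    log.event("bootstrap", "info", "ensemble aligned", B=cfg.B,
              stable=bool(stable))


def _assoc_labels(cfg):
    return category_labels(cfg.n_bins)


def _st_assoc(cfg, ctx, out, seed, log):
    cols = _assoc_labels(cfg)
    K = cfg.K
    table = assoc.state_given_stimulus(ctx["Z_group"], ctx["U_list"],
                                       lag=cfg.lag_steps, K=K)
    transitions = assoc.select_transitions(ctx["Z_group"],
                                           top_n=cfg.top_transitions)
    ttable = assoc.transition_given_stimulus(ctx["Z_group"], ctx["U_list"],
                                             lag=cfg.lag_steps,
                                             transitions=transitions)
    reals, nulls, treals, tnulls = [], [], [], []
    rng = np.random.default_rng(seed)
    for b, sample in enumerate(ctx["boot"]):
        reals.append(assoc.state_given_stimulus(sample["Z"], sample["U"],
                                                lag=cfg.lag_steps, K=K))
        treals.append(assoc.transition_given_stimulus(
            sample["Z"], sample["U"], lag=cfg.lag_steps,
            transitions=transitions))
        Zn = assoc.surrogate_null(sample["Z"], 1,
                                  seed=int(rng.integers(2**31)))[0]
        nulls.append(assoc.state_given_stimulus(Zn, sample["U"],
                                                lag=cfg.lag_steps, K=K))
        tnulls.append(assoc.transition_given_stimulus(
            Zn, sample["U"], lag=cfg.lag_steps, transitions=transitions))
    mask, pvals = assoc.significance(np.array(reals), np.array(nulls),
                                     alpha=cfg.alpha,
                                     correction=cfg.correction)
    tmask, tpvals = assoc.significance(np.array(treals), np.array(tnulls),
                                       alpha=cfg.alpha,
                                       correction=cfg.correction)
    srows = [f"state{k}" for k in range(K)]
    trows = [f"{i}->{j}" for (i, j) in transitions]
    write_matrix(out / "state_given_stimulus.tsv", table, srows, cols)
    write_matrix(out / "state_given_stimulus_mask.tsv", mask.astype(int),
                 srows, cols)
    write_matrix(out / "transition_given_stimulus.tsv", ttable, trows, cols)
    write_matrix(out / "transition_given_stimulus_mask.tsv",
                 tmask.astype(int), trows, cols)
    ctx["assoc_mask"] = mask
    ctx["transitions"] = transitions
    log.event("assoc", "info", "association tables computed",
              n_transitions=len(transitions),
              n_significant=int(mask.sum()) + int(tmask.sum()))


def _st_dynamics(cfg, ctx, out, seed, log):
    aligned = [b["params"] for b in ctx["boot"]]
    params = ctx["fit"].params
    K = cfg.K
    A_stack = np.array([p.A for p in aligned])
    stab = dyn.stability_test(A_stack, alpha=cfg.alpha, K=K)
    rows = []
    geoms = {}
    for k in range(K):
        amap = dyn.attractor_map(aligned, k, alpha=cfg.alpha)
        geoms[k] = dyn.state_geometry(ctx["X_group"], ctx["Z_group"], k)
        rows.append(np.concatenate([[stab[k]["p"], float(stab[k]["stable"]),
                                     geoms[k].mean_lifetime,
                                     geoms[k].occupancy],
                                    amap.roi_projection]))
        write_matrix(out / f"attractor_state{k}.tsv",
                     np.column_stack([amap.roi_projection,
                                      amap.roi_mask.astype(float)]),
                     col_labels=["value", "significant"])
        try:
            path, modal, split = dyn.average_trajectory(
                ctx["X_group"], ctx["Z_group"], k, horizon=10)
            field = dyn.vector_field_2d(params.A[k], params.b[k], path)
            with open(out / f"trajectory_state{k}.json", "w") as fh:
                json.dump({"mean_path": path.tolist(),
                           "modal": modal.tolist(), "split_index": split,
                           "attractor_2d": field["attractor_2d"].tolist(),
                           "grid": field["grid"].tolist(),
                           "vectors": field["vectors"].tolist()},
                          fh, sort_keys=True)
        except ValueError:
            log.event("dynamics", "warning",
                      f"no trajectory windows for state {k}")
    write_matrix(out / "state_summary.tsv", np.array(rows),
                 row_labels=[f"state{k}" for k in range(K)],
                 col_labels=["p_unstable", "stable", "mean_lifetime",
                             "occupancy"] + [f"roi{i:03d}"
                                             for i in range(params.N)])
    ctx["geometry"] = geoms
    log.event("dynamics", "info", "attractors and geometry computed")


def _st_steering(cfg, ctx, out, seed, log):
    cols = _assoc_labels(cfg)
    K = cfg.K
    centroids = np.array([ctx["geometry"][k].centroid for k in range(K)])
    restriction = ctx.get("assoc_mask")
    stacks, tstacks = [], []
    for sample in ctx["boot"]:
        mt = steering.maintenance_table(sample["X"], sample["Z"], sample["U"],
                                        centroids, sample["params"],
                                        restriction=restriction,
                                        column_labels=cols)
        stacks.append(mt.values)
        tt = steering.transition_table(sample["X"], sample["Z"], sample["U"],
                                       centroids, sample["params"],
                                       ctx["transitions"], column_labels=cols)
        tstacks.append(tt.values)
    stacks = np.array(stacks)
    tstacks = np.array(tstacks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean_table = np.nanmean(stacks, axis=0)
        tmean = np.nanmean(tstacks, axis=0)
    try:
        mask, _ = steering.steering_significance(stacks, alpha=cfg.alpha)
        tmask, _ = steering.steering_significance(tstacks, alpha=cfg.alpha)
    except ValueError:       # fewer than 20 bootstrap samples
        mask = np.zeros(mean_table.shape, dtype=bool)
        tmask = np.zeros(tmean.shape, dtype=bool)
        log.event("steering", "warning",
                  "too few bootstrap samples for significance")
    srows = [f"state{k}" for k in range(K)]
    trows = [f"{i}->{j}" for (i, j) in ctx["transitions"]]
    write_matrix(out / "steering_maintenance.tsv", mean_table, srows, cols)
    write_matrix(out / "steering_maintenance_mask.tsv", mask.astype(int),
                 srows, cols)
    write_matrix(out / "steering_transitions.tsv", tmean, trows, cols)
    write_matrix(out / "steering_transitions_mask.tsv", tmask.astype(int),
                 trows, cols)
    log.event("steering", "info", "steering tables computed")


def _st_importance(cfg, ctx, out, seed, log):
    params = ctx["fit"].params
    dsd = rimp.project_dynamics(params)
    series = []
    for Y, Z, U in zip(ctx["Y_list"], ctx["Z_group"], ctx["U_list"]):
        raw = rimp.importance(Y, Z, U, dsd)
        series.append(rimp.normalize_importance(raw))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN first rows
        mean_imp = np.nanmean(np.array([s.q for s in series]), axis=0)
    write_matrix(out / "importance_mean.tsv", mean_imp,
                 col_labels=series[0].roi_names)
    for k in range(cfg.K):
        try:
            locked, counts = rimp.state_locked_importance(series, k)
        except ValueError:
            continue
        write_matrix(out / f"importance_state{k}.tsv", locked,
                     col_labels=series[0].roi_names)
    log.event("importance", "info", "importance series computed")


def _st_maps(cfg, ctx, out, seed, log):
    K = cfg.K
    # participant-level maps under the group decode
    offsets = np.cumsum([0] + ctx["n_per_part"])
    def part_maps(Y_list, Z_list, slices):
        maps = []
        for lo, hi in slices:
            Y = np.concatenate(Y_list[lo:hi], axis=0)
            Z = np.concatenate(Z_list[lo:hi], axis=0)
            maps.append(state_regression(Y, Z, K=K).beta)
        return np.array(maps)            # (P, K, N)
    slices = list(zip(offsets[:-1], offsets[1:]))
    group_maps = part_maps(ctx["Y_list"], ctx["Z_group"], slices).mean(axis=0)
    # bootstrap stacks: average of participant maps per sample; nulls from
    # permuted labels
    rng = np.random.default_rng(seed)
    reals, nulls = [], []
    for sample in ctx["boot"]:
        # within a bootstrap sample each resampled run is one map unit
        sl = [(i, i + 1) for i in range(len(sample["Y"]))]
        reals.append(part_maps(sample["Y"], sample["Z"], sl).mean(axis=0))
        Zn = permuted_state_null(sample["Z"], seed=int(rng.integers(2**31)))
        nulls.append(part_maps(sample["Y"], Zn, sl).mean(axis=0))
    reals = np.array(reals)
    nulls = np.array(nulls)
    N = group_maps.shape[1]
    masks = np.zeros((K, N), dtype=bool)
    for k in range(K):
        try:
            masks[k], _ = map_significance(reals[:, k, :], nulls[:, k, :],
                                           alpha=cfg.alpha,
                                           n_comparisons=K * N)
        except ValueError:
            pass
    write_matrix(out / "state_maps.tsv", group_maps,
                 row_labels=[f"state{k}" for k in range(K)],
                 col_labels=[f"roi{i:03d}" for i in range(N)])
    write_matrix(out / "state_maps_mask.tsv", masks.astype(int),
                 row_labels=[f"state{k}" for k in range(K)],
                 col_labels=[f"roi{i:03d}" for i in range(N)])
    # transition-window responses for the selected transitions
    for (i, j) in ctx["transitions"][:3]:
        try:
            tr = transition_responses(ctx["Y_list"], ctx["Z_group"], (i, j))
            write_matrix(out / f"transition_response_{i}_{j}.tsv", tr.mean)
        except ValueError:
            pass
    log.event("maps", "info", "activity maps computed")


def _st_transfer(cfg, ctx, out, seed, log):
    study = ctx["study"]
    params = ctx["fit"].params
    # events: shock onsets of each run's paradigm
    events = []
    for part in study.participants:
        for run in part:
            shocks = np.nonzero(run["paradigm"].shock)[0] \
                if run["paradigm"] is not None else np.array([], dtype=int)
            events.append(shocks)
    Zs, _ = decode_transfer(params, ctx["Y_list"],
                            U_new_list=ctx["U_list"])
    table = transfer_significance(Zs, events, K=cfg.K, n_null=cfg.n_null,
                                  seed=seed, alpha=cfg.alpha,
                                  tr_s=cfg.tr_s)
    write_matrix(out / "transfer_state_by_step.tsv", table.values,
                 row_labels=[f"state{k}" for k in range(cfg.K)],
                 col_labels=[f"t{int(s)}" for s in table.window_steps])
    write_matrix(out / "transfer_mask.tsv", table.mask.astype(int),
                 row_labels=[f"state{k}" for k in range(cfg.K)],
                 col_labels=[f"t{int(s)}" for s in table.window_steps])
    log.event("transfer", "info", "transfer tables computed",
              n_windows=table.n_windows)


_STAGE_FUNCS = {
    "simulate": _st_simulate,
    "fit": _st_fit,
    "bootstrap": _st_bootstrap,
    "assoc": _st_assoc,
    "dynamics": _st_dynamics,
    "steering": _st_steering,
    "importance": _st_importance,
    "maps": _st_maps,
    "transfer": _st_transfer,
}
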