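"""End-to-end pipeline: simulate → decompose → kernel → map → ethogram → stats.

Configuration is a TOML file with ``[arena]``, ``[protocol]``,
``[simulation]``, ``[decomposition]``, ``[kernel]``, ``[map]``,
``[detectors]`` and ``[stats]`` tables (all optional; defaults apply).
``run_pipeline`` executes every stage in order, writes all artifacts as
TSV/HDF5/JSON under an output directory, and records a machine-readable run
manifest (package version, seed, config hash, per-stage counts) so a run
can be reproduced byte-for-byte from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena_events import compute_trial_metrics, detect_center_entry, detect_refuge_transitions, metrics_table
from .behavior_map import (
    BehaviorMap,
    DefensiveThresholds,
    build_feature_space,
    cluster_phenotypes,
    detect_defensive,
    embed_nm,
)
from .config import ArenaGeometry, StimulusProtocol, arena_from_dict, protocol_from_dict
from .decomposition import compute_locomotion, egocentric_align, segment_nm, zscore_velocity
from .dtak import kernel_matrix
from .errors import ConfigError
from .ethogram import (
    EpochWindows,
    Ethogram,
    classify_freezing_group,
    compare_groups,
    fraction_table,
    fractions,
    window_ethogram,
)
from .io import (
    write_behavior_map_tsv,
    write_ethogram_tsv,
    write_ground_truth,
    write_kernel_h5,
    write_pose_csv,
    write_segments_tsv,
    write_trajectory,
)
from .synthetic import simulate_cohort

log = logging.getLogger("loomkit")


def load_config(path) -> dict:
    path = Path(path)
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "arena" not in cfg:
        raise ConfigError(f"{path}: missing required [arena] table")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir, seed: int = 0) -> dict:
    """Run the full analysis on a simulated cohort; returns the manifest.

    Stages: simulate cohort → per-trial decomposition → pooled DTAK kernel →
    UMAP + locomotion feature space → phenotype clustering → defensive
    detection → ethogram windows/fractions → trial metrics → group stats.
    Any stage failure aborts with a stage-named message; artifacts written
    so far are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    arena = arena_from_dict(cfg.get("arena", {}))
    protocol = protocol_from_dict(cfg.get("protocol", {}))
    sim = dict(cfg.get("simulation", {}))
    dec = dict(cfg.get("decomposition", {}))
    ker = dict(cfg.get("kernel", {}))
    mp = dict(cfg.get("map", {}))
    det = dict(cfg.get("detectors", {}))
    st = dict(cfg.get("stats", {}))

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done", name)
            return result

        return deco

    # -- simulate ---------------------------------------------------------
    @stage("simulate")
    def _sim():
        trials, design = simulate_cohort(
            n_male=int(sim.get("n_male", 5)),
            n_female=int(sim.get("n_female", 5)),
            p_freeze_male=float(sim.get("p_freeze_male", 0.7)),
            p_freeze_female=float(sim.get("p_freeze_female", 0.5)),
            params={
                "arena": arena,
                "protocol": protocol,
                "frame_rate": float(sim.get("frame_rate", 30.0)),
                "noise_sd": float(sim.get("noise_sd", 0.2)),
                "acclimation_s": float(sim.get("acclimation_s", 60.0)),
                "p_escape": float(sim.get("p_escape", 0.9)),
            },
            seed=seed,
        )
        design.to_csv(outdir / "design.tsv", sep="\t", index=False)
        for trial in trials[: int(sim.get("save_pose_trials", 2))]:
            write_pose_csv(trial.skeleton, outdir / f"pose_{trial.animal_id}.csv")
        for trial in trials:
            write_trajectory(trial.trajectory, outdir / f"traj_{trial.animal_id}.tsv")
            write_ground_truth(
                trial.ground_truth,
                outdir / f"events_{trial.animal_id}.tsv",
                outdir / f"labels_{trial.animal_id}.tsv",
            )
        return trials, design

    trials, design = _sim
    manifest["stages"]["simulate"] = {"n_trials": len(trials)}

    # -- decompose --------------------------------------------------------
    @stage("decompose")
    def _dec():
        window = int(dec.get("window_frames", 12))
        smooth = int(dec.get("smooth_window", 5))
        all_segments = []
        for trial in trials:
            aligned = egocentric_align(trial.skeleton, trial_id=trial.animal_id)
            speeds = compute_locomotion(trial.skeleton, smooth_window=smooth)
            all_segments.extend(segment_nm(aligned, window_frames=window, speeds=speeds))
        write_segments_tsv(all_segments, outdir / "segments.tsv")
        return all_segments

    segments = _dec
    manifest["stages"]["decompose"] = {"n_segments": len(segments)}

    # -- kernel -----------------------------------------------------------
    max_seg = int(ker.get("max_segments", 400))
    if len(segments) > max_seg:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(segments), size=max_seg, replace=False))
        segments = [segments[i] for i in keep]
        log.info("subsampled to %d segments for the kernel stage", max_seg)

    @stage("kernel")
    def _ker():
        K = kernel_matrix(segments, sigma=ker.get("sigma"), normalized=True)
        write_kernel_h5(K, outdir / "kernel.h5")
        return K

    K = _ker
    manifest["stages"]["kernel"] = {"n_segments": K.n, "sigma": K.sigma}

    # -- map --------------------------------------------------------------
    @stage("map")
    def _map():
        emb = embed_nm(
            K,
            n_neighbors=int(mp.get("n_neighbors", 15)),
            min_dist=float(mp.get("min_dist", 0.1)),
            seed=seed,
        )
        loco = zscore_velocity([s.mean_speed for s in segments])
        pts = build_feature_space(emb, loco)
        k = int(mp.get("k", min(40, len(segments) - 1)))
        pid = cluster_phenotypes(pts, k=k, method=mp.get("method", "ward"), seed=seed)
        bmap = BehaviorMap(
            umap1=emb[:, 0],
            umap2=emb[:, 1],
            loco=loco,
            phenotype_id=pid,
            k=k,
            segment_ids=[s.segment_id for s in segments],
        )
        write_behavior_map_tsv(bmap, outdir / "behavior_map.tsv")
        return bmap

    bmap = _map
    manifest["stages"]["map"] = {"k": bmap.k}

    # -- ethogram + detectors --------------------------------------------
    thresholds = DefensiveThresholds(
        **{k: v for k, v in det.items() if k in DefensiveThresholds.__dataclass_fields__}
    )

    @stage("ethogram")
    def _etho():
        ethos = {}
        groups = {}
        for trial in trials:
            gt = trial.ground_truth
            etho = Ethogram(
                gt.labels, gt.frame_rate, trial_id=trial.animal_id, sex=trial.sex
            )
            if gt.stimulus_onset is not None:
                flight, freezing = detect_defensive(
                    trial.skeleton, trial.trajectory, gt.stimulus_onset, arena, thresholds
                )
                etho = etho.with_defensive(flight, freezing)
                groups[trial.animal_id] = classify_freezing_group(etho, gt.stimulus_onset)
            ethos[trial.animal_id] = etho
            write_ethogram_tsv(etho, outdir / f"ethogram_{trial.animal_id}.tsv")
        pd.Series(groups, name="group").to_csv(outdir / "groups.tsv", sep="\t")
        return ethos, groups

    ethos, groups = _etho
    manifest["stages"]["ethogram"] = {
        "n_freezing": sum(g == "Freezing" for g in groups.values())
    }

    # -- metrics ----------------------------------------------------------
    @stage("metrics")
    def _metrics():
        per_animal = {}
        for trial in trials:
            traj = trial.trajectory
            trigger = detect_center_entry(traj, arena)
            if trigger is None:
                continue
            transitions = detect_refuge_transitions(traj, arena)
            gt = trial.ground_truth
            per_animal[trial.animal_id] = compute_trial_metrics(
                traj,
                trigger,
                gt.flight_onset,
                transitions,
                acclimation_window=(0.0, trigger),
                arena=arena,
            )
        table = metrics_table(per_animal)
        table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        return table

    mtable = _metrics
    manifest["stages"]["metrics"] = {
        "n_trials": len(mtable),
        "escape_pct": float(100.0 * mtable["escaped"].mean()) if len(mtable) else None,
    }

    # -- stats ------------------------------------------------------------
    @stage("stats")
    def _stats():
        per_fracs = {}
        for trial in trials:
            gt = trial.ground_truth
            if gt.stimulus_onset is None or gt.refuge_entry is None:
                continue
            windows = EpochWindows.from_events(gt.stimulus_onset, gt.refuge_entry, gt.refuge_exit)
            sub = window_ethogram(ethos[trial.animal_id], windows)
            if "refuge" in sub:
                per_fracs[trial.animal_id] = fractions(sub["refuge"])
        if len(per_fracs) < 4:
            return None
        table = fraction_table(per_fracs)
        dsg = design[design["animal_id"].isin(table.index)]
        if dsg["sex"].nunique() < 2 or (dsg["sex"].value_counts() < 2).any():
            return None
        cmp = compare_groups(table, dsg, group_col="sex", alpha=float(st.get("alpha", 0.05)))
        cmp.posthoc.to_csv(outdir / "posthoc.tsv", sep="\t", index=False)
        cmp.anova.to_csv(outdir / "anova.tsv", sep="\t", index=False)
        return cmp

    comparison = _stats
    manifest["stages"]["stats"] = {"ran": comparison is not None}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
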