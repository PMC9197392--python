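"""End-to-end orchestration: simulate -> analyze -> compare.

A run reproduces, on synthetic sessions with known ground truth, the
structure of the study's comparisons: per-unit evoked-response tables for
every genotype x state x epoch cell, paired pre/post theta-burst
statistics per region and state, between-genotype group statistics, a
state x genotype ANOVA, plus the behavioral read-outs (gait metrics,
open-field locomotion, active wake, dystonia-score aggregation).

One root seed governs the whole run; per-stage seeds are derived from it
through ``numpy.random.SeedSequence((root_seed, *stage_indices))`` so
stages are independent yet fully reproducible: identical configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults as d
from . import gait as gait_mod
from . import io as cio
from . import openfield, responses, stats
from .simulate import (
    EphysSimConfig,
    GaitSimConfig,
    TrajectorySimConfig,
    gen_evoked_train,
    gen_footprints,
    gen_protocol,
    gen_trajectory,
)
from .types import EPOCHS, GENOTYPES, REGIONS, STATES, BehaviorScoreSeries

log = logging.getLogger("cerebellopipe")

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class RunConfig:
    """All constants of a full pipeline run, with their defaults."""

    seed: int = 0
    n_units_per_region: int = 40
    n_pulses: int = 150          # low-frequency probing pulses per session
    regions: tuple = REGIONS
    genotypes: tuple = GENOTYPES
    states: tuple = STATES
    epochs: tuple = EPOCHS
    genotype_gain: dict = field(default_factory=lambda: dict(d.GENOTYPE_GAIN))
    state_rate_factor: dict = field(
        default_factory=lambda: dict(d.STATE_RATE_FACTOR))
    plasticity_gain: dict = field(
        default_factory=lambda: dict(d.PLASTICITY_GAIN))
    gait: GaitSimConfig = field(default_factory=GaitSimConfig)
    gait_trials: int = 3
    trajectory: TrajectorySimConfig = field(
        default_factory=TrajectorySimConfig)
    score_blocks: int = 6        # 10-min blocks of dystonia scoring
    alpha: float = 0.05

    @property
    def session_duration(self) -> float:
        return self.n_pulses * d.LOW_FREQ_PERIOD_S


def derive_seed(root: int, *indices: int) -> int:
    """Deterministic per-stage sub-seed from the root seed."""
    ss = np.random.SeedSequence((root, *indices))
    return int(ss.generate_state(1)[0])


def _sanitize(v):
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        v = dataclasses.asdict(v)
    if isinstance(v, dict):
        return {str(k): _sanitize(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_sanitize(x) for x in v]
    if isinstance(v, np.generic):
        return v.item()
    return v


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_sanitize(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_responses(cfg: RunConfig) -> pd.DataFrame:
    """Per-unit response summaries over every genotype x state x epoch x
    region cell, with the simulation ground truth alongside."""
    protocol = gen_protocol("low_freq", cfg.session_duration)
    rows = []
    for gi, genotype in enumerate(cfg.genotypes):
        for si, state in enumerate(cfg.states):
            for ei, epoch in enumerate(cfg.epochs):
                plast = (cfg.plasticity_gain[(genotype, state)]
                         if epoch == "post_burst" else 1.0)
                for ri, region in enumerate(cfg.regions):
                    for ui in range(cfg.n_units_per_region):
                        sim = EphysSimConfig(
                            genotype_gain=cfg.genotype_gain[genotype],
                            state_rate_factor=cfg.state_rate_factor[state],
                            plasticity_gain=plast,
                            seed=derive_seed(cfg.seed, gi, si, ei, ri, ui),
                        )
                        unit_id = f"{genotype}_{state}_{region}_{ui:03d}"
                        train, truth = gen_evoked_train(
                            sim, protocol, region, cfg.session_duration,
                            unit_id=unit_id)
                        summ = responses.summarize_response(train, protocol)
                        rows.append({
                            "genotype": genotype, "state": state,
                            "epoch": epoch, "region": region,
                            **dataclasses.asdict(summ),
                            "true_baseline_rate": truth["true_baseline_rate"],
                            "true_evoked_delta": truth["true_evoked_delta"],
                        })
    return pd.DataFrame(rows)


def paired_prepost_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Paired Wilcoxon of post- vs pre-burst evoked rate change, per
    genotype x state x region (units are paired by id)."""
    rows = []
    for (genotype, state, region), grp in df.groupby(
            ["genotype", "state", "region"], sort=True):
        pre = grp[grp.epoch == "pre_burst"].sort_values("unit_id")
        post = grp[grp.epoch == "post_burst"].sort_values("unit_id")
        cmp_ = stats.compare_pre_post(
            pre["delta_rate"].to_numpy(), post["delta_rate"].to_numpy(),
            unit_ids=tuple(pre["unit_id"]))
        rows.append({
            "genotype": genotype, "state": state, "region": region,
            "test": "wilcoxon", "n": len(pre),
            "effect_median_post_minus_pre": cmp_.effect,
            "statistic": cmp_.statistic, "p_value": cmp_.p_value,
            "stars": stats.stars(cmp_.p_value),
        })
    return pd.DataFrame(rows)


def genotype_group_stats(df: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney WT vs mutant on the pre-burst evoked rate change,
    per state x region."""
    rows = []
    pre = df[df.epoch == "pre_burst"]
    for (state, region), grp in pre.groupby(["state", "region"], sort=True):
        a = grp[grp.genotype == "WT"]["delta_rate"].to_numpy()
        b = grp[grp.genotype == "GNAL"]["delta_rate"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        cmp_ = stats.compare_groups(a, b, labels=("WT", "GNAL"))
        rows.append({
            "state": state, "region": region, "test": cmp_.test,
            "n_wt": a.size, "n_gnal": b.size,
            "statistic": cmp_.statistic, "p_value": cmp_.p_value,
            "stars": stats.stars(cmp_.p_value),
        })
    return pd.DataFrame(rows)


def state_genotype_anova(df: pd.DataFrame, region: str) -> pd.DataFrame:
    """Two-way state x genotype ANOVA on pre-burst evoked rate changes."""
    pre = df[(df.epoch == "pre_burst") & (df.region == region)]
    return stats.two_way_anova(pre["delta_rate"], pre["state"],
                               pre["genotype"])


def _simulate_scores(cfg: RunConfig, genotype: str) -> BehaviorScoreSeries:
    """Two-rater ordinal dystonia scores: mutants under the agonist score
    high, wild types low (simulation choice)."""
    rng = np.random.default_rng(
        derive_seed(cfg.seed, 90, cfg.genotypes.index(genotype)))
    center = 3.0 if genotype == "GNAL" else 1.0
    raters = []
    base = np.clip(np.round(rng.normal(center, 0.5, cfg.score_blocks)), 0, 4)
    for _ in range(2):
        jitter = rng.integers(-1, 2, cfg.score_blocks) * \
            (rng.uniform(size=cfg.score_blocks) < 0.2)
        raters.append(np.clip(base + jitter, 0, 4).astype(int))
    return BehaviorScoreSeries(np.vstack(raters), ("rater_a", "rater_b"))


def run_experiment(cfg: RunConfig, out_dir) -> dict:
    """Execute the full synthetic pipeline and write the report bundle.

    Writes ``responses.csv`` (per-unit, all cells), ``prepost_stats.csv``,
    ``genotype_stats.csv``, ``anova_<region>.csv``, ``gait.csv``,
    ``openfield.json``, ``scores.json`` and ``manifest.json`` under
    ``out_dir``.  Identical config + seed reproduce byte-identical
    numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", cfg)

    df = simulate_responses(cfg)
    df.to_csv(out / "responses.csv", index=False, float_format=_FLOAT_FMT)
    for (genotype, state, epoch), grp in df.groupby(
            ["genotype", "state", "epoch"], sort=True):
        cell_dir = out / "cells"
        cell_dir.mkdir(exist_ok=True)
        grp.to_csv(cell_dir / f"{genotype}_{state}_{epoch}.csv",
                   index=False, float_format=_FLOAT_FMT)

    prepost = paired_prepost_stats(df)
    prepost.to_csv(out / "prepost_stats.csv", index=False,
                   float_format=_FLOAT_FMT)
    groups = genotype_group_stats(df)
    groups.to_csv(out / "genotype_stats.csv", index=False,
                  float_format=_FLOAT_FMT)
    anova_tables = {}
    for region in cfg.regions:
        table = state_genotype_anova(df, region)
        table.to_csv(out / f"anova_{region}.csv", float_format=_FLOAT_FMT)
        anova_tables[region] = table

    # --- behavior ---------------------------------------------------------
    gait_rows = []
    for gi, genotype in enumerate(cfg.genotypes):
        trials = []
        for t in range(cfg.gait_trials):
            gcfg = dataclasses.replace(
                cfg.gait, seed=derive_seed(cfg.seed, 80, gi, t))
            fp, _ = gen_footprints(gcfg)
            trials.append(gait_mod.compute_gait_metrics(fp))
        avg = gait_mod.average_trials(trials)
        gait_rows.append({"genotype": genotype,
                          **dataclasses.asdict(avg)})
    pd.DataFrame(gait_rows).to_csv(out / "gait.csv", index=False,
                                   float_format=_FLOAT_FMT)

    of_report = {}
    for gi, genotype in enumerate(cfg.genotypes):
        tcfg = dataclasses.replace(
            cfg.trajectory, seed=derive_seed(cfg.seed, 81, gi))
        traj, _ = gen_trajectory(tcfg)
        metrics = openfield.occupancy_metrics(traj)
        aw = openfield.active_wake(traj)
        of_report[genotype] = {
            "total_distance_cm": metrics.total_distance,
            "median_speed_cm_s": metrics.median_speed,
            "thigmotaxis_index": metrics.thigmotaxis_index,
            "pct_time_center": metrics.pct_time_center,
            "active_wake_pct": aw.aw_pct,
        }
    (out / "openfield.json").write_text(json.dumps(of_report, indent=2,
                                                   sort_keys=True))

    score_report = {}
    for genotype in cfg.genotypes:
        series = _simulate_scores(cfg, genotype)
        block_means, summary = openfield.aggregate_scores(series)
        score_report[genotype] = {
            "block_means": block_means.tolist(), **summary}
    (out / "scores.json").write_text(json.dumps(score_report, indent=2,
                                                sort_keys=True))

    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_cells": int(df.groupby(["genotype", "state", "epoch",
                                   "region"]).ngroups),
        "n_units": int(len(df)),
        "constants": {
            "bin_width_s": d.BIN_WIDTH_S,
            "baseline_s": d.BASELINE_S,
            "responsive_k": d.RESPONSIVE_K,
            "fast_spiking_threshold_hz": d.FAST_SPIKING_THRESHOLD_HZ,
            "volley_windows_s": d.VOLLEY_WINDOWS_S,
            "thigmotaxis_fraction": d.THIGMOTAXIS_FRACTION,
            "center_fraction": d.CENTER_FRACTION,
            "active_speed_cm_s": d.ACTIVE_SPEED_CM_S,
            "min_bout_s": d.MIN_BOUT_S,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "responses": df,
        "prepost": prepost,
        "groups": groups,
        "anova": anova_tables,
        "openfield": of_report,
        "scores": score_report,
        "manifest": manifest,
    }
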