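"""End-to-end orchestration: simulate behavior, synthesize and preprocess
recordings, compute per-channel synchronization, run the group statistics,
and the directional (Granger) analysis at the flagged channel.

Recordings are regenerated deterministically from per-dyad substreams of
the master seed, so the directional analysis can re-derive any dyad's
signals without holding the whole cohort in memory.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, causality, coherence, preprocessing, signal_synthesis, stats, task_model
from .config import RunConfig
from .errors import DyadsyncError
from .io import write_events_tsv, write_recording_tsv, write_snirf, write_table
from .task_model import DyadSession

__all__ = ["run_full", "dyad_seed_sequences", "preprocess_recording", "behavior_report"]

_GROUP_ORDER = ("delayed", "immediate", "none")


def dyad_seed_sequences(master_seed: int, n_dyads: int) -> list[np.random.SeedSequence]:
    """Counter-based per-dyad substreams of the master seed (the same
    spawning scheme the cohort simulator uses)."""
    return np.random.SeedSequence(master_seed).spawn(n_dyads)


def synthesize_dyad(
    session: DyadSession, cfg: RunConfig, seed: np.random.SeedSequence
) -> signal_synthesis.HyperscanRecording:
    """Synthesize one dyad's raw recording (with optional artifacts)."""
    rng = np.random.default_rng(seed)
    rec = signal_synthesis.synthesize_dyad_recording(
        session,
        layout=cfg.layout,
        acq=cfg.acquisition,
        coupling=cfg.coupling,
        noise=cfg.noise,
        seed=rng,
    )
    if cfg.pipeline.inject_artifacts and cfg.noise.artifact_rate > 0:
        rec, _ = signal_synthesis.inject_motion_artifacts(rec, cfg.noise, seed=rng)
    return rec


def preprocess_recording(
    rec: signal_synthesis.HyperscanRecording, cfg: RunConfig
) -> tuple[signal_synthesis.HyperscanRecording, list[preprocessing.ChannelQuality]]:
    """Quality screening, OD conversion, motion correction, Beer-Lambert."""
    rec, quality = preprocessing.reject_low_snr(rec, threshold=cfg.pipeline.snr_threshold)
    od = preprocessing.intensity_to_od(rec)
    mask = preprocessing.detect_motion_artifacts(od, cfg.artifacts)
    od = preprocessing.correct_motion(od, mask, cfg.artifacts)
    hb = preprocessing.od_to_hb(od)
    return hb, quality


def _dyad_hb(session: DyadSession, cfg: RunConfig, seed: np.random.SeedSequence):
    return preprocess_recording(synthesize_dyad(session, cfg, seed), cfg)


def behavior_report(sessions: Sequence[DyadSession]) -> dict:
    """Group ANOVAs and correlations over the behavioral summaries."""
    summ = task_model.summaries_to_frame(sessions)
    groups = {g: summ[summ["strategy"] == g] for g in _GROUP_ORDER if (summ["strategy"] == g).any()}
    report: dict = {"n_dyads": len(summ), "group_sizes": {g: len(v) for g, v in groups.items()}}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        labels = list(groups)
        for metric in ("mean_rt_s", "wr", "mean_rtd_s", "mean_threshold_s", "cc_s"):
            try:
                res = stats.one_way_anova([groups[g][metric] for g in labels], labels=labels)
            except DyadsyncError as exc:
                report[f"anova_{metric}"] = {"skipped": str(exc)}
                continue
            report[f"anova_{metric}"] = res.as_dict()
    for a, b, name in (
        ("cc_s", "wr", "corr_cc_wr"),
        ("mean_rtd_s", "wr", "corr_rtd_wr"),
        ("mean_threshold_s", "wr", "corr_threshold_wr"),
    ):
        try:
            c = stats.pearson_r(summ[a], summ[b])
        except DyadsyncError as exc:
            report[name] = {"skipped": str(exc)}
            continue
        report[name] = {"r": c.r, "n": c.n, "p": c.p}
    return report


def ibs_group_stats(ibs_df: pd.DataFrame, cfg: RunConfig) -> dict:
    """Per-group, per-channel one-sample t tests on the Fisher-Z contrast
    with BH-FDR across channels, plus per-channel between-group ANOVA."""
    report: dict = {"groups": {}, "anova_by_channel": {}, "fdr_q": cfg.stats.fdr_q}
    for group, gdf in ibs_df.groupby("strategy"):
        pvals, tstats, means = {}, {}, {}
        for ch, cdf in gdf[gdf["valid"]].groupby("channel"):
            vals = cdf["ibs_z"].to_numpy()
            if vals.size < 2 or np.std(vals, ddof=1) == 0:
                continue
            res = stats.one_sample_t(vals, tail=cfg.stats.ibs_tail)
            pvals[int(ch)] = res.p
            tstats[int(ch)] = res.t
            means[int(ch)] = float(np.mean(vals))
        entry = {"t": tstats, "p": pvals, "mean_ibs_z": means}
        if pvals:
            fdr = stats.bh_fdr(pvals, q=cfg.stats.fdr_q)
            entry["fdr_passed"] = sorted(fdr.passed)
            entry["fdr_adjusted_p"] = fdr.adjusted_p
        else:
            entry["fdr_passed"] = []
            entry["fdr_adjusted_p"] = {}
        report["groups"][group] = entry

    valid = ibs_df[ibs_df["valid"]]
    for ch, cdf in valid.groupby("channel"):
        by_group = [
            cdf[cdf["strategy"] == g]["ibs_z"].to_numpy()
            for g in _GROUP_ORDER
            if (cdf["strategy"] == g).sum() >= 2
        ]
        if len(by_group) >= 2:
            try:
                res = stats.one_way_anova(by_group, posthoc=False)
            except DyadsyncError:
                continue
            report["anova_by_channel"][int(ch)] = {
                "f": res.f,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "eta_p2": res.eta_p2,
            }
    return report


def _pick_gca_channel(report: dict, cfg: RunConfig) -> int | None:
    if isinstance(cfg.gca.channel, int):
        return cfg.gca.channel
    group = report["groups"].get(cfg.gca.group, {})
    passed = group.get("fdr_passed", [])
    if not passed:
        return None
    means = group.get("mean_ibs_z", {})
    return max(passed, key=lambda ch: means.get(ch, -np.inf))


def run_full(cfg: RunConfig, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Execute every stage and write result tables, reports, and the run
    manifest to the output directory.  Returns the manifest."""
    t_start = time.time()
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = cfg.master_seed if seed is None else int(seed)

    manifest: dict = {
        "version": __version__,
        "master_seed": master_seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "files": [],
    }
    files: list[str] = manifest["files"]

    def _record(path: Path):
        files.append(str(path.relative_to(out)))

    cfg.dump_yaml(out / "config.yaml")
    _record(out / "config.yaml")

    # --- behavior -------------------------------------------------------
    t0 = time.time()
    sessions = task_model.simulate_cohort(
        group_sizes=cfg.task.group_sizes, seed=master_seed, tie_rule=cfg.task.tie_rule
    )
    _record(write_table(task_model.trials_to_frame(sessions), out / "behavior_trials.tsv"))
    _record(write_table(task_model.summaries_to_frame(sessions), out / "behavior_summary.tsv"))
    behav = behavior_report(sessions)
    manifest["stages"]["behavior"] = {"seconds": round(time.time() - t0, 3), "n_dyads": len(sessions)}

    # --- signals / preprocessing / synchronization ----------------------
    t0 = time.time()
    seeds = dyad_seed_sequences(master_seed, len(sessions))
    ibs_rows = []
    quality_rows = []
    for session, sseq in zip(sessions, seeds):
        hb, quality = _dyad_hb(session, cfg, sseq)
        if cfg.pipeline.save_recordings:
            if cfg.pipeline.recording_format == "snirf":
                p1, p2 = write_snirf(hb, out / "recordings")
                _record(p1)
                _record(p2)
            else:
                (out / "recordings").mkdir(exist_ok=True)
                _record(write_recording_tsv(hb, out / "recordings" / f"{session.dyad_id}_hb.tsv"))
            _record(write_events_tsv(hb.timeline, out / "recordings" / f"{session.dyad_id}_events.tsv"))
        for q in quality:
            quality_rows.append(
                {
                    "dyad_id": session.dyad_id,
                    "participant": q.participant + 1,
                    "channel": q.channel,
                    "snr_ratio": q.snr_ratio,
                    "rejected": q.rejected,
                }
            )
        for r in coherence.ibs_per_dyad(
            hb,
            params=cfg.wavelet,
            band=cfg.band,
            baseline=cfg.pipeline.baseline_segments,
            single_precision=cfg.pipeline.single_precision,
        ):
            ibs_rows.append(
                {
                    "dyad_id": r.dyad_id,
                    "strategy": session.strategy.value,
                    "channel": r.channel,
                    "coh_task": r.coh_task,
                    "coh_rest": r.coh_rest,
                    "ibs": r.ibs,
                    "ibs_z": r.ibs_z,
                    "valid": r.valid,
                }
            )
    ibs_df = pd.DataFrame(ibs_rows)
    _record(write_table(ibs_df, out / "ibs.tsv"))
    _record(write_table(pd.DataFrame(quality_rows), out / "channel_quality.tsv"))
    manifest["stages"]["synchronization"] = {"seconds": round(time.time() - t0, 3)}

    # --- group statistics ----------------------------------------------
    t0 = time.time()
    ibs_stats = ibs_group_stats(ibs_df, cfg)
    summ = task_model.summaries_to_frame(sessions)
    target = _pick_gca_channel(ibs_stats, cfg)
    if target is not None:
        ch_ibs = ibs_df[(ibs_df["channel"] == target) & ibs_df["valid"]]
        merged = ch_ibs.merge(summ, on="dyad_id")
        if len(merged) >= 3:
            for metric, name in (("cc_s", "corr_ibs_cc"), ("wr", "corr_ibs_wr")):
                c = stats.pearson_r(merged["ibs_z"], merged[metric])
                ibs_stats[name] = {"r": c.r, "n": c.n, "p": c.p, "channel": target}
    manifest["stages"]["stats"] = {"seconds": round(time.time() - t0, 3)}

    # --- directional analysis -------------------------------------------
    t0 = time.time()
    gca_out: dict = {"channel": target}
    if target is not None:
        group_sessions = [
            (s, sq)
            for s, sq in zip(sessions, seeds)
            if s.strategy.value == cfg.gca.group
        ]
        recs = [
            _dyad_hb(s, cfg, sq)[0] for s, sq in group_sessions
        ]
        try:
            gc_results, gc_report = causality.cohort_gc(
                recs, target, max_order=cfg.gca.max_order, order=cfg.gca.order
            )
            gca_out.update(gc_report)
            gc_df = pd.DataFrame(
                [
                    {
                        "dyad_id": r.dyad_id,
                        "channel": r.channel,
                        "order": r.order,
                        "gc_1_to_2": r.gc_x_to_y,
                        "gc_2_to_1": r.gc_y_to_x,
                        "f_1_to_2": r.f_x_to_y,
                        "f_2_to_1": r.f_y_to_x,
                        "p_1_to_2": r.p_x_to_y,
                        "p_2_to_1": r.p_y_to_x,
                    }
                    for r in gc_results
                ]
            )
            _record(write_table(gc_df, out / "gca.tsv"))
        except DyadsyncError as exc:
            gca_out["error"] = str(exc)
    manifest["stages"]["gca"] = {"seconds": round(time.time() - t0, 3)}

    report = {"behavior": behav, "ibs": ibs_stats, "gca": gca_out}
    with open(out / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    _record(out / "stats_report.json")

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    tmp.replace(out / "manifest.json")
    return manifest
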