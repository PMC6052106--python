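"""End-to-end pipeline: simulate -> detect -> preprocess -> estimate ->
components/stats -> power, with per-stage artifacts and a JSON manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import CATEGORIES, EventStream, Modulation, NoiseModel
from .deconv import average_erp, glm_estimate
from .events import (DetectorThresholds, assign_rois, detect_eye_events,
                     recategorize_trials, roi_rank_stats)
from .io import write_eeg, write_estimates
from .power import ExperimentConfig, power_surface
from .preprocess import (epoch_and_baseline, exclude_participants, filter_eeg,
                         pool_virtual_electrodes, reject_epochs,
                         rereference_average, DEFAULT_VIRTUAL_ELECTRODES)
from .stats import (COMPONENT_WINDOWS, component_amplitude, component_table,
                    confusion_matrix, rm_anova, ttest_vs_zero, tukey_within,
                    unbiased_hit_rate)
from .synth import (default_roi_layout, make_default_kernels,
                    make_stimulus_catalog, make_trial_schedule,
                    render_gaze_samples, simulate_eeg, simulate_scanpath)

log = logging.getLogger("fixglm")

TARGET_CATEGORIES = ("neutral", "happiness", "surprise", "fear", "disgust")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _simulate_ratings(catalog, accuracy: float, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    others = {c: [o for o in TARGET_CATEGORIES if o != c] for c in TARGET_CATEGORIES}
    for _, e in catalog.entries[catalog.entries["is_target"]].iterrows():
        cat = e["category"]
        if rng.random() < accuracy:
            resp = cat
        else:
            resp = str(rng.choice(others[cat]))
        rows.append((e["stimulus_id"], cat, resp, int(rng.integers(-2, 3))))
    return pd.DataFrame(rows, columns=["stimulus_id", "category", "response", "arousal"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory result bundle.

    Every numeric artifact is reproducible from (config, seed) alone. Any
    stage failure raises :class:`StageError` naming the stage.
    """
    bundle: dict = {"manifest": {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
    }}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    order = ["simulate", "detect", "preprocess", "estimate", "stats", "power"]
    for stage in order:
        if not getattr(config.stages, stage):
            continue
        try:
            _STAGES[stage](config, state, bundle, out_dir)
        except Exception as exc:
            raise StageError(stage, exc) from exc
        log.info("stage %s done", stage)
    if out_dir:
        (out_dir / "manifest.json").write_text(
            json.dumps(bundle["manifest"], indent=1, default=str))
    return bundle


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, bundle: dict,
                    out_dir: Optional[Path]) -> None:
    rate = config.rate_hz
    kernels = make_default_kernels(rate, [
        Modulation(m.condition, m.site, tuple(m.window_ms), m.offset_uv, m.target)
        for m in config.modulations])
    layout = default_roi_layout()
    channels = tuple(dict.fromkeys(
        ch for members in DEFAULT_VIRTUAL_ELECTRODES.values() for ch in members))
    catalog = make_stimulus_catalog(config.composition, seed=config.seed)

    participants = {}
    for p in range(config.n_participants):
        pseed = (config.seed * 101 + p) % (2 ** 31)
        schedule = make_trial_schedule(catalog, seed=pseed)
        events = simulate_scanpath(schedule, layout, seed=pseed)
        rng = np.random.default_rng([config.seed, 909, p])
        ratings = _simulate_ratings(catalog, config.rating_accuracy, rng)
        ratings["participant"] = p
        trials = schedule.trials.merge(
            catalog.entries[["stimulus_id", "is_target"]], on="stimulus_id")
        target_trials = trials[trials["is_target"]][["trial_id", "stimulus_id"]].copy()
        target_trials["participant"] = p
        kept = recategorize_trials(ratings, target_trials)
        cond_map = dict(zip(kept["trial_id"], kept["condition"]))
        eeg = simulate_eeg(events, kernels,
                           NoiseModel(config.noise_exponent, config.noise_sd_uv,
                                      seed=pseed),
                           channels, rate, condition_by_trial=cond_map)
        participants[p] = {
            "schedule": schedule, "events": events, "ratings": ratings,
            "conditions": cond_map, "eeg": eeg,
        }
        if out_dir:
            events.write_text(out_dir / f"events_p{p:02d}.tsv")
            write_eeg(eeg, out_dir / f"eeg_p{p:02d}.dat")
    state.update(kernels=kernels, layout=layout, channels=channels,
                 catalog=catalog, participants=participants)
    bundle["manifest"]["stages"]["simulate"] = {
        "participants": config.n_participants,
        "trials_per_participant": len(catalog),
        "channels": len(channels),
    }


def _strip_ongoing_fixation(events: EventStream, window_start_ms: float,
                            tol_ms: float) -> pd.DataFrame:
    """Drop the fixation that is ongoing at the crop start (the residual
    cross fixation, which is not a scanpath event) and renumber ranks."""
    frame = events.frame.copy()
    fix = frame["event_type"] == "fixation"
    keep = ~(fix & (frame["onset_ms"] <= window_start_ms + tol_ms))
    frame = frame[keep].copy()
    fix_rows = frame["event_type"] == "fixation"
    frame.loc[fix_rows, "rank"] = np.arange(1, int(fix_rows.sum()) + 1)
    return frame


def _stage_detect(config: RunConfig, state: dict, bundle: dict,
                  out_dir: Optional[Path]) -> None:
    det = config.detector
    thr = DetectorThresholds(det.velocity_deg_s, det.acceleration_deg_s2,
                             det.motion_deg)
    layout = state["layout"]
    total_fix = 0
    for p, part in state["participants"].items():
        gaze = render_gaze_samples(part["events"], rate=det.gaze_rate_hz,
                                   jitter_sd=det.gaze_jitter_deg,
                                   seed=(config.seed * 113 + p) % (2 ** 31))
        frames = []
        for _, trial in part["schedule"].trials.iterrows():
            t0 = float(trial["stimulus_onset_ms"])
            t1 = t0 + float(trial["stimulus_duration_ms"])
            sel = (gaze.time_ms >= t0) & (gaze.time_ms <= t1)
            if sel.sum() < 3:
                continue
            from .containers import GazeRecording
            crop = GazeRecording(gaze.time_ms[sel], gaze.x_deg[sel],
                                 gaze.y_deg[sel], gaze.rate)
            detected = detect_eye_events(crop, thr, trial_id=trial["trial_id"])
            frame = _strip_ongoing_fixation(detected, t0,
                                            tol_ms=2000.0 / det.gaze_rate_hz)
            frames.append(frame)
        stim = part["events"].stimuli()
        detected_all = EventStream(pd.concat([stim, *frames], ignore_index=True))
        detected_all = assign_rois(detected_all, layout)
        part["detected_events"] = detected_all
        total_fix += len(detected_all.fixations())
        if out_dir:
            detected_all.write_text(out_dir / f"detected_p{p:02d}.tsv")
    bundle["manifest"]["stages"]["detect"] = {"fixations_detected": total_fix}


def _stage_preprocess(config: RunConfig, state: dict, bundle: dict,
                      out_dir: Optional[Path]) -> None:
    rej = config.rejection
    counts_rows = []
    for p, part in state["participants"].items():
        eeg = filter_eeg(part["eeg"])
        eeg = rereference_average(eeg)
        events = part.get("detected_events", part["events"])
        trials = part["schedule"].trials
        kept = [(tid, cond) for tid, cond in part["conditions"].items()]
        onsets = [float(trials.loc[trials["trial_id"] == tid,
                                   "stimulus_onset_ms"].iloc[0]) for tid, _ in kept]
        n_fix = events.fixations().groupby("trial_id").size()
        meta = pd.DataFrame({
            "trial_id": [tid for tid, _ in kept],
            "condition": [c for _, c in kept],
            "n_fixations": [int(n_fix.get(tid, 0)) for tid, _ in kept],
            "participant": p,
        })
        epochs, skipped = epoch_and_baseline(
            eeg, onsets, config.epoch_window_ms, config.baseline_ms, meta)
        epochs, report = reject_epochs(epochs, rej.variance_sd_multiplier,
                                       rej.min_fixations)
        epochs = pool_virtual_electrodes(epochs)
        part["epochs"] = epochs
        part["rejection_report"] = report
        for cond, cnt in epochs.metadata["condition"].value_counts().items():
            counts_rows.append((p, cond, cnt))
        if out_dir:
            report.to_csv(out_dir / f"rejection_p{p:02d}.tsv", sep="\t", index=False)
    counts = (pd.DataFrame(counts_rows, columns=["participant", "condition", "n"])
              .pivot_table(index="participant", columns="condition", values="n",
                           fill_value=0))
    mask = exclude_participants(counts, rej.min_epochs_per_condition)
    state["included"] = [p for p in counts.index if mask.loc[p]]
    bundle["manifest"]["stages"]["preprocess"] = {
        "epoch_counts": counts.to_dict(),
        "included_participants": state["included"],
        "virtual_electrodes": list(DEFAULT_VIRTUAL_ELECTRODES),
    }


def _stage_estimate(config: RunConfig, state: dict, bundle: dict,
                    out_dir: Optional[Path]) -> None:
    estimates = {}
    averages = {}
    for p in state["included"]:
        part = state["participants"][p]
        epochs = part["epochs"]
        events = part.get("detected_events", part["events"])
        for cond in sorted(epochs.metadata["condition"].unique()):
            sel = (epochs.metadata["condition"] == cond).to_numpy()
            sub = epochs.select(sel)
            est = glm_estimate(
                sub, events, config.estimation_windows_ms,
                condition=cond,
                compute_condition_number=config.compute_condition_number)
            estimates[(p, cond)] = est
            averages[(p, cond)] = average_erp(sub)
            if out_dir:
                write_estimates(est, out_dir / f"glm_p{p:02d}_{cond}")
    state["estimates"] = estimates
    state["averages"] = averages
    bundle["estimates"] = estimates
    bundle["manifest"]["stages"]["estimate"] = {"n_fits": len(estimates)}


def _stage_stats(config: RunConfig, state: dict, bundle: dict,
                 out_dir: Optional[Path]) -> None:
    # behavioral: unbiased hit rate per participant over surviving categories
    hu_rows = []
    for p, part in state["participants"].items():
        ratings = part["ratings"]
        keep = ratings[ratings["response"] != "fear"]
        keep = keep[keep["category"] != "fear"]
        cm = confusion_matrix(keep, [c for c in TARGET_CATEGORIES if c != "fear"])
        hu = unbiased_hit_rate(cm)
        for cat, v in hu.items():
            hu_rows.append((p, cat, v))
    hu_table = pd.DataFrame(hu_rows, columns=["participant", "category", "Hu"])

    # conditions every included participant has estimates for
    estimates = state["estimates"]
    participants = sorted({p for p, _ in estimates})
    conds = sorted({c for _, c in estimates})
    complete = [c for c in conds
                if all((p, c) in estimates for p in participants)]
    results: dict = {"hu": hu_table}
    comp = component_table({k: v for k, v in estimates.items() if k[1] in complete})
    results["component_table"] = comp
    if len(complete) >= 2 and len(participants) >= 2:
        anovas = {}
        tukeys = {}
        for comp_name in ("P1", "N170", "P2P3", "LPP"):
            sub = comp[comp["component"] == comp_name]
            anovas[comp_name] = rm_anova(sub, "amplitude_uv",
                                         ["electrode", "condition"])
            tukeys[comp_name] = tukey_within(sub, "amplitude_uv", "condition")
        results["rm_anova"] = anovas
        results["tukey"] = tukeys
        # EFRP t-tests vs zero: first-fixation kernel components at
        # parieto-occipital sites, each emotion minus neutral
        if "neutral" in complete:
            efrp_rows = []
            sites = ["left_parieto_occipital", "right_parieto_occipital",
                     "median_occipital"]
            for comp_name in ("Lambda", "P2efrp"):
                win = COMPONENT_WINDOWS[comp_name]
                for site in sites:
                    for cond in complete:
                        if cond == "neutral":
                            continue
                        diffs = []
                        for p in participants:
                            est_c = estimates[(p, cond)]
                            est_n = estimates[(p, "neutral")]
                            si = est_c.ch_names.index(site)
                            a_c = np.atleast_1d(component_amplitude(
                                est_c.estimates["fp1"], win))[si]
                            a_n = np.atleast_1d(component_amplitude(
                                est_n.estimates["fp1"], win))[si]
                            diffs.append(a_c - a_n)
                        if len(diffs) >= 2:
                            res = ttest_vs_zero(diffs)
                            efrp_rows.append((comp_name, site, cond, res["t"],
                                              res["df"], res["p"], res["np2"]))
            results["efrp_ttests"] = pd.DataFrame(
                efrp_rows, columns=["component", "site", "condition",
                                    "t", "df", "p", "np2"])
    bundle["stats"] = results
    if out_dir:
        hu_table.to_csv(out_dir / "hu.tsv", sep="\t", index=False)
        comp.to_csv(out_dir / "components.tsv", sep="\t", index=False)
        report = {}
        for name, df in results.get("rm_anova", {}).items():
            report[name] = df.to_dict(orient="records")
        (out_dir / "stats.json").write_text(json.dumps(report, indent=1,
                                                       default=float))
    bundle["manifest"]["stages"]["stats"] = {
        "conditions_tested": complete, "participants": participants}


def _stage_power(config: RunConfig, state: dict, bundle: dict,
                 out_dir: Optional[Path]) -> None:
    cfg = ExperimentConfig(effect_uv=config.power_effect_uv, alpha=config.alpha)
    grid = power_surface(config.power_participants, config.power_trials,
                         cfg, reps=config.power_reps, seed=config.seed)
    bundle["power"] = grid
    if out_dir:
        grid.to_frame().to_csv(out_dir / "power.tsv", sep="\t", index=False)
        (out_dir / "power.json").write_text(json.dumps({
            "n_participants": grid.n_participants, "trials": grid.trials,
            "power": grid.power.tolist(), "reps": grid.reps,
            "seed": grid.seed}, indent=1))
    bundle["manifest"]["stages"]["power"] = {
        "grid": [len(grid.n_participants), len(grid.trials)],
        "reps": grid.reps}


_STAGES = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "preprocess": _stage_preprocess,
    "estimate": _stage_estimate,
    "stats": _stage_stats,
    "power": _stage_power,
}
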