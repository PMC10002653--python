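"""End-to-end pipeline driver.

``run_pipeline`` chains simulate -> (optionally render + track + posture)
-> behavior -> features -> variability, writing every intermediate artifact
(trajectory table, segment table, events, report JSON) stamped with the
config hash and seed.  The trajectory-only fast path feeds ground-truth
positions forward, skipping the imaging stages.
"""
from __future__ import annotations

import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import behavior, features, io, posture, render, tracking, variability
from .config import RunConfig
from .simulate import GroundTruth, simulate_experiment

log = logging.getLogger("larvatrack")


def analyze_table(table: pd.DataFrame, config: RunConfig) -> dict:
    """Run behavior classification and feature extraction on a trajectory table.

    Mutates ``table`` in place (state column) and returns a report dict plus
    per-animal artifacts under ``'per_animal'`` / ``'segments'``.
    """
    ap = config.analysis
    fr = config.arena.frame_rate_hz
    axis_deg = config.thermal.axis_deg
    gradient_on = config.thermal.enabled

    all_segments = []
    speed_by_animal: dict[int, np.ndarray] = {}
    turnrate_bins: dict[int, np.ndarray] = {}
    speed_bins: dict[int, np.ndarray] = {}
    ni_by_animal: dict[int, float] = {}
    ni_means: list[float] = []
    handedness_by_animal: dict[int, float | None] = {}
    ni_windows_by_animal: dict[int, np.ndarray] = {}

    for animal_id, sub in table.groupby("animal_id"):
        sub = sub.sort_values("frame")
        x = sub["x_mm"].to_numpy(float)
        y = sub["y_mm"].to_numpy(float)
        exclude = sub["interpolated"].to_numpy(bool) | sub["contact"].to_numpy(bool)
        ks = features.kinematics(
            x, y, fr, smooth_window=ap.smooth_window_frames, v_min=ap.v_min_mm_s, exclude=exclude
        )
        bend = sub["bend_deg"].to_numpy(float) if sub["bend_deg"].notna().any() else None
        labels = behavior.classify_states(
            ks.heading_deg,
            fr,
            bend_deg=bend,
            bend_on_deg=ap.bend_on_deg,
            bend_off_deg=ap.bend_off_deg,
            heading_rate_on_deg_s=ap.heading_rate_on_deg_s,
            smooth_window=ap.smooth_window_frames,
            valid=~exclude,
        )
        table.loc[sub.index, "state"] = np.where(labels == behavior.STATE_TURN, "turn", "run")
        segs = behavior.segment_behaviors(labels, ks.heading_deg, fr, animal_id=int(animal_id))
        all_segments.append(segs)

        rate_series, summary = features.turn_statistics(segs, len(x), fr, window_min=ap.bin_min)
        handedness_by_animal[int(animal_id)] = summary.handedness
        run_mask = labels == behavior.STATE_RUN if ap.runs_only_ni else None
        nav = features.navigation_index(
            ks.speed_mm_s,
            ks.heading_deg,
            fr,
            axis_deg=axis_deg,
            window_min=ap.ni_window_min,
            v_min=ap.v_min_mm_s,
            run_mask=run_mask,
        )
        ni_by_animal[int(animal_id)] = nav.ni
        if not np.isnan(nav.ni):
            ni_means.append(nav.ni)
        ni_windows_by_animal[int(animal_id)] = nav.windows["ni"].to_numpy()
        speed_by_animal[int(animal_id)] = ks.speed_mm_s
        turnrate_bins[int(animal_id)] = rate_series["turn_rate_per_min"].to_numpy()
        bin_frames = max(1, int(round(ap.bin_min * 60 * fr)))
        sb = [
            np.nanmean(ks.speed_mm_s[s : s + bin_frames])
            if np.any(~np.isnan(ks.speed_mm_s[s : s + bin_frames]))
            else np.nan
            for s in range(0, len(x), bin_frames)
        ]
        speed_bins[int(animal_id)] = np.array(sb)

    segments = (
        pd.concat(all_segments, ignore_index=True)
        if all_segments
        else pd.DataFrame(
            columns=["animal_id", "state", "start_frame", "end_frame", "direction", "turn_size_deg"]
        )
    )

    pop_speed = features.binned_population_summary(speed_by_animal, fr, bin_min=ap.bin_min)
    slope = features.decline_slope(pop_speed, t_max_s=min(3600.0, config.duration_s))
    try:
        corr = features.speed_turnrate_correlation(speed_bins, turnrate_bins)
        corr_out = {
            "population": corr.r_population,
            "individual_mean": corr.r_individual_mean,
            "individual_sd": corr.r_individual_sd,
        }
    except ValueError:
        corr_out = {"population": None, "note": "too few bins"}

    ni_arr = np.array(ni_means)
    ni_section: dict = {
        "per_animal": ni_by_animal,
        "mean": float(ni_arr.mean()) if ni_arr.size else None,
        "sd": float(ni_arr.std(ddof=1)) if ni_arr.size >= 2 else None,
        "gradient": bool(gradient_on),
    }
    if not gradient_on:
        ni_section["note"] = "no gradient"
    if ni_arr.size >= 2:
        t = sstats.ttest_1samp(ni_arr, 0.0)
        ni_section["p_vs_zero"] = float(t.pvalue)

    bc_section: dict = {}
    if ni_arr.size >= 4:
        bcres = variability.bimodality_coefficient(ni_arr)
        bc_section = {
            "bc_per_animal_ni": bcres.bc,
            "n": bcres.n,
            "is_bimodal": bcres.is_bimodal,
            "bc_crit": variability.BC_CRIT,
            "small_sample_warning": bcres.n < 8,
        }

    directed = segments[(segments["state"] == "turn") & segments["direction"].notna()]
    n_left = int((directed["direction"] == "left").sum())
    n_right = int((directed["direction"] == "right").sum())
    n_tot = n_left + n_right
    report = {
        "ni": ni_section,
        "handedness": {
            "population": (n_left - n_right) / n_tot if n_tot else None,
            "per_animal": handedness_by_animal,
        },
        "decline_slope_mm_s2": slope,
        "speed_turnrate_correlation": corr_out,
        "bc": bc_section,
        "population_speed": pop_speed.to_dict(orient="list"),
        "per_animal_ni_windows": {k: v.tolist() for k, v in ni_windows_by_animal.items()},
    }
    report["_segments"] = segments
    return report


def table_from_tracks(
    tracks: list[tracking.Track],
    frames: list[np.ndarray],
    config: RunConfig,
) -> pd.DataFrame:
    """Build a trajectory table from tracked movies, including posture columns."""
    arena = config.arena
    ap = config.analysis
    fr = arena.frame_rate_hz
    h_px = frames[0].shape[0]
    s = arena.pixel_scale_mm
    rows = []
    for tr in tracks:
        pos = tr.centroid_mm(s, h_px)
        T = tr.n_frames
        e1 = np.full((T, 2), np.nan)
        e2 = np.full((T, 2), np.nan)
        bend = np.full(T, np.nan)
        for t, crop, origin in tracking.extract_crops(tr, frames, size=ap.crop_size_px):
            mid = posture.extract_midline(
                crop, threshold=ap.detect_threshold, n_points=ap.midline_points
            )
            if not mid.valid:
                continue
            pts = mid.points_px + np.array(origin)
            from .geometry import px_to_mm

            mx, my = px_to_mm(pts[:, 0], pts[:, 1], s, h_px)
            pts_mm = np.column_stack([mx, my])
            e1[t] = pts_mm[0]
            e2[t] = pts_mm[-1]
            bend[t] = posture.bend_angle(pts_mm)
        vel = np.gradient(
            np.column_stack(
                [
                    features.boxcar(np.nan_to_num(pos[:, 0]), ap.smooth_window_frames),
                    features.boxcar(np.nan_to_num(pos[:, 1]), ap.smooth_window_frames),
                ]
            ),
            axis=0,
        ) * fr
        ht = posture.assign_head_tail(
            e1, e2, vel, flip_penalty=None, v_min=ap.v_min_mm_s
        )
        frames_idx = np.arange(T)
        rows.append(
            pd.DataFrame(
                {
                    "time_s": frames_idx / fr,
                    "frame": frames_idx,
                    "animal_id": tr.animal_id,
                    "x_mm": pos[:, 0],
                    "y_mm": pos[:, 1],
                    "head_x_mm": ht.head[:, 0],
                    "head_y_mm": ht.head[:, 1],
                    "tail_x_mm": ht.tail[:, 0],
                    "tail_y_mm": ht.tail[:, 1],
                    "bend_deg": bend,
                    "state": "run",
                    "interpolated": tr.interpolated,
                    "contact": tr.contact,
                    "event_id": "",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[io.TRAJECTORY_COLUMNS]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured experiment end to end and write artifacts.

    Returns the experiment report.  Any stage failure marks the stage in the
    report and preserves earlier artifacts.
    """
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash, "seed": config.seed}
    (outdir / "config.toml").write_text(config.to_toml())
    report: dict = {"config_hash": config.config_hash, "seed": config.seed, "stages": {}}

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
                # timing goes to the log only, so reports are reproducible byte-for-byte
                report["stages"][name] = {"ok": True}
                log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
                return out
            except Exception as exc:  # noqa: BLE001 - stage isolation by design
                report["stages"][name] = {"ok": False, "error": f"{type(exc).__name__}: {exc}"}
                log.exception("stage %s failed", name)
                raise PipelineStageError(name) from exc

        return deco

    try:
        gt: GroundTruth = stage("simulate")(
            lambda: simulate_experiment(
                arena=config.arena,
                thermal=config.thermal if config.thermal.enabled else None,
                params=config.locomotion,
                controller=config.controller if config.use_robot else None,
                n_animals=config.n_animals,
                duration_s=config.duration_s,
                seed=config.seed,
            )
        )
        io.write_events_jsonl(gt.events, outdir / "events.jsonl", meta=meta)

        if config.render_frames:
            def _render_track():
                frames = list(render.iter_frames(gt, config.render, noise_seed=config.seed))
                render.write_tiff(outdir / "frames.tiff", frames)
                tracks, qc = tracking.track_movie(iter(frames), config.arena, config.analysis)
                io.write_json(qc, outdir / "tracking_qc.json")
                return table_from_tracks(tracks, frames, config)

            table = stage("track")(_render_track)
        else:
            table = stage("trajectory_fast_path")(gt.to_table)

        report_body = stage("analyze")(lambda: analyze_table(table, config))
        segments = report_body.pop("_segments")
        io.write_trajectory_table(table, outdir / "trajectory.csv", meta=meta)
        with (outdir / "segments.csv").open("w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            segments.to_csv(fh, index=False)
        report.update(report_body)
    except PipelineStageError:
        pass

    io.write_json(report, outdir / "report.json")
    return report


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; earlier artifacts are preserved."""
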