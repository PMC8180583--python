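"""End-to-end orchestration: config-driven cohort analysis and a synthetic
demo mode.

The pipeline reproduces the full analysis chain for every participant and
world: validity marking -> exclusion windows -> sector segmentation ->
descriptive gaze statistics (median/IQR, T-shape, direction and velocity
histograms) -> saccade detection and rates -> AOI dwell (corridors) ->
eye-in-world referencing (designated corridor) -> head statistics (VR) ->
drift from the end-of-session validation grid; then pools the per-cell
metrics into the within-subject 2x3 ANOVAs and paired t-tests, and writes
tidy tables plus a human-readable report.

Demo mode simulates a full cohort with the synthetic generator, writes it
out in the package's tabular formats, and runs the identical pipeline over
those files, so the demo also exercises every reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aoi import dwell_time
from .inference import (
    SECTOR_LEVELS,
    WORLD_LEVELS,
    paired_ttest,
    rm_anova_2x3,
    rm_anova_oneway,
)
from .io import (
    GazeRecording,
    read_aoi_track,
    read_gaze_table,
    read_head_pose,
    read_sector_map,
    slice_by_sector,
    write_aoi_track,
    write_gaze_table,
    write_head_pose,
    write_sector_map,
)
from .metrics import (
    cardinal_oblique_ratio,
    direction_histogram,
    heatmap,
    normalize_heatmaps,
    sample_velocities,
    summarize_gaze,
    tshape_ratio,
    velocity_histogram,
)
from .preprocess import (
    CalibrationGrid,
    apply_exclusion_windows,
    estimate_drift,
    mark_invalid_samples,
)
from .saccades import SaccadeParams, detect_saccades
from .worldref import eye_in_world_vertical, head_stats
from .synth import (
    default_params,
    simulate_aoi_track,
    simulate_cohort,
    simulate_validation_grid,
)

__all__ = ["RunConfig", "run_pipeline", "run_demo", "write_report",
           "METRIC_FAMILIES"]

#: The metric families fed to the world x sector ANOVAs.
METRIC_FAMILIES = (
    "median_x", "median_y", "iqr_x", "iqr_y",
    "tshape_ratio", "cardinal_oblique_ratio", "median_velocity",
    "saccade_rate",
)


@dataclasses.dataclass
class RunConfig:
    participants: list          # [{id, worlds: {world: {gaze, sectors, ...}}}]
    out_dir: str
    alpha: float = 0.05
    aoi_threshold: float = 1.0
    aoi_confidence: float = 0.9
    saccade: dict = dataclasses.field(default_factory=dict)
    heatmaps: bool = False
    eye_in_world_below_target: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclasses.dataclass
class ResultBundle:
    metrics: pd.DataFrame           # participant, world, sector, metric, value
    events: pd.DataFrame            # saccade events
    anovas: dict                    # metric -> AnovaResult
    head: pd.DataFrame | None
    dwell: pd.DataFrame | None
    eye_in_world: pd.DataFrame | None
    drift: pd.DataFrame | None
    manifest: dict
    log: list


def _load_recording(pid: str, world: str, spec: dict) -> GazeRecording:
    return read_gaze_table(spec["gaze"], participant_id=pid, world=world)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run the full analysis over every participant and world in the config.

    Deterministic given the input files; every stage's intermediate table is
    written under ``config.out_dir`` and listed in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    rows, event_rows, head_rows, dwell_rows, eiw_rows, drift_rows = \
        [], [], [], [], [], []
    sp_defaults = {"lam": 6.0, "window": 5, "min_duration": 0.006,
                   "merge_gap": 0.020}
    sp_defaults.update(config.saccade or {})

    for part in config.participants:
        pid = part["id"]
        for world, spec in part["worlds"].items():
            for key in ("gaze", "sectors"):
                if key not in spec or not Path(spec[key]).exists():
                    raise FileNotFoundError(
                        f"stage=load participant={pid} world={world}: "
                        f"missing {key} file {spec.get(key)!r}"
                    )
            rec = _load_recording(pid, world, spec)
            smap = read_sector_map(spec["sectors"])
            rec = mark_invalid_samples(rec)
            rec = apply_exclusion_windows(rec, smap)
            n_valid = int(rec.valid.sum())
            log.append(f"{pid}/{world}: {len(rec)} samples, {n_valid} valid "
                       f"({100 * n_valid / max(len(rec), 1):.1f}%), "
                       f"{int(rec.excluded.sum())} excluded")
            rows.append(dict(participant=pid, world=world, sector="all",
                             metric="valid_fraction",
                             value=n_valid / max(len(rec), 1)))

            lam = float(spec.get("lam", sp_defaults["lam"]))
            sp = SaccadeParams(lam=lam, window=int(sp_defaults["window"]),
                               min_duration=float(sp_defaults["min_duration"]),
                               merge_gap=float(sp_defaults["merge_gap"]))

            maps = {}
            for sector in SECTOR_LEVELS:
                segs = slice_by_sector(rec, smap, sector)
                if not segs:
                    continue
                merged = _concat_segments(segs)
                summ = summarize_gaze(merged)
                speed, _, _ = sample_velocities(merged)
                events = []
                for sgm in segs:
                    events.extend(detect_saccades(sgm, sp))
                rate = len(events) / (
                    sum(int(s.analyzable.sum()) for s in segs)
                    / rec.nominal_rate)
                vals = dict(
                    median_x=summ.median_x, median_y=summ.median_y,
                    iqr_x=summ.iqr_x, iqr_y=summ.iqr_y,
                    tshape_ratio=tshape_ratio(merged),
                    cardinal_oblique_ratio=cardinal_oblique_ratio(
                        direction_histogram(merged)),
                    median_velocity=float(np.median(speed)),
                    saccade_rate=rate,
                )
                for metric, value in vals.items():
                    rows.append(dict(participant=pid, world=world,
                                     sector=sector, metric=metric, value=value))
                for ev in events:
                    event_rows.append(dict(
                        participant=pid, world=world, sector=sector,
                        onset=ev.onset, offset=ev.offset,
                        amplitude=ev.amplitude, peak_speed=ev.peak_speed))
                vh = velocity_histogram(speed)
                for lab_i, cnt in enumerate(vh.counts):
                    rows.append(dict(participant=pid, world=world,
                                     sector=sector,
                                     metric=f"velbin_{lab_i}",
                                     value=cnt / max(vh.n, 1)))
                maps[sector] = heatmap(merged)
            if maps and config.heatmaps:
                # regularised for the log display scale (zero bins otherwise
                # undefined); the TSV grids stay unregularised
                norm = normalize_heatmaps(maps)
                disp = normalize_heatmaps(maps, regularizer=0.05)
                for sector, hm in norm.items():
                    np.savetxt(out / f"heatmap_{pid}_{world}_{sector}.tsv",
                               hm.grid, delimiter="\t", fmt="%.6g")
                    _render_heatmap(
                        disp[sector],
                        out / f"heatmap_{pid}_{world}_{sector}.png",
                        f"{pid} {world} {sector}")

            if "aoi" in spec and spec["aoi"]:
                track = read_aoi_track(spec["aoi"])
                corr = _concat_segments(slice_by_sector(rec, smap, "corridor"))
                res = dwell_time(corr, track,
                                 threshold=config.aoi_threshold,
                                 confidence=config.aoi_confidence,
                                 harmonize_range=(world == "VR"))
                dwell_rows.append(dict(participant=pid, world=world,
                                       dwell_fraction=res.dwell_fraction,
                                       mean_distance=res.mean_distance))

            if "horizon" in spec and spec["horizon"]:
                tr = pd.read_csv(spec["horizon"])
                corrs = slice_by_sector(rec, smap, "corridor")
                ref = corrs[4] if len(corrs) >= 5 else corrs[-1]
                eiw = eye_in_world_vertical(ref, tr["frame_t"].values,
                                            tr["horizon_y"].values)
                eiw = eiw[ref.analyzable & np.isfinite(eiw)]
                eiw_rows.append(dict(participant=pid, world=world,
                                     below_horizon_mean=float(np.mean(eiw)),
                                     below_horizon_sd=float(np.std(eiw, ddof=1))))

            if "head" in spec and spec["head"]:
                track = read_head_pose(spec["head"])
                for sector, st in head_stats(track, smap).items():
                    head_rows.append(dict(participant=pid, world=world,
                                          sector=sector, **st))

            if "validation_grid" in spec and spec["validation_grid"]:
                gdf = pd.read_csv(spec["validation_grid"])
                grid = CalibrationGrid(
                    gdf[["true_x", "true_y"]].values,
                    gdf[["meas_x", "meas_y"]].values)
                dr = estimate_drift(grid)
                drift_rows.append(dict(participant=pid, world=world,
                                       drift_x=dr.mean_offset[0],
                                       drift_y=dr.mean_offset[1],
                                       drift_magnitude=dr.mean_magnitude))

    metrics = pd.DataFrame(rows)
    events = pd.DataFrame(event_rows)
    anovas = {}
    for metric in METRIC_FAMILIES:
        sub = metrics[metrics["metric"] == metric]
        try:
            anovas[metric] = rm_anova_2x3(
                sub.rename(columns={"value": "value"}), alpha=config.alpha)
        except ValueError as exc:
            log.append(f"ANOVA skipped for {metric}: {exc}")

    head = pd.DataFrame(head_rows) if head_rows else None
    dwell = pd.DataFrame(dwell_rows) if dwell_rows else None
    eiw = pd.DataFrame(eiw_rows) if eiw_rows else None
    drift = pd.DataFrame(drift_rows) if drift_rows else None

    outputs = {}
    metrics.to_csv(out / "metrics.csv", index=False)
    outputs["metrics.csv"] = _sha256(out / "metrics.csv")
    events.to_csv(out / "saccade_events.csv", index=False)
    outputs["saccade_events.csv"] = _sha256(out / "saccade_events.csv")
    for name, df in (("head_stats.csv", head), ("dwell.csv", dwell),
                     ("eye_in_world.csv", eiw), ("drift.csv", drift)):
        if df is not None:
            df.to_csv(out / name, index=False)
            outputs[name] = _sha256(out / name)

    anova_rows = []
    for metric, res in anovas.items():
        for eff in res.effects.values():
            anova_rows.append(dict(
                metric=metric, effect=eff.name, F=eff.F, df_num=eff.df_num,
                df_den=eff.df_den, p_uncorrected=eff.p_uncorrected,
                mauchly_p=eff.mauchly_p, epsilon_gg=eff.epsilon_gg,
                p_reported=eff.p_reported, gg_applied=eff.gg_applied))
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
    outputs["anova.csv"] = _sha256(out / "anova.csv")

    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = dict(version=__version__, config_hash=cfg_hash,
                    n_participants=len(config.participants),
                    n_metric_rows=len(metrics), n_events=len(events),
                    outputs=outputs)
    bundle = ResultBundle(metrics=metrics, events=events, anovas=anovas,
                          head=head, dwell=dwell, eye_in_world=eiw,
                          drift=drift, manifest=manifest, log=log)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.txt").write_text(write_report(bundle))
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return bundle


def _render_heatmap(hm, path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    fig, ax = plt.subplots(figsize=(4, 4))
    e = hm.extent + 0.5
    im = ax.imshow(hm.grid, origin="upper", extent=(-e, e, e, -e),
                   norm=LogNorm(vmin=hm.grid.min(), vmax=hm.grid.max()),
                   cmap="inferno")
    ax.set_xlabel("horizontal gaze (deg)")
    ax.set_ylabel("vertical gaze (deg, down positive)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _concat_segments(segs: list[GazeRecording]) -> GazeRecording:
    if not segs:
        raise ValueError("no segments")
    if len(segs) == 1:
        return segs[0]
    return dataclasses.replace(
        segs[0],
        t=np.concatenate([s.t for s in segs]),
        x=np.concatenate([s.x for s in segs]),
        y=np.concatenate([s.y for s in segs]),
        pupil=np.concatenate([s.pupil for s in segs]),
        valid=np.concatenate([s.valid for s in segs]),
        excluded=np.concatenate([s.excluded for s in segs]),
    )


def _fmt_p(p: float) -> str:
    return "p < 0.001" if p < 0.001 else f"p = {p:.3f}"


def write_report(bundle: ResultBundle) -> str:
    """Human-readable summary: one line per metric and effect, in the
    conventional ``F(df1,df2) = ..., p = ...`` style, with epsilon_GG shown
    only where the Greenhouse-Geisser correction was applied (two-level
    effects are spherical by construction and print no epsilon)."""
    lines = ["gaitgaze analysis report", "=" * 24, ""]
    for metric, res in bundle.anovas.items():
        lines.append(f"{metric}:")
        for eff in res.effects.values():
            s = (f"  {eff.name}: F({eff.df_num},{eff.df_den}) = {eff.F:.2f}, "
                 f"{_fmt_p(eff.p_reported)}")
            if eff.gg_applied:
                s += f", eps_GG = {eff.epsilon_gg:.2f} (GG-corrected)"
            lines.append(s)
        lines.append("")
    if bundle.dwell is not None and len(bundle.dwell):
        piv = bundle.dwell.pivot(index="participant", columns="world")
        lines.append("AOI dwell (corridors): " + ", ".join(
            f"{w}: {100 * piv['dwell_fraction'][w].mean():.1f}%"
            for w in WORLD_LEVELS if w in piv["dwell_fraction"]))
        both = [w for w in WORLD_LEVELS if w in piv["dwell_fraction"]]
        if len(both) == 2 and piv["dwell_fraction"].notna().all().all():
            tt = paired_ttest(piv["dwell_fraction"]["VR"],
                              piv["dwell_fraction"]["RW"])
            lines.append(f"  VR vs RW: t({tt.df}) = {tt.t:.2f}, {_fmt_p(tt.p)}")
        lines.append("")
    if bundle.eye_in_world is not None and len(bundle.eye_in_world):
        for w, grp in bundle.eye_in_world.groupby("world"):
            lines.append(
                f"eye-in-world ({w}): gaze "
                f"{grp['below_horizon_mean'].mean():.1f} deg below horizon "
                f"(SD {grp['below_horizon_mean'].std(ddof=1):.1f})")
        lines.append("")
    if bundle.head is not None and len(bundle.head):
        for stat in ("pitch_mean", "roll_mean", "pitch_iqr", "roll_iqr"):
            piv = bundle.head.pivot_table(index="participant",
                                          columns="sector", values=stat)
            if (len(piv) >= 3 and all(s in piv for s in SECTOR_LEVELS)
                    and piv.notna().all().all()):
                eff = rm_anova_oneway(piv[list(SECTOR_LEVELS)].values,
                                      name=stat)
                s = (f"head {stat}: F({eff.df_num},{eff.df_den}) = "
                     f"{eff.F:.2f}, {_fmt_p(eff.p_reported)}")
                if eff.gg_applied:
                    s += f", eps_GG = {eff.epsilon_gg:.2f}"
                lines.append(s)
        lines.append("")
    if bundle.drift is not None and len(bundle.drift):
        for w, grp in bundle.drift.groupby("world"):
            lines.append(f"drift ({w}): {grp['drift_magnitude'].mean():.1f} deg "
                         f"(SD {grp['drift_magnitude'].std(ddof=1):.1f})")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Demo mode
# ---------------------------------------------------------------------------

def run_demo(seed: int, out_dir, *, n: int = 8, duration_scale: float = 1.0,
             heatmaps: bool = False) -> ResultBundle:
    """One-command synthetic-cohort demo.

    Simulates an 8-participant within-subject cohort at the study's
    conditions, writes every stream to disk in the package's tabular
    formats, builds a run config pointing at those files, and executes the
    standard pipeline on them.
    """
    out = Path(out_dir)
    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    params = default_params(seed)
    cohort = simulate_cohort(n, params, seed, duration_scale=duration_scale)
    below_target = {"VR": 2.2, "RW": 4.2}

    participants = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    for entry in cohort:
        pid = entry["participant_id"]
        worlds = {}
        # between-subject scatter in marker-directed gaze and in resting
        # gaze-to-horizon angle, mirroring the sizeable individual
        # differences the within-subject inference has to cope with
        dwell_jitter = rng.normal(0.0, 0.012, 2)
        horizon_jitter = rng.normal(0.0, 2.0)
        for wi, (world, (rec, headtrack, truth)) in enumerate(
                entry["sessions"].items()):
            plan = entry["plans"][world]
            base = data_dir / f"{pid}_{world}"
            write_gaze_table(rec, f"{base}_gaze.csv")
            write_sector_map(plan, f"{base}_sectors.csv")
            spec = {"gaze": f"{base}_gaze.csv", "sectors": f"{base}_sectors.csv"}

            frac = (0.035 if world == "VR" else 0.018) + dwell_jitter[wi]
            track, on_intervals = simulate_aoi_track(
                rec, plan, on_aoi_fraction=float(np.clip(frac, 0.001, 0.08)),
                rng=rng)
            truth.on_aoi_intervals = on_intervals
            write_aoi_track(track, f"{base}_aoi.csv")
            spec["aoi"] = f"{base}_aoi.csv"

            # per-participant horizon trace (deg) over the reference corridor.
            # The horizon is tracked in the same (drifting) camera frame as
            # gaze, so the session drift enters both channels and cancels in
            # the eye-in-world subtraction; the trace is placed so the true
            # below-horizon gaze matches the study-level target.
            corr_ivs = plan.with_label("corridor")
            ref = corr_ivs[4] if len(corr_ivs) >= 5 else corr_ivs[-1]
            ft = np.arange(ref[0], ref[1], 1 / 30.0)
            mu_y = truth.sector_summary["corridor"]["median_y"]
            t0 = min(iv[0] for iv in plan.intervals)
            t1 = max(iv[1] for iv in plan.intervals)
            wp = entry["world_params"][world]
            drift_y = wp.drift_total[1] * (ft - t0) / (t1 - t0)
            horizon = (mu_y - below_target[world] - horizon_jitter + drift_y
                       + rng.normal(0, 0.2, ft.size))
            pd.DataFrame({"frame_t": ft, "horizon_y": horizon}).to_csv(
                f"{base}_horizon.csv", index=False)
            spec["horizon"] = f"{base}_horizon.csv"

            if world == "VR":
                write_head_pose(headtrack, f"{base}_head.csv")
                spec["head"] = f"{base}_head.csv"

            true_pts, meas = simulate_validation_grid(
                entry["world_params"][world].drift_total, rng=rng)
            pd.DataFrame({
                "point_id": np.arange(9),
                "true_x": true_pts[:, 0], "true_y": true_pts[:, 1],
                "meas_x": meas[:, 0], "meas_y": meas[:, 1],
            }).to_csv(f"{base}_validation.csv", index=False)
            spec["validation_grid"] = f"{base}_validation.csv"
            worlds[world] = spec
        participants.append({"id": pid, "worlds": worlds})

    config = RunConfig(participants=participants, out_dir=str(out / "results"),
                       heatmaps=heatmaps)
    config.to_yaml(out / "config.yaml")
    return run_pipeline(config)
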