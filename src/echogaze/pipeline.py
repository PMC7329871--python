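"""Stage orchestration: simulate -> detect -> localize -> metrics -> stats.

Each stage reads/writes plain CSV/JSON (WAV for audio) and drops a
manifest carrying the config hash, the seed and input-file hashes, so
re-running a stage with identical inputs reproduces identical outputs.
The detect stage supports the feature-level bypass: when a pulse table
is supplied instead of audio, detection is skipped with a logged
notice and downstream stages run unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaLayout, default_layout
from .glmm import (collinearity_screen, fit_mixed_model,
                   model_selection_aicc, parametric_bootstrap_null)
from .gaze import gaze_records, in_wall_rate, delta_pulse_direction
from .kinematics import (count_by_type, max_flight_speed, meandering_width,
                         speed_profile, UndefinedMeanderError,
                         IncompleteFlightError)
from .localization import DirectivityFitError, localize_pulse, pulse_direction
from .signalproc import SpectrogramParams, compute_ipis, detect_and_extract
from .simulate import (SimulationConfig, simulate_cohort,
                       synthesize_received_levels)

log = logging.getLogger("echogaze")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        d = dataclasses.asdict(obj)
        return {str(k): v for k, v in d.items()}
    if isinstance(obj, dict):
        return {str(k): v for k, v in obj.items()}
    return str(obj)


def _config_dict(config) -> dict:
    def clean(v):
        if dataclasses.is_dataclass(v):
            v = dataclasses.asdict(v)
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v
    return clean(config)


def write_manifest(outdir: Path, stage: str, config, seed, inputs=()):
    cfg = _config_dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=_json_default).encode()
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": cfg,
        "input_sha256": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for p in inputs if Path(p).exists()},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


# ---------------------------------------------------------------------------


def run_simulate(config: SimulationConfig, seed: int, outdir,
                 write_levels: bool = False) -> dict:
    """Generate a cohort and write trajectory / pulse / level tables."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    flights = simulate_cohort(config, rng)
    layout = config.layout()

    traj_rows, level_rows = [], []
    pulse_frames = []
    for f in flights:
        n = len(f.times)
        traj_rows.append(pd.DataFrame({
            "bat_id": [f.bat_id] * n, "condition": [f.condition] * n,
            "flight_number": [f.flight_number] * n,
            "t": f.times, "x": f.positions[:, 0], "y": f.positions[:, 1],
            "z": f.positions[:, 2]}))
        pulse_frames.append(f.pulses)
        if write_levels and len(f.pulses):
            for rec in f.pulses.itertuples(index=False):
                levels, occ, _ = synthesize_received_levels(
                    (rec.x, rec.y), rec.true_direction_deg, layout, config, rng)
                row = {"bat_id": f.bat_id, "flight_number": f.flight_number,
                       "pulse_id": rec.pulse_id}
                row.update({f"ch{i:02d}": lv for i, lv in enumerate(levels)})
                row.update({f"occ{i:02d}": int(o) for i, o in enumerate(occ)})
                level_rows.append(row)

    pd.concat(traj_rows, ignore_index=True).to_csv(
        outdir / "trajectories.csv", index=False)
    pulses = pd.concat(pulse_frames, ignore_index=True)
    pulses.to_csv(outdir / "pulses.csv", index=False)
    cohorts = pd.DataFrame([{"bat_id": f.bat_id, "condition": f.condition,
                             "flight_number": f.flight_number,
                             "max_speed_drawn": f.max_speed_drawn,
                             "meander_drawn": f.meander_drawn}
                            for f in flights])
    cohorts.to_csv(outdir / "flights.csv", index=False)
    if write_levels:
        pd.DataFrame(level_rows).to_csv(outdir / "levels.csv", index=False)
    layout.to_yaml(outdir / "arena.yaml")
    write_manifest(outdir, "simulate", config, seed)
    log.info("simulate: %d flights, %d pulses in %.1fs",
             len(flights), len(pulses), time.time() - t0)
    return {"n_flights": len(flights), "n_pulses": len(pulses),
            "outdir": str(outdir)}


def run_detect(audio_path=None, pulses_csv=None, outdir=".",
               params: SpectrogramParams | None = None,
               threshold_db: float = -45.0) -> pd.DataFrame:
    """Detect pulses in telemetry audio, or pass a pulse table through."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pulses_csv is not None:
        log.info("detect: feature-level pulse table supplied, detection skipped")
        df = pd.read_csv(pulses_csv)
        df.to_csv(outdir / "detected_pulses.csv", index=False)
        return df
    if audio_path is None:
        raise ValueError("need either audio or a pulse table")
    from scipy.io import wavfile
    fs, audio = wavfile.read(audio_path)
    params = params or SpectrogramParams(fs_hz=float(fs))
    events = detect_and_extract(np.asarray(audio, dtype=float), params,
                                threshold_db=threshold_db)
    onsets = [e.tfm2_onset_s for e in events]
    df = pd.DataFrame({
        "pulse_id": np.arange(len(events)),
        "time_s": onsets,
        "peak_level_db": [e.peak_level_db for e in events]})
    if len(df) >= 2:
        ipis = compute_ipis(df["time_s"].to_numpy())
        df["ipi_ms"] = np.concatenate([[np.nan], ipis])
    df.to_csv(outdir / "detected_pulses.csv", index=False)
    log.info("detect: %d pulses from %s", len(df), audio_path)
    return df


def run_localize(pulses_csv, levels_csv, arena_yaml=None, outdir=".",
                 calibration=None) -> pd.DataFrame:
    """Augment a pulse table with fitted directions from array levels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pulses = pd.read_csv(pulses_csv)
    levels = pd.read_csv(levels_csv)
    layout = (ArenaLayout.from_yaml(arena_yaml) if arena_yaml
              else default_layout(pulses["condition"].iloc[0]))
    ch_cols = sorted(c for c in levels.columns if c.startswith("ch"))
    occ_cols = sorted(c for c in levels.columns if c.startswith("occ"))
    merged = pulses.merge(levels, on=["bat_id", "flight_number", "pulse_id"],
                          how="left")
    directions, widths, n_used = [], [], []
    n_failed = 0
    for rec in merged.itertuples(index=False):
        lv = np.array([getattr(rec, c) for c in ch_cols], dtype=float)
        occ = (np.array([getattr(rec, c) for c in occ_cols], dtype=float) > 0
               if occ_cols else None)
        try:
            fit = localize_pulse(lv, (rec.x, rec.y), layout, occluded_mask=occ,
                                 calibration=calibration)
            directions.append(pulse_direction(fit))
            widths.append(fit.width_deg)
            n_used.append(fit.n_channels_used)
        except (DirectivityFitError, ValueError):
            n_failed += 1
            directions.append(np.nan)
            widths.append(np.nan)
            n_used.append(0)
    out = pulses.copy()
    out["direction_deg"] = directions
    out["fit_width_deg"] = widths
    out["fit_n_channels"] = n_used
    out.to_csv(outdir / "localized_pulses.csv", index=False)
    log.info("localize: %d pulses, %d failed fits (dropped downstream)",
             len(out), n_failed)
    return out


def run_metrics(trajectories_csv, pulses_csv, arena_yaml=None,
                outdir=".") -> dict:
    """Per-flight kinematic/strobe metrics and per-pulse gaze records."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = pd.read_csv(trajectories_csv)
    pulses = pd.read_csv(pulses_csv)
    if "direction_deg" not in pulses.columns:
        log.info("metrics: no fitted directions, using true directions (bypass)")
        pulses = pulses.assign(direction_deg=pulses["true_direction_deg"])
    layout = (ArenaLayout.from_yaml(arena_yaml) if arena_yaml
              else default_layout(pulses["condition"].iloc[0]))
    keys = ["bat_id", "condition", "flight_number"]
    flight_rows, gaze_frames = [], []
    for (bat, cond, fl), tr in traj.groupby(keys, sort=True):
        pos = tr[["x", "y", "z"]].to_numpy()
        times = tr["t"].to_numpy()
        prof = speed_profile(times, pos)
        row = {"bat_id": bat, "condition": cond, "flight_number": fl}
        try:
            row["max_speed"] = max_flight_speed(prof, pos, layout)
        except IncompleteFlightError:
            row["max_speed"] = np.nan
        try:
            row["meander_width"] = meandering_width(times, pos)
        except UndefinedMeanderError:
            row["meander_width"] = np.nan
        sub = pulses[(pulses["bat_id"] == bat)
                     & (pulses["flight_number"] == fl)].reset_index(drop=True)
        if len(sub):
            gr = gaze_records(sub, layout)
            for c in keys:
                gr[c] = row[c]
            gaze_frames.append(gr)
            rate = in_wall_rate(gr) if np.isfinite(gr["gaze_angle_deg"]).any() else (np.nan, 0, 0)
            row["in_wall_pct"], row["in_wall_n"], row["directed_n"] = rate
            row["delta_pulse_direction_mean"] = float(np.mean(
                delta_pulse_direction(sub["direction_deg"].to_numpy()))) \
                if np.isfinite(sub["direction_deg"]).sum() >= 2 else np.nan
        flight_rows.append(row)
    metrics = pd.DataFrame(flight_rows)
    counts = count_by_type(pulses, cohorts=metrics[keys])
    metrics = metrics.merge(counts, on=keys, how="left")
    metrics.to_csv(outdir / "flight_metrics.csv", index=False)
    gaze = (pd.concat(gaze_frames, ignore_index=True) if gaze_frames
            else pd.DataFrame())
    gaze.to_csv(outdir / "gaze_records.csv", index=False)
    log.info("metrics: %d flights", len(metrics))
    return {"flight_metrics": metrics, "gaze_records": gaze}


def run_stats(flight_metrics_csv, outdir=".", seed: int = 0,
              n_boot: int = 200) -> dict:
    """The mixed-model battery on a per-flight metrics table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = pd.read_csv(flight_metrics_csv).dropna(subset=["max_speed"])
    rng = np.random.default_rng(seed)
    multi_cond = data["condition"].nunique() > 1
    cell_terms = (["condition", "flight_number", "condition:flight_number"]
                  if multi_cond else ["flight_number"])
    out = {}

    for response in ("total_pulses", "multiple_pulses", "doublet_pulses"):
        res = fit_mixed_model(data, response, cell_terms, family="poisson")
        null = fit_mixed_model(data, response, [], family="poisson")
        boot = parametric_bootstrap_null(res, null, n_sim=n_boot, rng=rng)
        emm_by = (["condition", "flight_number"] if multi_cond
                  else ["flight_number"])
        out[response] = {
            "coefficients": dict(zip(res.model.design.column_names,
                                     res.fe_params)),
            "se": dict(zip(res.model.design.column_names, res.bse)),
            "sigma_u": res.sigma_u,
            "aicc": res.aicc(),
            "r2": dict(zip(("marginal", "conditional"), res.r2_nakagawa())),
            "overdispersion": res.overdispersion(),
            "wald_type2": res.wald_type2().to_dict(orient="records"),
            "emmeans": res.marginal_means(emm_by).to_dict(orient="records"),
            "contrasts_tukey": res.pairwise_contrasts(emm_by).to_dict(orient="records"),
            "bootstrap_vs_null": boot,
        }

    # speed models: collinearity screen, then split candidates ranked by AICc
    screen = collinearity_screen(data["flight_number"], data["meander_width"])
    out["collinearity_screen"] = screen
    fl_terms = (["condition", "flight_number", "condition:flight_number"]
                if multi_cond else ["flight_number"])
    md_terms = (["condition", "meander_width", "condition:meander_width"]
                if multi_cond else ["meander_width"])
    res_fl = fit_mixed_model(data, "max_speed", fl_terms, family="gaussian")
    candidates, names = [res_fl], ["speed~flight"]
    if screen["split"]:
        res_md = fit_mixed_model(data.dropna(subset=["meander_width"]),
                                 "max_speed", md_terms, family="gaussian")
        if len(data.dropna(subset=["meander_width"])) == len(data):
            candidates.append(res_md)
            names.append("speed~meander")
    sel = (model_selection_aicc(candidates, names) if len(candidates) > 1
           else None)
    emm_by = (["condition", "flight_number"] if multi_cond else ["flight_number"])
    out["max_speed"] = {
        "coefficients": dict(zip(res_fl.model.design.column_names,
                                 res_fl.fe_params)),
        "sigma_u": res_fl.sigma_u,
        "emmeans": res_fl.marginal_means(emm_by).to_dict(orient="records"),
        "aicc_selection": (sel.to_dict(orient="records") if sel is not None
                           else "single candidate"),
        "split_triggered": screen["split"],
    }

    # pulse count vs standardised speed
    d2 = data.copy()
    d2["speed_z"] = (d2["max_speed"] - d2["max_speed"].mean()) / d2["max_speed"].std()
    sp_terms = (["speed_z", "condition", "speed_z:condition"] if multi_cond
                else ["speed_z"])
    res_sp = fit_mixed_model(d2, "total_pulses", sp_terms, family="poisson")
    out["total_pulses_vs_speed"] = {
        "coefficients": dict(zip(res_sp.model.design.column_names,
                                 res_sp.fe_params)),
        "se": dict(zip(res_sp.model.design.column_names, res_sp.bse)),
        "r2": dict(zip(("marginal", "conditional"), res_sp.r2_nakagawa())),
    }

    path = Path(outdir) / "model_summaries.json"
    path.write_text(json.dumps(out, indent=2, default=_json_default))
    write_manifest(outdir, "stats", {"seed": seed, "n_boot": n_boot}, seed,
                   inputs=[flight_metrics_csv])
    log.info("stats: summaries written to %s", path)
    return out


def run_report(stats_json, flight_metrics_csv, outdir=".") -> str:
    """Human-readable roll-up of the model battery."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = json.loads(Path(stats_json).read_text())
    metrics = pd.read_csv(flight_metrics_csv)
    lines = ["echogaze pipeline report", "=" * 40, ""]
    for cond, sub in metrics.groupby("condition"):
        lines.append(f"condition: {cond}")
        for fl, ss in sub.groupby("flight_number"):
            iw = ss["in_wall_n"].sum()
            dn = ss["directed_n"].sum()
            pct = round(100.0 * iw / dn) if dn else float("nan")
            lines.append(
                f"  flight {fl:>2}: mean total pulses "
                f"{ss['total_pulses'].mean():6.1f}, mean max speed "
                f"{ss['max_speed'].mean():4.2f} m/s, in-wall {pct}% ({iw}/{dn})")
        lines.append("")
    for name, block in summaries.items():
        if isinstance(block, dict) and "emmeans" in block:
            lines.append(f"model {name}: EMMs")
            for row in block["emmeans"]:
                cell = ", ".join(f"{k}={v}" for k, v in row.items()
                                 if k not in ("emmean", "se_link", "ci_lower", "ci_upper"))
                lines.append(f"  {cell}: {row['emmean']:.2f} "
                             f"[{row['ci_lower']:.2f}, {row['ci_upper']:.2f}]")
    text = "\n".join(lines)
    (outdir / "report.txt").write_text(text)
    return text
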