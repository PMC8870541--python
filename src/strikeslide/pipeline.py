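"""Pipeline stages: simulate → segment → analyze → report.

Each stage reads only the previous stage's files, so any stage can be
re-run standalone and outputs are fully determined by the configuration
and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from strikeslide import biomechanics
from strikeslide.adaptation import (
    analyze_transitions,
    fit_blocks,
    spatial_error,
    transitions_table,
)
from strikeslide.config import PipelineConfig
from strikeslide.design import ALUMINUM, BALSA, make_design
from strikeslide.physics import (
    PhysicalConstants,
    SlideEpisode,
    SurfaceCondition,
    fit_friction,
    optimal_cube_speed,
)
from strikeslide.segmentation import (
    SegmentationError,
    SegmentationParams,
    segment_trial,
)
from strikeslide.session_io import read_manifest, read_trial, write_session
from strikeslide.synth import (
    FOREARM,
    WRIST,
    ParticipantProfile,
    simulate_participant_session,
)


def _profile_for(config: PipelineConfig, participant_index: int) -> ParticipantProfile:
    n_wrist = round(config.n_participants * config.wrist_strategy_fraction)
    strategy = WRIST if participant_index < n_wrist else FOREARM
    return ParticipantProfile(
        subjective_mu0=config.subjective_mu0,
        learning_rate=config.learning_rate,
        strategy=strategy,
        body_mass=config.body_mass,
        forearm_length=config.forearm_length,
        hand_length=config.hand_length,
        motor_noise_sd=config.motor_noise_sd,
        marker_noise_sd=config.marker_noise_sd,
    )


def run_simulate(config: PipelineConfig, include_kinematics: bool = True) -> Path:
    """Simulate the cohort and write the session directory.

    Participants cycle through the four counterbalancing groups; the
    first ``wrist_strategy_fraction`` of the cohort are wrist-strategy
    movers.  Identical config + seed reproduce identical files.
    """
    outdir = Path(config.session_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    if manifest.exists():
        manifest.unlink()
    constants = PhysicalConstants(g=config.g, dt=config.dt)
    true_mu = {ALUMINUM: config.mu_aluminum, BALSA: config.mu_balsa}
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(config.n_participants)
    for p in range(config.n_participants):
        session = simulate_participant_session(
            _profile_for(config, p),
            make_design((p % 4) + 1, config.trials_per_block),
            constants,
            seed=seeds[p],
            true_mu=true_mu,
            include_kinematics=include_kinematics,
            participant=p + 1,
        )
        write_session(session, outdir)
    return manifest


def run_segment(config: PipelineConfig) -> Path:
    """Segment every trial in the session; write ``segmentation.csv``.

    Trials whose detectors fail are recorded with a ``error`` message
    instead of aborting the stage; the stage fails only if *no* trial
    segments.
    """
    session_dir = Path(config.session_dir)
    results = Path(config.results_dir)
    results.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(session_dir)
    params = SegmentationParams(
        onset_threshold=config.onset_threshold,
        stop_threshold=config.stop_threshold,
        contact_fraction=config.contact_fraction,
    )
    rows = []
    for row in manifest.itertuples():
        rec = read_trial(session_dir, row)
        out = {
            "participant": rec.participant, "block": rec.block,
            "trial": rec.trial, "trial_global": rec.trial_global,
            "slope_deg": rec.slope, "material": rec.material,
            "target_m": rec.target_distance,
        }
        try:
            seg = segment_trial(rec, params)
            out.update(
                idx_arming_start=seg.idx_arming_start,
                idx_arming_end=seg.idx_arming_end,
                idx_maxFS=seg.idx_maxFS,
                idx_minCS=seg.idx_minCS,
                idx_contact=seg.idx_contact,
                idx_cube_onset=seg.idx_cube_onset,
                idx_cube_stop=seg.idx_cube_stop,
                t_contact=seg.idx_contact * rec.dt,
                finger_speed_at_impact=seg.finger_speed_at_impact,
                initial_cube_speed=seg.initial_cube_speed,
                final_front_edge_m=seg.final_front_edge_position,
                error="",
            )
        except SegmentationError as exc:
            out["error"] = str(exc)
        rows.append(out)
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    if not ok.any():
        raise RuntimeError("segmentation failed on every trial")
    path = results / "segmentation.csv"
    table.to_csv(path, index=False)
    return path


def _optimal_speed_table(config: PipelineConfig) -> pd.DataFrame:
    """Optimal launch speed for every condition (the protocol's reference
    matrix), from the configured friction coefficients."""
    rows = []
    for d in (0.25, 0.50):
        for slope in (-10.0, 0.0, 10.0):
            for material, mu in ((ALUMINUM, config.mu_aluminum),
                                 (BALSA, config.mu_balsa)):
                rows.append(
                    {
                        "target_m": d, "slope_deg": slope, "material": material,
                        "optimal_speed": optimal_cube_speed(
                            d, SurfaceCondition(slope, mu, material), config.g
                        ),
                    }
                )
    return pd.DataFrame(rows)


def run_analyze(config: PipelineConfig) -> dict:
    """Analysis stage; consumes session files + ``segmentation.csv``.

    Emits per-trial friction estimates, the per-trial performance table,
    adaptation fits per block, block-transition reports, the per-trial
    kinetic-energy table, strategy cluster assignments, per-participant
    speed regressions, and the optimal-speed reference matrix.
    """
    session_dir = Path(config.session_dir)
    results = Path(config.results_dir)
    seg_path = results / "segmentation.csv"
    if not seg_path.exists():
        raise FileNotFoundError(f"{seg_path} missing; run the segment stage first")
    seg = pd.read_csv(seg_path, keep_default_na=False)
    manifest = read_manifest(session_dir)
    constants = PhysicalConstants(g=config.g, dt=config.dt)

    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = results / name
        df.to_csv(path, index=False)
        outputs[name] = path

    emit("optimal_speeds.csv", _optimal_speed_table(config))

    # --- per-trial performance + friction + kinetic energy
    model = biomechanics.segment_parameters(
        config.body_mass, config.forearm_length, config.hand_length
    )
    perf_rows, mu_rows, ke_rows = [], [], []
    amp_rows = []
    seg_ok = seg[seg["error"] == ""].set_index("trial_global", drop=False)
    for row in manifest.itertuples():
        key = (row.participant, row.trial_global)
        sub = seg_ok[(seg_ok["participant"] == row.participant)
                     & (seg_ok["trial_global"] == row.trial_global)]
        if sub.empty:
            continue
        s = sub.iloc[0]
        err = spatial_error(s["final_front_edge_m"], row.target_m)
        perf_rows.append(
            {
                "participant": row.participant, "group": row.group,
                "block": row.block, "trial": row.trial,
                "trial_global": row.trial_global, "slope_deg": row.slope_deg,
                "material": row.material, "target_m": row.target_m,
                "launch_speed": s["initial_cube_speed"],
                "finger_speed_at_impact": s["finger_speed_at_impact"],
                "spatial_error_pct": err,
            }
        )
        if not row.file:
            continue
        rec = read_trial(session_dir, row)
        i0, i1 = int(s["idx_cube_onset"]), len(rec.cube_y)
        start = max(int(s["idx_contact"]), 0)
        episode = SlideEpisode(
            times=rec.times[start:] - rec.times[start],
            positions=np.asarray(rec.cube_y[start:], dtype=float),
            v0=float(s["initial_cube_speed"]),
            condition=SurfaceCondition(row.slope_deg, 0.0, row.material),
            constants=constants,
        )
        try:
            est = fit_friction(episode, speed_threshold=config.onset_threshold)
            mu_rows.append(
                {
                    "participant": row.participant, "block": row.block,
                    "trial": row.trial, "trial_global": row.trial_global,
                    "material": row.material, "slope_deg": row.slope_deg,
                    "mu_k": est.mu, "deceleration": est.deceleration,
                    "n_samples": est.n_samples,
                }
            )
        except Exception:
            pass
        angles = biomechanics.joint_angle_series(rec.markers)
        idx_contact = int(s["idx_contact"])
        omegas = biomechanics.angular_velocities_at(angles, idx_contact, rec.dt)
        ke = biomechanics.kinetic_energy_at_impact(
            float(angles["theta_wrist"].iloc[idx_contact]),
            omegas["forearm"], omegas["wrist"], model,
            cube_mass=config.cube_mass,
            cube_speed=float(s["initial_cube_speed"]),
        )
        ke_rows.append(
            {
                "participant": row.participant, "block": row.block,
                "trial": row.trial, "trial_global": row.trial_global,
                "ke_forearm": ke.ke_forearm, "ke_hand": ke.ke_hand,
                "ke_total": ke.ke_total, "ke_cube": ke.ke_cube,
                "efficiency": ke.efficiency, "valid": ke.physically_valid,
            }
        )
        amps = biomechanics.angular_amplitude(
            angles, int(s["idx_arming_end"]), idx_contact
        )
        amp_rows.append(
            {
                "participant": row.participant, "block": row.block,
                "trial": row.trial, "slope_deg": row.slope_deg,
                "material": row.material, "target_m": row.target_m,
                **{f"amp_{k}": v for k, v in amps.items()},
            }
        )

    performance = pd.DataFrame(perf_rows)
    emit("performance.csv", performance)
    if mu_rows:
        emit("friction.csv", pd.DataFrame(mu_rows))
    if ke_rows:
        emit("kinetic_energy.csv", pd.DataFrame(ke_rows))

    # --- adaptation fits per block (cohort-mean series) and transitions
    if performance.empty:
        raise RuntimeError("no segmentable trials; nothing to analyze")
    emit("adaptation_fits.csv", fit_blocks(performance))
    transition_frames = []
    for group, gperf in performance.groupby("group"):
        if gperf["participant"].nunique() < 2:
            continue
        t = transitions_table(
            analyze_transitions(gperf, config.alpha_one_sample, config.alpha_paired)
        )
        t.insert(0, "group", group)
        transition_frames.append(t)
    if transition_frames:
        emit("transitions.csv", pd.concat(transition_frames, ignore_index=True))

    # --- strategy clustering + per-participant regressions
    if amp_rows:
        amp = pd.DataFrame(amp_rows)
        last = amp[amp["trial"] == amp["trial"].max()]
        feats = last.pivot_table(
            index="participant",
            columns=["target_m", "slope_deg", "material"],
            values=["amp_forearm", "amp_wrist", "amp_index"],
        )
        feats.columns = ["|".join(str(c) for c in col) for col in feats.columns]
        feats = feats.dropna(axis=1, how="any")
        if len(feats) >= 2:
            assignments = biomechanics.cluster_strategies(feats, seed=config.seed)
            emit(
                "clusters.csv",
                pd.DataFrame(
                    {
                        "participant": [a.participant for a in assignments],
                        "strategy": [a.cluster for a in assignments],
                    }
                ),
            )
        opt = _optimal_speed_table(config)
        merged = last.merge(opt, on=["target_m", "slope_deg", "material"])
        merged = merged.merge(
            performance[["participant", "block", "trial", "finger_speed_at_impact"]],
            on=["participant", "block", "trial"], how="left",
        )
        reg_rows = []
        for pid, grp in merged.groupby("participant"):
            if len(grp) < 3:
                continue
            for yname in ("amp_forearm", "amp_wrist", "amp_index",
                          "finger_speed_at_impact"):
                try:
                    fit = biomechanics.fit_linear_vs_optimal_speed(
                        grp["optimal_speed"], grp[yname]
                    )
                except ValueError:
                    continue
                reg_rows.append(
                    {
                        "participant": pid, "variable": yname,
                        "slope": fit.slope, "intercept": fit.intercept,
                        "r_squared": fit.r_squared, "retained": fit.retained,
                    }
                )
        if reg_rows:
            emit("regressions.csv", pd.DataFrame(reg_rows))
    return outputs


def run_report(config: PipelineConfig) -> Path:
    """Condense the analysis tables into a machine-readable summary."""
    results = Path(config.results_dir)
    perf_path = results / "performance.csv"
    if not perf_path.exists():
        raise FileNotFoundError(f"{perf_path} missing; run the analyze stage first")
    performance = pd.read_csv(perf_path)
    summary: dict = {
        "n_participants": int(performance["participant"].nunique()),
        "n_trials": int(len(performance)),
        "mean_spatial_error_pct": float(performance["spatial_error_pct"].mean()),
        "final_trial_mean_error_pct": float(
            performance[performance["trial"] == performance["trial"].max()]
            ["spatial_error_pct"].mean()
        ),
    }
    fric_path = results / "friction.csv"
    if fric_path.exists():
        fric = pd.read_csv(fric_path)
        summary["mean_mu_k"] = {
            m: float(g["mu_k"].mean()) for m, g in fric.groupby("material")
        }
    fits_path = results / "adaptation_fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        summary["adaptation"] = {
            str(int(r.block)): {
                "tau": None if pd.isna(r.tau) else float(r.tau),
                "r_squared": None if pd.isna(r.r_squared) else float(r.r_squared),
                "classification": r.classification,
            }
            for r in fits.itertuples()
        }
    trans_path = results / "transitions.csv"
    if trans_path.exists():
        trans = pd.read_csv(trans_path)
        summary["transitions"] = [
            {
                "group": int(r.group),
                "blocks": f"{int(r.block_from)}->{int(r.block_to)}",
                "material": r.material,
                "generalization": bool(r.generalization),
                "significant_change": bool(r.sig_change),
            }
            for r in trans.itertuples()
        ]
    clus_path = results / "clusters.csv"
    if clus_path.exists():
        clus = pd.read_csv(clus_path)
        summary["strategy_counts"] = clus["strategy"].value_counts().to_dict()
    ke_path = results / "kinetic_energy.csv"
    if ke_path.exists():
        ke = pd.read_csv(ke_path)
        summary["mean_ke_efficiency"] = float(ke["efficiency"].mean())
    out = results / "summary.json"
    out.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return out
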