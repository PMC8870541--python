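"""Plain-text session storage: delimited trajectory files plus a manifest.

A session directory holds:

* ``manifest.csv`` — one row per trial with the condition metadata and the
  relative path of the trial's trajectory file;
* ``p<participant>/trial_<n>.csv`` — per-trial time series: ``time_s``,
  ``<marker>_{x,y,z}`` for each marker, and ``cube_y`` (object front-edge
  position along the channel);
* ``p<participant>/ground_truth.json`` — simulator ground truth, present
  only for synthetic sessions.

Everything is uncompressed text so sessions can be inspected, diffed and
versioned; positions are written with 9 significant digits, enough to
round-trip the analysis results to float tolerance.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from strikeslide.synth import Session, TrialGroundTruth, TrialRecord

MARKER_NAMES = ("elbow", "wrist", "mcp", "fingertip")

MANIFEST_COLUMNS = [
    "participant", "group", "block", "trial", "trial_global",
    "slope_deg", "material", "target_m", "dt", "file",
]


def write_session(session: Session, outdir: str | Path) -> Path:
    """Write one participant's session; returns the manifest path.

    Appends to an existing ``manifest.csv`` so cohorts can share one
    session directory.
    """
    outdir = Path(outdir)
    pdir = outdir / f"p{session.participant:02d}"
    pdir.mkdir(parents=True, exist_ok=True)
    rows = []
    gt_out = {}
    for rec, gt in zip(session.trials, session.ground_truth):
        fname = f"p{session.participant:02d}/trial_{rec.trial_global:03d}.csv"
        if rec.times is not None:
            cols = {"time_s": rec.times}
            for name in MARKER_NAMES:
                m = rec.markers[name]
                for j, ax in enumerate("xyz"):
                    cols[f"{name}_{ax}"] = m[:, j]
            cols["cube_y"] = rec.cube_y
            pd.DataFrame(cols).to_csv(outdir / fname, index=False,
                                      float_format="%.9g")
        else:
            fname = ""
        rows.append(
            {
                "participant": rec.participant, "group": rec.group,
                "block": rec.block, "trial": rec.trial,
                "trial_global": rec.trial_global, "slope_deg": rec.slope,
                "material": rec.material, "target_m": rec.target_distance,
                "dt": rec.dt, "file": fname,
            }
        )
        gt_out[str(rec.trial_global)] = {
            "contact_time": gt.contact_time,
            "contact_index": gt.contact_index,
            "launch_speed": gt.launch_speed,
            "finger_impact_speed": gt.finger_impact_speed,
            "true_mu": gt.true_mu,
            "subjective_mu_pre": gt.subjective_mu_pre,
            "stop_position": gt.stop_position,
            "spatial_error_pct": gt.spatial_error_pct,
            "amplitudes": gt.amplitudes,
        }
    (pdir / "ground_truth.json").write_text(json.dumps(gt_out, indent=1))
    manifest = outdir / "manifest.csv"
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest.exists():
        existing = pd.read_csv(manifest, keep_default_na=False)
        existing = existing[existing["participant"] != session.participant]
        df = pd.concat([existing, df], ignore_index=True)
        df = df.sort_values(["participant", "trial_global"])
    df.to_csv(manifest, index=False)
    return manifest


def read_manifest(session_dir: str | Path) -> pd.DataFrame:
    path = Path(session_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.csv in {session_dir}")
    return pd.read_csv(path, keep_default_na=False)


def read_trial(session_dir: str | Path, row) -> TrialRecord:
    """Materialize one TrialRecord from a manifest row."""
    rec = TrialRecord(
        participant=int(row.participant), group=int(row.group),
        block=int(row.block), trial=int(row.trial),
        trial_global=int(row.trial_global), slope=float(row.slope_deg),
        material=str(row.material), target_distance=float(row.target_m),
        dt=float(row.dt),
    )
    if row.file:
        df = pd.read_csv(Path(session_dir) / row.file)
        rec.times = df["time_s"].to_numpy()
        rec.markers = {
            name: df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()
            for name in MARKER_NAMES
        }
        rec.cube_y = df["cube_y"].to_numpy()
    return rec


def read_session(session_dir: str | Path, participant: int) -> Session:
    """Read one participant's trials (and ground truth when present)."""
    from strikeslide.design import make_design

    session_dir = Path(session_dir)
    manifest = read_manifest(session_dir)
    mine = manifest[manifest["participant"] == participant]
    if mine.empty:
        raise ValueError(f"participant {participant} not in manifest")
    trials = [read_trial(session_dir, row) for row in mine.itertuples()]
    group = int(mine["group"].iloc[0])
    trials_per_block = int(mine.groupby("block")["trial"].max().max())
    gt_path = session_dir / f"p{participant:02d}" / "ground_truth.json"
    truths = []
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        for rec in trials:
            g = raw.get(str(rec.trial_global))
            truths.append(
                TrialGroundTruth(
                    contact_time=g["contact_time"],
                    contact_index=g["contact_index"],
                    launch_speed=g["launch_speed"],
                    finger_impact_speed=g["finger_impact_speed"],
                    true_mu=g["true_mu"],
                    subjective_mu_pre=g["subjective_mu_pre"],
                    stop_position=g["stop_position"],
                    spatial_error_pct=g["spatial_error_pct"],
                    amplitudes=g["amplitudes"],
                )
                if g is not None
                else TrialGroundTruth(math.nan, -1, math.nan, math.nan,
                                      math.nan, math.nan, math.nan, math.nan, {})
            )
    return Session(
        participant=participant,
        profile=None,  # profiles are not serialized with the raw data
        design=make_design(group, trials_per_block),
        trials=trials,
        ground_truth=truths,
    )
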