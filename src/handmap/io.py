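"""Plain-text persistence of the synthetic study and stage outputs.

A generated study is written as one directory per participant and
session, holding delimited tables (betas, residuals, wave-run time
series, event schedules, psychophysics trials) plus a JSON manifest
recording the configuration, seeds and ground truth.  Everything round-
trips, so downstream stages can be rerun from disk.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from handmap.config import FINGERS, SESSIONS, StudyConfig
from handmap import peripheral, synth

FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _betas_long(betas: np.ndarray) -> pd.DataFrame:
    r, c, v = betas.shape
    idx = pd.MultiIndex.from_product(
        [range(r), list(FINGERS[:c]), range(v)], names=["run", "condition", "voxel"]
    )
    return pd.DataFrame({"beta": betas.reshape(-1)}, index=idx).reset_index()


def _betas_from_long(df: pd.DataFrame) -> np.ndarray:
    runs = df["run"].max() + 1
    voxels = df["voxel"].max() + 1
    conds = df["condition"].nunique()
    order = {f: i for i, f in enumerate(FINGERS)}
    df = df.sort_values(["run", "condition", "voxel"], key=lambda s: s.map(order) if s.name == "condition" else s)
    return df["beta"].to_numpy().reshape(runs, conds, voxels)


def write_participant(pdata: synth.ParticipantData, root: Path, config: StudyConfig) -> list[Path]:
    """Write one participant's data; returns the files written."""
    written = []
    pdir = Path(root) / f"participant_{pdata.participant:02d}"
    for session in SESSIONS:
        sdir = pdir / session
        sdir.mkdir(parents=True, exist_ok=True)
        pats = pdata.patterns[session]
        f = sdir / "betas.csv"
        _write_csv(_betas_long(pats.betas), f)
        written.append(f)
        res = pats.residuals
        r, t, v = res.shape
        res_df = pd.DataFrame(
            res.reshape(r * t, v), columns=[f"voxel_{i}" for i in range(v)]
        )
        res_df.insert(0, "run", np.repeat(range(r), t))
        res_df.insert(1, "time", np.tile(range(t), r))
        f = sdir / "residuals.csv"
        _write_csv(res_df, f)
        written.append(f)
        drv = pd.DataFrame(
            {cond: pdata.drives[session][cond].values for cond in FINGERS},
            index=list(FINGERS),
        ).rename_axis("afferent_finger").reset_index()
        f = sdir / "drives.csv"
        _write_csv(drv, f)
        written.append(f)
    # localizer runs (baseline session only)
    ldir = pdir / "localizer"
    ldir.mkdir(parents=True, exist_ok=True)
    for run in pdata.wave_runs:
        df = pd.DataFrame(run.data, columns=[f"voxel_{i}" for i in range(run.data.shape[1])])
        df.insert(0, "time_s", np.arange(run.n_samples) * run.tr)
        f = ldir / f"wave_{run.direction}.csv"
        _write_csv(df, f)
        written.append(f)
        sched = pd.DataFrame(run.schedule, columns=["finger", "onset_s", "duration_s"])
        f = ldir / f"schedule_{run.direction}.csv"
        _write_csv(sched, f)
        written.append(f)
    # psychophysics
    trials = pd.concat(
        [
            tt.trials.assign(session=session)
            for (session, _f), tt in sorted(pdata.trials.items())
        ],
        ignore_index=True,
    )
    f = pdir / "trials.csv"
    _write_csv(trials, f)
    written.append(f)
    # ground truth
    truth = pd.DataFrame(pdata.tuning.weights, columns=[f"w_{f}" for f in FINGERS])
    truth.insert(0, "position", pdata.tuning.positions)
    truth["true_cluster"] = pdata.tuning.labels
    f = pdir / "ground_truth.csv"
    _write_csv(truth, f)
    written.append(f)
    return written


def write_study(participants: list, config: StudyConfig, root: Path) -> dict:
    """Write the whole study plus a manifest with content hashes."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    config.to_yaml(root / "config.yaml")
    files = [root / "config.yaml"]
    for pdata in participants:
        files += write_participant(pdata, root, config)
    manifest = {
        "seed": config.seed,
        "n_participants": config.n_participants,
        "files": {str(f.relative_to(root)): sha256_file(f) for f in files},
    }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_participant(root: Path, participant: int, config: StudyConfig) -> synth.ParticipantData:
    """Rehydrate one participant from disk (inverse of write_participant)."""
    pdir = Path(root) / f"participant_{participant:02d}"
    truth = pd.read_csv(pdir / "ground_truth.csv")
    tuning = synth.TuningMap(
        positions=truth["position"].to_numpy(),
        weights=truth[[f"w_{f}" for f in FINGERS]].to_numpy(),
        labels=truth["true_cluster"].to_numpy(dtype=str),
        finger_centers=(np.arange(5) + 0.5) * config.cortical_axis_length / 5.0,
    )
    patterns, drives = {}, {}
    for session in SESSIONS:
        sdir = pdir / session
        betas = _betas_from_long(pd.read_csv(sdir / "betas.csv"))
        res_df = pd.read_csv(sdir / "residuals.csv")
        vcols = [c for c in res_df.columns if c.startswith("voxel_")]
        r = res_df["run"].max() + 1
        t = res_df["time"].max() + 1
        residuals = res_df[vcols].to_numpy().reshape(r, t, len(vcols))
        patterns[session] = synth.VoxelPatternSet(
            session=session, betas=betas, residuals=residuals, ground_truth=tuning
        )
        drv = pd.read_csv(sdir / "drives.csv")
        drives[session] = {
            cond: peripheral.PeripheralDrive(
                condition=cond, values=drv[cond].to_numpy(), session=session
            )
            for cond in FINGERS
        }
    wave_runs = []
    for direction in ("forward", "backward"):
        df = pd.read_csv(pdir / "localizer" / f"wave_{direction}.csv")
        sched = pd.read_csv(pdir / "localizer" / f"schedule_{direction}.csv")
        vcols = [c for c in df.columns if c.startswith("voxel_")]
        wave_runs.append(
            synth.BoldRun(
                data=df[vcols].to_numpy(),
                tr=config.tr_seconds,
                schedule=list(sched.itertuples(index=False, name=None)),
                direction=direction,
            )
        )
    trials_df = pd.read_csv(pdir / "trials.csv")
    trials = {}
    for (session, finger), grp in trials_df.groupby(["session", "finger"]):
        trials[(session, finger)] = synth.TrialTable(trials=grp.reset_index(drop=True))
    return synth.ParticipantData(
        participant=participant, tuning=tuning, patterns=patterns,
        wave_runs=wave_runs, trials=trials, drives=drives,
    )


def load_study(root: Path) -> tuple[StudyConfig, list[synth.ParticipantData]]:
    root = Path(root)
    config = StudyConfig.from_yaml(root / "config.yaml")
    parts = [load_participant(root, p, config) for p in range(config.n_participants)]
    return config, parts


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
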