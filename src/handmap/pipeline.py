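"""End-to-end orchestration: simulate → contrasts → localize → remapping →
RSA → cortical model → psychophysics → report.

Each stage is an ordinary function over in-memory objects; the pipeline
wires them in dependency order, persists every intermediate table as a
delimited file, and writes a JSON summary plus a manifest with content
hashes.  Identical configuration and master seed reproduce every output
byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from handmap.config import CLUSTERS, FINGERS, SESSIONS, StudyConfig, finger_index
from handmap import cortical, glm, io, localizer, peripheral, psychophys, remapping, rsa, synth

log = logging.getLogger("handmap")


class StageError(RuntimeError):
    """Wraps a failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Study configuration plus per-stage analysis parameters."""

    study: StudyConfig = field(default_factory=StudyConfig)
    fdr_q: float = 0.01
    rsa_shrinkage: float | str = "auto"
    include_rest: bool = True
    settle_tol: float = 1e-6
    model_offset: float = 0.0
    gain_bounds: tuple = (0.25, 2.0)
    gain_grid_step: float = 0.05
    n_permutations: int = 5000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study"] = self.study.to_dict()
        d["gain_bounds"] = list(self.gain_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["study"] = StudyConfig.from_dict(d.get("study", {}))
        if "gain_bounds" in d:
            d["gain_bounds"] = tuple(d["gain_bounds"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list[synth.ParticipantData]:
    return synth.simulate_study(cfg.study)


def stage_contrasts(pdata: synth.ParticipantData) -> dict[str, glm.ContrastSet]:
    """The 11 task contrasts per session from the per-run finger betas."""
    return {
        session: glm.compute_contrasts(list(pdata.patterns[session].betas))
        for session in SESSIONS
    }


def stage_localize(pdata: synth.ParticipantData, cfg: PipelineConfig) -> localizer.ClusterMap:
    """Traveling-wave cluster definition over the whole simulated hand area."""
    refs = localizer.build_reference_models(
        tr=cfg.study.tr_seconds,
        on=cfg.study.wave_on_seconds,
        off=cfg.study.wave_off_seconds,
        n_cycles=cfg.study.wave_cycles,
    )
    fcmap = localizer.correlate_voxels(pdata.wave_runs, refs)
    hand_mask = np.ones(pdata.tuning.n_voxels, dtype=bool)
    return localizer.define_clusters(fcmap, hand_mask, q=cfg.fdr_q)


def stage_remapping(
    contrasts: dict[str, glm.ContrastSet],
    clusters: localizer.ClusterMap,
    blocked_finger: str = "D2",
) -> dict:
    """Activity tables, selectivity, and winner-takes-all counts per session."""
    blocked_cluster = CLUSTERS[finger_index(blocked_finger)]
    out = {"activity": {}, "selectivity": {}, "winner_counts": {}}
    subsets = {
        "five_finger": tuple(FINGERS),
        "four_finger": tuple(f for f in FINGERS if f != blocked_finger),
    }
    for session in SESSIONS:
        table = remapping.cluster_activity(contrasts[session], clusters)
        out["activity"][session] = table
        out["selectivity"][session] = remapping.cluster_selectivity(
            table, exclude_finger=blocked_finger, exclude_cluster=blocked_cluster
        )
        out["winner_counts"][session] = {
            name: remapping.winner_map_counts(
                contrasts[session], clusters, subset, target_cluster=blocked_cluster
            )[1]
            for name, subset in subsets.items()
        }
    out["selectivity_delta"] = out["selectivity"]["block"] - out["selectivity"]["baseline"]
    return out


def stage_rsa(
    pdata: synth.ParticipantData, cfg: PipelineConfig
) -> dict[str, rsa.RDM]:
    """Cross-nobis RDM per session, prewhitened with that session's residuals."""
    rdms = {}
    for session in SESSIONS:
        pats = pdata.patterns[session]
        whitener = rsa.noise_whitener(list(pats.residuals), shrinkage=cfg.rsa_shrinkage)
        rdms[session] = rsa.crossnobis_rdm(pats, whitener, include_rest=cfg.include_rest)
    return rdms


def group_mean_rdm(rdms: list[rsa.RDM]) -> rsa.RDM:
    mat = np.mean([r.matrix for r in rdms], axis=0)
    return rsa.RDM(conditions=rdms[0].conditions, matrix=mat, estimator=rdms[0].estimator)


def stage_model(
    activity_baseline: pd.DataFrame,
    activity_block: pd.DataFrame,
    drives_baseline: dict,
    drives_block: dict,
    cfg: PipelineConfig,
) -> dict:
    """Fit the recurrent model at baseline, predict the static block, and
    recover the two homeostatic gains from the block-session activity."""
    model = cortical.fit_baseline(
        activity_baseline.to_numpy(), drives_baseline, b=cfg.model_offset
    )
    base_resp = cortical.settle_all(model, drives_baseline, tol=cfg.settle_tol)
    base_rdm = cortical.model_rdm(base_resp, include_rest=cfg.include_rest)
    static_resp, static_rdm = cortical.predict_static_block(
        model, drives_block, include_rest=cfg.include_rest
    )
    blocked = cfg.study.blocked_finger
    g, gb = cortical.fit_gains(
        model, drives_block, activity_block.to_numpy(), blocked=blocked,
        bounds=cfg.gain_bounds, grid_step=cfg.gain_grid_step,
    )
    homeo = model.with_gains(g, gb, blocked)
    homeo_resp = cortical.settle_all(homeo, drives_block, tol=cfg.settle_tol)
    return {
        "model": model,
        "gain_global": g,
        "gain_blocked": gb,
        "responses": {
            "baseline": base_resp, "static_block": static_resp, "homeostatic_block": homeo_resp,
        },
        "rdms": {
            "baseline": base_rdm,
            "static_block": static_rdm,
            "homeostatic_block": cortical.model_rdm(homeo_resp, include_rest=cfg.include_rest),
        },
    }


def stage_psychophys(pdata: synth.ParticipantData) -> pd.DataFrame:
    """Weibull fit per finger and session.

    A finger performing at chance across the whole grating range (e.g. the
    blocked finger) may have no measurable 82% point; its threshold is
    recorded as missing rather than aborting the stage.
    """
    rows = []
    for (session, finger), table in sorted(pdata.trials.items()):
        row = dict(participant=pdata.participant, session=session, finger=finger)
        try:
            fit = psychophys.fit_weibull(table)
            row.update(
                threshold_mm=fit.threshold, slope=fit.slope,
                r_squared=fit.r_squared, extrapolated=fit.extrapolated,
            )
        except psychophys.FitError:
            row.update(
                threshold_mm=np.nan, slope=np.nan, r_squared=np.nan, extrapolated=True
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _run_stage(name: str, fn, *args, **kwargs):
    log.info("stage %s", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:          # noqa: BLE001 - re-raised with stage name
        raise StageError(name, exc) from exc


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write tables, a summary and a manifest.

    Returns the in-memory summary dictionary.  Any stage failure raises
    :class:`StageError` naming the stage; outputs written so far persist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    participants = _run_stage("simulate", stage_simulate, cfg)
    io.write_study(participants, cfg.study, outdir / "study")

    per_part = []
    for pdata in participants:
        contrasts = _run_stage("glm", stage_contrasts, pdata)
        clusters = _run_stage("localize", stage_localize, pdata, cfg)
        remap = _run_stage(
            "remapping", stage_remapping, contrasts, clusters, cfg.study.blocked_finger
        )
        rdms = _run_stage("rsa", stage_rsa, pdata, cfg)
        psy = _run_stage("psychophys", stage_psychophys, pdata)
        per_part.append(
            dict(pdata=pdata, contrasts=contrasts, clusters=clusters,
                 remap=remap, rdms=rdms, psy=psy)
        )

    # group summaries
    baseline_rdms = [pp["rdms"]["baseline"] for pp in per_part]
    block_rdms = [pp["rdms"]["block"] for pp in per_part]
    canonical = group_mean_rdm(baseline_rdms)
    rdm_change = _run_stage(
        "rsa", rsa.rdm_session_change,
        canonical, group_mean_rdm(block_rdms), canonical,
        cfg.study.blocked_finger, cfg.n_permutations,
    )
    mds = _run_stage("rsa", rsa.mds_group, baseline_rdms)

    mean_activity = {
        session: sum(pp["remap"]["activity"][session] for pp in per_part) / len(per_part)
        for session in SESSIONS
    }
    model_out = _run_stage(
        "model", stage_model,
        mean_activity["baseline"], mean_activity["block"],
        participants[0].drives["baseline"], participants[0].drives["block"], cfg,
    )

    summary = _write_report(cfg, outdir, per_part, mean_activity, rdm_change, mds, model_out)
    return summary


def _write_report(cfg, outdir, per_part, mean_activity, rdm_change, mds, model_out) -> dict:
    tables = outdir / "tables"
    tables.mkdir(exist_ok=True)
    files = []

    def save(df: pd.DataFrame, name: str, index=True):
        f = tables / name
        df.to_csv(f, index=index, float_format=io.FLOAT_FMT)
        files.append(f)

    for session in SESSIONS:
        save(mean_activity[session], f"activity_{session}.csv")
    sel = pd.DataFrame(
        {
            f"{pp['pdata'].participant}_{session}": pp["remap"]["selectivity"][session]
            for pp in per_part for session in SESSIONS
        }
    )
    save(sel, "selectivity.csv")
    counts_rows = []
    for pp in per_part:
        for session in SESSIONS:
            for subset, counts in pp["remap"]["winner_counts"][session].items():
                row = counts.to_dict()
                row.update(participant=pp["pdata"].participant, session=session, subset=subset)
                counts_rows.append(row)
    save(pd.DataFrame(counts_rows), "winner_counts.csv", index=False)
    for session in SESSIONS:
        save(
            pd.concat(
                [pp["rdms"][session].to_long().assign(participant=pp["pdata"].participant)
                 for pp in per_part],
                ignore_index=True,
            ),
            f"rdm_{session}.csv", index=False,
        )
    save(pd.concat([pp["psy"] for pp in per_part], ignore_index=True), "psychophys.csv", index=False)
    mds_df = pd.DataFrame(mds.mean_points, columns=["dim1", "dim2"])
    mds_df.insert(0, "condition", mds.conditions)
    save(mds_df, "mds_group_mean.csv", index=False)
    for name, rdm in model_out["rdms"].items():
        save(rdm.to_long(), f"model_rdm_{name}.csv", index=False)
    save(cortical.response_table(model_out["responses"]["baseline"]), "model_responses_baseline.csv")

    n_clusters = sum(
        1 for c in CLUSTERS if any(pp["clusters"].size(c) > 0 for pp in per_part)
    )
    summary = {
        "config": cfg.to_dict(),
        "counts": {
            "participants": len(per_part),
            "clusters": n_clusters,
            "contrasts_per_run_set": len(glm.CONTRAST_NAMES),
            "reference_models": localizer.build_reference_models(
                tr=cfg.study.tr_seconds, on=cfg.study.wave_on_seconds,
                off=cfg.study.wave_off_seconds, n_cycles=cfg.study.wave_cycles,
            ).n_lags,
        },
        "selectivity_delta_mean": {
            c: float(np.mean([pp["remap"]["selectivity_delta"][c] for pp in per_part]))
            for c in sel.index
        },
        "rdm_change": {
            k: v for k, v in rdm_change.items() if not isinstance(v, dict)
        },
        "rdm_rest_distance_pct_change": rdm_change.get("rest_distance_pct_change", {}),
        "model": {
            "gain_global": model_out["gain_global"],
            "gain_blocked": model_out["gain_blocked"],
            "offset_b": float(model_out["model"].b),
        },
        "psychophys_mean_threshold_mm": {
            session: float(
                pd.concat([pp["psy"] for pp in per_part])
                .query("session == @session")["threshold_mm"].mean()
            )
            for session in SESSIONS
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    files.append(outdir / "summary.json")

    manifest = {
        "seed": cfg.study.seed,
        "files": {str(f.relative_to(outdir)): io.sha256_file(f) for f in files},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
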