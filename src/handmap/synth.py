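"""Synthetic study generator with known ground truth.

Everything the analysis pipeline consumes is generated here: a topographic
voxel tuning map of the S1 hand area, per-run finger beta patterns with
matched residual time series for the baseline and nerve-block sessions,
traveling-wave localizer BOLD runs, and two-alternative forced-choice
psychophysics trial tables.

The hand area is modelled as a 1-D cortical strip.  Each voxel sits at a
position on the strip and is tuned to every finger with a weight that
decays as a Gaussian of the distance to that finger's preferred position,
so neighbouring fingers genuinely overlap — the property the
winner-takes-all "remapping" analysis turns on.  In the block session the
feedforward drive of every voxel is scaled by a global homeostatic gain
(default 0.75), except voxels of the blocked finger's own cluster, whose
gain is raised instead (default 1.25); the blocked finger's afferent
drive itself is reduced to a residual fraction (default 20%) by the
peripheral block operator before it reaches cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from handmap.config import (
    CLUSTERS,
    FINGERS,
    STREAM_TASK,
    STREAM_TRIALS,
    STREAM_TUNING,
    STREAM_WAVE,
    ConfigError,
    StudyConfig,
    finger_index,
)
from handmap import glm, peripheral, psychophys


# ---------------------------------------------------------------------------
# Tuning maps
# ---------------------------------------------------------------------------

@dataclass
class TuningMap:
    """Topographic finger tuning of the simulated hand area.

    ``weights[v, f]`` is voxel v's tuning to finger f, normalised so every
    voxel's maximal weight is 1; ``labels[v]`` is the voxel's true cluster
    ("C1".."C5" — the cluster of its preferred finger).
    """

    positions: np.ndarray          # (V,) along the cortical axis, sorted
    weights: np.ndarray            # (V, 5) nonnegative
    labels: np.ndarray             # (V,) of "C1".."C5"
    finger_centers: np.ndarray     # (5,) preferred positions of D1..D5

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    def cluster_mask(self, cluster: str) -> np.ndarray:
        return self.labels == cluster


def generate_tuning_map(config: StudyConfig, participant: int = 0) -> TuningMap:
    """Place voxels on the cortical strip and assign overlapping finger tuning.

    Voxel positions are drawn uniformly on the strip and sorted, finger
    centres are equally spaced, and the tuning weight of voxel v for
    finger f is ``exp(-(x_v - mu_f)^2 / (2 * tuning_width^2))`` (a one-hot
    assignment to the nearest finger when ``tuning_width == 0``), rescaled
    so each voxel's maximum weight is 1.
    """
    if config.n_voxels < 1:
        raise ConfigError("n_voxels must be >= 1")
    rng = config.child_rng(participant, STREAM_TUNING)
    L = config.cortical_axis_length
    pos = np.sort(rng.uniform(0.0, L, size=config.n_voxels))
    centers = (np.arange(5) + 0.5) * L / 5.0
    dist = pos[:, None] - centers[None, :]
    if config.tuning_width == 0:
        w = np.zeros((config.n_voxels, 5))
        w[np.arange(config.n_voxels), np.argmin(np.abs(dist), axis=1)] = 1.0
    else:
        w = np.exp(-(dist**2) / (2.0 * config.tuning_width**2))
        w = w / w.max(axis=1, keepdims=True)
    labels = np.array([CLUSTERS[j] for j in np.argmax(w, axis=1)])
    return TuningMap(positions=pos, weights=w, labels=labels, finger_centers=centers)


# ---------------------------------------------------------------------------
# Task beta patterns with residuals
# ---------------------------------------------------------------------------

@dataclass
class VoxelPatternSet:
    """Per-run condition beta patterns plus residual time series.

    ``betas`` is (n_runs, 5, n_voxels) — the finger-vs-rest effect of each
    condition in each run; ``residuals`` is (n_runs, n_timepoints,
    n_voxels) with the same spatial covariance as the beta noise, used by
    the RSA stage for prewhitening.
    """

    session: str
    betas: np.ndarray
    residuals: np.ndarray
    ground_truth: TuningMap | None = None

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]


def session_gain_vector(tuning: TuningMap, session: str, config: StudyConfig) -> np.ndarray:
    """Per-voxel multiplicative gain: 1 at baseline; in the block session the
    global gain everywhere except the blocked finger's cluster voxels, which
    get the blocked-cluster gain instead."""
    g = np.ones(tuning.n_voxels)
    if session == "block":
        g[:] = config.gain_global
        blocked_cluster = CLUSTERS[finger_index(config.blocked_finger)]
        g[tuning.cluster_mask(blocked_cluster)] = config.gain_blocked
    elif session != "baseline":
        raise ConfigError(f"unknown session {session!r}")
    return g


def noiseless_means(
    tuning: TuningMap,
    session: str,
    config: StudyConfig,
    drives: dict[str, peripheral.PeripheralDrive],
) -> np.ndarray:
    """(5, V) noiseless condition patterns: gain * (tuning @ drive)."""
    for f in FINGERS:
        if f not in drives:
            raise ValueError(f"missing drive for condition {f}")
        if np.asarray(drives[f].values).shape != (5,):
            raise ValueError("each drive must be a 5-vector")
    g = session_gain_vector(tuning, session, config)
    P = peripheral.drive_matrix(drives)          # (5 fingers, 5 conditions)
    return (g[:, None] * (tuning.weights @ P)).T   # (5 conditions, V)


def generate_session_patterns(
    tuning: TuningMap,
    session: str,
    config: StudyConfig,
    drives: dict[str, peripheral.PeripheralDrive],
    participant: int = 0,
) -> VoxelPatternSet:
    """Per-run betas = noiseless means + spatially correlated Gaussian noise,
    with residual time series sharing the same covariance."""
    means = noiseless_means(tuning, session, config, drives)
    rng = config.child_rng(participant, STREAM_TASK, extra=0 if session == "baseline" else 1)
    V = tuning.n_voxels
    chol = config.cov_factor()
    betas = np.empty((config.n_runs, 5, V))
    residuals = np.empty((config.n_runs, config.n_timepoints, V))
    for r in range(config.n_runs):
        z = rng.standard_normal((5, V))
        betas[r] = means + config.noise_sd * (z @ chol.T)
        zt = rng.standard_normal((config.n_timepoints, V))
        residuals[r] = config.noise_sd * (zt @ chol.T)
    return VoxelPatternSet(session=session, betas=betas, residuals=residuals, ground_truth=tuning)


# ---------------------------------------------------------------------------
# Traveling-wave BOLD runs
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """One traveling-wave localizer run (time x voxel)."""

    data: np.ndarray
    tr: float
    schedule: list          # rows (finger, onset_s, duration_s)
    direction: str          # "forward" | "backward"

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


def wave_schedule(config: StudyConfig, direction: str) -> list:
    """Finger block schedule of the traveling wave: within each cycle the five
    fingers are stimulated consecutively (8 s each by default), giving every
    finger one on-block and a 32-s off period per 40-s cycle.  Backward runs
    traverse the fingers in reverse order."""
    if direction not in ("forward", "backward"):
        raise ConfigError(f"direction must be 'forward' or 'backward', got {direction!r}")
    on = config.wave_on_seconds
    cycle = 5 * on
    order = list(FINGERS) if direction == "forward" else list(FINGERS)[::-1]
    sched = []
    for c in range(config.wave_cycles):
        for k, f in enumerate(order):
            sched.append((f, c * cycle + k * on, on))
    return sched


def wave_n_samples(config: StudyConfig) -> int:
    cycle = config.wave_on_seconds + config.wave_off_seconds
    total = config.wave_cycles * cycle
    n = total / config.tr_seconds
    if abs(n - round(n)) > 1e-9:
        raise ConfigError("run duration must be a whole number of TRs")
    return int(round(n))


def generate_wave_run(
    tuning: TuningMap, config: StudyConfig, direction: str, participant: int = 0, run: int = 0
) -> BoldRun:
    """Synthesise one localizer run.

    Each finger's boxcar is convolved (circularly — the stimulation is
    periodic, so the steady-state periodic response is used) with the
    double-gamma HRF, mixed through the tuning weights, and corrupted with
    spatially correlated Gaussian noise.
    """
    n = wave_n_samples(config)
    sched = wave_schedule(config, direction)
    box = glm.finger_boxcars(sched, n, config.tr_seconds)
    kernel = glm.double_gamma_hrf(config.tr_seconds)
    kpad = np.zeros(n)
    kpad[: kernel.size] = kernel[:n]
    conv = np.real(np.fft.ifft(np.fft.fft(box, axis=0) * np.fft.fft(kpad)[:, None], axis=0))
    signal = conv @ tuning.weights.T
    rng = config.child_rng(participant, STREAM_WAVE, extra=run)
    noise = config.noise_sd * (rng.standard_normal((n, tuning.n_voxels)) @ config.cov_factor().T)
    return BoldRun(data=signal + noise, tr=config.tr_seconds, schedule=sched, direction=direction)


# ---------------------------------------------------------------------------
# Psychophysics trials
# ---------------------------------------------------------------------------

#: grating widths (mm) of the tactile acuity test
GRATING_WIDTHS_MM = (0.5, 1.0, 1.5, 2.5, 3.5)


@dataclass
class TrialTable:
    """2AFC grating-orientation trials with the generating curve parameters."""

    trials: pd.DataFrame     # columns: finger, grating_width_mm, trial_index, correct
    threshold: float | None = None
    slope: float | None = None

    def accuracy_by_width(self) -> pd.Series:
        return self.trials.groupby("grating_width_mm")["correct"].mean()


def generate_psychophys_trials(
    threshold: float,
    slope: float,
    widths: Sequence[float] = GRATING_WIDTHS_MM,
    n_per_width: int = 20,
    seed: int | np.random.Generator = 0,
    finger: str = "D2",
    guess_rate: float = psychophys.DEFAULT_GUESS_RATE,
    lapse_rate: float = psychophys.DEFAULT_LAPSE_RATE,
    psychometric: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TrialTable:
    """Bernoulli 2AFC trials from a Weibull psychometric function.

    ``threshold`` is the grating width (mm) at which the generating curve
    reaches 82% correct and ``slope`` is the Weibull shape parameter; the
    Weibull scale is derived from the two (see
    :func:`handmap.psychophys.weibull_from_threshold`).  ``psychometric``
    may override the success-probability curve entirely.
    """
    widths = np.asarray(widths, dtype=float)
    if widths.size == 0:
        raise ValueError("widths must be nonempty")
    if n_per_width < 1:
        raise ValueError("n_per_width must be >= 1")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if psychometric is None:
        scale, shape = psychophys.weibull_from_threshold(threshold, slope, guess_rate, lapse_rate)
        psychometric = lambda x: psychophys.weibull(x, scale, shape, guess_rate, lapse_rate)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for w in widths:
        p = float(np.clip(psychometric(np.asarray([w]))[0], 0.0, 1.0))
        correct = rng.random(n_per_width) < p
        for t, c in enumerate(correct):
            rows.append((finger, w, t, bool(c)))
    df = pd.DataFrame(rows, columns=["finger", "grating_width_mm", "trial_index", "correct"])
    return TrialTable(trials=df, threshold=threshold, slope=slope)


# ---------------------------------------------------------------------------
# Whole-participant simulation
# ---------------------------------------------------------------------------

#: generating 82% thresholds (mm) for the acuity task: ordinary tactile
#: acuity at baseline; the blocked finger's threshold pushed far beyond the
#: tested range in the block session (performance near chance).
BASELINE_THRESHOLD_MM = 1.5
BLOCKED_THRESHOLD_MM = 30.0
PSYCHOMETRIC_SLOPE = 2.0


@dataclass
class ParticipantData:
    """Everything the pipeline consumes for one simulated participant."""

    participant: int
    tuning: TuningMap
    patterns: dict            # session -> VoxelPatternSet
    wave_runs: list           # [forward BoldRun, backward BoldRun]
    trials: dict              # (session, finger) -> TrialTable
    drives: dict              # session -> {condition -> PeripheralDrive}


def simulate_participant(config: StudyConfig, participant: int) -> ParticipantData:
    """Generate both sessions of one participant from the master seed."""
    spread = peripheral.build_spread(config.spread_scale)
    base_drives = peripheral.baseline_drives(spread)
    blk_drives = peripheral.blocked_drives(base_drives, config.blocked_finger, config.block_fraction)
    tuning = generate_tuning_map(config, participant)
    patterns = {
        "baseline": generate_session_patterns(tuning, "baseline", config, base_drives, participant),
        "block": generate_session_patterns(tuning, "block", config, blk_drives, participant),
    }
    wave_runs = [
        generate_wave_run(tuning, config, "forward", participant, run=0),
        generate_wave_run(tuning, config, "backward", participant, run=1),
    ]
    trials = {}
    for s_idx, session in enumerate(("baseline", "block")):
        for f_idx, f in enumerate(FINGERS):
            thr = BASELINE_THRESHOLD_MM
            if session == "block" and f == config.blocked_finger:
                thr = BLOCKED_THRESHOLD_MM
            rng = config.child_rng(participant, STREAM_TRIALS, extra=10 * s_idx + f_idx)
            trials[(session, f)] = generate_psychophys_trials(
                thr, PSYCHOMETRIC_SLOPE, GRATING_WIDTHS_MM, n_per_width=20, seed=rng, finger=f
            )
    return ParticipantData(
        participant=participant,
        tuning=tuning,
        patterns=patterns,
        wave_runs=wave_runs,
        trials=trials,
        drives={"baseline": base_drives, "block": blk_drives},
    )


def simulate_study(config: StudyConfig) -> list[ParticipantData]:
    """Simulate every participant of the study."""
    return [simulate_participant(config, p) for p in range(config.n_participants)]
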