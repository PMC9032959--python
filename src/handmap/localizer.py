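"""Traveling-wave finger mapping.

The localizer stimulates the five fingers consecutively (8 s each) around
a 40-s cycle, five cycles per run, once in forward (D1→D5) and once in
backward (D5→D1) order.  A voxel preferring one finger responds with a
characteristic temporal lag, so the analysis correlates each voxel's time
course with a bank of lag-shifted HRF-convolved reference models — one
per TR of the cycle (20 models at a 2-s TR) — assigns four consecutive
lags to each finger, Fisher-transforms and aggregates the correlations,
and labels each voxel with the winning finger.  Per finger, a
Benjamini–Hochberg FDR threshold (q < 0.01) over that finger's winning
voxels defines the finger-selective clusters C1–C5 inside the hand-area
mask; clusters need not be contiguous.

Backward runs contain the same lag structure under a reversed finger
order, so their lag→finger assignment is the forward assignment read in
reverse — equivalent to time-reversing the voxel time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from handmap.config import CLUSTERS, ConfigError
from handmap import glm

UNASSIGNED = "unassigned"
R_CLIP = 1.0 - 1e-6


@dataclass
class ReferenceModelSet:
    """Bank of lag-shifted reference time courses.

    ``models[k]`` is the HRF-convolved single-finger boxcar delayed by k
    TRs; lag k belongs to finger ``lag_to_finger[k]`` (forward order).
    """

    models: np.ndarray          # (n_lags, n_samples)
    lag_to_finger: np.ndarray   # (n_lags,) finger index 0..4, forward order
    tr: float
    cycle_seconds: float
    n_fingers: int

    @property
    def n_lags(self) -> int:
        return self.models.shape[0]

    def finger_lags(self, finger: int, direction: str = "forward") -> np.ndarray:
        """Lags belonging to ``finger`` for a run of the given direction."""
        if direction == "forward":
            return np.nonzero(self.lag_to_finger == finger)[0]
        if direction == "backward":
            return np.nonzero(self.lag_to_finger == self.n_fingers - 1 - finger)[0]
        raise ConfigError(f"direction must be 'forward' or 'backward', got {direction!r}")


def build_reference_models(
    tr: float = 2.0,
    on: float = 8.0,
    off: float = 32.0,
    n_fingers: int = 5,
    n_cycles: int = 5,
    hrf: np.ndarray | None = None,
) -> ReferenceModelSet:
    """Construct the lag-shifted reference models of one localizer run.

    The base model is the steady-state (circularly convolved) response to
    an ``on``-seconds block followed by ``off`` seconds of rest, repeated
    ``n_cycles`` times; shifting it by one TR at a time over the full
    cycle yields ``(on + off) / tr`` models.  Consecutive groups of
    ``n_lags / n_fingers`` lags are assigned to each finger.
    """
    cycle = on + off
    n_lags_f = cycle / tr
    if abs(n_lags_f - round(n_lags_f)) > 1e-9:
        raise ConfigError(f"cycle length {cycle}s is not divisible by tr={tr}s")
    n_lags = int(round(n_lags_f))
    if n_lags % n_fingers:
        raise ConfigError(f"{n_lags} lags cannot be split evenly over {n_fingers} fingers")
    per_finger = n_lags // n_fingers
    n_samples = n_cycles * n_lags
    if hrf is None:
        hrf = glm.double_gamma_hrf(tr)
    box = np.zeros(n_samples)
    on_samples = int(round(on / tr))
    for c in range(n_cycles):
        box[c * n_lags : c * n_lags + on_samples] = 1.0
    kpad = np.zeros(n_samples)
    kpad[: hrf.size] = hrf[:n_samples]
    base = np.real(np.fft.ifft(np.fft.fft(box) * np.fft.fft(kpad)))
    models = np.stack([np.roll(base, k) for k in range(n_lags)])
    lag_to_finger = np.repeat(np.arange(n_fingers), per_finger)
    return ReferenceModelSet(
        models=models, lag_to_finger=lag_to_finger, tr=tr,
        cycle_seconds=cycle, n_fingers=n_fingers,
    )


@dataclass
class FingerCorrelationMap:
    """Aggregated voxelwise finger correlations from the wave runs."""

    z: np.ndarray          # (n_voxels, 5) aggregated Fisher-z per finger
    p: np.ndarray          # (n_voxels, 5) per-finger p-values
    winner: np.ndarray     # (n_voxels,) argmax finger index (ties -> lowest)
    valid: np.ndarray      # (n_voxels,) False where r was undefined


def _pearson_matrix(models: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r between every model (rows) and every voxel column; returns (r, valid)."""
    n = data.shape[0]
    mz = models - models.mean(axis=1, keepdims=True)
    mz /= np.linalg.norm(mz, axis=1, keepdims=True)
    dz = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(dz, axis=0)
    valid = norms > 0
    dz = np.where(valid, dz / np.where(valid, norms, 1.0), 0.0)
    return mz @ dz, valid


def correlate_voxels(
    runs: Sequence, refs: ReferenceModelSet, aggregate: str = "mean"
) -> FingerCorrelationMap:
    """Correlate wave-run voxels with every reference model and aggregate.

    Per run, the Pearson r of each voxel with each lag model is clipped
    and Fisher-transformed; each finger's value is the ``aggregate``
    ("mean" or "max") of the z values over its lags (the lag→finger
    assignment reversed for backward runs), and fingers are then averaged
    across runs.  p-values come from the t statistic of the aggregated
    (back-transformed) correlation with n - 2 degrees of freedom.
    Constant-voxel time courses have undefined r and are flagged invalid.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    directions = {getattr(r, "direction", "forward") for r in runs}
    if not runs or directions - {"forward", "backward"}:
        raise ConfigError("runs must be a nonempty list of forward/backward BoldRuns")
    n_vox = runs[0].data.shape[1]
    n_fingers = refs.n_fingers
    z_sum = np.zeros((n_vox, n_fingers))
    valid_all = np.ones(n_vox, dtype=bool)
    n_time = None
    for run in runs:
        n_time = run.data.shape[0]
        r, valid = _pearson_matrix(refs.models, run.data)
        valid_all &= valid
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))   # (n_lags, n_vox)
        zf = np.empty((n_vox, n_fingers))
        for f in range(n_fingers):
            lags = refs.finger_lags(f, run.direction)
            zf[:, f] = z[lags].mean(axis=0) if aggregate == "mean" else z[lags].max(axis=0)
        z_sum += zf
    z_mean = z_sum / len(runs)
    rbar = np.tanh(z_mean)
    df = n_time - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rbar * np.sqrt(df / (1.0 - rbar**2))
    p = stats.t.sf(t, df)
    winner = np.argmax(z_mean, axis=1)
    return FingerCorrelationMap(z=z_mean, p=p, winner=winner, valid=valid_all)


@dataclass
class ClusterMap:
    """Per-voxel finger-cluster labels inside the hand-area mask."""

    labels: np.ndarray      # (n_voxels,) "C1".."C5" or "unassigned"
    hand_mask: np.ndarray   # (n_voxels,) bool

    def mask(self, cluster: str) -> np.ndarray:
        return self.labels == cluster

    def size(self, cluster: str) -> int:
        return int(self.mask(cluster).sum())

    def sizes(self) -> dict[str, int]:
        return {c: self.size(c) for c in CLUSTERS}

    @classmethod
    def from_truth(cls, labels: np.ndarray, hand_mask: np.ndarray | None = None) -> "ClusterMap":
        labels = np.asarray(labels)
        if hand_mask is None:
            hand_mask = np.ones(labels.shape[0], dtype=bool)
        return cls(labels=labels.copy(), hand_mask=np.asarray(hand_mask, dtype=bool))


def define_clusters(
    fcmap: FingerCorrelationMap, hand_mask: np.ndarray, q: float = 0.01
) -> ClusterMap:
    """Winner-takes-all cluster definition with per-finger FDR control.

    For each finger, Benjamini–Hochberg FDR at level ``q`` is applied to
    the p-values of the hand-mask voxels whose winning finger it is;
    survivors are labelled with that finger's cluster.  Clusters are
    disjoint by construction (each voxel has a unique winner).
    """
    if not 0.0 < q < 1.0:
        raise ConfigError(f"q must lie in (0, 1), got {q}")
    hand_mask = np.asarray(hand_mask, dtype=bool)
    if not hand_mask.any():
        raise ConfigError("hand mask is empty")
    labels = np.full(hand_mask.shape[0], UNASSIGNED, dtype=object)
    for f in range(fcmap.z.shape[1]):
        cand = hand_mask & fcmap.valid & (fcmap.winner == f)
        idx = np.nonzero(cand)[0]
        if idx.size == 0:
            continue
        reject, *_ = multipletests(fcmap.p[idx, f], alpha=q, method="fdr_bh")
        labels[idx[reject]] = CLUSTERS[f]
    return ClusterMap(labels=labels.astype(str), hand_mask=hand_mask)
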