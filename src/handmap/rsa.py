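"""Cross-validated Mahalanobis (cross-nobis) representational similarity.

Pattern dissimilarities between finger conditions are measured with the
cross-validated Mahalanobis distance: activity patterns are prewhitened
with a shrinkage estimate of the residual spatial covariance, condition
differences are computed independently in pairs of runs, and the inner
product between run pairs is averaged.  Cross-validation makes the
estimator unbiased — its expectation is exactly zero when two conditions
do not differ (individual estimates can go below zero).  Rest enters as
an extra condition with uniform activity of zero, so distance-from-rest
is meaningful without any mean-centering.

RDMs are visualised by classical MDS, aligned across participants with
scaling-free Procrustes (rotation/reflection + translation only) and
averaged; the displayed plane is rotated to carry the maximal
between-finger variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from handmap.config import FINGERS, finger_index

REST = "rest"


# ---------------------------------------------------------------------------
# Noise whitening
# ---------------------------------------------------------------------------

@dataclass
class NoiseWhitener:
    """Symmetric whitening transform from GLM residuals.

    ``transform.T @ transform`` equals the inverse of the shrunk residual
    covariance; applying ``transform`` to patterns (voxels on the last
    axis) makes the noise approximately white.
    """

    transform: np.ndarray
    shrinkage: float
    dof: int

    def apply(self, patterns: np.ndarray) -> np.ndarray:
        return np.asarray(patterns, dtype=float) @ self.transform.T


def _pooled_centered(residuals) -> tuple[np.ndarray, int]:
    if isinstance(residuals, np.ndarray) and residuals.ndim == 2:
        residuals = [residuals]
    runs = [np.asarray(r, dtype=float) for r in residuals]
    centered = [r - r.mean(axis=0, keepdims=True) for r in runs]
    dof = sum(r.shape[0] - 1 for r in runs)
    return np.vstack(centered), dof


def analytic_shrinkage(x: np.ndarray) -> float:
    """Ledoit–Wolf-style shrinkage intensity toward the diagonal.

    ``x`` holds centered samples in rows.  The intensity is the ratio of
    the summed sampling variances of the off-diagonal covariance entries
    to their summed squares, clipped to [0, 1].
    """
    n = x.shape[0]
    if n < 2:
        return 1.0
    s = (x.T @ x) / n
    x2 = x**2
    sum_w2 = (x2.T @ x2)                   # sum_t (x_ti x_tj)^2
    var_s = (sum_w2 / n - s**2) * n / (n - 1) ** 2
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = float(np.sum(s[off] ** 2))
    if denom <= 0:
        return 1.0
    return float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0))


def noise_whitener(
    residuals, shrinkage: float | str = "auto", floor: float = 1e-10
) -> NoiseWhitener:
    """Shrinkage covariance of the pooled residuals, inverted via its
    symmetric square root.

    ``residuals`` is one (time x voxel) array or a sequence/stack of them;
    runs are demeaned and pooled.  The covariance is shrunk toward its
    diagonal with an analytically chosen intensity (or a fixed one), and
    eigenvalues are floored (with a warning) if too few time points leave
    the estimate non-positive-definite.
    """
    x, dof = _pooled_centered(residuals)
    if dof < 1:
        raise ValueError("need more than one time point to estimate covariance")
    cov = (x.T @ x) / dof
    lam = analytic_shrinkage(x) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"shrinkage must lie in [0, 1], got {lam}")
    shrunk = (1.0 - lam) * cov + lam * np.diag(np.diag(cov))
    evals, evecs = np.linalg.eigh(shrunk)
    min_allowed = floor * max(evals.max(), 1.0)
    if evals.min() < min_allowed:
        warnings.warn(
            "residual covariance is not positive definite; applying a "
            f"regularization floor of {min_allowed:.3g} to its eigenvalues",
            RuntimeWarning,
        )
        evals = np.maximum(evals, min_allowed)
    transform = (evecs * evals**-0.5) @ evecs.T
    return NoiseWhitener(transform=transform, shrinkage=lam, dof=dof)


# ---------------------------------------------------------------------------
# RDMs
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """Symmetric condition-by-condition dissimilarity structure."""

    conditions: list[str]
    matrix: np.ndarray
    estimator: str = "crossnobis"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.conditions),) * 2:
            raise ValueError("matrix shape must match the condition list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        self.matrix = m

    # -- entry access -------------------------------------------------------
    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.conditions.index(a), self.conditions.index(b)])

    def finger_pairs(self, fingers: Sequence[str] | None = None) -> list[tuple[str, str]]:
        fingers = [f for f in (fingers or FINGERS) if f in self.conditions]
        return list(itertools.combinations(fingers, 2))

    def pair_values(self, pairs) -> np.ndarray:
        return np.array([self.get(a, b) for a, b in pairs])

    def mean_interfinger(self, fingers: Sequence[str] | None = None) -> float:
        return float(self.pair_values(self.finger_pairs(fingers)).mean())

    def rest_distances(self) -> pd.Series:
        if REST not in self.conditions:
            raise ValueError("RDM has no rest condition")
        return pd.Series(
            {f: self.get(f, REST) for f in self.conditions if f != REST},
            name="distance_from_rest",
        )

    def to_long(self) -> pd.DataFrame:
        rows = [
            (a, b, self.get(a, b))
            for a, b in itertools.combinations(self.conditions, 2)
        ]
        return pd.DataFrame(rows, columns=["condition_i", "condition_j", "distance"])


def crossnobis_rdm(
    patterns, whitener: NoiseWhitener | None = None, include_rest: bool = True
) -> RDM:
    """Cross-validated Mahalanobis distances between conditions.

    ``patterns`` is a (runs x conditions x voxels) array (or an object
    with a ``betas`` attribute of that shape; condition order D1..D5).
    For every condition pair the whitened pattern difference is computed
    in each run, the inner products over all unordered run pairs are
    averaged, and the result is normalised by the voxel count so values
    are comparable across regions of different size.  Rest is an all-zero
    pattern in every run.
    """
    betas = np.asarray(getattr(patterns, "betas", patterns), dtype=float)
    if betas.ndim != 3:
        raise ValueError(f"expected (runs, conditions, voxels), got shape {betas.shape}")
    n_runs, n_cond, n_vox = betas.shape
    if n_runs < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    conditions = list(FINGERS[:n_cond]) if n_cond <= 5 else [f"cond{i}" for i in range(n_cond)]
    if include_rest:
        betas = np.concatenate([betas, np.zeros((n_runs, 1, n_vox))], axis=1)
        conditions = conditions + [REST]
        n_cond += 1
    u = whitener.apply(betas) if whitener is not None else betas
    pairs = list(itertools.combinations(range(n_cond), 2))
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    deltas = u[:, ii, :] - u[:, jj, :]                     # (runs, pairs, voxels)
    s1 = deltas.sum(axis=0)
    cross = ((s1**2).sum(axis=-1) - (deltas**2).sum(axis=(0, 2))) / 2.0
    n_rp = n_runs * (n_runs - 1) / 2.0
    dist = cross / (n_rp * n_vox)
    mat = np.zeros((n_cond, n_cond))
    mat[ii, jj] = dist
    mat[jj, ii] = dist
    return RDM(conditions=conditions, matrix=mat, estimator="crossnobis")


def euclidean_rdm(responses: np.ndarray, conditions: Sequence[str]) -> RDM:
    """Plain pairwise Euclidean distances (used for model responses)."""
    responses = np.asarray(responses, dtype=float)
    diff = responses[:, None, :] - responses[None, :, :]
    mat = np.sqrt((diff**2).sum(axis=-1))
    return RDM(conditions=list(conditions), matrix=mat, estimator="euclidean")


# ---------------------------------------------------------------------------
# MDS + Procrustes group averaging
# ---------------------------------------------------------------------------

def classical_mds(rdm: RDM, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of an RDM.

    Double-centers the squared dissimilarities and keeps the leading
    eigenvectors; an RDM that is exactly a planar Euclidean distance
    matrix is reproduced up to rigid motion.
    """
    d2 = rdm.matrix**2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_dims]
    lam = np.maximum(evals[order], 0.0)
    return evecs[:, order] * np.sqrt(lam)


def procrustes_align(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Align ``source`` to ``target`` by rotation/reflection + translation.

    No scaling is applied, so each participant's inter-point distances
    are preserved exactly.  Returns the aligned points and the disparity
    (sum of squared point-wise differences after alignment).
    """
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    a, b = source - mu_s, target - mu_t
    r, _ = linalg.orthogonal_procrustes(a, b)
    aligned = a @ r + mu_t
    return aligned, float(np.sum((aligned - target) ** 2))


@dataclass
class GroupConfiguration:
    """Per-participant MDS points after alignment, plus the group mean."""

    conditions: list[str]
    participant_points: np.ndarray    # (n_participants, n_conditions, 2)
    mean_points: np.ndarray           # (n_conditions, 2)
    disparities: np.ndarray           # (n_participants,)


def mds_group(rdms: Sequence[RDM], n_dims: int = 2) -> GroupConfiguration:
    """Classical MDS per participant, scaling-free Procrustes to the first
    participant, group averaging, and a final rotation of all
    configurations onto the axes of maximal between-finger variance of
    the mean configuration."""
    conditions = rdms[0].conditions
    for r in rdms:
        if r.conditions != conditions:
            raise ValueError("all RDMs must share the same condition list")
    configs = [classical_mds(r, n_dims) for r in rdms]
    ref = configs[0]
    aligned, disp = [], []
    for cfg in configs:
        pts, d = procrustes_align(cfg, ref)
        aligned.append(pts)
        disp.append(d)
    aligned = np.stack(aligned)
    mean_pts = aligned.mean(axis=0)
    finger_rows = [i for i, c in enumerate(conditions) if c != REST] or list(range(len(conditions)))
    centered = mean_pts[finger_rows] - mean_pts[finger_rows].mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    rot = vt.T
    return GroupConfiguration(
        conditions=list(conditions),
        participant_points=aligned @ rot,
        mean_points=mean_pts @ rot,
        disparities=np.asarray(disp),
    )


# ---------------------------------------------------------------------------
# Session-change summaries
# ---------------------------------------------------------------------------

def rank_correlation(rdm_a: RDM, rdm_b: RDM, fingers: Sequence[str] | None = None) -> float:
    """Spearman rank correlation between interfinger dissimilarity vectors."""
    pairs = rdm_a.finger_pairs(fingers)
    rho, _ = stats.spearmanr(rdm_a.pair_values(pairs), rdm_b.pair_values(pairs))
    return float(rho)


def permutation_pvalue(
    rdm: RDM,
    canonical: RDM,
    fingers: Sequence[str] | None = None,
    n_permutations: int = 5000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Observed Spearman rho against a finger-label-permutation null.

    Permutes the finger labels of ``rdm`` and recomputes the rank
    correlation with the canonical RDM.  All label permutations are
    enumerated when feasible, otherwise sampled.  The p-value uses the
    add-one rule, so it can never be smaller than 1/(n+1).
    """
    fingers = [f for f in (fingers or FINGERS) if f in rdm.conditions]
    pairs = list(itertools.combinations(range(len(fingers)), 2))
    obs_vec = np.array([rdm.get(fingers[i], fingers[j]) for i, j in pairs])
    can_vec = np.array([canonical.get(fingers[i], fingers[j]) for i, j in pairs])
    obs, _ = stats.spearmanr(obs_vec, can_vec)
    all_perms = list(itertools.permutations(range(len(fingers))))
    if len(all_perms) <= n_permutations:
        perms = all_perms
    else:
        rng = rng or np.random.default_rng(0)
        perms = [tuple(rng.permutation(len(fingers))) for _ in range(n_permutations)]
    count = 0
    for perm in perms:
        vec = np.array([rdm.get(fingers[perm[i]], fingers[perm[j]]) for i, j in pairs])
        rho, _ = stats.spearmanr(vec, can_vec)
        if rho >= obs - 1e-12:
            count += 1
    return float(obs), count / len(perms)


def _pct_change(base: float, new: float) -> float:
    return 100.0 * (new - base) / base


def rdm_session_change(
    baseline: RDM,
    block: RDM,
    canonical: RDM | None = None,
    blocked_finger: str = "D2",
    n_permutations: int = 5000,
) -> dict:
    """Summaries of how the representational structure changed under block.

    Reports the percent change of mean interfinger dissimilarity
    (overall; among the nonblocked fingers; for the blocked finger's
    pairs with its neighbours and with non-neighbours), per-finger
    distance-from-rest changes where rest is present, the rank
    correlation between the two session RDMs (shape preservation), and —
    when a canonical RDM is supplied — the block RDM's rank correlation
    with it plus a label-permutation p-value.
    """
    if baseline.conditions != block.conditions:
        raise ValueError("baseline and block RDMs must share the same condition list")
    j = finger_index(blocked_finger)
    nonblocked = [f for f in FINGERS if f != blocked_finger]
    neighbors = [FINGERS[k] for k in (j - 1, j + 1) if 0 <= k < len(FINGERS)]
    non_neighbors = [f for f in nonblocked if f not in neighbors]
    out = {
        "pct_change_overall": _pct_change(
            baseline.mean_interfinger(), block.mean_interfinger()
        ),
        "pct_change_nonblocked": _pct_change(
            baseline.mean_interfinger(nonblocked), block.mean_interfinger(nonblocked)
        ),
        "pct_change_blocked_neighbors": _pct_change(
            np.mean([baseline.get(blocked_finger, f) for f in neighbors]),
            np.mean([block.get(blocked_finger, f) for f in neighbors]),
        ),
        "pct_change_blocked_non_neighbors": _pct_change(
            np.mean([baseline.get(blocked_finger, f) for f in non_neighbors]),
            np.mean([block.get(blocked_finger, f) for f in non_neighbors]),
        ),
        "rank_correlation_sessions": rank_correlation(baseline, block),
    }
    if REST in baseline.conditions:
        base_rest = baseline.rest_distances()
        block_rest = block.rest_distances()
        out["rest_distance_change"] = (block_rest - base_rest).to_dict()
        out["rest_distance_pct_change"] = (
            100.0 * (block_rest - base_rest) / base_rest
        ).to_dict()
    if canonical is not None:
        rho, p = permutation_pvalue(block, canonical, n_permutations=n_permutations)
        out["rank_correlation_canonical"] = rho
        out["permutation_pvalue"] = p
    return out
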