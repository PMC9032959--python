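"""Minimal general linear model stage.

Implements the canonical double-gamma haemodynamic response function (HRF),
boxcar design matrices with temporal derivatives, per-voxel ordinary
least-squares fitting, and the 11-contrast set used for the finger-tapping
tasks (each finger vs. rest, each finger vs. the other fingers, all fingers
vs. rest), with fixed-effects averaging across runs as the unweighted mean
of per-run contrast estimates.

Rest is an implicit baseline: only the five finger boxcars (plus their
temporal derivatives and an intercept) enter the design, so a finger's
beta already is its finger-vs-rest effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from handmap.config import FINGERS

#: conventional double-gamma parameters: response peak 6 s, undershoot peak
#: 16 s, unit dispersions, undershoot ratio 1/6.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 1.0 / 6.0


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


def double_gamma_hrf(tr: float, length: float = 32.0) -> np.ndarray:
    """Sample the double-gamma HRF at ``tr`` spacing on [0, length].

    The kernel is the difference of two gamma densities,
    ``g(t; 6, 1) - g(t; 16, 1) / 6``, normalised to unit peak.  Returns
    ``floor(length / tr) + 1`` samples; the value at t = 0 is exactly 0.
    """
    if tr <= 0 or length <= 0:
        raise ValueError("tr and length must be positive")
    t = np.arange(int(np.floor(length / tr)) + 1) * tr
    h = stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
    h = h - HRF_RATIO * stats.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP, scale=HRF_UNDERSHOOT_DISP
    )
    return h / np.max(h)


def finger_boxcars(schedule: Sequence[tuple[str, float, float]], n_samples: int, tr: float) -> np.ndarray:
    """Sample 0/1 indicator time courses (n_samples x 5) from an event schedule.

    ``schedule`` rows are (finger_label, onset_seconds, duration_seconds).
    A sample at time ``k * tr`` is on if it falls inside [onset, onset+duration).
    """
    box = np.zeros((n_samples, len(FINGERS)))
    t = np.arange(n_samples) * tr
    for finger, onset, duration in schedule:
        j = FINGERS.index(finger)
        box[(t >= onset) & (t < onset + duration), j] = 1.0
    return box


@dataclass
class DesignMatrix:
    """Time x regressor design with labelled columns.

    Columns: five HRF-convolved finger boxcars, their temporal derivatives,
    and an intercept (11 columns total).
    """

    matrix: np.ndarray
    labels: list[str]

    @property
    def finger_columns(self) -> list[int]:
        return [self.labels.index(f) for f in FINGERS]


def build_design(
    schedule: Sequence[tuple[str, float, float]], n_samples: int, tr: float,
    hrf: np.ndarray | None = None,
) -> DesignMatrix:
    """HRF-convolved boxcar design with temporal derivatives and intercept."""
    if hrf is None:
        hrf = double_gamma_hrf(tr)
    box = finger_boxcars(schedule, n_samples, tr)
    conv = np.column_stack(
        [np.convolve(box[:, j], hrf)[:n_samples] for j in range(box.shape[1])]
    )
    deriv = np.gradient(conv, axis=0)
    mat = np.column_stack([conv, deriv, np.ones(n_samples)])
    labels = list(FINGERS) + [f"{f}_deriv" for f in FINGERS] + ["intercept"]
    return DesignMatrix(mat, labels)


@dataclass
class GlmFit:
    """Per-voxel OLS fit: betas (regressor x voxel), residuals (time x voxel)."""

    betas: np.ndarray
    residuals: np.ndarray
    labels: list[str]
    dof: int

    def finger_betas(self) -> np.ndarray:
        """(5, n_voxels) betas of the finger regressors, in D1..D5 order."""
        idx = [self.labels.index(f) for f in FINGERS]
        return self.betas[idx]


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares of a (time x voxel) run on the design.

    Raises :class:`SingularDesignError` naming the collinear columns if
    the design is rank deficient.
    """
    X = design.matrix
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[0] != X.shape[0]:
        raise ValueError(f"row mismatch: data {data.shape[0]} vs design {X.shape[0]}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose R diagonal is (near) zero in a pivoted QR
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = r_diag < max(X.shape) * np.finfo(float).eps * r_diag.max()
        cols = [design.labels[i] for i in np.nonzero(bad)[0]] or design.labels
        raise SingularDesignError(cols)
    betas, *_ = np.linalg.lstsq(X, data, rcond=None)
    resid = data - X @ betas
    return GlmFit(betas=betas, residuals=resid, labels=list(design.labels), dof=X.shape[0] - rank)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

CONTRAST_NAMES = (
    [f"{f}_vs_rest" for f in FINGERS]
    + [f"{f}_vs_others" for f in FINGERS]
    + ["all_vs_rest"]
)


@dataclass
class ContrastSet:
    """The 11 task contrasts, per run and fixed-effects averaged.

    ``per_run`` is (n_runs, 11, n_voxels); ``average`` the unweighted mean
    across runs.  Temporal-derivative regressors never enter a contrast.
    """

    per_run: np.ndarray
    names: list[str]

    @property
    def average(self) -> np.ndarray:
        return self.per_run.mean(axis=0)

    def get(self, name: str, averaged: bool = True) -> np.ndarray:
        i = self.names.index(name)
        return self.average[i] if averaged else self.per_run[:, i]

    def finger_vs_rest(self, averaged: bool = True) -> np.ndarray:
        """(5, n_voxels) finger-vs-rest maps (run-averaged by default)."""
        idx = [self.names.index(f"{f}_vs_rest") for f in FINGERS]
        return self.average[idx] if averaged else self.per_run[:, idx]


def contrast_weights() -> np.ndarray:
    """(11, 5) weight matrix applied to the five finger betas."""
    n = len(FINGERS)
    w = np.zeros((11, n))
    for j in range(n):
        w[j, j] = 1.0                          # finger vs rest
        w[n + j] = -1.0 / (n - 1)              # finger vs others
        w[n + j, j] = 1.0
    w[2 * n] = 1.0 / n                         # all fingers vs rest
    return w


def compute_contrasts(finger_betas_per_run: Sequence[np.ndarray]) -> ContrastSet:
    """Contrasts from per-run finger beta maps.

    Accepts either :class:`GlmFit` objects or raw (5, n_voxels) arrays of
    finger-vs-rest betas, one per run.  Fixed-effects averaging is the
    unweighted mean across runs.
    """
    if len(finger_betas_per_run) == 0:
        raise ValueError("at least one run is required")
    mats = [
        fb.finger_betas() if isinstance(fb, GlmFit) else np.asarray(fb, dtype=float)
        for fb in finger_betas_per_run
    ]
    n_vox = mats[0].shape[1]
    for m in mats:
        if m.shape != (len(FINGERS), n_vox):
            raise ValueError(f"run beta shape {m.shape} != ({len(FINGERS)}, {n_vox})")
    w = contrast_weights()
    per_run = np.stack([w @ m for m in mats])
    return ContrastSet(per_run=per_run, names=list(CONTRAST_NAMES))
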