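"""Pooled afferent drives under single-finger stimulation.

Mechanical stimulation of one finger excites tactile afferents terminating
on the other fingers as well (skin and tissue couple mechanically), so
even "local" peripheral input is distributed across the hand.  This module
models that spread with a simple exponential kernel on finger index and
provides the nerve-block operator, which scales the blocked finger's
pooled drive down to a residual fraction in every stimulation condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from handmap.config import FINGERS, finger_index

#: default spread scale: nearest neighbour receives ~30% of self-drive
DEFAULT_SPREAD_SCALE = 1.0 / np.log(1.0 / 0.3)


@dataclass(frozen=True)
class SpreadModel:
    """Mechanical spread of afferent drive between fingers.

    ``matrix[i, j]`` is the pooled drive to finger ``i``'s afferents when
    finger ``j`` is stimulated; columns are normalised so self-drive is 1.
    """

    matrix: np.ndarray
    scale: float

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (5, 5) or (m < 0).any():
            raise ValueError("spread matrix must be 5x5 nonnegative")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("self-drive must be 1 after normalization")


@dataclass(frozen=True)
class PeripheralDrive:
    """Pooled per-finger afferent drive for one stimulation condition."""

    condition: str          # stimulated finger, "D1".."D5"
    values: np.ndarray      # 5-vector, ordered D1..D5
    session: str = "baseline"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (5,):
            raise ValueError(f"drive must be a 5-vector, got shape {v.shape}")
        if (v < 0).any():
            raise ValueError("afferent drives must be nonnegative")


def build_spread(scale: float = DEFAULT_SPREAD_SCALE) -> SpreadModel:
    """Exponential-decay spread: ``S[i, j] = exp(-|i - j| / scale)``.

    ``scale = 0`` degenerates to the identity (no spread).
    """
    if scale < 0:
        raise ValueError(f"spread scale must be >= 0, got {scale}")
    idx = np.arange(5)
    dist = np.abs(idx[:, None] - idx[None, :])
    if scale == 0:
        S = np.eye(5)
    else:
        S = np.exp(-dist / scale)
    return SpreadModel(matrix=S, scale=scale)


def baseline_drives(spread: SpreadModel) -> dict[str, PeripheralDrive]:
    """One drive per single-finger stimulation condition (baseline)."""
    return {
        f: PeripheralDrive(condition=f, values=spread.matrix[:, j].copy(), session="baseline")
        for j, f in enumerate(FINGERS)
    }


def apply_block(drive: PeripheralDrive, finger: str, fraction: float) -> PeripheralDrive:
    """Scale the blocked finger's pooled drive by ``fraction``.

    The nerve block silences (most of) the blocked finger's afferents, so
    its pooled drive drops to ``fraction`` of baseline in *every*
    stimulation condition; all other entries are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    j = finger_index(finger)
    values = drive.values.copy()
    values[j] *= fraction
    return replace(drive, values=values, session="block")


def blocked_drives(
    drives: dict[str, PeripheralDrive], finger: str, fraction: float
) -> dict[str, PeripheralDrive]:
    """Apply the block operator to every stimulation condition."""
    return {cond: apply_block(d, finger, fraction) for cond, d in drives.items()}


def drive_matrix(drives: dict[str, PeripheralDrive]) -> np.ndarray:
    """(5, 5) matrix with column j = drive vector under stimulation of finger j."""
    return np.column_stack([drives[f].values for f in FINGERS])
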