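"""Study configuration and deterministic seed derivation.

A :class:`StudyConfig` holds every knob of the synthetic two-session study:
the size of the simulated hand area, the topographic overlap of finger
tuning, noise structure, and the nerve-block parameters (residual afferent
fraction and the homeostatic gain constants applied in the block session).

Seed policy
-----------
All randomness flows from a single integer master seed.  Child seeds are
derived with :class:`numpy.random.SeedSequence` spawned from the fixed
tuple ``(master_seed, participant_index, stream_id)`` where ``stream_id``
is a small named constant per data stream (task runs, wave runs, trials).
Identical config + seed therefore regenerates the whole study
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
import yaml

FINGERS = ("D1", "D2", "D3", "D4", "D5")
CLUSTERS = ("C1", "C2", "C3", "C4", "C5")
SESSIONS = ("baseline", "block")

# stream ids for SeedSequence derivation (fixed; see module docstring)
STREAM_TUNING = 1
STREAM_TASK = 2
STREAM_WAVE = 3
STREAM_TRIALS = 4


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class StudyConfig:
    """Parameters of the synthetic nerve-block study.

    Parameters
    ----------
    n_participants : int
        Number of simulated participants.
    n_voxels : int
        Voxels in the S1 hand-area mask.
    cortical_axis_length : float
        Length of the 1-D cortical axis along which voxels are placed
        (arbitrary units; finger centres are equally spaced on it).
    tuning_width : float
        Gaussian decay scale of a voxel's finger tuning with distance
        along the axis.  0 gives perfectly selective voxels.
    n_runs : int
        Imaging runs per session/task.
    n_timepoints : int
        Residual time points emitted per task run (for prewhitening).
    noise_sd : float
        SD of the additive Gaussian noise on betas / BOLD samples.
    residual_cov : "identity" or (n_voxels, n_voxels) SPD matrix
        Spatial covariance of the noise and residuals.
    block_fraction : float
        Residual afferent drive of the blocked finger (0.20 = activity
        reduced to 20% of baseline).
    gain_global : float
        Multiplicative gain applied to every cluster in the block session
        (homeostatic global reduction, default 0.75).
    gain_blocked : float
        Gain applied to the blocked finger's cluster instead of the global
        one (homeostatic up-regulation, default 1.25).
    blocked_finger : str
        The anaesthetized finger (default "D2").
    wave_on_seconds, wave_off_seconds, wave_cycles : stimulation schedule
        of the traveling-wave localizer (8 s on / 32 s off, 5 cycles).
    spread_scale : float
        Exponential length scale of mechanical afferent spread between
        fingers; the default gives the nearest neighbour ~30% of the
        stimulated finger's drive.
    tr_seconds : float
        Sampling interval of the BOLD time series.
    seed : int
        Master seed.
    """

    n_participants: int = 8
    n_voxels: int = 200
    cortical_axis_length: float = 10.0
    tuning_width: float = 1.0
    n_runs: int = 4
    n_timepoints: int = 100
    noise_sd: float = 0.4
    residual_cov: Union[str, np.ndarray] = "identity"
    block_fraction: float = 0.20
    gain_global: float = 0.75
    gain_blocked: float = 1.25
    blocked_finger: str = "D2"
    wave_on_seconds: float = 8.0
    wave_off_seconds: float = 32.0
    wave_cycles: int = 5
    spread_scale: float = field(default=float(1.0 / np.log(1.0 / 0.3)))
    tr_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_participants", "n_voxels", "n_runs", "n_timepoints", "wave_cycles"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.block_fraction <= 1.0:
            raise ConfigError(f"block_fraction must lie in [0, 1], got {self.block_fraction}")
        if self.tuning_width < 0:
            raise ConfigError(f"tuning_width must be >= 0, got {self.tuning_width}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.gain_global <= 0 or self.gain_blocked <= 0:
            raise ConfigError("gains must be > 0")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be > 0")
        if self.blocked_finger not in FINGERS:
            raise ConfigError(f"unknown finger label {self.blocked_finger!r}")
        if isinstance(self.residual_cov, str):
            if self.residual_cov != "identity":
                raise ConfigError("residual_cov must be 'identity' or an SPD matrix")
        else:
            cov = np.asarray(self.residual_cov, dtype=float)
            if cov.shape != (self.n_voxels, self.n_voxels):
                raise ConfigError("residual_cov shape must be (n_voxels, n_voxels)")
            if not np.allclose(cov, cov.T):
                raise ConfigError("residual_cov must be symmetric")
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ConfigError("residual_cov must be positive definite")

    # -- covariance helpers -------------------------------------------------
    def cov_matrix(self) -> np.ndarray:
        if isinstance(self.residual_cov, str):
            return np.eye(self.n_voxels)
        return np.asarray(self.residual_cov, dtype=float)

    def cov_factor(self) -> np.ndarray:
        """Cholesky factor used to colour white noise."""
        return np.linalg.cholesky(self.cov_matrix())

    # -- seeds --------------------------------------------------------------
    def child_rng(self, participant: int, stream: int, extra: int = 0) -> np.random.Generator:
        """Deterministic per-participant, per-stream generator."""
        ss = np.random.SeedSequence((int(self.seed), int(participant), int(stream), int(extra)))
        return np.random.default_rng(ss)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["residual_cov"], str):
            d["residual_cov"] = np.asarray(d["residual_cov"]).tolist()
        return {
            k: (v.item() if isinstance(v, np.generic) else v) for k, v in d.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        rc = d.get("residual_cov", "identity")
        if not isinstance(rc, str):
            d["residual_cov"] = np.asarray(rc, dtype=float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def finger_index(label: str) -> int:
    try:
        return FINGERS.index(label)
    except ValueError as exc:
        raise ConfigError(f"unknown finger label {label!r}") from exc


def cluster_index(label: str) -> int:
    try:
        return CLUSTERS.index(label)
    except ValueError as exc:
        raise ConfigError(f"unknown cluster label {label!r}") from exc
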