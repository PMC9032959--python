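"""Five-unit recurrent cortical model of the finger clusters.

Each cortical cluster i updates its activity as

    c_i(t) = alpha_i * w_i^T p + b + l_i^T c(t-1)

where ``p`` is the vector of pooled peripheral inputs from the five
fingers, ``w_i`` the feedforward weights of cluster i, ``b`` a scalar
offset, ``l_i`` the lateral connection field (short-range excitation,
long-range inhibition, a function of inter-cluster distance only), and
``alpha_i`` a multiplicative gain on the feedforward term only — the
lateral and offset terms are not scaled.  Iterating from rest (c = 0)
settles to the fixed point of the linear system, typically within six
time steps for the default kernel.

The nerve block is modelled by feeding blocked peripheral drives through
the model.  Holding all parameters fixed gives the *static* prediction,
which collapses the blocked finger's representation disproportionately;
letting two gain parameters vary — one shared by the non-blocked units
and one for the blocked unit — implements the homeostatic account (the
fitted values in the reference configuration are 0.75 and 1.25).

The offset ``b`` and the sign pattern of the lateral kernel are jointly
unidentifiable (shifting the assumed rest state trades one for the
other); no attempt is made to resolve this.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from handmap.config import FINGERS, finger_index
from handmap.peripheral import PeripheralDrive, drive_matrix
from handmap.rsa import RDM, REST, euclidean_rdm

#: default lateral kernel by inter-cluster distance: short-range
#: excitation, long-range inhibition (spectral radius ~0.22 < 1)
DEFAULT_LATERAL_KERNEL = (0.0, 0.15, -0.05, -0.10, -0.10)


class NonConvergenceError(RuntimeError):
    """Settlement did not converge within the iteration budget."""

    def __init__(self, message: str, last_state: np.ndarray):
        super().__init__(message)
        self.last_state = last_state


def lateral_matrix(kernel: Sequence[float] = DEFAULT_LATERAL_KERNEL) -> np.ndarray:
    """Distance-dependent lateral connectivity: L[i, j] = kernel[|i - j|]."""
    kernel = np.asarray(kernel, dtype=float)
    idx = np.arange(5)
    return kernel[np.abs(idx[:, None] - idx[None, :])]


@dataclass
class CorticalModel:
    """Gains, feedforward weights, offset and lateral connectivity."""

    alpha: np.ndarray           # (5,) per-cluster gains
    W: np.ndarray               # (5, 5), row i = w_i
    b: float
    L: np.ndarray               # (5, 5) lateral connections
    gain_on_lateral: bool = False   # alternative reading: gain scales the
                                    # lateral+offset input as well

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.alpha.shape != (5,) or self.W.shape != (5, 5) or self.L.shape != (5, 5):
            raise ValueError("alpha must be (5,), W and L must be (5, 5)")
        rad = self.spectral_radius()
        if rad >= 1.0:
            raise ValueError(f"lateral matrix spectral radius {rad:.3f} >= 1; dynamics diverge")

    def spectral_radius(self) -> float:
        L = self.L * self.alpha[:, None] if self.gain_on_lateral else self.L
        return float(np.max(np.abs(np.linalg.eigvals(L))))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "W": self.W.tolist(),
            "b": float(self.b),
            "L": self.L.tolist(),
            "gain_on_lateral": bool(self.gain_on_lateral),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorticalModel":
        return cls(
            alpha=np.asarray(d["alpha"], float),
            W=np.asarray(d["W"], float),
            b=float(d["b"]),
            L=np.asarray(d["L"], float),
            gain_on_lateral=bool(d.get("gain_on_lateral", False)),
        )

    def with_gains(self, gain_global: float, gain_blocked: float, blocked: str = "D2") -> "CorticalModel":
        """Constrained gain vector: the blocked unit's gain *replaces* the
        shared one (e.g. (0.75, 1.25, 0.75, 0.75, 0.75) for a D2 block)."""
        alpha = np.full(5, float(gain_global))
        alpha[finger_index(blocked)] = float(gain_blocked)
        return replace(self, alpha=alpha)

    def step(self, c: np.ndarray, p: np.ndarray) -> np.ndarray:
        if self.gain_on_lateral:
            return self.alpha * (self.W @ p + self.b + self.L @ c)
        return self.alpha * (self.W @ p) + self.b + self.L @ c


@dataclass
class CorticalResponse:
    """Settled cluster activities for one stimulation condition."""

    condition: str
    c: np.ndarray
    iterations: int
    converged: bool


def _drive_vector(p) -> np.ndarray:
    return np.asarray(getattr(p, "values", p), dtype=float)


def settle(
    model: CorticalModel, p, tol: float = 1e-6, max_iter: int = 100
) -> CorticalResponse:
    """Iterate the update equation from rest until the activity settles.

    Starts at c = 0 and stops when the max-norm change drops below
    ``tol``; raises :class:`NonConvergenceError` (carrying the last
    state) if ``max_iter`` is reached first.  ``iterations`` counts the
    update steps that changed the state by at least ``tol`` (with no
    lateral connections the model settles in one step).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pv = _drive_vector(p)
    cond = getattr(p, "condition", "")
    c = np.zeros(5)
    for it in range(1, max_iter + 1):
        c_new = model.step(c, pv)
        if np.max(np.abs(c_new - c)) < tol:
            return CorticalResponse(condition=cond, c=c_new, iterations=it - 1, converged=True)
        c = c_new
    raise NonConvergenceError(
        f"settlement did not converge within {max_iter} iterations", c
    )


def fixed_point(model: CorticalModel, p) -> np.ndarray:
    """Closed-form settled state: solve (I - L) c = diag(alpha) W p + b."""
    pv = _drive_vector(p)
    if model.gain_on_lateral:
        A = np.eye(5) - model.L * model.alpha[:, None]
        rhs = model.alpha * (model.W @ pv + model.b)
    else:
        A = np.eye(5) - model.L
        rhs = model.alpha * (model.W @ pv) + model.b
    if model.spectral_radius() >= 1.0:
        raise ValueError("spectral radius >= 1: no stable fixed point")
    return np.linalg.solve(A, rhs)


def settle_all(
    model: CorticalModel, drives: dict[str, PeripheralDrive], tol: float = 1e-6,
    max_iter: int = 100,
) -> dict[str, CorticalResponse]:
    return {f: settle(model, drives[f], tol, max_iter) for f in FINGERS}


def response_table(responses: dict[str, CorticalResponse]) -> pd.DataFrame:
    """(condition x cluster) settled-activity table, rows D1..D5."""
    return pd.DataFrame(
        {f: responses[f].c for f in FINGERS}, index=[f"C{i+1}" for i in range(5)]
    ).T


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_baseline(
    target: pd.DataFrame | np.ndarray,
    drives: dict[str, PeripheralDrive],
    L: np.ndarray | None = None,
    b: float | None = 0.0,
    method: str = "regression",
    n_iter: int = 200,
    tol: float = 1e-12,
) -> CorticalModel:
    """Fit feedforward weights (and optionally the offset) so the settled
    responses match the baseline activity table (all gains fixed at 1).

    ``target`` is (5 stimulation conditions x 5 clusters).  The
    closed-form ``"regression"`` method regresses the lateral-corrected
    targets ``(I - L) C`` on the drives; ``"iterative"`` starts from the
    plain multiple regression (ignoring the lateral term) and repeatedly
    adjusts the regression targets by the settled-activity error until
    the settled responses reproduce the data.  Both agree on noiseless
    targets.

    With five stimulation conditions the shared offset ``b`` is not
    identifiable jointly with ``W`` (the constant column lies in the span
    of the drives), mirroring the rest-state ambiguity of the model.  By
    default ``b`` is held fixed at 0; pass a known value, or ``b=None``
    to estimate the minimum-norm joint solution.
    """
    if L is None:
        L = lateral_matrix()
    C = np.asarray(target, dtype=float).T          # (clusters, conditions)
    P = drive_matrix(drives)                       # (fingers, conditions)
    if np.linalg.matrix_rank(P) < 5:
        raise np.linalg.LinAlgError(
            "drive matrix is rank deficient: feedforward weights not identifiable"
        )

    def regress(M: np.ndarray) -> tuple[np.ndarray, float]:
        # rows of M are per-cluster targets over conditions
        if b is not None:
            W = np.linalg.lstsq(P.T, (M - b).T, rcond=None)[0].T
            return W, float(b)
        # shared offset: joint minimum-norm least squares over all clusters
        X = np.zeros((25, 26))
        for i in range(5):
            X[5 * i : 5 * i + 5, 5 * i : 5 * i + 5] = P.T
        X[:, 25] = 1.0
        coef, *_ = np.linalg.lstsq(X, M.reshape(-1), rcond=None)
        return coef[:25].reshape(5, 5), float(coef[25])

    if method == "regression":
        W, b_hat = regress((np.eye(5) - L) @ C)
    elif method == "iterative":
        M = C.copy()                               # ignore lateral term initially
        W, b_hat = regress(M)
        for _ in range(n_iter):
            model = CorticalModel(alpha=np.ones(5), W=W, b=b_hat, L=L)
            settled = np.column_stack(
                [fixed_point(model, drives[f]) for f in FINGERS]
            )
            err = C - settled
            if np.max(np.abs(err)) < tol:
                break
            M = M + err
            W, b_hat = regress(M)
    else:
        raise ValueError("method must be 'regression' or 'iterative'")
    return CorticalModel(alpha=np.ones(5), W=W, b=b_hat, L=L)


def predict_static_block(
    model: CorticalModel,
    blocked: dict[str, PeripheralDrive],
    include_rest: bool = True,
    tol: float = 1e-9,
) -> tuple[dict[str, CorticalResponse], RDM]:
    """Settle the baseline-fitted model on blocked drives without changing
    any parameter, and return the responses with their Euclidean RDM."""
    if not np.allclose(model.alpha, 1.0):
        raise ValueError("static prediction requires the baseline model (all gains 1)")
    responses = settle_all(model, blocked, tol=tol)
    return responses, model_rdm(responses, include_rest=include_rest)


def gain_sse(
    model: CorticalModel,
    gains: tuple[float, float],
    blocked_drives: dict[str, PeripheralDrive],
    target: np.ndarray,
    blocked: str,
) -> float:
    """Squared error of the settled responses under a candidate gain pair."""
    cand = model.with_gains(gains[0], gains[1], blocked)
    settled = np.column_stack([fixed_point(cand, blocked_drives[f]) for f in FINGERS])
    return float(np.sum((settled - target.T) ** 2))


def fit_gains(
    model: CorticalModel,
    blocked_drives: dict[str, PeripheralDrive],
    target: pd.DataFrame | np.ndarray,
    blocked: str = "D2",
    bounds: tuple[float, float] = (0.25, 2.0),
    grid_step: float = 0.05,
) -> tuple[float, float]:
    """Two-parameter homeostatic gain fit.

    Finds the shared gain of the non-blocked units and the blocked unit's
    gain that minimise the squared error between the settled responses on
    blocked drives and the block-session activity table, by a coarse grid
    search over ``bounds`` followed by local refinement.  Candidates with
    divergent dynamics are discarded with a warning.
    """
    target = np.asarray(target, dtype=float)
    grid = np.arange(bounds[0], bounds[1] + grid_step / 2, grid_step)
    best, best_sse = None, np.inf
    for g, gb in itertools.product(grid, grid):
        try:
            sse = gain_sse(model, (g, gb), blocked_drives, target, blocked)
        except ValueError:
            warnings.warn(f"gain candidate ({g:.2f}, {gb:.2f}) discarded: divergent dynamics")
            continue
        if sse < best_sse:
            best, best_sse = (g, gb), sse
    if best is None:
        raise RuntimeError("no stable gain candidate found on the search grid")

    def objective(x):
        try:
            return gain_sse(model, (x[0], x[1]), blocked_drives, target, blocked)
        except ValueError:
            return np.inf

    res = optimize.minimize(
        objective, x0=np.asarray(best), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
    )
    x = res.x if res.fun <= best_sse else np.asarray(best)
    return float(x[0]), float(x[1])


def model_rdm(
    responses: dict[str, CorticalResponse] | Sequence[CorticalResponse],
    include_rest: bool = True,
) -> RDM:
    """Euclidean distances between the settled 5-unit response vectors,
    optionally with rest as the zero vector."""
    if isinstance(responses, dict):
        responses = [responses[f] for f in FINGERS if f in responses]
    conditions = [r.condition or f"cond{i}" for i, r in enumerate(responses)]
    vecs = [r.c for r in responses]
    if len(vecs) < 2:
        raise ValueError("need at least 2 conditions for an RDM")
    if include_rest:
        conditions = conditions + [REST]
        vecs = vecs + [np.zeros(5)]
    return euclidean_rdm(np.stack(vecs), conditions)
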