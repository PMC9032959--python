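"""Univariate cluster activity, selectivity, and winner-takes-all maps.

These are the analyses in which apparent "remapping" of a deprived
cortical territory can arise purely methodologically: because finger
tuning overlaps, excluding the deprived finger from a winner-takes-all
assignment re-labels its cluster's voxels with the neighbouring fingers
even when nothing about the underlying map has changed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from handmap.config import CLUSTERS, FINGERS, ConfigError, cluster_index, finger_index
from handmap.glm import ContrastSet
from handmap.localizer import ClusterMap, UNASSIGNED


def _finger_maps(contrasts) -> np.ndarray:
    """(5, V) run-averaged finger-vs-rest maps from a ContrastSet or array."""
    if isinstance(contrasts, ContrastSet):
        return contrasts.finger_vs_rest()
    arr = np.asarray(contrasts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 5:
        raise ValueError(f"expected (5, n_voxels) finger maps, got {arr.shape}")
    return arr


def cluster_activity(contrasts, clusters: ClusterMap) -> pd.DataFrame:
    """Mean finger-vs-rest activity of every finger in every cluster.

    Returns a 5x5 DataFrame (rows = fingers, columns = clusters); entries
    of empty clusters are NaN (missing, not zero).
    """
    maps = _finger_maps(contrasts)
    if not any(clusters.size(c) for c in CLUSTERS):
        raise ConfigError("cluster map has no assigned voxels")
    table = pd.DataFrame(np.nan, index=list(FINGERS), columns=list(CLUSTERS))
    for c in CLUSTERS:
        m = clusters.mask(c)
        if m.any():
            table[c] = maps[:, m].mean(axis=1)
    return table


def cluster_selectivity(
    table: pd.DataFrame, exclude_finger: str | None = "D2", exclude_cluster: str | None = "C2"
) -> pd.Series:
    """Target-minus-nontarget selectivity per retained cluster.

    For each cluster (its target finger being the one it is selective
    for), selectivity is the target finger's mean activity minus the mean
    activity of the nontarget fingers; the excluded finger is dropped
    from the nontargets and the excluded cluster from the output, leaving
    three nontarget fingers per cluster with the defaults.
    """
    if exclude_finger is not None:
        finger_index(exclude_finger)
    if exclude_cluster is not None:
        cluster_index(exclude_cluster)
    out = {}
    for c in CLUSTERS:
        if c == exclude_cluster:
            continue
        target = FINGERS[cluster_index(c)]
        if target == exclude_finger:
            raise ConfigError(
                f"cannot exclude finger {target}: it is the target of retained cluster {c}"
            )
        nontargets = [f for f in FINGERS if f != target and f != exclude_finger]
        out[c] = float(table.loc[target, c] - table.loc[nontargets, c].mean())
    return pd.Series(out, name="selectivity")


@dataclass
class WinnerMap:
    """Per-voxel winner-takes-all finger assignment.

    ``labels[v]`` is the winning finger or ``"unassigned"`` (maximum not
    above zero, when positivity thresholding is on, the fate of voxels
    with no supra-zero response).
    """

    labels: np.ndarray
    finger_subset: tuple[str, ...]
    thresholded: bool

    def count(self, finger: str) -> int:
        return int((self.labels == finger).sum())


def winner_takes_all(
    contrasts,
    finger_subset: Iterable[str] = FINGERS,
    threshold_positive: bool = True,
) -> WinnerMap:
    """Assign every voxel to the finger with the strongest response.

    Only fingers in ``finger_subset`` compete.  With positivity
    thresholding (the default), voxels whose maximal response does not
    exceed 0 are left unassigned; without it every voxel is assigned.
    Ties go to the lowest finger index.
    """
    subset = tuple(finger_subset)
    if not subset:
        raise ConfigError("finger subset must be nonempty")
    idx = [finger_index(f) for f in subset]
    maps = _finger_maps(contrasts)[idx]
    win = np.argmax(maps, axis=0)
    labels = np.asarray([subset[k] for k in win], dtype=object)
    if threshold_positive:
        labels[maps.max(axis=0) <= 0] = UNASSIGNED
    return WinnerMap(labels=labels.astype(str), finger_subset=subset, thresholded=threshold_positive)


def winner_map_counts(
    contrasts,
    clusters: ClusterMap,
    finger_subset: Iterable[str] = FINGERS,
    target_cluster: str = "C2",
    threshold_positive: bool = True,
) -> tuple[WinnerMap, pd.Series]:
    """Winner-takes-all map plus voxel counts inside the target cluster.

    Counts cover each finger in the subset, the unassigned voxels, and
    the grouped tallies used to quantify apparent invasion of a deprived
    territory: the target cluster's own finger (when included), its
    immediate neighbours, and the non-neighbouring fingers.
    """
    wmap = winner_takes_all(contrasts, finger_subset, threshold_positive)
    tmask = clusters.mask(target_cluster)
    in_cluster = wmap.labels[tmask]
    counts = {f: int((in_cluster == f).sum()) for f in wmap.finger_subset}
    counts[UNASSIGNED] = int((in_cluster == UNASSIGNED).sum())
    t_idx = cluster_index(target_cluster)
    target_finger = FINGERS[t_idx]
    neighbors = [FINGERS[j] for j in (t_idx - 1, t_idx + 1) if 0 <= j < len(FINGERS)]
    non_neighbors = [f for f in FINGERS if f != target_finger and f not in neighbors]
    if target_finger in wmap.finger_subset:
        counts[f"group_{target_finger}"] = counts[target_finger]
    counts["group_neighbors"] = sum(counts.get(f, 0) for f in neighbors)
    counts["group_non_neighbors"] = sum(counts.get(f, 0) for f in non_neighbors)
    return wmap, pd.Series(counts, name=f"counts_in_{target_cluster}")


def session_delta(baseline: pd.Series | pd.DataFrame, block: pd.Series | pd.DataFrame):
    """Per-entry block-minus-baseline change of any summary table."""
    return block - baseline
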