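"""Cluster-based permutation testing for paired condition comparisons.

One engine serves both the 1-D spectra comparison and the 2-D comodulogram
comparison: cell-wise paired t-values are thresholded at ``thresh_p``
(two-sided), contiguous suprathreshold cells (positive and negative
separately; 4-connectivity in 2-D) form clusters whose mass is the sum of
t-values, and each observed mass is referred to the permutation distribution
of the maximum absolute cluster mass under random sign flips of the
subject-wise difference maps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage, stats

from .core import StructureError

__all__ = ["Cluster", "ClusterTestResult", "paired_cluster_test"]


@dataclass
class Cluster:
    cells: np.ndarray  #: indices into the flattened map
    mass: float  #: integrated t-value (sign retained)
    p: float

    def bounds(self, shape) -> tuple:
        """(min, max) index along each axis — cluster bounding box."""
        idx = np.unravel_index(self.cells, shape)
        return tuple((int(ax.min()), int(ax.max())) for ax in idx)


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    df: int
    t_thresh: float
    clusters: List[Cluster] = field(default_factory=list)
    n_perm: int = 0

    def significant(self, cluster_p: float = 0.05) -> List[Cluster]:
        return [c for c in self.clusters if c.p < cluster_p]


def _connectivity(ndim: int) -> np.ndarray:
    # 4-connectivity in 2-D, simple adjacency in 1-D
    return ndimage.generate_binary_structure(ndim, 1)


def _cluster_masses(t_map: np.ndarray, t_thresh: float, structure: np.ndarray):
    """List of (cells, mass) for suprathreshold clusters of either sign."""
    out = []
    finite = np.isfinite(t_map)
    for sign in (1.0, -1.0):
        above = finite & (sign * t_map > t_thresh)
        if not above.any():
            continue
        labels, n = ndimage.label(above, structure=structure)
        for k in range(1, n + 1):
            cells = np.flatnonzero(labels.ravel() == k)
            out.append((cells, float(t_map.ravel()[cells].sum())))
    return out


def paired_cluster_test(
    a: np.ndarray,
    b: np.ndarray,
    thresh_p: float = 0.01,
    n_perm: int = 500,
    seed: Optional[int] = None,
) -> ClusterTestResult:
    """Paired cluster-mass permutation test of ``b`` vs ``a``.

    Parameters
    ----------
    a, b:
        Arrays of shape ``(n_subjects, *map_shape)`` with paired subjects
        along the first axis; NaN cells are treated as missing everywhere.
    thresh_p:
        Two-sided cell-wise p-value forming the cluster threshold.
    n_perm:
        Number of sign-flip permutations for the max-mass null.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StructureError(
            f"conditions must be paired subject-wise: shapes {a.shape} vs {b.shape}"
        )
    n_sub = a.shape[0]
    if n_sub < 3:
        raise StructureError(f"need >= 3 paired subjects, got {n_sub}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small; cluster p-values will be coarse",
            stacklevel=2,
        )
    map_shape = a.shape[1:]
    diffs = (b - a).reshape(n_sub, -1)
    valid = np.all(np.isfinite(diffs), axis=0)

    df = n_sub - 1
    t_thresh = float(stats.t.ppf(1.0 - thresh_p / 2.0, df))
    sq_sum = np.sum(diffs**2, axis=0)  # invariant under sign flips

    def t_from_means(means: np.ndarray) -> np.ndarray:
        # means: (..., n_cells); pooled with the flip-invariant sum of squares
        var = (sq_sum - n_sub * means**2) / df
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = means / np.sqrt(var / n_sub)
        t = np.where(valid, t, np.nan)
        return t

    t_obs = t_from_means(diffs.mean(axis=0)).reshape(map_shape)
    structure = _connectivity(t_obs.ndim)
    observed = _cluster_masses(t_obs, t_thresh, structure)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    perm_means = signs @ diffs / n_sub  # (n_perm, n_cells)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_perm = t_from_means(perm_means[i]).reshape(map_shape)
        masses = _cluster_masses(t_perm, t_thresh, structure)
        if masses:
            null_max[i] = max(abs(m) for _, m in masses)

    clusters = []
    for cells, mass in observed:
        p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_perm)
        clusters.append(Cluster(cells=cells, mass=mass, p=float(p)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterTestResult(
        t_map=t_obs, df=df, t_thresh=t_thresh, clusters=clusters, n_perm=n_perm
    )
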