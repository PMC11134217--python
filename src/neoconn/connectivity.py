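"""Functional connectivity at regional and voxel scales.

Edge weights between BOLD signals come in two flavours: the absolute
Pearson correlation (``abs_r``) and the Fisher z-transform of positive
correlations (``fisher_z_pos``).  Voxel-level analysis additionally zeroes
connections between voxels lying within a short distance of one another
(default 10 mm) to suppress shared local signal.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import ConnectivityMatrix, RegionalSeries, VoxelPatch

__all__ = [
    "abs_pearson",
    "fisher_z_positive",
    "voxel_mean_connectivity",
    "region_mean_connectivity",
]

R_CAP_DEFAULT = 0.999999


def _corrcoef(data: np.ndarray, labels: list[str]) -> np.ndarray:
    if data.shape[1] < 3:
        raise ValueError("need at least 3 frames to correlate")
    if not np.all(np.isfinite(data)):
        raise ValueError("series contains non-finite values")
    sd = data.std(axis=1)
    dead = [lab for lab, s in zip(labels, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance regions: {dead}")
    r = np.corrcoef(data)
    return np.clip(r, -1.0, 1.0)


def abs_pearson(series: RegionalSeries) -> ConnectivityMatrix:
    """|Pearson r| between every pair of regional signals (diagonal 0)."""
    r = _corrcoef(series.data, series.labels)
    values = np.abs(r)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(mode="abs_r", values=values, labels=list(series.labels))


def fisher_z_positive(
    series: RegionalSeries, r_cap: float = R_CAP_DEFAULT
) -> ConnectivityMatrix:
    """Fisher z of positive correlations; negatives are zeroed.

    Correlations are capped at ``r_cap`` before ``atanh`` so numerically
    identical signals yield a large finite weight rather than infinity.
    """
    r = _corrcoef(series.data, series.labels)
    z = np.arctanh(np.minimum(np.clip(r, 0.0, None), r_cap))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        mode="fisher_z_pos", values=z, labels=list(series.labels)
    )


def voxel_mean_connectivity(
    patch: VoxelPatch,
    exclusion_mm: float = 10.0,
    exclude_from_denominator: bool = False,
) -> np.ndarray:
    """Per-voxel mean of |r| to all other voxels, with local exclusion.

    Pairs of voxels whose centres lie strictly within ``exclusion_mm`` of
    each other have their connectivity zeroed.  By default zeroed pairs
    still count in the averaging denominator (mean over all other voxels);
    set ``exclude_from_denominator`` to average over retained pairs only.
    """
    if patch.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    labels = [f"voxel_{i}" for i in range(patch.n_voxels)]
    r = np.abs(_corrcoef(patch.series, labels))
    np.fill_diagonal(r, 0.0)
    dist = squareform(pdist(patch.coordinates))
    near = dist < exclusion_mm
    np.fill_diagonal(near, True)
    r[near] = 0.0
    if exclude_from_denominator:
        counts = np.maximum((~near).sum(axis=1), 1)
    else:
        counts = patch.n_voxels - 1
    return r.sum(axis=1) / counts


def region_mean_connectivity(matrix: ConnectivityMatrix) -> np.ndarray:
    """Mean connectivity of each region to all other regions."""
    n = matrix.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions")
    return matrix.values.sum(axis=1) / (n - 1)
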