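"""Core data containers shared across the pipeline.

The pipeline moves data through four representations: per-subject regional
BOLD series, per-subject motion traces, region-by-region connectivity
matrices, and density-thresholded weighted networks whose graph metrics are
summarised as metric-versus-density curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalSeries",
    "MotionTrace",
    "ConnectivityMatrix",
    "VoxelPatch",
    "WeightedNetwork",
    "MetricCurve",
    "QcReport",
    "default_region_labels",
]

#: Number of anatomical regions in the parcellation (left/right halves of 45
#: labelled regions plus the two cerebellar hemispheres).
N_REGIONS_DEFAULT = 92


def default_region_labels(n_regions: int = N_REGIONS_DEFAULT) -> list[str]:
    """Zero-padded generic region labels (``roi_01`` ...)."""
    width = max(2, len(str(n_regions)))
    return [f"roi_{i + 1:0{width}d}" for i in range(n_regions)]


@dataclass
class RegionalSeries:
    """One subject's regional BOLD time series.

    Parameters
    ----------
    labels
        Ordered region names, one per row of ``data``.
    data
        ``(n_regions, n_frames)`` real matrix of BOLD samples.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    """

    labels: list[str]
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("series data must be 2-D (regions x frames)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} rows"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Relative displacement between consecutive frames, in millimetres.

    For a scan of ``n`` frames the trace holds ``n - 1`` nonnegative values;
    ``displacements[t]`` links frame ``t`` to frame ``t + 1``.
    """

    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float).ravel()
        if self.displacements.size and np.any(self.displacements < 0):
            raise ValueError("displacements must be nonnegative")

    def __len__(self) -> int:
        return self.displacements.size


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative association matrix with a zero diagonal.

    ``mode`` records the edge-weight definition: ``abs_r`` (absolute Pearson
    correlation, values in [0, 1]) or ``fisher_z_pos`` (Fisher z of
    positive correlations, values >= 0).
    """

    mode: str
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.mode not in ("abs_r", "fisher_z_pos"):
            raise ValueError(f"unknown connectivity mode {self.mode!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("connectivity weights must be nonnegative")
        if self.mode == "abs_r" and np.any(v > 1 + 1e-12):
            raise ValueError("abs_r weights must lie in [0, 1]")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class VoxelPatch:
    """A small patch of voxel time series with spatial coordinates.

    Used for voxel-level mean connectivity with short-distance exclusion;
    coordinates are voxel centres in millimetres.
    """

    coordinates: np.ndarray
    series: np.ndarray
    region_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.series = np.asarray(self.series, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n_voxels, 3)")
        if self.series.shape[0] != self.coordinates.shape[0]:
            raise ValueError("one series row per voxel required")
        uniq = np.unique(self.coordinates, axis=0)
        if uniq.shape[0] != self.coordinates.shape[0]:
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class WeightedNetwork:
    """Undirected weighted network (symmetric matrix, zero diagonal)."""

    labels: list[str]
    weights: np.ndarray
    density: float = field(default=0.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w
        n = w.shape[0]
        possible = n * (n - 1) / 2
        realized = np.count_nonzero(np.triu(w, 1)) / possible if possible else 0.0
        # density is informational; recompute so it always matches the matrix
        self.density = realized

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class MetricCurve:
    """A network metric evaluated across the density grid."""

    metric: str
    densities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.densities.size:
            raise ValueError("one value (row) per density required")
        if self.densities.size >= 2 and np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")

    @property
    def auc(self) -> float:
        from .metrics import metric_auc

        return metric_auc(self)


@dataclass
class QcReport:
    """Per-subject motion quality-control summary."""

    subject_id: str
    frames_in: int
    frames_removed_start: int
    frames_removed_end: int
    longest_clean_window_frames: int
    min_frames_required: int
    included: bool
    reason: str = "ok"
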