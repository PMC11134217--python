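"""Motion quality control and temporal filtering.

Three scrubbing/inclusion rules operate on the inter-frame displacement
trace:

* edge trimming — leading and trailing frames whose adjoining displacement
  exceeds 0.25 mm are removed, working strictly outside-in;
* clean-window inclusion — a scan is usable only if it contains at least
  5 continuous minutes during which no inter-frame displacement exceeds
  1 mm;
* high-pass filtering — fluctuations below 0.01 Hz (including the mean)
  are removed from every regional series by regressing out a
  discrete-cosine basis, which is exact for DC, phase-free, and linear.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .core import MotionTrace, QcReport, RegionalSeries

__all__ = [
    "trim_edges",
    "longest_clean_window",
    "min_frames_required",
    "passes_inclusion",
    "highpass_filter",
    "qc_subject",
]

EDGE_TRIM_MM = 0.25
WINDOW_MAX_MM = 1.0
MIN_MINUTES = 5.0
HIGHPASS_CUTOFF_HZ = 0.01


def trim_edges(
    series: RegionalSeries,
    trace: MotionTrace,
    threshold_mm: float = EDGE_TRIM_MM,
) -> tuple[RegionalSeries, MotionTrace, dict]:
    """Remove leading/trailing frames bounded by large displacements.

    Frames are dropped from the start while the first remaining
    displacement exceeds ``threshold_mm``, then from the end while the last
    remaining displacement does; interior frames are never touched.  If the
    trace is exhausted the single orphan frame is dropped too (an empty
    scan), since a one-frame series carries no signal.
    """
    disp = trace.displacements
    if len(disp) != series.n_frames - 1:
        raise ValueError(
            f"trace length {len(disp)} does not match "
            f"{series.n_frames} frames (expected {series.n_frames - 1})"
        )
    start, end = 0, len(disp)
    while start < end and disp[start] > threshold_mm:
        start += 1
    while end > start and disp[end - 1] > threshold_mm:
        end -= 1
    if start == end and len(disp) > 0 and start > 0:
        # every displacement was removed: nothing usable remains
        trimmed = RegionalSeries(
            labels=series.labels,
            data=series.data[:, :0],
            tr_seconds=series.tr_seconds,
        )
        report = {
            "frames_removed_start": start,
            "frames_removed_end": len(disp) + 1 - start,
        }
        return trimmed, MotionTrace(displacements=disp[:0]), report
    trimmed = RegionalSeries(
        labels=series.labels,
        data=series.data[:, start : end + 1],
        tr_seconds=series.tr_seconds,
    )
    report = {
        "frames_removed_start": start,
        "frames_removed_end": len(disp) - end,
    }
    return trimmed, MotionTrace(displacements=disp[start:end]), report


def longest_clean_window(
    trace: MotionTrace, max_disp_mm: float = WINDOW_MAX_MM
) -> int:
    """Longest run of frames whose connecting displacements are all small.

    A run of ``k`` consecutive displacements <= ``max_disp_mm`` spans
    ``k + 1`` frames.  An empty trace counts as a single frame.
    """
    disp = trace.displacements
    if disp.size == 0:
        warnings.warn("empty motion trace: treating as a single frame")
        return 1
    clean = disp <= max_disp_mm
    best = run = 0
    for ok in clean:
        run = run + 1 if ok else 0
        best = max(best, run)
    return best + 1


def min_frames_required(
    tr_seconds: float, min_minutes: float = MIN_MINUTES
) -> int:
    """Frames needed to span ``min_minutes`` of continuous scanning."""
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    return math.ceil(min_minutes * 60.0 / tr_seconds)


def passes_inclusion(
    trace: MotionTrace,
    tr_seconds: float,
    max_disp_mm: float = WINDOW_MAX_MM,
    min_minutes: float = MIN_MINUTES,
) -> bool:
    """True iff the scan holds a clean window of at least ``min_minutes``."""
    return longest_clean_window(trace, max_disp_mm) >= min_frames_required(
        tr_seconds, min_minutes
    )


def highpass_filter(
    series: RegionalSeries,
    cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
    tr_seconds: float | None = None,
) -> RegionalSeries:
    """Remove fluctuations below ``cutoff_hz`` from every region.

    Implemented as regression on a discrete-cosine (DCT-II) basis: the mean
    and every cosine component with frequency below the cutoff are
    projected out.  The basis is orthogonal, so the projection is a single
    matrix product; the output is exactly zero-mean per region and the
    operation is linear.
    """
    tr = series.tr_seconds if tr_seconds is None else tr_seconds
    n = series.n_frames
    if n < 4:
        raise ValueError("need at least 4 frames to filter")
    nyquist = 1.0 / (2.0 * tr)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency "
            f"{nyquist:.4g} Hz"
        )
    # DCT-II basis vector k has frequency k / (2 N TR)
    n_comp = int(np.ceil(cutoff_hz * 2 * n * tr)) - 1
    n_comp = max(n_comp, 0)
    t = np.arange(n)
    basis = [np.full(n, 1.0 / np.sqrt(n))]
    for k in range(1, n_comp + 1):
        vec = np.cos(np.pi * k * (2 * t + 1) / (2 * n))
        basis.append(vec / np.linalg.norm(vec))
    B = np.column_stack(basis)
    data = series.data
    filtered = data - (data @ B) @ B.T
    return RegionalSeries(
        labels=series.labels, data=filtered, tr_seconds=series.tr_seconds
    )


def qc_subject(
    subject_id: str,
    series: RegionalSeries,
    trace: MotionTrace,
    edge_trim_mm: float = EDGE_TRIM_MM,
    window_max_mm: float = WINDOW_MAX_MM,
    min_minutes: float = MIN_MINUTES,
    cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
) -> tuple[RegionalSeries | None, QcReport]:
    """Full per-subject QC: trim edges, test inclusion, high-pass filter.

    Returns the filtered, trimmed series (or None if excluded) and a
    report.  The edge trim runs before the clean-window test, and the
    filter is applied last, only to included subjects.
    """
    frames_in = series.n_frames
    trimmed, trimmed_trace, info = trim_edges(series, trace, edge_trim_mm)
    if trimmed.n_frames == 0:
        report = QcReport(
            subject_id=subject_id,
            frames_in=frames_in,
            frames_removed_start=info["frames_removed_start"],
            frames_removed_end=info["frames_removed_end"],
            longest_clean_window_frames=0,
            min_frames_required=min_frames_required(series.tr_seconds, min_minutes),
            included=False,
            reason="edge_trim_empty",
        )
        return None, report
    window = longest_clean_window(trimmed_trace, window_max_mm)
    needed = min_frames_required(series.tr_seconds, min_minutes)
    included = window >= needed
    report = QcReport(
        subject_id=subject_id,
        frames_in=frames_in,
        frames_removed_start=info["frames_removed_start"],
        frames_removed_end=info["frames_removed_end"],
        longest_clean_window_frames=window,
        min_frames_required=needed,
        included=included,
        reason="ok" if included else "window_fail",
    )
    if not included:
        return None, report
    return highpass_filter(trimmed, cutoff_hz), report
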