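"""Readers and writers for the on-disk cohort layout.

Layout of a cohort directory::

    manifest.csv            subject_id,group,sex,ga_birth_weeks,pma_scan_weeks,site
    cohort.yaml             acquisition parameters (tr_seconds, n_frames, ...)
    series/<subject>.tsv    region label + one column per frame
    motion/<subject>.txt    one displacement (mm) per consecutive frame pair
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import MotionTrace, RegionalSeries
from .synthetic import MANIFEST_COLUMNS, Cohort

__all__ = [
    "write_cohort",
    "read_manifest",
    "read_series",
    "write_series",
    "read_motion_trace",
    "write_motion_trace",
    "load_cohort_dir",
]


def write_series(series: RegionalSeries, path: str | Path) -> None:
    df = pd.DataFrame(series.data, index=series.labels)
    df.index.name = "region"
    df.columns = [f"frame_{i + 1}" for i in range(series.n_frames)]
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_series(path: str | Path, tr_seconds: float) -> RegionalSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegionalSeries(
        labels=[str(x) for x in df.index],
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
    )


def write_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, trace.displacements, fmt="%.6f")


def read_motion_trace(path: str | Path) -> MotionTrace:
    values = np.loadtxt(path, dtype=float, ndmin=1)
    return MotionTrace(displacements=values)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "series").mkdir(parents=True, exist_ok=True)
    (outdir / "motion").mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "cohort.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "tr_seconds": cohort.config.tr_seconds,
                "n_frames": cohort.config.n_frames,
                "n_regions": cohort.config.n_regions,
                "seed": cohort.config.seed,
            },
            fh,
        )
    for sid, series in cohort.series.items():
        write_series(series, outdir / "series" / f"{sid}.tsv")
    for sid, trace in cohort.traces.items():
        write_motion_trace(trace, outdir / "motion" / f"{sid}.txt")
    return outdir


def load_cohort_dir(
    path: str | Path,
) -> tuple[pd.DataFrame, dict[str, RegionalSeries], dict[str, MotionTrace], float]:
    """Load a cohort directory; returns (manifest, series, traces, tr)."""
    path = Path(path)
    manifest = read_manifest(path / "manifest.csv")
    with open(path / "cohort.yaml") as fh:
        meta = yaml.safe_load(fh)
    tr = float(meta["tr_seconds"])
    series: dict[str, RegionalSeries] = {}
    traces: dict[str, MotionTrace] = {}
    for sid in manifest["subject_id"]:
        series_path = path / "series" / f"{sid}.tsv"
        trace_path = path / "motion" / f"{sid}.txt"
        if series_path.exists():
            series[sid] = read_series(series_path, tr)
        if trace_path.exists():
            traces[sid] = read_motion_trace(trace_path)
    return manifest, series, traces, tr
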