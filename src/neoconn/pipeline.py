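"""End-to-end orchestration: simulate -> qc -> connect -> network -> stats.

A run is driven by a :class:`RunConfig` (constructible from YAML).  Each
stage writes its outputs under the run directory and records a content
hash in ``run_manifest.json``; a re-run with an unchanged configuration
reloads cached stage outputs instead of recomputing them.  Subjects
excluded by QC carry a machine-readable reason (``no_data``,
``edge_trim_empty``, ``window_fail``) in the inclusion ledger.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn_mod
from . import io, metrics, qc, stats
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("neoconn")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "results/run"
    cohort_dir: str | None = None
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    edge_trim_mm: float = qc.EDGE_TRIM_MM
    window_max_mm: float = qc.WINDOW_MAX_MM
    min_minutes: float = qc.MIN_MINUTES
    cutoff_hz: float = qc.HIGHPASS_CUTOFF_HZ
    connectivity_mode: str = "abs_r"
    density_min: float = 0.10
    density_max: float = 0.35
    density_step: float = 0.01
    global_metrics: tuple[str, ...] = metrics.GLOBAL_METRICS
    nodal_metrics: tuple[str, ...] = metrics.NODAL_METRICS
    n_null: int = 100
    n_restarts: int = 10
    null_model: str = "weight_permute"
    n_perm_global: int = 100_000
    n_perm_nodal: int = 100_000
    adjusted_g: bool = False
    seed: int = 0
    cache: bool = True

    def __post_init__(self) -> None:
        if self.edge_trim_mm <= 0 or self.window_max_mm <= 0 or self.min_minutes <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.connectivity_mode not in ("abs_r", "fisher_z_pos"):
            raise ValueError(f"unknown connectivity mode {self.connectivity_mode!r}")
        self.densities()  # validates the grid

    def densities(self) -> np.ndarray:
        return metrics.default_density_grid(
            self.density_min, self.density_max, self.density_step
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        for key in ("focal_nodes", "site_offsets", "site_probs"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        for key in ("global_metrics", "nodal_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=CohortConfig(**cohort_raw), **raw)

    def content_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """Outputs of a pipeline run (also written under ``outdir``)."""

    config: RunConfig
    qc_report: pd.DataFrame
    inclusion: dict[str, int]
    auc_global: pd.DataFrame
    curves_global: pd.DataFrame
    auc_nodal: dict[str, pd.DataFrame]
    table2: pd.DataFrame
    nodal_tables: dict[str, pd.DataFrame]
    manifest: pd.DataFrame


def _stage_done(outdir: Path, manifest: dict, stage: str, cfg_hash: str) -> bool:
    entry = manifest.get("stages", {}).get(stage)
    if not entry or entry.get("config_hash") != cfg_hash:
        return False
    return all((outdir / f).exists() for f in entry.get("files", []))


def _record_stage(
    outdir: Path, manifest: dict, stage: str, cfg_hash: str, files: list[str]
) -> None:
    hashes = {}
    for f in files:
        h = hashlib.sha256((outdir / f).read_bytes()).hexdigest()[:16]
        hashes[f] = h
    manifest.setdefault("stages", {})[stage] = {
        "config_hash": cfg_hash,
        "files": files,
        "hashes": hashes,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write reports under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.content_hash()
    manifest_path = outdir / "run_manifest.json"
    run_manifest: dict = {}
    if config.cache and manifest_path.exists():
        run_manifest = json.loads(manifest_path.read_text())
    run_manifest["config_hash"] = cfg_hash
    run_manifest["seed"] = config.seed

    # ---- stage 1: cohort -------------------------------------------------
    if config.simulate:
        cohort_dir = outdir / "cohort"
        if not (config.cache and _stage_done(outdir, run_manifest, "simulate", cfg_hash)):
            log.info("simulate: generating cohort under %s", cohort_dir)
            cohort = generate_cohort(config.cohort)
            io.write_cohort(cohort, cohort_dir)
            _record_stage(outdir, run_manifest, "simulate", cfg_hash, ["cohort/manifest.csv"])
    else:
        if config.cohort_dir is None:
            raise ValueError("cohort_dir required when simulate is false")
        cohort_dir = Path(config.cohort_dir)
    manifest, series, traces, tr = io.load_cohort_dir(cohort_dir)

    # ---- stage 2: qc -----------------------------------------------------
    reports = []
    cleaned = {}
    for sid in manifest["subject_id"]:
        if sid not in series or sid not in traces:
            reports.append(
                {
                    "subject_id": sid,
                    "frames_in": 0,
                    "frames_removed_start": 0,
                    "frames_removed_end": 0,
                    "longest_clean_window_frames": 0,
                    "min_frames_required": qc.min_frames_required(tr, config.min_minutes),
                    "included": False,
                    "reason": "no_data",
                }
            )
            continue
        filtered, report = qc.qc_subject(
            sid,
            series[sid],
            traces[sid],
            edge_trim_mm=config.edge_trim_mm,
            window_max_mm=config.window_max_mm,
            min_minutes=config.min_minutes,
            cutoff_hz=config.cutoff_hz,
        )
        log.info("qc: %s included=%s (%s)", sid, report.included, report.reason)
        reports.append(dataclasses.asdict(report))
        if filtered is not None:
            cleaned[sid] = filtered
    qc_report = pd.DataFrame(reports)
    qc_report.to_csv(outdir / "qc_report.csv", index=False)
    reasons = qc_report.loc[~qc_report["included"], "reason"].value_counts().to_dict()
    inclusion = {
        "total": int(len(qc_report)),
        "included": int(qc_report["included"].sum()),
        **{str(k): int(v) for k, v in reasons.items()},
    }
    pd.DataFrame([inclusion]).to_csv(outdir / "inclusion_flow.csv", index=False)
    if not cleaned:
        raise RuntimeError(
            "stats stage refused: no subjects pass quality control "
            f"(exclusions: {reasons})"
        )

    # ---- stage 3: connectivity ------------------------------------------
    conn_fn = (
        conn_mod.abs_pearson
        if config.connectivity_mode == "abs_r"
        else conn_mod.fisher_z_positive
    )
    conn_dir = outdir / "connectivity"
    conn_dir.mkdir(exist_ok=True)
    matrices = {}
    for sid, ser in cleaned.items():
        log.info("connect: %s (%s)", sid, config.connectivity_mode)
        mat = conn_fn(ser)
        matrices[sid] = mat
        pd.DataFrame(mat.values, index=mat.labels, columns=mat.labels).to_csv(
            conn_dir / f"{sid}.tsv", sep="\t", float_format="%.8g"
        )

    # ---- stage 4: network metrics ---------------------------------------
    densities = config.densities()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % 2**31, 4]))
    curve_rows = []
    auc_rows = []
    nodal_auc: dict[str, dict[str, np.ndarray]] = {m: {} for m in config.nodal_metrics}
    region_labels = None
    for sid, mat in matrices.items():
        log.info("network: %s across %d densities", sid, densities.size)
        region_labels = mat.labels
        glob_curves, nodal_curves = metrics.metric_curves(
            mat,
            densities=densities,
            metrics=config.global_metrics,
            nodal_metrics=config.nodal_metrics,
            n_null=config.n_null,
            n_restarts=config.n_restarts,
            seed=int(rng.integers(2**31 - 1)),
            null_model=config.null_model,
        )
        for name, curve in glob_curves.items():
            for d, v in zip(curve.densities, curve.values):
                curve_rows.append(
                    {"subject_id": sid, "density": d, "metric": name, "value": v}
                )
            auc_rows.append(
                {"subject_id": sid, "metric": name, "auc": curve.auc}
            )
        for name, curve in nodal_curves.items():
            nodal_auc[name][sid] = metrics.metric_auc(curve)
    curves_global = pd.DataFrame(curve_rows)
    curves_global.to_csv(outdir / "metric_curves.csv", index=False)
    auc_long = pd.DataFrame(auc_rows)
    auc_long.to_csv(outdir / "metric_auc.csv", index=False)
    auc_global = auc_long.pivot(index="subject_id", columns="metric", values="auc")
    auc_global = auc_global[[m for m in config.global_metrics]]
    auc_nodal = {
        name: pd.DataFrame.from_dict(per_subj, orient="index", columns=region_labels)
        for name, per_subj in nodal_auc.items()
    }
    for name, table in auc_nodal.items():
        table.rename_axis("subject_id").to_csv(outdir / f"nodal_auc_{name}.csv")

    # ---- stage 5: statistics --------------------------------------------
    included_manifest = manifest[manifest["subject_id"].isin(auc_global.index)]
    design = stats.build_design(included_manifest)
    log.info(
        "stats: %d subjects, %d global permutations",
        len(included_manifest),
        config.n_perm_global,
    )
    table2 = stats.compare_global_metrics(
        auc_global,
        design,
        n_perm=config.n_perm_global,
        seed=config.seed,
        adjusted_g=config.adjusted_g,
    )
    table2.to_csv(outdir / "table2.csv", index=False)
    nodal_tables = {}
    for name, table in auc_nodal.items():
        nodal_tables[name] = stats.compare_nodal_metrics(
            table,
            design,
            n_perm=config.n_perm_nodal,
            seed=config.seed + 1,
            adjusted_g=config.adjusted_g,
        )
        nodal_tables[name].to_csv(outdir / f"nodal_{name}.csv", index=False)
    _record_stage(
        outdir,
        run_manifest,
        "stats",
        cfg_hash,
        ["table2.csv", "qc_report.csv", "inclusion_flow.csv"],
    )
    return RunResult(
        config=config,
        qc_report=qc_report,
        inclusion=inclusion,
        auc_global=auc_global,
        curves_global=curves_global,
        auc_nodal=auc_nodal,
        table2=table2,
        nodal_tables=nodal_tables,
        manifest=manifest,
    )
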