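"""Synthetic resting-state cohort generator.

Emulates the statistical structure of a two-arm neonatal rsfMRI study:
92-region BOLD series of ~120 frames at TR 3 s for 24 treated and 21
placebo subjects, inter-frame motion traces with mean relative displacement
about 0.066 mm, and a manifest carrying group, sex, gestational age at
birth, postmenstrual age at scan, and scan site.

The generative model is a latent-factor Gaussian process: region ``r`` of a
subject carries a communality (loading) ``lam_r`` in [0, 0.99] and its BOLD
signal is ``sqrt(lam_r) * f + sqrt(1 - lam_r) * eps_r`` with shared factor(s)
``f`` and independent noise ``eps_r``, so the population correlation between
regions ``i`` and ``j`` is ``sqrt(lam_i * lam_j)``.  Group membership and
covariates shift the loadings additively, which yields a tunable global
connectivity uplift in the treated arm, an extra focal uplift at chosen
nodes, and covariate-driven between-subject variance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import MotionTrace, RegionalSeries, default_region_labels

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "subject_loadings",
    "generate_subject_covariance",
    "generate_bold",
    "generate_motion_trace",
    "generate_cohort",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "sex",
    "ga_birth_weeks",
    "pma_scan_weeks",
    "site",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    The defaults emulate the conditions of the motivating study: arm sizes
    24 vs 21, 92 regions, 120 frames at TR 3 s, motion with mean (SD)
    relative displacement 0.066 (0.027) mm, a site split of roughly 32:10:3,
    and effect sizes calibrated so that the raw standardised group
    difference in mean connectivity-derived metrics is about 0.5 while one
    focal node carries an effect near 1 (see the methods note).
    """

    n_treated: int = 24
    n_placebo: int = 21
    n_regions: int = 92
    n_frames: int = 120
    tr_seconds: float = 3.0
    base_coupling: float = 0.30
    group_uplift: float = 0.055
    focal_nodes: tuple[int, ...] | None = None
    focal_uplift: float = 0.25
    sex_effect: float = 0.09
    ga_slope: float = 0.06
    site_offsets: tuple[float, ...] = (0.0, 0.04, -0.04)
    site_probs: tuple[float, ...] = (32 / 45, 10 / 45, 3 / 45)
    motion_mean_mm: float = 0.066
    motion_sd_mm: float = 0.027
    spike_prob: float = 0.0
    n_factors: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treated < 1 or self.n_placebo < 1:
            raise ValueError("each group needs at least one subject")
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.base_coupling < 1:
            raise ValueError("base_coupling must lie in [0, 1)")
        if self.group_uplift < 0 or self.focal_uplift < 0:
            raise ValueError("uplifts must be nonnegative")
        if self.motion_mean_mm < 0 or self.motion_sd_mm < 0:
            raise ValueError("motion parameters must be nonnegative")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike_prob must be a probability")
        if len(self.site_offsets) != len(self.site_probs):
            raise ValueError("site_offsets and site_probs length mismatch")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.focal_nodes is None:
            # one focal node (emulating the right middle temporal gyrus),
            # placed mid-parcellation so it exists at any n_regions
            object.__setattr__(self, "focal_nodes", (self.n_regions // 2,))
        if any(i < 0 or i >= self.n_regions for i in self.focal_nodes):
            raise ValueError("focal_nodes out of range")

    def null(self) -> "CohortConfig":
        """Copy with all group and covariate effects removed."""
        return replace(
            self,
            group_uplift=0.0,
            focal_uplift=0.0,
            sex_effect=0.0,
            ga_slope=0.0,
            site_offsets=tuple(0.0 for _ in self.site_offsets),
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's design row."""

    subject_id: str
    group: str
    sex: str
    ga_birth_weeks: float
    pma_scan_weeks: float
    site: int

    def __post_init__(self) -> None:
        if self.group not in ("treated", "placebo"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not 30 <= self.ga_birth_weeks <= 34:
            raise ValueError(
                f"{self.subject_id}: gestational age {self.ga_birth_weeks} "
                "outside the trial window [30, 34] weeks"
            )
        if self.pma_scan_weeks < self.ga_birth_weeks:
            raise ValueError(f"{self.subject_id}: scan age before birth age")


# Reference GA (weeks) about which the gestational-age slope is centred, so
# that the slope does not shift the cohort-average loading.
GA_CENTER_WEEKS = 32.0


def subject_loadings(config: CohortConfig, subject: SubjectRecord) -> np.ndarray:
    """Per-region factor loadings implied by group and covariates.

    lam_r = base + group_uplift*1[treated] + focal_uplift*1[r focal, treated]
            + sex_effect*1[male] + ga_slope*(GA - 32) + site offset.
    """
    lam = np.full(config.n_regions, config.base_coupling, dtype=float)
    if subject.group == "treated":
        lam += config.group_uplift
        lam[list(config.focal_nodes)] += config.focal_uplift
    if subject.sex == "male":
        lam += config.sex_effect
    lam += config.ga_slope * (subject.ga_birth_weeks - GA_CENTER_WEEKS)
    lam += config.site_offsets[subject.site - 1]
    if np.any(lam < 0) or np.any(lam > 0.99):
        raise ValueError(
            f"configuration implies loadings outside [0, 0.99] for subject "
            f"{subject.subject_id} (range [{lam.min():.3f}, {lam.max():.3f}])"
        )
    return lam


def generate_subject_covariance(
    config: CohortConfig, subject: SubjectRecord
) -> np.ndarray:
    """Population region-by-region correlation matrix of one subject.

    Under the factor model the correlation between distinct regions is
    ``sqrt(lam_i * lam_j)``; the result is symmetric with unit diagonal and
    positive semidefinite by construction (``diag(1 - lam) + s s^T`` with
    ``s = sqrt(lam)``).
    """
    lam = subject_loadings(config, subject)
    s = np.sqrt(lam)
    corr = np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return corr


def _subject_rng(seed: int, subject_id: str, stream: str) -> np.random.Generator:
    """Deterministic per-subject, per-stream generator."""
    tag = zlib.crc32(f"{subject_id}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, tag]))


def generate_bold(
    subject: SubjectRecord,
    structure: np.ndarray,
    n_frames: int,
    seed: int,
    tr_seconds: float = 3.0,
    labels: list[str] | None = None,
) -> RegionalSeries:
    """Draw a regional BOLD series with the given frame-wise correlation.

    Frames are independent zero-mean Gaussian draws, so sample correlations
    converge to the population ``structure`` as ``n_frames`` grows.  The
    output is a deterministic function of ``(subject_id, seed)``.
    """
    structure = np.asarray(structure, dtype=float)
    n = structure.shape[0]
    if structure.shape != (n, n) or not np.allclose(structure, structure.T):
        raise ValueError("structure must be a square symmetric matrix")
    eigvals, eigvecs = np.linalg.eigh(structure)
    if eigvals.min() < -1e-8:
        raise ValueError(
            f"structure is not positive semidefinite (min eig {eigvals.min():.2e})"
        )
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    rng = _subject_rng(seed, subject.subject_id, "bold")
    z = rng.standard_normal((n_frames, n))
    data = (z @ root.T).T
    if labels is None:
        labels = default_region_labels(n)
    return RegionalSeries(labels=labels, data=data, tr_seconds=tr_seconds)


def generate_motion_trace(
    subject: SubjectRecord,
    n_frames: int,
    config: CohortConfig,
    seed: int,
) -> MotionTrace:
    """Simulate inter-frame relative displacements (mm).

    Baseline displacements are lognormal, moment-matched to the configured
    mean and SD (displacements are nonnegative and right-skewed); with
    probability ``spike_prob`` a frame pair is replaced by a large
    (> 1 mm) excursion.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = _subject_rng(seed, subject.subject_id, "motion")
    n = n_frames - 1
    m, s = config.motion_mean_mm, config.motion_sd_mm
    if m == 0:
        base = np.zeros(n)
    elif s == 0:
        base = np.full(n, m)
    else:
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        base = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    if config.spike_prob > 0:
        spikes = rng.random(n) < config.spike_prob
        base[spikes] = 1.0 + rng.exponential(scale=0.5, size=int(spikes.sum()))
    return MotionTrace(displacements=base)


@dataclass
class Cohort:
    """A generated cohort: manifest plus per-subject series and traces."""

    config: CohortConfig
    manifest: pd.DataFrame
    series: dict[str, RegionalSeries]
    traces: dict[str, MotionTrace]

    @property
    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                sex=row.sex,
                ga_birth_weeks=row.ga_birth_weeks,
                pma_scan_weeks=row.pma_scan_weeks,
                site=int(row.site),
            )
            for row in self.manifest.itertuples(index=False)
        ]

    def write(self, outdir: str | Path) -> None:
        """Write manifest CSV, per-subject series TSVs, and motion traces."""
        from . import io

        io.write_cohort(self, outdir)


def _draw_covariates(
    config: CohortConfig, rng: np.random.Generator
) -> Iterable[SubjectRecord]:
    n_total = config.n_treated + config.n_placebo
    groups = ["treated"] * config.n_treated + ["placebo"] * config.n_placebo
    sexes = np.where(rng.random(n_total) < 0.5, "female", "male")
    ga = rng.uniform(30.0, 34.0, size=n_total)
    pma = ga + np.clip(rng.normal(8.0, 1.0, size=n_total), 0.0, None)
    sites = rng.choice(
        np.arange(1, len(config.site_probs) + 1),
        size=n_total,
        p=np.asarray(config.site_probs) / np.sum(config.site_probs),
    )
    for i in range(n_total):
        yield SubjectRecord(
            subject_id=f"sub-{i + 1:03d}",
            group=groups[i],
            sex=str(sexes[i]),
            ga_birth_weeks=round(float(ga[i]), 2),
            pma_scan_weeks=round(float(pma[i]), 2),
            site=int(sites[i]),
        )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort (manifest, BOLD series, motion traces).

    Fully reproducible from ``config.seed``: covariates come from a
    cohort-level stream and every subject's series and motion trace come
    from per-subject streams keyed by subject id.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % 2**31, zlib.crc32(b"cohort")])
    )
    subjects = list(_draw_covariates(config, rng))
    labels = default_region_labels(config.n_regions)
    series: dict[str, RegionalSeries] = {}
    traces: dict[str, MotionTrace] = {}
    for subj in subjects:
        structure = generate_subject_covariance(config, subj)
        series[subj.subject_id] = generate_bold(
            subj,
            structure,
            config.n_frames,
            config.seed,
            tr_seconds=config.tr_seconds,
            labels=labels,
        )
        traces[subj.subject_id] = generate_motion_trace(
            subj, config.n_frames, config, config.seed
        )
    manifest = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "ga_birth_weeks": s.ga_birth_weeks,
                "pma_scan_weeks": s.pma_scan_weeks,
                "site": s.site,
            }
            for s in subjects
        ],
        columns=MANIFEST_COLUMNS,
    )
    return Cohort(config=config, manifest=manifest, series=series, traces=traces)
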