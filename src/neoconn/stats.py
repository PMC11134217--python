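"""Covariate-adjusted group inference and effect sizes.

Group differences are tested nonparametrically with the Freedman–Lane
permutation scheme: the outcome is regressed on the nuisance block (sex,
gestational age at birth, their interaction, and scan site), the residuals
are permuted over subjects and added back to the nuisance fit, and the full
model's group t statistic is recomputed for every permutation.  Effect
sizes are reported as Hedges g (pooled-SD standardised mean difference with
small-sample correction); multiplicity across nodes is controlled with the
Benjamini–Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_design",
    "hedges_g",
    "hedges_g_from_summary",
    "freedman_lane",
    "bh_fdr",
    "compare_global_metrics",
    "compare_nodal_metrics",
]


@dataclass
class DesignMatrix:
    """Full-rank design: intercept + nuisance block + group indicator."""

    matrix: np.ndarray
    columns: list[str]
    group_col: int
    subject_ids: list[str]

    @property
    def nuisance(self) -> np.ndarray:
        keep = [i for i in range(self.matrix.shape[1]) if i != self.group_col]
        return self.matrix[:, keep]


def build_design(manifest: pd.DataFrame) -> DesignMatrix:
    """Design matrix from a cohort manifest.

    Columns: intercept, group (treated = 1), sex (male = 1), centred
    gestational age at birth, sex x GA interaction, and scan-site
    indicators (first site is the reference).  Sites present in only one
    group are collapsed into the reference with a warning, since their
    indicator would be confounded with treatment.
    """
    df = manifest.copy()
    group = (df["group"] == "treated").astype(float).to_numpy()
    sex = (df["sex"] == "male").astype(float).to_numpy()
    ga = df["ga_birth_weeks"].to_numpy(dtype=float)
    ga_c = ga - ga.mean()
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(df)),
        "group": group,
        "sex_male": sex,
        "ga_birth_c": ga_c,
        "sex_x_ga": sex * ga_c,
    }
    sites = sorted(df["site"].unique())
    for s in sites[1:]:
        mask = (df["site"] == s).to_numpy()
        groups_here = set(df.loc[mask, "group"])
        if len(groups_here) < 2:
            warnings.warn(
                f"site {s} contains a single treatment group; collapsing "
                "into the reference site"
            )
            continue
        cols[f"site_{s}"] = mask.astype(float)
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(
        matrix=X,
        columns=list(cols.keys()),
        group_col=list(cols.keys()).index("group"),
        subject_ids=[str(s) for s in df["subject_id"]],
    )


def hedges_g_from_summary(
    mean_t: float,
    sd_t: float,
    n_t: int,
    mean_p: float,
    sd_p: float,
    n_p: int,
) -> tuple[float, tuple[float, float]]:
    """Hedges g (treated minus placebo) from group summary statistics.

    ``g = J * (m_t - m_p) / s_pooled`` with the pooled SD over both groups
    and the small-sample correction ``J = 1 - 3 / (4 df - 1)``,
    ``df = n_t + n_p - 2``.  The 95% CI uses the normal-approximation
    standard error ``SE^2 = (n_t + n_p)/(n_t n_p) + g^2 / (2 df)``.
    """
    if n_t < 2 or n_p < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n_t + n_p - 2
    s_pooled = np.sqrt(((n_t - 1) * sd_t**2 + (n_p - 1) * sd_p**2) / df)
    if s_pooled == 0:
        raise ValueError("zero pooled standard deviation")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (mean_t - mean_p) / s_pooled
    se = np.sqrt((n_t + n_p) / (n_t * n_p) + g**2 / (2.0 * df))
    return float(g), (float(g - 1.96 * se), float(g + 1.96 * se))


def hedges_g(
    treated_values: np.ndarray, placebo_values: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Hedges g with 95% CI from raw per-group samples."""
    t = np.asarray(treated_values, dtype=float)
    p = np.asarray(placebo_values, dtype=float)
    return hedges_g_from_summary(
        t.mean(), t.std(ddof=1), t.size, p.mean(), p.std(ddof=1), p.size
    )


def _group_t(X: np.ndarray, Y: np.ndarray, group_col: int) -> np.ndarray:
    """t statistic of the group coefficient for each column of Y."""
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coefs
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    var_g = sigma2 * xtx_inv[group_col, group_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_g > 0, coefs[group_col] / np.sqrt(np.maximum(var_g, 1e-300)), np.inf * np.sign(coefs[group_col]))
    return t


def freedman_lane(
    y: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    permutations: np.ndarray | None = None,
) -> tuple[float, float]:
    """Freedman–Lane permutation test of the group effect.

    The outcome is regressed on the nuisance block; for each permutation
    the residuals are shuffled over subjects, added back to the nuisance
    fit, and the group t statistic of the full model is recomputed.  The
    two-sided p-value uses the add-one estimator
    ``(1 + #{|t*| >= |t_obs|}) / (1 + n_perm)`` so it is never zero.
    ``permutations`` may supply an explicit (n_perm, n) index array, e.g.
    the full permutation group for exact enumeration on tiny samples.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = design.matrix
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"outcome length {y.size} != {n} subjects")
    if n <= p:
        raise ValueError("more design columns than subjects")
    t_obs = float(_group_t(X, y[:, None], design.group_col)[0])
    Z = design.nuisance
    beta_z, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ beta_z
    resid = y - fitted
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.array([rng.permutation(n) for _ in range(n_perm)])
    else:
        permutations = np.asarray(permutations, dtype=int)
        n_perm = permutations.shape[0]
    y_star = fitted[:, None] + resid[permutations].T
    t_star = _group_t(X, y_star, design.group_col)
    t_abs = abs(t_obs)
    if np.isinf(t_abs):
        exceed = int(np.sum(np.isinf(t_star)))
    else:
        exceed = int(np.sum(np.abs(t_star) >= t_abs - 1e-12))
    p_perm = (1 + exceed) / (1 + n_perm)
    return t_obs, float(p_perm)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, *_ = multipletests(p, method="fdr_bh")
    return p_adj


def _adjusted_g(
    y: np.ndarray, design: DesignMatrix
) -> tuple[float, tuple[float, float]]:
    """Covariate-adjusted g: group coefficient over residual SD, with the
    same small-sample correction and CI form as the raw variant."""
    X = design.matrix
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ (X.T @ y)
    resid = y - X @ coefs
    dof = n - p
    sigma = float(np.sqrt((resid**2).sum() / dof))
    if sigma == 0:
        raise ValueError("zero residual standard deviation")
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    g = float(j * coefs[design.group_col] / sigma)
    group = X[:, design.group_col]
    n_t, n_p_ = int(group.sum()), int((1 - group).sum())
    se = np.sqrt((n_t + n_p_) / (n_t * n_p_) + g**2 / (2.0 * dof))
    return g, (float(g - 1.96 * se), float(g + 1.96 * se))


def _comparison_row(
    name: str,
    y: np.ndarray,
    design: DesignMatrix,
    group_mask: np.ndarray,
    n_perm: int,
    seed: int,
    adjusted_g: bool,
) -> dict:
    t_obs, p_perm = freedman_lane(y, design, n_perm=n_perm, seed=seed)
    if adjusted_g:
        g, ci = _adjusted_g(y, design)
    else:
        g, ci = hedges_g(y[group_mask], y[~group_mask])
    return {
        "outcome": name,
        "placebo_mean": float(y[~group_mask].mean()),
        "placebo_sd": float(y[~group_mask].std(ddof=1)),
        "treated_mean": float(y[group_mask].mean()),
        "treated_sd": float(y[group_mask].std(ddof=1)),
        "hedges_g": g,
        "g_ci_low": ci[0],
        "g_ci_high": ci[1],
        "t_obs": t_obs,
        "p_perm": p_perm,
    }


def _align(table: pd.DataFrame, design: DesignMatrix) -> pd.DataFrame:
    missing = [s for s in design.subject_ids if s not in table.index]
    if missing:
        raise ValueError(f"missing subjects in outcome table: {missing}")
    return table.loc[design.subject_ids]


def compare_global_metrics(
    auc_table: pd.DataFrame,
    design: DesignMatrix,
    n_perm: int = 100_000,
    seed: int = 0,
    adjusted_g: bool = False,
) -> pd.DataFrame:
    """Group comparison of per-subject global-metric AUC values.

    ``auc_table`` is indexed by subject id with one column per metric.
    Returns one row per metric with group means/SDs, Hedges g and CI, the
    observed t, the permutation p, and BH-FDR across the metric family.
    """
    auc_table = _align(auc_table, design)
    group_mask = design.matrix[:, design.group_col] == 1
    rng = np.random.default_rng(seed)
    rows = [
        _comparison_row(
            metric,
            auc_table[metric].to_numpy(dtype=float),
            design,
            group_mask,
            n_perm,
            int(rng.integers(2**31 - 1)),
            adjusted_g,
        )
        for metric in auc_table.columns
    ]
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_perm"].to_numpy())
    return out


def compare_nodal_metrics(
    nodal_table: pd.DataFrame,
    design: DesignMatrix,
    n_perm: int = 100_000,
    seed: int = 0,
    adjusted_g: bool = False,
) -> pd.DataFrame:
    """Per-node group comparison with BH-FDR across nodes.

    ``nodal_table`` is indexed by subject id with one column per node
    (region label).  Returns one row per node.
    """
    nodal_table = _align(nodal_table, design)
    group_mask = design.matrix[:, design.group_col] == 1
    rng = np.random.default_rng(seed)
    rows = [
        _comparison_row(
            node,
            nodal_table[node].to_numpy(dtype=float),
            design,
            group_mask,
            n_perm,
            int(rng.integers(2**31 - 1)),
            adjusted_g,
        )
        for node in nodal_table.columns
    ]
    out = pd.DataFrame(rows).rename(columns={"outcome": "node"})
    out["p_fdr"] = bh_fdr(out["p_perm"].to_numpy())
    return out
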