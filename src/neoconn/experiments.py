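"""Validation experiments: worked examples, oracle checks, calibration, power.

Each function runs one self-contained experiment on top of the package's
public API and returns plain numbers, so the same code backs the analysis
drivers, the validation test suite, and the reproducibility script.  All
randomness flows from an explicit seed.

Problem sizes follow the package's validation protocol: oracle equivalence
on 200 random graphs of at most 8 nodes; type-I calibration on 500 null
cohorts at reduced size (10 + 10 subjects, 30 regions, 60 frames,
500 permutations); power and localization on 50 replicate cohorts at the
full study geometry (24 + 21 subjects, 92 regions, 120 frames).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import reference as R
from .connectivity import abs_pearson
from .core import WeightedNetwork, default_region_labels
from .metrics import (
    GLOBAL_METRICS,
    characteristic_path_length,
    clustering_coefficient,
    default_density_grid,
    draw_null_networks,
    global_efficiency,
    local_efficiency,
    metric_auc,
    metric_curves,
    modularity,
    proportional_threshold,
    small_worldness,
    transitivity,
)
from .qc import min_frames_required
from .stats import (
    bh_fdr,
    build_design,
    compare_nodal_metrics,
    freedman_lane,
    hedges_g,
    hedges_g_from_summary,
)
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "PUBLISHED_GLOBAL_SUMMARIES",
    "worked_example_effect_sizes",
    "structural_counts",
    "metric_oracle_max_error",
    "type1_calibration",
    "null_fdr_discoveries",
    "global_power",
    "focal_localization",
    "null_draw_small_worldness",
    "deterministic_invariants",
    "clustering_auc_by_subject",
]

# Published group summary statistics (mean, SD of the metric AUC per arm;
# 24 treated vs 21 placebo) used as inputs to the effect-size worked
# examples.  The three metrics listed are the ones whose printed g values
# match the unadjusted pooled-SD computation exactly.
PUBLISHED_GLOBAL_SUMMARIES = {
    "transitivity": {"treated": (0.43, 0.10), "placebo": (0.38, 0.09)},
    "characteristic_path_length": {"treated": (2.92, 0.39), "placebo": (3.04, 0.41)},
    "modularity": {"treated": (0.30, 0.07), "placebo": (0.29, 0.05)},
}
N_TREATED, N_PLACEBO = 24, 21


def worked_example_effect_sizes() -> dict[str, float]:
    """Hedges g recomputed from the published group summaries."""
    out = {}
    for metric, groups in PUBLISHED_GLOBAL_SUMMARIES.items():
        (m_t, s_t), (m_p, s_p) = groups["treated"], groups["placebo"]
        g, _ = hedges_g_from_summary(m_t, s_t, N_TREATED, m_p, s_p, N_PLACEBO)
        out[metric] = g
    return out


def structural_counts() -> dict[str, int]:
    """Structural constants implied by the study design."""
    labels = default_region_labels()
    n = len(labels)
    rng = np.random.default_rng(0)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    from .core import ConnectivityMatrix

    net = proportional_threshold(ConnectivityMatrix("abs_r", v, labels), 0.10)
    return {
        "n_nodes": n,
        "n_region_pairs": n * (n - 1) // 2,
        "min_frames_5min_tr3": min_frames_required(3.0),
        "edges_at_density_010": net.n_edges,
    }


def _random_small_net(rng: np.random.Generator) -> WeightedNetwork | None:
    n = int(rng.integers(4, 9))
    w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    w = np.triu(w, 1)
    w = w + w.T
    if np.count_nonzero(w) == 0:
        return None
    return WeightedNetwork(labels=[f"n{i}" for i in range(n)], weights=w)


def metric_oracle_max_error(n_graphs: int = 200, seed: int = 0) -> dict:
    """Max |fast - brute-force| over random small graphs, all 7 metrics.

    Clustering/transitivity/local efficiency against triple enumeration,
    path metrics against Floyd-Warshall, modularity against exhaustive
    partition search, and small-worldness against a sigma recomputed from
    brute-force clustering and path length on the identical null sample.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    n_checked = 0
    while n_checked < n_graphs:
        net = _random_small_net(rng)
        if net is None:
            continue
        n_checked += 1
        errs = []
        c1, m1 = clustering_coefficient(net)
        c2, m2 = R.clustering_brute(net)
        errs.append(np.max(np.abs(c1 - c2)))
        errs.append(abs(m1 - m2))
        errs.append(abs(transitivity(net) - R.transitivity_brute(net)))
        e1, em1 = local_efficiency(net)
        e2, em2 = R.local_efficiency_brute(net)
        errs.append(np.max(np.abs(e1 - e2)))
        errs.append(abs(em1 - em2))
        errs.append(abs(global_efficiency(net) - R.global_efficiency_brute(net)))
        try:
            cpl = characteristic_path_length(net)
            errs.append(abs(cpl - R.characteristic_path_length_brute(net)))
        except ValueError:
            pass
        q1, _ = modularity(net, n_restarts=10, seed=int(rng.integers(2**31 - 1)))
        q2, _ = R.modularity_exhaustive(net)
        errs.append(abs(q1 - q2))
        # sigma on a shared null sample, brute C and L on both sides
        try:
            nulls = draw_null_networks(net, n_null=5, seed=int(rng.integers(2**31 - 1)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s1 = small_worldness(net, null_nets=nulls)
            c_net = R.clustering_brute(net)[1]
            l_net = R.characteristic_path_length_brute(net)
            c_bar = np.mean([R.clustering_brute(x)[1] for x in nulls])
            l_bar = np.mean([R.characteristic_path_length_brute(x) for x in nulls])
            if c_bar > 0:
                errs.append(abs(s1 - (c_net / c_bar) / (l_net / l_bar)))
        except ValueError:
            pass
        max_err = max(max_err, float(np.max(errs)))
    return {"max_abs_error": max_err, "n_graphs": n_checked}


REDUCED_NULL = dict(n_treated=10, n_placebo=10, n_regions=30, n_frames=60)


def clustering_auc_by_subject(
    cohort, nodal: bool = False
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Clustering-coefficient AUC per subject (optionally per node)."""
    glob, nod = {}, {}
    for sid, ser in cohort.series.items():
        mat = abs_pearson(ser)
        curves, nodal_curves = metric_curves(
            mat,
            metrics=("clustering_coefficient",),
            nodal_metrics=("clustering_coefficient",) if nodal else (),
            seed=0,
        )
        glob[sid] = curves["clustering_coefficient"].auc
        if nodal:
            nod[sid] = metric_auc(nodal_curves["clustering_coefficient"])
    glob_s = pd.Series(glob)
    if not nodal:
        return glob_s, None
    labels = next(iter(cohort.series.values())).labels
    return glob_s, pd.DataFrame.from_dict(nod, orient="index", columns=labels)


def _null_cohort_p(seed: int, n_perm: int) -> float:
    cfg = CohortConfig(seed=seed, **REDUCED_NULL).null()
    cohort = generate_cohort(cfg)
    design = build_design(cohort.manifest)
    y, _ = clustering_auc_by_subject(cohort)
    _, p = freedman_lane(
        y.loc[design.subject_ids].to_numpy(), design, n_perm=n_perm, seed=seed
    )
    return p


def type1_calibration(
    n_cohorts: int = 500, n_perm: int = 500, seed: int = 0, alpha: float = 0.05
) -> dict:
    """False-positive rate of the adjusted permutation test on null cohorts.

    Generates fully null synthetic cohorts (no group or covariate
    effects), runs the whole pipeline down to the clustering-AUC group
    test, and reports the rejection rate at ``alpha`` plus a
    Kolmogorov-Smirnov uniformity p-value for the null p-values.
    """
    base = np.random.default_rng(seed).integers(0, 2**30)
    ps = np.array(
        [_null_cohort_p(int(base) + i, n_perm) for i in range(n_cohorts)]
    )
    return {
        "type1_rate": float(np.mean(ps < alpha)),
        "ks_uniform_p": float(kstest(ps, "uniform").pvalue),
        "n_cohorts": n_cohorts,
        "p_values": ps,
    }


def null_fdr_discoveries(
    n_cohorts: int = 20, n_perm: int = 500, seed: int = 0
) -> dict:
    """Mean count of FDR-significant nodes on null nodal tables (~0)."""
    base = int(np.random.default_rng(seed).integers(0, 2**30))
    counts = []
    for i in range(n_cohorts):
        cfg = CohortConfig(seed=base + i, **REDUCED_NULL).null()
        cohort = generate_cohort(cfg)
        design = build_design(cohort.manifest)
        _, nodal = clustering_auc_by_subject(cohort, nodal=True)
        res = compare_nodal_metrics(nodal, design, n_perm=n_perm, seed=base + i)
        counts.append(int((res["p_fdr"] < 0.05).sum()))
    return {
        "mean_discoveries": float(np.mean(counts)),
        "total_discoveries": int(np.sum(counts)),
        "n_cohorts": n_cohorts,
    }


def global_power(n_reps: int = 50, n_perm: int = 1000, seed: int = 0) -> dict:
    """Detection rate of the global connectivity uplift at full cohort size.

    Replicate cohorts carry the default global uplift (raw population
    Hedges g about 0.5) and no focal effect; success means the
    clustering-coefficient comparison reports positive g with adjusted
    permutation p < 0.05.
    """
    base = int(np.random.default_rng(seed).integers(0, 2**30))
    hits, gs = [], []
    for i in range(n_reps):
        cfg = dataclasses.replace(CohortConfig(seed=base + i), focal_uplift=0.0)
        cohort = generate_cohort(cfg)
        design = build_design(cohort.manifest)
        y = clustering_auc_by_subject(cohort)[0].loc[design.subject_ids].to_numpy()
        mask = design.matrix[:, design.group_col] == 1
        g, _ = hedges_g(y[mask], y[~mask])
        _, p = freedman_lane(y, design, n_perm=n_perm, seed=base + i)
        hits.append(bool(g > 0 and p < 0.05))
        gs.append(g)
    return {
        "detection_rate": float(np.mean(hits)),
        "mean_raw_g": float(np.mean(gs)),
        "n_reps": n_reps,
    }


def focal_localization(n_reps: int = 50, n_perm: int = 999, seed: int = 0) -> dict:
    """How often the focal node attains the smallest nodal p-value.

    Replicate cohorts carry only the focal uplift at one node (no global
    effect); per-node clustering AUCs are tested with the adjusted
    permutation test and ties at the smallest p are broken by |t|.
    """
    base = int(np.random.default_rng(seed).integers(0, 2**30))
    hits = []
    for i in range(n_reps):
        cfg = dataclasses.replace(CohortConfig(seed=base + i), group_uplift=0.0)
        cohort = generate_cohort(cfg)
        design = build_design(cohort.manifest)
        _, nodal = clustering_auc_by_subject(cohort, nodal=True)
        res = compare_nodal_metrics(nodal, design, n_perm=n_perm, seed=base + i)
        ranked = res.assign(abs_t=res["t_obs"].abs()).sort_values(
            ["p_perm", "abs_t"], ascending=[True, False]
        )
        focal_label = nodal.columns[cfg.focal_nodes[0]]
        hits.append(bool(ranked.iloc[0]["node"] == focal_label))
    return {"localization_rate": float(np.mean(hits)), "n_reps": n_reps}


def null_draw_small_worldness(
    n_inputs: int = 20, n_null: int = 100, seed: int = 0
) -> dict:
    """Mean small-worldness of networks that are themselves null draws.

    Sigma normalises by the random-network expectation, so a network drawn
    from the null model should score about 1.
    """
    rng = np.random.default_rng(seed)
    from .core import ConnectivityMatrix

    sigmas = []
    while len(sigmas) < n_inputs:
        n = 30
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        labels = [f"n{i}" for i in range(n)]
        base = proportional_threshold(ConnectivityMatrix("abs_r", v, labels), 0.25)
        from .metrics import null_network

        net = null_network(base, seed=int(rng.integers(2**31 - 1)))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sigmas.append(
                    small_worldness(
                        net, n_null=n_null, seed=int(rng.integers(2**31 - 1))
                    )
                )
        except ValueError:
            continue
    return {"mean_sigma": float(np.mean(sigmas)), "n_inputs": n_inputs}


def deterministic_invariants(seed: int = 0) -> dict:
    """Quick structural identities: constant-curve AUC and density nesting."""
    d = default_density_grid()
    auc_dev = abs(metric_auc((d, np.full(d.size, 0.4))) - 0.4)
    rng = np.random.default_rng(seed)
    n = 40
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    from .core import ConnectivityMatrix

    mat = ConnectivityMatrix("abs_r", v, [f"n{i}" for i in range(n)])
    violations = 0
    prev = None
    for dens in d:
        mask = proportional_threshold(mat, float(dens)).weights > 0
        if prev is not None and not np.all(mask[prev]):
            violations += 1
        prev = mask
    return {"auc_constant_deviation": float(auc_dev), "nesting_violations": violations}
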