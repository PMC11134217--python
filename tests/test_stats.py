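"""Hedges g, Freedman-Lane permutation inference, BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from neoconn import reference as R
from neoconn.stats import (
    bh_fdr,
    build_design,
    compare_global_metrics,
    compare_nodal_metrics,
    freedman_lane,
    hedges_g,
    hedges_g_from_summary,
)
from neoconn.synthetic import CohortConfig, generate_cohort


def tiny_manifest(n=12, seed=0):
    return generate_cohort(
        CohortConfig(n_treated=n // 2, n_placebo=n - n // 2, n_regions=3,
                     n_frames=10, seed=seed)
    ).manifest


class TestHedgesG:
    @pytest.mark.parametrize(
        "mean_t, sd_t, mean_p, sd_p, expected",
        [
            (0.43, 0.10, 0.38, 0.09, 0.51),  # transitivity AUC
            (2.92, 0.39, 3.04, 0.41, -0.30),  # characteristic path length
            (0.30, 0.07, 0.29, 0.05, 0.16),  # modularity
        ],
    )
    def test_published_group_summaries(self, mean_t, sd_t, mean_p, sd_p, expected):
        # group means/SDs for 24 treated vs 21 placebo reproduce the
        # reported pooled-SD Hedges g at 2 decimal places
        g, _ = hedges_g_from_summary(mean_t, sd_t, 24, mean_p, sd_p, 21)
        assert round(g, 2) == expected

    def test_ci_brackets_g(self):
        g, (lo, hi) = hedges_g_from_summary(0.43, 0.10, 24, 0.38, 0.09, 21)
        assert lo < g < hi
        assert lo == pytest.approx(-0.08, abs=0.02)
        assert hi == pytest.approx(1.11, abs=0.02)

    def test_identical_samples_give_zero(self, rng):
        x = rng.standard_normal(10)
        y = np.concatenate([x, x])[:10]
        g, _ = hedges_g(x, x + 0.0)
        assert g == 0.0

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.standard_normal(12), rng.standard_normal(9) + 0.4
        g_ab, _ = hedges_g(a, b)
        g_ba, _ = hedges_g(b, a)
        assert g_ab == pytest.approx(-g_ba, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            hedges_g(np.ones(5), np.ones(6))


class TestFreedmanLane:
    def test_perfect_separation_attains_minimum_p(self):
        manifest = tiny_manifest(14, seed=1)
        design = build_design(manifest)
        y = design.matrix[:, design.group_col].astype(float)
        _, p = freedman_lane(y, design, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_identity_permutations_give_p_one(self):
        manifest = tiny_manifest(14, seed=2)
        design = build_design(manifest)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(14)
        perms = np.tile(np.arange(14), (50, 1))
        _, p = freedman_lane(y, design, permutations=perms)
        assert p == 1.0

    def test_t_invariant_to_nuisance_shift(self, rng):
        manifest = tiny_manifest(16, seed=3)
        design = build_design(manifest)
        y = rng.standard_normal(16)
        shift = 3.0 * design.nuisance[:, 1] - 2.0 * design.nuisance[:, 2]
        t1, _ = freedman_lane(y, design, n_perm=10, seed=0)
        t2, _ = freedman_lane(y + shift, design, n_perm=10, seed=0)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_matches_exact_enumeration_on_tiny_n(self):
        # all n! permutations against an independently coded enumeration
        # whose t statistic comes from statsmodels OLS
        rng = np.random.default_rng(4)
        n = 6
        manifest = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["treated"] * 3 + ["placebo"] * 3,
                "sex": ["male", "female"] * 3,
                "ga_birth_weeks": rng.uniform(30, 34, n).round(2),
                "pma_scan_weeks": 40.0,
                "site": 1,
            }
        )
        design = build_design(manifest)
        y = rng.standard_normal(n)
        all_perms = np.array(list(itertools.permutations(range(n))))
        _, p_ours = freedman_lane(y, design, permutations=all_perms)

        def sm_group_t(yv, d):
            fit = sm.OLS(yv, d.matrix).fit()
            return fit.tvalues[d.group_col]

        p_exact = R.exact_permutation_p(y, design, sm_group_t)
        # our add-one estimator counts n! sampled perms, the oracle counts
        # n! + the observed; both count |t*| >= |t_obs| identically
        assert p_ours * (1 + len(all_perms)) == pytest.approx(
            p_exact * (1 + len(all_perms)), abs=1.0
        )
        assert p_ours == pytest.approx(p_exact, abs=1 / len(all_perms))

    def test_rank_deficient_design_rejected(self):
        manifest = tiny_manifest(10, seed=5)
        manifest["ga_birth_weeks"] = 32.0  # GA column collinear w/ intercept
        with pytest.raises(ValueError, match="rank"):
            build_design(manifest)


class TestBhFdr:
    def test_equal_p_values_unchanged(self):
        assert np.allclose(bh_fdr(np.full(7, 0.03)), 0.03)

    def test_step_up_hand_computation(self):
        got = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_order_statistics(self, rng):
        p = rng.uniform(size=30)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


class TestComparisons:
    def test_global_report_shape_and_determinism(self):
        manifest = tiny_manifest(16, seed=6)
        design = build_design(manifest)
        rng = np.random.default_rng(0)
        auc = pd.DataFrame(
            rng.standard_normal((16, 3)),
            index=design.subject_ids,
            columns=["clustering_coefficient", "transitivity", "modularity"],
        )
        a = compare_global_metrics(auc, design, n_perm=200, seed=7)
        b = compare_global_metrics(auc, design, n_perm=200, seed=7)
        assert a.equals(b)
        assert list(a["outcome"]) == list(auc.columns)
        assert ((a["p_fdr"] >= a["p_perm"] - 1e-12)).all()

    def test_missing_subject_listed(self):
        manifest = tiny_manifest(10, seed=7)
        design = build_design(manifest)
        auc = pd.DataFrame(
            np.zeros((9, 1)), index=design.subject_ids[:-1], columns=["m"]
        )
        with pytest.raises(ValueError, match=design.subject_ids[-1]):
            compare_global_metrics(auc, design, n_perm=10)

    def test_nodal_report_has_fdr_across_nodes(self):
        manifest = tiny_manifest(14, seed=8)
        design = build_design(manifest)
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(
            rng.standard_normal((14, 5)),
            index=design.subject_ids,
            columns=[f"roi_{i}" for i in range(5)],
        )
        res = compare_nodal_metrics(tab, design, n_perm=100, seed=9)
        assert len(res) == 5
        assert (res["p_fdr"] >= res["p_perm"] - 1e-12).all()

    def test_adjusted_g_tracks_model_coefficient_sign(self):
        manifest = tiny_manifest(20, seed=9)
        design = build_design(manifest)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(20) + 2.0 * design.matrix[:, design.group_col]
        auc = pd.DataFrame({"m": y}, index=design.subject_ids)
        res = compare_global_metrics(auc, design, n_perm=100, seed=0, adjusted_g=True)
        assert res["hedges_g"].iloc[0] > 0
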