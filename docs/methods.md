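# Methods

`neoconn` implements a group-comparison analysis of neonatal resting-state
functional connectomes: from per-subject regional BOLD time series and
head-motion traces, through connectivity matrices and density-thresholded
weighted networks, to graph metrics aggregated over a density range and
covariate-adjusted nonparametric inference. A synthetic cohort generator
emulating the statistical structure of a two-arm neonatal trial makes every
stage testable end to end without access to clinical data.

## Synthetic cohort model

Each subject's regional signals follow a single-shared-factor Gaussian
model. Region `r` carries a communality (loading) `lam_r` in `[0, 0.99]`
and its signal is

    x_r(t) = sqrt(lam_r) * f(t) + sqrt(1 - lam_r) * eps_r(t),

with a common factor `f` and independent noise `eps_r`, all standard
normal and independent across frames. The population correlation between
regions `i != j` is therefore `sqrt(lam_i * lam_j)`, and the implied
correlation matrix `diag(1 - lam) + sqrt(lam) sqrt(lam)^T` is positive
semidefinite by construction. The number of factors is configurable; with
`k` factors the per-factor loadings are split `lam/k`, leaving the
pairwise correlations unchanged.

Loadings shift additively with the design:

    lam_r = base + group_uplift * 1[treated]
                 + focal_uplift * 1[r focal, treated]
                 + sex_effect * 1[male] + ga_slope * (GA - 32) + site offset.

Defaults (frozen after a one-off calibration pilot):

| parameter        | default | rationale |
| ---------------- | ------- | --------- |
| `n_treated` / `n_placebo` | 24 / 21 | study arm sizes |
| `n_regions` / `n_frames` / `tr_seconds` | 92 / 120 / 3.0 | parcellation count, scan length, repetition time |
| `base_coupling`  | 0.30    | mid-range neonatal `|r|` values |
| `group_uplift`   | 0.055   | raw population Hedges g of the clustering-coefficient AUC about 0.5 |
| `focal_uplift`   | 0.25    | a single-node effect strong enough to dominate the nodal comparison (analogous to the reported focal finding with g near 1) |
| `sex_effect` / `ga_slope` / `site_offsets` | 0.09 / 0.06 per wk / (0, 0.04, -0.04) | covariate-driven loading variance roughly 1.7x the sampling SD (see below) |
| `motion_mean_mm` / `motion_sd_mm` | 0.066 / 0.027 | reported mean (SD) relative inter-frame displacement |
| site proportions | 32:10:3 | reported site split |
| GA at birth      | uniform on [30, 34] wk | trial entry window |
| PMA at scan      | GA + N(8, 1) wk | term-equivalent scanning |

The calibration pilot measured the sampling-only SD of the
clustering-coefficient AUC (0.024 at the default geometry) and its
response slope to a uniform loading shift (about 0.49 per unit loading).
Covariate effects are deliberately sizeable: the raw between-subject SD is
then about twice the sampling SD, so the raw standardized group difference
is near 0.5 while the covariate-adjusted permutation test — which removes
the covariate variance — retains roughly 90% power at n = 45. This
reproduces the qualitative pattern of the motivating study, where adjusted
permutation p-values are more significant than the raw effect sizes alone
would suggest.

Motion traces are lognormal, moment-matched to the target mean and SD
(displacements are nonnegative and right-skewed), with optional Bernoulli
"spike" frames exceeding 1 mm (`spike_prob`, default 0: the study cohort's
included scans were low-motion).

What the generator does *not* emulate: hemodynamic response dynamics,
temporal autocorrelation (frames are independent draws), scanner noise
physics, spatial voxel structure, and the modular community organisation
of real connectomes (a single factor yields one global core, so absolute
modularity values run lower than in real neonatal data). Passing tests
therefore demonstrate the correctness and calibration of the *pipeline*,
not fidelity of any biological claim.

A focal loading uplift has a non-obvious consequence under proportional
thresholding: the focal node's edges strengthen and crowd into the
retained set, its degree rises sharply, and its *own* weighted clustering
coefficient falls (the triangle sum grows more slowly than
`k (k - 1)`). The nodal comparison is two-sided, so localization is
unaffected; the sign of the focal nodal effect should not be
over-interpreted.

## Quality control

Three rules operate on the displacement trace (one value per consecutive
frame pair, in mm):

1. **Edge trimming** (0.25 mm): leading frames are dropped while the first
   remaining displacement exceeds the threshold, then trailing frames
   likewise; interior spikes are never trimmed. The operation is
   idempotent. If every displacement is consumed the scan is excluded
   (`edge_trim_empty`).
2. **Clean-window inclusion** (1 mm cap, 5 minutes): a scan is included
   iff it contains a run of consecutive displacements all at or below the
   cap spanning at least `ceil(300 / TR)` frames (100 at TR 3 s). A run
   of `k` clean displacements spans `k + 1` frames.
3. **High-pass filtering** (0.01 Hz): the mean and every discrete-cosine
   basis component with frequency below the cutoff (`f_k = k / (2 N TR)`)
   are projected out of each region. The DCT basis is orthogonal, so the
   filter is a single projection: exactly linear, phase-free, and
   zero-mean by construction; components well above the cutoff are
   preserved to within a few percent.

Order of operations: trim, then the clean-window test, then the filter
(applied only to included subjects). Whether the original analysis trimmed
before or after filtering is not documented; trim-first is this package's
convention and only affects the handful of edge frames.

## Connectivity

Two edge-weight definitions: `abs_r` (absolute Pearson correlation,
in [0, 1]) and `fisher_z_pos` (Fisher z of positive correlations,
negatives zeroed; correlations are capped at 0.999999 before `atanh` so
numerically identical signals give a large finite weight — proportional
thresholding requires finite weights). Diagonals are zero; zero-variance
regions raise an error naming the offending labels.

Voxel-level analysis (small synthetic patches only): pairwise `|r|` with
pairs of voxels closer than 10 mm zeroed. The boundary is strict (`< 10
mm`; pairs at exactly 10 mm are retained) and zeroed pairs stay in the
averaging denominator by default — the per-voxel mean is over *all* other
voxels; a denominator-excluding variant is available. Region-mean
connectivity is the mean of a region's off-diagonal row.

## Networks and metrics

**Proportional thresholding.** At density `d`, the strongest
`floor(d * n(n-1)/2)` edges are retained with their weights; ties are
broken by ascending node-pair order, so edge sets are deterministic and
nested across the grid (0.10 to 0.35 in steps of 0.01, 26 densities).
Zero-weight pairs never count as connections, so the realized density can
fall below the request on sparse matrices.

**Segregation.** Weighted clustering uses the geometric-mean (Onnela)
form on max-normalised weights `w' = w / max(w)`:
`C_i = sum_jk (w'_ij w'_ik w'_jk)^(1/3) / (k_i (k_i - 1))`, zero for
degree < 2; transitivity is the collectively normalised ratio of the same
numerator and denominator sums. Local efficiency of node `u` applies the
analogous cube-root form to neighbour weights and inverse shortest paths
within the neighbourhood subgraph. All three are invariant to uniform
weight rescaling.

**Integration.** Shortest paths use edge length `1 / w` on the *raw*
weights (Dijkstra). Characteristic path length is the mean over finite
pairs, with the count of unreachable pairs reported alongside — at
density 0.10 a 92-node network is occasionally disconnected, and
averaging finite distances keeps subjects comparable without infinities;
global efficiency needs no special case (`1 / inf = 0`). Because path
lengths keep the natural weight scale, these two metrics are not
scale-invariant (they scale as `1/w` and `w` respectively); the
triangle-based metrics are.

**Modularity.** Weighted Newman modularity at resolution 1. For graphs of
at most 10 nodes the optimal partition is found exactly by enumerating
restricted growth strings (Bell(10) ~ 1.2e5 partitions) — local search
demonstrably misses the optimum on some tiny graphs whose optimal
partition has an empty attraction basin. Larger graphs use seeded Louvain
with `n_restarts` starts (default 10), each polished by alternating a
single-node-move hill climb, greedy community merges, and
cross-community pair swaps until no move improves Q. Deterministic given
the seed; the reported Q is the best over restarts.

**Small-worldness.** `sigma = (C / C_null) / (L / L_null)`, with `C_null`
and `L_null` means over 100 null networks. The null model redraws the
topology uniformly among simple graphs with the same node and edge count
and randomly reassigns the *exact* multiset of empirical edge weights
("same size and edge weight distribution", read literally); a
degree-preserving rewiring variant is available behind a flag. Sigma is
about 1 for networks that are themselves null draws and above 1 for
lattice-like substrates.

**AUC.** Each metric's density profile is summarised by the trapezoidal
mean `sum_i (Y_i + Y_{i+1})/2 * (d_{i+1} - d_i) / (d_N - d_1)` — the
average metric value over the density range, removing dependence on any
single threshold.

## Inference

The design matrix holds an intercept, the group indicator (treated = 1),
sex, centred gestational age at birth, their interaction, and site
indicators. Sex and GA main effects accompany the interaction
(hierarchical convention). Sites containing a single treatment group are
collapsed into the reference with a warning, since their indicator would
be confounded with treatment.

**Freedman-Lane.** The outcome is regressed on the nuisance block; the
residuals are permuted over subjects, added back to the nuisance fit, and
the full model's group t statistic is recomputed for each permutation.
The two-sided p uses the add-one estimator `(1 + #{|t*| >= |t_obs|}) /
(1 + n_perm)`, never zero. Permutations are unrestricted over subjects
(no exchangeability blocks for site or twin pairs; a caller can supply an
explicit permutation set, which the exact-enumeration tests use).
Defaults follow the study: 100 000 permutations for global and nodal
comparisons, 10 000 for pairwise/voxel-scale screens.

**Effect sizes.** Hedges g = `J * (m_t - m_p) / s_pooled` with
`J = 1 - 3/(4 df - 1)`, `df = n_t + n_p - 2`; the 95% CI uses the
normal-approximation SE `sqrt((n_t + n_p)/(n_t n_p) + g^2/(2 df))`. The
default g is computed from raw group values; a covariate-adjusted variant
(group coefficient over residual SD) is available behind a flag, as
published effect sizes in this literature are sometimes adjusted and
sometimes not.

**Multiplicity.** Benjamini-Hochberg step-up FDR across nodes (and,
informationally, across the seven global metrics). Note BH adjustment is
monotone in the order statistics but not idempotent.

## Numerical conventions and degenerate inputs

- Correlations are clipped to [-1, 1] before any transform.
- An empty motion trace counts as a single frame (flagged with a warning).
- Metric ties in thresholding resolve by ascending `(i, j)`.
- Edgeless graphs: transitivity and global efficiency 0; modularity and
  characteristic path length raise errors.
- The permutation t statistic for a zero-residual fit is `inf`; only
  equally infinite permuted statistics count as exceedances.
- All stochastic steps (BOLD draws, motion, permutations, modularity
  restarts, null networks) derive their generators from explicit seeds;
  per-subject streams are keyed by a CRC of the subject id, so cohorts are
  reproducible subject-by-subject.

## Validation protocol and problem sizes

The test suite and `scripts/acceptance.py` run, at sizes chosen to keep a
desktop run short while leaving Monte-Carlo error small:

- worked-example effect sizes recomputed from published group summary
  statistics (instant; exact to printed precision);
- structural constants of the design: 92 nodes, 4186 region pairs, 100
  frames for 5 minutes at TR 3 s, 418 edges at density 0.10;
- oracle equivalence of all seven metrics against brute-force
  implementations (triple enumeration, Floyd-Warshall, exhaustive
  partition search, sigma on a shared null sample) on 200 random graphs
  of at most 8 nodes, tolerance 1e-10;
- type-I calibration of the adjusted permutation test over 500 null
  cohorts at reduced size (10 + 10 subjects, 30 regions, 60 frames, 500
  permutations), with a Kolmogorov-Smirnov uniformity check, and
  near-zero BH-FDR discoveries on 20 null nodal tables;
- detection of the calibrated global uplift and localization of the focal
  uplift in 50 replicate cohorts each at the full study geometry;
- aggregation invariants (constant-curve AUC, density nesting, null-draw
  sigma near 1).

## Known limitations

- The generator's independence across frames understates the temporal
  autocorrelation of real BOLD data, so its sampling noise is optimistic
  for a fixed frame count.
- Voxel-level inference is limited to small patches and mean-connectivity
  summaries; no cluster-level spatial statistics are provided.
- The finite-pairs convention for characteristic path length makes the
  metric non-monotone at densities where components merge.
- The heuristic modularity search carries no optimality guarantee above
  10 nodes (restarts mitigate; Q values at 92 nodes are stable across
  seeds to ~1e-3 in practice).
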