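# Methods

This note records the models, conventions and numerical choices behind
`connectome_backbone`, including the places where the underlying
methodology is silent and a concrete convention had to be picked.

## The backbone model

The unit of analysis is an unweighted, undirected graph over a fixed
cortical atlas (78 AAL regions by default, 39 per hemisphere, left and
right labels paired by stem).  Fiber counts are treated as evidence for
the *existence* of a connection, never as edge weights: path lengths are
hop counts.

**Connectivity SNR.** For a group of subjects, each region pair gets
`SNR = mean / SD` of its fiber count across subjects (reciprocal
coefficient of variation).  Conventions:

- SD uses the sample (n−1) denominator; the choice is conventional and
  undocumented in the source methodology.
- Subjects without the connection contribute zeros to mean and SD —
  absence of a tract is signal, not missingness.
- `SD = 0` with `mean > 0` (perfect consistency) maps to `SNR = +inf`
  and ranks above every finite SNR, ordered among the sentinels by mean;
  `mean = 0` maps to `SNR = 0`.
- SNR is invariant to scaling all of a pair's counts by a constant, so
  it does not depend on how many fibers tractography reconstructs
  overall (neonatal images yield fewer fibers); this is asserted as a
  property test.

**Cost thresholding.** The backbone at target cost `c` keeps the top
`E = round(c * K)` pairs by SNR, `K = N(N−1)/2`, rounding half-up (the
methodology states a cost, not an edge count, so a deterministic
convention is required; at `N = 78`, `c = 0.21` gives exactly 631
edges).  Ties break by higher mean, then lexicographic pair index, which
makes edge sets nested across costs and the whole sweep deterministic.

## Efficiency, centrality, null models

- `E_glob` sums `1/d_ij` over ordered pairs with disconnected pairs
  contributing 0 (the infinite-distance sentinel maps to 0 in every
  `1/d` sum).
- `E_loc` applies `E_glob` to each node's neighbor-induced subgraph with
  the subgraph's own node count in the normalization; nodes of degree
  ≤ 1 contribute 0 (their subgraph has < 2 nodes — the degenerate case
  is unspecified upstream, this is the standard Latora–Marchiori
  reading).
- Betweenness sums over unordered pairs and normalizes by
  `(N−1)(N−2)/2`, so a star hub attains exactly 1.  Shortest-path
  counts come from BFS; the interior count uses the identity
  `sigma_jk(i) = sigma_ji * sigma_ik` iff `d_ji + d_ik = d_jk`.
- Vulnerability recomputes `E_glob` on the damaged graph with its own
  `N−1` normalization (the efficiency definition applied verbatim to
  the remaining graph); values can be negative.
- Rewired nulls preserve the exact degree sequence by double-edge swaps
  with `10 * |E|` attempts (default), rejecting self-loops and
  duplicates; graphs with no legal swap (stars) return unchanged.
- The "regular lattice" comparator is a circulant ring lattice filled by
  circular-distance tiers (distance-1 ring first), the Watts–Strogatz
  convention; the construction is unspecified upstream.  Default
  ensemble size is 100 realizations (the upstream count is unstated;
  100 stabilizes the ensemble SD on 78-node graphs in seconds).

## Communities and roles

Modularity is `Q = sum_s [ l_s/L − (d_s/(2L))^2 ]`.  Detection is the
agglomerative fast-greedy optimizer: start from singletons, repeatedly
merge the connected pair with the largest
`dQ = l_uv/L − 2 (d_u/2L)(d_v/2L)`, track the best Q along the merge
path, return that partition.  Merge ties break on the lowest
community-id pair (ids are smallest member node indices) for full
determinism.  Only connected pairs merge, so components agglomerate
independently and isolated nodes remain singletons.

Node roles use within-module degree z-scores (population SD; a module
with uniform within-degrees gets z = 0 rather than ±inf) and
participation coefficients.  The numeric role boundaries follow the
Guimerà–Amaral cartography (non-hub: A ≤ 0.05 < B ≤ 0.62 < C ≤ 0.80
< D; hub, z > 2.5: E ≤ 0.30 < F ≤ 0.75 < G) because the original
cutoffs are unreadable in the source text; they are configurable
(`RoleThresholds`).  Degree-0 nodes have undefined P; they are reported
as P = 0, role A, with a `degenerate` flag.

## Degree-distribution fits

Fits operate on the CCDF `P(K >= k)` (explicitly preferred upstream to
reduce noise), not the histogram.  The broad-scale form is
`P(K >= k) = c k^(alpha−1) exp(−k/k_c)`, fitted by nonlinear least
squares on `log P` with multi-start initialization (alpha in {1.5, 2.5,
3.5} x k_c in {k_max/4, k_max, 4 k_max}); `k_c` is bounded at 1e6, and
estimates at or beyond the observed range mean "no visible cutoff"
(pure power law).  The log-log straight line is fitted over the
power-law regime `k <= k_c` by default ("linear decay before the sharp
cutoff"), with an explicit range override; a constant CCDF is flagged
degenerate with slope 0 and R² = 1 by the zero-variance convention.
R² is computed in log space as `1 − SS_res/SS_tot`.

## Permutation tests

Statistic: difference of group means (configurable).  The two-sided p
is the literal proportion of relabelings with `|stat| >= |observed|` —
no +1 correction, for fidelity to the stated definition — with a
warning when p = 0 (which only means p < 1/n_perm).  Default 1000
permutations.  An exhaustive mode enumerates all `C(n_a+n_b, n_a)`
splits; the 3-vs-3 example `[0,0,0]` vs `[1,1,1]` gives p = 2/20 = 0.1
exactly.

Group-level backbone metrics have one value per group, so the
resampling unit is the subject: each relabeling rebuilds both group
backbones from the permuted subject sets and recomputes the metric
difference.  The upstream resampling unit is unstated; subject
relabeling is the only unit that preserves the backbone construction,
and it is configurable via the lower-level `permutation_test`.

Hemispheric symmetry regresses right-hemisphere node betweenness on the
left partner (pairing by label stem), reporting slope, Pearson r and
normal-theory confidence bands; a zero-variance regressor yields NaN
results rather than an error.

## The synthetic cohort: what it does and does not emulate

The generator states a world matching the emulated study design: 39
subjects (18 male / 21 female) scanned at three ages ("2wk", "1yr",
"2yr"), 78 paired cortical regions.  Since the design is longitudinal,
**one planted backbone is shared by all groups**; age effects enter
through fiber lengths and optional count-mean multipliers.

- **Planted backbone**: a stochastic block model over 5 hemisphere-aware
  modules — two left/right module pairs (16+16 and 14+14 regions) plus
  one bilateral medial-style module (18) — with `p_in = 0.70`,
  `p_out = 0.094`, chosen so the expected backbone size is ~631 edges,
  i.e. the analysis cost of 0.21 where the network becomes fully
  connected.
- **Counts**: negative-binomial (mean 50, dispersion 5) on true edges —
  overdispersion is what makes the SNR statistic discriminative — with
  a per-scan lognormal scale factor (sigma 0.2) for subject
  variability.  Spurious connections appear independently per scan with
  probability 0.10 and counts `1 + NB(mean 1, dispersion 0.5)`: present
  but inconsistent, exactly what the SNR filter must reject.  No
  distributional statement about fiber counts exists upstream; these
  are this package's modeling choices.
- **Lengths**: lognormal, `length = group_mean * base_pair * jitter`,
  with unit-mean base (sigma 0.4) shared across all scans (lengths live
  in a common stereotaxic space) and small per-scan jitter (sigma 0.1).
  Group means are 40.22 / 66.16 / 62.45 mm — the reported developmental
  pattern of long-fiber maturation.

Not emulated, hence not established by green tests: node-level
left-right edge mirroring (so hemispheric betweenness correlations are
near zero here, unlike the ~0.4–0.5 of real cortex); realistic
broad-scale degree tails of the default backbone (an SBM's degree
distribution is a binomial mixture — the truncated power-law fit is
validated on constructed model data instead); distance-dependent edge
probability; and any spatial geometry.  Because per-pair base lengths
are shared across scans, between-group length contrasts are sharper
than in real data (all three pairwise length differences come out
significant on the default cohort, where the original analysis found
the two older groups indistinguishable).

## Reproducibility and scaling

Every stochastic step takes a seed; the pipeline derives stage seeds as
`(master * 100003 + stage) mod 2^31`.  Rerunning `run_all` with the
same seed reproduces the JSON report byte for byte.  The default full
pipeline (78 regions, 117 scans, 100-null ensembles, 200 permutations
per comparison) runs in under two minutes on one CPU; the test suite
uses scaled-down ensembles (20 nulls, ≤ 200 permutations) and completes
in well under a minute.
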