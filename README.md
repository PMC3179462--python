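# connectome-backbone

Structural brain-network analysis from multi-subject fiber-count
matrices, for researchers studying white-matter connectivity with
tractography-derived region-pair counts (e.g. developmental or
population connectome studies).

Given per-subject symmetric fiber-count matrices over a fixed cortical
atlas (78 AAL regions, 39 per hemisphere, by default), the package:

1. **builds a consistency backbone** — per region pair the connectivity
   SNR, the reciprocal coefficient of variation of the fiber count
   across subjects, `SNR_ij = mu_ij / sigma_ij`; the SNR matrix is
   thresholded to a target network cost
   `Cost = |E| / (N(N-1)/2)` (default 0.21, the cost at which the
   78-node network becomes fully connected);
2. **quantifies small-world topology** — global efficiency
   `E_glob = (1/(N(N-1))) * sum_{i != j} 1/d_ij` and local efficiency
   `E_loc = mean_i E_glob(G_i)` (neighbor-induced subgraphs), compared
   against degree-preserving rewired nulls and matched ring lattices
   over a cost sweep; small-world means `E_loc > E_loc(random)` and
   `E_glob > E_glob(lattice)`;
3. **detects modules and classifies node roles** — modularity
   `Q = sum_s [ l_s/L - (d_s/(2L))^2 ]` maximized by fast-greedy
   agglomeration, then z-P cartography: within-module degree z-score
   (hub if z > 2.5) vs participation coefficient
   `P_i = 1 - sum_s (kappa_is / k_i)^2`, yielding role letters A-G;
4. **characterizes the degree distribution** — CCDF `P(K >= k)` with a
   straight-line log-log fit and the broad-scale truncated power law
   `P(K >= k) = c k^(alpha-1) exp(-k/k_c)`, both scored by R²;
5. **compares groups** — betweenness
   `B_i = sum_{j<k} sigma_jk(i)/sigma_jk / ((N-1)(N-2)/2)`,
   vulnerability `V_i = (E_glob - E_glob^{-i})/E_glob`, left-right
   hemispheric symmetry regression, and permutation tests (subject
   relabeling with backbone rebuilds) for group-level metrics;
6. **simulates cohorts** — a seeded generator producing 39 subjects x 3
   age groups over a planted modular (stochastic-block-model) backbone
   with negative-binomial count noise, spurious connections, and
   age-dependent lognormal fiber lengths, so the entire pipeline is
   testable without any imaging data.

## Worked example

```python
import connectome_backbone as cb

cohort, planted, modules = cb.sample_cohort(cb.CohortConfig(seed=1))
snr = cb.compute_snr(cohort, group="1yr")
backbone = cb.threshold_to_cost(snr, 0.21)
print(backbone.n_edges, cb.largest_component_size(backbone))
# 631 78        <- round(0.21 * 3003) edges; no isolated nodes at cost 0.21

sweep = cb.smallworld_sweep(snr, [0.10, 0.15, 0.21, 0.30], n_null=20, seed=2)
print([r["small_world"] for r in sweep])
# [True, True, True, True]

part = cb.detect_communities(backbone)
print(round(part.q, 3), part.n_modules)
# 0.413 5       <- vs rewired-null Q of about 0.16 +/- 0.01
```

631 of the 3003 region pairs survive the SNR threshold (a 0.991 Jaccard
overlap with the planted backbone), the network is small-world at every
cost — locally far more clustered than degree-matched random graphs,
globally far shorter-pathed than a lattice — and greedy modularity
recovers the five planted modules with Q far above chance.  The
`examples/` scripts walk through each capability and print what the
numbers mean; `cb.run_all(cb.PipelineConfig(seed=7))` runs everything
(simulation through group statistics) and emits a reproducible JSON
report.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the data-independent reference quantity from scratch by
running the package — it builds a 10-node star graph and evaluates the
normalized betweenness centrality of its hub — and writes the result as
JSON.
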