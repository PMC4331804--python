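# nfapin

Essential-protein prediction from **active** protein–protein interaction
(PPI) networks built with dynamic gene-expression profiles.

Topological centrality on a static PPI network is a classical way to rank
candidate essential proteins, but static interactomes carry many false
positives and ignore *when* proteins are actually present. `nfapin`
restricts the static network to interactions whose two endpoint proteins
are simultaneously *active* — expressed above a gene-specific threshold at
the same time point of a time-course expression experiment — and ranks
proteins by centrality on this noise-filtered active network (NF-APIN)
instead.

## The method

Given a static PPI graph `G = (V, E)`, an expression matrix with one
length-`M` series per gene, and a reference list of known essential
proteins:

1. **Time-dependence test.** Each profile `x = (x_1, …, x_M)` is fitted by
   an AR(p) model `x_m = β0 + β1 x_{m−p} + … + βp x_{m−1} + ε_m` and by a
   constant model `x_m = β0 + ε_m`, both by maximum likelihood over the
   shared span `m = p+1…M`. The likelihood ratio
   `Λ = (σ̂² / σ̂c²)^{(M−p)/2}` gives the statistic

       F = (M − 2p − 1)/p · (σ̂c²/σ̂² − 1)  ~  F(p, M − 2p − 1)

   under the constant-model null. All orders `1 ≤ p ≤ (M−1)/2` are
   scanned; a gene is *time-dependent* when the minimum p-value falls
   below a preset `α` (default 0.01).
2. **Noise filter.** Genes that are time-independent *and* have very
   small mean expression are discarded.
3. **Active threshold.** Every remaining gene gets the cutoff
   `threshold = u + kσ(1 − F)` with damping `F = 1/(1 + σ²)`, where `u`,
   `σ` are the mean and standard deviation of its profile and
   `k ∈ [0, 3]` (default 2.5). A protein is active at time `t` when its
   expression there strictly exceeds its threshold.
4. **Active network.** An edge `(u, v) ∈ E` belongs to the active network
   at time `t` when both `u` and `v` are active at `t`; centralities are
   computed on the union of the per-time edge sets.
5. **Centrality and evaluation.** Six measures — degree (DC), betweenness
   (BC), closeness (CC), subgraph (SC, the diagonal of `exp(A)`), local
   average connectivity (LAC), and the sum of incident edge clustering
   coefficients `ECC(u,v) = Z_{u,v} / min(d_u−1, d_v−1)` (NC) — rank the
   proteins; rankings are scored by top-k essential counts, cumulative
   jackknife curves with (normalized) area under the curve, and overlap
   reports between the static-network ("PPIN") and active-network
   ("APPIN") predictions.

A synthetic module generates AR/null expression series and random
networks with a planted co-active module and enriched essential labels,
so the entire pipeline runs and is tested without any external data.

## Worked example

```sh
nfapin simulate -o demo --seed 11          # 50 proteins, 120 interactions
nfapin -v run demo/network.tsv demo/expression.tsv demo/essential.txt \
       -o out --ks 5,10,15
```

The log reports each stage (`read 50 nodes / 120 edges`, `active network:
4 nodes, 2 edges in the union graph`, …) and `out/evaluation_counts.tsv`
compares the two networks:

```
measure  network  auc    auc_normalized  top_5  top_10  top_15
DC       PPIN     433.5  0.68            3      4       5
DC       APPIN    494.5  0.7757          4      6       9
BC       PPIN     412.5  0.6471          4      4       6
BC       APPIN    494.5  0.7757          4      6       9
LAC      PPIN     395.5  0.6204          1      2       4
LAC      APPIN    494.5  0.7757          4      6       9
```

Here 15 of the 50 proteins are essential, enriched inside the planted
co-active module. Reading the DC rows: degree centrality on the static
network puts 4 true essentials in its top 10, while on the active network
it finds 6, and its normalized jackknife area rises from 0.68 to 0.78 —
the active network concentrates the ranking on the co-active module where
the essentials sit. `out/evaluation_overlaps.tsv` decomposes the top-k
essential sets of the two networks (shared vs network-specific finds),
and per-gene dependence calls, thresholds, activity flags, per-time
active edges and centrality scores are all written alongside.

Every stage is also available as its own subcommand (`filter-genes`,
`thresholds`, `build-network`, `centrality`, `evaluate`) and as plain
library functions (`nfapin.call_dependence`, `nfapin.activity_matrix`,
`nfapin.build_active_network`, `nfapin.compare_networks`, …).

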