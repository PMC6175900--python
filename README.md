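# espstrat

Tumor stratification from somatic mutation profiles over
mutual-exclusivity-filtered gene interaction networks — **evolutionarily
selected pathways** (ESPs) — together with the simulation framework that
shows when pathway-based stratification succeeds and when it is drowned out
by cancer-irrelevant interactions.

## Who this is for

Computational cancer-genomics groups who have (a) a binary patient-by-gene
somatic mutation matrix (or MAF-lite calls), (b) an undirected
protein-interaction network, and optionally clinical survival, expression or
cell-line drug-response tables, and who want network-smoothed mutation
subtypes that are robust to the huge number of non-cancer interactions in
public interactomes.

## The method

1. **ESP selection.** For every interaction (i, j) present in the network,
   count patients with both genes mutated (a), only i (b), only j (c),
   neither (d), and score mutual exclusivity with the exact one-tailed
   Fisher test, p = P(X ≤ a) for X hypergeometric with the observed margins.
   The k = 100 most exclusive interactions form the cancer-type-specific ESP
   map. If nothing is scorable, the method degenerates to consensus
   clustering of the raw profiles.
2. **Network propagation** (random walk with restart). With A the adjacency
   matrix and B_ij = A_ij / Σ_j A_ij,

       F_{t+1} = (1 − α) F_t B + α F_0,      α = 0.5,

   iterated from the binary profile F_0 until ‖F_{t+1} − F_t‖ < 10⁻⁶, then
   each patient row is rescaled to sum to 1 (mutational-load independence).
3. **Embedding and consensus clustering.** log(F + c) = U S Vᵀ with
   c = 1/(number of genes); the d-dimensional embedding is M_d = S_d^{1/2} U_dᵀ.
   For each d in 10…50, k-means++ (200 starts, 100 iterations) clusters the
   rows of the patients' cosine-similarity matrix; binary co-clustering
   matrices are averaged into a consensus matrix, and a final k-means++ on
   the cosine similarity between consensus rows gives subtypes at each
   resolution k = 2…6.
4. **Characteristic ESPs.** Per subtype, genes whose propagated scores are
   enriched versus the remaining cohort (one-sided Welch t-test; p < 0.05
   for k < 4, p < 0.1 for k ≥ 4) are mapped back onto the ESP map; the
   induced subnetwork is the subtype's signature, and can re-cluster a
   cohort on its own (a single-gene signature reduces to that gene's
   mutation status).
5. **Evaluation.** Adjusted Rand index against known labels, Cox
   proportional-hazards / log-rank survival association, rank-sum contrasts
   of log(IC50) drug response and of expression PC1 between signature-defined
   groups.

The `simulate` module generates the benchmark cohorts: 1000 tumors × 1000
genes, two equal subtypes driven by 25-gene frequently mutated pathways
(FMPs, 2 genes mutated per tumor, within-pathway edge density 0.2) and/or a
frequently mutated gene (FMG, mutated in one subtype, overall frequency
0.5), Erdős–Rényi or preferential-attachment background edges at per-pair
density m, and per-cell background mutations at rate l.

## Worked example

```python
import espstrat as es

cfg = es.SimulationConfig(scenario="fmp_with_fmg",
                          random_edge_density=0.01,
                          background_rate=0.01, seed=7)
sim = es.simulate_cohort(cfg)

opts = es.StratifyOptions(
    embedding=es.EmbeddingConfig(d_range=(10, 20, 30, 40, 50),
                                 kmeans_starts=20))
assignment = es.propagate_and_cluster(sim.cohort, sim.network, k=2,
                                      options=opts, seed=7)
print(round(es.adjusted_rand_index(sim.true_labels, assignment.labels), 3))
```

prints

```
0.956
```

i.e. at 1 % random-interaction density and 1 % background mutation rate the
two pathway-driven subtypes are recovered with adjusted Rand index ≈ 0.96
for this seed. Raising `random_edge_density` to 0.02 for the same seed
prints `0.338`: a twofold increase in irrelevant interactions collapses
pathway recovery, which is the motivation for filtering interactions by
mutual exclusivity before propagating.

The same pipeline runs from the shell:

```
espstrat simulate --scenario fmp_with_fmg -m 0.01 -l 0.01 --seed 7 --outdir sim/
espstrat stratify --cohort sim/cohort.tsv --network sim/network.tsv \
         --mode esp --outdir out/
espstrat sweep --scenario fmp_with_fmg --values 0,0.01,0.02 \
         --replicates 20 --out sweep.csv
```

`stratify --mode` selects the network baseline: `esp` (exclusivity-filtered
interactions), `empty` (no network), `full_network`, `me_only` (exclusive
pairs without interaction evidence) or `random_network` (degree-preserving
label shuffles, statistics averaged over replicates).

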