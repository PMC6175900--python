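# Methods

## Model and procedure

`espstrat` stratifies tumor cohorts by smoothing binary somatic mutation
profiles over a gene interaction network and clustering the smoothed
profiles. Its distinguishing step is *edge selection*: instead of
propagating over a full interactome, it keeps only the k interactions whose
gene pairs are most mutually exclusively mutated in the cohort — an
evolutionary signature of functional redundancy within a pathway. The
pipeline is: exact one-tailed Fisher scoring of every biophysical edge →
top-k selection (ESP map) → random walk with restart → row normalization →
log/truncated-SVD embedding → consensus k-means++ over a range of embedding
dimensions → per-subtype signature subnetworks by differential propagated
score.

### Mutual exclusivity

For genes i, j the 2×2 table (a = co-mutated, b, c = singly mutated,
d = neither) is scored with p = P(X ≤ a) under the hypergeometric law with
fixed margins, computed exactly via `scipy.stats.hypergeom.cdf` (vectorized
over all candidate pairs through the gene-by-gene Gram matrix of the call
matrix). Edges whose genes are unmutated score p = 1 and can still be
selected when the supply of informative edges is short; ties at the
k-boundary break lexicographically on the sorted gene pair so that
selection is deterministic. No multiple-testing correction is applied to
the ranking — selection is top-k by raw p-value. If no edge is scorable the
ESP map is flagged degenerate and clustering proceeds on unpropagated
profiles.

### Propagation

F_{t+1} = (1 − α) F_t B + α F_0 with B the row-normalized adjacency.
Defaults: α = 0.5 (restart probability; the result is insensitive over
roughly 0.5–0.8), convergence threshold 10⁻⁶ on the **Frobenius** norm of
successive iterates (the natural matrix reading of a summed elementwise
change), `max_iter` 1000 as a safety cap (the iteration contracts
geometrically at rate 1 − α, so ~40 iterations suffice at the default
tolerance). Degree-0 genes carry a zero transition row; mass parked on them
decays toward α·F₀. Mutations in genes absent from the network are dropped
when F₀ is built. Patients left with an all-zero row are kept, logged, and
excluded from row normalization. A closed-form fixed point
αF₀(I − (1−α)B)⁻¹ is provided as an independent oracle and is used by the
tests, never by the pipeline itself.

### Embedding and consensus clustering

The embedding is M_d = S_d^{1/2} U_dᵀ from log(F + c) = U S Vᵀ, with natural
log and c = 1/(number of genes) guarding zeros. For each d (default every
integer in 10–50; clipped to [2, min(patients, genes) − 1] for small
inputs) the patients' cosine-similarity matrix is clustered by k-means++
with the similarity rows as feature vectors — the literal reading of
"cluster patients using the cosine patient similarity matrix"; spherical
(cosine-distance) k-means was evaluated during development and rejected
because it recovers planted subtypes even in regimes where the benchmark
design expects failure, i.e. it does not reproduce the documented behavior
of the procedure. Binary co-clustering matrices are averaged into the
consensus matrix (entries are exact co-clustering fractions), and a final
k-means++ on the cosine similarity between consensus rows yields labels.
Defaults: 200 starts, 100 Lloyd iterations. One master seed drives
deterministic per-dimension child seeds, so runs are bit-reproducible and
parallelizable. Empty k-means clusters are handled by scikit-learn's
internal point relocation, which never returns an empty cluster.

### Signature subnetworks

Per subtype, propagated scores are compared against the remaining cohort
with a Welch (unequal-variance) t-test, one-sided for enrichment by default
(two-sided available); genes passing the resolution-dependent cutoff
(0.05 for k < 4, 0.1 for k ≥ 4, no multiple-testing correction) induce a
subnetwork of the ESP map. Genes passing the cutoff but isolated in the map
are retained as singletons unless `connected_only` is set. Constant score
vectors produce NaN test statistics, which are treated as p = 1.
Re-clustering by a single-gene signature uses the gene's binarized mutation
column directly. For small targeted panels the re-clustering supports
Euclidean distance and disabled load normalization, because with few genes
cosine similarity is unstable and total mutation count is informative.

## Synthetic cohorts

The generator emulates the structure that matters for pathway-vs-gene
stratification and nothing else: 1000 tumors × 1000 genes (defaults), two
exactly equal subtypes, per-subtype 25-gene pathways (disjoint, FMG
outside both), exactly `muts_per_pathway` = 2 mutated genes per tumor drawn
uniformly from the tumor's own subtype pathway, an FMG mutated in every
tumor of one subtype and no tumor of the other (marginal frequency 0.5),
and iid per-cell background mutations at rate l OR-combined on top
(designated cells are never unset). Networks: Erdős–Rényi within-pathway
edges at density 0.2 (default) plus Erdős–Rényi background edges at
per-pair probability m; or star pathways (hub = first gene of the pathway
under the seeded permutation) with preferential-attachment background edges
(endpoints ∝ degree + 1, duplicates rejected) whose count is drawn
Binomial(C(n,2), m) to match the Erdős–Rényi count distribution — the exact
attachment variant is not critical and any degree-biased sampler with the
matched expected count would do.

What the generator does **not** emulate: mutation-rate heterogeneity across
patients and genes, copy-number and expression effects, gene-length bias,
subclonal structure, and interactome degree distributions. Passing the
simulation benchmarks therefore demonstrates correctness of the machinery
and the documented sensitivity of propagation-based clustering to random
interactions — not performance on real cohorts.

## Study sizes and numerical choices

The benchmark experiments (tests and `scripts/acceptance.py`) run the
full-scale 1000 × 1000 conditions but reduce the clustering settings to
embedding dimensions {10, 20, 30, 40, 50} with 20 k-means++ starts and 20
replicates per condition; a replicate then takes a few seconds on one CPU.
Unit and property tests use small instances (tens of tumors/genes) because
they check exact invariants, not effect sizes. Per-replicate seeds derive
from `numpy.random.SeedSequence(master, index)` and stay below 2³¹.

Rank tests use midranks; exact null distributions are used when the sample
is tie-free and small (scipy's policy), otherwise the normal approximation
with tie correction. The expression-association PC1 sign is fixed so the
loading vector sums nonnegative; the test's tail direction is the caller's
declaration. The random-network survival baseline averages log-rank
chi-square statistics across replicates *before* converting to a p-value.

## Known limitations

* The mutual-exclusivity score treats all patients as exchangeable; it does
  not condition on per-patient mutation burden, so hypermutators inflate
  co-occurrence and deflate exclusivity.
* All-pairs exclusivity scoring (`me_only_pairs`) materializes the
  gene-by-gene Gram matrix — fine to ~20k genes, quadratic beyond.
* Gene identity is exact symbol match; no alias resolution.
* Consensus clustering reports no model-selection criterion for k; all
  resolutions in the requested range are returned.
* In the pathway+FMG benchmark scenario the FMG is, by construction,
  perfectly aligned with the true subtype split; recovery at high
  random-edge density is therefore dominated by the FMG's propagated
  signature, and the pathway contribution must be read from the FMP-only
  scenario.
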