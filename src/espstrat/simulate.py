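"""Synthetic somatic-mutation cohorts with pathway- or gene-driven subtypes.

The generator emulates a cohort of tumors split into two equal hidden
subtypes, each driven by one of two disjoint mutation structures:

* **FMP** (frequently mutated pathway): a 25-gene set per subtype; every
  tumor carries mutations in a small random subset (default 2) of its own
  subtype's pathway genes.
* **FMG** (frequently mutated gene): a single gene outside both pathways,
  mutated in every tumor of one subtype and in none of the other, so its
  marginal mutation frequency is 0.5 at equal subtype sizes.

Three scenarios combine these: ``fmp_with_fmg`` (both structures),
``fmg_only`` (pathway subnetworks exist in the network but carry no mutation
enrichment) and ``fmp_only`` (no FMG).  On top of the designated structure,
every cell of the matrix can independently receive a passenger ("background")
mutation at rate ``background_rate`` (symbol *l*); background draws never
unset designated cells (OR-combination).

Networks come in two flavours: ``er_dense_fmp`` makes each pathway an
Erdos-Renyi-dense subgraph (within-pathway pair probability
``within_density``) embedded in Erdos-Renyi background edges at per-pair
probability ``random_edge_density`` (symbol *m*); ``pa_star_fmp`` makes each
pathway a star and adds background edges by preferential attachment with the
same expected count m*C(n_genes, 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneNetwork, MutationCohort

logger = logging.getLogger("espstrat")

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_network",
    "run_recovery_sweep",
    "summarize_experiment",
]

SCENARIOS = ("fmp_with_fmg", "fmg_only", "fmp_only")
NETWORK_MODELS = ("er_dense_fmp", "pa_star_fmp")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the reference study conditions."""

    n_tumors: int = 1000
    n_genes: int = 1000
    n_subtypes: int = 2
    pathway_size: int = 25
    muts_per_pathway: int = 2
    within_density: float = 0.2
    random_edge_density: float = 0.0  # m: per-pair background edge probability
    background_rate: float = 0.0  # l: per-cell passenger mutation probability
    scenario: str = "fmp_with_fmg"
    network_model: str = "er_dense_fmp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.network_model not in NETWORK_MODELS:
            raise ValueError(f"unknown network model {self.network_model!r}")
        if self.n_subtypes != 2:
            raise ValueError("the simulation model defines exactly 2 subtypes")
        if self.pathway_size * self.n_subtypes + 1 > self.n_genes:
            raise ValueError(
                "n_genes must accommodate both pathways plus the FMG: "
                f"{self.pathway_size}*{self.n_subtypes}+1 > {self.n_genes}"
            )
        for name in ("within_density", "random_edge_density", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name, hi in (("random_edge_density", 0.025), ("background_rate", 0.025)):
            if getattr(self, name) > hi:
                logger.warning(
                    "%s=%g exceeds the conventional sweep range [0, %g]",
                    name, getattr(self, name), hi,
                )
        if self.muts_per_pathway > self.pathway_size:
            raise ValueError("muts_per_pathway cannot exceed pathway_size")


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus network and the ground truth that drove it."""

    cohort: MutationCohort
    network: GeneNetwork
    true_labels: np.ndarray  # subtype index per tumor, aligned to cohort.patients
    pathway_genes: tuple[tuple[str, ...], ...]  # per-subtype gene sets
    fmg: str | None
    config: SimulationConfig

    def __post_init__(self) -> None:
        counts = np.bincount(self.true_labels, minlength=self.config.n_subtypes)
        if len(set(counts)) != 1:
            raise ValueError("subtypes must be equal-sized")
        sets = [set(p) for p in self.pathway_genes]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("pathway gene sets must be disjoint")
            if self.fmg is not None and self.fmg in sets[i]:
                raise ValueError("FMG must lie outside every pathway")


def _designate(config: SimulationConfig, rng: np.random.Generator):
    """Seeded choice of pathway gene sets and the FMG.

    The first gene of each pathway under this permutation doubles as the
    star hub in the preferential-attachment network model.
    """
    genes = np.array([f"g{i:04d}" for i in range(config.n_genes)])
    perm = rng.permutation(config.n_genes)
    s = config.pathway_size
    pathways = tuple(
        tuple(genes[perm[k * s : (k + 1) * s]]) for k in range(config.n_subtypes)
    )
    fmg = None if config.scenario == "fmp_only" else str(genes[perm[config.n_subtypes * s]])
    return genes, pathways, fmg


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort, its network, and the ground-truth labels.

    Bit-reproducible for a fixed ``config.seed``: designation, mutation
    placement and network construction each consume an independent child
    stream of the seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_designate, rng_mut, rng_net = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    genes, pathways, fmg = _designate(config, rng_designate)
    gene_index = {g: j for j, g in enumerate(genes)}

    n = config.n_tumors
    labels = np.zeros(n, dtype=int)
    labels[rng_mut.permutation(n)[: n // 2]] = 1

    calls = np.zeros((n, config.n_genes), dtype=np.int8)

    if config.scenario in ("fmp_with_fmg", "fmp_only"):
        pw_cols = [
            np.array([gene_index[g] for g in pathways[k]])
            for k in range(config.n_subtypes)
        ]
        for t in range(n):
            hit = rng_mut.choice(
                config.pathway_size, size=config.muts_per_pathway, replace=False
            )
            calls[t, pw_cols[labels[t]][hit]] = 1
    if config.scenario in ("fmp_with_fmg", "fmg_only"):
        # FMG mutated with probability 1.0 in subtype 0, never in subtype 1
        calls[labels == 0, gene_index[fmg]] = 1

    if config.background_rate > 0:
        background = rng_mut.random(calls.shape) < config.background_rate
        calls |= background.astype(np.int8)

    cohort = MutationCohort(
        patients=tuple(f"t{i:04d}" for i in range(n)),
        genes=tuple(genes),
        calls=calls,
        cancer_type=f"simulated:{config.scenario}",
    )
    network = simulate_network(config, pathways, fmg, rng=rng_net)
    return SimulatedCohort(
        cohort=cohort,
        network=network,
        true_labels=labels,
        pathway_genes=pathways,
        fmg=fmg,
        config=config,
    )


def simulate_network(
    config: SimulationConfig,
    pathway_genes,
    fmg=None,
    rng: np.random.Generator | None = None,
) -> GeneNetwork:
    """Build the gene network around the designated pathway gene sets.

    All ``n_genes`` symbols become nodes (isolated genes are kept), so the
    cohort maps onto the network without dropping columns.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    genes = sorted({g for pw in pathway_genes for g in pw})
    all_genes = tuple(f"g{i:04d}" for i in range(config.n_genes))
    missing = set(genes) - set(all_genes)
    if missing:
        raise ValueError(f"pathway genes outside the gene universe: {missing}")

    if config.network_model == "er_dense_fmp":
        pairs = _er_dense_edges(config, pathway_genes, all_genes, rng)
    else:
        pairs = _pa_star_edges(config, pathway_genes, all_genes, rng)
    return GeneNetwork.from_edges(pairs, extra_nodes=all_genes)


def _er_dense_edges(config, pathway_genes, all_genes, rng):
    """Each unordered pair is an independent Bernoulli edge: probability
    ``within_density`` inside a pathway, ``random_edge_density`` elsewhere."""
    n = config.n_genes
    gene_index = {g: j for j, g in enumerate(all_genes)}
    pw_id = np.full(n, -1)
    for k, pw in enumerate(pathway_genes):
        for g in pw:
            pw_id[gene_index[g]] = k
    iu, ju = np.triu_indices(n, k=1)
    within = (pw_id[iu] >= 0) & (pw_id[iu] == pw_id[ju])
    prob = np.where(within, config.within_density, config.random_edge_density)
    hit = rng.random(iu.shape[0]) < prob
    arr = np.asarray(all_genes, dtype=object)
    return list(zip(arr[iu[hit]], arr[ju[hit]]))


def _pa_star_edges(config, pathway_genes, all_genes, rng):
    """Pathways as stars (first gene = hub) plus preferential-attachment
    background edges with expected count m * C(n_genes, 2).

    Endpoints of each background edge are drawn with probability proportional
    to (degree + 1); self-pairs and duplicates are rejected and redrawn.
    """
    n = config.n_genes
    gene_index = {g: j for j, g in enumerate(all_genes)}
    edges: set[tuple[int, int]] = set()
    for pw in pathway_genes:
        hub = gene_index[pw[0]]
        for leaf in pw[1:]:
            j = gene_index[leaf]
            edges.add((min(hub, j), max(hub, j)))
    n_pairs = n * (n - 1) // 2
    n_background = rng.binomial(n_pairs, config.random_edge_density)
    degree = np.zeros(n, dtype=float)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    added = 0
    while added < n_background:
        w = degree + 1.0
        w /= w.sum()
        u, v = rng.choice(n, size=2, p=w)
        if u == v:
            continue
        e = (min(u, v), max(u, v))
        if e in edges:
            continue
        edges.add(e)
        degree[u] += 1
        degree[v] += 1
        added += 1
    return [(all_genes[u], all_genes[v]) for u, v in sorted(edges)]


# ---------------------------------------------------------------------------
# sweep experiment driver
# ---------------------------------------------------------------------------

SWEEPABLE = ("background_rate", "random_edge_density", "within_density")


def _replicate_seed(base_seed: int, index: int) -> int:
    """Deterministic per-replicate seed derived from the master seed."""
    return int(
        np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def run_recovery_sweep(
    base: SimulationConfig,
    sweep_param: str,
    values,
    replicates: int = 20,
    scenarios=None,
    pipeline=None,
) -> pd.DataFrame:
    """Sweep one generator parameter and score subtype recovery.

    For each (scenario, sweep value, replicate) triple the driver simulates a
    cohort+network, propagates the mutation profiles over the simulated
    network, consensus-clusters the tumors into two groups, and scores the
    adjusted Rand index against the ground-truth subtypes.  A pipeline
    failure on a replicate is recorded as a missing ARI, never dropped.

    Returns a tidy table with columns
    ``sweep_param, value, scenario, replicate, seed, ari``.
    """
    from .pipeline import StratifyOptions, propagate_and_cluster
    from .evaluate import adjusted_rand_index

    if sweep_param not in SWEEPABLE:
        raise ValueError(f"sweep_param must be one of {SWEEPABLE}")
    values = list(values)
    if not values:
        raise ValueError("sweep grid must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if scenarios is None:
        scenarios = (base.scenario,)
    if pipeline is None:
        pipeline = StratifyOptions()

    rows = []
    idx = 0
    for scenario in scenarios:
        for value in values:
            for rep in range(replicates):
                seed = _replicate_seed(base.seed, idx)
                idx += 1
                cfg = replace(
                    base, scenario=scenario, seed=seed, **{sweep_param: value}
                )
                try:
                    sim = simulate_cohort(cfg)
                    assignment = propagate_and_cluster(
                        sim.cohort, sim.network, k=2, options=pipeline, seed=seed
                    )
                    ari = adjusted_rand_index(sim.true_labels, assignment.labels)
                except Exception:  # noqa: BLE001 — recorded, not silently dropped
                    logger.exception(
                        "replicate failed: scenario=%s %s=%g rep=%d",
                        scenario, sweep_param, value, rep,
                    )
                    ari = math.nan
                rows.append(
                    {
                        "sweep_param": sweep_param,
                        "value": value,
                        "scenario": scenario,
                        "replicate": rep,
                        "seed": seed,
                        "ari": ari,
                    }
                )
    return pd.DataFrame(rows)


def summarize_experiment(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sweep table to (value, scenario) means and SDs of ARI."""
    return (
        table.groupby(["sweep_param", "scenario", "value"], as_index=False)["ari"]
        .agg(mean_ari="mean", sd_ari="std", n="count")
    )
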