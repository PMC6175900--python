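"""Mutual-exclusivity scoring of gene pairs and ESP map construction.

An evolutionarily selected pathway (ESP) map is the subgraph of a biophysical
interaction network whose edges link gene pairs that are mutually exclusively
mutated in a tumor cohort.  Each candidate edge is scored with the one-tailed
Fisher exact test for *depletion* of co-mutation: with patient counts

    a = both genes mutated,   b = only the first,
    c = only the second,      d = neither,

the p-value is the probability, under the fixed-margin hypergeometric null,
of observing a co-mutation count <= a.  The top ``k`` (default 100) smallest
p-values among network edges form the ESP map.  When no biophysical edge can
be scored the map is degenerate and downstream propagation is skipped, so the
method reduces to clustering unpropagated mutation profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import GeneNetwork, MutationCohort

logger = logging.getLogger("espstrat")

__all__ = [
    "ScoredEdge",
    "ESPMap",
    "mutual_exclusivity_p",
    "exclusivity_p_from_counts",
    "build_esp_map",
    "me_only_pairs",
    "randomize_network",
    "write_esp_map",
]


@dataclass(frozen=True)
class ScoredEdge:
    gene_a: str
    gene_b: str
    p_value: float
    rank: int


@dataclass(frozen=True)
class ESPMap:
    """Mutual-exclusivity-selected edges, sorted by ascending p-value."""

    cancer_type: str
    scored_edges: tuple[ScoredEdge, ...]
    k: int
    source: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        ps = [e.p_value for e in self.scored_edges]
        if any(not 0.0 <= p <= 1.0 for p in ps):
            raise ValueError("p-values must lie in [0, 1]")
        if any(p1 > p2 for p1, p2 in zip(ps, ps[1:])):
            raise ValueError("scored edges must be sorted by ascending p-value")
        if len(self.scored_edges) > self.k:
            raise ValueError("more scored edges than the selection cutoff k")

    @property
    def n_edges(self) -> int:
        return len(self.scored_edges)

    def gene_set(self) -> frozenset:
        return frozenset(
            g for e in self.scored_edges for g in (e.gene_a, e.gene_b)
        )

    def edge_pairs(self) -> list[tuple[str, str]]:
        return [tuple(sorted((e.gene_a, e.gene_b))) for e in self.scored_edges]

    def to_network(self) -> GeneNetwork:
        return GeneNetwork.from_edges(self.edge_pairs())


def _pair_counts(calls: np.ndarray, i: np.ndarray, j: np.ndarray):
    """Vectorized 2x2 tables for column index pairs (i, j) of a 0/1 matrix.

    Co-mutation counts come from the gene-by-gene Gram matrix (exact in
    float64 for any realistic patient count)."""
    n = calls.shape[0]
    x = calls.astype(np.float64)
    co = x.T @ x
    totals = np.rint(np.diag(co)).astype(np.int64)
    a = np.rint(co[i, j]).astype(np.int64)
    return a, totals[i], totals[j], n


def exclusivity_p_from_counts(a, b, c, d) -> float:
    """One-tailed depletion p for a single 2x2 table given as four counts."""
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    n = a + b + c + d
    return float(hypergeom.cdf(a, n, a + b, a + c))


def mutual_exclusivity_p(cohort: MutationCohort, gene_i: str, gene_j: str) -> float:
    """Exact one-tailed Fisher p-value for mutual exclusivity of two genes.

    Symmetric in its gene arguments; equals 1 when either gene is unmutated
    (the single attainable table).
    """
    col = {g: j for j, g in enumerate(cohort.genes)}
    for g in (gene_i, gene_j):
        if g not in col:
            raise KeyError(f"gene {g!r} not present in cohort")
    x = cohort.calls[:, col[gene_i]].astype(bool)
    y = cohort.calls[:, col[gene_j]].astype(bool)
    a = int((x & y).sum())
    b = int((x & ~y).sum())
    c = int((~x & y).sum())
    d = int((~x & ~y).sum())
    return exclusivity_p_from_counts(a, b, c, d)


def _rank_and_cut(genes_a, genes_b, pvals, k: int) -> tuple[ScoredEdge, ...]:
    """Sort by (p, lexicographic sorted pair) and keep the k smallest."""
    items = []
    for ga, gb, p in zip(genes_a, genes_b, pvals):
        ga, gb = sorted((str(ga), str(gb)))
        items.append((float(p), ga, gb))
    items.sort()
    return tuple(
        ScoredEdge(gene_a=ga, gene_b=gb, p_value=p, rank=r + 1)
        for r, (p, ga, gb) in enumerate(items[:k])
    )


def build_esp_map(
    cohort: MutationCohort,
    network: GeneNetwork,
    k: int = 100,
    cancer_type: str | None = None,
) -> ESPMap:
    """Score every network edge with both endpoints in the cohort and keep
    the ``k`` most mutually exclusive.

    Edges whose genes are never mutated score p = 1 and rank last (ties at
    the k-boundary break lexicographically on the sorted gene pair).  When no
    edge can be scored — no shared genes, or no network gene is mutated — the
    map is empty and flagged degenerate.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    label = cohort.cancer_type if cancer_type is None else cancer_type
    col = {g: j for j, g in enumerate(cohort.genes)}
    eligible = [
        (u, v) for u, v in network.edge_pairs() if u in col and v in col
    ]
    shared = [g for g in network.nodes if g in col]
    any_mutated = bool(shared) and bool(
        cohort.calls[:, [col[g] for g in shared]].any()
    )
    if not eligible or not any_mutated:
        logger.warning(
            "degenerate ESP map for %r: no scorable mutually exclusive edge; "
            "stratification will proceed without network information", label,
        )
        return ESPMap(
            cancer_type=label, scored_edges=(), k=k,
            source=f"network[{network.n_edges} edges]", degenerate=True,
        )
    i = np.array([col[u] for u, _ in eligible])
    j = np.array([col[v] for _, v in eligible])
    a, m1, m2, n = _pair_counts(cohort.calls, i, j)
    pvals = hypergeom.cdf(a, n, m1, m2)
    edges = _rank_and_cut([u for u, _ in eligible], [v for _, v in eligible], pvals, k)
    return ESPMap(
        cancer_type=label, scored_edges=edges, k=k,
        source=f"network[{network.n_edges} edges]",
    )


def me_only_pairs(
    cohort: MutationCohort, k: int = 100, cancer_type: str | None = None
) -> ESPMap:
    """Top-k mutually exclusive gene pairs ignoring interaction evidence.

    This is the edge-selection rule of the interaction-free baseline: every
    unordered gene pair is a candidate.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    label = cohort.cancer_type if cancer_type is None else cancer_type
    mutated = cohort.calls.any(axis=0)
    if int(mutated.sum()) < 2:
        raise ValueError("need at least two genes with at least one mutation")
    n_g = cohort.n_genes
    i, j = np.triu_indices(n_g, k=1)
    a, m1, m2, n = _pair_counts(cohort.calls, i, j)
    pvals = hypergeom.cdf(a, n, m1, m2)
    genes = np.asarray(cohort.genes, dtype=object)
    edges = _rank_and_cut(genes[i], genes[j], pvals, k)
    return ESPMap(cancer_type=label, scored_edges=edges, k=k, source="all_pairs")


def randomize_network(network: GeneNetwork, seed: int) -> GeneNetwork:
    """Shuffle gene-name annotations, preserving the edge topology.

    The degree multiset is preserved exactly; only which gene carries which
    degree changes.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot randomize an empty network")
    rng = np.random.default_rng(seed)
    nodes = list(network.nodes)
    permuted = [nodes[t] for t in rng.permutation(len(nodes))]
    relabel = dict(zip(nodes, permuted))
    edges = frozenset(
        frozenset((relabel[u], relabel[v])) for u, v in network.edge_pairs()
    )
    return GeneNetwork(nodes=network.nodes, edges=edges)


def write_esp_map(espmap: ESPMap, tsv_path, summary_path=None) -> None:
    """Serialize as TSV (geneA, geneB, p_value, rank, cancer_type) plus an
    optional JSON sidecar carrying the degenerate flag."""
    with open(tsv_path, "w") as fh:
        fh.write("geneA\tgeneB\tp_value\trank\tcancer_type\n")
        for e in espmap.scored_edges:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.p_value:.6g}\t{e.rank}\t"
                f"{espmap.cancer_type}\n"
            )
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(
                {
                    "cancer_type": espmap.cancer_type,
                    "k": espmap.k,
                    "n_edges": espmap.n_edges,
                    "degenerate": espmap.degenerate,
                    "source": espmap.source,
                },
                fh,
                indent=2,
            )
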