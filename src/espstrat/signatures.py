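"""Characteristic subnetworks per subtype and ESP-only re-clustering.

After stratification, each subtype is contrasted against the remaining
cohort gene-by-gene with a Welch t-test on propagated mutation scores
(one-sided by default: characteristic genes are *enriched* in the subtype).
Genes passing the resolution-dependent cutoff — 0.05 below four subtypes,
0.1 at four or more — are mapped back onto the ESP map; the induced
subnetwork is the subtype's characteristic ESP.

A characteristic ESP can then be used on its own to re-cluster a cohort
(:func:`esp_validate_cluster`): restrict the cohort to the ESP genes,
propagate over the ESP-induced subnetwork and split into two groups.  A
single-gene ESP reduces to the binarized mutation status of that gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneNetwork, MutationCohort
from .propagate import (
    PropagationConfig,
    mutation_matrix_for,
    propagate,
    transition_matrix,
)
from .stratify import EmbeddingConfig, SubtypeAssignment, kmeans_consensus

logger = logging.getLogger("espstrat")

__all__ = ["CharacteristicESP", "detect_characteristic_esps", "esp_validate_cluster"]


@dataclass(frozen=True)
class CharacteristicESP:
    subtype: int
    gene_pvalues: dict  # gene -> t-test p-value (genes passing the cutoff)
    edges: tuple[tuple[str, str], ...]  # induced from the ESP map
    p_cutoff: float

    def __post_init__(self) -> None:
        genes = set(self.gene_pvalues)
        for u, v in self.edges:
            if u not in genes or v not in genes:
                raise ValueError("induced edge endpoint outside the gene list")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.gene_pvalues))

    def to_network(self) -> GeneNetwork:
        return GeneNetwork.from_edges(self.edges, extra_nodes=self.genes)


def default_p_cutoff(k: int) -> float:
    """Resolution-dependent significance cutoff: 0.05 for k<4, 0.1 for k>=4."""
    return 0.05 if k < 4 else 0.1


def detect_characteristic_esps(
    profile,
    assignment: SubtypeAssignment,
    espmap,
    p_cutoff: float | None = None,
    two_sided: bool = False,
    connected_only: bool = False,
) -> list[CharacteristicESP]:
    """Per-subtype differentially propagated genes mapped onto the ESP map.

    ``espmap`` may be an :class:`~espstrat.espmap.ESPMap` or any object with
    ``gene_set()``/``edge_pairs()`` (e.g. a :class:`GeneNetwork`), so the
    detector also runs directly against a simulated network.  Subtypes with
    fewer than two patients are skipped with a warning.  With
    ``connected_only`` genes left isolated in the induced subnetwork are
    dropped; by default they are kept as singleton nodes.
    """
    if assignment.k < 2:
        raise ValueError("signature detection needs at least 2 subtypes")
    F = profile.F if hasattr(profile, "F") else np.asarray(profile, dtype=float)
    prof_genes = tuple(profile.genes)
    if len(assignment.labels) != F.shape[0]:
        raise ValueError("assignment does not cover the profile's patients")
    if p_cutoff is None:
        p_cutoff = default_p_cutoff(assignment.k)

    map_genes = set(espmap.gene_set())
    cols = [j for j, g in enumerate(prof_genes) if g in map_genes]
    genes = [prof_genes[j] for j in cols]
    X = F[:, cols]
    map_edges = [tuple(sorted(e)) for e in espmap.edge_pairs()]

    alternative = "two-sided" if two_sided else "greater"
    out: list[CharacteristicESP] = []
    for s in range(assignment.k):
        mask = assignment.labels == s
        if mask.sum() < 2 or (~mask).sum() < 2:
            logger.warning("subtype %d too small for a t-test; skipped", s)
            continue
        res = stats.ttest_ind(
            X[mask], X[~mask], axis=0, equal_var=False, alternative=alternative
        )
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        selected = {g: float(p) for g, p in zip(genes, pvals) if p < p_cutoff}
        edges = tuple(
            e for e in map_edges if e[0] in selected and e[1] in selected
        )
        if connected_only:
            linked = {g for e in edges for g in e}
            selected = {g: p for g, p in selected.items() if g in linked}
        out.append(
            CharacteristicESP(
                subtype=s, gene_pvalues=selected, edges=edges, p_cutoff=p_cutoff
            )
        )
    return out


def esp_validate_cluster(
    cohort: MutationCohort,
    esp: CharacteristicESP,
    distance: str = "cosine",
    normalize_load: bool = True,
    prop_config: PropagationConfig | None = None,
    embed_config: EmbeddingConfig | None = None,
) -> SubtypeAssignment:
    """Two-group clustering of a cohort using only one characteristic ESP.

    With ``distance='euclidean'`` and ``normalize_load=False`` this is the
    configuration for small targeted sequencing panels, where few genes are
    observed and total mutation count carries signal.
    """
    if distance not in ("cosine", "euclidean"):
        raise ValueError(f"unknown distance {distance!r}")
    esp_genes = [g for g in esp.genes if g in set(cohort.genes)]
    if not esp_genes:
        raise ValueError("no characteristic-ESP gene present in the cohort")

    col = {g: j for j, g in enumerate(cohort.genes)}
    if len(esp_genes) == 1:
        labels = cohort.calls[:, col[esp_genes[0]]].astype(int)
        consensus = (labels[:, None] == labels[None, :]).astype(float)
        return SubtypeAssignment(
            labels=labels,
            k=2,
            consensus=consensus,
            patients=cohort.patients,
            provenance={"mode": "single_gene", "gene": esp_genes[0]},
        )

    subnet = esp.to_network().subgraph(esp_genes)
    tm = transition_matrix(subnet)
    F0 = mutation_matrix_for(cohort, tm.genes)
    if F0.sum() == 0:
        logger.warning(
            "no ESP gene is mutated in the cohort; single trivial cluster"
        )
        n = cohort.n_patients
        return SubtypeAssignment(
            labels=np.zeros(n, dtype=int),
            k=2,
            consensus=np.ones((n, n)),
            patients=cohort.patients,
            provenance={"mode": "unmutated_esp"},
        )
    prof = propagate(
        F0, tm, prop_config, patients=cohort.patients,
        row_normalize=normalize_load,
    )
    return kmeans_consensus(prof, k=2, config=embed_config, metric=distance)
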