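"""Low-dimensional embedding and consensus clustering of propagated profiles.

Each propagated profile matrix F is embedded by a truncated SVD of
``log(F + c)`` (c is a small pseudo-count, by default the reciprocal of the
gene count, guarding the log of exact zeros): with ``log(F + c) = U S V^T``
the d-dimensional patient embedding is ``M_d = S_d^{1/2} U_d^T``.

Clustering is consensus k-means++: for each embedding dimension d in
``d_range`` the patients' cosine-similarity matrix is clustered by k-means++
(rows of the similarity matrix as feature vectors), each result contributes a
binary co-clustering matrix, their average is the consensus matrix, and a
final k-means++ on the cosine similarity between consensus rows yields the
subtype labels.  The whole procedure is a pure function of (profile, k,
config.seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics.pairwise import cosine_similarity

from .propagate import PropagatedProfile

logger = logging.getLogger("espstrat")

__all__ = [
    "EmbeddingConfig",
    "SubtypeAssignment",
    "SubtypeHierarchy",
    "embed",
    "kmeans_consensus",
    "build_hierarchy",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """SVD embedding and k-means++ settings.

    ``c=None`` means the reciprocal of the number of genes in the profile.
    ``d_range`` is clipped to [2, min(n_patients, n_genes) - 1] for small
    inputs.
    """

    c: float | None = None
    d_range: tuple[int, ...] = tuple(range(10, 51))
    kmeans_starts: int = 200
    kmeans_max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c is not None and self.c <= 0:
            raise ValueError("pseudo-count c must be positive")
        if not self.d_range:
            raise ValueError("d_range must be nonempty")
        if min(self.d_range) < 1:
            raise ValueError("embedding dimensions must be >= 1")

    def clipped_d_range(self, n_patients: int, n_genes: int) -> tuple[int, ...]:
        hi = min(n_patients, n_genes) - 1
        ds = sorted({min(max(d, 2), hi) for d in self.d_range if hi >= 2})
        if not ds:
            ds = [1]
        return tuple(ds)


@dataclass(frozen=True)
class SubtypeAssignment:
    labels: np.ndarray
    k: int
    consensus: np.ndarray  # patients x patients co-clustering frequencies
    patients: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min(initial=0) < 0 or lab.max(initial=0) >= self.k:
            raise ValueError("labels must lie in {0..k-1}")
        c = self.consensus
        if c.shape != (len(lab), len(lab)):
            raise ValueError("consensus shape must match patient count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient": list(self.patients), "k": self.k, "label": self.labels}
        )


def _as_matrix(profile) -> tuple[np.ndarray, tuple[str, ...], int]:
    if isinstance(profile, PropagatedProfile):
        return profile.F, profile.patients, len(profile.genes)
    mat = np.asarray(profile, dtype=float)
    return mat, tuple(f"p{i}" for i in range(mat.shape[0])), mat.shape[1]


def embed(profile, d: int, c: float | None = None) -> np.ndarray:
    """Truncated-SVD patient embedding ``M_d = S_d^{1/2} U_d^T`` (d x patients)."""
    mat, _, n_genes = _as_matrix(profile)
    if d < 1 or d > min(mat.shape):
        raise ValueError(f"d={d} outside [1, {min(mat.shape)}]")
    if c is None:
        c = 1.0 / n_genes
    u, s, _ = np.linalg.svd(np.log(mat + c), full_matrices=False)
    return np.sqrt(s[:d])[:, None] * u[:, :d].T


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n)]


def _kmeans_labels(features, k, starts, max_iter, seed) -> np.ndarray:
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=starts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    )
    return km.fit_predict(features)


def kmeans_consensus(
    profile, k: int, config: EmbeddingConfig | None = None, metric: str = "cosine"
) -> SubtypeAssignment:
    """Consensus k-means++ over the embedding-dimension range.

    ``metric='cosine'`` (default) clusters the rows of the patients'
    cosine-similarity matrix at each d; ``metric='euclidean'`` clusters the
    embedding vectors directly — used for small targeted gene panels where
    cosine similarity is unstable.
    """
    if config is None:
        config = EmbeddingConfig()
    if metric not in ("cosine", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    mat, patients, n_genes = _as_matrix(profile)
    n = mat.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} patients")
    if k == 1:
        return SubtypeAssignment(
            labels=np.zeros(n, dtype=int),
            k=1,
            consensus=np.ones((n, n)),
            patients=patients,
            provenance={"d_values": [], "seeds": []},
        )
    c = config.c if config.c is not None else 1.0 / n_genes
    ds = config.clipped_d_range(n, mat.shape[1])
    seeds = _child_seeds(config.seed, len(ds) + 1)

    log_mat = np.log(mat + c)
    u, s, _ = np.linalg.svd(log_mat, full_matrices=False)

    consensus = np.zeros((n, n))
    for d, seed in zip(ds, seeds[:-1]):
        m_d = np.sqrt(s[:d])[:, None] * u[:, :d].T
        if metric == "cosine":
            features = cosine_similarity(m_d.T)
        else:
            features = m_d.T
        labels = _kmeans_labels(
            features, k, config.kmeans_starts, config.kmeans_max_iter, seed
        )
        consensus += (labels[:, None] == labels[None, :]).astype(float)
    consensus /= len(ds)

    if metric == "cosine":
        final_features = cosine_similarity(consensus)
    else:
        final_features = consensus
    labels = _kmeans_labels(
        final_features, k, config.kmeans_starts, config.kmeans_max_iter, seeds[-1]
    )
    return SubtypeAssignment(
        labels=labels,
        k=k,
        consensus=consensus,
        patients=patients,
        provenance={"d_values": list(ds), "seeds": seeds, "metric": metric},
    )


@dataclass(frozen=True)
class SubtypeHierarchy:
    """Assignments at each resolution k plus layer-to-layer overlap counts."""

    assignments: dict  # k -> SubtypeAssignment
    overlaps: dict  # (k, k+1) -> DataFrame of patient counts

    def patients(self) -> tuple[str, ...]:
        return next(iter(self.assignments.values())).patients


def build_hierarchy(
    profile, k_range=range(2, 7), config: EmbeddingConfig | None = None,
    metric: str = "cosine",
) -> SubtypeHierarchy:
    """Cluster at every resolution in ``k_range`` and cross-tabulate layers."""
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range must be nonempty")
    assignments = {
        k: kmeans_consensus(profile, k, config, metric=metric) for k in ks
    }
    overlaps = {}
    for k1, k2 in zip(ks, ks[1:]):
        a, b = assignments[k1].labels, assignments[k2].labels
        table = pd.crosstab(
            pd.Series(a, name=f"k{k1}"), pd.Series(b, name=f"k{k2}")
        )
        overlaps[(k1, k2)] = table
    return SubtypeHierarchy(assignments=assignments, overlaps=overlaps)
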