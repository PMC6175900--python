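"""Random walk with restart of patient mutation profiles over a gene network.

The walk iterates

    F_{t+1} = (1 - alpha) F_t B + alpha F_0

from the binary profile F_0, where B is the row-normalized adjacency matrix
(B[i, j] = A[i, j] / deg(i)) and ``alpha`` is the restart probability; larger
alpha keeps more mass on the originally mutated genes.  Iteration stops when
the Frobenius norm of successive iterates drops below ``tol``.  After
convergence each row is rescaled to sum to one so that stratification is
independent of mutational load; all-zero rows (patients with no mutation on
the network) pass through unchanged.

Degree-0 genes carry an all-zero transition row: mass parked there decays
toward the restart term.  Mutations in genes absent from the network are
dropped before propagation by construction of F_0
(:func:`mutation_matrix_for`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import GeneNetwork, MutationCohort

logger = logging.getLogger("espstrat")

__all__ = [
    "PropagationConfig",
    "TransitionMatrix",
    "PropagatedProfile",
    "transition_matrix",
    "mutation_matrix_for",
    "propagate",
    "propagate_closed_form",
    "propagate_cohort",
]


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.5  # restart probability
    tol: float = 1e-6  # Frobenius norm threshold on successive iterates
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-normalized transition matrix over an ordered gene list."""

    genes: tuple[str, ...]
    matrix: sp.csr_array  # row-stochastic except all-zero degree-0 rows
    zero_rows: np.ndarray  # boolean mask of degree-0 genes

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def transition_matrix(network: GeneNetwork, gene_order=None) -> TransitionMatrix:
    """B[i, j] = A[i, j] / deg(i); degree-0 genes get an all-zero row."""
    genes = tuple(gene_order) if gene_order is not None else network.nodes
    if set(genes) < network.gene_set():
        raise ValueError("gene_order must cover every network node")
    index = {g: i for i, g in enumerate(genes)}
    rows, cols = [], []
    for u, v in network.edge_pairs():
        iu, iv = index[u], index[v]
        rows += [iu, iv]
        cols += [iv, iu]
    n = len(genes)
    adj = sp.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    degree = np.asarray(adj.sum(axis=1)).ravel()
    zero = degree == 0
    if zero.any():
        logger.info("transition matrix: %d isolated gene(s)", int(zero.sum()))
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, degree))
    b = sp.csr_array(sp.diags_array(inv) @ adj)
    return TransitionMatrix(genes=genes, matrix=b, zero_rows=zero)


def mutation_matrix_for(cohort: MutationCohort, genes) -> np.ndarray:
    """Binary patient-by-gene matrix in network gene order.

    Genes absent from the cohort yield zero columns; cohort mutations in
    genes outside ``genes`` are dropped (they do not map to the network).
    """
    col = {g: j for j, g in enumerate(cohort.genes)}
    out = np.zeros((cohort.n_patients, len(genes)), dtype=float)
    for j, g in enumerate(genes):
        if g in col:
            out[:, j] = cohort.calls[:, col[g]]
    return out


@dataclass(frozen=True)
class PropagatedProfile:
    F: np.ndarray  # patients x genes, nonnegative
    patients: tuple[str, ...]
    genes: tuple[str, ...]
    iterations_used: int
    converged: bool
    row_normalized: bool


def propagate(
    F0: np.ndarray,
    B: TransitionMatrix,
    config: PropagationConfig | None = None,
    patients=None,
    row_normalize: bool = True,
) -> PropagatedProfile:
    """Iterate the restart walk to its fixed point and row-normalize.

    ``row_normalize=False`` skips the final mutational-load normalization
    (used when clustering cohorts from small targeted gene panels, where the
    total mutation count itself is informative).
    """
    if config is None:
        config = PropagationConfig()
    F0 = np.asarray(F0, dtype=float)
    if F0.ndim != 2 or F0.shape[1] != B.n_genes:
        raise ValueError(
            f"F0 must be patients x {B.n_genes} genes, got {F0.shape}"
        )
    if patients is None:
        patients = tuple(f"p{i}" for i in range(F0.shape[0]))
    n_silent = int((F0.sum(axis=1) == 0).sum())
    if n_silent:
        logger.warning(
            "%d patient(s) have no mutation on the network; their propagated "
            "profile is all-zero and is clustered as such", n_silent,
        )
    mat = B.matrix
    F = F0.copy()
    alpha = config.alpha
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        F_next = (1.0 - alpha) * (F @ mat) + alpha * F0
        delta = float(np.linalg.norm(F_next - F))
        F = F_next
        if delta < config.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "propagation did not converge in %d iterations", config.max_iter
        )
    if row_normalize:
        sums = F.sum(axis=1, keepdims=True)
        np.divide(F, sums, out=F, where=sums > 0)
    return PropagatedProfile(
        F=F,
        patients=tuple(patients),
        genes=B.genes,
        iterations_used=it,
        converged=converged,
        row_normalized=row_normalize,
    )


def propagate_closed_form(F0: np.ndarray, B, alpha: float) -> np.ndarray:
    """Fixed point of the restart walk by direct linear solve:
    ``alpha * F0 @ inv(I - (1 - alpha) B)``.  No row normalization."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    b = B.dense() if isinstance(B, TransitionMatrix) else np.asarray(B, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    n = b.shape[0]
    system = np.eye(n) - (1.0 - alpha) * b
    # F (I - (1-a)B) = a F0  =>  solve the transposed system for F^T
    return np.linalg.solve(system.T, alpha * F0.T).T


def propagate_cohort(
    cohort: MutationCohort,
    network: GeneNetwork,
    config: PropagationConfig | None = None,
    row_normalize: bool = True,
) -> PropagatedProfile:
    """Map a cohort onto a network and propagate (convenience wrapper)."""
    tm = transition_matrix(network)
    F0 = mutation_matrix_for(cohort, tm.genes)
    return propagate(
        F0, tm, config, patients=cohort.patients, row_normalize=row_normalize
    )
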