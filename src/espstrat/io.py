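"""Reading, validating, filtering and writing cohort-level inputs.

Somatic mutation cohorts are binary patient-by-gene call matrices; networks
are undirected, unweighted gene graphs. All on-disk formats are plain
tab-delimited text:

* ``binary_tsv`` — first row gene symbols, first column patient ids, 0/1 cells.
* ``maf_lite``  — header ``patient<TAB>gene<TAB>variant_class``, one somatic
  mutation per row (``variant_class`` may be absent, in which case every row
  qualifies).
* ``edge_list`` — ``geneA<TAB>geneB``; ``sif`` — ``geneA<TAB>relation<TAB>geneB``.
* clinical TSV — ``patient<TAB>time<TAB>event[<TAB>covariate...]``.

Gene identity is exact string match on symbols; no alias resolution is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("espstrat")

__all__ = [
    "MutationCohort",
    "ClinicalTable",
    "GeneNetwork",
    "ExpressionMatrix",
    "CohortIOError",
    "EmptyCohortError",
    "ICGC_VARIANT_CLASSES",
    "read_mutation_calls",
    "write_mutation_calls",
    "filter_cohort",
    "read_network",
    "write_network",
    "read_clinical",
    "write_clinical",
    "read_expression",
    "write_expression",
]

#: Qualifying consequence classes used for ICGC-style variant calls: any of
#: these marks the gene as altered in the patient; all other classes
#: (e.g. silent/synonymous) are ignored.
ICGC_VARIANT_CLASSES = frozenset(
    {
        "missense variant",
        "frameshift variant",
        "non-conservative missense variant",
        "initiator codon variant",
        "stop-gain",
    }
)


class CohortIOError(ValueError):
    """Malformed input file or unusable parser options."""


class EmptyCohortError(CohortIOError):
    """Filtering removed every patient from a cohort."""


@dataclass(frozen=True)
class MutationCohort:
    """Binary patient-by-gene somatic mutation calls.

    ``calls[i, j] == 1`` iff patient ``patients[i]`` carries at least one
    qualifying non-silent mutation in gene ``genes[j]``.
    """

    patients: tuple[str, ...]
    genes: tuple[str, ...]
    calls: np.ndarray
    cancer_type: str = ""
    #: set False by :func:`filter_cohort` when the cohort is too small to use
    eligible: bool = True

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        object.__setattr__(self, "calls", calls)
        if calls.shape != (len(self.patients), len(self.genes)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.patients)} patients x {len(self.genes)} genes"
            )
        if calls.size and not np.isin(calls, (0, 1)).all():
            raise ValueError("mutation calls must be binary (0/1)")
        for name, ids in (("patient", self.patients), ("gene", self.genes)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calls, index=list(self.patients), columns=list(self.genes)
        )

    def restrict_genes(self, genes) -> "MutationCohort":
        """Subset to ``genes`` (in the given order), dropping absent symbols."""
        keep = [g for g in genes if g in set(self.genes)]
        col = {g: j for j, g in enumerate(self.genes)}
        idx = [col[g] for g in keep]
        return replace(self, genes=tuple(keep), calls=self.calls[:, idx])


@dataclass(frozen=True)
class ClinicalTable:
    """Right-censored survival outcomes, optionally with covariates."""

    data: pd.DataFrame  # index: patient id; columns: time, event[, covariates]

    def __post_init__(self) -> None:
        df = self.data
        if not {"time", "event"} <= set(df.columns):
            raise ValueError("clinical table needs 'time' and 'event' columns")
        if df.index.has_duplicates:
            raise ValueError("duplicate patient identifiers")
        if (df["time"] < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def patients(self) -> tuple[str, ...]:
        return tuple(self.data.index)


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, unweighted gene interaction graph.

    Node list may exceed the union of edge endpoints so that isolated genes
    (e.g. cohort genes with no surviving interaction) remain representable.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset]  # frozenset of 2-element frozensets

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-loop or malformed edge: {set(e)}")
            if not e <= node_set:
                raise ValueError(f"edge endpoint outside node list: {set(e)}")

    @classmethod
    def from_edges(cls, pairs, extra_nodes=()) -> "GeneNetwork":
        """Build from (u, v) pairs; duplicates/reversals collapse, loops drop."""
        edges = set()
        nodes: dict[str, None] = {}  # insertion-ordered
        n_loops = 0
        for u, v in pairs:
            u, v = str(u), str(v)
            if u == v:
                n_loops += 1
                nodes.setdefault(u)
                continue
            nodes.setdefault(u)
            nodes.setdefault(v)
            edges.add(frozenset((u, v)))
        for n in extra_nodes:
            nodes.setdefault(str(n))
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        return cls(nodes=tuple(nodes), edges=frozenset(edges))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def gene_set(self) -> frozenset:
        return frozenset(self.nodes)

    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for u, v in self.edge_pairs():
            d[u] += 1
            d[v] += 1
        return d

    def subgraph(self, genes) -> "GeneNetwork":
        """Induced subgraph on ``genes`` (absent symbols ignored)."""
        keep = [g for g in self.nodes if g in set(genes)]
        keep_set = set(keep)
        edges = frozenset(e for e in self.edges if e <= keep_set)
        return GeneNetwork(nodes=tuple(keep), edges=edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edge_pairs())
        return g


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued patient-by-gene expression."""

    data: pd.DataFrame  # index: patient id; columns: gene symbols

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate patient or gene identifiers")


# ---------------------------------------------------------------------------
# mutation calls
# ---------------------------------------------------------------------------

def read_mutation_calls(
    path,
    format: str = "binary_tsv",
    allowed_variant_classes=None,
    cancer_type: str = "",
) -> MutationCohort:
    """Read mutation calls from ``maf_lite`` or ``binary_tsv`` text.

    With ``maf_lite`` input, a (patient, gene) cell is set to 1 when at least
    one row for that pair has a qualifying ``variant_class``; multiple
    qualifying rows collapse to a single 1.  When the file carries no
    ``variant_class`` column every row qualifies (upstream non-silent
    filtering is assumed).
    """
    if format == "binary_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise CohortIOError(f"{path}: non-binary cell in binary_tsv matrix")
        return MutationCohort(
            patients=tuple(map(str, df.index)),
            genes=tuple(map(str, df.columns)),
            calls=values.astype(np.int8),
            cancer_type=cancer_type,
        )
    if format == "maf_lite":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, on_bad_lines="error")
        except pd.errors.ParserError as exc:
            raise CohortIOError(f"{path}: {exc}") from exc
        missing = {"patient", "gene"} - set(df.columns)
        if missing:
            raise CohortIOError(f"{path}: maf_lite missing columns {sorted(missing)}")
        bad = df[["patient", "gene"]].isna().any(axis=1)
        if bad.any():
            # +2: header line plus 1-based numbering
            raise CohortIOError(
                f"{path}: malformed row at line {int(bad.idxmax()) + 2}"
            )
        if allowed_variant_classes is not None and "variant_class" in df.columns:
            df = df[df["variant_class"].isin(set(allowed_variant_classes))]
        patients = tuple(pd.unique(df["patient"])) if len(df) else ()
        genes = tuple(sorted(pd.unique(df["gene"]))) if len(df) else ()
        calls = np.zeros((len(patients), len(genes)), dtype=np.int8)
        if len(df):
            pi = {p: i for i, p in enumerate(patients)}
            gi = {g: j for j, g in enumerate(genes)}
            calls[
                df["patient"].map(pi).to_numpy(),
                df["gene"].map(gi).to_numpy(),
            ] = 1
        return MutationCohort(
            patients=patients, genes=genes, calls=calls, cancer_type=cancer_type
        )
    raise CohortIOError(f"unknown mutation-call format {format!r}")


def write_mutation_calls(cohort: MutationCohort, path) -> None:
    """Write a cohort as a binary_tsv matrix."""
    cohort.to_frame().to_csv(path, sep="\t")


def filter_cohort(
    cohort: MutationCohort,
    min_patients_per_type: int = 100,
    min_mutations_per_patient: int = 10,
) -> MutationCohort:
    """Apply the cohort eligibility filters.

    Patients with fewer than ``min_mutations_per_patient`` total mutations are
    removed first; if fewer than ``min_patients_per_type`` patients survive,
    the whole cohort is flagged ineligible (``eligible=False``).  The gene
    list is never altered.
    """
    if min_patients_per_type < 0 or min_mutations_per_patient < 0:
        raise ValueError("filter thresholds must be nonnegative")
    load = cohort.calls.sum(axis=1)
    keep = load >= min_mutations_per_patient
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_cohort: dropped %d patient(s) with < %d mutations",
            n_dropped,
            min_mutations_per_patient,
        )
    if not keep.any():
        raise EmptyCohortError(
            f"all {cohort.n_patients} patients fall below the "
            f"{min_mutations_per_patient}-mutation threshold"
        )
    patients = tuple(p for p, k in zip(cohort.patients, keep) if k)
    eligible = len(patients) >= min_patients_per_type
    if not eligible:
        logger.warning(
            "cohort %r ineligible: %d surviving patients < %d",
            cohort.cancer_type,
            len(patients),
            min_patients_per_type,
        )
    return replace(
        cohort, patients=patients, calls=cohort.calls[keep], eligible=eligible
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(path, format: str = "edge_list") -> GeneNetwork:
    """Read an ``edge_list`` (2-column) or ``sif`` (3-column) text network."""
    if format not in ("edge_list", "sif"):
        raise CohortIOError(f"unknown network format {format!r}")
    need = 2 if format == "edge_list" else 3
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < need:
                raise CohortIOError(
                    f"{path}:{lineno}: expected {need} columns, got {len(tokens)}"
                )
            if format == "edge_list":
                pairs.append((tokens[0], tokens[1]))
            else:  # sif: middle token is the (ignored) relation type
                pairs.append((tokens[0], tokens[2]))
    return GeneNetwork.from_edges(pairs)


def write_network(network: GeneNetwork, path, format: str = "edge_list") -> None:
    if format not in ("edge_list", "sif"):
        raise CohortIOError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        for u, v in network.edge_pairs():
            if format == "edge_list":
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\tpp\t{v}\n")


# ---------------------------------------------------------------------------
# clinical & expression tables
# ---------------------------------------------------------------------------

def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={df.columns[0]: "time", df.columns[1]: "event"})
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.index.name = "patient"
    df.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    return ExpressionMatrix(data=pd.read_csv(path, sep="\t", index_col=0))


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.data.copy()
    df.index.name = "patient"
    df.to_csv(path, sep="\t")
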