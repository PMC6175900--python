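"""End-to-end stratification pipelines and network baselines.

The main driver wires the stages together: load and filter the cohort,
select the propagation network according to ``network_mode``, propagate,
consensus-cluster at each resolution, detect characteristic subnetworks and
optionally report survival associations.  The five network modes are

* ``esp`` — mutual-exclusivity-filtered biophysical edges (the method),
* ``empty`` — no network: consensus clustering of raw mutation profiles,
* ``full_network`` — the whole input network, no exclusivity filter,
* ``me_only`` — top-k exclusive pairs with no biophysical constraint,
* ``random_network`` — degree-preserving label shuffles of the input
  network, re-filtered and re-run per replicate, with test statistics
  averaged across replicates before a p-value is derived.

A pipeline run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io as cio
from .espmap import ESPMap, build_esp_map, me_only_pairs, randomize_network, write_esp_map
from .evaluate import survival_association
from .io import GeneNetwork, MutationCohort
from .propagate import (
    PropagationConfig,
    mutation_matrix_for,
    propagate,
    transition_matrix,
)
from .signatures import detect_characteristic_esps
from .stratify import EmbeddingConfig, SubtypeAssignment, build_hierarchy, kmeans_consensus

logger = logging.getLogger("espstrat")

__all__ = [
    "StratifyOptions",
    "PipelineConfig",
    "propagate_and_cluster",
    "run_stratification",
    "run_random_network_baseline",
]

NETWORK_MODES = ("esp", "empty", "full_network", "me_only", "random_network")


@dataclass(frozen=True)
class StratifyOptions:
    """Propagation plus clustering settings used by the in-memory driver."""

    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    metric: str = "cosine"
    normalize_load: bool = True


def propagate_and_cluster(
    cohort: MutationCohort,
    network: GeneNetwork | None,
    k: int,
    options: StratifyOptions | None = None,
    seed: int | None = None,
) -> SubtypeAssignment:
    """Propagate a cohort over a network (or not) and consensus-cluster.

    ``network=None`` (or a network without edges) is the degenerate path:
    the binary profiles are clustered unpropagated.
    """
    if options is None:
        options = StratifyOptions()
    embed_cfg = options.embedding
    if seed is not None:
        embed_cfg = dataclasses.replace(embed_cfg, seed=int(seed))
    if network is None or network.n_edges == 0:
        profile = cohort.calls.astype(float)
        return kmeans_consensus(profile, k, embed_cfg, metric=options.metric)
    tm = transition_matrix(network)
    F0 = mutation_matrix_for(cohort, tm.genes)
    prof = propagate(
        F0,
        tm,
        options.propagation,
        patients=cohort.patients,
        row_normalize=options.normalize_load,
    )
    return kmeans_consensus(prof, k, embed_cfg, metric=options.metric)


@dataclass(frozen=True)
class PipelineConfig:
    """File-level pipeline configuration (mirrors the YAML config keys)."""

    cohort_path: str
    network_path: str | None = None
    cohort_format: str = "binary_tsv"
    network_format: str = "edge_list"
    variant_classes: tuple[str, ...] | None = None
    clinical_path: str | None = None
    network_mode: str = "esp"
    k_top_me: int = 100
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    min_patients_per_type: int = 100
    min_mutations_per_patient: int = 10
    apply_cohort_filter: bool = True
    metric: str = "cosine"
    normalize_load: bool = True
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    d_range: tuple[int, ...] = tuple(range(10, 51))
    kmeans_starts: int = 200
    kmeans_max_iter: int = 100
    seed: int = 0
    outdir: str = "espstrat_out"

    def __post_init__(self) -> None:
        if self.network_mode not in NETWORK_MODES:
            raise ValueError(f"network_mode must be one of {NETWORK_MODES}")
        if self.network_mode != "empty" and self.network_path is None:
            raise ValueError(f"network_mode={self.network_mode!r} needs a network_path")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("k_range", "d_range", "variant_classes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def options(self) -> StratifyOptions:
        return StratifyOptions(
            propagation=PropagationConfig(
                alpha=self.alpha, tol=self.tol, max_iter=self.max_iter
            ),
            embedding=EmbeddingConfig(
                d_range=self.d_range,
                kmeans_starts=self.kmeans_starts,
                kmeans_max_iter=self.kmeans_max_iter,
                seed=self.seed,
            ),
            metric=self.metric,
            normalize_load=self.normalize_load,
        )


def _select_network(config, cohort, network, seed=None):
    """Resolve network_mode into the graph propagation runs over (or None)."""
    mode = config.network_mode
    if mode == "empty":
        return None, None
    if mode == "full_network":
        return network, None
    if mode == "esp" or mode == "random_network":
        net = network if seed is None else randomize_network(network, seed)
        esp = build_esp_map(cohort, net, k=config.k_top_me)
        return (None if esp.degenerate else esp.to_network()), esp
    if mode == "me_only":
        esp = me_only_pairs(cohort, k=config.k_top_me)
        return esp.to_network(), esp
    raise AssertionError(mode)


def _load_inputs(config: PipelineConfig):
    cohort = cio.read_mutation_calls(
        config.cohort_path,
        format=config.cohort_format,
        allowed_variant_classes=config.variant_classes,
    )
    if config.apply_cohort_filter:
        cohort = cio.filter_cohort(
            cohort, config.min_patients_per_type, config.min_mutations_per_patient
        )
    network = None
    if config.network_path is not None:
        network = cio.read_network(config.network_path, format=config.network_format)
    clinical = None
    if config.clinical_path is not None:
        clinical = cio.read_clinical(config.clinical_path)
    return cohort, network, clinical


def run_stratification(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write every artifact under ``outdir``.

    Returns the artifact bundle in memory: the (possibly None) ESP map, the
    subtype hierarchy, characteristic ESPs per resolution, and optional
    survival reports.  Any stage failure aborts with the stage name; artifacts
    written before the failure are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        t0 = time.perf_counter()
        cohort, network, clinical = _load_inputs(config)
        logger.info(
            "load: %d patients x %d genes (eligible=%s) in %.1fs",
            cohort.n_patients, cohort.n_genes, cohort.eligible,
            time.perf_counter() - t0,
        )

        stage = "network_selection"
        prop_network, esp = _select_network(config, cohort, network)
        if esp is not None:
            write_esp_map(esp, outdir / "espmap.tsv", outdir / "espmap_summary.json")

        stage = "propagate+cluster"
        options = config.options()
        if prop_network is None or prop_network.n_edges == 0:
            profile = cohort.calls.astype(float)
        else:
            tm = transition_matrix(prop_network)
            F0 = mutation_matrix_for(cohort, tm.genes)
            profile = propagate(
                F0, tm, options.propagation, patients=cohort.patients,
                row_normalize=options.normalize_load,
            )
        hierarchy = build_hierarchy(
            profile, k_range=config.k_range, config=options.embedding,
            metric=options.metric,
        )
        frames = [a.to_frame() for a in hierarchy.assignments.values()]
        assignments_df = pd.concat(frames, ignore_index=True)
        assignments_df.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
        for k, a in hierarchy.assignments.items():
            pd.DataFrame(
                a.consensus, index=list(a.patients), columns=list(a.patients)
            ).to_csv(outdir / f"consensus_k{k}.tsv", sep="\t")
        with open(outdir / "hierarchy_overlaps.json", "w") as fh:
            json.dump(
                {
                    f"{k1}->{k2}": tab.to_dict()
                    for (k1, k2), tab in hierarchy.overlaps.items()
                },
                fh, indent=2, default=int,
            )

        stage = "signatures"
        characteristic = {}
        sig_source = esp if esp is not None and not esp.degenerate else prop_network
        if sig_source is not None and hasattr(profile, "F"):
            rows = []
            for k, a in hierarchy.assignments.items():
                esps = detect_characteristic_esps(profile, a, sig_source)
                characteristic[k] = esps
                for ce in esps:
                    for g in ce.genes:
                        rows.append(
                            {"k": k, "subtype": ce.subtype, "gene": g,
                             "p_value": ce.gene_pvalues[g]}
                        )
            pd.DataFrame(
                rows, columns=["k", "subtype", "gene", "p_value"]
            ).to_csv(outdir / "characteristic_esps.tsv", sep="\t", index=False)

        stage = "reports"
        survival = {}
        if clinical is not None:
            for k, a in hierarchy.assignments.items():
                try:
                    survival[k] = survival_association(a, clinical)
                except ValueError as exc:
                    survival[k] = {"error": str(exc)}
            with open(outdir / "survival.json", "w") as fh:
                json.dump(survival, fh, indent=2, default=float)

        with open(outdir / "run_config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, default=list)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return {
        "cohort": cohort,
        "espmap": esp,
        "hierarchy": hierarchy,
        "characteristic_esps": characteristic,
        "survival": survival,
    }


def run_random_network_baseline(
    config: PipelineConfig,
    replicates: int = 100,
    true_labels=None,
    k: int = 2,
) -> dict:
    """Degree-preserving random-network baseline.

    Per replicate: shuffle the network's gene labels, re-select the top-k
    mutually exclusive edges, propagate and cluster.  Log-rank statistics (if
    clinical data are given) are averaged across replicates *before* the
    p-value is derived; recovery ARIs (if ground-truth labels are given) are
    averaged as well.
    """
    if config.network_mode != "random_network":
        raise ValueError("config.network_mode must be 'random_network'")
    cohort, network, clinical = _load_inputs(config)
    if network is None:
        raise ValueError("random-network baseline needs an input network")
    options = config.options()
    master = np.random.SeedSequence(config.seed)
    rep_seeds = [int(s % (2**31)) for s in master.generate_state(replicates)]
    stats_rows = []
    for r, seed in enumerate(rep_seeds):
        prop_net, esp = _select_network(config, cohort, network, seed=seed)
        assignment = propagate_and_cluster(
            cohort, prop_net, k=k, options=options, seed=seed
        )
        row = {"replicate": r, "seed": seed, "degenerate": esp.degenerate}
        if clinical is not None:
            try:
                rep = survival_association(assignment, clinical)
                row["logrank_statistic"] = rep["statistic"]
            except ValueError:
                row["logrank_statistic"] = np.nan
        if true_labels is not None:
            from .evaluate import adjusted_rand_index

            row["ari"] = adjusted_rand_index(true_labels, assignment.labels)
        stats_rows.append(row)

    report: dict = {"replicates": replicates, "per_replicate": stats_rows}
    if clinical is not None:
        mean_stat = float(
            np.nanmean([r["logrank_statistic"] for r in stats_rows])
        )
        report["mean_logrank_statistic"] = mean_stat
        report["logrank_p_from_mean"] = float(sps.chi2.sf(mean_stat, df=k - 1))
    if true_labels is not None:
        report["mean_ari"] = float(np.nanmean([r["ari"] for r in stats_rows]))
    return report
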