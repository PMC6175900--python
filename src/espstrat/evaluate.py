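"""Quantitative evaluation: clustering agreement, survival, drug response
and expression association.

All hypothesis tests return a JSON-serializable record naming the test, the
statistic, the p-value, the group sizes and the options used.  Ranks are
midranks; exact rank-test p-values are used when the sample permits (no
ties), otherwise the normal approximation with tie correction applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .io import ClinicalTable, ExpressionMatrix
from .stratify import SubtypeAssignment

logger = logging.getLogger("espstrat")

__all__ = [
    "DrugResponseTable",
    "adjusted_rand_index",
    "survival_association",
    "drug_response_test",
    "expression_association",
]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (permutation model)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"label vectors must be 1-D and equal length: {a.shape} vs {b.shape}"
        )
    return float(adjusted_rand_score(a, b))


def survival_association(
    assignment: SubtypeAssignment, clinical: ClinicalTable
) -> dict:
    """Cox proportional-hazards fit of subtype indicators on survival.

    Returns the overall log-rank p-value across subtypes and per-subtype
    hazard ratios against subtype 0 as reference.  Patients lacking clinical
    data (or subtype labels) are excluded with a logged count.
    """
    labels = pd.Series(
        assignment.labels, index=list(assignment.patients), name="subtype"
    )
    joined = clinical.data.join(labels, how="inner").dropna(subset=["subtype"])
    n_dropped = len(assignment.patients) - len(joined)
    if n_dropped:
        logger.info(
            "survival_association: %d patient(s) without clinical data excluded",
            n_dropped,
        )
    groups = joined.groupby("subtype")["event"].sum()
    usable = groups[groups >= 1]
    if joined["subtype"].nunique() < 2 or len(usable) < 2:
        raise ValueError(
            "no survival contrast: need >= 2 subtypes with >= 1 observed "
            "event each after joining clinical data"
        )
    lr = multivariate_logrank_test(
        joined["time"], joined["subtype"], joined["event"]
    )
    dummies = pd.get_dummies(
        joined["subtype"].astype(int), prefix="subtype", drop_first=True
    ).astype(float)
    design = pd.concat([joined[["time", "event"]], dummies], axis=1)
    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    hazard_ratios = {
        name.replace("subtype_", "vs0:"): float(np.exp(coef))
        for name, coef in cph.params_.items()
    }
    return {
        "test": "cox_ph_logrank",
        "statistic": float(lr.test_statistic),
        "p_value": float(lr.p_value),
        "hazard_ratios": hazard_ratios,
        "n_used": int(len(joined)),
        "n_dropped": int(n_dropped),
        "events_per_subtype": {int(k): int(v) for k, v in groups.items()},
    }


@dataclass(frozen=True)
class DrugResponseTable:
    """log(IC50) per (cell line, drug), with a lineage label per cell line."""

    data: pd.DataFrame  # columns: cell_line, drug, log_ic50, lineage

    def __post_init__(self) -> None:
        need = {"cell_line", "drug", "log_ic50"}
        if not need <= set(self.data.columns):
            raise ValueError(f"drug response table needs columns {sorted(need)}")
        if not np.isfinite(self.data["log_ic50"].to_numpy(dtype=float)).all():
            raise ValueError("log_ic50 must be finite")
        if self.data.duplicated(["cell_line", "drug"]).any():
            raise ValueError("duplicate (cell line, drug) measurement")


def drug_response_test(
    labels,
    responses: DrugResponseTable,
    drug: str,
    alternative: str = "greater",
    paired: bool = False,
) -> dict:
    """Rank test for higher log(IC50), i.e. resistance, in the mutated group.

    ``labels`` maps cell line -> group (1 = ESP-mutated, 0 = not).  The
    default is the unpaired one-sided Wilcoxon rank-sum (Mann-Whitney) test;
    ``paired=True`` switches to the signed-rank test for matched response
    vectors of equal length.
    """
    lab = pd.Series(labels)
    sub = responses.data[responses.data["drug"] == drug]
    sub = sub[sub["cell_line"].isin(lab.index)]
    g = lab.reindex(sub["cell_line"]).to_numpy()
    y = sub["log_ic50"].to_numpy(dtype=float)
    y1, y0 = y[g == 1], y[g == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError(
            f"both groups must be nonempty for drug {drug!r}: "
            f"mutated={len(y1)}, non-mutated={len(y0)}"
        )
    if paired:
        if len(y1) != len(y0):
            raise ValueError("paired test needs equal group sizes")
        res = stats.wilcoxon(y1, y0, alternative=alternative)
        name = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(y1, y0, alternative=alternative)
        name = "wilcoxon_rank_sum"
    return {
        "test": name,
        "drug": drug,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_mutated": int(len(y1)),
        "n_non_mutated": int(len(y0)),
        "options": {"alternative": alternative, "paired": paired},
    }


def expression_association(
    esp_labels,
    expression: ExpressionMatrix,
    gene_set,
    alternative: str = "greater",
) -> dict:
    """Rank test on the first principal component of a gene-set expression
    submatrix between ESP-mutated (1) and non-mutated (0) patients.

    PC1's sign is fixed so the loading vector sums to a nonnegative value;
    the tail direction is the caller's choice via ``alternative``.
    """
    lab = pd.Series(esp_labels)
    genes = [g for g in gene_set if g in set(expression.data.columns)]
    if not genes:
        raise ValueError("gene_set shares no gene with the expression matrix")
    patients = [p for p in expression.data.index if p in set(lab.index)]
    sub = expression.data.loc[patients, genes].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, abs(centered).max()):
        raise ValueError("degenerate first principal component (constant expression)")
    sign = 1.0 if vt[0].sum() >= 0 else -1.0
    pc1 = sign * u[:, 0] * s[0]
    g = lab.reindex(patients).to_numpy()
    x1, x0 = pc1[g == 1], pc1[g == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both label groups must be nonempty")
    res = stats.mannwhitneyu(x1, x0, alternative=alternative)
    return {
        "test": "pc1_rank_sum",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_mutated": int(len(x1)),
        "n_non_mutated": int(len(x0)),
        "n_genes": len(genes),
        "options": {"alternative": alternative},
    }
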