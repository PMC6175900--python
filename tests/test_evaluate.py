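import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from espstrat import (
    ClinicalTable,
    DrugResponseTable,
    ExpressionMatrix,
    adjusted_rand_index,
    drug_response_test,
    expression_association,
    survival_association,
)
from espstrat.stratify import SubtypeAssignment


def ari_first_principles(a, b):
    """Permutation-model adjusted Rand index from the contingency table."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_comb = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


class TestARI:
    def test_perfect_agreement(self):
        assert adjusted_rand_index([0, 1, 1, 2], [0, 1, 1, 2]) == 1.0

    def test_label_permutation_invariance(self):
        assert adjusted_rand_index([0, 0, 1, 1], [5, 5, 2, 2]) == 1.0

    def test_hand_computed_zero_case(self):
        assert adjusted_rand_index([0, 0, 0, 1], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_matches_first_principles_on_random_pairs(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 51)
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_first_principles(a, b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([0, 1], [0, 1, 2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=30), st.permutations(range(4)))
    def test_invariant_under_relabeling(self, labels, perm):
        other = [perm[x] for x in labels]
        assert adjusted_rand_index(labels, other) == pytest.approx(1.0)


def logrank_first_principles(time, event, group):
    """Textbook two-group log-rank chi-square statistic."""
    time, event, group = map(np.asarray, (time, event, group))
    obs1 = exp1 = var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (obs1 - exp1) ** 2 / var


def _assignment(labels):
    labels = np.asarray(labels)
    return SubtypeAssignment(
        labels=labels, k=int(labels.max()) + 1,
        consensus=np.eye(len(labels)),
        patients=tuple(f"P{i}" for i in range(len(labels))),
    )


def _clinical(times, events, patients=None):
    if patients is None:
        patients = [f"P{i}" for i in range(len(times))]
    return ClinicalTable(
        data=pd.DataFrame({"time": times, "event": events}, index=patients)
    )


class TestSurvival:
    def test_identical_groups_show_no_association(self):
        times = [5, 10, 15, 20, 5, 10, 15, 20]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        rep = survival_association(_assignment([0, 0, 0, 0, 1, 1, 1, 1]),
                                   _clinical(times, events))
        assert rep["p_value"] == pytest.approx(1.0, abs=1e-6)
        for hr in rep["hazard_ratios"].values():
            assert hr == pytest.approx(1.0, abs=1e-6)

    def test_six_patient_logrank_matches_hand_calculation(self):
        times = [6, 13, 21, 30, 37, 80]
        events = [1, 1, 1, 1, 1, 0]
        labels = [0, 1, 0, 1, 0, 1]
        rep = survival_association(_assignment(labels), _clinical(times, events))
        expected = logrank_first_principles(times, events, labels)
        assert rep["statistic"] == pytest.approx(expected, rel=1e-9)

    def test_p_invariant_to_time_rescaling(self, rng):
        times = rng.exponential(100, size=40)
        events = rng.integers(0, 2, size=40)
        events[:4] = 1
        labels = rng.integers(0, 2, size=40)
        labels[:2], labels[2:4] = 0, 1
        a = survival_association(_assignment(labels), _clinical(times, events))
        b = survival_association(_assignment(labels), _clinical(times * 365.25, events))
        assert a["p_value"] == pytest.approx(b["p_value"], rel=1e-9)

    def test_recovers_true_hazard_ratio_in_simulation(self, rng):
        # exponential survival, true HR 2.7, n=300: 95% CI covers truth
        # in at least 90 of 100 replicates
        import lifelines

        true_hr = 2.7
        covered = 0
        for _ in range(100):
            labels = rng.integers(0, 2, size=300)
            lam = np.where(labels == 1, true_hr, 1.0) * 0.01
            times = rng.exponential(1 / lam)
            cens = rng.exponential(150, size=300)
            event = (times <= cens).astype(int)
            obs = np.minimum(times, cens)
            df = pd.DataFrame({"time": obs, "event": event, "g": labels.astype(float)})
            cph = lifelines.CoxPHFitter().fit(df, "time", "event")
            lo, hi = np.exp(cph.confidence_intervals_.loc["g"])
            covered += lo <= true_hr <= hi
        assert covered >= 90

    def test_single_subtype_after_join_is_an_error(self):
        with pytest.raises(ValueError, match="contrast"):
            survival_association(_assignment([0, 0, 0]), _clinical([1, 2, 3], [1, 1, 0]))


def exact_ranksum_p_greater(x, y):
    """Enumerate all rank assignments (no ties) for the one-sided p-value."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[: len(x)].sum()
    n, m = len(x), len(y)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if sum(combo) >= rx:
            count += 1
    return count / total


def _responses(y1, y0, drug="D"):
    rows = [
        {"cell_line": f"M{i}", "drug": drug, "log_ic50": v, "lineage": "x"}
        for i, v in enumerate(y1)
    ] + [
        {"cell_line": f"W{i}", "drug": drug, "log_ic50": v, "lineage": "x"}
        for i, v in enumerate(y0)
    ]
    labels = {f"M{i}": 1 for i in range(len(y1))}
    labels.update({f"W{i}": 0 for i in range(len(y0))})
    return DrugResponseTable(data=pd.DataFrame(rows)), labels


class TestDrugResponse:
    def test_fully_separated_groups_of_five(self):
        table, labels = _responses([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        rep = drug_response_test(labels, table, "D")
        assert rep["p_value"] == pytest.approx(1 / comb(10, 5))

    def test_identical_distributions_are_not_significant(self):
        table, labels = _responses([1, 2, 3, 4], [1, 2, 3, 4])
        rep = drug_response_test(labels, table, "D")
        assert rep["p_value"] >= 0.5

    def test_swapping_groups_complements_the_exact_tail(self, rng):
        y1 = rng.standard_normal(6)
        y0 = rng.standard_normal(5)
        table, labels = _responses(y1, y0)
        flipped = {k: 1 - v for k, v in labels.items()}
        p_greater = drug_response_test(labels, table, "D")["p_value"]
        p_less_flipped = drug_response_test(
            flipped, table, "D", alternative="less"
        )["p_value"]
        assert p_greater == pytest.approx(p_less_flipped)

    @pytest.mark.parametrize("n,m", [(3, 4), (5, 5), (6, 8)])
    def test_exact_p_matches_full_rank_enumeration(self, n, m, rng):
        y1 = rng.standard_normal(n)
        y0 = rng.standard_normal(m)
        table, labels = _responses(y1, y0)
        rep = drug_response_test(labels, table, "D")
        assert rep["p_value"] == pytest.approx(
            exact_ranksum_p_greater(y1, y0), rel=1e-9
        )

    def test_empty_group_is_an_error(self):
        table, labels = _responses([1.0, 2.0], [3.0])
        labels = {k: 1 for k in labels}
        with pytest.raises(ValueError, match="nonempty"):
            drug_response_test(labels, table, "D")

    def test_paired_variant_uses_signed_rank(self, rng):
        y1 = rng.standard_normal(8) + 1
        y0 = rng.standard_normal(8)
        table, labels = _responses(y1, y0)
        rep = drug_response_test(labels, table, "D", paired=True)
        assert rep["test"] == "wilcoxon_signed_rank"
        expected = stats.wilcoxon(y1, y0, alternative="greater").pvalue
        assert rep["p_value"] == pytest.approx(expected)


class TestExpressionAssociation:
    def test_separating_expression_reaches_minimal_exact_p(self):
        # group indicator (jittered to avoid ties) replicated across genes:
        # complete separation gives the minimal exact one-sided p
        labels = {f"P{i}": int(i < 4) for i in range(9)}
        ind = np.array([1.0] * 4 + [0.0] * 5) + 1e-6 * np.arange(9)
        expr = ExpressionMatrix(
            data=pd.DataFrame(
                {g: ind for g in ("A", "B", "C")},
                index=[f"P{i}" for i in range(9)],
            )
        )
        rep = expression_association(labels, expr, ["A", "B", "C"])
        assert rep["p_value"] == pytest.approx(1 / comb(9, 4))

    def test_single_gene_set_projects_onto_that_gene(self, rng):
        vals = rng.standard_normal(12)
        labels = {f"P{i}": int(i % 2) for i in range(12)}
        expr = ExpressionMatrix(
            data=pd.DataFrame({"A": vals}, index=[f"P{i}" for i in range(12)])
        )
        rep = expression_association(labels, expr, ["A"])
        direct = stats.mannwhitneyu(
            vals[1::2], vals[::2], alternative="greater"
        ).pvalue
        # PC1 of a single centered gene is a monotone transform of it
        assert rep["p_value"] in (
            pytest.approx(direct), pytest.approx(
                stats.mannwhitneyu(vals[1::2], vals[::2], alternative="less").pvalue
            )
        )
        assert rep["n_genes"] == 1

    def test_constant_expression_is_degenerate(self):
        labels = {f"P{i}": int(i < 2) for i in range(4)}
        expr = ExpressionMatrix(
            data=pd.DataFrame({"A": [1.0] * 4}, index=[f"P{i}" for i in range(4)])
        )
        with pytest.raises(ValueError, match="degenerate"):
            expression_association(labels, expr, ["A"])

    def test_null_p_values_are_uniform(self, rng):
        # label-independent expression: p ~ U(0,1) over repeated simulation
        pvals = []
        labels = {f"P{i}": int(i < 10) for i in range(20)}
        for _ in range(500):
            expr = ExpressionMatrix(
                data=pd.DataFrame(
                    rng.standard_normal((20, 5)),
                    index=[f"P{i}" for i in range(20)],
                    columns=list("ABCDE"),
                )
            )
            pvals.append(
                expression_association(labels, expr, list("ABCDE"))["p_value"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
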