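import json
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from espstrat import (
    GeneNetwork,
    MutationCohort,
    build_esp_map,
    exclusivity_p_from_counts,
    me_only_pairs,
    mutual_exclusivity_p,
    randomize_network,
    write_esp_map,
)


def enumeration_p(a, b, c, d):
    """Independent oracle: exhaustive fixed-margin hypergeometric tail.

    Sums P(co-mutation count = x) for x <= a over all attainable tables.
    """
    n = a + b + c + d
    m1, m2 = a + b, a + c
    total = comb(n, m2)
    acc = 0
    for x in range(0, min(m1, m2) + 1):
        if m1 - x <= n - m2:  # table attainable
            acc += comb(m1, x) * comb(n - m1, m2 - x)
        if x == a:
            break
    return acc / total


class TestExclusivityP:
    def test_exhaustive_agreement_for_all_tables_up_to_n30(self):
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        assert exclusivity_p_from_counts(a, b, c, d) == pytest.approx(
                            enumeration_p(a, b, c, d), abs=1e-12
                        )

    def test_agrees_with_one_sided_fisher(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            expected = fisher_exact([[a, b], [c, d]], alternative="less")[1]
            assert exclusivity_p_from_counts(a, b, c, d) == pytest.approx(
                expected, rel=1e-9
            )

    def test_worked_example(self):
        # 10+10 mutated patients, no overlap, 80 double wild type
        assert exclusivity_p_from_counts(0, 10, 10, 80) == pytest.approx(
            comb(90, 10) / comb(100, 10)
        )

    def test_degenerate_margins_give_p_one(self):
        assert exclusivity_p_from_counts(0, 0, 0, 12) == 1.0

    def test_symmetric_in_gene_order(self, small_cohort):
        p1 = mutual_exclusivity_p(small_cohort, "TP53", "KRAS")
        p2 = mutual_exclusivity_p(small_cohort, "KRAS", "TP53")
        assert p1 == p2

    def test_missing_gene_raises(self, small_cohort):
        with pytest.raises(KeyError):
            mutual_exclusivity_p(small_cohort, "TP53", "MYC")


def _exclusive_cohort():
    """100 patients; G1/G2 perfectly exclusive (25/25), G3/G4 co-mutated."""
    calls = np.zeros((100, 4), dtype=np.int8)
    calls[:25, 0] = 1
    calls[25:50, 1] = 1
    calls[:30, 2] = 1
    calls[:30, 3] = 1
    return MutationCohort(
        patients=tuple(f"P{i}" for i in range(100)),
        genes=("G1", "G2", "G3", "G4"),
        calls=calls,
    )


class TestBuildESPMap:
    def test_perfectly_exclusive_edge_ranks_first(self):
        cohort = _exclusive_cohort()
        network = GeneNetwork.from_edges([("G1", "G2"), ("G3", "G4"), ("G1", "G3")])
        esp = build_esp_map(cohort, network, k=100)
        assert esp.n_edges == 3
        assert (esp.scored_edges[0].gene_a, esp.scored_edges[0].gene_b) == ("G1", "G2")
        assert esp.scored_edges[0].p_value == pytest.approx(
            enumeration_p(0, 25, 25, 50)
        )
        ps = [e.p_value for e in esp.scored_edges]
        assert ps == sorted(ps)

    def test_k_larger_than_supply_returns_everything(self):
        cohort = _exclusive_cohort()
        network = GeneNetwork.from_edges([("G1", "G2")])
        esp = build_esp_map(cohort, network, k=1000)
        assert esp.n_edges == 1 and not esp.degenerate

    def test_unlimited_k_equals_all_shared_edges(self):
        cohort = _exclusive_cohort()
        network = GeneNetwork.from_edges(
            [("G1", "G2"), ("G2", "G3"), ("G3", "MYC")]  # MYC not in cohort
        )
        esp = build_esp_map(cohort, network, k=10**9)
        assert set(esp.edge_pairs()) == {("G1", "G2"), ("G2", "G3")}

    def test_unmutated_network_genes_give_degenerate_map(self):
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[:, 0] = 1  # only G1 mutated, but G1 not in the network
        cohort = MutationCohort(
            tuple(f"P{i}" for i in range(10)), ("G1", "G2", "G3"), calls
        )
        network = GeneNetwork.from_edges([("G2", "G3")])
        esp = build_esp_map(cohort, network)
        assert esp.degenerate and esp.n_edges == 0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            build_esp_map(_exclusive_cohort(), GeneNetwork.from_edges([]), k=0)

    def test_tsv_serialization(self, tmp_path):
        esp = build_esp_map(
            _exclusive_cohort(), GeneNetwork.from_edges([("G1", "G2")])
        )
        write_esp_map(esp, tmp_path / "esp.tsv", tmp_path / "esp.json")
        lines = (tmp_path / "esp.tsv").read_text().splitlines()
        assert lines[0].split("\t") == ["geneA", "geneB", "p_value", "rank", "cancer_type"]
        assert len(lines) == 2
        summary = json.loads((tmp_path / "esp.json").read_text())
        assert summary["degenerate"] is False and summary["n_edges"] == 1


class TestMeOnlyPairs:
    def test_most_exclusive_pair_ranks_first_without_network(self):
        esp = me_only_pairs(_exclusive_cohort(), k=3)
        assert (esp.scored_edges[0].gene_a, esp.scored_edges[0].gene_b) == ("G1", "G2")
        assert esp.n_edges == 3

    def test_identical_mutation_columns_tie_break_lexicographically(self):
        calls = np.zeros((10, 3), dtype=np.int8)
        calls[:5, :] = 1
        cohort = MutationCohort(
            tuple(f"P{i}" for i in range(10)), ("B", "C", "A"), calls
        )
        esp = me_only_pairs(cohort, k=3)
        assert all(e.p_value == 1.0 for e in esp.scored_edges)
        assert [(e.gene_a, e.gene_b) for e in esp.scored_edges] == [
            ("A", "B"), ("A", "C"), ("B", "C")
        ]

    def test_k_one_returns_single_best(self):
        esp = me_only_pairs(_exclusive_cohort(), k=1)
        assert esp.n_edges == 1

    def test_needs_two_mutated_genes(self):
        calls = np.zeros((5, 3), dtype=np.int8)
        calls[:, 0] = 1
        cohort = MutationCohort(("P1", "P2", "P3", "P4", "P5"), ("A", "B", "C"), calls)
        with pytest.raises(ValueError, match="two genes"):
            me_only_pairs(cohort)


class TestRandomizeNetwork:
    def test_degree_multiset_preserved(self, rng):
        pairs = {(f"G{rng.integers(20)}", f"G{rng.integers(20)}") for _ in range(40)}
        net = GeneNetwork.from_edges(pairs)
        shuffled = randomize_network(net, seed=4)
        assert sorted(net.degrees().values()) == sorted(shuffled.degrees().values())
        assert set(shuffled.nodes) == set(net.nodes)

    def test_single_edge_network_stays_single_edge(self):
        net = GeneNetwork.from_edges([("A", "B")])
        shuffled = randomize_network(net, seed=0)
        assert shuffled.n_edges == 1

    def test_seeded_determinism(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        assert randomize_network(net, 7).edges == randomize_network(net, 7).edges
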