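"""Enrichment, confinement, network inference, and co-expression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copa_regulon import (
    Edge,
    ExpressionCompendium,
    NetworkSpec,
    OutlierCalls,
    RegulonNetwork,
    coexpression,
    confinement,
    infer_network,
    lineage_enrichment,
    master_regulator,
    simulate_perturbations,
)
from conftest import random_compendium


def exact_hypergeom_tail(N, K, n, k):
    """P[X >= k] for X ~ Hypergeom(N, K, n), by exact enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def _calls_from_flags(compendium, flags):
    shape = flags.shape
    return OutlierCalls(
        gene_ids=compendium.gene_ids,
        sample_ids=compendium.sample_ids,
        row_fold=np.where(flags, 100.0, 1.0),
        col_fold=np.where(flags, 100.0, 1.0),
        is_outlier=flags,
        row_cutoff=32.0,
        col_cutoff=64.0,
    )


def _labelled_compendium(n_genes, lineage_sizes):
    sample_ids, lineages = [], {}
    for lin, size in lineage_sizes.items():
        for i in range(size):
            sid = f"{lin}_{i}"
            sample_ids.append(sid)
            lineages[sid] = lin
    values = np.ones((n_genes, len(sample_ids)))
    return ExpressionCompendium(
        gene_ids=[f"G{i}" for i in range(n_genes)],
        sample_ids=sample_ids, values=values, lineages=lineages)


class TestLineageEnrichment:
    def test_perfectly_confined_outlier_matches_closed_form(self):
        comp = _labelled_compendium(1, {"ovary": 5, "other": 95})
        flags = np.zeros((1, 100), dtype=bool)
        flags[0, :5] = True  # all 5 ovary samples, nowhere else
        df = lineage_enrichment(_calls_from_flags(comp, flags), comp)
        row = df[df.lineage == "ovary"].iloc[0]
        assert row["p_value"] == pytest.approx(1 / math.comb(100, 5), rel=1e-12)

    def test_zero_count_pairs_are_omitted(self):
        comp = _labelled_compendium(2, {"a": 3, "b": 3})
        flags = np.zeros((2, 6), dtype=bool)
        flags[0, 0] = True
        df = lineage_enrichment(_calls_from_flags(comp, flags), comp)
        assert set(zip(df.gene, df.lineage)) == {("G0", "a")}

    def test_ubiquitous_outlier_has_p_one_everywhere(self):
        comp = _labelled_compendium(1, {"a": 4, "b": 6})
        flags = np.ones((1, 10), dtype=bool)
        df = lineage_enrichment(_calls_from_flags(comp, flags), comp)
        assert (df["p_value"] == 1.0).all()

    def test_single_lineage_rejected(self):
        comp = _labelled_compendium(1, {"a": 5})
        flags = np.ones((1, 5), dtype=bool)
        with pytest.raises(ValueError):
            lineage_enrichment(_calls_from_flags(comp, flags), comp)

    def test_matches_exhaustive_enumeration_small_populations(self):
        from scipy import stats
        for N in (5, 12, 30):
            for n in range(1, N + 1):
                for K in range(1, N + 1):
                    for k in range(1, min(n, K) + 1):
                        expected = exact_hypergeom_tail(N, K, n, k)
                        got = float(stats.hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expected, rel=1e-10)

    def test_bh_qvalues_are_monotone_and_bounded(self, rng):
        comp = random_compendium(rng, n_genes=30, n_samples=40, n_lineages=4)
        flags = rng.random((30, 40)) < 0.1
        df = lineage_enrichment(_calls_from_flags(comp, flags), comp)
        assert ((df.q_value >= df.p_value - 1e-12) & (df.q_value <= 1)).all()
        ordered = df.sort_values("p_value")
        assert ordered["q_value"].is_monotonic_increasing


class TestConfinement:
    def test_exclusive_expression_is_confined(self):
        comp = _labelled_compendium(1, {"ovary": 3, "other": 7})
        values = comp.values.copy()
        values[0] = [10, 10, 10, 0, 0, 0, 0, 0, 0, 0]
        comp = ExpressionCompendium(comp.gene_ids, comp.sample_ids, values,
                                    comp.lineages)
        df = confinement(comp, "ovary")
        assert df["confinement_score"].iloc[0] == pytest.approx(10 / 0.01)
        assert bool(df["confined"].iloc[0])

    def test_uniform_expression_is_not_confined(self):
        comp = _labelled_compendium(1, {"ovary": 3, "other": 7})
        comp = ExpressionCompendium(comp.gene_ids, comp.sample_ids,
                                    comp.values * 10, comp.lineages)
        df = confinement(comp, "ovary")
        assert df["confinement_score"].iloc[0] == pytest.approx(10 / 10.01)
        assert not bool(df["confined"].iloc[0])

    def test_silent_gene_fails_expression_floor(self):
        comp = _labelled_compendium(1, {"ovary": 3, "other": 7})
        values = comp.values * 0.01
        comp = ExpressionCompendium(comp.gene_ids, comp.sample_ids, values,
                                    comp.lineages)
        df = confinement(comp, "ovary", score_threshold=0.1)
        assert not bool(df["confined"].iloc[0])

    def test_scores_match_loop_oracle(self, rng):
        comp = random_compendium(rng, n_genes=20, n_samples=16, n_lineages=4)
        df = confinement(comp, "L0")
        labels = comp.lineage_labels()
        for gi, gene in enumerate(comp.gene_ids):
            mean_in = np.mean([comp.values[gi, si]
                               for si in range(16) if labels[si] == "L0"])
            mean_out = np.mean([comp.values[gi, si]
                                for si in range(16) if labels[si] != "L0"])
            assert df["confinement_score"].iloc[gi] == pytest.approx(
                mean_in / (mean_out + 0.01), rel=1e-12)

    def test_unknown_lineage_rejected(self, rng):
        comp = random_compendium(rng)
        with pytest.raises(ValueError):
            confinement(comp, "nonexistent")


NETWORK_GENES = ["PAX8", "CDH6", "CLDN16", "FGF18", "FOLR1", "SLC34A2",
                 "SOX17", "SPON1", "WNT7A"]


@st.composite
def network_specs(draw):
    members = NETWORK_GENES[1:]
    n_activated = draw(st.integers(1, len(members)))
    perm = draw(st.permutations(members))
    return NetworkSpec(
        anchor="PAX8",
        activated=tuple(perm[:n_activated]),
        independent=tuple(perm[n_activated:]),
        knockdown_effect=draw(st.floats(0.05, 0.49)),
        noise_log2_sd=0.0,
        seed=draw(st.integers(0, 10_000)),
    )


class TestNetworkInference:
    def test_anchor_activates_all_but_the_independent_member(self):
        table = simulate_perturbations(NetworkSpec(noise_log2_sd=0.0))
        net = infer_network(table)
        anchor_edges = {e.target for e in net.edges if e.source == "PAX8"}
        assert anchor_edges == set(NETWORK_GENES[1:]) - {"FOLR1"}
        assert all(e.sign == "activation" for e in net.edges
                   if e.source == "PAX8")
        assert master_regulator(net) == ["PAX8"]

    def test_all_unchanged_gives_empty_edge_set(self):
        from copa_regulon import PerturbationTable
        table = PerturbationTable(("A", "B"), ("A", "B"), np.ones((2, 2)))
        assert not infer_network(table).edges

    def test_upregulation_becomes_repression_edge(self):
        from copa_regulon import PerturbationTable
        rel = np.array([[1.0, 4.0], [1.0, 1.0]])
        net = infer_network(PerturbationTable(("A", "B"), ("A", "B"), rel))
        (edge,) = net.edges
        assert (edge.source, edge.target, edge.sign) == ("A", "B", "repression")
        assert edge.magnitude == pytest.approx(2.0)

    def test_threshold_order_enforced(self):
        from copa_regulon import PerturbationTable
        table = PerturbationTable(("A",), ("A",), np.ones((1, 1)))
        with pytest.raises(ValueError):
            infer_network(table, down_threshold=1.5)

    @given(spec=network_specs())
    @settings(max_examples=50, deadline=None)
    def test_noiseless_simulation_recovers_planted_edges_exactly(self, spec):
        net = infer_network(simulate_perturbations(spec))
        got = {(e.source, e.target, e.sign) for e in net.edges}
        assert got == set(spec.planted_edges())
        assert master_regulator(net) == [spec.anchor]

    def test_master_regulator_tie_returns_both_sorted(self):
        edges = [Edge("B", "x", "activation", 1.0),
                 Edge("B", "y", "activation", 1.0),
                 Edge("A", "y", "activation", 1.0),
                 Edge("A", "x", "activation", 1.0)]
        net = RegulonNetwork(nodes=frozenset("ABxy"), edges=frozenset(edges))
        assert master_regulator(net) == ["A", "B"]

    def test_empty_network_has_no_master(self):
        net = RegulonNetwork(nodes=frozenset("AB"), edges=frozenset())
        with pytest.raises(ValueError):
            master_regulator(net)


class TestCoexpression:
    def test_duplicated_gene_rows_correlate_perfectly(self, rng):
        comp = random_compendium(rng, n_genes=5, n_samples=30, zero_fraction=0)
        values = comp.values.copy()
        values[1] = values[0]
        comp = ExpressionCompendium(comp.gene_ids, comp.sample_ids, values,
                                    comp.lineages)
        df = coexpression(comp, ["G000", "G001"])
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_gene_is_flagged_not_an_error(self, rng):
        comp = random_compendium(rng, n_genes=3, n_samples=10, zero_fraction=0)
        values = comp.values.copy()
        values[2] = 7.0
        comp = ExpressionCompendium(comp.gene_ids, comp.sample_ids, values,
                                    comp.lineages)
        df = coexpression(comp, ["G000", "G002"])
        assert not bool(df["defined"].iloc[0])
        assert np.isnan(df["r"].iloc[0])

    def test_matches_textbook_formula(self, rng):
        comp = random_compendium(rng, n_genes=10, n_samples=30)
        genes = list(comp.gene_ids)
        df = coexpression(comp, genes)
        x = np.log2(comp.values + 1)
        for _, row in df.iterrows():
            i, j = genes.index(row.gene_a), genes.index(row.gene_b)
            a, b = x[i] - x[i].mean(), x[j] - x[j].mean()
            r = (a * b).sum() / np.sqrt((a ** 2).sum() * (b ** 2).sum())
            assert row["r"] == pytest.approx(r, abs=1e-12)

    def test_symmetric_in_the_pair(self, rng):
        comp = random_compendium(rng, n_genes=4, n_samples=12)
        ab = coexpression(comp, ["G000", "G001"])
        ba = coexpression(comp, ["G001", "G000"])
        assert ab["r"].iloc[0] == pytest.approx(ba["r"].iloc[0], rel=1e-12)

    def test_unknown_gene_rejected(self, rng):
        comp = random_compendium(rng, n_genes=3, n_samples=5)
        with pytest.raises(ValueError):
            coexpression(comp, ["G000", "NOPE"])
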