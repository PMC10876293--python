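"""Network gating, prevalence filtering, and export round-trips."""

import numpy as np
import networkx as nx
import pytest

from gutnet.correlation import CorrelationResult
from gutnet.data import AbundanceTable, TaxonAnnotation
from gutnet.network import (
    build_network,
    export_network,
    filter_by_prevalence,
    prevalence,
    read_edge_tsv,
)


def table_with_presence(present_counts, n_samples=19):
    """One taxon per entry, present (count 1) in the first k samples."""
    rows = []
    for k in present_counts:
        rows.append([1] * k + [0] * (n_samples - k))
    rows.append([1] * n_samples)  # keeps every column nonzero
    return AbundanceTable(
        [f"T{i}" for i in range(len(present_counts))] + ["ubiquitous"],
        [f"S{j}" for j in range(n_samples)],
        np.array(rows),
    )


class TestPrevalence:
    def test_fractions(self):
        t = table_with_presence([5, 0, 19])
        prev = prevalence(t)
        assert prev[0] == pytest.approx(5 / 19)
        assert prev[1] == 0.0
        assert prev[2] == 1.0

    def test_filter_inclusive_boundary(self):
        # 6/19 = 31.6% kept at 30%; 5/19 = 26.3% dropped
        t = table_with_presence([6, 5])
        kept = filter_by_prevalence(t, 0.30)
        assert kept.taxa == ["T0", "ubiquitous"]

    def test_filter_zero_is_identity(self):
        t = table_with_presence([6, 5])
        assert filter_by_prevalence(t, 0.0).taxa == t.taxa

    def test_all_removed_is_error(self):
        t = AbundanceTable(
            ["A", "B"], ["S1", "S2", "S3", "S4"],
            np.array([[1, 1, 0, 0], [0, 0, 1, 1]]),
        )
        with pytest.raises(ValueError):
            filter_by_prevalence(t, 0.9)


def corr_with(taxa, entries, pvals):
    d = len(taxa)
    rho = np.eye(d)
    p = np.ones((d, d))
    for (i, j), r in entries.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), v in pvals.items():
        p[i, j] = p[j, i] = v
    return CorrelationResult(taxa=taxa, rho=rho, method="clr_pearson", pvalues=p)


@pytest.fixture
def four_taxon_table():
    rng = np.random.default_rng(8)
    return AbundanceTable(
        ["A", "B", "C", "D"], [f"S{i}" for i in range(10)],
        rng.poisson(30, size=(4, 10)) + 1,
    )


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "rho,p,expect_edge,expect_sign",
        [
            (0.29, 0.001, False, None),  # below magnitude gate
            (-0.30, 0.01, True, "co_exclusion"),  # inclusive boundary
            (0.30, 0.01, True, "co_occurrence"),
            (0.9, 0.06, False, None),  # fails significance
            (0.9, 0.05, False, None),  # alpha gate is strict
        ],
    )
    def test_gates(self, four_taxon_table, rho, p, expect_edge, expect_sign):
        corr = corr_with(["A", "B", "C", "D"], {(0, 1): rho}, {(0, 1): p})
        net = build_network(corr, four_taxon_table)
        assert net.has_edge("A", "B") == expect_edge
        if expect_edge:
            assert net.edges["A", "B"]["sign"] == expect_sign

    def test_node_attributes(self, four_taxon_table):
        ann = TaxonAnnotation({"A": "virulent", "B": "symbiotic"})
        corr = corr_with(["A", "B", "C", "D"], {(0, 1): -0.5}, {(0, 1): 0.01})
        net = build_network(corr, four_taxon_table, annotation=ann)
        assert net.nodes["A"]["taxon_class"] == "virulent"
        assert 0 < net.nodes["A"]["mean_abundance"] < 1
        assert net.nodes["A"]["prevalence"] == 1.0

    def test_isolated_dropped_by_default(self, four_taxon_table):
        corr = corr_with(["A", "B", "C", "D"], {(0, 1): 0.5}, {(0, 1): 0.01})
        net = build_network(corr, four_taxon_table)
        assert set(net.nodes) == {"A", "B"}
        retained = build_network(corr, four_taxon_table, retain_isolated=True)
        assert set(retained.nodes) == {"A", "B", "C", "D"}

    def test_edge_count_monotone_in_thresholds(self, four_taxon_table):
        entries = {(0, 1): 0.35, (0, 2): -0.6, (1, 3): 0.31, (2, 3): 0.8}
        pvals = {(0, 1): 0.04, (0, 2): 0.001, (1, 3): 0.049, (2, 3): 0.02}
        corr = corr_with(["A", "B", "C", "D"], entries, pvals)
        last = None
        for r_min in (0.0, 0.3, 0.5, 0.9):
            n = build_network(corr, four_taxon_table, r_min=r_min).number_of_edges()
            assert last is None or n <= last
            last = n
        last = None
        for alpha in (0.05, 0.03, 0.01, 0.0005):
            n = build_network(corr, four_taxon_table, alpha=alpha).number_of_edges()
            assert last is None or n <= last
            last = n

    def test_sign_always_matches_rho(self, four_taxon_table):
        entries = {(0, 1): 0.35, (0, 2): -0.6, (2, 3): 0.8}
        pvals = {k: 0.01 for k in entries}
        net = build_network(corr_with(["A", "B", "C", "D"], entries, pvals), four_taxon_table)
        for _, _, attrs in net.edges(data=True):
            assert (attrs["sign"] == "co_occurrence") == (attrs["rho"] > 0)

    def test_taxa_mismatch_rejected(self, four_taxon_table):
        corr = corr_with(["A", "B", "C"], {}, {})
        with pytest.raises(ValueError):
            build_network(corr, four_taxon_table)

    def test_missing_pvalues_rejected(self, four_taxon_table):
        corr = CorrelationResult(["A", "B", "C", "D"], np.eye(4), "clr_pearson")
        with pytest.raises(ValueError):
            build_network(corr, four_taxon_table)


class TestExport:
    @pytest.fixture
    def small_net(self, four_taxon_table):
        entries = {(0, 1): -0.5, (2, 3): 0.7}
        pvals = {k: 0.01 for k in entries}
        ann = TaxonAnnotation({"A": "virulent", "B": "symbiotic"})
        return build_network(
            corr_with(["A", "B", "C", "D"], entries, pvals), four_taxon_table, annotation=ann
        )

    def test_edge_tsv_round_trip(self, small_net, tmp_path):
        p = tmp_path / "edges.tsv"
        export_network(small_net, p, "edge_tsv")
        back = read_edge_tsv(p)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, small_net.edges))
        assert back.edges["A", "B"]["sign"] == "co_exclusion"

    def test_graphml_parses_with_colors(self, small_net, tmp_path):
        p = tmp_path / "net.graphml"
        export_network(small_net, p, "graphml")
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 2
        colors = {frozenset(e): attrs["color"] for *e, attrs in g.edges(data=True)}
        assert colors[frozenset({"A", "B"})] == "blue"  # co-exclusion
        assert colors[frozenset({"C", "D"})] == "red"  # co-occurrence
        assert g.nodes["A"]["taxon_class"] == "virulent"
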