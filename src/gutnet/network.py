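"""Signed co-occurrence / co-exclusion network construction.

A correlation matrix with bootstrap p-values becomes an undirected signed
graph under two gates: statistical significance (p < alpha, raw by default;
the study applied no multiple-testing correction) and correlation magnitude
(|rho| >= 0.3, an inclusive boundary). Nodes carry the attributes used in
Cytoscape-style rendering: mean relative abundance (node size), prevalence,
and the virulent/symbiotic/oral/other annotation class. Edges positive in
rho are co-occurrences (rendered red), negative co-exclusions (blue).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .correlation import CorrelationResult
from .data import AbundanceTable, TaxonAnnotation, mean_relative_abundance

EDGE_COLORS = {"co_occurrence": "red", "co_exclusion": "blue"}


def prevalence(table: AbundanceTable) -> np.ndarray:
    """Per-taxon fraction of samples with nonzero count."""
    return (table.counts > 0).mean(axis=1)


def filter_by_prevalence(table: AbundanceTable, min_prevalence: float) -> AbundanceTable:
    """Keep taxa present in at least ``min_prevalence`` of samples (inclusive)."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    prev = prevalence(table)
    keep = [t for t, p in zip(table.taxa, prev) if p >= min_prevalence]
    if not keep:
        raise ValueError("prevalence filter removed every taxon")
    return table.subset_taxa(keep)


def build_network(
    corr: CorrelationResult,
    table: AbundanceTable,
    r_min: float = 0.3,
    alpha: float = 0.05,
    annotation: TaxonAnnotation | None = None,
    retain_isolated: bool = False,
    fdr: bool = False,
    group: str | None = None,
) -> nx.Graph:
    """Gate a correlation result into a signed microbial network.

    An edge (i, j) exists iff p[i,j] < alpha and |rho[i,j]| >= r_min.
    With ``fdr=True`` the alpha gate applies to Benjamini-Hochberg adjusted
    p-values instead of raw ones (off by default, matching the study rule).
    Isolated taxa are dropped unless ``retain_isolated``; reported node
    counts then reflect connected taxa, the convention of network figures.
    """
    if corr.taxa != table.taxa:
        raise ValueError("correlation and table taxa differ (order matters)")
    if corr.pvalues is None:
        raise ValueError("correlation has no bootstrap p-values; run bootstrap_pvalues first")
    annotation = annotation or TaxonAnnotation()
    rho, pvals = corr.rho, corr.pvalues
    d = len(corr.taxa)
    iu = np.triu_indices(d, k=1)
    pflat = pvals[iu]
    if fdr:
        pflat = multipletests(pflat, method="fdr_bh")[1]

    g = nx.Graph(
        r_min=r_min,
        alpha=alpha,
        method=corr.method,
        fdr=fdr,
        group=group or "",
        n_samples=table.n_samples,
    )
    mean_ab = mean_relative_abundance(table)
    prev = prevalence(table)
    for k, taxon in enumerate(table.taxa):
        g.add_node(
            taxon,
            mean_abundance=float(mean_ab[k]),
            prevalence=float(prev[k]),
            taxon_class=annotation.of(taxon),
        )
    for i, j, p in zip(iu[0], iu[1], pflat):
        r = rho[i, j]
        if p < alpha and abs(r) >= r_min:
            sign = "co_occurrence" if r > 0 else "co_exclusion"
            g.add_edge(
                corr.taxa[i], corr.taxa[j],
                rho=float(r), pvalue=float(pvals[i, j]), sign=sign,
            )
    if not retain_isolated:
        g.remove_nodes_from([n for n in list(g.nodes) if g.degree[n] == 0])
    return g


def export_network(net: nx.Graph, path: str | Path, format: str = "edge_tsv") -> None:
    """Write the network as an edge TSV or GraphML (Cytoscape-ready).

    GraphML edges carry a ``color`` attribute: red for co-occurrence, blue
    for co-exclusion.
    """
    path = Path(path)
    if format == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("taxonA\ttaxonB\trho\tpvalue\tsign\n")
            for u, v, attrs in sorted(net.edges(data=True)):
                fh.write(
                    f"{u}\t{v}\t{attrs['rho']:.6g}\t{attrs['pvalue']:.6g}\t{attrs['sign']}\n"
                )
    elif format == "graphml":
        g = net.copy()
        for _, _, attrs in g.edges(data=True):
            attrs["color"] = EDGE_COLORS[attrs["sign"]]
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Rebuild a network from an edge TSV written by :func:`export_network`."""
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            g.add_edge(
                rec["taxonA"], rec["taxonB"],
                rho=float(rec["rho"]), pvalue=float(rec["pvalue"]), sign=rec["sign"],
            )
    return g
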