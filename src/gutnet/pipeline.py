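"""End-to-end per-cohort workflow.

One network is constructed per group on that group's samples only (no
cross-group pooling): split by group -> prevalence filter -> correlate ->
bootstrap -> gate into a network -> summarize -> compare the two groups'
edge-sign compositions. Deterministic given the seed; a manifest records
parameters and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .correlation import CorrelationResult, bootstrap_pvalues, clr_pearson, sparcc
from .data import (
    AbundanceTable,
    SampleGroups,
    TaxonAnnotation,
    read_abundance_table,
    read_annotation,
    read_groups,
)
from .netstats import NetworkComparison, NetworkSummary, compare_networks, summarize_network
from .network import build_network, export_network, filter_by_prevalence

log = logging.getLogger("gutnet")


@dataclass
class RunConfig:
    counts_path: str
    groups_path: str | None = None
    annotation_path: str | None = None
    method: str = "sparcc"
    r_min: float = 0.3
    alpha: float = 0.05
    prevalence_min: float = 0.0
    n_bootstrap: int = 1000
    seed: int = 0
    out_dir: str = "gutnet_out"
    retain_isolated: bool = False
    fdr: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("r_min", "alpha", "prevalence_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def correlate(
    table: AbundanceTable, method: str = "sparcc", seed: int | None = None, **kwargs
) -> CorrelationResult:
    """Dispatch to the chosen correlation estimator."""
    if method == "sparcc":
        return sparcc(table, seed=seed, **kwargs)
    if method == "clr_pearson":
        return clr_pearson(table, **kwargs)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass
class GroupResult:
    group: str
    table: AbundanceTable
    correlation: CorrelationResult
    network: nx.Graph
    summary: NetworkSummary


@dataclass
class PipelineResult:
    groups: dict[str, GroupResult]
    comparison: NetworkComparison | None
    manifest: dict


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_abundance_table(config.counts_path)
    groups = read_groups(config.groups_path) if config.groups_path else SampleGroups(
        {s: "all" for s in table.samples}
    )
    groups.validate_against(table, min_per_group=3)
    annotation = (
        read_annotation(config.annotation_path)
        if config.annotation_path
        else TaxonAnnotation.default()
    )

    results: dict[str, GroupResult] = {}
    rows = []
    for gi, group in enumerate(groups.groups()):
        members = [s for s in table.samples if groups.labels.get(s) == group]
        if not members:
            continue
        log.info("group %s: %d samples", group, len(members))
        sub = table.subset_samples(members)
        if config.prevalence_min > 0:
            sub = filter_by_prevalence(sub, config.prevalence_min)
            log.info("group %s: %d taxa pass prevalence >= %.2f", group, sub.n_taxa, config.prevalence_min)
        seed = config.seed + gi  # distinct stream per group, still seed-determined
        corr = correlate(sub, method=config.method, seed=seed)
        corr = bootstrap_pvalues(sub, corr, n_bootstrap=config.n_bootstrap, seed=seed)
        net = build_network(
            corr, sub,
            r_min=config.r_min, alpha=config.alpha, annotation=annotation,
            retain_isolated=config.retain_isolated, fdr=config.fdr, group=group,
        )
        summary = summarize_network(net, n_samples=sub.n_samples)
        results[group] = GroupResult(group, sub, corr, net, summary)
        export_network(net, out / f"network_{group}.edges.tsv", "edge_tsv")
        export_network(net, out / f"network_{group}.graphml", "graphml")
        rows.append({"group": group, **summary.as_row()})

    pd.DataFrame(rows).to_csv(out / "summary.tsv", sep="\t", index=False, lineterminator="\n")

    comparison = None
    labels = list(results)
    if len(labels) >= 2:
        a, b = results[labels[0]].summary, results[labels[1]].summary
        if a.n_correlations > 0 and b.n_correlations > 0:
            comparison = compare_networks(a, b)
            with open(out / "comparison.tsv", "w", encoding="utf-8") as fh:
                fh.write("group_a\tgroup_b\ttest\tstatistic\tp_value\tratio_a\tratio_b\n")
                fh.write(
                    f"{labels[0]}\t{labels[1]}\t{comparison.test}\t"
                    f"{comparison.statistic:.6g}\t{comparison.p_value:.6g}\t"
                    f"{comparison.ratio_a:.6g}\t{comparison.ratio_b:.6g}\n"
                )

    manifest = {
        "gutnet_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "inputs": {
            "counts": _checksum(config.counts_path),
            "groups": _checksum(config.groups_path) if config.groups_path else None,
            "annotation": _checksum(config.annotation_path) if config.annotation_path else None,
        },
        "groups": {g: r.summary.as_row() for g, r in results.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(results, comparison, manifest)
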