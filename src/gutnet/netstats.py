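"""Network summary statistics, group comparison, and abundance-ratio markers.

The central deliverable of a cohort network is a one-row descriptive
summary — node count, edge count, co-occurrence and co-exclusion counts,
and their ratios — plus a two-group homogeneity test on the edge-sign
composition (co-occurrences vs co-exclusions per cohort), and cross-class
tallies that quantify virulent/symbiotic co-exclusion structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .data import AbundanceTable, SampleGroups, TaxonAnnotation


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (1.725 -> 1.73), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class NetworkSummary:
    """One descriptive row: counts and ratios of a signed cohort network.

    ``ratio_cc_ce`` is None (undefined) when there are no co-exclusions;
    the fractions are None for an empty network. Rounded values are for
    reporting; the unrounded ones are retained alongside.
    """

    n_samples: int
    n_nodes: int
    n_correlations: int
    n_cooccurrence: int
    n_coexclusion: int
    ratio_cc_ce: float | None
    frac_cc: float | None
    frac_ce: float | None
    ratio_cc_ce_exact: float | None
    frac_cc_exact: float | None
    frac_ce_exact: float | None

    def as_row(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_nodes": self.n_nodes,
            "n_correlations": self.n_correlations,
            "n_cooccurrence": self.n_cooccurrence,
            "n_coexclusion": self.n_coexclusion,
            "ratio_cc_ce": self.ratio_cc_ce,
            "frac_cc": self.frac_cc,
            "frac_ce": self.frac_ce,
        }


def summary_from_counts(
    n_samples: int,
    n_nodes: int,
    n_cooccurrence: int,
    n_coexclusion: int,
    round_to: int = 2,
) -> NetworkSummary:
    """Build a summary row directly from printed/known counts."""
    total = n_cooccurrence + n_coexclusion
    ratio = n_cooccurrence / n_coexclusion if n_coexclusion > 0 else None
    fcc = n_cooccurrence / total if total > 0 else None
    fce = n_coexclusion / total if total > 0 else None
    rnd = lambda v: None if v is None else round_half_away(v, round_to)
    return NetworkSummary(
        n_samples, n_nodes, total, n_cooccurrence, n_coexclusion,
        rnd(ratio), rnd(fcc), rnd(fce), ratio, fcc, fce,
    )


def summarize_network(net: nx.Graph, n_samples: int | None = None, round_to: int = 2) -> NetworkSummary:
    """Descriptive statistics of a signed network."""
    if n_samples is None:
        n_samples = int(net.graph.get("n_samples", 0))
    signs = [attrs["sign"] for _, _, attrs in net.edges(data=True)]
    cc = sum(1 for s in signs if s == "co_occurrence")
    ce = sum(1 for s in signs if s == "co_exclusion")
    summary = summary_from_counts(n_samples, net.number_of_nodes(), cc, ce, round_to)
    return summary


@dataclass
class NetworkComparison:
    """2x2 homogeneity test of edge-sign composition between two networks."""

    contingency: tuple[tuple[int, int], tuple[int, int]]
    statistic: float | None
    p_value: float
    test: str
    ratio_a: float | None
    ratio_b: float | None


def compare_networks(
    a: NetworkSummary, b: NetworkSummary, test: str = "chi2"
) -> NetworkComparison:
    """Test whether two networks differ in co-occurrence/co-exclusion mix.

    ``chi2`` is the Pearson chi-square without continuity correction
    (the default; it reproduces the printed cohort comparisons),
    ``chi2_yates`` adds the continuity correction, ``fisher`` is exact.
    """
    if a.n_correlations == 0 or b.n_correlations == 0:
        raise ValueError("both networks need at least one edge to compare")
    obs = np.array(
        [[a.n_cooccurrence, a.n_coexclusion], [b.n_cooccurrence, b.n_coexclusion]]
    )
    if test in ("chi2", "chi2_yates"):
        if (obs.sum(axis=0) == 0).any():
            raise ValueError("chi-square undefined with a zero column margin; use fisher")
        stat, p, _, _ = stats.chi2_contingency(obs, correction=(test == "chi2_yates"))
        statistic = float(stat)
    elif test == "fisher":
        statistic, p = stats.fisher_exact(obs)
        statistic = float(statistic)
    else:
        raise ValueError(f"unknown test {test!r}")
    return NetworkComparison(
        contingency=((int(obs[0, 0]), int(obs[0, 1])), (int(obs[1, 0]), int(obs[1, 1]))),
        statistic=statistic,
        p_value=float(p),
        test=test,
        ratio_a=a.ratio_cc_ce_exact,
        ratio_b=b.ratio_cc_ce_exact,
    )


@dataclass
class CrossClassSummary:
    """Edge tallies per unordered annotation-class pair and per sign."""

    counts: dict[tuple[str, str], dict[str, int]]
    total_edges: int
    virulent_symbiotic_coexclusion_fraction: float

    def pair(self, a: str, b: str) -> dict[str, int]:
        key = tuple(sorted((a, b)))
        return self.counts.get(key, {"co_occurrence": 0, "co_exclusion": 0})


def cross_class_summary(net: nx.Graph, annotation: TaxonAnnotation) -> CrossClassSummary:
    """Bin every edge by the class pair of its endpoints and its sign."""
    counts: dict[tuple[str, str], dict[str, int]] = {}
    total = 0
    for u, v, attrs in net.edges(data=True):
        key = tuple(sorted((annotation.of(u), annotation.of(v))))
        bucket = counts.setdefault(key, {"co_occurrence": 0, "co_exclusion": 0})
        bucket[attrs["sign"]] += 1
        total += 1
    vs = counts.get(("symbiotic", "virulent"), {}).get("co_exclusion", 0)
    frac = vs / total if total > 0 else 0.0
    return CrossClassSummary(counts, total, frac)


@dataclass
class RatioMarkerResult:
    """Per-sample log2 abundance ratio of two taxa, with a group comparison."""

    log_ratios: dict[str, float]
    medians: dict[str, float]
    statistic: float | None
    p_value: float | None


def abundance_ratio_marker(
    table: AbundanceTable,
    numerator_taxon: str,
    denominator_taxon: str,
    groups: SampleGroups | None = None,
) -> RatioMarkerResult:
    """log2((count_num + 1) / (count_den + 1)) per sample, rank-sum across groups.

    The study's validation-cohort marker is Escherichia / Bifidobacterium.
    """
    for t in (numerator_taxon, denominator_taxon):
        if t not in table.taxa:
            raise ValueError(f"taxon {t!r} not in table")
    num = table.counts[table.taxa.index(numerator_taxon)].astype(float)
    den = table.counts[table.taxa.index(denominator_taxon)].astype(float)
    lr = np.log2((num + 1.0) / (den + 1.0))
    log_ratios = dict(zip(table.samples, lr.tolist()))
    if groups is None:
        return RatioMarkerResult(log_ratios, {}, None, None)
    labels = groups.groups()
    if len(labels) != 2:
        raise ValueError("group comparison requires exactly two groups")
    vals = {
        g: np.array([log_ratios[s] for s in table.samples if groups.labels.get(s) == g])
        for g in labels
    }
    for g, v in vals.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    u, p = stats.mannwhitneyu(vals[labels[0]], vals[labels[1]], alternative="two-sided")
    medians = {g: float(np.median(v)) for g, v in vals.items()}
    return RatioMarkerResult(log_ratios, medians, float(u), float(p))
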