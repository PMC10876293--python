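"""Recovery and calibration benchmarks on synthetic cohorts.

These routines exercise the whole estimator stack against planted truth:
edge recovery on correlated cohorts, false-positive calibration on null
cohorts, the two-group virulent/symbiotic co-exclusion contrast, and
enterotype recovery. They power the numbered analysis drivers and the
acceptance checks; each takes an explicit seed and returns plain dicts.
"""

from __future__ import annotations

import numpy as np

from .correlation import bootstrap_pvalues, sparcc
from .enterotype import assign_enterotypes
from .netstats import compare_networks, cross_class_summary, summarize_network
from .network import build_network
from .simulate import SimulationConfig, simulate_counts, simulate_enterotype_table

# disjoint pairs keep the planted matrix PSD without repair shrinkage
RECOVERY_EDGES = [(0, 1, 0.8), (2, 3, -0.8), (4, 5, 0.8), (6, 7, -0.8), (8, 9, 0.8)]

# two-group design: shared positive backbone + case-only virulent/symbiotic
# co-exclusions (taxon indices follow default_taxon_names: 0-3 virulent,
# 4-9 symbiotic, the rest unannotated)
SHARED_EDGES = [(10 + 2 * k, 11 + 2 * k, 0.75) for k in range(8)]
CASE_COEXCLUSIONS = [
    (0, 4, -0.6), (0, 5, -0.6), (1, 6, -0.6), (1, 7, -0.6),
    (2, 8, -0.6), (2, 9, -0.6), (3, 4, -0.6), (3, 8, -0.6),
]


def planted_edge_recovery(
    seed: int,
    n_taxa: int = 20,
    n_samples: int = 200,
    planted=None,
    n_bootstrap: int = 1000,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> dict:
    """Build a network on one synthetic cohort and score it against truth.

    Returns recall over planted edges and the fraction of non-planted
    taxon pairs that appear as edges.
    """
    planted = RECOVERY_EDGES if planted is None else planted
    cfg = SimulationConfig(
        n_taxa=n_taxa, n_samples_per_group=n_samples, planted_edges=planted, seed=seed
    )
    table, _, _, truth = simulate_counts(cfg)
    corr = sparcc(table, seed=seed)
    corr = bootstrap_pvalues(table, corr, n_bootstrap=n_bootstrap, seed=seed)
    net = build_network(corr, table, r_min=r_min, alpha=alpha)
    found = {frozenset((u, v)) for u, v in net.edges}
    planted_pairs = {frozenset((table.taxa[i], table.taxa[j])) for i, j, _ in planted}
    n_pairs = n_taxa * (n_taxa - 1) // 2
    recall = len(found & planted_pairs) / len(planted_pairs)
    false_pairs = len(found - planted_pairs) / (n_pairs - len(planted_pairs))
    return {
        "recall": recall,
        "false_pair_rate": false_pairs,
        "n_edges": len(found),
        "n_planted": len(planted_pairs),
    }


def null_calibration(
    seed: int,
    n_taxa: int = 50,
    n_samples: int = 500,
    n_bootstrap: int = 1000,
    n_seeds: int = 10,
    r_min: float = 0.3,
) -> dict:
    """Calibration on data with no planted structure.

    Over ``n_seeds`` independent cohorts: the fraction of seeds whose
    SparCC estimate has no off-diagonal |rho| >= r_min, and (for the first
    cohort) the fraction of taxon pairs with bootstrap p < 0.05.
    """
    iu = np.triu_indices(n_taxa, k=1)
    clean = 0
    first_table = None
    first_corr = None
    for k in range(n_seeds):
        cfg = SimulationConfig(n_taxa=n_taxa, n_samples_per_group=n_samples, seed=seed + k)
        table, _, _, _ = simulate_counts(cfg)
        corr = sparcc(table, seed=seed + k)
        if np.abs(corr.rho[iu]).max() < r_min:
            clean += 1
        if k == 0:
            first_table, first_corr = table, corr
    res = bootstrap_pvalues(first_table, first_corr, n_bootstrap=n_bootstrap, seed=seed)
    p05_rate = float((res.pvalues[iu] < 0.05).mean())
    return {
        "p05_rate": p05_rate,
        "frac_seeds_without_spurious_edge": clean / n_seeds,
        "max_abs_rho_first_seed": float(np.abs(first_corr.rho[iu]).max()),
        "n_seeds": n_seeds,
    }


def two_group_contrast(
    seed: int,
    n_taxa: int = 30,
    n_samples_per_group: int = 100,
    n_bootstrap: int = 500,
) -> dict:
    """Case-only virulent/symbiotic co-exclusions through the full pipeline.

    Simulates a two-group cohort (shared positive backbone in both groups,
    negative virulent-symbiotic edges planted in the case group only),
    builds one network per group, and returns the cross-class co-exclusion
    fractions plus the edge-sign homogeneity test.
    """
    cfg = SimulationConfig(
        n_taxa=n_taxa,
        n_samples_per_group=n_samples_per_group,
        planted_edges=SHARED_EDGES,
        case_edges=CASE_COEXCLUSIONS,
        group_mode="two_group",
        seed=seed,
    )
    table, groups, annotation, _ = simulate_counts(cfg)
    fractions, summaries = {}, {}
    for gi, group in enumerate(groups.groups()):
        sub = table.subset_samples(groups.samples_in(group))
        corr = sparcc(sub, seed=seed + gi)
        corr = bootstrap_pvalues(sub, corr, n_bootstrap=n_bootstrap, seed=seed + gi)
        net = build_network(corr, sub, annotation=annotation, group=group)
        fractions[group] = cross_class_summary(net, annotation).virulent_symbiotic_coexclusion_fraction
        summaries[group] = summarize_network(net, n_samples=sub.n_samples)
    comparison = compare_networks(summaries["case"], summaries["control"])
    return {
        "case_vs_coexclusion_fraction": fractions["case"],
        "control_vs_coexclusion_fraction": fractions["control"],
        "comparison_p": comparison.p_value,
        "case_summary": summaries["case"].as_row(),
        "control_summary": summaries["control"].as_row(),
    }


def enterotype_recovery(seed: int, n_per_cluster: int = 10) -> dict:
    """Cluster-method accuracy on three planted indicator-genus communities."""
    table, truth = simulate_enterotype_table(n_per_cluster=n_per_cluster, seed=seed)
    res = assign_enterotypes(table, method="cluster")
    acc = float(np.mean([res.labels[s] == truth[s] for s in truth]))
    return {
        "accuracy": acc,
        "n_samples": len(truth),
        "mean_silhouette": res.mean_silhouette,
    }
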