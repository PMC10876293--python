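"""Enterotype assignment from genus relative abundances.

Samples are clustered on the square root of the Jensen-Shannon divergence
between their genus composition profiles using PAM (k-medoids, k=3), then
each cluster is labelled by its indicator genus: ET_B (Bacteroides),
ET_P (Prevotella), ET_F (Firmicutes, most prominently Ruminococcus — keyed
here on the Ruminococcus genus). A transparent per-sample driver rule
(argmax relative abundance among the three indicators) is also provided.
Exact concordance with the reference web classifier is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .data import AbundanceTable, relative_abundance

INDICATOR_GENERA = {"ET_B": "Bacteroides", "ET_P": "Prevotella", "ET_F": "Ruminococcus"}
JSD_EPS = 1e-12


@dataclass
class EnterotypeAssignment:
    labels: dict[str, str]  # sample -> ET_B / ET_P / ET_F
    medoids: list[int]  # sample indices of cluster medoids (cluster method)
    cluster_indicator: dict[int, str]  # cluster id -> indicator genus
    mean_silhouette: float | None
    method: str
    ties: list[str]  # samples whose driver rule was tied (driver method)


def jsd_matrix(fractions: np.ndarray) -> np.ndarray:
    """Pairwise sqrt Jensen-Shannon divergence between sample columns.

    JSD(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M), M = (P + Q)/2, natural log;
    the square root is a metric, bounded by sqrt(ln 2). Zeros are replaced
    by a small epsilon and columns renormalized.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 2:
        raise ValueError("expected a taxa x samples matrix")
    f = np.maximum(f, JSD_EPS)
    f = f / f.sum(axis=0, keepdims=True)
    n = f.shape[1]
    logf = np.log(f)
    # entropy of each column and of each pairwise mixture
    h = -(f * logf).sum(axis=0)  # H(P_a)
    d = np.zeros((n, n))
    for a in range(n):
        m = (f[:, a][:, None] + f[:, a + 1:]) / 2.0
        hm = -(m * np.log(m)).sum(axis=0)
        jsd = hm - (h[a] + h[a + 1:]) / 2.0
        d[a, a + 1:] = d[a + 1:, a] = np.sqrt(np.maximum(jsd, 0.0))
    return d


def pam_cluster(
    distances: np.ndarray, k: int = 3, seed: int | None = None
) -> tuple[list[int], np.ndarray]:
    """Deterministic PAM: greedy BUILD then SWAP to a local optimum.

    Ties are broken toward the lowest index, so the result depends only on
    the distance matrix (``seed`` accepted for interface symmetry).
    Returns (medoid indices, per-sample cluster labels in 0..k-1).
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
                    break
            if improved:
                break
    labels = np.argmin(d[:, medoids], axis=1)
    return medoids, labels


def assign_enterotypes(table: AbundanceTable, method: str = "cluster") -> EnterotypeAssignment:
    """Assign every sample to ET_B / ET_P / ET_F.

    ``cluster``: sqrt-JSD distances -> PAM(k=3) -> clusters labelled by
    matching indicator genera to clusters so that total mean indicator
    abundance is maximized (a 3x3 assignment problem).
    ``driver``: per-sample argmax of relative abundance among the three
    indicator genera (ties broken lexicographically and flagged).
    """
    present = [g for g in INDICATOR_GENERA.values() if g in table.taxa]
    if not present:
        raise ValueError(
            "table contains none of the indicator genera "
            f"{sorted(INDICATOR_GENERA.values())}"
        )
    rel = relative_abundance(table)

    if method == "driver":
        labels, ties = {}, []
        ets = sorted(INDICATOR_GENERA)  # lexicographic: ET_B, ET_F, ET_P
        for s_idx, sample in enumerate(table.samples):
            vals = {
                et: (rel[table.taxa.index(g), s_idx] if g in table.taxa else 0.0)
                for et, g in INDICATOR_GENERA.items()
            }
            top = max(vals.values())
            winners = [et for et in ets if vals[et] == top]
            if len(winners) > 1:
                ties.append(sample)
            labels[sample] = winners[0]
        return EnterotypeAssignment(labels, [], {}, None, "driver", ties)

    if method != "cluster":
        raise ValueError(f"unknown method {method!r}")
    if table.n_samples < 4:
        raise ValueError("cluster method needs at least 4 samples")
    dist = jsd_matrix(rel)
    if np.allclose(dist, 0.0):
        raise ValueError("all samples are identical; clustering is degenerate")
    medoids, cluster_ids = pam_cluster(dist, k=3)

    # mean indicator-genus abundance per cluster; maximize the 3x3 matching
    ets = list(INDICATOR_GENERA)
    score = np.zeros((3, len(ets)))
    for c in range(3):
        members = cluster_ids == c
        for e, et in enumerate(ets):
            g = INDICATOR_GENERA[et]
            score[c, e] = rel[table.taxa.index(g), members].mean() if g in table.taxa else 0.0
    rows, cols = linear_sum_assignment(-score)
    cluster_to_et = {int(r): ets[int(c)] for r, c in zip(rows, cols)}

    labels = {s: cluster_to_et[int(c)] for s, c in zip(table.samples, cluster_ids)}
    sil = None
    if len(set(cluster_ids.tolist())) > 1:
        sil = float(silhouette_score(dist, cluster_ids, metric="precomputed"))
    indicator = {c: INDICATOR_GENERA[et] for c, et in cluster_to_et.items()}
    return EnterotypeAssignment(labels, medoids, indicator, sil, "cluster", [])
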