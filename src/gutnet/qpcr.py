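"""qPCR relative quantification (delta-Ct) and marker group tests.

A target's abundance relative to total bacterial DNA follows from the
cycle-threshold difference: with amplification efficiency E per cycle,
target/total = E^-(Ct_target - Ct_all), i.e. on the log10 scale
-(delta Ct) * log10(E). E = 2 is perfect doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CtRecord, SampleGroups


@dataclass
class RelativeQuant:
    sample: str
    target: str
    log_relative_abundance: float  # log10 target-to-total ratio
    group: str | None = None


def relative_quant(record: CtRecord, efficiency: float = 2.0) -> RelativeQuant:
    """Delta-Ct normalization: log10 relative abundance = -dCt * log10(E)."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    delta_ct = record.ct_target - record.ct_all_bacteria
    value = -delta_ct * math.log10(efficiency)
    return RelativeQuant(record.sample, record.target, value)


@dataclass
class MarkerTestResult:
    target: str
    medians: dict[str, float]
    statistic: float
    p_value: float
    n_per_group: dict[str, int]


def marker_group_test(
    quants: list[RelativeQuant], groups: SampleGroups
) -> MarkerTestResult:
    """Two-sided Mann-Whitney on log relative abundances between two groups."""
    labels = groups.groups()
    if len(labels) != 2:
        raise ValueError("marker test requires exactly two groups")
    targets = {q.target for q in quants}
    if len(targets) != 1:
        raise ValueError(f"quants mix targets {sorted(targets)}; test one at a time")
    by_group: dict[str, list[float]] = {g: [] for g in labels}
    for q in quants:
        g = groups.labels.get(q.sample)
        if g is None:
            raise ValueError(f"sample {q.sample!r} has no group label")
        by_group[g].append(q.log_relative_abundance)
    for g, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    a, b = (np.asarray(by_group[g], dtype=float) for g in labels)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return MarkerTestResult(
        target=targets.pop(),
        medians={g: float(np.median(by_group[g])) for g in labels},
        statistic=float(u),
        p_value=float(p),
        n_per_group={g: len(by_group[g]) for g in labels},
    )
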