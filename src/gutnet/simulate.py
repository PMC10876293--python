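"""Synthetic compositional count tables with planted correlation structure.

The generator emulates the shape of genus-level sequencing tables: latent
absolute abundances are lognormal with a planted basis correlation matrix,
structural zeros are injected per taxon (controlling prevalence), the
latent vector is closed to proportions, and counts are drawn multinomially
at a lognormal sequencing depth. Because the depth constraint is applied
after correlating the basis, the resulting counts carry exactly the
compositional distortion that basis-correlation estimators exist to undo —
so planted edges are a fair recovery target, not a tautology.

In ``two_group`` mode a second ("case") cohort is generated in which
virulent taxa are shifted up, symbiotic taxa down, and additional negative
virulent-symbiotic basis correlations are planted only in that cohort,
mimicking the co-exclusion signature reported in carcinogenesis cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    AbundanceTable,
    SampleGroups,
    TaxonAnnotation,
    DEFAULT_SYMBIOTIC,
    DEFAULT_VIRULENT,
)

MIN_DEPTH = 100


def default_taxon_names(n_taxa: int) -> list[str]:
    """Named virulent/symbiotic genera first, then generic genus labels."""
    named = list(DEFAULT_VIRULENT) + list(DEFAULT_SYMBIOTIC)
    names = named[:n_taxa]
    names += [f"Genus{i:03d}" for i in range(len(names), n_taxa)]
    return names


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate a small shotgun cohort."""

    n_taxa: int = 30
    n_samples_per_group: int = 50
    depth_log_mean: float = float(np.log(50_000))  # ~50k reads/sample
    depth_log_sd: float = 0.4
    basis_log_mean: np.ndarray | None = None  # default: evenly graded 4 -> 0
    basis_log_sd: float | np.ndarray = 1.0
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    zero_inflation: float | np.ndarray = 0.0  # per-taxon structural dropout
    group_mode: str = "single"  # or "two_group"
    case_edges: list[tuple[int, int, float]] | None = None  # planted in case only
    case_log_fold: dict[int, float] | None = None  # latent mean shifts in case
    group_labels: tuple[str, str] = ("case", "control")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.group_mode not in ("single", "two_group"):
            raise ValueError(f"unknown group_mode {self.group_mode!r}")
        if np.exp(self.depth_log_mean) < MIN_DEPTH:
            raise ValueError("depth parameters must yield depths >= 100")
        for i, j, rho in self.planted_edges + (self.case_edges or []):
            if i == j or not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa):
                raise ValueError(f"invalid planted edge ({i},{j})")
            if abs(rho) > 0.95:
                raise ValueError("planted |rho| must be <= 0.95")
        z = np.broadcast_to(np.asarray(self.zero_inflation, float), (self.n_taxa,))
        if z.min() < 0 or z.max() >= 1:
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted structure: per-group basis correlation matrices and labels."""

    taxa: list[str]
    corr: dict[str, np.ndarray]  # group label -> planted correlation matrix
    classes: dict[str, str]
    depths: dict[str, np.ndarray]  # group label -> realized per-sample depths

    def edges(self, group: str, r_min: float = 0.0) -> list[tuple[str, str, float, str]]:
        """Planted pairs with |rho| >= r_min in a group, with signs."""
        c = self.corr[group]
        out = []
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                rho = c[i, j]
                if rho != 0.0 and abs(rho) >= r_min:
                    sign = "co_occurrence" if rho > 0 else "co_exclusion"
                    out.append((self.taxa[i], self.taxa[j], float(rho), sign))
        return out


def make_correlation_matrix(n_taxa: int, edges: list[tuple[int, int, float]]) -> np.ndarray:
    """Identity plus planted off-diagonal entries, repaired to be PSD.

    Repair clips eigenvalues at 1e-8 and renormalizes the diagonal back to 1,
    so users can plant many edges without hand-building a valid matrix.
    """
    c = np.eye(n_taxa)
    for i, j, rho in edges:
        c[i, j] = c[j, i] = rho
    vals, vecs = np.linalg.eigh(c)
    if vals.min() < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        c = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    return c


def _default_classes(taxa: list[str]) -> dict[str, str]:
    classes = {}
    for t in taxa:
        if t in DEFAULT_VIRULENT:
            classes[t] = "virulent"
        elif t in DEFAULT_SYMBIOTIC:
            classes[t] = "symbiotic"
        else:
            classes[t] = "other"
    return classes


def _simulate_group(
    corr: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    zero_p: np.ndarray,
    n_samples: int,
    depth_log_mean: float,
    depth_log_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    d = corr.shape[0]
    cov = corr * np.outer(sd, sd)
    # jitter keeps Cholesky stable after eigenvalue clipping
    chol = np.linalg.cholesky(cov + np.eye(d) * 1e-10)
    z = mean[:, None] + chol @ rng.standard_normal((d, n_samples))
    w = np.exp(z)
    drop = rng.random((d, n_samples)) < zero_p[:, None]
    w = np.where(drop, 0.0, w)
    # a sample must keep at least one taxon; restore its largest latent taxon
    dead = w.sum(axis=0) == 0
    if dead.any():
        top = np.argmax(z[:, dead], axis=0)
        w[top, np.nonzero(dead)[0]] = np.exp(z[top, np.nonzero(dead)[0]])
    p = w / w.sum(axis=0, keepdims=True)
    depths = np.maximum(
        np.round(rng.lognormal(depth_log_mean, depth_log_sd, size=n_samples)).astype(int),
        MIN_DEPTH,
    )
    counts = np.empty((d, n_samples), dtype=np.int64)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depths[s], p[:, s])
    return counts, depths


def simulate_counts(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SampleGroups, TaxonAnnotation, SyntheticTruth]:
    """Generate a count table (plus groups, annotation and planted truth)."""
    rng = np.random.default_rng(config.seed)
    d = config.n_taxa
    taxa = default_taxon_names(d)
    classes = _default_classes(taxa)

    mean = (
        np.asarray(config.basis_log_mean, float)
        if config.basis_log_mean is not None
        else np.linspace(4.0, 0.0, d)
    )
    if mean.shape != (d,):
        raise ValueError("basis_log_mean must have one entry per taxon")
    sd = np.broadcast_to(np.asarray(config.basis_log_sd, float), (d,)).copy()
    zero_p = np.broadcast_to(np.asarray(config.zero_inflation, float), (d,)).copy()

    base_corr = make_correlation_matrix(d, config.planted_edges)

    if config.group_mode == "single":
        counts, depths = _simulate_group(
            base_corr, mean, sd, zero_p, config.n_samples_per_group,
            config.depth_log_mean, config.depth_log_sd, rng,
        )
        samples = [f"S{i + 1:03d}" for i in range(config.n_samples_per_group)]
        table = AbundanceTable(taxa, samples, counts)
        groups = SampleGroups({s: "all" for s in samples})
        truth = SyntheticTruth(taxa, {"all": base_corr}, classes, {"all": depths})
        return table, groups, TaxonAnnotation(dict(classes)), truth

    case_label, control_label = config.group_labels
    case_edges = config.case_edges
    if case_edges is None:
        # default co-exclusion signature: each virulent taxon against one symbiont
        vir = [i for i, t in enumerate(taxa) if classes[t] == "virulent"]
        sym = [i for i, t in enumerate(taxa) if classes[t] == "symbiotic"]
        case_edges = [(v, s, -0.7) for v, s in zip(vir, sym)]
    case_corr = make_correlation_matrix(d, config.planted_edges + case_edges)

    case_mean = mean.copy()
    fold = config.case_log_fold
    if fold is None:
        fold = {}
        for i, t in enumerate(taxa):
            if classes[t] == "virulent":
                fold[i] = +1.5
            elif classes[t] == "symbiotic":
                fold[i] = -1.5
    for i, delta in fold.items():
        case_mean[i] += delta

    n = config.n_samples_per_group
    counts_case, depths_case = _simulate_group(
        case_corr, case_mean, sd, zero_p, n, config.depth_log_mean, config.depth_log_sd, rng
    )
    counts_ctrl, depths_ctrl = _simulate_group(
        base_corr, mean, sd, zero_p, n, config.depth_log_mean, config.depth_log_sd, rng
    )
    samples = [f"{case_label}_{i + 1:03d}" for i in range(n)] + [
        f"{control_label}_{i + 1:03d}" for i in range(n)
    ]
    table = AbundanceTable(taxa, samples, np.hstack([counts_case, counts_ctrl]))
    groups = SampleGroups(
        {s: (case_label if k < n else control_label) for k, s in enumerate(samples)}
    )
    truth = SyntheticTruth(
        taxa,
        {case_label: case_corr, control_label: base_corr},
        classes,
        {case_label: depths_case, control_label: depths_ctrl},
    )
    return table, groups, TaxonAnnotation(dict(classes)), truth


def planted_network(
    truth: SyntheticTruth, r_min: float, group: str | None = None
) -> list[tuple[str, str, float, str]]:
    """Planted edge list with signs at threshold |rho| >= r_min (inclusive)."""
    if group is None:
        group = next(iter(truth.corr))
    return truth.edges(group, r_min)


def simulate_enterotype_table(
    n_per_cluster: int = 10,
    n_other: int = 12,
    dominance: float = 8.0,
    depth: int = 20_000,
    seed: int = 0,
) -> tuple[AbundanceTable, dict[str, str]]:
    """Three planted community types, each dominated by one indicator genus.

    Returns the table and the true per-sample enterotype labels
    (ET_B = Bacteroides, ET_P = Prevotella, ET_F = Ruminococcus).
    """
    rng = np.random.default_rng(seed)
    indicators = ["Bacteroides", "Prevotella", "Ruminococcus"]
    labels = ["ET_B", "ET_P", "ET_F"]
    taxa = indicators + [f"Genus{i:03d}" for i in range(n_other)]
    d = len(taxa)
    samples, truth, cols = [], {}, []
    for c, label in enumerate(labels):
        for k in range(n_per_cluster):
            name = f"{label}_{k + 1:02d}"
            mean = np.zeros(d)
            mean[c] = np.log(dominance)
            z = mean + 0.3 * rng.standard_normal(d)
            p = np.exp(z) / np.exp(z).sum()
            cols.append(rng.multinomial(depth, p))
            samples.append(name)
            truth[name] = label
    table = AbundanceTable(taxa, samples, np.column_stack(cols))
    return table, truth
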