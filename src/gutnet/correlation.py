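"""Compositional correlation inference.

Sequencing counts are compositional: only relative information survives the
depth constraint, so Pearson correlation of raw proportions is spurious.
Two estimators are provided:

* ``clr_pearson`` — Pearson correlation of centred log-ratio (CLR)
  transformed abundances, the transparent textbook approach.
* ``sparcc`` — basis-correlation estimation from log-ratio variances with a
  sparsity assumption and iterative exclusion of strongly correlated pairs,
  the approach of the SparCC/FastSpar tools. This is the default.

Significance comes from a bootstrap null that permutes each taxon's counts
independently across samples, destroying associations while preserving the
marginal count distribution of every taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AbundanceTable

OMEGA_FLOOR = 1e-8  # clamp for negative basis-variance solutions


def _unchecked_table(taxa: list[str], samples: list[str], counts: np.ndarray) -> AbundanceTable:
    # bootstrap-internal: permuted counts may transiently violate the
    # no-all-zero-column invariant, which the estimators tolerate
    t = object.__new__(AbundanceTable)
    t.taxa = taxa
    t.samples = samples
    t.counts = counts
    return t


@dataclass
class FractionEstimate:
    """Strictly positive per-sample proportions (zeros resolved)."""

    fractions: np.ndarray  # (n_taxa, n_samples), columns sum to 1
    method: str
    pseudocount: float

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size and f.min() <= 0:
            raise ValueError("fractions must be strictly positive")
        colsums = f.sum(axis=0)
        if f.size and np.max(np.abs(colsums - 1.0)) > 1e-9:
            raise ValueError("fraction columns must sum to 1")
        self.fractions = f


@dataclass
class CorrelationResult:
    """Symmetric taxon-taxon correlation matrix with optional bootstrap p-values."""

    taxa: list[str]
    rho: np.ndarray
    method: str
    pvalues: np.ndarray | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    params: dict = field(default_factory=dict)
    zero_variance_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        d = len(self.taxa)
        if rho.shape != (d, d):
            raise ValueError("rho shape does not match taxa")
        if np.max(np.abs(rho - rho.T)) > 1e-12:
            raise ValueError("rho must be symmetric")
        self.rho = rho


def estimate_fractions(
    table: AbundanceTable,
    method: str = "pseudocount",
    pseudocount: float = 1.0,
    rng: np.random.Generator | None = None,
) -> FractionEstimate:
    """Resolve zero counts into strictly positive proportions.

    ``pseudocount``: f = (count + c) / (depth + D*c), deterministic.
    ``dirichlet``: one draw from Dirichlet(count + 1) per sample (the SparCC
    convention); requires ``rng``.
    """
    counts = table.counts.astype(float)
    if method == "pseudocount":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        f = (counts + pseudocount) / (counts.sum(axis=0, keepdims=True) + table.n_taxa * pseudocount)
    elif method == "dirichlet":
        if rng is None:
            rng = np.random.default_rng()
        g = rng.standard_gamma(counts + 1.0)
        # guard against underflow for very sparse high-dimensional samples
        g = np.maximum(g, 1e-300)
        f = g / g.sum(axis=0, keepdims=True)
        f = np.maximum(f, 1e-12)
        f = f / f.sum(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown zero-handling method {method!r}")
    return FractionEstimate(f, method, pseudocount)


def clr_transform(fractions: FractionEstimate | np.ndarray) -> np.ndarray:
    """Centred log-ratio: log f minus the per-sample mean of log f.

    Each column of the result sums to 0.
    """
    f = fractions.fractions if isinstance(fractions, FractionEstimate) else np.asarray(fractions, float)
    if f.size and f.min() <= 0:
        raise ValueError("CLR requires strictly positive fractions")
    logf = np.log(f)
    return logf - logf.mean(axis=0, keepdims=True)


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlations; zero-variance rows get rho 0 off-diagonal.

    Returns (rho, zero_variance_mask).
    """
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    zero = sd < 1e-300
    sd_safe = np.where(zero, 1.0, sd)
    r = (xc @ xc.T) / np.outer(sd_safe, sd_safe)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), zero


def clr_pearson(
    table: AbundanceTable,
    method: str = "pseudocount",
    pseudocount: float = 1.0,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """Pearson correlation across samples of CLR-transformed abundances."""
    if table.n_samples < 3:
        raise ValueError("clr_pearson requires at least 3 samples")
    fractions = estimate_fractions(table, method=method, pseudocount=pseudocount, rng=rng)
    z = clr_transform(fractions)
    rho, zero = _pearson_matrix(z)
    return CorrelationResult(
        taxa=list(table.taxa),
        rho=rho,
        method="clr_pearson",
        params={"zero_method": method, "pseudocount": pseudocount},
        zero_variance_taxa=[table.taxa[i] for i in np.nonzero(zero)[0]],
    )


def variation_matrix(fractions: FractionEstimate | np.ndarray) -> np.ndarray:
    """T[i,j] = unbiased sample variance over samples of log(f_i / f_j).

    Computed from the covariance of log fractions:
    Var(log f_i - log f_j) = Var(log f_i) + Var(log f_j) - 2 Cov(log f_i, log f_j).
    """
    f = fractions.fractions if isinstance(fractions, FractionEstimate) else np.asarray(fractions, float)
    if f.shape[1] < 3:
        raise ValueError("variation matrix requires at least 3 samples")
    if f.min() <= 0:
        raise ValueError("fractions must be strictly positive")
    logf = np.log(f)
    cov = np.cov(logf)  # unbiased, ddof=1
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum((t + t.T) / 2.0, 0.0)
    np.fill_diagonal(t, 0.0)
    return t


def _sparcc_system(t_mat: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    """Solve for basis variances given the variation matrix and excluded pairs."""
    d = t_mat.shape[0]
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_vec = t_mat.sum(axis=1)
    for i, j in excluded:
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
    omega = np.linalg.solve(m, t_vec)
    return np.maximum(omega, OMEGA_FLOOR)


def basis_variances(t_mat: np.ndarray) -> np.ndarray:
    """Sparsity-approximation basis variances from a variation matrix.

    Solves M w = t with t_i = sum_{j != i} T[i,j] and M = (D-2) I + 1 (the
    all-ones matrix); negative solutions are clamped to a small floor.
    Requires D >= 4 (the system is ill-posed below).
    """
    d = t_mat.shape[0]
    if d < 4:
        raise ValueError("basis variance estimation requires at least 4 taxa")
    return _sparcc_system(t_mat, set())


def basis_correlations(t_mat: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """rho[i,j] = (w_i + w_j - T[i,j]) / (2 sqrt(w_i w_j)), clipped to [-1, 1]."""
    omega = np.asarray(omega, dtype=float)
    if omega.min() <= 0:
        raise ValueError("basis variances must be positive")
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - t_mat) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_single(
    t_mat: np.ndarray,
    n_exclusion_iter: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """One SparCC estimate: iterative strong-pair exclusion on a variation matrix."""
    d = t_mat.shape[0]
    excluded: set[tuple[int, int]] = set()
    omega = _sparcc_system(t_mat, excluded)
    rho = basis_correlations(t_mat, omega)
    iu = np.triu_indices(d, k=1)
    for _ in range(n_exclusion_iter):
        vals = np.abs(rho[iu])
        order = np.argsort(-vals, kind="stable")  # ties: lowest pair index first
        pick = None
        for k in order:
            if vals[k] <= exclusion_threshold:
                break
            pair = (int(iu[0][k]), int(iu[1][k]))
            if pair not in excluded:
                pick = pair
                break
        if pick is None:
            break
        excluded.add(pick)
        # stop excluding if some taxon would lose nearly all its pairs
        per_taxon = np.zeros(d, dtype=int)
        for i, j in excluded:
            per_taxon[i] += 1
            per_taxon[j] += 1
        if per_taxon.max() >= d - 3:
            break
        omega = _sparcc_system(t_mat, excluded)
        rho = basis_correlations(t_mat, omega)
    return rho


def sparcc(
    table: AbundanceTable,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    n_estimates: int = 20,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationResult:
    """SparCC basis correlations: median over Dirichlet-resampled estimates.

    Each estimate draws fractions from Dirichlet(count + 1), computes the
    log-ratio variation matrix, and runs the iterative exclusion loop; the
    final matrix is the element-wise median over estimates.
    """
    if table.n_taxa < 4:
        raise ValueError("sparcc requires at least 4 taxa")
    if table.n_samples < 3:
        raise ValueError("sparcc requires at least 3 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    estimates = np.empty((n_estimates, table.n_taxa, table.n_taxa))
    for e in range(n_estimates):
        frac = estimate_fractions(table, method="dirichlet", rng=rng)
        t_mat = variation_matrix(frac)
        estimates[e] = _sparcc_single(t_mat, n_exclusion_iter, exclusion_threshold)
    rho = np.median(estimates, axis=0)
    rho = (rho + rho.T) / 2.0
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationResult(
        taxa=list(table.taxa),
        rho=rho,
        method="sparcc",
        seed=seed,
        params={
            "n_exclusion_iter": n_exclusion_iter,
            "exclusion_threshold": exclusion_threshold,
            "n_estimates": n_estimates,
        },
    )


def _recompute(table: AbundanceTable, observed: CorrelationResult, rng: np.random.Generator) -> np.ndarray:
    if observed.method == "sparcc":
        p = observed.params
        return sparcc(
            table,
            n_exclusion_iter=p.get("n_exclusion_iter", 10),
            exclusion_threshold=p.get("exclusion_threshold", 0.1),
            n_estimates=p.get("n_estimates", 20),
            rng=rng,
        ).rho
    if observed.method == "clr_pearson":
        p = observed.params
        return clr_pearson(
            table,
            method=p.get("zero_method", "pseudocount"),
            pseudocount=p.get("pseudocount", 1.0),
            rng=rng,
        ).rho
    raise ValueError(f"unknown correlation method {observed.method!r}")


def bootstrap_pvalues(
    table: AbundanceTable,
    observed: CorrelationResult,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    null: str = "permute",
) -> CorrelationResult:
    """Two-sided bootstrap p-values for an observed correlation matrix.

    Each round independently permutes every taxon's counts across samples
    (``null="permute"``, the FastSpar behaviour: associations are destroyed,
    per-taxon margins preserved) or resamples samples with replacement
    (``null="resample"``), recomputes the correlation matrix by the same
    method, and applies the add-one rule
    p = (1 + #{|rho_b| >= |rho_obs|}) / (n_bootstrap + 1), so p is in (0, 1].
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if null not in ("permute", "resample"):
        raise ValueError(f"unknown null {null!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed.rho)
    exceed = np.zeros_like(abs_obs)
    counts = table.counts
    d, n = counts.shape
    for _ in range(n_bootstrap):
        if null == "permute":
            perm = np.argsort(rng.random((d, n)), axis=1)  # independent row permutations
            shuffled = np.take_along_axis(counts, perm, axis=1)
        else:
            cols = rng.integers(0, n, size=n)
            shuffled = counts[:, cols]
        boot_table = _unchecked_table(list(table.taxa), list(table.samples), shuffled)
        rho_b = _recompute(boot_table, observed, rng)
        exceed += np.abs(rho_b) >= abs_obs - 1e-15
    pvals = (1.0 + exceed) / (n_bootstrap + 1.0)
    pvals = (pvals + pvals.T) / 2.0
    np.fill_diagonal(pvals, 1.0)
    return CorrelationResult(
        taxa=list(observed.taxa),
        rho=observed.rho,
        method=observed.method,
        pvalues=pvals,
        n_bootstrap=n_bootstrap,
        seed=seed,
        params=dict(observed.params, null=null),
        zero_variance_taxa=list(observed.zero_variance_taxa),
    )
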