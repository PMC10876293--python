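# Methods

## Scope and design

`gutnet` implements a cohort-comparison workflow for microbial
co-occurrence structure: genus-count tables in, per-cohort signed networks
and their descriptive statistics out, plus enterotype assignment and a
ΔCt qPCR marker stage. Each stage lives in the library (`src/gutnet/`);
the `analysis/` drivers narrate the study-style runs and the `gutnet` CLI
exposes every stage as a subcommand.

## Correlation estimation

Two estimators are provided because the field describes SparCC loosely as
"Pearson on CLR" while the tools implement basis-correlation estimation;
we implement both and default to `sparcc`.

**CLR-Pearson.** Fractions by pseudocount (default 1):
f = (count + c)/(depth + D·c); CLR per sample: log f − mean(log f);
Pearson across samples. A taxon with zero variance after CLR gets
correlation 0 and is flagged (`zero_variance_taxa`), since its correlation
is undefined.

**SparCC.** Per estimate: one Dirichlet(count + 1) fraction draw; the
variation matrix T_ij = Var(log f_i/f_j) computed from the covariance of
log fractions (unbiased, n−1 — implementations differ here, so it is
stated); basis variances from M ω = t with M = (D−2)I + **1**; basis
correlations ρ_ij = (ω_i + ω_j − T_ij)/(2√(ω_i ω_j)), clipped to [−1, 1].
The exclusion loop removes, up to 10 times, the not-yet-excluded pair with
the largest |ρ| above 0.1 from the t-sums (decrementing M accordingly) and
re-solves; it stops early when any taxon would retain fewer than three
partners. The final matrix is the element-wise **median** over 20 draws
(median, not mean: robust to outlier draws). Negative ω solutions are
clamped to 1e-8. Estimation requires D ≥ 4; the linear system is ill-posed
below.

The iteration/exclusion/estimate counts are tool conventions, exposed as
parameters; they are not facts about any particular dataset.

**Bootstrap significance.** Each round permutes every taxon's counts
independently across samples — associations are destroyed while each
taxon's marginal count distribution is preserved — and recomputes the same
estimator with the same parameters. Two-sided add-one rule:
p = (1 + #{|ρ_b| ≥ |ρ_obs|})/(B + 1), so p ∈ (0, 1] and p = 0 is
impossible. Default B = 1000. Resampling samples with replacement is
available behind `null="resample"`; permutation is the default because it
is what the reference tooling does. p-values are symmetrized and the
diagonal fixed at 1.

## Network construction

Edge gate: p < α (strict) **and** |ρ| ≥ r_min (inclusive — the interval
convention "−1 to −0.3, +0.3 to +1" reads as closed; no boundary case is
observable at 2-decimal reporting, so the choice is documented rather than
empirical). Defaults r_min = 0.3, α = 0.05 with **raw** p-values; a
Benjamini–Hochberg option exists but is off by default, matching the
stated per-edge rule of the study design this mirrors. Isolated taxa are
dropped by default so node counts mean "taxa shown in the network";
`retain_isolated=True` keeps them. Nodes carry mean relative abundance
(the rendering size attribute), prevalence, and annotation class; GraphML
export colors co-occurrence red and co-exclusion blue.

Prevalence = fraction of samples with count > 0; `filter_by_prevalence`
keeps taxa at or above the threshold (inclusive: 6/19 = 31.6% passes a 30%
filter, 5/19 = 26.3% does not).

## Summary statistics and comparison

`summary_from_counts` / `summarize_network` produce the descriptive row
(nodes, correlations, co-occurrences, co-exclusions,
co-occurrence/co-exclusion ratio, sign fractions). Ratios are rounded
half-away-from-zero to 2 decimals for reporting; exact values are kept
alongside. The ratio is *undefined* (None), not infinity, when there are
no co-exclusions. Two of the published cells this package's desk checks
target (1.72 for 666/386 = 1.7254; 5.18 for 87/17 = 5.1176) disagree with
any rounding of their own counts; we treat them as printing artifacts and
report the recomputed values (1.73, 5.12).

Cohort comparison: Pearson chi-square without continuity correction on the
2×2 co-occurrence/co-exclusion table. The source tables never name their
test, but this choice reproduces all four of their printed comparison
p-values (1.9e-23 ≤ 2.2e-22, 0.6625, 0.01687, 0.00726) from the printed
counts, which is as strong an identification as the desk data allow. Yates
and Fisher variants are exposed; Fisher is required when a margin is zero.

Cross-class structure: each edge is binned by the unordered annotation
class pair of its endpoints; the virulent/symbiotic co-exclusion fraction
is that bin's co-exclusion count over all edges (0 for an empty network).
Unannotated taxa default to class "other" — the study style annotates only
selected genera.

## Synthetic cohorts

The generator is the package's test bed and defines its study conditions.
Per sample: latent log-basis abundances from a multivariate normal with a
planted correlation matrix (graded means, default log-abundance 4 → 0
across taxa, unit log-SD); exponentiation; per-taxon structural dropout
(zero inflation) applied *before* closure, because prevalence filters
address exactly such structural zeros; closure to proportions; multinomial
counts at a lognormal depth (default mean ≈ 50,000 reads, log-SD 0.4,
floor 100). Column sums equal realized depths exactly. Planted matrices
are repaired to PSD by eigenvalue clipping at 1e-8 and diagonal
renormalization, so users can plant arbitrary edge sets; repair can leave
small off-target correlations, which is why recovery benchmarks plant
disjoint pairs (block-diagonal, no repair needed) and why the truth object
exposes a threshold when listing planted edges. Two-group mode adds
case-only negative virulent–symbiotic edges (default −0.7, one per
virulent genus) and shifts case means (+1.5 virulent, −1.5 symbiotic in
log units — roughly a 4.5-fold change, the magnitude of dysbiosis the
marker stage is meant to detect). All draws flow from one seeded
generator; identical seeds give bit-identical tables.

What the generator does **not** emulate: phylogenetic correlation between
related genera, overdispersion beyond lognormal-multinomial, batch or
primer effects, and read-level error. Passing recovery tests therefore
shows the estimator stack is correct under compositional closure, uneven
depth and zero inflation — not that real cohorts of this size would yield
the same power.

**Benchmark problem sizes** (the package's own choices, stated so results
are interpretable): planted-edge recovery uses 20 taxa × 200 samples with
five disjoint |ρ| = 0.8 edges and 1000 bootstraps; null calibration uses
50 taxa × 500 samples over 10 seeds (point estimates) plus one
1000-round bootstrap; the two-group contrast uses 30 taxa × 100
samples/group with an 8-edge shared positive backbone and 8 case-only
co-exclusions at −0.6, 500 bootstraps. The backbone exists so the control
network is non-empty and the 2×2 sign-composition test is defined; 8 + 8
edges is the smallest design whose expected chi-square p is comfortably
below 0.05.

## Enterotypes

Distances: square root of the Jensen–Shannon divergence (natural log)
between per-sample genus profiles, zeros replaced by 1e-12 and columns
renormalized; sqrt-JSD is a metric bounded by √ln 2, following the
original enterotyping convention. Clustering: PAM with k fixed at 3 (the
three canonical enterotypes; silhouette is reported, not used for model
selection), deterministic BUILD + first-improvement SWAP with
lowest-index tie-breaks. Cluster labels: the 3×3 assignment of indicator
genera (Bacteroides → ET_B, Prevotella → ET_P, Ruminococcus → ET_F) to
clusters that maximizes total mean indicator abundance (Hungarian
algorithm), which reduces to "each cluster gets the indicator it is
richest in" whenever the clusters are well separated. ET_F canonically
denotes Firmicutes over-representation; we key on the Ruminococcus genus,
its most prominent member, since the package operates at genus rank. The
original web classifier is not reimplemented and exact concordance with it
is not claimed; the transparent `driver` rule (per-sample argmax among the
three indicators, lexicographic tie-break, ties flagged) is provided for
auditability.

## qPCR markers

log10 relative abundance = −ΔCt · log10(E), ΔCt = Ct_target − Ct_all.
Efficiency E defaults to 2.0 (perfect doubling) and is a parameter because
calibration curves are lab-specific. The quantity is invariant to adding a
constant to both Cts and strictly monotone in each. Group comparison:
two-sided Mann–Whitney on the log values — a nonparametric default
appropriate for qPCR log ratios; no distributional claim is made. Only
relative (ΔCt-based) quantities are reported; absolute per-gram
quantification would need standard-curve constants that are not part of
the package's inputs. Count-based marker ratios (`abundance_ratio_marker`)
use log2((n+1)/(d+1)) with the +1 guarding zeros.

## Numerical choices and degenerate inputs

- Fractional counts are rejected, not rounded; all-zero sample columns are
  an error (they carry no compositional information and would corrupt
  prevalence and CLR).
- Dirichlet draws guard against gamma underflow (floor 1e-300, fraction
  floor 1e-12 then renormalize).
- Correlations and p-value matrices are explicitly symmetrized; diagonals
  pinned to 1.
- PAM on an all-zero distance matrix (identical samples) raises instead of
  returning an arbitrary 3-way split.
- Comparison of networks with an empty edge set raises; the chi-square
  refuses zero column margins and points to Fisher.
- The pipeline derives each group's RNG stream from the run seed plus the
  group index: groups are independent but the whole run is reproducible
  from one integer.

## Known limitations

- SparCC's sparsity assumption fails for densely correlated communities;
  the exclusion loop mitigates but does not remove the bias.
- Permutation bootstrap tests the no-association null per pair; it does
  not control family-wise error (by design, matching the per-edge rule;
  the FDR flag exists for stricter use).
- Enterotype labels depend on the indicator-genus convention; cohorts
  where none of the three indicators is present are rejected rather than
  guessed.
- Printed-count desk checks validate arithmetic and the comparison test,
  not the upstream profiling pipeline that produced those counts.
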