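# Methods

This note documents the models, conventions and design choices behind
`germeval`, in the order the pipeline applies them.

## Trait scheme and encoding

A descriptor scheme is an ordered list of traits, each either categorical
(with an ordered list of nominal class labels) or quantitative (with units
and a recording precision). The bundled default is the 17-trait IPGRI
cardamom scheme: 15 categorical descriptors (49 classes in total) and two
quantitative ones, cluster internodal length (cm, recorded to 0.1) and
capsules per cluster (integer counts).

Quantitative traits are stratified into **ten sigma-bin levels**: with trait
mean X̄ and sample SD σ, cut point k (k = 1..9) sits at X̄ + (−2 + 0.5(k−1))σ.
Level 1 is x < X̄ − 2σ, level 10 is x ≥ X̄ + 2σ, and interior levels are
half-open [lower, upper) intervals of width 0.5σ. The left-closed interior
convention is forced by the published endpoint definitions (strict `<` at
the bottom, `≥` at the top) and makes the levels a complete partition; a
value exactly at X̄ falls in level 6. The SD uses the n−1 denominator, the
default of the mainstream statistics packages this workflow is normally run
in. A constant trait has no scale and raises a degenerate-scale error where
a binning is explicitly requested; profile-style summaries instead collapse
such a trait to a single central level (H′ = 0), which is the informative
answer for a subset with no variation.

Every trait is expanded to 0/1 class indicators, one column per (trait,
class) pair, quantitative traits contributing their ten levels. All classes
are kept (no reference-category dropping): the downstream covariance PCA and
pseudoinverse-based checks tolerate the resulting block collinearity, and
keeping all classes makes the loadings table directly readable per class.
The default scheme therefore yields 69 indicator columns, and every row sums
to exactly 17. Two near-duplicate descriptors (panicle branching
presence/absence and branching pattern) are both retained, as the descriptor
catalogue lists them separately; their collinearity is tolerated downstream.
Missing values are rejected at load time rather than imputed — the workflow
targets complete descriptor scoring.

## Shannon–Wiener diversity

H′ = −Σᵢ Pᵢ ln Pᵢ over a trait's class counts, in nats, with zero-count
classes contributing nothing (0·ln 0 := 0). The implementation uses
compensated summation and is tested against a direct high-precision oracle
to 1e-12. Comparisons to two-decimal published values use ±0.005.

Subset-average diversity (used for conservation accounting) is the mean of
the 17 per-trait H′ values computed **on the subset only**, with quantitative
bins refit on the subset — consistent with the second-stage analysis being a
fresh run. Note that the standard coefficient of variation
CV% = 100·SD/mean is reported for quantitative traits; published CV values
for this kind of survey are not always consistent with that definition, and
this package always computes the standard one.

## Covariance PCA

PCA is run on the **covariance** matrix of the raw 0/1 indicators (no
correlation scaling), sample covariance with n−1. Eigenvalues are sorted
descending; each eigenvector's sign is fixed so its largest-magnitude
loading is positive. The sign convention matters: it is applied *before*
membership rescaling, making the downstream F-values bit-reproducible (a
sign flip would map u → 1 − u and change F). Within a degenerate eigenspace
(tied eigenvalues, e.g. the zero tail produced by one-hot collinearity) the
eigenvectors are only defined up to rotation; tests therefore compare
leading well-separated components only. Tiny negative eigenvalues from
roundoff are clipped to zero.

Component selection keeps the leading run of components whose contribution
rates cⱼ = 100·λⱼ/Σλ are all ≥ 6% (falling back to the top 3 when the run is
empty), or a fixed top-k. On indicator data the eigenvalue spectrum is flat,
so small draws select 2–3 components; both policies are exposed.

## Composite F-value

The composite evaluation follows the membership-function lineage used for
germplasm scoring: per selected component, u = (S − min S)/(max S − min S);
weights are the selected components' contribution rates normalized **over
the selection** (so F spans [0, 1]; normalizing over all components is
available as an option and shrinks the range); F = Σⱼ wⱼuⱼ. A degenerate
component (all scores equal) maps to u = 0.5 with a warning. Ranking is a
strict permutation: descending F with ties broken by ascending accession id.

Because u is affine in the scores and the scores are affine in the
indicators, F is an exact affine function of the indicator columns — the
package's strongest internal consistency check (full-design OLS R² ≥
1 − 1e-9), and the reason stepwise regression on F can reach near-perfect
fits.

## Stepwise selection equation

Classic forward/backward stepwise OLS: at each step the candidate with the
smallest partial-F p-value enters if p < entry α (default 0.05, removal
α = 0.10 — the conventional defaults of the statistics suites this procedure
comes from); after each entry, included terms with p > removal α are pruned,
worst first. Partial F compares residual sums of squares, with p from the
F(1, df) distribution. Perfectly collinear candidates (no rank increase) are
dropped with a warning — unavoidable with complete one-hot blocks, where
each trait's last class is implied by the others. Entry stops once the fit
is numerically perfect (RSS below 1e-12 of the total sum of squares).

Two statistical caveats are deliberate: per-term entry testing at α means
the *family-wise* probability of admitting at least one noise term grows
with the candidate count (≈ 1 − 0.95^m), so null-behavior guarantees are
only meaningful for small candidate pools; and greedy stepwise is not
guaranteed to match the best subset of equal size in adversarial designs —
tests verify agreement on well-conditioned random designs.

## Hierarchical grouping

Unweighted average linkage (UPGMA, the "between-groups" method) on plain
Euclidean distances over the selected PC scores. Rows are canonicalized by
ascending accession id before linkage, so the dendrogram and every cut are
exactly invariant to input row order. `cut_k` produces exactly k groups,
labeled 1..k in order of first appearance among the sorted leaves. k = 6 is
a configuration default replicating the reference study design, not an
inferred optimum; no automatic k selection is attempted. Group profiles
report within-group class percentages (quantitative traits over their ten
levels, bins fit on the full table) and flag dominance at ≥ 80%. The
dendrogram exports to Newick with merge heights as node depths.

## Varieties and two-stage conservation selection

The stature rule maps height classes "<2 m" and "2-3 m" to 'Malabar' and
">3 m" to 'Mysore'/'Vazhukka' (the class boundaries leave no ambiguity at
exactly 3 m). The capsule rule maps light green/yellow to 'Malabar' and
green/dark green to 'Mysore'/'Vazhukka'. The two rules' agreement rate is
reported, never assumed.

Stage 1 is the overall top-k1 (default 14) by composite F. Stage 2 re-runs
the **entire** analysis on the height-defined tall subset — fresh binning,
fresh PCA, fresh membership — because the second-stage evaluation is a
separate analysis of that subset, and takes the top-k2 (default 12) ids not
already selected; duplicates are skipped rather than counted, so the union
is exactly k1 + k2 = 26. The report carries per-cluster-group counts,
coverage against a minimum per group (default 2), and the subset-average H′
of stage 1 and of the union. Union H′ ≥ stage-1 H′ is *not* a theorem
(entropy is not monotone under subset growth); under generator defaults the
direction holds in ≥ 80% of seeded replicates, which is asserted
statistically, not pointwise.

## Synthetic generator

Defaults reproduce the reference survey conditions: n = 288; categorical
classes drawn independently per accession from the survey's marginal
frequencies (bundled in `germeval.reference`); quantitative traits from
normals matching the published mean/SD (internodal length 2.79/1.55 cm,
capsules per cluster 10.75/3.74), truncated by rejection to the published
[min, max] ([0.5, 18] and [3, 25]) and rounded to recording precision. In
multi-group mode, accessions are assigned uniformly to groups and each
group's class probabilities are drawn from Dirichlet(c·p_marginal), where
the concentration c controls divergence: c = 0.5 gives near-degenerate,
strongly separated groups (used for clustering-recovery tests at Rand index
≥ 0.9); large c approaches the single-group model. Quantitative parameters
are shared across groups — separation is carried by the categorical traits.

What passing tests on this generator do and do not show: they validate the
machinery (encoding, eigenstructure, ranking, selection logic, determinism)
under realistic marginal frequencies, but single-group draws have
independent traits, so the PCA spectrum is flatter and the group structure
weaker than in real collections, where traits co-vary through shared
ancestry and environment. Results on real data will show stronger leading
components and cleaner groups than the defaults suggest.

## Problem sizes and numerical conventions

Tests and the acceptance suite run at the study's own scale — 288
accessions, 69 indicators — which completes in seconds; replicate-based
checks use 50–100 seeded replicates. Eigendecomposition uses a dense
symmetric solver; oracle comparisons use an independent SVD route (1e-10)
and a quadratic-scan UPGMA (1e-10). All randomness flows through
`numpy.random.default_rng(seed)`; every simulation in tests and scripts is
seeded, and pipeline outputs are byte-identical across reruns at a fixed
seed and configuration.

## Known limitations

* Nominal classes only: no ordinal distance semantics in the descriptors.
* No factor rotation, robust/sparse PCA, or alternative linkages.
* Stepwise inference is entry/removal partial-F only; no post-selection
  inference, no regularized alternatives.
* The generator does not model trait–trait dependence within groups,
  geographic origin, or measurement error.
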