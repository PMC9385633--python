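# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical choices that affect results, and
what the synthetic benchmarks do and do not demonstrate.

## Cohort harmonization

Multiple cohorts are merged on the intersection of their gene identifiers
(output order is lexicographic, so results do not depend on input order).
Under the default `quantile` method every column is quantile-normalized onto
the pooled reference distribution — the rank-wise mean of all sorted columns
— and genes are then median-centered across the merged matrix. This removes
platform-level location/scale differences while preserving within-cohort
rank structure; a cohort that is a constant shift of another becomes
distributionally identical to it. `median-center` and `none` are available
for data already co-normalized. A single-cohort call only median-centers,
which makes the harmonized output an exact fixed point of re-harmonization.
Note that re-splitting an already harmonized matrix by cohort label and
re-quantile-normalizing is *not* an exact identity: gene-median centering
breaks the equal-column-distribution property that quantile normalization
creates. Gene identifiers are opaque strings; no aliasing service is
consulted (the tool runs offline).

Duplicate gene rows collapse by per-gene maximum, the common microarray
convention when multiple probes map to one symbol.

## Robust PCA (principal component pursuit)

The harmonized matrix M is split as M = L + S by minimizing
‖L‖\* + λ‖S‖₁, solved with the inexact augmented-Lagrangian iteration
(singular-value thresholding alternating with entrywise shrinkage,
μ increased geometrically). Defaults: λ = 1/√max(n, m) — the standard PCP
choice, exact recovery for incoherent low-rank plus sparse corruption —
tol 1e-7 on ‖M − L − S‖_F/‖M‖_F, max 500 iterations (non-convergence is
flagged, not raised).

The `objective_history` diagnostic records the merit of the *feasible* pair
(L_t, M − L_t), an upper bound on the constrained optimum. The raw objective
evaluated on the iterates themselves is not monotone (early iterates are
far from feasible, so ‖L‖\* + λ‖S‖₁ is meaningless there); the feasible
merit decreases monotonically to numerical precision and is what the
convergence test asserts.

Caveat: when the low-rank structure is itself sparse-supported (as in the
synthetic cohorts, where each latent component loads on a disjoint gene
block), PCP's incoherence assumption is violated and the optimizer may
legitimately route spiky structured entries into S. L still captures the
latent subspace; S should be read as "aberrant entries", not "pure noise".

## ICA with a smoothed-density contrast

ICA is run in gene space: rows (genes) are observations, and each sample
profile is a mixture of independent gene-contribution sources. After
whitening to `n_components` dimensions (default: the number of principal
components explaining 80% of the variance of L), an orthogonal rotation is
sought by a symmetric fixed-point iteration.

The smoothed-density contrast models each source as a tilted Gaussian
f(s) = φ(s)·exp(g(s)) with g a cubic B-spline (30 basis functions) fitted to
binned counts (120 bins) by penalized Poisson regression (second-difference
penalty, λ = n^(1/3)). The score ψ = (log f)′ = −s + g′(s) then adapts to
the actual source distribution; the Gaussian carrier keeps the log-density
linear in the tails where data are sparse. The penalty scaling was chosen
from a generic sweep on Laplace-source benchmarks; performance is flat
across an order of magnitude around it.

The contrast is applied as a **two-stage estimator**: a robust logcosh
fixed point first locates the separating rotation, then the spline score
refines it. The refinement recovers the efficiency of a density-adapted
score; running the data-driven score from random starts instead can create
spurious attractors for spike-at-zero (sparse) sources — on such data all
random restarts were observed to converge to a 45° mixture of two sparse
components, a configuration with far *lower* kurtosis than the true sources.
`contrast="logcosh"` selects the plain fixed point.

Restart r is seeded with `seed + r`; restarts are aggregated by greedy
|Pearson| matching of contribution vectors against the first restart (ties
broken by component index), with the consensus taken as the centrotype (the
member with the highest mean within-cluster |r|) and `restart_stability`
reported per component. Contribution columns are scaled to unit variance;
the mixing matrix is the least-squares readout of the centered data on the
contributions.

At n = 500 with 3 Laplace sources the mean Amari index is ≈ 0.04 — the
finite-sample limit for this contrast class (FastICA-logcosh measures the
same). Individual instances fluctuate around it, which is why identifiability
checks average over seeded replicates rather than scoring one draw.

## Component selection and orientation

A component is selected when |excess kurtosis| ≥ 3 (population definition,
4th standardized moment − 3; 0 for a Gaussian) *and* at least one gene set
reaches FDR ≤ 0.05 in pre-ranked enrichment of its contribution vector. The
kurtosis cutoff of 3 corresponds to a Laplace-or-heavier tail; both gates
are configurable since "high kurtosis" admits no universal constant.
Orientation flips a component (contributions and mixing together) so a
chosen reference signature is positively enriched; the flip is recorded and
re-application is a no-op.

## Pre-ranked enrichment and the two-tailed weight

ES is the signed extreme of the weighted Kolmogorov–Smirnov running sum:
genes sorted by decreasing score (ties broken by stable gene-id order), hits
increment by |score|^p normalized over the set (p = 1 by default, the classic
weighted statistic), misses decrement uniformly. The running sum divides by
its own final cumulative hit weight, so a set occupying the top of the
ranking scores exactly 1 in floating point. Significance uses gene-label
permutation (random same-size sets; pre-ranked inputs have no phenotype
labels to permute), default 1000 draws: p is the same-sign tail fraction
with add-one smoothing, NES = ES / mean |ES\*| over same-sign permutation
scores, and BH FDR is applied across a collection.

The two-tailed regulon variant computes ES separately for the activated and
repressed targets and reports dES = ES⁺ − ES⁻ ∈ [−2, 2]. A regulon with one
empty mode is scored one-sided, sign-adjusted and flagged. Under random
target placement dES centers on zero but a single draw fluctuates at
O(1/√k); the |dES| ≥ 1 selection gate sits far outside this null spread for
realistic regulon sizes.

## Mutual information and network inference

The default MI estimator bins both variables into ⌈√(n/5)⌉ equal-frequency
bins and evaluates the plug-in MI of the contingency table. Because
equal-frequency binning fixes the margins, each cell count is
hypergeometric under independence, so the *exact* expected plug-in MI under
the permutation null has a closed form; the estimator subtracts it (then
clips at 0). This removes the O(cells/2n) plug-in bias — ~0.1 nats at
n = 10⁵, two orders above the estimator's own noise — while staying
deterministic. Exact symmetry in the arguments is enforced by canonicalizing
the argument order before summation (float addition is order-sensitive at
1 ulp). A Gaussian-copula closed-form estimator (−½·ln(1−ρ²) on normal
scores) is available as `estimator="gaussian"`.

Candidate TF–target edges are tested against a sample-label permutation
null. Since the binning is rank-based, the null distribution of the plug-in
MI depends only on (n, margins) and is shared by every pair; one null of
`n_perm` draws (default 1000) serves the whole matrix. This is exact up to
ties in the expression values (ties are broken deterministically by the
stable ranking). P-values are BH-adjusted over all pairs; edges survive at
adjusted p ≤ 0.01. Note the granularity constraint: the smallest attainable
permutation p is 1/(n_perm+1), and BH inflates it by the pair count — with
too few permutations every edge is silently rejected, so the function warns
when 1/(n_perm+1) > α/10.

DPI pruning evaluates every triangle on the pre-pruning MI values (hence
order-independent) and removes the weakest edge when it is strictly below
(1 − tolerance) × the smaller of the other two; tolerance 0 (strict) by
default, 1 disables pruning, exact ties are kept. Modes are the sign of the
regulator–target Spearman correlation (zero correlation → +1, flagged).

## Master regulators and the gradient

A component's target set is the genes whose loading deviates from the mean
by more than 2 SD. Each regulon is scored by the one-sided hypergeometric
tail of its overlap with that set, and weighted by dES on the component
ranking. Selection requires p < 0.01 and |dES| ≥ 1. A TF qualifying in
several components keeps one record per component; the gradient consumes
the per-regulator *sum* of its component weights.

The gradient for patient j is Σᵢ dESᵢ · GEᵢⱼ over selected regulators
present in the matrix, standardized across the cohort (z-score with sample
SD). The dES weight is per-regulator, constant across patients; a
per-patient single-sample enrichment variant is deliberately not
implemented. Consequences of the definition: scaling all weights by c > 0
leaves the standardized score unchanged, as does adding a constant to any
gene's expression.

The discovery pipeline scores the gradient on the RPCA low-rank matrix
rather than the raw harmonized one (config `gradient_on_lowrank`, on by
default): outlying entries on regulator genes propagate directly into the
weighted sum, and the sparse part is precisely the layer the decomposition
designates as aberrant. On synthetic cohorts with 2% planted outliers this
raises the true-weight gradient fidelity from ρ ≈ 0.93 to ≈ 0.998.
Projection applies the same unsupervised denoising to the new cohort, then
the fitted weights restricted to shared regulators (≥ 50% of non-zero
weights required by default), re-standardized within that cohort.

## Survival association

Cox models use lifelines (partial likelihood, Efron ties); covariates are
standardized first so hazard ratios are per SD, matching the continuous
gradient's interpretation. Constant or exactly collinear covariates raise.
The optimal cutpoint scans every threshold leaving ≥ 10% of the cohort per
side using a vectorized log-rank statistic over all splits; the minimum
nominal p is reported *and* the Lausen–Schumacher maximally-selected
rank-statistic correction, which is the recommended value — under the null
the corrected p holds the 5% level while the nominal p rejects ~40% of the
time. PCA + Cox fits one univariate model per principal-coordinate
dimension and reports the best dimension with each input component's
squared-loading contribution to it.

## Synthetic cohorts: what they emulate, and what they do not

Defaults: 200 samples × 1200 genes, 3 latent Laplace components, 24 TFs
(8 per component, loadings ±U(0.8, 1.2)) each with 25 signed targets
(attenuation U(0.6, 0.9)), Gaussian noise SD 0.3 (log2 scale), 2% sparse
outliers of magnitude 5–10, per-gene baseline N(8, 1). Survival is
exponential with log-hazard −0.7 per unit of the first latent component and
independent exponential censoring (~25–30% censored). Laplace sources
(excess kurtosis 3) are chosen so planted components sit exactly at the
selection gate's intended regime. Methylation links ~8% of CpGs to the
first component with negative slope on the logit scale — hypermethylation
at the low-gradient end; the linked fraction is kept a small minority
because an SD-outlier rule is only meaningful for minority signals (real
gradient-linked CpG sets are a few percent of the array). A third of lipid
subfamilies move linearly with the gradient.

Not emulated: tumor purity and copy-number effects, cohort-specific batch
structure beyond location/scale shifts, overlapping regulons, feedback or
combinatorial regulation, dropout, probe-level noise. Passing the synthetic
benchmarks therefore demonstrates correctness of the estimators and the
pipeline plumbing under the model's own assumptions — not biological
validity on real cohorts, whose regulon counts and hazard ratios depend on
data this package does not ship.

Generation is a pure function of (parameters, seed) with separate
structure/sampling streams, so a validation cohort can re-sample patients
from the same structural draw.

## Problem sizes and Monte-Carlo design in the test suite

End-to-end checks run the default 200 × 1200 cohort (a few seconds per
pipeline pass). Estimator checks with irreducible Monte-Carlo spread —
sample kurtosis of heavy-tailed draws, the Amari index at n = 500, Cox
log-HR at n = 2000 — are asserted on the mean of a handful of seeded
replicates at the stated n, keeping the Monte-Carlo error small relative to
the tolerance instead of gambling on a single draw. Null-calibration checks
(cutpoint correction, permutation-GSEA p) use 500 replicates.

## Known limitations

- ES = ±1 degenerate cases (set spanning a ranking prefix) are exact, but
  NES for very small sets at low permutation counts is noisy; raise
  `n_perm` for publication-grade FDRs.
- The shared permutation null for edge significance assumes tie-free
  expression values; heavily tied data (e.g. zero-inflated counts) would
  need per-pair nulls.
- The maxstat correction is an asymptotic tail bound; for n < ~50 it can be
  conservative.
- `fit_ica` requires the requested component count not to exceed the
  numerical rank; rank-deficient inputs must be reduced first.
- Regulon inference power depends strongly on n_perm and cohort size; the
  warning thresholds flag, but cannot repair, underpowered settings.
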