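# Methods

This note documents the models and procedures implemented in `sigdriver`,
the choices made where the design was genuinely open, and what the
synthetic testbeds do and do not establish.

## Signature detection

A subtype signature S_k is the set of genes dysregulated *specifically*
in subtype k. Two filters are applied per gene:

**Statistical filter.** An empirical-Bayes moderated two-sample t-test of
subtype k against all other samples (other tumor subtypes pooled together
with normals). Per-gene pooled variances s²_g (d = n₁+n₂−2 df) are shrunk
toward a prior s₀² with d₀ prior df,

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),

where (d₀, s₀²) are fitted across genes by matching the moments of
log s²_g to a scaled-F model (digamma/trigamma moment equations, Newton
inversion of the trigamma function). The moderated t uses s̃²_g and
d₀ + d degrees of freedom, capped at the pooled df of all genes; when the
observed spread of log-variances is no larger than sampling alone
explains, d₀ = ∞ and every gene receives the average variance. Setting
`prior_df=0` disables shrinkage and recovers the ordinary pooled t, which
the tests use as an independent oracle; a second test cross-checks the
default path against Bioconductor limma (agreement to 1e-8 on a shared
fixture). p-values are two-sided and BH-adjusted (statsmodels);
significance is `p_adj < alpha` with α = 0.05 by default — a conventional
choice, as the method is insensitive to α an order of magnitude either
way on the planted fixtures.

**Specificity filter.** With group means μ_ℓ over the K tumor subtypes
plus the normal group as one extra group,

    Δ_k  = min(|μ_k − min_{ℓ≠k} μ_ℓ|, |μ_k − max_{ℓ≠k} μ_ℓ|)
    Δ′_k = max_{ℓ≠k} μ_ℓ − min_{ℓ≠k} μ_ℓ
    FC_k = Δ_k − Δ′_k.

A gene is specific to k iff μ_k strictly exceeds (direction "up") or is
strictly below ("down") every other group mean and FC_k > FCT. Strict
inequalities mean exact ties yield direction "none". Treating normals as
their own comparison group prevents calling tumor-wide changes
subtype-specific. FCT (log2 units, default 1.0) is the key
resolution/stability dial: raising it demands larger subtype-specific
deviations relative to the background spread of the other groups, which
empirically stabilizes the iterative loop (see below).

## Iterative subtyping

Given a genes × samples log2 matrix with tumor/normal annotation, the
loop is:

1. Cluster the tumors on the current gene set (initially the top 10% of
   genes by tumor-sample variance).
2. Cut the dendrogram into K clusters; absorb each singleton into the
   cluster with the nearest centroid → K′ core clusters of size ≥ 2.
3. Detect signatures S_1..S_{K′} on the **full** matrix; Φ = ∪S_k.
4. Dissolve clusters with |S_k| below |Φ|/(4K′) (bad clusters), each
   sample moving to the nearest remaining cluster's centroid → K″.
5. Set the clustering gene set to Φ and K = K″ + ΔK (ΔK = 1), and repeat
   until the partition and K″ repeat in consecutive iterations, or
   `max_iter` (default 10) is reached.

Convergence is declared on identical consecutive partitions, which is
stricter than merely an unchanged subtype count; in practice the planted
fixtures converge in 2–4 iterations.

### Clustering geometry

Samples are embedded spectrally: similarity W = (1+r)/2 with r the
Pearson correlation over the current gene set; symmetric normalization
M = D^{-1/2} W D^{-1/2}; the top `embed_dims` (default K) nontrivial
eigenvectors, **scaled by their eigenvalues**, then row-normalized to the
unit sphere. Eigenvalue scaling matters: with K larger than the true
structure, the extra eigenvectors are noise directions with near-zero
eigenvalues, and scaling suppresses them so that real clusters stay tight
in the embedding. Eigenvector signs are fixed (largest-magnitude entry
positive), making the embedding deterministic across runs and backends.

The dendrogram over the embedded samples uses **single linkage** by
default. This is deliberate: the loop starts from a deliberately too
large K, and what happens on over-cutting decides everything. Single
linkage peels the most isolated samples one at a time — exactly the
singletons step 2 absorbs — whereas average/complete/Ward linkage bisect
real clusters into balanced sibling fragments. Sibling fragments are
poison for the specificity rule: each sibling's mean matches the other's,
so both lose their entire signature, Φ collapses, and the loop cannot
recover. `linkage_method` accepts any scipy linkage for comparison.

### Dissolving bad clusters

Bad clusters are dissolved **one at a time** (smallest signature first,
ties by cluster size), each sample moving to the nearest remaining —
good *or* bad — cluster, with signatures re-detected after every
dissolution. The one-at-a-time order lets two sibling fragments of one
real subtype reunite (restoring their joint signature) before any good
cluster can absorb their samples; dissolving all bad clusters at once
into good ones would scatter a fragmented subtype irrecoverably and
causes a persistent 3↔2 oscillation on planted data. The single-pass
variant remains available (`merge_bad_clusters` without a `redetect`
callback) for the simple case of one junk cluster.

When an over-cut is so severe that *no* cluster retains any signature
(Φ = ∅ at K′ > 1 — even an 18/2 split of a subtype zeroes both parts),
the loop reduces resolution gradually, merging the two nearest clusters
and re-detecting until a signature appears. Only if Φ is still empty
with all tumors in one cluster (tested against the normals) does the run
abort with advice to lower FCT — at that point the data genuinely
support no signature at the requested specificity.

## Driver ranking

For subtype k with signature genes a (J of them) and candidate CNA genes
b (L of them), the between-set covariance C_ab (J × L) is the sample
covariance over **the subtype's own samples only**, then row-centered
(each signature gene's mean covariance across candidates subtracted).
Thin SVD C_ab = UΣVᵀ gives driver potentials

    ŵ_b = C_abᵀ u₁ = σ₁ v₁,     u₁ᵀ C_ab C_abᵀ u₁ = σ₁²,

the candidates' loadings along the leading covariance direction. Both
identities are asserted on every projection; u₁'s sign is fixed by its
largest-magnitude entry.

**Permutation null.** Gene sets of size J are redrawn uniformly without
replacement from all genes excluding the candidates, the projection is
recomputed, and all null ŵ_b entries are pooled into one empirical
distribution (a per-candidate null would need orders of magnitude more
permutations for the same tail resolution; under the null all candidates
are exchangeable against random signatures). Two-sided p-values use the
add-one estimator p = (1 + #{|null| ≥ |ŵ_bl|}) / (1 + N_null), so p is
never zero; default 1,000 permutations. Ranking is by p, ties broken by
larger |ŵ_bl|, then gene id. The same row-centering is applied to real
and null computations.

Row-centering has one consequence worth knowing: every projection's
potentials sum to zero, so *absolute* levels of ŵ_b are only comparable
within one projection. To compare candidates against a reference set
(e.g. the background genes of the synthetic testbed),
`candidate_vs_null_potentials` scores both as columns of one shared
C_ab — the reference columns then dominate the centering, and planted
location shifts in the candidates become visible.

## Cross-dataset validation

Two cohorts are restricted to common genes; each gene in each cohort is
affinely rescaled to mean (m₁+m₂)/2 and SD sqrt(s₁²/n₁ + s₂²/n₂)
(sample moments, ddof = 1; n_i = cohort sizes). Note this target SD is
deliberately small (standard-error-like), which is why signatures are
always detected on each cohort's *original* scale and only the k-NN
transfer runs in the normalized space. Labels transfer by majority vote
among the k = 3 nearest training tumors (Euclidean distance over the
training cohort's Φ), ties broken by the single nearest neighbor. Since
integer subtype labels are arbitrary per cohort, identities are aligned
by greedy maximum signature-gene overlap before the confusion matrix and
accuracy (trace/total) are computed.

## Synthetic testbeds

**Driver testbed** (`generate_driver_testbed`): an i.i.d. N(0,1) genes ×
cases matrix (defaults 10,000 × 100); the first 100 genes are signature,
the next 200 candidates, the rest NSNC background. Each signature gene j
is updated as x̃_j = Σ_i w_i c_ij x_i + x_j using the candidates'
*initialized* values, with c_ij ~ U(0,1) and per-candidate weights w_i
drawn per regime: U[−1,0], U[0,1], 0, or U[−1,1]. A scaled version
(1,000 genes, 50 signature, 100 candidates) runs the same qualitative
checks in seconds: positive weights push candidate potentials above the
NSNC null, negative below, zero shows no difference, and mixed weights
fatten both tails without moving the center.

**Subtype testbed** (`generate_subtype_testbed`): N(0, σ²) background
(σ = 1) over 2,000 genes; 3 subtypes × 20 tumors plus 10 normals; each
subtype owns a disjoint 50-gene block, half shifted +3 and half −3 in
that subtype's tumors only. The 2-unit gap between the planted deviation
(3) and the background spread makes FCT = 1 the natural operating point.

What these testbeds do **not** emulate: correlated gene modules,
heavy-tailed microarray noise, batch effects, probe-level artifacts,
overlapping signatures between subtypes, or CNA dosage structure.
Passing tests demonstrate correctness of the machinery and its
calibration under the stated generative model, not performance on any
real cohort.

## Numerical and degenerate-input choices

- All tabular I/O is TSV; duplicate gene rows collapse by mean with a
  warning; any non-numeric cell is a hard parse error naming gene and
  sample.
- Variance filtering uses tumor samples only; exact variance ties break
  lexicographically by gene id.
- Correlations involving a zero-variance sample profile are treated as 0
  in the similarity; constant genes contribute zero covariance.
- A zero C_ab yields σ₁ = 0 and zero potentials with a warning rather
  than an error.
- All stochastic steps (generators, permutation draws) take explicit
  integer seeds through numpy's `default_rng`; clustering, embedding and
  SVD are deterministic given inputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the subtype testbed at its
default size (2,000 genes, 60 tumors + 10 normals) across K_init = 2..20
and FCT ∈ {0, 0.25, 0.5, 1, 2} over 20 seeds, and the driver testbed at
the scaled size with 500 permutations — sizes at which the planted
effects are comfortably detectable while a full run of everything stays
within a few minutes on one core.

## Known limitations

- The convergence proof is empirical, not theoretical; pathological
  geometries could still oscillate (the trace records every iteration
  for diagnosis).
- Specificity with strict inequalities is brittle when two true subtypes
  share a dysregulated gene at exactly the same level; such genes are
  excluded by design.
- The permutation null treats candidates as exchangeable; strong
  variance heterogeneity among candidates would argue for a
  per-candidate null at higher permutation cost.
- k-NN label transfer assumes the cohorts share subtype structure; a
  subtype absent from the training cohort cannot be predicted.
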