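# Methods

## Data model

The substrate is a phylotype count table (taxa × samples, non-negative
integers; TSV on disk with taxa as rows) plus per-sample metadata:
phenotype (normal / adenoma / carcinoma), biopsy site (control / lesion
/ adjacent), clinicopathologic stage (LGDP, HGDP, ECRC, LCRC) and a
`pair_id` linking each lesion to the adjacent-mucosa biopsy from the
same subject. Validation enforces the schema cross-invariants (controls
are unpaired, each pair is one lesion plus one adjacent sample of one
subject, stages match phenotypes).

**Rarefaction** subsamples each sample to a fixed depth (default 1,000
reads) *without replacement* (multivariate hypergeometric) — the
ecology-standard choice; samples below the target depth are dropped and
reported. The handling of shallow samples is not dictated by the data
format; dropping is the least surprising option and is surfaced in the
return value so callers can audit it.

**Rare-taxon binning** pools taxa whose share of the grand read total
falls below a cutoff into a single `RARE_BIN` pseudo-taxon. The
denominator is the grand total (so "0.1 %" means 0.1 % of all reads);
column sums are preserved exactly, and the bin row is always present so
matrix dimensions are stable across cutoff sweeps.

## Dirichlet multinomial mixtures

A sample with counts `x_j` in component `k` has marginal likelihood

    DM(x_j | alpha_k) = n_j! / prod_t x_jt! *
        Gamma(A_k) / Gamma(A_k + n_j) *
        prod_t Gamma(x_jt + alpha_kt) / Gamma(alpha_kt),

with `A_k = sum_t alpha_kt`. The multinomial coefficient is constant in
`alpha` and omitted during fitting (available via `log_coef=True`,
under which the pmf normalises to one — checked by exhaustive
enumeration in the tests).

**EM.** The E-step computes responsibilities proportional to
`pi_k · DM(x_j | alpha_k)`. The M-step updates `pi` in closed form and
maximizes each component's responsibility-weighted log-likelihood plus
log-prior over `log alpha` with L-BFGS using the analytic digamma
gradient (first M-step capped at 100 quasi-Newton iterations, later
ones at 30; an update that fails to improve keeps the previous point,
so the penalized objective trace is non-decreasing — asserted by the
tests per iteration). Convergence: relative objective change below
`tol` (default 1e-6; the K-selection sweeps use 1e-5). Restart 0 seeds
responsibilities from PAM labels on Bray–Curtis distances; further
restarts are random. Default 2 restarts; the study-sized runs in the
test-suite and acceptance script use 1 restart, which is sufficient for
the well-separated synthetic components and keeps a full K = 1..7 sweep
of a 259-sample cohort under ~10 s.

**Priors.** Each `log alpha_kt` carries an i.i.d. normal prior (mean 0,
sd 10) — weak enough to leave estimates untouched, strong enough to
keep the posterior mode finite when a taxon is absent from a component;
mixture weights carry a uniform Dirichlet(1) prior. Evidence values are
comparable across K only within this fixed configuration.

**Laplace evidence.** `log p(X) ≈ log p(X | theta*) + log p(theta*) +
(P/2) log 2π − ½ log |H|`, with `P = K·T + (K−1)` free parameters. `H`
(negative Hessian of the log posterior at the mode) is approximated
block-diagonally: one analytic block per component in `log alpha`
(diagonal plus a rank-one term from the shared total-concentration
curvature, weighted by the responsibilities at the mode) and a
finite-difference block for the K−1 free mixture weights. Non-positive
blocks are ridge-regularized (escalating from 1e-8 of the diagonal
scale) with a warning. The finite-difference weight block leaves ~1e-5
relative noise, which is why the label-permutation test allows a 0.01
absolute slack on quantities of magnitude ~1e5.

**Assignment.** Posterior responsibilities under the fitted model;
hard labels are argmax with ties broken toward the lowest component
index. Components are lettered A, B, … by descending mixture weight —
the lettering criterion is a package convention, chosen because it is
deterministic and stable under refitting.

## Cluster-number cross-checks

PAM (BUILD + greedy SWAP k-medoids, implemented here because the
installed scikit-learn has no k-medoids) with the Calinski–Harabasz
index on NMDS coordinates provides the medoid-based estimate of the
cluster number. CH needs centroids, which a bare distance matrix lacks;
computing it on the NMDS configuration is a documented deviation from
coordinate-free usage. NMDS minimizes Kruskal stress-1 by alternating
isotonic regression of configuration distances on dissimilarity ranks
with Guttman updates, starting from classical MDS (restart 0) plus
random restarts; stress-1 is rank-based, hence invariant under
monotone transforms of the input dissimilarities. Procrustes similarity
`R = sqrt(1 − residual SS)` after centring/scaling/rotation compares
ordinations across rarity cutoffs. The rarity sweep recommends the
smallest cutoff at which the DMM-optimal K and the CH-optimal k agree
on the largest jointly supported value — one reasonable
operationalization of "the two methods agree"; the full per-cutoff
record is returned so other rules can be applied.

## Markers and MCPI

Fold changes are ratios of arithmetic group means of relative
abundances with a pseudocount `eps = 1e-6` on both numerator and
denominator — below the 1e-3 resolution of depth-1,000 rarefaction, so
it only guards zeros. Increased markers need FC ≥ 1.5; decreased
markers use the reciprocal threshold ≤ 1/1.5 (the natural symmetric
completion of the stated increase criterion). The MCPI pools the C and
C′ (resp. A and A′) marker sets; whether lesion and lesion-adjacent
marker sets should instead be weighted separately is not decidable from
the index's verbal definition, so pooling — the simpler reading — is
implemented behind a single function that can be swapped. The
difference-of-two-log-ratios form makes the score exactly antisymmetric
under exchanging the carcinoma and adenoma sides, and invariant to taxa
outside the panel; both are asserted in the tests.

Per-stage marker analysis: within-pair fold change
`(x_lesion + eps)/(x_adjacent + eps)`, Wilcoxon signed-rank on the log
fold changes across pairs in a stage, BH correction across taxa within
each stage (one correction family per stage); stages with fewer than 3
pairs are flagged and left untested.

## Statistical primitives

Inverse Simpson diversity `1/sum p_i^2`. Mann–Whitney U, Wilcoxon
signed-rank (zeros dropped, midranks with tie-corrected variance) and
the two-sample KS test delegate to scipy behind a uniform result type;
exact enumeration modes are used automatically at small tie-free n, and
the tests verify the exact p-values against direct enumeration of rank
assignments / sign patterns.

The Monte-Carlo Fisher exact test for r × c tables uses the null
hypergeometric probability of the table as its statistic (the standard
choice for the two-sided r × c test), samples fixed-margin tables
uniformly (Patefield algorithm via `scipy.stats.random_table`), and
reports per-repeat `p = (1 + #{P_sim ≤ P_obs}) / (1 + n_replicates)`
averaged over repeats with its Monte-Carlo standard error — mirroring
the "mean P over iterations" reporting convention for such tests, and
making desk-scale runs honest about their MC noise. Equality of table
probabilities is tested with a 1e-7 relative tolerance on the log
scale. BH step-up adjustment is implemented directly and checked
against both a brute-force evaluation of the definition and
statsmodels.

## SparCC

Per inference iteration (default 20): per-sample fractions are drawn
from a Dirichlet posterior with unit pseudocounts; log-ratio variances
`t_ij` feed the sparsity-assumption linear system
`sum_j t_ij = (T−2) w_i + sum_j w_j` for the basis variances; basis
correlations follow as `(w_i + w_j − t_ij)/(2 sqrt(w_i w_j))`, clipped
to [−1, 1]. Up to 100 exclusion iterations remove the currently
strongest pair above the 0.1 exclusion threshold (the original
algorithm's default) and re-solve; exclusions are capped per taxon so
the system stays determined, with a least-squares fallback. The final
estimate averages the inference iterations. All-zero taxa are excluded
with a warning.

Permutation p-values shuffle every taxon's counts independently across
samples (the original SparCC null: margins preserved, correlations
destroyed) and re-estimate; two-sided
`p = (1 + #{|rho_sim| ≥ |rho_obs|})/(1 + n_sim)`. The number of
permutations bounds the attainable q-value: with `m` pairs tested, the
floor after BH is roughly `m / (rank · (n_sim + 1))`, so edge-exact
analyses need `n_sim` in the thousands while distribution-level
calibration is stable at a few hundred.

Paired-site analysis treats taxa-at-lesion and taxa-at-adjacent as
separate variables on subject-matched observations: within-site blocks
are the plain single-site estimates on the paired samples, and the
cross-site block combines cross-site log-ratio variances with the
within-site basis variances. The construction of "between-site"
correlations is not uniquely determined by the verbal description; the
stacked-variable reading implemented here has the two properties one
would demand of it (cross-site self-correlation → 1 for identical
compositions, cross-block → 0 for independent sites), both asserted in
tests.

Network construction keeps pairs with `|rho| ≥ 0.3` (the conventional
visualization threshold) and BH q ≤ 0.05 within each disease state;
state comparisons report a KS test on the off-diagonal correlation
distributions, a 2 × 2 sign-concordance table with Fisher's exact test
over pairs significant in both states, and counts of strong (≥ 0.5)
positive correlations.

## Synthetic cohorts

`CohortSpec` defaults encode the emulated study design: 61 controls,
47 adenoma and 52 carcinoma lesion/adjacent pairs (259 biopsies),
K = 5 metacommunities, ~100 taxa, per-sample depths negative-binomial
with mean 8,000 and size 3.2 (matching a mean ± sd of roughly
8,200 ± 4,500 before rarefaction to 1,000), lesion/adjacent concordance
0.64 for adenomas and 0.61 for carcinomas. Component Dirichlet
parameters are a shared log-normal base profile (sd 1.5) with 12
signature taxa per component boosted by +2.5 on the log scale, scaled
to concentration θ = 50 — enough within-component heterogeneity to be
overdispersed relative to multinomial sampling (asserted in tests)
while keeping components separable, spanning the spectrum from tight to
variable community types. Discordant pairs redraw the lesion component
uniformly from the other components; an "attractor" kernel preset
instead funnels discordant lesions into one designated component, for
studying directional lesion shifts.

Planted markers default to 8 taxa per phenotype × direction at fold
change 3, drawn from the 60th–95th percentile of mean abundance, with
the adjacent tissue receiving the square root of the lesion's fold
change. Abundance matters: at θ = 50 the proportion of a mid-abundance
taxon varies across samples with a coefficient of variation above
100 %, so a 3-fold shift on such a taxon is physically undetectable at
realistic group sizes; real disease-marker taxa in this setting are
abundant community members, and the band reflects that. The
known-basis compositional generator for correlation calibration
likewise anchors planted-pair taxa at the median log abundance — in
the rare tail, read-sampling noise (a few reads per sample) attenuates
any estimator's recovered correlation.

What the generator does *not* emulate: phylogenetic structure among
taxa, taxonomy-dependent effects, depth-quality covariation,
contamination, subject-level covariates (age, sex, medication), or
phenotype-dependent mixture weights. Passing tests therefore
demonstrate correctness of the estimators under the generating model's
assumptions, not robustness to every artefact of real amplicon data.

## Problem sizes and numerical notes

The test-suite and acceptance script run the study-sized analyses at
the cohort's natural scale (259 samples, 100 taxa, K = 1..7) and the
correlation calibration at 50 taxa × 200 samples with 300–500
permutations; the edge-exact network demonstration uses 20 taxa with
2,500 permutations so the BH floor clears the 0.05 FDR threshold.
Monte-Carlo Fisher desk runs use 500–10,000 replicates with the MC
standard error reported alongside.

Degenerate inputs: zero-depth samples are rejected before model
fitting; all-zero taxa are excluded from SparCC; empty marker panels
abort MCPI with an error (the CLI skips the stage with a warning);
stages or subsets with fewer than 3 pairs are flagged rather than
tested; non-positive-definite Hessian blocks are ridge-regularized and
flagged. Ties: posterior ties break toward the lowest component index;
PAM cost ties break by seeded random choice among maximizers.

## Known limitations

- The Laplace evidence is a local approximation around one EM mode;
  with poorly separated components or few samples per component the
  K-selection can be unstable (the restarts and the PAM initialisation
  mitigate, not eliminate, this).
- SparCC's sparsity assumption degrades with dominant taxa or dense
  correlation structure; estimates on rare taxa are attenuated by read
  sampling regardless of method.
- The MCPI pooling convention (C with C′, A with A′) is one of two
  defensible readings of the index's definition; the alternative
  (separate lesion/adjacent weighting) can be swapped in behind the
  same interface.
- PAM's SWAP stage is O(k·n²) per pass; for cohorts far beyond ~10³
  samples a subsampled BUILD or CLARA-style variant would be needed.
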