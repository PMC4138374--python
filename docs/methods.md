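# Methods

This note documents the statistical models and procedures implemented in
`ricemix`, the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Setting

The pipeline analyzes log2-scale gene expression measured under a 2 x 2
factorial of planting density (high, HD; low, LD) and nitrogen supply
(sufficient, SN; limiting, LN), with replicated samples at two developmental
timepoints (21 and 31 days). LDSN — low density, sufficient nitrogen — is the
optimal growth condition and serves as the control for every contrast and as
the calibrator for qPCR quantification. Expression values are assumed already
normalized upstream; the pipeline ingests a genes x samples matrix of finite
log2 values and rejects (never imputes) missing data.

All profile-shaped arrays use the fixed condition order
(LDSN, LDLN, HDSN, HDLN).

## Responsive-gene calling

For each gene and timepoint, three contrasts against LDSN are formed: HD
(HDSN vs LDSN), LN (LDLN vs LDSN), and HDLN (HDLN vs LDSN). A gene is
*responsive* in a contrast when both

1. the linear fold change `2^(mean log2 difference)` passes the cutoff in
   either direction (default 2; equivalently |log2 FC| >= 1), and
2. the Benjamini–Hochberg adjusted p-value of a two-sample t-test on the
   replicate log2 values is below alpha (default 0.05), adjusted per contrast
   across all genes.

The per-gene test is a pooled-variance Student t by default (replicate groups
of 3 make the equal-variance form the natural choice); Welch's t is
selectable. When both groups have zero variance the test is degenerate and
p is set to 1 for equal means, 0 otherwise. BH adjustment is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`.

The three responsive sets are partitioned into the seven disjoint regions of
a three-way Venn diagram, and the HD/LN co-response is summarized as
|HD ∩ LN| / |HD| (the union denominator is available as an option; the
fraction is undefined and reported as such when HD is empty).

The clustering input set is selected at a stricter 3-fold cutoff: genes
responsive to HD and *not* responsive to LN. Whether the significance
criterion is re-applied at the stricter cutoff is configurable
(`apply_bh`, default on).

## Step 1: mixture-model clustering of condition profiles

Each selected gene is reduced to its 4-vector of condition means (replicates
averaged, unstandardized by default) and the profiles are clustered with a
finite Gaussian mixture. Two engines are provided.

### Eigen-decomposed Gaussian mixtures (GPCM)

Component covariances are constrained through the eigen-decomposition
`Sigma_g = lambda_g D_g A_g D_g'` — volume `lambda_g`, orientation `D_g`,
shape `A_g` (diagonal, det 1). Eight models are implemented (EII, VII, EEI,
VEI, EVI, VVI, EEE, VVV); the orientation-constrained remainder of the family
is out of scope. M-steps are closed form except VEI, whose volume/shape
coordinate ascent is warm-started from the previous EM iteration so the
Q-function never decreases (a few inner iterations suffice at p = 4).

Fitting is by EM from k-means++ hard assignments (10 restarts by default,
seed-controlled), convergence at relative log-likelihood change < 1e-8 or 500
iterations, best restart returned. Degeneracy is handled by flooring
covariance eigenvalues at 1e-6 x the data variance (fits that needed the
floor are flagged `regularized`) and by abandoning restarts whose smallest
component weight falls below 1/n.

Model and component count are selected by maximizing
`BIC = 2*loglik − m*log n`, where m counts weights (G−1), means (G*p) and
covariance parameters per model. The search is joint over (G, model); ties
break toward smaller G, then the simpler model. Cells with n < G*(p+1) are
flagged infeasible rather than fitted.

### Mixtures of factor analyzers (PGMM)

The alternate engine uses `Sigma_g = Lambda_g Lambda_g' + Psi_g` with p x q
loadings and diagonal noise, fitted by AECM: cycle 1 updates weights and
means (labels missing), cycle 2 updates loadings and noise (labels and latent
factors missing), with component inverses through the Woodbury identity.
Constraint codes are three letters over (loadings common, noise common,
noise isotropic). UUU, UCU, UUC, UCC, CCU and CCC have closed-form CM-steps
and are implemented; CUU and CUC require an iterative row-wise loading solver
and are rejected with a clear error. The latent dimension respects a
Ledermann-style bound implemented as the ceiling of the Ledermann root,
giving q <= 2 at p = 4; the default is q = 1. Loadings are identified only up
to rotation, so all assertions and recovery checks compare the implied
covariance `Lambda Lambda' + Psi`, never `Lambda` itself.

## Step 2: density-split sub-clustering and discordance

Each step-1 component's profiles are split by planting density into two
2-dimensional data sets — the (SN, LN) pair under HD and the (SN, LN) pair
under LD — and each is clustered into two groups (k-means with k = 2, best of
10 k-means++ starts by within-cluster sum of squares, or a G = 2 GPCM
depending on strategy). Components with fewer than 4 genes (2k) skip step 2.
If all points of a set coincide, the split is degenerate: one cluster holds
everything (documented convention).

The two 2-cluster solutions carry arbitrary label indices, so sub-clusters
are matched across densities by the nitrogen trend of their centers (the
LN − SN coordinate difference), pairing the HD cluster with the LD cluster of
most similar trend. A gene whose matched sub-cluster differs between
densities is flagged *discordant*: its nitrogen response follows one trend
under low density and another under high density. Trend matching was chosen
over minimal-Hamming label matching because Hamming matching is degenerate
exactly when half of a component is discordant — both pairings then disagree
on half the genes and the choice reduces to a coin flip on noise — whereas
center trends remain comparable across densities at any discordance
fraction. Running step 2 on a single density is available as a configuration
option, in which case discordance is undefined and left unset.

Four strategies combine the engines: GPCM or PGMM for step 1, k-means or
G = 2 GPCM for step 2. On well-separated data with comparable component
variances the two step-2 methods reduce to nearest-center assignment and
agree exactly.

## qPCR and metabolite quantification

Relative expression uses the 2^-ddCt method at assumed perfect doubling:
per replicate, dCt = Ct_target − Ct_actin2; ddCt subtracts the calibrator
condition's (LDSN) mean dCt; fold = 2^-ddCt. Condition-level fold is the mean
of per-replicate folds, which also feed a pooled t-test of replicate dCt
values against the calibrator. Because ddCt is a double difference, folds are
invariant to plate-wide Ct shifts. The calibrator's mean ddCt is 0 by
construction, hence its mean-based fold is 1.

GC-MS component areas are filtered at signal-to-noise >= 5 (boundary
inclusive) and normalized by dividing each area by the same sample's ribitol
internal-standard area; ribitol normalizes to 1, and a missing or
non-positive standard is an error naming the sample. Components detectable
but below the quantifiability threshold are carried with
`quantifiable=False` ("ND"), excluded from means and never imputed as zero.

Group comparisons use one-way ANOVA with Fisher's LSD,
`t(1−alpha/2, df_error) * sqrt(2*MSE/n)` for balanced groups and the
harmonic-mean pair size otherwise; pairwise flags are reported regardless of
the omnibus F (which is flagged separately). An optional square-root
transform (non-negative data only) precedes the ANOVA. Tukey's HSD
(statsmodels) and a Shapiro–Wilk residual-normality p (scipy) are reported
alongside rather than re-derived.

## Synthetic data

The generators invert the pipeline's own models so every stage is testable
without external data.

* **Expression**: gene latent 4-condition profiles are drawn from a planted
  Gaussian mixture (any of the eight covariance models); a configurable
  fraction of genes is flat ("null") at a baseline drawn per gene
  (N(8, 1.5^2) log2 units); replicate observations add independent
  N(0, noise_sd^2) noise, independently per timepoint. Defaults emulate the
  targeted study's structure: 21,179 genes, 4 conditions, 3 replicates,
  2 timepoints, 95% null, 8 profile classes with ~2 log2 effects,
  noise SD 0.25 log2 (a typical array replicate SD).
* **Discordance** is planted by removing a clustered gene's nitrogen offset
  under one randomly chosen density (only in clusters whose profile has a
  nonzero offset) — the minimal structure step 2 is designed to detect. The
  truth labels and flags are returned for recovery scoring.
* **Ct tables** invert 2^-ddCt at efficiency 2:
  `Ct = base − log2(relative abundance) + noise`, reference gene constant up
  to noise. **Metabolite tables** set area = concentration x the sample's
  ribitol area x multiplicative log-normal noise, with per-component S/N
  drawn uniformly from a range.

All generators are pure functions of their seed.

### What the simulations do and do not show

The generator reproduces the *statistical* structure the analysis assumes —
a Gaussian mixture over condition-mean profiles with exchangeable replicate
noise. It does not emulate probe-level effects, intensity-dependent variance,
correlated replicates, batch structure, or chromatographic artifacts.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under their own model, not performance on real arrays.

Two regimes matter for the two-step evaluation. When planted nitrogen
offsets are comparable to the between-component separation, BIC correctly
resolves discordant subgroups as their own mixture components, and
discordance is no longer a within-component property — recovery against the
planted grouping is then ill-posed. The end-to-end recovery experiments
therefore use components whose baseline separation (2 log2 between adjacent
components, >= 10 sigma) dominates the +/-1.2 log2 nitrogen offsets
(6 sigma), with the component count searched up to the planted value; in this
regime step-1 recovery is exact (ARI 1.0) and discordance
sensitivity/specificity exceed 0.95 even with half of each component planted
discordant. The per-component step-2 machinery is additionally validated
directly on true components, where recovery is essentially perfect.

## Problem sizes used in the checked experiments

Simulation scales were chosen so each experiment's Monte-Carlo error is small
relative to the property being checked: EM monotonicity on 100 datasets x 8
models; BIC selection consistency on 100 replicates of 300 genes at 5-sigma
separation; false-discovery control on 500 global-null replicates of 2,000
genes; discordance recovery on 50 replicates of 160 genes across 8
components; factor-model recovery at n = 5,000. The acceptance script runs
reduced replicate counts (20–100) of the same scenarios.

## Known limitations

* Only the eight eigen-decomposition models above; no orientation-constrained
  (EEV/VEV/...) models, no t-mixtures, no missing-data EM.
* PGMM constraints with common loadings but component-specific noise
  (CUU, CUC) are not implemented.
* The 2^-ddCt method assumes perfect doubling; no amplification-efficiency
  calibration.
* Discordance flags are only defined when both densities are sub-clustered
  and the component has at least 4 genes.
* BH control is per contrast within a timepoint; no joint modelling across
  timepoints or contrasts.
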