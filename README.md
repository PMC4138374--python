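# ricemix

Mixture-model analysis of crop stress transcriptomics: responsive-gene
calling, three-way Venn partitioning, two-step model-based clustering of
condition profiles, 2^-ddCt qPCR quantification, and internal-standard
metabolite normalization — with synthetic-data generators that reproduce the
statistical structure the analysis assumes, so the whole pipeline is testable
offline.

## The problem

Plants grown at high planting density (HD) compete for light, nutrients and
space; nitrogen limitation (LN) is a candidate explanation for much of the
response. To separate density stress from nitrogen stress, expression is
measured under a 2 x 2 factorial — density (HD/LD) x nitrogen (SN/LN) — with
replicates at two timepoints, and every contrast is formed against the
optimal LDSN control. The pipeline answers, per timepoint:

1. Which genes respond to HD, to LN, and to the combined stress (fold-change
   cutoff + Benjamini–Hochberg FDR), and how do those sets overlap?
2. Among genes responsive to density but *not* nitrogen (3-fold cutoff),
   which co-regulated profile groups exist? Profiles
   (LDSN, LDLN, HDSN, HDLN) are clustered with a Gaussian mixture whose
   component covariances are eigen-decomposed,
   `Sigma_g = lambda_g D_g A_g D_g'` (GPCM; eight constraint patterns
   EII…VVV), or with a mixture of factor analyzers,
   `Sigma_g = Lambda_g Lambda_g' + Psi_g` (PGMM), selecting the component
   count G and model by `BIC = 2*loglik − m*log n`.
3. Within each profile group, does a gene's nitrogen response follow a
   different trend under high density than under low density? Each
   component's profiles are split by density into (SN, LN) pairs, each pair
   set is clustered with k = 2, sub-clusters are matched across densities by
   their center nitrogen trend, and genes whose sub-cluster flips are flagged
   *discordant*.
4. qPCR validation via 2^-ddCt against an actin2 reference and the LDSN
   calibrator, and GC-MS metabolite tables filtered at S/N >= 5 and
   normalized to the ribitol internal standard, compared by one-way ANOVA
   with Fisher's LSD.

See `docs/methods.md` for the full model descriptions, parameter defaults and
design decisions.

## Worked example

```python
import numpy as np
from ricemix import synth, datamodel, de, twostep

# plant 4 response classes (HD-enhanced, HD-suppressed, LN-only,
# combined-only) among 80% flat genes; 30% of clustered genes are
# nitrogen-discordant between densities
pm = np.array([
    [8.0, 8.8, 11.0, 11.8],
    [8.0, 7.2,  5.0,  4.2],
    [8.0, 11.0, 8.0, 11.0],
    [8.0, 8.0,  8.0, 10.0],
])
cfg = synth.SimConfig(n_genes=1000, frac_null=0.8, frac_discordant=0.3,
                      K_true=4, profile_means=pm,
                      covariance_params={"volume": 0.04}, noise_sd=0.2,
                      timepoints=(21,), seed=42)
m, truth, flags = synth.simulate_expression(cfg)

res = de.call_responsive(m, 21, fold_cutoff=2.0, alpha=0.05)
print("venn counts:", de.venn_partition(res).counts)
print("HD∩LN / HD:", round(de.overlap_fraction(res), 3))

dens = de.density_specific_genes(m, 21, fold_cutoff=3.0)
print("density-specific genes:", len(dens))

keep = [p for p in datamodel.condition_means(m, 21) if p.gene_id in dens]
ids, X = datamodel.profiles_to_matrix(keep)
ts = twostep.run_two_step(ids, X, strategy="gpcm-kmeans", seed=7,
                          G_range=[2], n_starts=5)
print("selected G:", ts.step1_fit.G, "model:", ts.step1_fit.model_name)
print(ts.to_frame().head(5).to_string(index=False))
```

prints

```
venn counts: {'HD_only': 0, 'LN_only': 9, 'HDLN_only': 40, 'HD_LN': 0,
              'HD_HDLN': 81, 'LN_HDLN': 36, 'HD_LN_HDLN': 21}
HD∩LN / HD: 0.206
density-specific genes: 99
selected G: 2 model: EEI
  gene_id  component  hd_sublabel  ld_sublabel  discordant
gene00017          0            2            1        True
gene00019          0            1            1       False
gene00039          0            1            1       False
gene00080          0            2            1        True
gene00124          0            1            1       False
```

Reading the output: the two HD-responsive classes pass the 3-fold
density-specific selection (99 of the 100 planted genes; the LN-only and
combined-only classes are excluded), the mixture recovers the two profile
groups (diagonal equal-covariance model EEI), and per gene the step-2
sub-cluster under each density plus the discordance flag are reported —
40 of 99 genes are flagged, recovering the planted discordant set with
sensitivity and specificity 0.82 at this noise level. On the qPCR side:

```python
from ricemix import quant
ct = synth.simulate_ct({"ACS1": {"HDSN": 9.0}}, noise_sd=0.0, seed=0)
for r in quant.ddct_folds(ct):
    print(f"{r.gene} {r.condition}: ddCt={r.delta_delta_ct:+.2f} fold={r.fold:.2f}")
```

```
ACS1 HDSN: ddCt=-3.17 fold=9.00
ACS1 LDSN: ddCt=+0.00 fold=1.00
```

a planted 9-fold HDSN/LDSN expression difference is recovered exactly from
the Ct table (ddCt = −log2 9), with the calibrator at fold 1 by construction.

The same stages are available as a CLI:

```sh
ricemix simulate --out-dir sim --seed 1 --n-genes 2000
ricemix run-all --values sim/expression.tsv --meta sim/samples.tsv \
        --out-dir run --seed 1
```

`run-all` writes per-timepoint DE tables, Venn summaries, two-step cluster
tables and a manifest (config hash, versions, seed); identical seeds give
byte-identical outputs.

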