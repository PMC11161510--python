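# sarcomics

Integration of handcrafted MRI radiomics, autoencoder-derived deep
radiomics and bulk transcriptomics for soft-tissue sarcoma (STS)
prognosis.

Locally advanced STS is radiologically and molecularly heterogeneous,
and neither imaging nor expression profiling alone stratifies
metastatic risk well. This package re-implements, as a tested and
reusable pipeline, an analysis strategy in which

1. multi-sequence MRI (T1-weighted, T2-weighted, contrast-enhanced
   T1-weighted) is intensity-harmonized (resampling to 1×1×4 mm, bias
   field removal, histogram matching, rescaling to [−10000, 10000]) and
   discretized to 256 gray levels;
2. 59 texture features per sequence (13 first-order, 21 GLCM at
   distances 1/2/4, 11 GLRLM, 3 NGLDM, 11 GLZLM) plus 4 shape features
   are extracted from the tumor volume and filtered for reproducibility
   (two-way absolute-agreement ICC ≥ 0.90 across repeat segmentations);
3. a convolutional autoencoder (CAE) and a half-supervised CAE (HSCAE,
   reconstruction loss plus λ times a Cox partial-likelihood loss on a
   linear risk head) encode the background-removed tumor center slice
   into deep radiomics features;
4. each feature space is grouped by consensus clustering — B resampled
   leave-40%-out subsamples, average-linkage hierarchical clustering on
   the Pearson distance d(x,y) = 1 − r(x,y) — with clusters named
   A, B, C… by decreasing size and held-out subjects assigned to the
   nearest centroid in Pearson distance;
5. groupings are related to clinical variables (chi-square, Mann–Whitney,
   SARCULATOR Pr-OS categories, the 2-of-3 semantic radiophenotype rule)
   and to metastasis-free survival (Kaplan–Meier, log-rank, uni-/
   multivariable Cox with backward-AIC selection, Harrell c-index in
   5-fold cross-validation with bootstrap model comparison);
6. the combined radiomics × transcriptomics group of worst prognosis is
   profiled by per-gene Welch t-tests gated at fold-change 2 with
   Benjamini–Hochberg control, hypergeometric geneset enrichment, and a
   nearest-shrunken-centroid (PAM) discriminant signature.

Because the patient images are not public, a first-class synthetic
cohort generator plants the same statistical structure (group-dependent
tumor phenotypes, log-additive exponential survival, negative-binomial
counts with fold-change-2 differential genes and batch effects), so
every stage is testable end to end.

## Worked example

```python
import pandas as pd
from sarcomics.synthetic import generate_cohort
from sarcomics.harmonize import harmonize_volume, discretize
from sarcomics.radiomics import extract_features
from sarcomics.consensus import consensus_cluster
from sarcomics import survival as sv

cohort = generate_cohort(60, seed=0)

rows = []
for study in cohort.studies:
    disc = {}
    for name, vol in study.channels.items():
        h, m = harmonize_volume(vol, study.mask)
        disc[name] = discretize(h, m)
    rows.append(extract_features(disc, m, spacing=m.spacing))
features = pd.DataFrame(rows, index=cohort.clinical.index)

model = consensus_cluster(features, k_range=(2, 3, 4), B=200, seed=0)
records = cohort.survival.join(model.labels.rename("cluster"))
stat, df, p = sv.logrank_test(records, records["cluster"])
print(model.k, model.labels.value_counts().to_dict(), round(p, 4))
```

prints

```
2 {'A': 30, 'B': 30} 0.0166
```

i.e. consensus clustering of the 181 handcrafted features selects two
groups (named A and B by the size-then-order convention), and the
log-rank test finds their metastasis-free survival curves to differ
(p ≈ 0.017): cluster A is enriched for the planted aggressive imaging
phenotype, which carries the higher hazard.

The same run end-to-end, including the deep branch and differential
expression, is available from the shell:

```bash
sarcomics run --seed 0 --outdir run0
sarcomics report --outdir run0
```

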