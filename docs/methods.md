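# Methods

This note documents the models, parameter choices and numerical
conventions of the `sarcomics` package, and what its synthetic-cohort
tests do and do not establish about real data.

## Synthetic cohort model

The generator plants the statistical structure the downstream analyses
assume, at desk scale.

**Imaging phenotypes.** Each subject belongs to one of two imaging
groups. Group A (proportion 0.60) draws tumor diameter from
N(120, 50²) mm, has texture contrast 2.0 and probabilities 0.70 for a
central necrotic core, a peritumoral contrast-enhancing rim and patchy
T2 heterogeneity; group B (0.40) draws N(64, 34²) mm with contrast 0.6
and probabilities 0.15/0.20/0.25. These sizes and proportions follow
the deep-radiomics group contrasts of the motivating study (the
aggressive cluster is the more numerous one with roughly double the
median diameter). Tumors are random ellipsoids clipped strictly inside
the grid; channel intensities are a fixed tissue level (T1 0.35, T2
0.55, CE 0.70 against background 0.15, arbitrary units) modulated by a
smooth ±8% multiplicative bias field and Gaussian-filtered noise whose
standard deviation is 0.05 × texture contrast. Necrosis drops central
CE enhancement to 25% of the base level; the rim raises CE in a
2-voxel dilation shell. The default acquisition grid is 64×64×16 at
2×2×4 mm so harmonization genuinely resamples.

**Survival.** Metastasis-free survival is exponential with rate
λ₀·exp(β_img + β_expr): λ₀ = 0.003/month (≈ 84% five-year
survival in the best cell, matching the indolent group of the study),
β_img = ln 3.3 for imaging group A, β_expr = ln 2.6 for expression
group A_RNA (the univariable hazard ratios reported for those groups),
with independent exponential censoring at 0.012/month (≈ 30% event
fraction overall). Exponential laws were chosen for closed-form
oracles; the memoryless hazard is a simplification of real MFS.

**Expression.** Counts are negative-binomial. Gene relative abundances
are log-normal; gene-wise dispersions are 0.15 × a log-normal(0, 0.4)
factor, matching the over-dispersion voom assumes. 200 of 2000 genes
(default desk scale; real cohorts have ~20k genes) are shifted by one
log2 unit between expression groups — half up, half down. Batches act
multiplicatively on gene means (log-normal, σ = 0.35) and dispersions
(σ = 0.25); library sizes are uniform on [2×10⁵, 10⁶]. The imaging and
expression groups are mixed independently by default, reproducing the
study's key structural finding that radiomics and transcriptomics
groupings are non-redundant; the mixing matrix is an explicit
parameter so that dependence is controllable.

**What the generator does not emulate:** MR physics (coil profiles,
fat suppression, partial-volume effects), anatomical context,
non-ellipsoidal growth, informative censoring, gene–gene correlation
networks, and GC/length count biases. Passing tests therefore
establish the correctness and calibration of the algorithms under the
assumed generative laws, not clinical performance.

## Imaging harmonization

Fixed order: resample → bias-correct → histogram-match → rescale.
Resampling maps output voxel centers into input index space and
interpolates linearly (order-1 `map_coordinates`, edge-clamped);
output shape is round(extent/target). Bias correction fits a
polynomial (default order 2) to log-intensities inside the mask by
least squares and divides out the exponentiated field, preserving the
in-mask mean — the same contract as N4-type correction, chosen because
it is exactly testable with planted fields. Histogram matching is
quantile mapping through 256 evenly spaced empirical quantiles with
monotone knot enforcement; a constant reference collapses the output
(documented degenerate case). Rescaling maps [min, max] affinely to
[−10000, 10000]; constants map to the lower bound. Discretization bins
in-mask intensities into 1..256 by min–max, making all texture
features invariant to positive affine intensity transforms. The center
slice is the floor-midpoint of the mask extent along the third axis
with out-of-mask pixels zeroed.

## Handcrafted radiomics

Texture families follow the standard (IBSI-aligned) definitions with
the counts fixed at 13 first-order, 7 GLCM statistics × distances
{1,2,4}, 11 GLRLM, 3 NGLDM, 11 GLZLM = 59 per sequence, plus 4 shape
features. Conventions worth noting:

- Second-order matrices aggregate the 13 unique 3-D directions;
  GLCMs are symmetrized and normalized to sum 1; run percentage is
  normalized per direction so an all-length-1 image has RP = 1.
- Gray levels enter formulas at their 1-based values (so low/high
  gray-level emphasis terms are well defined).
- Degenerate cases give documented neutral values, never NaN:
  single-level GLCM correlation = 1, NGLDM coarseness capped at 10⁶,
  entropy of a point mass = 0. All entropies use log base 2.
- Zones are 26-connected components of equal level (single labelling
  pass; validated against explicit flood fill).
- Surface area uses a marching-cubes mesh rather than voxel-face
  counting: face counting overestimates curved surfaces by up to 50%
  (a digitized ball's face-counted sphericity plateaus near 0.67), and
  the mesh estimator is the standard recommendation. Sphericity is
  π^⅓(6V)^⅔/A; compacity is the surface-to-volume ratio A/V (mm⁻¹).

Reproducibility is scored with the two-way absolute-agreement
single-measurement ICC (the strictest common variant) from the
classical mean-square decomposition; features below 0.90 are dropped.
Zero-variance features yield undefined ICC and are treated as failing.

## Deep radiomics

The CAE encodes the [0,1]-normalized, background-removed 64×64 CE
center slice through four stride-2 3×3 convolution blocks (channels
16/32/64/64) into a dense latent vector (default 1024, the deep
feature dimension of the motivating design); the decoder mirrors it
with nearest-neighbor upsampling + convolution (avoiding checkerboard
artifacts) and a sigmoid output. Training uses Adam (base rate
1.5×10⁻³, cosine-decayed to 0 over the default 40 epochs, batch 16)
with random horizontal/vertical flip augmentation by default; a
fuller augmentation set (±20° rotation, ±10% zoom, mild elastic
deformation, ±5% intensity jitter) is available. The network stack is
a small in-repo numpy implementation (im2col convolutions, manual
backprop) verified against numerical gradients; it is deliberately
CPU-scale.

The HSCAE is the identical code path with λ > 0: the loss is
MSE + λ × (negative batch-wise Cox partial log-likelihood with Breslow
ties of a linear risk head on the latent vector). This form was chosen
because it directly targets the survival signal that the prognostic
grouping is meant to capture; λ defaults to 0.05–0.3 at desk scale
(the reconstruction term dominates, the risk head orients the latent).
"Leave-10%-out repeated 100 times" is implemented as repeated random
90/10 splits recording held-out reconstruction MSE per repeat, with
the repeat count configurable (5 by default for testing; 1 suffices
for the reconstruction contract; 100 mirrors the original protocol).
The reconstruction contract is MSE < 0.01 on the [0,1] scale
("below 1%"). Class-activation maps are Grad-CAM on the last encoder
convolution with respect to the risk output: channel weights are
spatial gradient means, the weighted activation sum is rectified and
bilinearly upsampled.

## Consensus clustering

Features are center-scaled (population SD; zero-variance columns
dropped with a warning). Each of B resamples keeps a random 60% of
subjects ("leave-one-out of 40%"), clusters them by average-linkage
hierarchical clustering on the Pearson distance, and increments
co-cluster/co-sample counts; consensus(i,j) is their ratio, with
never-co-sampled pairs (only possible at very small B) imputed at 0.5.
The final partition cuts the average-linkage tree of 1 − consensus.

**Choice of k.** The criterion had to be fixed here (the original
analysis reports the resulting k but not the rule). Two standard
candidates fail on planted data: the delta-area rule degenerates
because the area term at k = 2 always dominates and splits beyond the
true k keep adding area, and PAC cannot distinguish a stable-but-wrong
coarse merge (or stable realized-noise substructure) from true
clusters, since both drive ambiguity to zero. The package instead
maximizes the mean silhouette width of the consensus partition under
the full-data Pearson distance, which penalizes both merging distinct
groups and splitting tight ones; candidates whose smallest cluster
falls below 5% of the cohort are disqualified (outlier singletons
otherwise make any k look stable), and ties go to the smaller k.
The acceptance suite measures planted-k recovery at strong separation
over 20 seeds for k = 2 and k = 3 (≥ 19/20 required). `k_fixed`
overrides the criterion.

Clusters are renamed A, B, C… by decreasing size (ties keep original
order). Centroids are per-cluster means of scaled features and are
stored with the scaler; new observations are standardized with the
stored parameters and assigned to the centroid at minimal Pearson
distance, ties to the lexicographically first name.

## Survival statistics

Cox models use Efron tie handling (lifelines) with Wald 95% CIs;
categorical covariates are reference-coded (first Categorical level,
else lexicographic). Multivariable fits are complete-case with dropped
subjects counted; backward selection freezes the complete-case set of
the full model so AICs are comparable, and removes the covariate whose
removal most decreases AIC until no removal does. Harrell's c-index
counts pairs orderable under censoring (earlier time with an event),
ties in risk as ½; it is implemented in-repo and checked exactly
against pair enumeration. Cross-validated c-indices use folds
stratified by the event indicator; fold means are reported with a
percentile interval across folds (crude at 5 folds, by construction).
Bootstrap model comparison resamples subjects with replacement,
recomputes both CV c-indices with shared fold seeds (paired
differences; identical specifications give exactly zero), and reports
the two-sided percentile p-value — sidedness was unstated in the
source and two-sided is the conservative choice. Chi-square tests are
Pearson, Yates-corrected only for 2×2 tables — the convention
validated to four decimals against the three published
radiomics-vs-transcriptomics association p-values. Group-location
tests default to rank tests (Mann–Whitney with asymptotic tie-corrected
p for two groups, Kruskal–Wallis beyond); normality-gated t-tests were
deliberately dropped. SARCULATOR Pr-OS categories: low ≤ 0.51 <
intermediate ≤ 0.66 < high. The semantic radiophenotype is high-risk
iff ≥ 2 of {heterogeneous T2 signal, necrosis, peritumoral
enhancement}. The combined group keeps the (radiomics, RNA) pair and a
binary contrast of the double-worst combination ("AxA") against all
others.

## Transcriptomics

Log2-CPM uses a 0.5 count offset. The voom-style weights come from a
single-pass mean–variance trend: square-rooted residual SDs under the
group-means model are lowess-regressed (frac 0.5) on mean log2 count,
and each observation's weight is the inverse fourth power of its
interpolated trend value; no second-round reweighting. ComBat batch
correction delegates to scanpy's parametric empirical-Bayes
implementation (single batch is the identity; singleton batches are
rejected). Differential expression is per-gene Welch t-tests on log2
expression (unweighted; the pooled-variance option exists in scipy but
Welch is the safer default), gated at BH-adjusted p < 0.05 AND
|log2FC| ≥ 1 — the fold-change-2 gate is from the source protocol, the
alpha is this package's (configurable) choice. Note that genes planted
exactly at fold change 2 sit on the gate boundary and are called only
about half the time; recovery contracts therefore plant log2FC = 2.
Enrichment is hypergeometric over-representation of the DE genes per
set with BH across sets plus the up-regulated proportion per set;
ranked GSEA is out of scope. PAM follows the nearest-shrunken-centroid
construction: d_kj = (x̄_kj − x̄_j)/(m_k(s_j + s₀)) with s₀ the median
pooled SD, soft-thresholded at Δ; Δ is picked by the one-standard-error
rule on the class-stratified CV error curve; empty signatures flag the
model and predictions fall back to the majority prior.

## Problem sizes

Default test/acceptance scales were chosen so the full pipeline stays
CPU-friendly while every contract remains sharp: cohorts of 24–200
subjects, 400–2000 genes, B = 40–200 consensus resamples (the
full-scale protocol value is 10⁴ and is the CLI default), CAE at 64×64
with ~2M parameters, 10–20 seeds per Monte-Carlo contract. The
consensus Monte-Carlo error shrinks as 1/√B, so small-B runs differ
from the B = 10⁴ protocol only in sampling noise, which the tests
verify directly.

## Known limitations

- The harmonization surrogate removes smooth polynomial bias only; it
  is not an N4 reimplementation and will under-correct bias fields
  with higher spatial frequency than the chosen order.
- The CAE stack is single-channel and 2-D by design (the deep branch
  of the source analysis is too); no pre-trained weights, no GPU.
- The exact prognostic-loss form, architecture and augmentation set of
  the original HSCAE are not public; the ones here are explicit,
  documented stand-ins with the same contracts.
- Bootstrap c-index comparison is computationally heavy (B × folds
  Cox fits); use modest B in exploration.
- Voom weights are computed but the default DGE t-test is unweighted;
  a weighted test is a possible extension.
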