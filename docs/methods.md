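# Methods

`pestgs` implements a four-stage pipeline for genomic selection of
pest-resistant germplasm: (1) convolutional networks score leaf photographs
into a binary mild/severe damage label and a continuous 0–5 pest damage
score (PDS); (2) per-image scores are aggregated into per-accession
phenotypes and compared against a phylogenetic ordering with Spearman's
footrule; (3) a linear mixed model maps the phenotypes to SNPs; (4)
GWAS-ranked markers feed a suite of machine-learning genomic-selection
models under a fixed cross-validation protocol. A synthetic-data module
generates every input with known ground truth, so each stage is verifiable
at desk scale. This note records the models, their assumptions, the
defaults, and what the synthetic conditions do and do not demonstrate.

## Synthetic leaves

A leaf image is a green ellipse (random orientation and axis ratio) with a
midrib, lateral veins, and low-frequency colour mottling, on a soil-coloured
background. Feeding damage is rendered as irregular background-coloured
blobs clipped to the blade; blobs are added, with per-blob radius shrinking
on overshoot, until the realised damaged-area fraction is within ±0.02 of
the request. The stored `damage_fraction` is the realised value, and labels
derive from it:

- binary label: 1 iff damage > 25% of the blade;
- severity class: 1 for ≤20%, stepping by one class per additional 20%
  (class 5 above 80%).

The two rules intentionally use different thresholds, so fractions in
(0.20, 0.25] are severity 2 with binary label 0, and there is no severity 0
even though the regression head can emit values below 1. Rendering detail
is deliberately minimal: the networks must learn *area of damage*, nothing
else, and passing tests on these images says nothing about photographic
nuisance factors (lighting, focus, occlusion, non-pest lesions). The
damage-fraction distribution of generated datasets defaults to uniform on
[0, 0.95]; this is a choice, not an inference from any real cohort.

## Synthetic cohorts

Genotypes follow a Balding–Nichols model: ancestral alternate-allele
frequencies are uniform on `maf_range` (default 0.05–0.5); each of
`n_pops` (default 3) sub-populations draws its own frequency from a Beta
distribution with variance `fst · p(1−p)` (default F_ST 0.1, matching a
moderately structured germplasm panel). Haplotypes are thresholded AR(1)
Gaussians: within blocks of `ld_block_len` SNPs (default 10, SNPs every
500 bp on 5 chromosomes) adjacent latent variables share correlation
`ld_rho` (default 0.9), which yields adjacent dosage r² around 0.2–0.4
decaying with distance; blocks and chromosomes reset the chain. Missing
calls are injected at `missing_rate` and stored as a sentinel — never
imputed in the matrix itself (association drops them per SNP; kinship
mean-imputes transiently).

Phenotypes are additive: `n_qtl` SNPs (default 50) get N(0,1) effects; the
environmental variance is scaled so Var(genetic)/Var(total) equals `h2`
(default 0.6). The continuous phenotype maps liability affinely onto
[0, 5]; the binary phenotype thresholds the standardised liability at
`liability_threshold` (default 0, i.e. a balanced cohort). One liability
carries both trait types, mirroring a study design where the same damage
severity is read out both ways. The simulator reports the causal indices
and true genetic values for recovery tests.

The ordered tree is a ladder (caterpillar) topology whose tip order
interpolates between a uniform random permutation (`signal=0`) and the
exact phenotype rank order (`signal=1`) by partial shuffling.

## Damage networks

Because the scoring networks are the package's own contribution, they run
on a small in-repo NumPy engine (`pestgs.nn`): NHWC 'same' convolutions via
im2col, 2×2 max pooling, two-conv residual blocks with 1×1 projections,
global average pooling, dense layers, inverted dropout, and a scaled
sigmoid head; losses are MSE (with MAE tracked) and binary cross-entropy;
the optimiser is Adam. All randomness (initialisation, shuffling, dropout)
flows from caller-supplied seeds, so training runs are bit-reproducible on
one machine.

The PDS regressor is a VGG-style backbone, then exactly four residual
blocks (two convolutions each; full-scale filters 512/256/128/64), global
average pooling, three 1024-unit ReLU layers each followed by dropout 0.3,
and a 1-unit sigmoid scaled by 5 — the forward output is bounded in [0, 5]
for any weights. Binary classifiers share the engine with a two-layer
4096-unit head, dropout 0.5, and a plain sigmoid paired with BCE. The six
selectable binary backbones (alexnet … densenet121) are *architecture
presets at configurable scale inside this engine* — VGG-style stacks, with
residual stages for the resnet-named ones — not reproductions of the
published topologies; their early-stopping patience runs from 20 (alexnet)
to 40 (densenet121), interpolated between. `tiny` presets (64 px input,
backbone [16, 32], residual filters [32, 16, 8, 8], 64-unit head) exist so
the full train/score loop runs on one CPU in minutes. An optional
`freeze_backbone` flag excludes backbone parameters from optimisation when
externally trained weights are loaded; no weights ship with the package.

Training uses early stopping on validation loss: an improvement is a strict
decrease by ≥1e-6; training halts after `patience` non-improving epochs
(35 for the regressor by default; 300-epoch cap) and the best-epoch weights
are restored. Hyperparameter search is a 5-fold CV grid over learning rate
{1e-4, 1e-3, 1e-2} and batch size {32, 64, 128}; fold membership is a pure
function of the seed; ties break toward the lower learning rate, then the
smaller batch. Regression targets are the severity classes as labelled
(1–5); the true damage fraction is kept alongside for property tests such
as the monotonicity of predicted score in true damage.

At desk scale (600 training leaves at 64 px) the tiny regressor reaches
held-out MAE ≈ 0.27 on the 0–5 scale with Spearman ρ ≈ 0.99 against the
true fraction, and the tiny classifier ≈ 95% accuracy; these numbers
bound what the architecture can do on clean synthetic leaves, not on
photographs.

## Accession phenotypes and the footrule test

Per-accession phenotypes aggregate per-image scores: the binary phenotype
is 0 iff the mean severe-probability is below 0.5 (exactly 0.5 maps to
severe, since the mild rule is strictly "below"); the continuous phenotype
is the arithmetic mean of the per-image damage scores. Group comparisons
wrap stock statistics: Shapiro–Wilk per group, Bartlett across groups,
pairwise two-sided Wilcoxon rank-sum tests; undersized groups are flagged
and skipped rather than fatal.

Spearman's footrule between two rankings of n elements is the sum of
absolute position differences (range 0 to ⌊n²/2⌋; mean (n²−1)/3 under a
uniform random permutation). The association test draws `n_perm` random
orders (default 1000, with 100 as the protocol preset), computes their
distances to the tree order, and reports a two-sided one-sample t-test of
that null sample against the observed distance. Note what this t-test is:
a test of equality with the null *mean*, whose statistic grows like
√n_perm for any fixed discrepancy — it is the protocol statistic, not a
calibrated association test. The result therefore also carries a one-sided
empirical permutation p-value P(null ≤ observed), which is uniform under
no association; tests of calibration use that field. Phenotype ties in the
rank order break by accession id (stable).

## GWAS

SNPs are filtered on missingness (≤0.05) and MAF (≥0.05), boundaries kept
(exclusion applies strictly beyond the thresholds); the filter is
idempotent. Kinship is the centred GRM K = ZZ′/m. The association model is
the exact mixed model y = Wα + xβ + u + ε, u ~ N(0, σ²_g K),
ε ~ N(0, σ²_e I), with W an intercept by default (principal-component
covariates optional via a slower per-SNP path; binary phenotypes are
analysed as quantitative 0/1). One eigendecomposition of K rotates the
problem; for every SNP the restricted likelihood is profiled over
λ = σ²_g/σ²_e on a 100-point log grid (1e-5…1e5) with golden-section
refinement, vectorised across SNPs; β and its standard error come from GLS
at the optimum and (β/se)² is referred to χ²₁. With K forced to zero the
scan reproduces OLS to machine precision, and on a structured polygenic
null (n=300, m=5000, h²=0.5) the p-values are uniform with genomic-control
λ ≈ 1.0. Significant SNPs (P < 1e-5, the protocol's fixed line) merge into
QTLs within 100 kb (the merge radius is this package's choice).

Window statistics: Hudson's F_ST as a ratio of averages per window
(pairwise means when more than two populations), π as per-window expected
heterozygosity 2p(1−p)·2n/(2n−1) summed per bp, and LD r² as the squared
dosage correlation over jointly non-missing samples. Windows are 1-based
inclusive; empty windows are omitted.

## Genomic selection

Markers are LD-pruned in sliding windows (100 SNPs, step 50, r² ≤ 0.2;
the removed member of an offending pair is the lower-MAF SNP, ties to the
later position — the victim rule is fixed here and asserted by an
exhaustive post-scan on every run), then ranked by ascending Wald p with
(chrom, pos) tie-breaks. Marker-count grids follow the protocol
({1, 10, 50*, 100, 500, 2000, 5000, ALL} binary;
{10, 52*, 100, 500, 2000, 5000, 10000, ALL} continuous), where the starred
"all significant" entries are replaced by the cohort's actual
significant-hit count and entries beyond the available markers are
dropped.

The CV protocol: 10% of samples are drawn once per master seed as an
untouched holdout; each of `n_iter` iterations (default 100) re-splits the
remaining 90% 4:1 and scores every (learner, count) combination on the
validation fifth — accuracy for binary, Pearson r for continuous; the
comparison is the mean over iterations, and only the winner is refitted on
the full 90% and scored once on the holdout (binary adds the point-biserial
correlation). Whether the holdout should be redrawn per iteration is left
as a flag-level alternative; the default fixes it per master seed so the
comparison never touches test phenotypes. Learners: logistic regression,
SVC, random forest, Gaussian naive Bayes (binary); lasso, ridge, elastic
net, SVR, random forest (continuous); a closed-form kernel-ridge GBLUP
baseline is available but outside the compared suites. Support-vector
kernels {linear, poly, rbf} are chosen by CV with ties to linear. Dosages
are column-standardised for all but the tree models. Ridge's default
penalty equals the marker count (the ridge-BLUP equivalence for
standardised markers with equal per-marker effect variance); a fixed unit
penalty under-shrinks severely once markers outnumber samples.

One desk-scale behaviour deserves a flag. On a simulated cohort (n=400,
m=2000, 50 QTLs, h²=0.6) the metric-vs-marker-count curve rises to the
causal-sufficient count (~100) and stays flat through the stepwise counts,
but *drops* at the all-markers entry: after pruning to r² ≤ 0.2 the ~850
retained markers are effectively independent, and whole-genome accuracy is
capped near √(h²·n/(n+Me)) ≈ 0.4 regardless of learner or shrinkage. Real
resequencing panels behave differently — massive LD makes hundreds of
thousands of markers act as few effective segments — so the package treats
the stepwise GWAS-ranked counts as the selection curve and reports the
all-markers entry as a separate whole-genome baseline. Conclusions about
"more markers never hurt" do not transfer from such desk-scale cohorts to
dense real panels, in either direction.

## Problem sizes and determinism

Default verification sizes — 600 training leaves at 64 px, GWAS cohorts of
n=300 with m=2000–5000 SNPs, 50 recovery replicates, GS with n=400 and 20
CV iterations — were chosen so the whole verification pass completes in a
few minutes on one CPU while keeping every statistical check comfortably
powered. Every stochastic component (simulators, weight initialisation,
batching, dropout, fold and holdout assignment, permutation draws) derives
from explicit seeds through independent `SeedSequence` streams, and all
writers emit fixed-format text, so any stage rerun with the same seed
reproduces byte-identical TSV/JSON output.

## Known limitations

- Synthetic leaves exercise the area-of-damage contract only; no claim is
  made about real photographs, and the deterministic colour-based leaf
  detector assumes a green-dominant leaf on a non-green background.
- The named binary backbones are scale-configurable stand-ins, not the
  published architectures; full-scale presets are CPU-hostile.
- The LMM treats binary traits as quantitative, as the protocol does;
  no liability-scale transformation is applied to effect sizes.
- Hudson's F_ST with more than two populations is a mean of pairwise
  estimates, not a joint estimator.
- The t-test form of the footrule test is reported for protocol fidelity;
  calibrated inference should use the empirical permutation p-value.
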