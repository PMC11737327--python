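# Methods

## Problem and pipeline

`genocam` studies case/control genome-wide association data with an image
classifier. Genotypes at biallelic SNPs are coded by minor-allele dosage
(AA = 0, Aa = 1, aa = 2, missing = −1). Each sample's genotype vector is laid
out on a square pixel grid, colored by an encoder, and the resulting images
are classified case-vs-control by a small convolutional network. Risk SNPs
are then screened from the trained network's Grad-CAM attribution maps.
The pipeline is four stages — simulate (or load), encode, train, screen —
each of which reads the previous stage's on-disk artifacts.

## Genotype simulation

Controls are drawn per SNP from Hardy–Weinberg proportions
((1−q)², 2q(1−q), q²) at minor-allele frequency q; cases from the
retrospective distribution P(g | case) ∝ P(g)·RR(g) with RR(AA) = 1,
RR(Aa) = rr_het, RR(aa) = rr_hom — the standard rare-disease approximation
for case/control sampling. Defaults:

| parameter | default | meaning |
| --- | --- | --- |
| n_cases / n_controls | 4,000 / 4,000 | balanced design |
| n_null_snps / n_risk_snps | 1,800 / 200 | 10% of SNPs carry risk |
| maf range | Uniform(0.05, 0.5) | post-QC common variants |
| rr_het | 1.5 | heterozygote relative risk |
| rr_hom | rr_het² | multiplicative (allelic) risk model |
| missing_rate | 0 | post-QC data is essentially complete |

The multiplicative model matches the model family of PLINK-style
case/control simulators and makes rr_het the single effect-size knob.
Risk SNPs are scattered uniformly over the SNP order so image layouts do
not cluster them. Under a fixed seed the generator is bit-reproducible.

What the simulator does *not* emulate: linkage disequilibrium (SNPs are
independent), population structure, genotyping batch effects, and
covariates. Passing benchmarks on this generator therefore demonstrate
that the pipeline recovers independent marginal effects, not that it
handles correlated real-world genotype structure.

## QC and association pre-screen

QC applies, in order: individual missingness (> 5% dropped), SNP
missingness (> 5%), MAF (< 5%, computed on all remaining samples), and
Hardy–Weinberg equilibrium (1-df chi-square p < 1% computed on controls
only — cases may deviate from HWE through genuine association). The
association pre-screen is the allelic 1-df chi-square on the 2×2
minor/major × case/control allele-count table without continuity
correction; genotype g contributes g minor and 2−g major alleles.
Monomorphic SNPs report p = 1 with a flag rather than erroring
mid-pipeline. The exact HWE test is noted as future work; at pre-screen
scale the chi-square approximation is conventional.

## Image encoders

The minimal square side for n SNPs is the smallest s with s² ≥ n
(2,000 SNPs → 45). Layouts are invertible SNP↔cell maps:

* end-to-end (row-major) for the color (CC) and Chen encoders;
* chromosome rows for Yue: each chromosome starts a fresh row and pads its
  last row, so the minimal feasible side is the smallest s with
  Σ_c ⌈len_c / s⌉ ≤ s. For single-chromosome data the two coincide.

Encoder tables: CC maps AA/Aa/aa → (0,0,255)/(0,170,0)/(85,0,0) with black
padding, making all four cell states distinct (lossless); Chen maps
AA/Aa/aa → 0/154/254, where AA collides with padding by construction — a
documented information loss of that scheme, preserved faithfully; Yue codes
the 10 unordered base pairs 1–10 (lexicographic AA, AC, AG, AT, CC, CG,
CT, GG, GT, TT — any fixed bijection carries the same information) scaled
by 25. Missing genotypes render as the padding value in every encoder and
decode back to −1 only where the palette allows (CC). Images are stored as
8-bit PNG/BMP only; lossy formats are refused so decode∘encode stays exact.

## Classifier

Fixed skeleton: three stages of conv(k×k, 'same', stride 1) → ReLU →
maxpool(2×2, stride 2), inverted dropout on the last conv activations,
flatten, dense → 2-way softmax. The four tuned hyperparameters and their
box: filter size ∈ {3,5,7}; learning rate ∈ [1e−3, 1] (log scale);
momentum ∈ [0.9, 0.98]; L2 ∈ [1e−10, 1e−2] (log scale). Training is plain
minibatch SGD with momentum and cross-entropy + L2 on weight matrices, at
most 60 epochs, returning the epoch snapshot with the best validation
accuracy on a stratified 6:2:2 train/validation/test split.

Open choices and defaults: conv widths (32, 64, 128), dropout 0.5,
batch size 128, He initialization, all configurable and echoed into run
reports. Model inputs are pixels scaled by 1/255 and then centered by the
training set's per-channel mean; centering is part of the model boundary
because all-positive channel inputs measurably slow SGD at the learning
rates in the box. The forward/backward passes are explicit numpy
(im2col convolutions), which both keeps the dependency surface small and
exposes exact gradients of the class score with respect to the last conv
activations for Grad-CAM. Divergence (non-finite loss) aborts the trial
with a dedicated exception that the hyperparameter optimizer treats as a
failed trial, not a fatal error.

Hyperparameter search is sequential model-based optimization: a Gaussian
process (Matern 5/2 + white noise) on the unit-cube-scaled box, expected
improvement maximized over a seeded random candidate cloud plus local
perturbations of the incumbent; the categorical filter size is relaxed to
a continuous coordinate and rounded. Default budget 20 trials, first 5
random.

## Grad-CAM screening

For every *test* sample the model predicts as a case (true labels play no
role), the Grad-CAM map at the last conv layer is: α_k = spatial mean of
∂(case logit)/∂A^k; map = ReLU(Σ_k α_k A^k), bilinearly upsampled to input
resolution. Maps are accumulated first and min–max normalized second (so
confident samples weigh more); a constant accumulated grid normalizes to
all ones with a degeneracy flag rather than dividing by zero. Per-SNP
weights are read at each SNP's layout cell (padding dropped), the top
⌈5% · n⌉ by weight are screened (ties broken by ascending SNP index for
reproducibility), and gene-level scoring joins an offline snp→gene TSV and
a reference risk-gene list: risk-gene ratio = |screened genes ∩ reference|
/ |screened genes|, not applicable when no screened SNP is annotated.
Everything downstream of the trained model is deterministic.

## Desk-scale benchmark and its observed ceiling

The reference benchmark (`genocam.benchmark`) runs the whole pipeline at
desk scale: 2,000 samples × 400 SNPs with 40 risk SNPs at rr_het = 2,
side-20 images, fixed hyperparameters (filter 5, lr 0.01, momentum 0.9,
L2 1e−6), conv widths (8, 16, 32), batch 64, ≤ 40 epochs. These sizes keep
a full multi-seed battery tractable on one CPU.

A structural property of this configuration is worth documenting. At input
side 20 the three stride-2 poolings leave a 2×2 spatial grid, so the dense
readout sees only four coarse receptive fields; convolution weights are
shared across positions, so SNP-specific weighting — which is what the
additive risk signal rewards — is only expressible through within-block
position sensitivity shared across the four blocks. Empirically the
benchmark classifier plateaus around 0.7 test accuracy while a tuned
logistic regression on the raw genotype codes of the same data reaches
about 0.86 and the true-parameter likelihood-ratio classifier about 0.93;
refitting an optimally regularized linear readout on the trained network's
own penultimate features reproduces the network's accuracy almost exactly,
showing the pooled representation (not optimization) is the binding
constraint. At the publication-scale geometry (side 45, a 5×5 final grid,
4× the samples) this ceiling relaxes considerably. The color-vs-grayscale
comparison and the Grad-CAM screening enrichment are evaluated under the
same conditions for both encoders, so relative conclusions are unaffected
by the ceiling.

## Numerical details

* Chi-square p-values via the survival function of scipy's chi2 at 1 df.
* Max-pool ties route gradients to the first maximal element (argmax
  convention); odd trailing rows/columns are dropped (45 → 22 → 11 → 5).
* Min–max normalization maps a constant grid to all ones, flagged.
* PLINK text reader anchors codes to the per-SNP majority allele,
  lexicographic on ties; a SNP whose sample minor-allele count exceeds half
  re-anchors, so round trips are exact whenever sample majority matches the
  generating major allele.
* All stochastic stages take explicit seeds; training is deterministic on a
  fixed seed up to BLAS reduction order.
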