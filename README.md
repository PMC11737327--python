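# genocam

Color-image genotype encoding, CNN case/control classification, and
Grad-CAM risk-SNP screening for genome-wide association studies (GWAS).

Case/control GWAS data is a samples × SNPs matrix of minor-allele dosages
(AA = 0, Aa = 1, aa = 2). `genocam` converts each sample into a square
image, trains a convolutional network to classify cases against controls,
and then reads the trained network's attention back to SNP coordinates to
screen candidate risk SNPs. It is aimed at researchers studying
image-based deep-learning approaches to GWAS: it bundles a case/control
genotype simulator, standard QC and association pre-screening, three
genotype-to-image encoders, a fully seeded CNN with Bayesian
hyperparameter optimization, and a Grad-CAM screening stage — all usable
from Python or from a thin command-line interface.

## The methods in brief

**Encoding.** For n SNPs the minimal square side is the smallest s with
s² ≥ n (2,000 SNPs → 45×45). The color encoder (CC) maps
AA → (0, 0, 255), Aa → (0, 170, 0), aa → (85, 0, 0), padding → (0, 0, 0):
every cell state has a distinct color, so encoding is lossless. Two
grayscale baselines are included: Chen (AA/Aa/aa → 0/154/254, where AA
collides with padding — a real information loss, preserved faithfully) and
Yue (the 10 unordered base pairs coded 1–10, ×25, chromosome-per-row
layout).

**Classifier.** Three stages of conv(k×k, 'same') → ReLU → maxpool(2×2,
stride 2), dropout on the last conv stage, flatten, dense → 2-way softmax;
SGD with momentum, ≤ 60 epochs, best-validation-epoch selection on a
stratified 6:2:2 split. Four hyperparameters are tunable by Gaussian-process
Bayesian optimization (expected improvement): filter size ∈ {3, 5, 7},
learning rate ∈ [10⁻³, 1], momentum ∈ [0.9, 0.98], L2 ∈ [10⁻¹⁰, 10⁻²].

**Screening.** For test samples the model predicts as cases, Grad-CAM maps
at the last conv layer (αₖ = spatial mean of ∂score/∂Aᵏ, map =
ReLU(Σₖ αₖ Aᵏ), bilinearly upsampled) are accumulated, min–max normalized
into per-pixel weights, read off at each SNP's layout cell, and the top 5%
of SNPs are screened. Offline snp→gene annotation plus a reference
risk-gene list yields the risk-gene ratio |screened ∩ reference| /
|screened|.

**Simulation.** Controls follow Hardy–Weinberg proportions at each SNP's
MAF; cases follow the retrospective distribution P(g|case) ∝ P(g)·RR(g)
with a multiplicative risk model (rr_hom = rr_het²). QC (missingness, MAF,
HWE) and the allelic chi-square pre-screen mirror standard GWAS practice.

See `docs/methods.md` for assumptions, defaults, numerical details, and
known limitations (including how attribution resolution scales with image
side).

## Worked example

```bash
python examples/simulate_and_prescreen.py
```

```
simulated 1000 samples x 500 SNPs (50 risk)
QC: individual missingness > 0.05: removed 0
QC: SNP missingness > 0.05: removed 0
QC: MAF < 0.05: removed 2
QC: HWE p < 0.01 (controls): removed 9
after QC: 1000 samples x 489 SNPs
pre-screen P<=0.01 keeps 55 SNPs, 49 of them planted risk
```

The simulator planted 50 risk SNPs with heterozygote relative risk 2. QC
removes a couple of SNPs whose sampled MAF fell below 5% and a few
chance Hardy–Weinberg failures; the allelic pre-screen at P ≤ 0.01 then
keeps 55 SNPs, 49 of which are genuinely risk — the remaining ~6 are the
expected ~1% false positives among the null SNPs.

```bash
python examples/train_and_screen.py
```

```
best epoch 14: val accuracy 0.767
test: accuracy 0.800 recall 0.700 precision 0.875 f1 0.778
top-5% screen selects 5 SNPs, 0 of them planted risk
```

On a 600-sample toy set the classifier reaches 0.80 test accuracy (chance
is 0.5), showing the planted signal is learned; at this tiny image side
the Grad-CAM grid is too coarse for reliable SNP-level localization (the
example and `docs/methods.md` discuss why resolution grows with image
side).

The other examples cover the three encoders
(`encode_genotype_images.py`) and the Bayesian optimizer
(`optimize_hyperparameters.py`). The same pipeline is available as a CLI:

```bash
genocam run-all --out runs/demo --cases 200 --controls 200 \
    --null-snps 160 --risk-snps 40 --max-epochs 10 --seed 0
```

with `simulate`, `encode`, `train`, and `screen` subcommands for the
individual resumable stages.

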