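# gsimpute

Reference-panel genotype imputation with a residual convolutional
denoising autoencoder, built for **low-density across-population genomic
selection (LA-GS)** in crops.

## The problem

Across-population genomic selection needs the same markers genotyped in
every population, but breeding populations are typically genotyped on
different low-density chips whose intersection is far too small for
genome-wide prediction. With marker sets A (population I), B
(population II) and P (reference panel), `gsimpute` standardizes both
populations onto the shared set **(A ∪ B) ∩ P** by *reconstructive
imputation*: population I is imputed against the panel at the positions
of population II's chip (and vice versa), so the markers to fill form
systematic missing columns mixed with each sample's own sporadic gaps.

## The method

Genotypes are coded 1 (A₁A₁), 2 (A₁A₂), 3 (A₂A₂), 0 (missing) and
one-hot encoded as [1,0,0] / [0,1,0] / [0,0,1] / [0,0,0]. A denoising
autoencoder of eight same-padded 1-D convolutions (input channels
3-32-64-64-128-64-64-32, kernel 15, stride 1), with max-pooling /
repeat-upsampling, identity residual skips and layer normalization, maps
a corrupted window of up to 1000 markers to per-position 3-class scores,
trained with cross-entropy, Adam (lr 10⁻³, ε 10⁻⁸, weight decay 10⁻⁵),
batch 64, ≤150 epochs, a reduce-on-plateau schedule (×0.9, patience 0)
after epoch 100 and best-loss checkpointing. Dropout adapts to the
window's genotype missing rate *mr* as `0.3 − (mr − 0.1)/8`.

The decisive ingredient is **data-adaptive masked-marker generation by
automatic sample matching**: each testing sample is ranked by its mean
Manhattan distance to the panel, greedily matched (without replacement)
to its nearest panel samples, and its exact missing pattern is stamped
onto them — so the network trains on precisely the missingness it must
impute. For general imputation the training set is additionally
augmented with KNN-imputed testing samples carrying masks borrowed from
their nearest testing neighbours.

A GBLUP module (`y = Xβ + a + e`, `a ~ N(0, G_a σ_a²)` with the VanRaden
relationship matrix and REML over h² by eigendecomposition) demonstrates
the downstream across-population prediction step.

## Worked example

```python
from gsimpute import (SimulationConfig, simulate_panel, derive_populations,
                      mask_genotypes, GeneralImputation, NetworkConfig, evaluate)

sim = SimulationConfig(n_panel=150, n_pop1=20, n_pop2=2, p=200,
                       n_founder_haplotypes=8, switch_rate=0.01, seed=42)
panel = simulate_panel(sim)
pop1, _ = derive_populations(panel, size_a=200, size_b=200, overlap=1.0, seed=43)

masked, mask = mask_genotypes(pop1, rate=0.3, pattern="sporadic", seed=44)
cfg = NetworkConfig(window=200, max_epochs=60, seed=45)
result = GeneralImputation(masked, panel, cfg).fit()
print(result.summary())
report = evaluate(result.genotypes, pop1, mask)
print(report.to_text())
```

prints

```
Imputation result
-----------------
samples              : 20
markers              : 200
windows trained      : 1
entries imputed      : 1200
input missing rate   : 0.3000
dropped target loci  : 0

masked entries evaluated : 1200
genotype CR              : 0.7950
allelic CR (all alleles) : 0.8896
genotype r2              : 0.6587
heterozygous-locus CR    : 0.6852

 maf_low  maf_high  n_masked  minor_cr   all_cr       r2
    0.00      0.05        30  0.000000 0.966667 0.920635
    0.05      0.10       101  0.733333 0.955446 0.875037
    0.10      0.20       281  0.593750 0.886121 0.675075
    0.20      0.30       190  0.689655 0.886842 0.666299
    0.30      0.40       208  0.748387 0.831731 0.342557
    0.40      0.50       215  0.809278 0.834884 0.287134
```

Of the 1200 genotypes hidden at a 30% sporadic rate, 79.5% are recovered
exactly (genotype CR) and 89.0% of alleles are correct; the squared
correlation between imputed and true codes is 0.66. The MAF table shows
the expected pattern: minor-allele CR rises with MAF while all-allele CR
falls, because at low MAF accuracy is carried by the abundant major
allele.

The same objects drive the LA-GS workflow: `two_way_impute(pop1, pop2,
panel, cfg)` returns two results on the identical (A ∪ B) ∩ P marker
set, ready for `GBLUP(y_train, r1.genotypes, r2.genotypes).fit()`.

A thin CLI mirrors the library: `gsimpute simulate | general |
reconstruct | twoway | gblup` (see `gsimpute --help`). VCF, the
marker-rows CSV/TXT genotype dialect and two-column position files are
supported; imputed output is the complete integer genotype table.

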