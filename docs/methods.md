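# Methods

This note documents the models, algorithms and design choices behind
`gsimpute`, the assumptions they rest on, and what the synthetic test
system does and does not establish about real data.

## Genotype representation

Biallelic SNP genotypes are integer-coded per sample × marker: 0 missing,
1 A₁A₁, 2 A₁A₂, 3 A₂A₂, with A₁ the allele matching the reference
genome. Phase is accepted on input and discarded: code 2 covers 0/1 and
1/0, phased or not. One-hot encoding maps 0 → [0,0,0] and codes 1–3 to
the corresponding unit vector, so a missing genotype is the zero vector
and contributes nothing to the first convolution.

Markers are identified by (chromosome, position) throughout. Loci whose
(ref, alt) pair disagrees between a target and the panel — including
swapped alleles — are dropped with a warning rather than strand-flipped:
silent flips can corrupt codes undetectably, and nothing in the method
depends on recovering those loci. Duplicate keys keep the first
occurrence. Multi-allelic and non-SNP records are skipped. In the CSV
dialect, sample columns begin after the right-most header named `ref`,
`alt` or `QCcode`; when only `QCcode` is present placeholder alleles A/G
are assigned (allele identity is never used downstream of such files).

## Masked-marker generation by automatic matching

The network is a denoising autoencoder: it learns to reconstruct clean
panel genotypes from deliberately corrupted copies. Random corruption
teaches the wrong task when the data to impute have structured
missingness (whole chip-absent marker columns plus per-sample dropouts).
The matching algorithm corrupts the panel with the testing set's own
patterns:

1. numeric-code the panel (Tr, n samples) and testing set (Te, m);
2. mean-fill Te's missing entries with panel column means;
3. compute the n × m Manhattan distance matrix;
4. average each testing sample's distance to the panel;
5. order testing samples by descending mean distance;
6. each testing sample, in order, claims its nearest still-unclaimed
   panel sample and stamps its missing positions onto it;
7. repeat rounds over the ordered list until every panel sample is
   claimed.

Ties (equal mean distances, equal nearest distances, voting ties in the
KNN step) always break to the smallest sample index or smallest
genotype code; matching is therefore fully deterministic. When n < m a
single round stops once panel samples are exhausted. The most distant
testing samples choose first: they are at greatest risk of being
matched badly, so they get the pick of the panel.

For general imputation the training set is augmented. The testing set is
first completed by k-nearest-neighbour majority vote (k = 5 by default;
distances on self-mean-filled codes; the vote is over the k nearest
samples with an observed call at the gap). The m × m testing distance
matrix, its diagonal raised to twice the maximum so no sample matches
itself, orders samples both descending and ascending by mean distance;
each pass greedily matches every arranged sample to its nearest
remaining KNN row without replacement and stamps the arranged sample's
missing pattern onto it, and each row's two masks are unioned. A
position originally missing in the matched row itself is never masked
there: its "clean" value is only a KNN estimate, so supervising on it
would train the network toward the KNN guess rather than the truth (the
only coherent alternative — excluding the arranged sample's own missing
positions from its own stamp — would empty the mask entirely). The n panel rows and m KNN rows are stacked
into the clean set, their corrupted counterparts into the training
input.

Matching runs once per training window, on that window's markers.
Re-generating masks every epoch is available (`remask_each_epoch`) but
off by default: the corrupted set is a deterministic function of the
data, so re-sampling changes nothing in the reconstructive case and only
adds cost.

## Network and training

Eight same-padded 1-D convolutions (kernel 15, stride 1, padding 7) with
input channels 3-32-64-64-128-64-64-32; the final convolution maps 32
channels to 3 class scores per position. ReLU follows every convolution
except the score layer; layer normalization (over channels, per
position) follows each ReLU and precedes each residual addition.
Max-pooling (factor 2) after convolutions 2 and 4 and repeat-upsampling
before convolutions 6 and 8 give a symmetric hourglass; window lengths
not divisible by 4 are zero-padded on the right internally and cropped
on output. Identity skips wrap the two channel-preserving 64→64
convolutions (one encoder-side, one decoder-side) — the only places an
un-projected identity is shape-compatible. Dropout (inverted) is applied
after each pooling stage; its rate follows the empirical rule
`0.3 − (mr − 0.1)/8` where mr is the corrupted training input's missing
fraction, computed per window — heavier corruption already regularizes
the task, so dropout backs off linearly.

Training minimizes cross-entropy between predicted scores and clean
genotype classes at every position whose clean genotype is known;
positions with unknown truth (originally missing panel entries never
occur — the panel is missing-free by contract — but KNN-augmented rows
keep their estimated values) are included, while a `loss_on_masked_only`
option restricts the loss to corrupted positions. Optimization is Adam
(lr 10⁻³, ε 10⁻⁸, L2 weight decay 10⁻⁵), batch 64, at most 150 epochs.
The monitored quantity is the full training-set loss recomputed each
epoch in evaluation mode (there is no validation split; none is
described for the procedure and the training set is the supervision).
Parameters are checkpointed whenever the monitored loss improves and the
best checkpoint is restored after training. From epoch 101 the learning
rate is multiplied by 0.9 after any epoch that fails to improve on the
best monitored loss (patience 0, min mode). A single integer seed drives
weight initialization, batch shuffling and dropout, making runs exactly
reproducible.

The engine is a self-contained NumPy implementation: im2col convolution
through BLAS matrix products, hand-written backward passes
(finite-difference-verified), max-pool argmax routing, and Adam. It is
single-threaded-CPU oriented and deliberately small — the architecture
above is the entire surface it must support.

Prediction takes the argmax over the 3 class scores (codes 1–3) at
missing positions; observed positions pass through unchanged.

## Windows and orchestration

Chromosomes train in non-overlapping windows of `window` markers
(default 1000). A terminal remainder r < window is handled by a
*reverse* window: training spans the last `window` markers, but its
predictions are used only on the final r — every marker is imputed by
exactly one window, and terminal regions see a full-width training
context. A chromosome shorter than the window trains as a single window.

General imputation restricts target and panel to their shared loci
(target-only loci are dropped and counted), then runs
matching + augmentation, training and prediction per window.
Reconstructive imputation builds the target over (A ∪ B) ∩ P — columns
in B \ A enter as all-missing (systematic) columns carrying panel
ref/alt metadata — and uses the reconstructive matching without
augmentation (augmentation adds nothing when the dominant pattern is
shared systematic columns, and skipping it halves the training cost).
Two-way imputation is literally two independent one-way runs; both
outputs land on the same (A ∪ B) ∩ P key set.

Ablation flags reproduce the component-removal variants at orchestrator
level: `matching=False` masks each panel row uniformly at random at the
testing set's mean per-sample missing count; `augmentation=False` skips
the KNN stacking; `residual`, `layernorm`, `batchnorm` and `dynamic_lr`
toggle the corresponding network/training pieces.

## Accuracy metrics

All statistics are computed over the evaluation mask (entries hidden on
purpose, truth known). Genotype CR is the fraction of masked entries
imputed to the exact code — both alleles must match. Allelic CR counts
allele copies: with alt-dosage c = code − 1 an entry contributes
2 − |c_true − c_imp| correct alleles out of 2; the minor-allele scope
restricts the denominator to true minor-allele copies (monomorphic loci
drop out). Genotype r² is the squared Pearson correlation of integer
codes over the mask, reported as undefined — never zero — when either
vector is constant (e.g. truth restricted to heterozygotes).
Heterozygous-locus CR is genotype CR restricted to true code-2 entries.
MAF bins use half-open intervals (0,0.05], (0.05,0.1], (0.1,0.2],
(0.2,0.3], (0.3,0.4], (0.4,0.5] with per-locus MAF computed from the
truth genotypes of the evaluated samples (that is the distribution the
evaluation is actually drawn from; panel frequencies are a defensible
alternative). Mask generators: systematic masking hides round(rate · p)
whole marker columns, sporadic masking hides round(rate · p) entries per
sample; rounding is to nearest, ties to even.

## Synthetic study system

The simulator is a Li-Stephens-flavoured haplotype-copying mosaic: per
locus allele frequencies are drawn uniformly above a MAF floor, founder
haplotypes are Bernoulli draws, and each sample haplotype copies a
founder, switching to a uniformly random founder between adjacent
markers with probability `switch_rate` (default 0.02) and flipping
alleles at `mutation_rate` (default 0.005). Defaults (200 panel samples,
1000 markers, 20 founders, 5% MAF floor) give tight local LD that decays
with distance and Hardy–Weinberg genotype frequencies — the structure
the autoencoder must learn. Derived populations share the panel's
founders (so imputation is learnable) and are genotyped on marker
subsets A and B with an exactly controlled overlap; an `unrelated`
switch draws fresh founders as a negative control. What this does *not*
emulate: realistic recombination maps, population stratification beyond
founder sharing, genotyping error, selection, or pedigree structure —
passing tests on this system show the machinery is correct and that
accuracy responds to LD and to matching as designed, not that any
particular accuracy level transfers to real crops.

A perfectly duplicated-marker panel (`duplicated_marker_panel`) provides
the sharpest probe: every even column equals its odd neighbour, so a
masked member of any pair is exactly recoverable; destroying the
pairing by per-column permutation collapses accuracy to the
major-genotype frequency. The test suite uses this contrast to verify
that the network's skill comes from marker-marker dependence and not
from class priors.

Phenotypes are purely additive: y = Σ β_q z_q + e with z ∈ {−1, 0, 1},
standard-normal effects at `n_qtl` random loci, and residual variance
set from the realized genetic variance to hit the target h² (default
0.5, 50 QTL).

## GBLUP

G_a is the VanRaden matrix: columns of the {−1,0,1} marker matrix
centred at 2p_j − 1 and the cross-product normalized by Σ 2p_j(1−p_j),
with frequencies from the combined train+test samples. The restricted
likelihood is profiled over h² ∈ (0,1) on the eigendecomposition of the
training-set G_a and maximized by bounded scalar optimization (xatol
10⁻⁶); at a fixed variance ratio the resulting BLUPs coincide with the
ridge-regression (RR-BLUP) closed form, which the tests verify to 10⁻⁶.
Fixed effects are an intercept only. Degenerate fits fall back to
h² = 0.5 and are flagged on the results object. Predictability is the
Pearson correlation between predicted and observed phenotypes.

## Problem sizes in the test suite

The suite exercises the full machinery at desk scale, chosen so the
whole run stays comfortably inside a coffee break on one CPU: the
denoising-skill check trains 50 epochs on a 200 × 200 duplicated-pair
panel; the ablation comparison trains 20 paired runs (10 seeds ×
matched/random) of 25 epochs on 60 × 80 mosaic panels; the end-to-end
LA-GS workflow simulates 280 markers, two-way imputes two populations
(windows of 140, 25 epochs) and compares GBLUP predictability of the
imputed (A ∪ B) ∩ P set (270 markers) against the 5-marker chip
intersection. Orchestration tests run 3-epoch trainings — they check
contracts, not accuracy.

## Known limitations

* The network engine is CPU/NumPy; very large panels or 1000-marker
  windows train slowly compared to GPU deep-learning stacks, though the
  windowed design bounds memory.
* Genotype output is hard calls; no dosages or imputation-quality scores
  are emitted.
* No phasing, no indels, no multi-allelic sites, no HMP format.
* Allele mismatches are dropped, never flipped; panels with systematic
  strand differences should be harmonized upstream.
* GBLUP is intercept-only (no environments/replicates) and single-trait.
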