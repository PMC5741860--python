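# hbdmix

Age-based partitioning of individual genomic inbreeding with a multi-class
homozygosity-by-descent (HBD) mixture hidden Markov model.

## The problem

Two alleles are homozygous-by-descent (autozygous) when both descend from a
single ancestral allele.  The inbreeding coefficient F of an individual is
the probability that a random locus is HBD — but that probability only has
meaning relative to a base population, and segments inherited from recent
ancestors are long while those from remote ancestors have been whittled
down by recombination.  Classical estimators (pedigree F, homozygosity, GRM
diagonals, rule-based runs of homozygosity) return a single number tied to
one implicit base population.  `hbdmix` instead decodes each genome into a
mosaic of non-HBD and *age-stratified* HBD segments, so inbreeding can be
partitioned by the age of the common ancestor and computed with respect to
any base population.

The package is aimed at quantitative and population geneticists working
with dense SNP-array or sequence genotypes in livestock, companion or wild
populations — anywhere recent inbreeding must be separated from background
autozygosity due to historical effective population size.

## The model

A genome is a mosaic of segments from K classes (K−1 HBD + 1 non-HBD).
Class-k segment lengths are Exp(R_k) in Morgans — R_k ≈ 2× the number of
generations to the common ancestor — and each new segment's class is drawn
from mixing proportions m_k.  Along a marker map this is an HMM with

    a(k,l) = e^(−R_k d)·[k=l] + (1 − e^(−R_k d))·m_l

transitions over d Morgans.  Inside HBD segments a marker is homozygous AA
with probability f_A(1−ε), BB with (1−f_A)(1−ε), heterozygous with ε; in
non-HBD segments genotypes follow Hardy–Weinberg proportions.  Sequence
data enter through genotype likelihoods (VCF PL/GL) integrated over the
three genotypes.  Fitting is per-individual EM (rates constrained to
[1, 8192]); forward–backward gives local and genome-wide HBD
probabilities; Viterbi gives discrete HBD segments; BIC compares models.
Three flavours: `1R` (one HBD class, shared rate), `KR` (free rates) and
`MixKR` (fixed dyadic rates 2, 4, …, 8192 — only mixing fitted, classes
comparable across individuals).

The genome-averaged probability of the HBD classes with R_k ≤ T is the
inbreeding coefficient F_G-T with the base population set ~T/2 generations
back; F_G uses all HBD classes.

Alongside the HMM the package provides the benchmark estimators (F_HOM,
F_ExHOM, F_GRM1, F_GRM2, F_UNI, pedigree F_PED), a plink-style sliding
window ROH caller with per-panel presets and F_ROH, PLINK/VCF/pedigree IO
with QC filters, and a synthetic mosaic-genome generator with full ground
truth.

## Worked example

Simulate five genomes (5 × 1-Morgan chromosomes, ~6.3K markers) from a
one-class truth with rate R = 20 and stationary HBD fraction 0.25, then fit
the 14-class MixKR model:

```python
import numpy as np
from hbdmix import HbdMixtureModel
from hbdmix.hmm import HbdModel
from hbdmix.simulate import (SimConfig, simulate_map,
                             simulate_frequencies, simulate_mosaic)

truth_model = HbdModel(rates=np.array([20.0, 20.0]),
                       mixing=np.array([0.25, 0.75]),
                       epsilon=0.002, kind="1R")
config = SimConfig(model=truth_model, n_chromosomes=5, chrom_length=1.0,
                   marker_spacing=0.0008, seed=7)
mmap = simulate_map(config)
freqs = simulate_frequencies(mmap.n_markers, 1.0, 1.0, maf_floor=0.01, seed=8)
geno, truth = simulate_mosaic(config, mmap, freqs, n_individuals=5, seed=9)

res = HbdMixtureModel(geno, mmap, kind="MixKR", K=14,
                      epsilon=0.002, freqs=freqs).fit()
print(res.summary())
```

```
HBD mixture model results
============================================================
model kind:        MixKR (K=14)
individuals:       5
markers:           6255
epsilon:           0.002
mean log-lik:      -4619.09
mean BIC:          9351.82
------------------------------------------------------------
inbreeding coefficient F_G (all HBD classes):
  mean 0.2719   min 0.2211   max 0.3435
------------------------------------------------------------
mean genome fraction per class:
  HBD_R2         0.0000
  HBD_R4         0.0222
  HBD_R8         0.1010
  HBD_R16        0.1379
  HBD_R32        0.0047
  ...
  nonHBD         0.7281
```

The fitted HBD mass concentrates in the dyadic classes bracketing the true
rate (R = 8 and R = 16 around the generative R = 20), and the cohort mean
F_G of 0.272 matches the simulated stationary HBD fraction.  Per
individual the estimates track the recorded truth closely:

```python
print("truth:", np.round(truth.hbd_fraction(), 4))
print("F_G:  ", np.round(res.inbreeding().to_numpy(), 4))
```
```
truth: [0.2221 0.2324 0.3438 0.2517 0.3065]
F_G:   [0.2211 0.237  0.3435 0.2495 0.3086]
```

`res.inbreeding(T=32)` gives the coefficients with the base population ~16
generations back, `res.segments()` the Viterbi HBD segments, and
`res.f_t_curve()` the full F_G-T curve per individual.

A `hbdmix` command-line tool wraps the same functionality:
`hbdmix simulate | qc | fit | decode | estimate | roh | report`.

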