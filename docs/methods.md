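# Methods

## The model

`hbdmix` treats a diploid genome as a mosaic of segments from K classes: one
non-HBD class and K−1 homozygosity-by-descent (HBD) classes indexed by age.
Segment lengths in class k are exponential with rate R_k (Morgans⁻¹).
Because an inbreeding loop of g generations gives an expected IBD-segment
length of 1/(2g) Morgans, R_k is roughly twice the number of generations to
the common ancestor: small rates mean long, recent segments; large rates
mean short, ancient ones.  Each new segment's class is drawn independently
from mixing proportions m_k (the frequency of segments of each class).

This renewal process is a hidden Markov chain along the marker map.  Between
markers separated by d Morgans,

    a(k, l) = exp(−R_k d)·[k = l] + (1 − exp(−R_k d))·m_l :

the current segment survives the interval with exponential survival and, on
termination, the next class is drawn from m (self-transitions allowed; two
adjacent segments of the same class merge indistinguishably, which is
harmless for all derived quantities).  The transition algebra is the
minimal formulation consistent with exponential lengths and
mixing-proportion class entry; chromosome chains restart from m
(chromosomes independent, log-likelihoods add).

Emissions depend only on HBD vs non-HBD.  With allele-A frequency f:

* HBD: P(AA) = f(1−ε), P(BB) = (1−f)(1−ε), P(AB) = ε, where ε is the
  probability of observing a heterozygote inside an HBD segment
  (genotyping/sequencing error, mutation).
* non-HBD: Hardy–Weinberg proportions f², 2f(1−f), (1−f)², with no error
  term (an error-in-non-HBD switch exists but defaults off).
* Missing genotypes emit 1 under every state (uninformative) and do not
  count toward the BIC sample size.
* With genotype probabilities (sequence data, PL/GL fields), emissions are
  integrated over the three genotypes.

Markers fixed in the reference (f = 0 or 1) carry no HBD/non-HBD contrast;
they are retained by the HMM (QC normally removes them) but excluded by the
frequency-weighted classical estimators.

## Model flavours and fitting

* **1R** — one HBD + one non-HBD class sharing a single free rate; the
  most robust two-state model.
* **KR** — K classes, each rate free.
* **MixKR** — fixed dyadic rates 2¹ … 2^(K−1) for the HBD classes and
  2^(K−1) for the non-HBD class (default K = 14, rates 2…8192); only the
  mixing proportions are fitted, so classes are comparable across
  individuals.

Parameters are fitted **per individual** by EM (default cap 1000
iterations).  The E-step computes, by scaled forward–backward, the expected
number of segment entries into each class (chromosome starts included) and
the expected stay/jump counts per inter-marker interval.  The M-step sets
m_k proportional to expected entries; each free rate maximizes its
1-D expected complete-data log-likelihood term

    Q_k(R) = −R·Σ_t w_stay(t,k)·d_t + Σ_t w_jump(t,k)·log(1 − e^(−R·d_t))

by bounded scalar search (tolerance 1e-4 in the rate), clamped to
[1, 8192]; an M-step candidate is rejected if it does not improve Q, so the
log-likelihood trace is monotone up to floating-point rounding.  For the 1R
model the Q terms of both states are summed and a single shared rate is
optimized.

Initialization: mixing uniform; free rates at the geometric midpoints of K
equal log-width bins spanning [1, 8192] (staggered, so EM can separate the
classes — a single shared midpoint would be a symmetric stationary point
for multi-rate KR models).  EM is deterministic given the data.

Convergence: `tol` stops EM when the log-likelihood gains less than the
threshold in one iteration.  The default is 1e-4; the large simulation
studies in `benchmarks.py` use 1e-3 for the 14-class MixKR fits on ~240K
markers, where the derived genome-wide quantities are stable to ~1e-4 well
before the mixing proportions settle.

Numerics: per-marker scaling constants (not log-space) in the forward and
backward passes, with the log-likelihood accumulated from the scaling
factors; Viterbi in log-space with ties broken to the lowest state index.
The inner recursions are numba-compiled and exploit the
diagonal-plus-rank-one transition structure (O(T·K) per pass) and the
compression of inter-marker distances to unique values (a regular grid
costs one survival row).

Model choice uses BIC = −2 logL + p·ln(n): p counts free rates plus K−1
free mixing proportions; n is the number of non-missing marker
observations for that individual (the natural per-individual sample size —
the source method does not print its convention, so this one is documented
as an assumption).  Ties prefer fewer parameters.

## Derived quantities

Genome-wide class fractions are unweighted means of the per-marker
posterior over all autosomal markers (a spacing-weighted option exists).
The threshold inbreeding coefficient F_G-T sums the fractions of HBD
classes with R_k ≤ T, i.e. the probability of sampling an HBD locus with
the base population set ~T/2 generations back; F_G with no threshold
includes every HBD class.  Viterbi segments are maximal runs of one HBD
class, with bp bounds at the first/last marker of the run and inclusive
lengths (end − start + 1).  The segment-length histogram uses half-open
[low, high) bins from ≤1 kb to 50–100 Mb, lowest bin closed at 0.

## Classical estimators

F_HOM (proportion of homozygous SNPs), F_ExHOM ((O−E)/(N−E) excess
homozygosity), F_GRM1 (GRM diagonal, shared denominator Σ2f(1−f)), F_GRM2
(GRM diagonal, per-SNP weights), F_UNI (correlation between uniting
gametes), and F_PED (exact recursive tabular kinship: F = kinship of the
parents, unknown parents unrelated; any exact kinship algorithm gives
identical output, verified against Wright path counting over the complete
enumeration of pedigree shapes up to 5 members).  The frequency vector is
always an explicit argument — typically computed on a designated reference
subset — never silently in-sample.  Missing genotypes are skipped per
individual with N adjusted.

## ROH caller

plink-style two-stage scan.  Windows of 50 SNPs slide along each
chromosome; a window is a hit if it has no heterozygote and at most five
missing calls; a SNP is eligible when ≥5% of the windows covering it are
hits (the source tool's default threshold; exposed) and the SNP itself is
not heterozygous.  Eligible runs are split at inter-SNP gaps above the
preset maximum and kept when they satisfy the SNP-count (≥15), minimum
length, and density rules.  Presets bind the per-panel parameters:
LD = (≥5 Mb, gap ≤1 Mb, ≤500 kb/SNP), 50K = (≥1 Mb, ≤500 kb, ≤100 kb/SNP),
HD = (≥100 kb, ≤200 kb, ≤10 kb/SNP); a `relaxed` preset gives the
20-SNP-window, 10-SNP-minimum variant.  F_ROH is the summed ROH length over
the autosome length.

## Synthetic data

The generator produces exactly what the HMM models: per chromosome a
renewal mosaic (class from m, length from Exp(R_k), truncated at the
chromosome end; the first class drawn from m, matching the HMM's
chromosome-reset convention), genotype emission per marker from the
segment class, and a truth record of every segment.  Allele frequencies
are Beta(a, b) draws with a minor-allele-frequency floor applied by
resampling (truncation would put an atom at the floor).  Physical
coordinates follow the fixed 1 cM/Mb conversion (bp = 1 + round(g/1e-8)).
Marker densities are dimensioned after commercial cattle panels on a
~25-Morgan genome: ~280 (LD-like), ~1300 (50K-like) and ~24,000 (HD-like)
markers per Morgan.  `gene_drop` propagates founder haplotypes (labelled,
so realized IBD is recoverable) down a pedigree with Haldane/Poisson
recombination — the no-interference model consistent with
exponential-length segments.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, SNP ascertainment, allele-frequency drift between the
base population and the sample, mutation, or genotyping error outside ε.
Consequently a fit given the true generative frequencies can recover
ancient autozygosity from the marginal excess homozygosity *at any marker
density* — real panels lose ancient HBD at low density largely because the
signal there lives in haplotype structure the markers no longer tag, and
because estimated frequencies absorb drift.  Passing simulation tests
therefore demonstrate the correctness of the inference machinery under the
model's own assumptions, not panel-transferability on real data (see
"Benchmark studies").

## Benchmark studies (`hbdmix.benchmarks`)

Problem sizes were chosen to exercise realistic panel densities while
keeping each study in the minutes range on one core:

* *Oracle agreement*: 200 random instances with ≤8 markers and ≤3 states,
  forward–backward and Viterbi vs exhaustive enumeration (tolerance
  1e-10).
* *EM behaviour*: 1000 full iterations on one individual (4 Morgans,
  50K-like density), monotonicity to 1e-8 and rate bounds.
* *Recovery*: 20 individuals × 10 Morgans (ten 1-Morgan chromosomes) at
  HD-like density from a 1R truth with R = 20, stationary HBD fraction
  0.25, ε = 0.002; 1R and Mix14R fits.
* *Age partition*: 20 single-individual replicates (2 Morgans, HD-like)
  with recent (R = 10, fraction 0.10) and ancient (R = 1000, fraction
  0.15) classes; Mix14R decoding of recent-segment mass and BIC choice
  between 2- and 3-state KR models.
* *Density*: 20 individuals × 10 Morgans, HD-like, from a four-class truth
  mirroring the age profile of an intensively selected cattle population
  (R = 4, 32, 256, 2048 with background fractions 0.041, 0.054, 0.180 and
  a per-individual very-recent fraction uniform on [0, 0.10] — real
  cohorts differ in recent inbreeding, and without that heterogeneity a
  cross-panel correlation only measures estimation noise).  Each panel is
  fitted with the dyadic grid its density supports (upper rate = largest
  power of two below one over the marker spacing, so 14 classes at HD-like
  density, 11 at 20× and 9 at 85× thinning): segments shorter than the
  marker spacing cannot be captured as segments, and capping the grid is
  what makes the inbreeding coefficient base-population-consistent with
  the panel.  Because the generator has no LD (above), ancient
  autozygosity retains a marginal excess-homozygosity signal at every
  density, so the magnitude of the real-data density effect is attenuated
  (a modest monotone decrease rather than a several-fold drop); the
  recent-class coefficients and the individual ranking across panels are
  the faithful comparisons.
* *Pedigree check*: complete enumeration of pedigree shapes up to 5
  members (6031 pedigrees), tabular kinship vs Wright path counting.
* *ROH*: HD-preset calls on the recovery cohort vs true HBD fractions.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| ε | 0.002 | heterozygote-in-HBD error probability (exposed everywhere; a typical array error rate — the source analyses do not print a value) |
| K (MixKR) | 14 | 13 dyadic HBD classes + non-HBD |
| rate bounds | [1, 8192] | EM constraint on fitted rates |
| EM cap / tol | 1000 / 1e-4 | iterations; per-iteration log-likelihood gain |
| QC | ind call ≥0.90, SNP call ≥0.95, MAF ≥0.01, HWE p ≥0.001 | individuals filtered before SNPs |
| Mendel rule | >1 conflicting parent–offspring pair | opposite homozygotes, needs a pedigree |
| map conversion | 1 cM/Mb | physical↔genetic proxy |

## Known limitations

Single non-HBD class only; no X chromosome; no haplotype-based IBD between
individuals; BED (binary PLINK) input not implemented; the mosaic
simulator's realism caveats above.  The HWE filter is the 1-df chi-square
approximation (an exact test would behave better at tiny counts).
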