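"""Synthetic mosaic genomes with known age-stratified autozygosity.

The generator produces exactly the data the mixture HMM models: each
chromosome of each individual is a renewal process of segments — a class is
drawn from the model's mixing proportions, its length from Exp(R_k), and the
process repeats until the chromosome is tiled.  Genotypes are then emitted
from per-marker allele frequencies: Hardy-Weinberg proportions inside
non-HBD segments, and inside HBD segments homozygous AA with probability
f(1-eps), homozygous BB with probability (1-f)(1-eps), heterozygous with
probability eps.  The recorded truth (every segment with its class) is the
ground truth every downstream stage is scored against.

Marker panels are regular grids whose densities can mimic commercial arrays
(roughly 7K, 32K and 600K SNPs on a ~25-Morgan cattle-sized genome, i.e.
about 280, 1300 and 24000 markers per Morgan).  ``gene_drop`` additionally
propagates founder haplotypes down a pedigree with Haldane (Poisson,
no-interference) recombination, so pedigree-expected and realized
autozygosity can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, MORGAN_PER_BP, GenotypeData, MarkerMap, Pedigree
from .hmm import HbdModel

#: markers per Morgan mimicking the LD (~7K), 50K (~32K) and HD (~600K)
#: genotyping panels on a ~25-Morgan genome.
PANEL_DENSITY = {"LD": 280.0, "50K": 1300.0, "HD": 24000.0}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    model: HbdModel
    n_chromosomes: int = 1
    chrom_length: float = 1.0        # Morgans
    marker_spacing: float = 0.001    # Morgans between adjacent markers
    freq_beta_a: float = 1.0
    freq_beta_b: float = 1.0
    maf_floor: float = 0.01
    epsilon: float | None = None     # defaults to model.epsilon
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.chrom_length <= 0 or self.marker_spacing <= 0:
            raise ValueError("lengths and spacings must be positive")
        if self.freq_beta_a <= 0 or self.freq_beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        eps = self.model.epsilon if self.epsilon is None else self.epsilon
        if not (0.0 <= eps < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        self.epsilon = eps
        if not np.isclose(self.model.mixing.sum(), 1.0, atol=1e-8):
            raise ValueError("model mixing proportions must sum to 1")


@dataclass
class SimTruth:
    """True mosaic: every simulated segment, plus per-class genome fractions.

    ``segments`` columns: individual, chrom, start_m, end_m, class_index
    (class ``nonhbd_state`` is the non-HBD class).  ``class_fractions`` is an
    (n_individuals, K) array of genome-length fractions per class, rows
    summing to 1.
    """

    segments: pd.DataFrame
    class_fractions: np.ndarray
    individuals: list = field(default_factory=list)
    nonhbd_state: int = 0

    def hbd_fraction(self, max_rate_class: int | None = None) -> np.ndarray:
        """Per-individual genome fraction in HBD classes (optionally only
        classes with index <= max_rate_class)."""
        hbd = [k for k in range(self.class_fractions.shape[1]) if k != self.nonhbd_state]
        if max_rate_class is not None:
            hbd = [k for k in hbd if k <= max_rate_class]
        return self.class_fractions[:, hbd].sum(axis=1)

    def marker_classes(self, mmap: MarkerMap) -> np.ndarray:
        """(n_individuals, n_markers) true class index at each marker."""
        out = np.empty((len(self.individuals), mmap.n_markers), dtype=np.int64)
        by_key = {k: g for k, g in self.segments.groupby(["individual", "chrom"])}
        for i, ind in enumerate(self.individuals):
            for sl in mmap.chromosome_slices():
                chrom = mmap.chrom[sl.start]
                seg = by_key[(ind, chrom)]
                ends = seg["end_m"].to_numpy()
                cls = seg["class_index"].to_numpy()
                pos = mmap.morgans[sl]
                j = np.searchsorted(ends, pos, side="left")
                j = np.minimum(j, len(cls) - 1)
                out[i, sl] = cls[j]
        return out


def simulate_frequencies(n_markers: int, a: float, b: float,
                         maf_floor: float = 0.0, seed: int = 0) -> np.ndarray:
    """Draw allele-A frequencies from Beta(a, b), resampling (not truncating)
    any draw whose minor-allele frequency falls below ``maf_floor``."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if not (0 <= maf_floor < 0.5):
        raise ValueError("maf_floor must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    f = rng.beta(a, b, size=n_markers)
    bad = np.minimum(f, 1.0 - f) < maf_floor
    while np.any(bad):
        f[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = np.minimum(f, 1.0 - f) < maf_floor
    return f


def simulate_map(config: SimConfig) -> MarkerMap:
    """Regular marker grid: positions 0, spacing, ..., chrom_length on each
    chromosome; physical positions at the fixed 1 cM/Mb conversion (1-based,
    so genetic position g maps to bp = round(g / 1e-8) + 1)."""
    n_per = int(round(config.chrom_length / config.marker_spacing)) + 1
    if n_per < 1:
        raise ValueError("chromosome would carry no markers")
    chroms, bps, morg = [], [], []
    for c in range(1, config.n_chromosomes + 1):
        g = np.arange(n_per) * config.marker_spacing
        g[-1] = min(g[-1], config.chrom_length)
        chroms.extend([str(c)] * n_per)
        morg.extend(g)
        bps.extend((np.round(g / MORGAN_PER_BP).astype(np.int64) + 1).tolist())
    return MarkerMap(chroms, bps, morg)


def _draw_segments(model: HbdModel, length: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Tile [0, length] with renewal segments; returns (classes, ends)."""
    if length <= 0.0:  # degenerate single-marker chromosome
        cls = rng.choice(model.K, size=1, p=model.mixing)
        return cls, np.array([0.0])
    mean_len = float(np.dot(model.mixing, 1.0 / model.rates))
    classes_parts, lens_parts = [], []
    total = 0.0
    while total < length:
        n = max(16, int((length - total) / mean_len * 1.5) + 8)
        cls = rng.choice(model.K, size=n, p=model.mixing)
        lens = rng.exponential(1.0 / model.rates[cls])
        classes_parts.append(cls)
        lens_parts.append(lens)
        total += float(lens.sum())
    cls = np.concatenate(classes_parts)
    lens = np.concatenate(lens_parts)
    ends = np.cumsum(lens)
    keep = np.searchsorted(ends, length, side="left") + 1
    cls, ends = cls[:keep], ends[:keep]
    ends[-1] = length  # truncate the final segment at the chromosome end
    return cls, ends


def simulate_mosaic(config: SimConfig, mmap: MarkerMap, freqs: np.ndarray,
                    n_individuals: int, seed: int | None = None
                    ) -> tuple[GenotypeData, SimTruth]:
    """Simulate genotypes for a cohort of mosaic genomes.

    Chromosome starts draw the first segment's class from the mixing
    proportions (stationary in segment frequency), matching the HMM's
    chromosome-reset convention.
    """
    model = config.model
    if model.K < 2:
        raise ValueError("model needs at least one HBD and one non-HBD class")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = np.asarray(freqs, dtype=np.float64)
    if len(freqs) != mmap.n_markers:
        raise ValueError("freqs length must match map")
    eps = config.epsilon
    individuals = [f"ind{i + 1}" for i in range(n_individuals)]
    codes = np.empty((n_individuals, mmap.n_markers), dtype=np.int8)
    rows = []
    fractions = np.zeros((n_individuals, model.K))
    total_len = sum(
        float(mmap.morgans[sl][-1] - mmap.morgans[sl][0])
        for sl in mmap.chromosome_slices()
    )
    chrom_slices = list(mmap.chromosome_slices())
    for i, ind in enumerate(individuals):
        for sl in chrom_slices:
            chrom = mmap.chrom[sl.start]
            origin = float(mmap.morgans[sl][0])
            length = float(mmap.morgans[sl][-1]) - origin
            cls, ends = _draw_segments(model, length, rng)
            starts = np.concatenate([[0.0], ends[:-1]])
            for k, s, e in zip(cls, starts, ends):
                rows.append((ind, chrom, float(s) + origin, float(e) + origin, int(k)))
            np.add.at(fractions[i], cls, ends - starts)
            # genotype emission: map markers to segments
            pos = mmap.morgans[sl] - origin
            seg_of = np.minimum(np.searchsorted(ends, pos, side="left"), len(cls) - 1)
            marker_cls = cls[seg_of]
            hbd = marker_cls != model.nonhbd_state
            f = freqs[sl]
            u = rng.random(len(f))
            g = np.empty(len(f), dtype=np.int8)
            # non-HBD: Hardy-Weinberg
            p0 = (1 - f) ** 2
            p1 = 2 * f * (1 - f)
            g_non = np.where(u < p0, 0, np.where(u < p0 + p1, 1, 2)).astype(np.int8)
            # HBD: BB w.p. (1-f)(1-eps), AB w.p. eps, AA w.p. f(1-eps)
            q0 = (1 - f) * (1 - eps)
            g_hbd = np.where(u < q0, 0, np.where(u < q0 + eps, 1, 2)).astype(np.int8)
            g = np.where(hbd, g_hbd, g_non)
            codes[i, sl] = g
        fractions[i] /= total_len
    segments = pd.DataFrame(
        rows, columns=["individual", "chrom", "start_m", "end_m", "class_index"]
    )
    truth = SimTruth(
        segments=segments,
        class_fractions=fractions,
        individuals=individuals,
        nonhbd_state=model.nonhbd_state,
    )
    return GenotypeData(individuals, codes, freqs=freqs), truth


def downsample_panel(geno: GenotypeData, mmap: MarkerMap, keep_every: int
                     ) -> tuple[GenotypeData, MarkerMap]:
    """Thin the marker panel, keeping every ``keep_every``-th marker."""
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every == 1:
        return geno, mmap
    idx = np.arange(0, mmap.n_markers, keep_every)
    if len(idx) == 0:
        raise ValueError("downsampling would remove every marker")
    return geno.subset_markers(idx), mmap.subset(idx)


@dataclass
class GeneDropResult:
    """Gene-dropped genotypes plus the transmitted founder-haplotype labels
    (from which true IBD/autozygous segments are recoverable)."""

    genotypes: GenotypeData
    labels: dict  # individual -> (2, n_markers) founder-haplotype label array

    def autozygosity(self, individual: str) -> float:
        """Realized autozygous genome fraction (marker-wise label identity)."""
        lab = self.labels[individual]
        return float(np.mean(lab[0] == lab[1]))


def gene_drop(pedigree: Pedigree, mmap: MarkerMap, freqs: np.ndarray,
              seed: int = 0) -> GeneDropResult:
    """Drop founder haplotypes down a pedigree.

    Founder haplotypes are drawn independently per marker from the allele
    frequencies and each receives a unique label; non-founders inherit one
    recombined gamete from each parent.  A parent missing from the pedigree
    is treated as an unrelated founder drawn on the fly.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=np.float64)
    n = mmap.n_markers
    haplos: dict[str, np.ndarray] = {}    # individual -> (2, n) allele-A indicator
    labels: dict[str, np.ndarray] = {}    # individual -> (2, n) founder labels
    next_label = 0

    def new_founder() -> tuple[np.ndarray, np.ndarray]:
        nonlocal next_label
        hap = (rng.random((2, n)) < freqs).astype(np.int8)
        lab = np.empty((2, n), dtype=np.int64)
        lab[0] = next_label
        lab[1] = next_label + 1
        next_label += 2
        return hap, lab

    for rec in pedigree.records:
        hap = np.empty((2, n), dtype=np.int8)
        lab = np.empty((2, n), dtype=np.int64)
        parents = (rec.sire, rec.dam)
        if all(p is None or p not in haplos for p in parents):
            hap, lab = new_founder()
        else:
            for j, p in enumerate(parents):
                if p is None or p not in haplos:
                    fh, fl = new_founder()
                    hap[j], lab[j] = fh[0], fl[0]
                else:
                    # one shared recombination pattern transmits both the
                    # allele and its founder label
                    pair = np.stack([haplos[p][0], haplos[p][1]])
                    lpair = np.stack([labels[p][0], labels[p][1]])
                    choice = _gamete_choice(mmap, rng)
                    cols = np.arange(n)
                    hap[j] = pair[choice, cols]
                    lab[j] = lpair[choice, cols]
        haplos[rec.individual] = hap
        labels[rec.individual] = lab

    individuals = pedigree.individuals
    codes = np.stack([haplos[i].sum(axis=0) for i in individuals]).astype(np.int8)
    return GeneDropResult(
        genotypes=GenotypeData(individuals, codes, freqs=freqs),
        labels={i: labels[i] for i in individuals},
    )


def _gamete_choice(mmap: MarkerMap, rng) -> np.ndarray:
    """Which parental haplotype (0/1) each marker of a gamete comes from."""
    n = mmap.n_markers
    choice = np.empty(n, dtype=np.int64)
    for sl in mmap.chromosome_slices():
        d = mmap.distances(sl)
        switch = rng.random(len(d)) < 0.5 * (1.0 - np.exp(-2.0 * d))
        cur = int(rng.integers(0, 2))
        idx = sl.start
        choice[idx] = cur
        for t in range(len(d)):
            if switch[t]:
                cur = 1 - cur
            choice[idx + 1 + t] = cur
    return choice
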