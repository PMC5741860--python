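"""Sliding-window rule-based runs-of-homozygosity (ROH) detection.

Mirrors the plink scanning semantics: a window of ``window_snps``
consecutive SNPs is a "hit" when it contains at most ``window_max_het``
heterozygotes and at most ``window_max_missing`` missing genotypes; a SNP is
eligible when the proportion of windows covering it that are hits reaches
``window_hit_threshold`` (and the SNP itself is not heterozygous).  Maximal
runs of eligible SNPs are split where the gap between adjacent SNPs exceeds
``max_gap_bp`` and kept only if they contain at least ``min_snps`` SNPs,
span at least ``min_length_bp`` and have at most ``min_density_bp_per_snp``
base pairs per SNP.  F_ROH is the summed ROH length over the autosome
length.

``PRESETS`` binds the per-panel parameter triples used with low-density
(LD, ~7K), 50K and HD (~600K) arrays: at least one SNP per 500/100/10 kb,
minimum lengths 5 Mb / 1 Mb / 100 kb and maximum gaps 1 Mb / 500 kb /
200 kb.  ``PRESETS["relaxed"]`` is the less stringent 20-SNP-window,
10-SNP-minimum variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeData, MarkerMap


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 50
    window_max_het: int = 0
    window_max_missing: int = 5
    window_hit_threshold: float = 0.05
    min_snps: int = 15
    min_length_bp: int = 1_000_000
    max_gap_bp: int = 500_000
    min_density_bp_per_snp: int = 100_000

    def __post_init__(self):
        if min(self.window_snps, self.min_snps) < 1:
            raise ValueError("window_snps and min_snps must be >= 1")
        if self.window_max_het < 0 or self.window_max_missing < 0:
            raise ValueError("window tolerances must be >= 0")
        if not (0.0 < self.window_hit_threshold <= 1.0):
            raise ValueError("window_hit_threshold must be in (0, 1]")


PRESETS: dict[str, RohParams] = {
    "LD": RohParams(min_length_bp=5_000_000, max_gap_bp=1_000_000,
                    min_density_bp_per_snp=500_000),
    "50K": RohParams(min_length_bp=1_000_000, max_gap_bp=500_000,
                     min_density_bp_per_snp=100_000),
    "HD": RohParams(min_length_bp=100_000, max_gap_bp=200_000,
                    min_density_bp_per_snp=10_000),
    "relaxed": RohParams(window_snps=20, min_snps=10, min_length_bp=100_000,
                         max_gap_bp=200_000, min_density_bp_per_snp=10_000),
}


@dataclass
class RohSegment:
    individual: str
    chromosome: str
    start_bp: int
    end_bp: int
    start_snp: str
    end_snp: str
    n_snps: int
    length_bp: int


def scan_homozygous_windows(codes_row: np.ndarray, mmap: MarkerMap,
                            params: RohParams) -> np.ndarray:
    """Per-SNP eligibility flags from the sliding-window scan.

    Chromosomes shorter than one window fall back to a single
    whole-chromosome window.
    """
    codes_row = np.asarray(codes_row)
    eligible = np.zeros(len(codes_row), dtype=bool)
    for sl in mmap.chromosome_slices():
        sub = codes_row[sl]
        n = len(sub)
        het = (sub == 1).astype(np.int64)
        miss = (sub == MISSING).astype(np.int64)
        w = min(params.window_snps, n)
        n_win = n - w + 1
        het_c = np.concatenate([[0], np.cumsum(het)])
        miss_c = np.concatenate([[0], np.cumsum(miss)])
        het_in = het_c[w:] - het_c[:-w]
        miss_in = miss_c[w:] - miss_c[:-w]
        hit = (het_in <= params.window_max_het) & (miss_in <= params.window_max_missing)
        hit_c = np.concatenate([[0], np.cumsum(hit.astype(np.int64))])
        idx = np.arange(n)
        lo = np.maximum(0, idx - w + 1)
        hi = np.minimum(idx, n_win - 1)
        n_cover = hi - lo + 1
        n_hits = hit_c[hi + 1] - hit_c[lo]
        frac = n_hits / n_cover
        eligible[sl] = (frac >= params.window_hit_threshold) & (sub != 1)
    return eligible


def call_roh(flags: np.ndarray, codes_row: np.ndarray, mmap: MarkerMap,
             params: RohParams, individual: str = "ind") -> list[RohSegment]:
    """Assemble eligible SNPs into ROH segments subject to the gap, SNP
    count, length and density rules."""
    segments: list[RohSegment] = []
    for sl in mmap.chromosome_slices():
        chrom = mmap.chrom[sl.start]
        sub_flags = flags[sl]
        bp = mmap.bp[sl]
        ids = mmap.snp_ids[sl]
        idx = np.nonzero(sub_flags)[0]
        if len(idx) == 0:
            continue
        # split runs at non-eligible SNPs or at gaps exceeding max_gap_bp
        breaks = np.nonzero(
            (np.diff(idx) > 1) | (np.diff(bp[idx]) > params.max_gap_bp)
        )[0]
        run_bounds = np.split(idx, breaks + 1)
        for run in run_bounds:
            n_snps = len(run)
            length = int(bp[run[-1]] - bp[run[0]] + 1)
            if n_snps < params.min_snps:
                continue
            if length < params.min_length_bp:
                continue
            if length / n_snps > params.min_density_bp_per_snp:
                continue
            segments.append(RohSegment(
                individual=individual,
                chromosome=chrom,
                start_bp=int(bp[run[0]]),
                end_bp=int(bp[run[-1]]),
                start_snp=str(ids[run[0]]),
                end_snp=str(ids[run[-1]]),
                n_snps=n_snps,
                length_bp=length,
            ))
    return segments


def find_roh(geno: GenotypeData, mmap: MarkerMap, params: RohParams | str = "50K"
             ) -> pd.DataFrame:
    """Scan and call ROH for every individual; plink .hom-style table."""
    if isinstance(params, str):
        params = PRESETS[params]
    rows = []
    for i, ind in enumerate(geno.individuals):
        flags = scan_homozygous_windows(geno.codes[i], mmap, params)
        for seg in call_roh(flags, geno.codes[i], mmap, params, individual=ind):
            rows.append((ind, ind, seg.chromosome, seg.start_snp, seg.end_snp,
                         seg.start_bp, seg.end_bp, seg.length_bp / 1000.0,
                         seg.n_snps))
    return pd.DataFrame(
        rows,
        columns=["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP"],
    )


def f_roh(segments, autosome_length_bp: int, individuals=None) -> pd.Series:
    """Proportion of the genome covered by ROH, per individual.

    ``segments`` is the table from :func:`find_roh`; ``individuals``
    optionally fixes the output index (individuals without ROH get 0).
    """
    if autosome_length_bp <= 0:
        raise ValueError("autosome length must be positive")
    if len(segments):
        lengths = segments.assign(LEN=segments["KB"] * 1000.0)
        total = lengths.groupby("IID")["LEN"].sum()
    else:
        total = pd.Series(dtype=float)
    if individuals is not None:
        total = total.reindex(individuals, fill_value=0.0)
    return (total / autosome_length_bp).rename("F_ROH")
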