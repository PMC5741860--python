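"""Genotype, map and pedigree file handling, QC filters, allele frequencies.

Readers/writers cover PLINK-style text PED/MAP, minimal VCF (GT, and PL/GL
genotype likelihoods for sequence data, via cyvcf2) and whitespace-separated
pedigree files.  The QC filter applies the usual array-data rules: an
individual call-rate pass first, then per-SNP call rate, minor allele
frequency, a 1-df Hardy-Weinberg chi-square test and (when a pedigree is
available) a Mendelian rule that removes SNPs with opposite-homozygote
conflicts in more than one distinct parent-offspring pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import chi2

from .data import MISSING, MORGAN_PER_BP, GenotypeData, MarkerMap, Pedigree

# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------


def read_plink_text(ped_path, map_path) -> tuple[GenotypeData, MarkerMap]:
    """Read a PLINK text fileset (.ped genotypes + .map positions).

    MAP columns: chrom, snp id, genetic position (cM), bp, and optionally
    the A and B allele labels (bim-style extended map; without them the
    allele orientation of SNPs monomorphic in the file is data-driven).
    PED columns: FID IID PAT MAT SEX PHENO then two allele symbols per SNP;
    "0 0" is a missing genotype.  Genotype codes count copies of the A
    allele.
    """
    chroms, ids, morgans, bps = [], [], [], []
    map_alleles: list | None = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{map_path}:{lineno}: expected 4 columns")
        chroms.append(parts[0])
        ids.append(parts[1])
        morgans.append(float(parts[2]) / 100.0)  # cM on disk -> Morgans
        bps.append(int(parts[3]))
        if map_alleles is not None and len(parts) >= 6:
            map_alleles.append((parts[4], parts[5]))
        else:
            map_alleles = None
    n_snps = len(chroms)

    individuals, rows, allele_pairs = [], [], [set() for _ in range(n_snps)]
    raw_rows = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_snps:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
            )
        individuals.append(parts[1])
        alleles = parts[6:]
        pairs = [(alleles[2 * i], alleles[2 * i + 1]) for i in range(n_snps)]
        raw_rows.append(pairs)
        for i, (a1, a2) in enumerate(pairs):
            for a in (a1, a2):
                if a != "0":
                    allele_pairs[i].add(a)

    allele_labels = np.empty((n_snps, 2), dtype=object)
    for i, seen in enumerate(allele_pairs):
        if map_alleles is not None:
            allele_labels[i] = map_alleles[i]
            extra = seen - set(map_alleles[i])
            if extra:
                raise ValueError(
                    f"SNP {ids[i]}: allele symbols {sorted(extra)} not in map"
                )
            continue
        seen = sorted(seen)
        if len(seen) > 2:
            raise ValueError(f"SNP {ids[i]}: more than two alleles {seen}")
        a = seen[0] if seen else "A"
        b = seen[1] if len(seen) > 1 else ("B" if a != "B" else "A2")
        allele_labels[i] = (a, b)

    codes = np.full((len(individuals), n_snps), MISSING, dtype=np.int8)
    for r, pairs in enumerate(raw_rows):
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            codes[r, i] = int(a1 == allele_labels[i][0]) + int(a2 == allele_labels[i][0])

    mmap = MarkerMap(chroms, bps, morgans, allele_labels, ids)
    return GenotypeData(individuals, codes), mmap


def write_plink_text(geno: GenotypeData, mmap: MarkerMap, ped_path, map_path) -> None:
    """Write a PLINK text fileset; inverse of :func:`read_plink_text`."""
    with open(map_path, "w") as fh:
        for i in range(mmap.n_markers):
            a, b = mmap.alleles[i]
            fh.write(
                f"{mmap.chrom[i]}\t{mmap.snp_ids[i]}\t{mmap.morgans[i] * 100.0:.8g}"
                f"\t{mmap.bp[i]}\t{a}\t{b}\n"
            )
    with open(ped_path, "w") as fh:
        for r, ind in enumerate(geno.individuals):
            fields = [ind, ind, "0", "0", "0", "-9"]
            for i in range(mmap.n_markers):
                c = geno.codes[r, i]
                a, b = mmap.alleles[i]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [b, b]
                elif c == 1:
                    fields += [a, b]
                else:
                    fields += [a, a]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, use_likelihoods: bool = False):
    """Read biallelic SNPs from a VCF.

    Genotype codes count copies of the REF allele.  When ``use_likelihoods``
    and PL (Phred-scaled) or GL (log10) fields are present, per-genotype
    probabilities are filled as normalized likelihoods, ordered by REF-allele
    count (hom-ALT, het, hom-REF).  Multiallelic records are skipped (their
    count is reported).  Returns (GenotypeData, MarkerMap, n_skipped).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, bps, morgans, ids, alleles = [], [], [], [], []
    code_rows, prob_rows = [], []
    n_skipped = 0
    any_liks = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        chroms.append(var.CHROM)
        bps.append(var.POS)
        morgans.append(var.POS * MORGAN_PER_BP)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
        gts = var.genotype.array()
        codes = np.full(len(individuals), MISSING, dtype=np.int8)
        ok = (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
        # REF-allele copies = 2 - sum of ALT indicators
        codes[ok] = (2 - gts[ok, 0] - gts[ok, 1]).astype(np.int8)
        code_rows.append(codes)
        if use_likelihoods:
            liks = _genotype_probs(var, len(individuals))
            if liks is not None:
                any_liks = True
            prob_rows.append(liks)
    vcf.close()
    if not chroms:
        raise ValueError(f"no biallelic SNP records in {path}")
    codes = np.stack(code_rows, axis=1)
    mmap = MarkerMap(chroms, bps, morgans, np.array(alleles, dtype=object), ids)
    genoprobs = None
    if use_likelihoods and any_liks:
        n_ind, n_mark = codes.shape
        genoprobs = np.empty((n_ind, n_mark, 3))
        for j, liks in enumerate(prob_rows):
            if liks is None:
                liks = _hard_probs(codes[:, j])
            genoprobs[:, j, :] = liks
    return GenotypeData(individuals, codes, genoprobs=genoprobs), mmap, n_skipped


def _hard_probs(codes: np.ndarray) -> np.ndarray:
    out = np.full((len(codes), 3), 1.0 / 3.0)
    for g in (0, 1, 2):
        out[codes == g] = np.eye(3)[g]
    return out


def _genotype_probs(var, n_ind) -> np.ndarray | None:
    """Normalized genotype probabilities from PL or GL, ordered by REF count.

    VCF stores likelihoods in ALT-count order (hom-REF, het, hom-ALT); the
    returned triples are flipped to REF-count order (0, 1, 2 REF copies)."""
    pl = None
    try:
        pl = var.format("PL")
    except Exception:
        pl = None
    if pl is not None:
        lik = np.power(10.0, -np.asarray(pl, dtype=float)[:, :3] / 10.0)
    else:
        try:
            gl = var.format("GL")
        except Exception:
            gl = None
        if gl is None:
            return None
        lik = np.power(10.0, np.asarray(gl, dtype=float)[:, :3])
    lik = np.where(np.isfinite(lik), lik, 0.0)
    s = lik.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    lik = lik / s
    return lik[:, ::-1]  # ALT-count order -> REF-count order


def write_vcf(geno: GenotypeData, mmap: MarkerMap, path) -> None:
    """Write genotypes as a minimal GT-only VCF (text, uncompressed)."""
    gt_map = {MISSING: "./.", 0: "1/1", 1: "0/1", 2: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in mmap.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals) + "\n"
        )
        for i in range(mmap.n_markers):
            a, b = mmap.alleles[i]
            gts = "\t".join(gt_map[int(c)] for c in geno.codes[:, i])
            fh.write(
                f"{mmap.chrom[i]}\t{mmap.bp[i]}\t{mmap.snp_ids[i]}\t{a}\t{b}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# pedigree files
# ---------------------------------------------------------------------------


def read_pedigree(path) -> Pedigree:
    """Read a 3-4 column whitespace-separated pedigree
    (individual, sire, dam[, birth_year]); unknown parents coded 0."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split())
    return Pedigree.from_tuples(rows)


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            year = "" if r.birth_year is None else f"\t{r.birth_year}"
            fh.write(f"{r.individual}\t{r.sire or 0}\t{r.dam or 0}{year}\n")


# ---------------------------------------------------------------------------
# allele frequencies and QC
# ---------------------------------------------------------------------------


def apply_marker_filter(geno: GenotypeData, mmap: MarkerMap,
                        keep=None, drop=None):
    """Allow/deny-list hook for externally curated marker sets (e.g. SNPs
    flagged as incorrectly mapped by linkage/LD evidence).  ``keep`` and
    ``drop`` are iterables of SNP ids; ``keep`` wins when both are given."""
    ids = mmap.snp_ids
    if keep is not None:
        mask = np.isin(ids, np.asarray(list(keep), dtype=object))
    elif drop is not None:
        mask = ~np.isin(ids, np.asarray(list(drop), dtype=object))
    else:
        return geno, mmap
    if not mask.any():
        raise ValueError("marker filter removed every marker")
    idx = np.nonzero(mask)[0]
    return geno.subset_markers(idx), mmap.subset(idx)


def allele_frequencies(geno: GenotypeData, subset=None) -> np.ndarray:
    """Allele-A frequency per marker, f = (2 nAA + nAB) / (2 n_called).

    ``subset`` restricts the computation to those individual IDs (the
    reference population); markers with no called genotype get NaN.
    """
    codes = geno.codes
    if subset is not None:
        pos = [i for i, ind in enumerate(geno.individuals) if ind in set(subset)]
        if not pos:
            raise ValueError("subset does not intersect the genotyped individuals")
        codes = codes[pos]
    called = codes != MISSING
    n_called = called.sum(axis=0)
    a_count = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, a_count / (2.0 * n_called), np.nan)
    return f


def hwe_chi2(codes_col: np.ndarray) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions on one SNP's
    genotype counts.  Returns (statistic, p-value)."""
    called = codes_col[codes_col != MISSING]
    n = len(called)
    if n == 0:
        return 0.0, 1.0
    n_aa = int(np.sum(called == 2))
    n_ab = int(np.sum(called == 1))
    f = (2 * n_aa + n_ab) / (2.0 * n)
    exp = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2]) * n
    obs = np.array([n - n_aa - n_ab, n_ab, n_aa], dtype=float)
    mask = exp > 0
    stat = float(np.sum((obs[mask] - exp[mask]) ** 2 / exp[mask]))
    return stat, float(chi2.sf(stat, df=1))


@dataclass
class QcReport:
    """Per-rule removal counts from :func:`qc_filter`."""

    n_individuals_removed: int = 0
    n_snp_callrate: int = 0
    n_snp_maf: int = 0
    n_snp_hwe: int = 0
    n_snp_mendel: int = 0
    mendel_checked: bool = False
    removed_individuals: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"individuals_removed\t{self.n_individuals_removed}",
            f"snps_callrate\t{self.n_snp_callrate}",
            f"snps_maf\t{self.n_snp_maf}",
            f"snps_hwe\t{self.n_snp_hwe}",
        ]
        if self.mendel_checked:
            lines.append(f"snps_mendel\t{self.n_snp_mendel}")
        else:
            lines.append("snps_mendel\tnot_checked_no_pedigree")
        return "\n".join(lines) + "\n"


def qc_filter(geno: GenotypeData, mmap: MarkerMap, *,
              ind_callrate_min: float = 0.90,
              snp_callrate_min: float = 0.95,
              maf_min: float = 0.01,
              hwe_p_min: float = 0.001,
              pedigree: Pedigree | None = None,
              ) -> tuple[GenotypeData, MarkerMap, QcReport]:
    """Apply array-data QC: drop low-call-rate individuals first, then SNPs
    failing call rate, MAF, Hardy-Weinberg (1-df chi-square) or the
    Mendelian opposite-homozygote rule (needs a pedigree; a SNP is removed
    when conflicts occur in more than one distinct parent-offspring pair)."""
    for thr in (ind_callrate_min, snp_callrate_min, maf_min, hwe_p_min):
        if not (0.0 <= thr <= 1.0):
            raise ValueError("QC thresholds must be in [0, 1]")
    report = QcReport()
    called = geno.codes != MISSING
    ind_cr = called.mean(axis=1)
    keep_ind = ind_cr >= ind_callrate_min
    report.n_individuals_removed = int((~keep_ind).sum())
    report.removed_individuals = [
        ind for ind, k in zip(geno.individuals, keep_ind) if not k
    ]
    individuals = [ind for ind, k in zip(geno.individuals, keep_ind) if k]
    codes = geno.codes[keep_ind]

    n_ind = codes.shape[0]
    keep_snp = np.ones(codes.shape[1], dtype=bool)
    called = codes != MISSING
    cr = called.mean(axis=0) if n_ind else np.zeros(codes.shape[1])
    fail_cr = cr < snp_callrate_min
    report.n_snp_callrate = int(fail_cr.sum())
    keep_snp &= ~fail_cr

    n_called = called.sum(axis=0)
    a_count = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, a_count / (2.0 * n_called), np.nan)
    maf = np.minimum(f, 1.0 - f)
    fail_maf = keep_snp & (~np.isfinite(maf) | (maf < maf_min))
    report.n_snp_maf = int(fail_maf.sum())
    keep_snp &= ~fail_maf

    fail_hwe = np.zeros_like(keep_snp)
    for j in np.nonzero(keep_snp)[0]:
        _, p = hwe_chi2(codes[:, j])
        if p < hwe_p_min:
            fail_hwe[j] = True
    report.n_snp_hwe = int(fail_hwe.sum())
    keep_snp &= ~fail_hwe

    if pedigree is not None:
        report.mendel_checked = True
        idx = {ind: i for i, ind in enumerate(individuals)}
        pairs = []
        for rec in pedigree.records:
            if rec.individual not in idx:
                continue
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent in idx:
                    pairs.append((idx[rec.individual], idx[parent]))
        if pairs:
            conflicts = np.zeros(codes.shape[1], dtype=np.int64)
            for ci, pi in pairs:
                child, par = codes[ci], codes[pi]
                opposite = ((child == 0) & (par == 2)) | ((child == 2) & (par == 0))
                conflicts += opposite.astype(np.int64)
            fail_mendel = keep_snp & (conflicts > 1)
            report.n_snp_mendel = int(fail_mendel.sum())
            keep_snp &= ~fail_mendel

    if not keep_snp.any():
        raise ValueError("QC removed every marker")
    idx_keep = np.nonzero(keep_snp)[0]
    out = GenotypeData(
        individuals,
        codes[:, idx_keep],
        None if geno.genoprobs is None else geno.genoprobs[keep_ind][:, idx_keep],
        None if geno.freqs is None else geno.freqs[idx_keep],
    )
    return out, mmap.subset(idx_keep), report
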