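"""Classical (non-HMM) inbreeding coefficient estimators.

Six benchmark estimators of individual inbreeding F:

* ``f_hom``    — observed homozygosity, the proportion of homozygous SNPs.
* ``f_exhom``  — excess homozygosity, (O - E)/(N - E) with E the
  Hardy-Weinberg expected homozygote count (the plink ``--het`` statistic).
* ``f_grm1``   — diagonal of the genomic relationship matrix with a single
  shared denominator: sum (x - 2f)^2 / sum 2f(1-f) - 1 (VanRaden form).
* ``f_grm2``   — GRM diagonal with per-SNP weights:
  mean[(x - 2f)^2 / (2f(1-f))] - 1.
* ``f_uni``    — correlation between uniting gametes:
  mean[(x^2 - (1+2f)x + 2f^2) / (2f(1-f))] (Yang et al.'s estimator).
* ``f_ped``    — exact pedigree inbreeding, F(i) = kinship(sire, dam),
  computed by recursive tabular kinship; unknown parents are unrelated
  founders.

All genomic estimators take the frequency vector as an explicit argument
(typically computed on a designated reference population) and skip missing
genotypes per individual, adjusting N.  Markers fixed in the reference
(f = 0 or 1) carry zero weight and are excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeData, Pedigree


def _masked(geno: GenotypeData):
    codes = geno.codes.astype(np.float64)
    obs = geno.codes != MISSING
    return codes, obs


def f_hom(geno: GenotypeData) -> pd.Series:
    """Proportion of homozygous SNPs among non-missing genotypes."""
    codes, obs = _masked(geno)
    n = obs.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("individual with no called genotype")
    hom = (obs & (geno.codes != 1)).sum(axis=1)
    return pd.Series(hom / n, index=geno.individuals, name="F_HOM")


def f_exhom(geno: GenotypeData, freqs) -> pd.Series:
    """Excess homozygosity (O - E)/(N - E), E = sum over non-missing markers
    of 1 - 2 f (1 - f)."""
    freqs = np.asarray(freqs, dtype=np.float64)
    codes, obs = _masked(geno)
    e_hom_marker = 1.0 - 2.0 * freqs * (1.0 - freqs)
    o = (obs & (geno.codes != 1)).sum(axis=1).astype(float)
    e = obs @ e_hom_marker
    n = obs.sum(axis=1).astype(float)
    denom = n - e
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(denom != 0, (o - e) / denom, np.nan)
    return pd.Series(val, index=geno.individuals, name="F_ExHOM")


def _polymorphic(freqs) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=np.float64)
    return np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)


def f_grm1(geno: GenotypeData, freqs) -> pd.Series:
    """GRM-diagonal estimator with one shared denominator."""
    freqs = np.asarray(freqs, dtype=np.float64)
    codes, obs = _masked(geno)
    use = obs & _polymorphic(freqs)[None, :]
    dev2 = np.where(use, (codes - 2.0 * freqs) ** 2, 0.0)
    w = 2.0 * freqs * (1.0 - freqs)
    denom = use @ np.where(_polymorphic(freqs), w, 0.0)
    val = dev2.sum(axis=1) / denom - 1.0
    return pd.Series(val, index=geno.individuals, name="F_GRM1")


def f_grm2(geno: GenotypeData, freqs) -> pd.Series:
    """GRM-diagonal estimator weighting each SNP by its own 2f(1-f)."""
    freqs = np.asarray(freqs, dtype=np.float64)
    codes, obs = _masked(geno)
    poly = _polymorphic(freqs)
    use = obs & poly[None, :]
    w = np.where(poly, 2.0 * freqs * (1.0 - freqs), 1.0)
    term = np.where(use, (codes - 2.0 * freqs) ** 2 / w, 0.0)
    n = use.sum(axis=1)
    val = term.sum(axis=1) / n - 1.0
    return pd.Series(val, index=geno.individuals, name="F_GRM2")


def f_uni(geno: GenotypeData, freqs) -> pd.Series:
    """Estimator based on the correlation between uniting gametes."""
    freqs = np.asarray(freqs, dtype=np.float64)
    codes, obs = _masked(geno)
    poly = _polymorphic(freqs)
    use = obs & poly[None, :]
    w = np.where(poly, 2.0 * freqs * (1.0 - freqs), 1.0)
    term = np.where(
        use,
        (codes ** 2 - (1.0 + 2.0 * freqs) * codes + 2.0 * freqs ** 2) / w,
        0.0,
    )
    n = use.sum(axis=1)
    val = term.sum(axis=1) / n
    return pd.Series(val, index=geno.individuals, name="F_UNI")


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------


class KinshipCalculator:
    """Exact recursive (tabular) kinship on a pedigree.

    phi(i, i) = (1 + F_i)/2 with F_i = phi(sire_i, dam_i); for i != j with j
    not an ancestor of i, phi(i, j) = (phi(i, sire_j) + phi(i, dam_j))/2.
    Unknown parents contribute 0 (unrelated founders).  Memoized; exact for
    any acyclic pedigree.
    """

    def __init__(self, pedigree: Pedigree):
        self.ped = pedigree
        self.order = {iid: i for i, iid in enumerate(pedigree.individuals)}
        self._memo: dict[tuple[str, str], float] = {}

    def kinship(self, a: str | None, b: str | None) -> float:
        if a is None or b is None:
            return 0.0
        if a not in self.order or b not in self.order:
            return 0.0
        if self.order.get(a, -1) > self.order.get(b, -1):
            a, b = b, a
        key = (a, b)
        if key in self._memo:
            return self._memo[key]
        sire_b, dam_b = self.ped.parents(b)
        if a == b:
            val = 0.5 * (1.0 + self.kinship(sire_b, dam_b))
        else:
            # b is the later individual in topological order, so a is not a
            # descendant of b and the recursion on b's parents is valid
            val = 0.5 * (self.kinship(a, sire_b) + self.kinship(a, dam_b))
        self._memo[key] = val
        return val

    def inbreeding(self, iid: str) -> float:
        sire, dam = self.ped.parents(iid)
        return self.kinship(sire, dam)


def f_ped(pedigree: Pedigree) -> pd.Series:
    """Pedigree inbreeding coefficient for every individual."""
    calc = KinshipCalculator(pedigree)
    vals = {iid: calc.inbreeding(iid) for iid in pedigree.individuals}
    return pd.Series(vals, name="F_PED")


def equivalent_generations(pedigree: Pedigree) -> pd.Series:
    """Convenience pedigree-completeness metric: sum over known ancestors of
    (1/2)^generation (a discounted ancestor count)."""
    memo: dict[str, float] = {}

    def eq(iid: str | None) -> float:
        if iid is None or iid not in pedigree:
            return 0.0
        if iid in memo:
            return memo[iid]
        sire, dam = pedigree.parents(iid)
        val = sum(
            0.5 * (1.0 + eq(p)) for p in (sire, dam) if p is not None and p in pedigree
        )
        memo[iid] = val
        return val

    return pd.Series({iid: eq(iid) for iid in pedigree.individuals}, name="EqGen")


def estimate_all(geno: GenotypeData, freqs, pedigree: Pedigree | None = None
                 ) -> pd.DataFrame:
    """All genomic estimators (and F_PED when a pedigree is given) as one
    individual-by-estimator table."""
    table = pd.DataFrame({
        "F_HOM": f_hom(geno),
        "F_ExHOM": f_exhom(geno, freqs),
        "F_GRM1": f_grm1(geno, freqs),
        "F_GRM2": f_grm2(geno, freqs),
        "F_UNI": f_uni(geno, freqs),
    })
    if pedigree is not None:
        table["F_PED"] = f_ped(pedigree).reindex(table.index)
    return table
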