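"""Core in-memory containers: marker maps, genotype matrices, pedigrees.

Genotypes are coded as the number of copies of allele A (the first-listed /
reference allele): 0, 1 or 2; missing genotypes use the sentinel ``MISSING``
(-1).  Genetic positions are stored in Morgans, physical positions as 1-based
base pairs.  The physical<->genetic conversion used throughout the package is
1 cM/Mb (1e-8 Morgan per bp), a standard proxy for cattle-like genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: Morgans per base pair under the fixed 1 cM/Mb conversion.
MORGAN_PER_BP: float = 1e-8


class MarkerMap:
    """Ordered autosomal SNP map with physical and genetic coordinates.

    Parameters
    ----------
    chrom : sequence of str
        Chromosome label per marker; markers must be grouped by chromosome.
    bp : sequence of int
        1-based physical positions, strictly increasing within chromosome.
    morgans : sequence of float
        Genetic positions in Morgans, non-decreasing within chromosome.
    alleles : (n, 2) array-like of str, optional
        Allele labels (A, B) per marker; defaults to ("A", "B").
    snp_ids : sequence of str, optional
    """

    def __init__(self, chrom, bp, morgans, alleles=None, snp_ids=None):
        self.chrom = np.asarray(chrom, dtype=object)
        self.bp = np.asarray(bp, dtype=np.int64)
        self.morgans = np.asarray(morgans, dtype=np.float64)
        n = len(self.chrom)
        if not (len(self.bp) == len(self.morgans) == n):
            raise ValueError("chrom, bp and morgans must have equal length")
        if alleles is None:
            alleles = np.tile(np.array(["A", "B"], dtype=object), (n, 1))
        self.alleles = np.asarray(alleles, dtype=object).reshape(n, 2)
        if snp_ids is None:
            snp_ids = np.array(
                [f"snp_{c}_{p}" for c, p in zip(self.chrom, self.bp)], dtype=object
            )
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self._validate()

    def _validate(self) -> None:
        for sl in self.chromosome_slices():
            bp = self.bp[sl]
            mg = self.morgans[sl]
            if len(bp) == 0:
                raise ValueError("empty chromosome in map")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(
                    f"physical positions not strictly increasing on {self.chrom[sl.start]}"
                )
            if np.any(np.diff(mg) < 0):
                raise ValueError(
                    f"genetic positions decreasing on {self.chrom[sl.start]}"
                )

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order (first-appearance order)."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chromosome_slices(self) -> Iterator[slice]:
        """Yield one contiguous slice per chromosome, in map order."""
        if len(self.chrom) == 0:
            return
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                yield slice(start, i)
                start = i

    def distances(self, sl: slice) -> np.ndarray:
        """Inter-marker distances in Morgans for one chromosome slice."""
        return np.diff(self.morgans[sl])

    def total_length_bp(self) -> int:
        """Summed chromosome spans (last - first marker + 1) in bp."""
        return int(
            sum(self.bp[sl][-1] - self.bp[sl][0] + 1 for sl in self.chromosome_slices())
        )

    def total_length_morgans(self) -> float:
        return float(
            sum(self.morgans[sl][-1] - self.morgans[sl][0] for sl in self.chromosome_slices())
        )

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.chrom[idx], self.bp[idx], self.morgans[idx],
            self.alleles[idx], self.snp_ids[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "snp_id": self.snp_ids,
                "morgans": self.morgans,
                "bp": self.bp,
                "allele_a": self.alleles[:, 0],
                "allele_b": self.alleles[:, 1],
            }
        )


class GenotypeData:
    """Genotype codes (and optionally genotype probabilities) for a cohort.

    ``codes`` is an (n_individuals, n_markers) int8 matrix of allele-A counts
    with ``MISSING`` for no-calls.  ``genoprobs`` optionally carries
    (n_individuals, n_markers, 3) probabilities of (hom-B/aa, het, hom-A/AA)
    genotypes ordered by allele-A count (0, 1, 2), each row summing to 1; it
    is used by the HMM for sequence-type data.  ``freqs`` holds per-marker
    frequencies of allele A.
    """

    def __init__(self, individuals: Sequence[str], codes, genoprobs=None, freqs=None):
        self.individuals = list(individuals)
        self.codes = np.asarray(codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.individuals):
            raise ValueError("codes must be (n_individuals, n_markers)")
        self.genoprobs = None
        if genoprobs is not None:
            gp = np.asarray(genoprobs, dtype=np.float64)
            if gp.shape != (*self.codes.shape, 3):
                raise ValueError("genoprobs must be (n_individuals, n_markers, 3)")
            rowsum = gp.sum(axis=2)
            if np.any(np.abs(rowsum - 1.0) > 1e-6):
                raise ValueError("genoprob triples must sum to 1 within 1e-6")
            self.genoprobs = gp
        self.freqs = None if freqs is None else np.asarray(freqs, dtype=np.float64)
        if self.freqs is not None:
            if len(self.freqs) != self.codes.shape[1]:
                raise ValueError("freqs length must match marker count")
            finite = np.isfinite(self.freqs)
            if np.any((self.freqs[finite] < 0) | (self.freqs[finite] > 1)):
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def row(self, individual: str | int) -> np.ndarray:
        if isinstance(individual, str):
            individual = self.individuals.index(individual)
        return self.codes[individual]

    def subset_markers(self, idx) -> "GenotypeData":
        idx = np.asarray(idx)
        return GenotypeData(
            self.individuals,
            self.codes[:, idx],
            None if self.genoprobs is None else self.genoprobs[:, idx, :],
            None if self.freqs is None else self.freqs[idx],
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeData":
        pos = [self.individuals.index(i) for i in ids]
        return GenotypeData(
            [self.individuals[p] for p in pos],
            self.codes[pos],
            None if self.genoprobs is None else self.genoprobs[pos],
            self.freqs,
        )


@dataclass
class PedigreeRecord:
    individual: str
    sire: str | None
    dam: str | None
    birth_year: int | None = None


class Pedigree:
    """Individual/sire/dam triples with optional birth years.

    Unknown parents are ``None`` (written/read as "0").  Construction
    topologically sorts the records so parents precede offspring and raises
    on cycles.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records = self._toposort(list(records))
        self._index = {r.individual: r for r in self.records}

    @staticmethod
    def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
        by_id = {r.individual: r for r in records}
        if len(by_id) != len(records):
            raise ValueError("duplicate individual in pedigree")
        order: list[PedigreeRecord] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if iid not in by_id:
                return  # parent not in file: treated as founder
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                cycle = stack[stack.index(iid):] + [iid]
                raise ValueError(f"pedigree cycle: {' -> '.join(cycle)}")
            state[iid] = 0
            stack.append(iid)
            rec = by_id[iid]
            for parent in (rec.sire, rec.dam):
                if parent is not None:
                    visit(parent, stack)
            stack.pop()
            state[iid] = 1
            order.append(rec)

        for iid in by_id:
            visit(iid, [])
        return order

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        rec = self._index.get(iid)
        if rec is None:
            return (None, None)
        return (rec.sire, rec.dam)

    def birth_year(self, iid: str) -> int | None:
        rec = self._index.get(iid)
        return None if rec is None else rec.birth_year

    @property
    def individuals(self) -> list[str]:
        return [r.individual for r in self.records]

    def founders(self) -> list[str]:
        return [
            r.individual
            for r in self.records
            if (r.sire is None or r.sire not in self._index)
            and (r.dam is None or r.dam not in self._index)
        ]

    @classmethod
    def from_tuples(cls, rows) -> "Pedigree":
        recs = []
        for row in rows:
            iid, sire, dam = row[:3]
            year = row[3] if len(row) > 3 else None
            recs.append(
                PedigreeRecord(
                    str(iid),
                    None if sire in (None, "0", 0, "") else str(sire),
                    None if dam in (None, "0", 0, "") else str(dam),
                    None if year in (None, "", "0") else int(year),
                )
            )
        return cls(recs)
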