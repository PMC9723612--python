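"""Core containers shared across the pipeline.

Alleles and genotypes use a common 3-value coding: ``MISSING = 0``,
``REF = 1``, ``ALT = 2``.  The two parental haplotypes of the diploid donor
are labelled arbitrarily; a :class:`Haplotype` records, per heterozygous SNP,
which allele haplotype 1 carries.  The signed view (+1 for REF, -1 for ALT,
0 for missing) makes concordance computations plain dot products.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import sparse

MISSING: int = 0
REF: int = 1
ALT: int = 2

_BASES = frozenset("ACGT")


class Phase(IntEnum):
    """Phase annotation of a heterozygous SNP in the input VCF."""

    UNPHASED = 0
    H1_REF = 1  # haplotype 1 carries the reference allele (GT 0|1)
    H1_ALT = 2  # haplotype 1 carries the alternate allele (GT 1|0)


def complement_code(code: np.ndarray | int) -> np.ndarray | int:
    """Swap REF and ALT codes, leaving MISSING untouched."""
    arr = np.asarray(code)
    out = arr.copy()
    out[arr == REF] = ALT
    out[arr == ALT] = REF
    if np.isscalar(code):
        return int(out)
    return out


@dataclass(frozen=True)
class SNPRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    phase: Phase = Phase.UNPHASED

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT: "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


class SNPTable:
    """Ordered biallelic heterozygous SNPs of one chromosome."""

    def __init__(
        self,
        chrom: str,
        positions: Sequence[int],
        ref_alleles: Sequence[str],
        alt_alleles: Sequence[str],
        phase: Sequence[int] | None = None,
    ) -> None:
        self.chrom = str(chrom)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_alleles = np.asarray(ref_alleles, dtype="U1")
        self.alt_alleles = np.asarray(alt_alleles, dtype="U1")
        if phase is None:
            phase = np.zeros(len(self.positions), dtype=np.int8)
        self.phase = np.asarray(phase, dtype=np.int8)
        n = len(self.positions)
        if not (len(self.ref_alleles) == len(self.alt_alleles) == len(self.phase) == n):
            raise ValueError("SNPTable field lengths differ")
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if n and self.positions[0] < 1:
            raise ValueError("SNP positions must be >= 1")
        for arr in (self.ref_alleles, self.alt_alleles):
            if n and not set(arr.tolist()) <= _BASES:
                raise ValueError("alleles must be single bases in ACGT")
        if n and np.any(self.ref_alleles == self.alt_alleles):
            raise ValueError("ref and alt alleles must differ at every SNP")

    @classmethod
    def from_records(cls, records: Iterable[SNPRecord]) -> "SNPTable":
        recs = list(records)
        if not recs:
            return cls("", [], [], [], [])
        chrom = recs[0].chrom
        if any(r.chrom != chrom for r in recs):
            raise ValueError("all records must share one chromosome")
        return cls(
            chrom,
            [r.pos for r in recs],
            [r.ref_allele for r in recs],
            [r.alt_allele for r in recs],
            [int(r.phase) for r in recs],
        )

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> SNPRecord:
        return SNPRecord(
            self.chrom,
            int(self.positions[i]),
            str(self.ref_alleles[i]),
            str(self.alt_alleles[i]),
            Phase(int(self.phase[i])),
        )

    @property
    def records(self) -> Iterator[SNPRecord]:
        return (self[i] for i in range(len(self)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SNPTable):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ref_alleles, other.ref_alleles)
            and np.array_equal(self.alt_alleles, other.alt_alleles)
            and np.array_equal(self.phase, other.phase)
        )

    def __repr__(self) -> str:
        return f"SNPTable(chrom={self.chrom!r}, n_snps={len(self)})"


class BarcodeList:
    """Ordered unique cell barcodes."""

    def __init__(self, barcodes: Sequence[str]) -> None:
        self.barcodes = tuple(str(b) for b in barcodes)
        if any(not b for b in self.barcodes):
            raise ValueError("barcodes must be non-empty strings")
        seen: set[str] = set()
        for b in self.barcodes:
            if b in seen:
                raise ValueError(f"duplicate barcode: {b!r}")
            seen.add(b)
        self._index = {b: i for i, b in enumerate(self.barcodes)}

    def index(self, barcode: str) -> int:
        return self._index[barcode]

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def __len__(self) -> int:
        return len(self.barcodes)

    def __getitem__(self, i: int) -> str:
        return self.barcodes[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.barcodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodeList):
            return NotImplemented
        return self.barcodes == other.barcodes

    def __repr__(self) -> str:
        return f"BarcodeList(n={len(self)})"


class Haplotype:
    """Per-SNP allele assignment of parental haplotype 1 (may be MISSING)."""

    def __init__(self, snps: SNPTable, hap1: Sequence[int]) -> None:
        self.snps = snps
        self.hap1 = np.asarray(hap1, dtype=np.int8)
        if len(self.hap1) != len(snps):
            raise ValueError("haplotype length must equal number of SNPs")
        if len(self.hap1) and not set(np.unique(self.hap1)) <= {MISSING, REF, ALT}:
            raise ValueError("haplotype entries must be MISSING/REF/ALT")

    @property
    def n_phased(self) -> int:
        return int(np.count_nonzero(self.hap1))

    @property
    def phased_mask(self) -> np.ndarray:
        return self.hap1 != MISSING

    def signed(self) -> np.ndarray:
        """+1 where hap1 carries REF, -1 where ALT, 0 where missing."""
        s = np.zeros(len(self.hap1), dtype=np.int8)
        s[self.hap1 == REF] = 1
        s[self.hap1 == ALT] = -1
        return s

    def complement(self) -> "Haplotype":
        return Haplotype(self.snps, complement_code(self.hap1))

    def copy(self) -> "Haplotype":
        return Haplotype(self.snps, self.hap1.copy())

    def __len__(self) -> int:
        return len(self.hap1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Haplotype):
            return NotImplemented
        return self.snps == other.snps and np.array_equal(self.hap1, other.hap1)

    def __repr__(self) -> str:
        return f"Haplotype(n_snps={len(self)}, n_phased={self.n_phased})"


class GenotypeMatrix:
    """Cells x SNPs genotype calls in {MISSING, REF, ALT}."""

    def __init__(self, barcodes: BarcodeList, snps: SNPTable, geno: np.ndarray) -> None:
        self.barcodes = barcodes
        self.snps = snps
        self.geno = np.asarray(geno, dtype=np.int8)
        if self.geno.shape != (len(barcodes), len(snps)):
            raise ValueError("genotype matrix shape mismatch")
        if self.geno.size and not set(np.unique(self.geno)) <= {MISSING, REF, ALT}:
            raise ValueError("genotype entries must be MISSING/REF/ALT")

    def signed(self) -> np.ndarray:
        s = np.zeros(self.geno.shape, dtype=np.int8)
        s[self.geno == REF] = 1
        s[self.geno == ALT] = -1
        return s

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def __repr__(self) -> str:
        return f"GenotypeMatrix(cells={self.n_cells}, snps={len(self.snps)})"


def _as_count_matrix(m, shape: tuple[int, int]) -> sparse.csr_matrix:
    m = sparse.csr_matrix(m, shape=shape, dtype=np.int64)
    m.sum_duplicates()
    m.eliminate_zeros()
    m.sort_indices()
    if m.nnz and m.data.min() < 0:
        raise ValueError("allele counts must be non-negative")
    return m


class AlleleCountMatrix:
    """Sparse cells x SNPs counts of reference- and alternate-allele reads."""

    def __init__(self, snps: SNPTable, barcodes: BarcodeList, ref_counts, alt_counts) -> None:
        self.snps = snps
        self.barcodes = barcodes
        shape = (len(barcodes), len(snps))
        self.ref_counts = _as_count_matrix(ref_counts, shape)
        self.alt_counts = _as_count_matrix(alt_counts, shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref_counts.shape

    def total(self) -> sparse.csr_matrix:
        return (self.ref_counts + self.alt_counts).tocsr()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCountMatrix):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.barcodes == other.barcodes
            and (self.ref_counts != other.ref_counts).nnz == 0
            and (self.alt_counts != other.alt_counts).nnz == 0
        )

    def __repr__(self) -> str:
        return f"AlleleCountMatrix(cells={len(self.barcodes)}, snps={len(self.snps)})"
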