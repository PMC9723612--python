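"""Synthetic single-gamete datasets with known truth.

Emulates the data the pipeline consumes: two parental haplotypes over a
ladder of heterozygous SNPs, per-gamete crossover placements, sparse
Poisson read sampling with an allele-miscall rate, and optional template
switch errors.  Defaults mirror the validation regime of droplet single-cell
DNA sequencing: 100 gametes, ~21,000 hetSNPs over a 5 Mb region, 6 inserted
crossovers per gamete, mean coverage 0.5 reads per gamete per SNP, miscall
rate 0.005.

Crossover breakpoints are drawn uniformly among SNP gaps subject to a
minimum pairwise separation (default 100 gaps).  The separation emulates
manual insertion of distinguishable crossovers: without it a pair of
breakpoints can land so close together that the intervening segment carries
no read support in that gamete, which makes the event unrecoverable by
construction rather than by method error.  Set ``min_breakpoint_sep=0`` for
fully unconstrained placement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .core import ALT, REF, AlleleCountMatrix, BarcodeList, Haplotype, SNPTable

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    chrom: str = "chr1"
    n_cells: int = 100
    n_snps: int = 21000
    region_bp: int = 5_000_000
    snp_positions: np.ndarray | None = None  # overrides n_snps/region_bp when given
    crossovers_per_cell: int | tuple[int, ...] = 6  # scalar or one value per cell
    min_breakpoint_sep: int = 100  # minimum separation between breakpoints, in SNP gaps
    coverage_mean: float = 0.5  # expected reads per cell per SNP
    miscall_rate: float = 0.005  # probability a read reports the wrong allele
    template_switch_positions: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.miscall_rate < 0.5:
            raise ValueError("miscall_rate must be in [0, 0.5)")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")

    def crossovers_array(self) -> np.ndarray:
        k = np.asarray(self.crossovers_per_cell, dtype=np.int64)
        if k.ndim == 0:
            k = np.full(self.n_cells, int(k), dtype=np.int64)
        if len(k) != self.n_cells:
            raise ValueError("crossovers_per_cell must be scalar or one per cell")
        return k


@dataclass(frozen=True)
class TruthSet:
    snps: SNPTable  # unphased annotation, as the pipeline would see it
    hap_truth: Haplotype
    breakpoint_gaps: tuple[np.ndarray, ...]  # per cell, gap indices (between SNP g and g+1)
    breakpoint_bp: tuple[np.ndarray, ...]  # per cell, midpoints of those gaps
    gamete_states: np.ndarray  # (n_cells, n_snps) in {1=H1, 2=H2}
    switch_positions: tuple[int, ...] = ()
    corrupted_hap: Haplotype | None = None


def _draw_breakpoints(rng: np.random.Generator, n_gaps: int, k: int, min_sep: int) -> np.ndarray:
    """Uniform draw of k distinct gap indices, min_sep apart and away from the ends."""
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > n_gaps:
        raise ValueError(f"cannot place {k} crossovers in {n_gaps} SNP gaps")
    lo, hi = min_sep, n_gaps - min_sep  # keep terminal segments observable
    if hi - lo < k:
        raise ValueError(
            f"cannot place {k} breakpoints with separation >= {min_sep} in {n_gaps} gaps"
        )
    for _ in range(10_000):
        gaps = np.sort(rng.choice(np.arange(lo, hi), size=k, replace=False))
        if k == 1 or np.diff(gaps).min() >= min_sep:
            return gaps.astype(np.int64)
    raise ValueError(
        f"could not place {k} breakpoints with separation >= {min_sep} in {n_gaps} gaps"
    )


def simulate_truth(cfg: SimulationConfig) -> TruthSet:
    """Draw parental haplotypes, per-gamete breakpoints and gamete states."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.snp_positions is not None:
        positions = np.asarray(cfg.snp_positions, dtype=np.int64)
    else:
        if cfg.n_snps > cfg.region_bp:
            raise ValueError("more SNPs than base pairs in the region")
        positions = np.sort(rng.choice(cfg.region_bp, size=cfg.n_snps, replace=False)) + 1
    n_snps = len(positions)
    ref_idx = rng.integers(0, 4, n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, n_snps)) % 4
    snps = SNPTable(cfg.chrom, positions, _BASES[ref_idx], _BASES[alt_idx])
    hap1 = rng.choice(np.array([REF, ALT], dtype=np.int8), size=n_snps)
    hap_truth = Haplotype(snps, hap1)

    ks = cfg.crossovers_array()
    states = np.empty((cfg.n_cells, n_snps), dtype=np.int8)
    bp_gaps, bp_mid = [], []
    for c in range(cfg.n_cells):
        gaps = _draw_breakpoints(rng, n_snps - 1, int(ks[c]), cfg.min_breakpoint_sep)
        start = int(rng.integers(1, 3))  # fair coin over H1/H2
        flips = np.zeros(n_snps, dtype=np.int64)
        flips[gaps + 1] = 1
        states[c] = np.where(np.cumsum(flips) % 2 == 0, start, 3 - start)
        bp_gaps.append(gaps)
        bp_mid.append((positions[gaps] + positions[gaps + 1]) / 2.0)
    truth = TruthSet(
        snps=snps,
        hap_truth=hap_truth,
        breakpoint_gaps=tuple(bp_gaps),
        breakpoint_bp=tuple(bp_mid),
        gamete_states=states,
    )
    if cfg.template_switch_positions:
        truth = insert_template_switch(truth, cfg.template_switch_positions)
    return truth


def sample_counts(truth: TruthSet, cfg: SimulationConfig) -> AlleleCountMatrix:
    """Sparse binomial read sampling from the gamete haplotypes.

    Per cell per SNP the read count is Poisson(``coverage_mean``); each read
    reports the gamete's true allele with probability 1 - ``miscall_rate``
    and the other allele otherwise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_cells, n_snps = truth.gamete_states.shape
    n = rng.poisson(cfg.coverage_mean, (n_cells, n_snps))
    wrong = rng.binomial(n, cfg.miscall_rate)
    # the gamete's true allele: hap1 allele under state H1, complement under H2
    h = truth.hap_truth.hap1[None, :]
    true_allele = np.where(truth.gamete_states == 1, h, 3 - h)
    ref = np.where(true_allele == REF, n - wrong, wrong)
    alt = n - ref
    barcodes = BarcodeList([f"CELL{c:05d}" for c in range(n_cells)])
    return AlleleCountMatrix(
        truth.snps, barcodes, sparse.csr_matrix(ref), sparse.csr_matrix(alt)
    )


def insert_template_switch(truth: TruthSet, positions) -> TruthSet:
    """Attach a corrupted haplotype, complemented from each position onward.

    The original truth is retained; the switch positions are recorded
    verbatim for recovery scoring.
    """
    positions = tuple(int(p) for p in positions)
    n = len(truth.hap_truth)
    if any(p < 0 or p >= n for p in positions):
        raise ValueError("switch position out of range")
    hap1 = truth.hap_truth.hap1.copy()
    flips = np.zeros(n, dtype=np.int64)
    for p in positions:
        flips[p] += 1
    odd = np.cumsum(flips) % 2 == 1
    hap1[odd] = np.where(hap1[odd] == REF, ALT, REF).astype(np.int8)
    return replace(
        truth,
        switch_positions=positions,
        corrupted_hap=Haplotype(truth.snps, hap1),
    )


def simulate_dataset(cfg: SimulationConfig) -> tuple[TruthSet, AlleleCountMatrix]:
    truth = simulate_truth(cfg)
    return truth, sample_counts(truth, cfg)


def crossover_recovery(truth: TruthSet, crossovers: pd.DataFrame, barcodes: BarcodeList) -> pd.DataFrame:
    """Score called crossovers against the inserted truth, per cell.

    A true breakpoint is recovered when some called interval
    ``(left_pos, right_pos)`` of that cell contains it.  Returns one row per
    cell with the inserted/called/recovered counts.
    """
    rows = []
    for c, barcode in enumerate(barcodes):
        called = crossovers[crossovers["barcode"] == barcode]
        lefts = called["left_pos"].to_numpy()
        rights = called["right_pos"].to_numpy()
        n_rec = 0
        for bp in truth.breakpoint_bp[c]:
            if np.any((lefts < bp) & (bp < rights)):
                n_rec += 1
        rows.append(
            {
                "barcode": barcode,
                "n_inserted": len(truth.breakpoint_bp[c]),
                "n_called": len(called),
                "n_recovered": n_rec,
            }
        )
    return pd.DataFrame(rows)


def write_dataset(
    prefix: str, truth: TruthSet, counts: AlleleCountMatrix
) -> dict:
    """Write the dataset in the formats the pipeline consumes.

    Unphased VCF + barcode list + ref/alt MatrixMarket matrices + a truth TSV
    (hap1 allele and per-cell breakpoints as JSON-ish columns).
    """
    from .gamete_io import write_int_mtx, write_phased_vcf

    snps = truth.snps
    # unphased VCF: GT 0/1 for every hetSNP
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={snps.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for i in range(len(snps)):
        lines.append(
            f"{snps.chrom}\t{snps.positions[i]}\t.\t{snps.ref_alleles[i]}\t"
            f"{snps.alt_alleles[i]}\t.\tPASS\t.\tGT\t0/1"
        )
    paths = {
        "vcf": f"{prefix}.vcf",
        "barcodes": f"{prefix}_barcodes.txt",
        "ref_mtx": f"{prefix}_ref.mtx",
        "alt_mtx": f"{prefix}_alt.mtx",
        "truth_hap": f"{prefix}_truth_hap.txt",
        "truth_xo": f"{prefix}_truth_crossovers.txt",
        "truth_vcf": f"{prefix}_truth_phased.vcf",
    }
    Path(paths["vcf"]).write_text("\n".join(lines) + "\n")
    Path(paths["barcodes"]).write_text("\n".join(counts.barcodes) + "\n")
    write_int_mtx(paths["ref_mtx"], counts.ref_counts)
    write_int_mtx(paths["alt_mtx"], counts.alt_counts)
    hap = truth.hap_truth
    hap_base = np.full(len(snps), ".", dtype="U1")
    hap_base[hap.hap1 == REF] = snps.ref_alleles[hap.hap1 == REF]
    hap_base[hap.hap1 == ALT] = snps.alt_alleles[hap.hap1 == ALT]
    pd.DataFrame(
        {"chrom": snps.chrom, "pos": snps.positions, "hap1_allele": hap_base}
    ).to_csv(paths["truth_hap"], sep="\t", index=False)
    xo_rows = [
        {"barcode": counts.barcodes[c], "gap_index": int(g), "breakpoint_bp": float(bp)}
        for c in range(len(counts.barcodes))
        for g, bp in zip(truth.breakpoint_gaps[c], truth.breakpoint_bp[c])
    ]
    pd.DataFrame(xo_rows, columns=["barcode", "gap_index", "breakpoint_bp"]).to_csv(
        paths["truth_xo"], sep="\t", index=False
    )
    write_phased_vcf(paths["truth_vcf"], snps, hap)
    return paths
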