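"""Readers and writers for every standard format the pipeline touches.

Input side: VCF of heterozygous SNPs (cyvcf2), coordinate-sorted indexed BAM
with cell barcodes in the CB tag (pysam), plain-text barcode lists.
Intermediate side: MatrixMarket sparse allele-count matrices, a SNP
annotation TSV, a phased VCF with pipe-separated genotypes, and the Viterbi
segment table.

Coordinate conventions: VCF/annotation positions are 1-based; MatrixMarket
indices are 1-based on disk (scipy handles the shift); everything in memory
is 0-based.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import io as spio
from scipy import sparse

from .core import ALT, MISSING, REF, AlleleCountMatrix, BarcodeList, Haplotype, Phase, SNPTable

SEGMENT_COLUMNS = [
    "barcode",
    "chrom",
    "first_snp_pos",
    "last_snp_pos",
    "state",
    "n_snps",
    "n_reads",
    "log_lik_ratio",
]


def read_hetsnps(vcf_path: str | os.PathLike, chrom: str, min_qual: float = 0.0) -> SNPTable:
    """Read biallelic heterozygous SNVs for one chromosome from a VCF.

    Keeps records with a single-base REF and ALT, heterozygous genotype
    (0/1, 0|1 or 1|0 in the first sample) and QUAL >= ``min_qual`` (records
    with missing QUAL pass).  The phase field is set from pipe-separated
    genotypes: 0|1 -> H1_REF, 1|0 -> H1_ALT, otherwise UNPHASED.
    """
    vcf_path = os.fspath(vcf_path)
    if not os.path.exists(vcf_path):
        raise FileNotFoundError(vcf_path)
    try:
        vcf = VCF(vcf_path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise IOError(f"cannot read VCF {vcf_path}: {exc}") from exc
    positions, refs, alts, phases = [], [], [], []
    try:
        for v in vcf:
            if v.CHROM != chrom:
                continue
            if len(v.ALT) != 1:
                continue
            ref, alt = v.REF, v.ALT[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                continue
            if v.QUAL is not None and v.QUAL < min_qual:
                continue
            if not v.genotypes:
                continue
            gt = v.genotypes[0]
            if len(gt) < 3:
                raise ValueError(f"malformed genotype at {v.CHROM}:{v.POS}")
            a, b, phased = gt[0], gt[1], gt[-1]
            if {a, b} != {0, 1}:
                continue  # not heterozygous (or half-missing)
            if phased:
                phase = Phase.H1_REF if a == 0 else Phase.H1_ALT
            else:
                phase = Phase.UNPHASED
            positions.append(v.POS)
            refs.append(ref)
            alts.append(alt)
            phases.append(int(phase))
    finally:
        vcf.close()
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    return SNPTable(
        chrom,
        [positions[i] for i in order],
        [refs[i] for i in order],
        [alts[i] for i in order],
        [phases[i] for i in order],
    )


def read_barcodes(path: str | os.PathLike) -> BarcodeList:
    """Read a one-barcode-per-line text file, skipping blank lines."""
    with open(path) as fh:
        barcodes = [line.strip() for line in fh]
    return BarcodeList([b for b in barcodes if b])


def count_alleles(
    bam_path: str | os.PathLike,
    snps: SNPTable,
    barcodes: BarcodeList,
    min_mapq: int = 20,
    min_baseq: int = 13,
) -> AlleleCountMatrix:
    """Count ref- and alt-allele reads per cell at each SNP.

    Reads that are duplicates, secondary or supplementary, below ``min_mapq``,
    without a CB tag, or with a CB not in ``barcodes`` are ignored; bases
    below ``min_baseq`` or matching neither allele (including deletions/N)
    contribute nothing.
    """
    import pysam

    bam_path = os.fspath(bam_path)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if not bam.has_index():
            raise IOError(f"BAM index not found for {bam_path}")
        if snps.chrom not in bam.references:
            raise ValueError(f"chromosome {snps.chrom!r} absent from BAM header")
        positions = snps.positions  # 1-based
        cell_of = {b: i for i, b in enumerate(barcodes)}
        rows, cols, ref_data, alt_data = [], [], [], []
        for read in bam.fetch(snps.chrom):
            if (
                read.is_unmapped
                or read.is_duplicate
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
            ):
                continue
            try:
                cb = read.get_tag("CB")
            except KeyError:
                continue
            cell = cell_of.get(cb)
            if cell is None:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                j = int(np.searchsorted(positions, pos1))
                if j >= len(positions) or positions[j] != pos1:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos]
                if base == snps.ref_alleles[j]:
                    rows.append(cell)
                    cols.append(j)
                    ref_data.append(1)
                    alt_data.append(0)
                elif base == snps.alt_alleles[j]:
                    rows.append(cell)
                    cols.append(j)
                    ref_data.append(0)
                    alt_data.append(1)
    shape = (len(barcodes), len(snps))
    ref = sparse.coo_matrix((ref_data, (rows, cols)), shape=shape)
    alt = sparse.coo_matrix((alt_data, (rows, cols)), shape=shape)
    return AlleleCountMatrix(snps, barcodes, ref, alt)


# ---------------------------------------------------------------------------
# phase outputs: sparse matrices + SNP annotation + phased VCF + barcodes


def _mtx_path(prefix: str, tag: str) -> str:
    return f"{prefix}_{tag}.mtx"


def write_int_mtx(path: str | os.PathLike, matrix) -> None:
    """MatrixMarket coordinate-integer writer.

    scipy falls back to a ``real`` header for matrices with no stored
    entries; patch it so the declared field is always ``integer``.
    """
    coo = sparse.coo_matrix(matrix).astype(np.int64)
    spio.mmwrite(path, coo, field="integer", symmetry="general")
    if coo.nnz == 0:
        p = Path(os.fspath(path) if str(path).endswith(".mtx") else f"{path}.mtx")
        lines = p.read_text().splitlines()
        lines[0] = lines[0].replace(" real ", " integer ")
        p.write_text("\n".join(lines) + "\n")


def write_phased_vcf(path: str | os.PathLike, snps: SNPTable, hap: Haplotype) -> None:
    """Write the inferred haplotype as a single-sample phased VCF.

    GT is 0|1 where haplotype 1 carries the reference allele and 1|0 where
    it carries the alternate; SNPs with a missing assignment are omitted.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={snps.chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for i in range(len(snps)):
        h = hap.hap1[i]
        if h == MISSING:
            continue
        gt = "0|1" if h == REF else "1|0"
        lines.append(
            f"{snps.chrom}\t{snps.positions[i]}\t.\t{snps.ref_alleles[i]}\t"
            f"{snps.alt_alleles[i]}\t.\tPASS\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phase_outputs(prefix: str | os.PathLike, counts: AlleleCountMatrix, hap: Haplotype) -> dict:
    """Write allele-count matrices, SNP annotation, phased VCF and barcodes.

    Files: ``<prefix>_ref.mtx``, ``<prefix>_alt.mtx`` (MatrixMarket
    coordinate integer, cells as rows), ``<prefix>_snpAnnot.txt`` (TSV),
    ``<prefix>_phased.vcf`` and ``<prefix>_barcodes.txt``.
    """
    if len(hap) != len(counts.snps):
        raise ValueError("haplotype length must match number of SNPs")
    prefix = os.fspath(prefix)
    paths = {
        "ref_mtx": _mtx_path(prefix, "ref"),
        "alt_mtx": _mtx_path(prefix, "alt"),
        "snp_annot": f"{prefix}_snpAnnot.txt",
        "phased_vcf": f"{prefix}_phased.vcf",
        "barcodes": f"{prefix}_barcodes.txt",
    }
    write_int_mtx(paths["ref_mtx"], counts.ref_counts)
    write_int_mtx(paths["alt_mtx"], counts.alt_counts)

    snps = counts.snps
    hap_base = np.full(len(snps), ".", dtype="U1")
    hap_base[hap.hap1 == REF] = snps.ref_alleles[hap.hap1 == REF]
    hap_base[hap.hap1 == ALT] = snps.alt_alleles[hap.hap1 == ALT]
    annot = pd.DataFrame(
        {
            "chrom": snps.chrom,
            "pos": snps.positions,
            "ref": snps.ref_alleles,
            "alt": snps.alt_alleles,
            "phase": snps.phase,
            "inferred_hap1_allele": hap_base,
        }
    )
    annot.to_csv(paths["snp_annot"], sep="\t", index=False)
    write_phased_vcf(paths["phased_vcf"], snps, hap)
    Path(paths["barcodes"]).write_text("\n".join(counts.barcodes) + "\n")
    return paths


def read_phase_outputs(prefix: str | os.PathLike) -> tuple[AlleleCountMatrix, Haplotype]:
    """Inverse of :func:`write_phase_outputs` (exact round trip)."""
    prefix = os.fspath(prefix)
    ref = sparse.csr_matrix(spio.mmread(_mtx_path(prefix, "ref")))
    alt = sparse.csr_matrix(spio.mmread(_mtx_path(prefix, "alt")))
    annot = pd.read_csv(f"{prefix}_snpAnnot.txt", sep="\t", dtype={"inferred_hap1_allele": str})
    if ref.shape != alt.shape:
        raise ValueError("ref and alt matrices have different shapes")
    if ref.shape[1] != len(annot):
        raise ValueError(
            f"matrix has {ref.shape[1]} SNP columns but annotation has {len(annot)} rows"
        )
    chrom = str(annot["chrom"].iloc[0]) if len(annot) else ""
    snps = SNPTable(
        chrom,
        annot["pos"].to_numpy(),
        annot["ref"].astype(str).to_numpy(),
        annot["alt"].astype(str).to_numpy(),
        annot["phase"].to_numpy(),
    )
    barcodes = read_barcodes(f"{prefix}_barcodes.txt")
    if len(barcodes) != ref.shape[0]:
        raise ValueError("barcode count does not match matrix rows")
    hb = annot["inferred_hap1_allele"].astype(str).to_numpy()
    hap1 = np.full(len(snps), MISSING, dtype=np.int8)
    hap1[hb == snps.ref_alleles] = REF
    hap1[hb == snps.alt_alleles] = ALT
    counts = AlleleCountMatrix(snps, barcodes, ref, alt)
    return counts, Haplotype(snps, hap1)


# ---------------------------------------------------------------------------
# segment tables and diagnostic tracks


def write_segments(path: str | os.PathLike, segments: pd.DataFrame) -> None:
    segments = segments.loc[:, SEGMENT_COLUMNS]
    segments.to_csv(path, sep="\t", index=False)


def read_segments(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    return df


def write_switch_track(path: str | os.PathLike, track, snps: SNPTable) -> None:
    """Write the per-candidate switch-score track (snp_index, pos, score)."""
    df = pd.DataFrame(
        {
            "snp_index": track.candidate_indices,
            "pos": snps.positions[track.candidate_indices]
            if len(track.candidate_indices)
            else [],
            "score": track.scores,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_genotype_diagnostics(path: str | os.PathLike, geno_matrix, hap: Haplotype) -> None:
    """Per-cell, per-SNP match-vs-template codes behind the diagnostic plots.

    Long TSV with one row per informative (cell, SNP): code 1 when the cell's
    genotype matches haplotype 1, 2 when it matches the complement.
    """
    sg = geno_matrix.signed().astype(np.int32)
    hs = hap.signed().astype(np.int32)
    m = sg * hs[None, :]
    cells, snp_idx = np.nonzero(m)
    codes = np.where(m[cells, snp_idx] > 0, 1, 2)
    df = pd.DataFrame(
        {
            "barcode": np.asarray(geno_matrix.barcodes.barcodes)[cells],
            "snp_index": snp_idx,
            "pos": geno_matrix.snps.positions[snp_idx],
            "match": codes,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def haplotype_from_phase_field(snps: SNPTable) -> Haplotype:
    """Build a Haplotype from the phase annotation of a (phased) SNP table."""
    hap1 = np.full(len(snps), MISSING, dtype=np.int8)
    hap1[snps.phase == int(Phase.H1_REF)] = REF
    hap1[snps.phase == int(Phase.H1_ALT)] = ALT
    return Haplotype(snps, hap1)
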