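"""Template-based haplotype phasing from gamete genotype co-segregation.

The donor's two haplotypes are reconstructed chromosome by chromosome from
the genotypes of many haploid gametes.  Because crossovers are rare, a gamete
that carries none on a chromosome reproduces one parental haplotype exactly;
the algorithm looks for a pair of gametes with (near-)identical genotype
sequences, uses one as a template haplotype backbone, and fills in the
template's missing SNPs by majority vote over local linkage with the other
gametes.  Allele labels are arbitrary, so two genotype sequences that are
global complements of each other carry the same haplotype information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ALT,
    MISSING,
    REF,
    AlleleCountMatrix,
    GenotypeMatrix,
    Haplotype,
    complement_code,
)


@dataclass(frozen=True)
class TemplateSelection:
    template_cell: int
    partner_cell: int
    n_shared: int
    concordance: float
    fallback_used: bool


def call_genotypes(
    counts: AlleleCountMatrix, min_total: int = 1, min_purity: float = 0.8
) -> GenotypeMatrix:
    """Call per-cell genotypes from allele counts by majority allele.

    A call is MISSING when coverage is below ``min_total``, the majority
    fraction is below ``min_purity``, or ref and alt counts tie.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if not 0.5 < min_purity <= 1.0:
        raise ValueError("min_purity must be in (0.5, 1]")
    ref = np.asarray(counts.ref_counts.todense(), dtype=np.int64)
    alt = np.asarray(counts.alt_counts.todense(), dtype=np.int64)
    total = ref + alt
    geno = np.where(ref > alt, REF, ALT).astype(np.int8)
    major = np.maximum(ref, alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        purity = np.where(total > 0, major / np.maximum(total, 1), 0.0)
    bad = (total < min_total) | (purity < min_purity) | (ref == alt)
    geno[bad] = MISSING
    return GenotypeMatrix(counts.barcodes, counts.snps, geno)


def select_template(
    G: GenotypeMatrix, min_shared: int = 30, min_concordance: float = 0.99
) -> TemplateSelection:
    """Pick the template cell from the most concordant cell pair.

    Pair concordance is the fraction of co-covered SNPs with equal genotypes,
    maximised over the two label orientations (equal or all-complement).
    Among pairs with at least ``min_shared`` co-covered SNPs and concordance
    at least ``min_concordance`` — the pairs whose genotype sequences look
    like "the same haplotype" — the pair with the most co-covered SNPs wins
    (then higher concordance, then lowest indices): the amount of shared
    evidence, not a chance-perfect match over a handful of SNPs, decides.
    The pair member covering more SNPs becomes the template.  When no pair
    qualifies, the most-covered single cell is used as a fallback template
    (switch errors it introduces are repaired downstream).
    """
    n_cells = G.n_cells
    if n_cells < 2:
        raise ValueError("template selection requires at least 2 cells")
    S = G.signed().astype(np.int32)
    nonzero = (S != 0).astype(np.int32)
    agree_minus_disagree = S @ S.T
    shared = nonzero @ nonzero.T
    n_agree = (shared + agree_minus_disagree) // 2
    with np.errstate(divide="ignore", invalid="ignore"):
        conc_same = np.where(shared > 0, n_agree / np.maximum(shared, 1), 0.0)
    conc = np.maximum(conc_same, 1.0 - conc_same)

    iu, ju = np.triu_indices(n_cells, k=1)
    valid = (shared[iu, ju] >= min_shared) & (conc[iu, ju] >= min_concordance)
    coverage = nonzero.sum(axis=1)
    fallback = TemplateSelection(
        template_cell=int(np.argmax(coverage)),
        partner_cell=int(np.argmax(coverage)),
        n_shared=0,
        concordance=0.0,
        fallback_used=True,
    )
    if not valid.any():
        return fallback
    ii, jj = iu[valid], ju[valid]
    cc, ss = conc[ii, jj], shared[ii, jj]
    # lexicographic max on (n_shared, concordance), lowest (i, j) on ties
    order = np.lexsort((jj, ii, -cc, -ss))
    best = order[0]
    i, j = int(ii[best]), int(jj[best])
    template, partner = (i, j) if coverage[i] >= coverage[j] else (j, i)
    return TemplateSelection(
        template_cell=template,
        partner_cell=partner,
        n_shared=int(ss[best]),
        concordance=float(cc[best]),
        fallback_used=False,
    )


def template_haplotype(G: GenotypeMatrix, sel: TemplateSelection) -> Haplotype:
    """Use the template cell's genotype sequence as the haplotype backbone."""
    return Haplotype(G.snps, G.geno[sel.template_cell].copy())


def impute_missing(
    G: GenotypeMatrix,
    hap: Haplotype,
    window: int = 10,
    min_link_cells: int = 2,
    link_threshold: float = 0.8,
) -> Haplotype:
    """Fill missing template SNPs from local SNP linkage across gametes.

    For each missing SNP, every gamete covering it is oriented against the
    current haplotype over its nearest ``window`` informative SNPs on each
    side.  A flank with >= 2 informative SNPs is decisive when its
    concordance reaches ``link_threshold`` (same orientation) or falls below
    ``1 - link_threshold`` (complement orientation); the gamete votes its own
    genotype or the complement only when its available flanks are decisive
    and agree, and abstains otherwise — in particular when the two flanks
    disagree, the signature of a crossover or haplotype flip between them.
    The majority allele is assigned when at least ``min_link_cells`` votes
    agree and the majority fraction reaches ``link_threshold``.  Passes
    repeat until the phased set stops growing; existing assignments are
    never overwritten.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0.5 < link_threshold <= 1.0:
        raise ValueError("link_threshold must be in (0.5, 1]")
    sg = G.signed().astype(np.int64)
    hap1 = hap.hap1.copy()
    n_snps = len(hap1)
    while True:
        hs = np.zeros(n_snps, dtype=np.int64)
        hs[hap1 == REF] = 1
        hs[hap1 == ALT] = -1
        missing_idx = np.flatnonzero(hap1 == MISSING)
        if len(missing_idx) == 0:
            break
        votes_ref = np.zeros(n_snps, dtype=np.int64)
        votes_alt = np.zeros(n_snps, dtype=np.int64)
        for c in range(G.n_cells):
            m = sg[c] * hs  # +1 match, -1 mismatch, 0 uninformative
            inf = np.flatnonzero(m)
            if len(inf) < 2:
                continue
            cum = np.concatenate(([0], np.cumsum(m[inf])))
            covered = sg[c, missing_idx] != 0
            targets = missing_idx[covered]
            if len(targets) == 0:
                continue
            pos = np.searchsorted(inf, targets)
            n_left = np.minimum(window, pos)
            n_right = np.minimum(window, len(inf) - pos)
            s_left = cum[pos] - cum[pos - n_left]
            s_right = cum[pos + n_right] - cum[pos]

            def _orient(s, n):
                # +1 same orientation, -1 complement, 0 indecisive/unavailable.
                # Matches (n+s)/2 and mismatches (n-s)/2 are compared against
                # the same threshold so the rule is exactly label-symmetric.
                need = 2.0 * link_threshold * n
                o = np.zeros(len(n), dtype=np.int8)
                avail = n >= 2
                o[avail & (n + s >= need)] = 1
                o[avail & (n - s >= need)] = -1
                return o, avail

            o_left, avail_left = _orient(s_left, n_left)
            o_right, avail_right = _orient(s_right, n_right)
            both = avail_left & avail_right
            orient = np.zeros(len(targets), dtype=np.int8)
            orient[both & (o_left == o_right)] = o_left[both & (o_left == o_right)]
            only_left = avail_left & ~avail_right
            only_right = avail_right & ~avail_left
            orient[only_left] = o_left[only_left]
            orient[only_right] = o_right[only_right]
            own = G.geno[c, targets]
            vote = np.zeros(len(targets), dtype=np.int8)
            vote[orient == 1] = own[orient == 1]
            vote[orient == -1] = complement_code(own[orient == -1])
            np.add.at(votes_ref, targets[vote == REF], 1)
            np.add.at(votes_alt, targets[vote == ALT], 1)
        total = votes_ref + votes_alt
        major = np.maximum(votes_ref, votes_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(total > 0, major / np.maximum(total, 1), 0.0)
        assign = (
            (hap1 == MISSING)
            & (votes_ref != votes_alt)
            & (major >= min_link_cells)
            & (frac >= link_threshold)
        )
        if not assign.any():
            break
        hap1[assign & (votes_ref > votes_alt)] = REF
        hap1[assign & (votes_alt > votes_ref)] = ALT
    return Haplotype(hap.snps, hap1)


def phase_dataset(
    counts: AlleleCountMatrix,
    min_total: int = 1,
    min_purity: float = 0.8,
    min_shared: int = 30,
    min_concordance: float = 0.99,
    window: int = 10,
    min_link_cells: int = 2,
    link_threshold: float = 0.8,
) -> tuple[Haplotype, TemplateSelection, GenotypeMatrix]:
    """Genotype calling + template selection + imputation in one call."""
    G = call_genotypes(counts, min_total=min_total, min_purity=min_purity)
    sel = select_template(G, min_shared=min_shared, min_concordance=min_concordance)
    hap = template_haplotype(G, sel)
    hap = impute_missing(
        G, hap, window=window, min_link_cells=min_link_cells, link_threshold=link_threshold
    )
    return hap, sel, G
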