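"""High-level compositions of the pipeline stages.

These are the library equivalents of the CLI subcommands: ``autophase`` is
phase followed by switch correction on the same genotype matrix, and the
crossover workflow is Viterbi calling followed by comap filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .comap import FilterParams, crossovers_from_segments
from .core import AlleleCountMatrix, GenotypeMatrix, Haplotype
from .crossover_hmm import HMMParams, ViterbiResult, call_crossovers_dataset
from .phasing import TemplateSelection, phase_dataset
from .switch_correction import (
    DEFAULT_MIN_SCORE,
    SwitchCall,
    SwitchScoreTrack,
    correct_switches,
)


@dataclass
class AutophaseResult:
    haplotype: Haplotype
    raw_haplotype: Haplotype
    selection: TemplateSelection
    genotypes: GenotypeMatrix
    switch_call: SwitchCall
    switch_track: SwitchScoreTrack


def autophase(
    counts: AlleleCountMatrix,
    min_total: int = 1,
    min_purity: float = 0.8,
    min_shared: int = 30,
    min_concordance: float = 0.99,
    window: int = 10,
    min_link_cells: int = 2,
    link_threshold: float = 0.8,
    link_ratio_threshold: float = 0.7,
    epsilon: float = 0.1,
    min_score: float = DEFAULT_MIN_SCORE,
    min_gap: int = 20,
) -> AutophaseResult:
    """Phase from allele counts, then detect and repair switch errors."""
    hap_raw, sel, G = phase_dataset(
        counts,
        min_total=min_total,
        min_purity=min_purity,
        min_shared=min_shared,
        min_concordance=min_concordance,
        window=window,
        min_link_cells=min_link_cells,
        link_threshold=link_threshold,
    )
    hap, call, track = correct_switches(
        G,
        hap_raw,
        link_ratio_threshold=link_ratio_threshold,
        window=window,
        epsilon=epsilon,
        min_score=min_score,
        min_gap=min_gap,
    )
    return AutophaseResult(
        haplotype=hap,
        raw_haplotype=hap_raw,
        selection=sel,
        genotypes=G,
        switch_call=call,
        switch_track=track,
    )


def call_and_filter(
    counts: AlleleCountMatrix,
    hap: Haplotype,
    params: HMMParams | None = None,
    filters: FilterParams | None = None,
    out_prefix: str | None = None,
) -> tuple[ViterbiResult, pd.DataFrame, pd.DataFrame]:
    """Viterbi crossover calling + comap filtering.

    Returns the Viterbi result, the filtered crossover table and the per-cell
    QC table.
    """
    result = call_crossovers_dataset(counts, hap, params=params, out_prefix=out_prefix)
    segments = result.to_segments_frame()
    crossovers, qc = crossovers_from_segments(segments, filters=filters)
    return result, crossovers, qc
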