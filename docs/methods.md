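# Methods

## The problem

A diploid individual carries two haplotypes per chromosome. Each haploid
gamete (sperm, pollen, egg) inherits a mosaic of the two, switching haplotype
at meiotic crossovers. Sequencing many gametes of one donor at low depth —
typically a droplet single-cell DNA protocol producing one cell-barcoded BAM —
gives, at each heterozygous SNP (hetSNP), a handful of reads per gamete that
support one allele or the other. From these data the package:

1. reconstructs the donor's chromosome-scale haplotypes from allele
   co-segregation across gametes (`phasing`),
2. detects and repairs switch errors in the reconstruction
   (`switch_correction`),
3. assigns each gamete a haplotype-state path along the chromosome and calls
   crossovers at state changes (`crossover_hmm`),
4. filters the calls, builds genetic maps and compares gamete groups
   (`comap`).

Everything is testable without external data through `synthetic_data`, which
generates gamete datasets with known haplotypes, crossover positions and
switch errors in the exact formats the pipeline consumes.

## Phasing by template and local linkage

Because crossovers are rare (order 10⁻⁸ per bp per meiosis), a gamete that
carries none on a chromosome reproduces one parental haplotype exactly.
Genotypes are first called per gamete per SNP by majority allele
(`min_total` ≥ 1 read, majority fraction ≥ `min_purity` = 0.8). All gamete
pairs are then compared; pair concordance is the fraction of co-covered SNPs
with equal genotypes, maximised over the two label orientations since a
sequence and its global complement carry the same haplotype. Among pairs
with ≥ `min_shared` = 30 co-covered SNPs and concordance ≥ `min_concordance`
= 0.99, the pair with the most co-covered SNPs wins and its better-covered
member becomes the template: the amount of shared evidence, not a
chance-perfect match over a few SNPs, should decide. When no pair qualifies
(common when every gamete carries several crossovers), the most-covered
single gamete is the fallback template; its crossovers become switch errors
that the correction stage repairs.

Missing template SNPs are imputed from local linkage. For a missing SNP,
each covering gamete is oriented against the current haplotype over its
nearest ≤ `window` = 10 informative SNPs on each side. A flank with ≥ 2
informative SNPs is *decisive* when its concordance is ≥ `link_threshold`
= 0.8 (same orientation) or ≤ 0.2 (complement). A gamete votes its own
genotype (or its complement) only when its available flanks are decisive and
agree; disagreeing flanks are the signature of a crossover — in the gamete or
in the haplotype — between them, and the gamete abstains. Requiring
*per-flank* agreement is deliberate: a combined two-flank concordance lets
gametes whose flanks straddle a haplotype flip cast confidently wrong votes,
which seeds a patchwork of misoriented SNPs around every template crossover.
With abstention, those few SNPs simply remain unphased. The majority allele
is assigned when ≥ `min_link_cells` = 2 votes agree at majority fraction
≥ `link_threshold`; passes repeat until the phased set stops growing, and a
template assignment is never overwritten.

## Switch scores and correction

A switch error complements the haplotype from one SNP onward. Candidate
sites are phased SNPs whose adjacent-pair linkage support — the fraction of
gametes covering both SNPs of the pair whose genotype pair is
haplotype-consistent — falls below `link_ratio_threshold` = 0.7, or whose
pair is covered by fewer than two gametes.

The switch score at SNP k contrasts, per gamete, the likelihood that the two
flanks (nearest ≤ `window` informative SNPs before k; k and the following
≤ `window` − 1) have opposite haplotype orientations versus the same
orientation, assuming a per-SNP genotype error rate `epsilon` = 0.1. With
per-flank (match − mismatch) sums a and b, the per-gamete contribution
reduces to (|a−b| − |a+b|)/2 · ln((1−ε)/ε); the sum over gametes is positive
when the data favour a switch at k. The statistic is a block-splitting
likelihood test adapted to haploid gametes, kept behind one function so it
can be swapped.

Correction is iterative: score all candidates, accept the single strongest
peak above `min_score` = ln 10⁴ (peaks are compared only against track
neighbours closer than `min_gap` = 20 SNPs), complement the haplotype from
that position onward, and re-score. Iteration matters: around a sparsely
phased stretch one underlying switch produces high scores at several nearby
candidates, and re-scoring after the first correction removes the
secondaries instead of accepting them as extra (parity-breaking) switches.
The loop stops when no peak reaches `min_score`, refusing to toggle a site
twice. `autophase` is exactly phase followed by this correction and writes
byte-identical outputs to running the two steps separately.

## Crossover calling

Per gamete, covered phased SNPs form a chain over hidden states H1/H2 (which
parental haplotype the local segment derives from). Emissions are full
binomial log-probabilities of the haplotype-1-supporting read count with
success probability `theta2` = 0.9 under H1 and `theta1` = 0.1 under H2 —
deliberately loose to absorb mapping artefacts and residual phasing errors.
The per-gap transition probability defaults to distance scaling,
p = gap_bp · cmPmb · 10⁻⁸ with `cmPmb` = 0.1 cM/Mb, clamped to
[`p_min` = 10⁻¹⁰, `p_max` = 0.25]; a constant per-gap probability
(`p_const`) is available. Zero-coverage SNPs are omitted from the chain
rather than modelled as missing emissions, matching the sparse output
format. Viterbi decoding (ties broken toward the previous state) yields the
state path; maximal same-state runs become segments; a segment's confidence
is the log-likelihood ratio of the decoded full path against the same path
with the segment's states reversed — only the segment's emissions, its
boundary transitions and (for a leading segment) the initial-state term
differ. Emissions include the binomial coefficient; it cancels in every
ratio and comparison, so only reported likelihood scales are affected.

A consequence of the distance-scaled prior worth knowing: when the SNP next
to a true crossover carries a single read, moving the boundary past it costs
only ln(θ₂/θ₁) ≈ 2.2, so a nearby gap more than ~9× larger can legitimately
attract the MAP boundary. The crossover *count* is unaffected, but the
reported interval then excludes the true breakpoint. With `p_const` the
boundary is placed purely by read evidence and only a miscalled read on a
single-read boundary SNP (probability ≈ miscall rate) can displace it. At
coverage 0.5 and miscall 0.005 the simulation study measures the true
breakpoint inside the called interval for ≈ 93% of crossovers under the
distance-scaled default and ≈ 98% under constant transitions; the residual
misses are evidence-faithful and no decoder could avoid them.

## Crossover landscapes and comparisons

Segment tables are filtered in one pass: whole gametes are dropped below
`min_cell_snps` = 200 covered SNPs or above `max_raw_co` = 10 raw crossovers
per chromosome; segments failing `min_seg_snps` = 3, `min_seg_llr` = 10 or
`min_seg_bp` = 10⁵ are removed, their SNPs absorbed into the nearest left
surviving neighbour, and adjacent same-state survivors re-merged (spans,
SNPs, reads and LLRs combined). Single-pass evaluation on the original
segments makes the retained crossover count provably non-increasing as any
threshold tightens. Each remaining state change is a crossover on the
interval (last SNP of the left segment, first SNP of the right), with
confidence the smaller flanking LLR. The bp-span default suits mammalian
chromosomes with uneven marker density; on the uniform simulated SNP ladder
the span filter is turned off and the SNP-count and LLR filters do the work.

Crossover mass is distributed over genomic bins proportionally to interval
overlap (a crossover's position is only known to an interval); midpoint
assignment is available. Per-bin recombination fractions (group mean mass
per gamete) become centiMorgans through Kosambi,
d = 25·ln((1+2r)/(1−2r)), or Haldane, d = −50·ln(1−2r); both are undefined
at r ≥ 0.5 and error there unless clamping is requested. Bins should be
chosen fine enough that r stays well below 0.5. Group differences in total
genetic distance are tested by percentile bootstrap (resampling gametes with
replacement within groups) and by two-sided permutation with the add-one
correction p = (1 + #{|d*| ≥ |d|})/(B+1); inside resamples, per-bin rates
are clamped just below 0.5 so an extreme resample keeps the statistic
finite. Diagnostics include per-bin phasing concordance against a reference
haplotype (100-SNP bins, after whole-chromosome orientation by majority
vote) and the contradictory-allele read frequency, the minority-haplotype
read fraction per gamete in 1000-SNP bins.

## The synthetic-data generator

`SimulationConfig` defaults describe the validation regime: 100 gametes,
21,000 hetSNPs uniformly placed over 5 Mb, 6 crossovers per gamete, Poisson
read coverage with mean 0.5 per gamete per SNP, and a 0.005 probability that
a read reports the wrong allele. Breakpoints are drawn uniformly among SNP
gaps subject to a minimum pairwise separation of 100 gaps, also enforced
against the chromosome ends. The separation emulates *inserted* crossovers,
i.e. events that are recoverable in principle: without it, a breakpoint can
fall so close to a neighbour or to a chromosome end that the intervening
segment carries no read support in a given gamete, an event no method could
detect. Set `min_breakpoint_sep=0` for unconstrained placement. Template
switch errors are inserted by complementing the true haplotype from chosen
positions onward, keeping the original for scoring.

What the generator does *not* emulate: read length and mapping artefacts
(reads are reduced to per-SNP allele evidence), uneven marker density,
regions of homozygosity, crossover interference, chromatid-level
correlations, and doublets or barcode collisions. Passing tests therefore
demonstrate the correctness of the inference given the binomial read model,
not robustness to alignment pathologies — the hetSNP filtering upstream of
this package is where those are handled.

## Validation studies and problem sizes

The test suite and `scripts/acceptance.py` run, at sizes chosen to exercise
the full regime of interest:

- the full-scale simulation (100 × 21,000, three fixed seeds in the tests):
  all six crossovers recovered in every gamete and ≤ 95 hetSNPs phased
  discordantly (measured: 27–43);
- Viterbi and segment-LLR checks against exhaustive path enumeration on 200
  random chains of ≤ 10 SNPs (agreement to 10⁻⁹);
- switch recovery over 50 replicates (100 gametes × 1000 SNPs, coverage
  0.3): detection within 5 phased SNPs and ≥ 99.9% corrected accuracy
  required in ≥ 95% of replicates;
- resampling calibration on null data (Poisson crossovers, random labels;
  50 bins of 20 kb so per-bin rates stay far from 0.5): permutation type-I
  error 0.05 ± 0.02 over 400 simulations at B = 199, and bootstrap 95% CI
  covering zero in ≥ 90% of 50 replicates with 60 gametes per group — a
  group size at which the percentile bootstrap's asymptotics are
  trustworthy;
- bit-exact round trips of the MatrixMarket/annotation/phased-VCF outputs
  and byte-identical segment files from the BAM-driven and
  saved-matrix-driven crossover callers.

## Known limitations

- Diploid donors only; no polyploid support.
- Template selection is pair-based and can adopt a gamete whose crossovers
  nearly coincide with another's; the switch-correction stage repairs this,
  so accuracy guarantees hold for the composed phase + correction workflow.
- The distance-scaled transition prior trades boundary placement for
  rate-consistency (see above); use `p_const` when interval fidelity around
  single-read boundary SNPs matters more than the recombination-rate prior.
- Genotyping errors baked into the template (a miscalled single read on a
  template-covered SNP, ≈ 0.4% of covered SNPs at these settings) are never
  revisited; they dominate the residual discordant-SNP count.
- The per-gamete HMM treats SNPs independently given the state; correlated
  mapping artefacts violate this and are the main reason the loose emission
  parameters (0.1/0.9) are the default.
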