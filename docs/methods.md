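# Methods

This note documents the models and decision rules implemented by
`cgprofiler`, the parameters that matter, what the synthetic data emulate,
and the choices made where the assay's published rules leave the design
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sample QC

A tumor sample passes QC iff its mean on-target depth is ≥ 150X **and**
≥ 75% of panel bases are covered at 100X. Both comparisons are inclusive,
matching the assay's "greater than or equal to" phrasing. The gate is
monotone in both arguments by construction. Depth profiles are stored as
per-base integer arrays over the panel intervals; BED intervals are 0-based
half-open, VCF positions 1-based, and all internal arithmetic is 0-based
half-open.

## TMB

TMB = (number of eligible somatic variants) / (effective panel size in Mb).

A variant is *eligible* when all of: it passed caller filters; it is not a
likely-germline dbSNP site (the `in_dbsnp` flag stands in for a live dbSNP
lookup); it lies in a coding region; it is not synonymous; VAF ≥ 5%,
alt depth ≥ 5, total depth ≥ 15 (all inclusive). The *effective panel
size* counts only coding panel bases whose total depth is ≥ 15X, so a
poorly covered sample has a smaller denominator rather than a deflated
numerator. An effective size of zero makes TMB uncomputable — an error,
never a score of 0. TMB-High is called at score ≥ 10 mut/Mb; the published
rule does not state inclusivity and we use ≥, matching common practice for
the 10 mut/Mb label.

### In-silico dilution (tumor-fraction stability)

`mix_and_subsample` mixes tumor and normal material at a parts ratio
(tumor fraction = t/(t+n)) and downsamples to a target depth. Two modes
honor the same binomial contract: read collections (tumor-origin count
binomial in the fraction, then without-replacement draws from each pool)
and per-site allele counts (binomial tumor-origin draw, hypergeometric alt
draw from each pool's alt/ref composition). Requesting more depth than
either pool holds is an error.

`tmb_stability_experiment` thins the depth profile binomially to each
target mean depth, dilutes each variant's VAF by the tumor fraction via a
binomial alt-read redraw at its local depth, re-applies the full
eligibility filter to the *observed* values (the 5% cutoff applies
post-dilution), and recomputes TMB; each row carries the QC flag of its
thinned profile. Two regimes follow directly from the binomial structure:
variants planted comfortably above 0.05/fraction stay eligible and TMB is
stable; variants at truth VAF 0.10 diluted to fraction 0.10 fall to 1%
observed VAF, far below the 5% cutoff, and TMB collapses toward zero. The
experiment's default fixture plants VAFs uniform on [0.25, 0.45] over a
100 kb desk-scale panel (40 variants), so the stability boundary it
reports depends on — and is interpreted relative to — that planted
spectrum; a fixture with mass near 5%/fraction would move the boundary up.

## MSI

The per-locus statistic is a deliberate, testable surrogate for the
production tool it replaces: a two-sample chi-squared test comparing the
tumor and normal repeat-length histograms (2×L contingency table over the
union of observed lengths, adjacent bins greedily merged until every
expected count is ≥ 5), rejecting at `alpha` (default 0.05), **and** a
requirement that the tumor modal repeat length differ from the normal one.
The modal-shift requirement suppresses statistically significant but
biologically meaningless one-unit wobble at very high depth. A locus is
*detected* (and enters the denominator) only when both samples have
≥ `min_reads` (default 20) reads; under-covered loci are excluded rather
than counted as stable. A sample is MSI-High when
100 × unstable/detected ≥ 20% (inclusive); zero detected loci yields
UNCALLABLE, never MSS.

The PCR classifier takes the five NCI mononucleotide markers (BAT-25,
BAT-26, MONO-27, NR-21, NR-24) and calls MSI-High at ≥ 2 altered markers.

## Gene amplification

Coverage is summarised in 100-bp bins over panel regions. The
panel-of-normals baseline is the per-bin median of library-size-normalized
(unit-mean scaled) coverage across ≥ 2 normal samples (the assay's own
baseline used 90); per-bin dispersion is the MAD, and bins with zero median
are masked. A GC-correction hook exists but is off by default.

A sample's per-bin copy ratio is its normalized coverage divided by the
baseline level, then recentred by the median ratio across usable bins.
The recentring matters: total-count scaling is biased by the amplified
bins themselves (with k of N bins amplified at ratio r, naive scaling
deflates every ratio by (N−k+kr)/N), and the median is robust to any
amplified fraction below one half. A gene's segment mean is the plain mean
of its unmasked bin ratios — one segment per gene, no change-point
segmentation, because the assay reports gene-level calls only. Amplified
iff segment mean ≥ 2.0 (linear scale, inclusive): at purity 1 that is four
or more copies, which makes +3-copy reference standards callable (expected
ratio (2+3)/2 = 2.5). Copy ratio is invariant to global multiplicative
scaling of the sample's coverage. Losses are reported descriptively at
segment mean ≤ 0.5 without an analytically validated threshold. Purity is
a known confounder: ratios are not purity-corrected.

## Gene fusions

Detection is DNA-level (intron-targeted probes); each piece of evidence is
a soft-clipped read whose clipped remainder re-aligns to a second locus.
Evidence with clips shorter than `min_clip` (default 20 bp), loci outside
panel genes, or both loci in the same gene is excluded. Evidence joins a
cluster when both partner loci agree within `tolerance` (default 5 bp;
single linkage, so agreement is transitive). Both read orientations of a
junction collapse to one call; the gene pair is reported alphabetically.
`spanning_reads` counts distinct read ids; the consensus breakpoint is the
modal position (smallest on ties). A fusion is reported at ≥ 2 spanning
reads. The clustering tolerance and minimum clip length are configuration
with the stated defaults — the published rule fixes only the ≥ 2-read
threshold.

## ctDNA / MRD tracking

The composite ranking score is an explicit weighted sum — the ordering
logic, not the exact weights, is the tested contract:

| component | definition | default weight |
| --- | --- | --- |
| vaf_term | min(tissue VAF / 0.5, 1) | 0.30 |
| pathogenicity_term | annotation score in [0, 1] | 0.25 |
| type_term | 1.0 truncating/frameshift; 0.8 missense hotspot (recurrence ≥ 20); 0.6 other missense; 0.3 other | 0.15 |
| dbfreq_term | log10(1 + recurrence)/log10(1 + 1000), capped at 1 | 0.20 |
| whitelist_term | 1 if internally validated tumor-derived | 0.10 |

Weights must sum to 1; a missing annotation zeroes its term with a warning
but never fails. Ties in the ranking break by tissue VAF descending, then
position. The top min(5, available) variants are selected; fewer than 2
candidates sets an insufficient-tracking-set flag. Splice variants score
0.3 (the "other" class): the type enumeration reserves 1.0 for truncating
events in the narrow sense (nonsense/frameshift).

A plasma amplicon is evaluable at coverage ≥ 10,000X (inclusive); a
timepoint is ctDNA-positive when any evaluable amplicon's VAF is
**strictly above** 0.05%. All amplicons unsuccessful ⇒ uncallable, never
negative. No background-error subtraction is applied by default (the
published rule is a plain threshold); at the default conditions the false
positive risk is the binomial tail P(Bin(100000, 10⁻⁴) > 50) ≈ 10⁻⁴ per
amplicon. Longitudinal series yield clearance (positive→negative) and
molecular relapse (negative→positive) events; uncallable timepoints carry
no state change; a series positive at every callable timepoint (≥ 2) is
flagged persistent MRD. The cfDNA input requirement (≥ 0.15 ng/µL or
≥ 3 ng) is recorded as a pre-analytic flag, not enforced computationally.

## Validation statistics

Confusion counts use exact-allele matching on (chrom, pos, ref, alt) after
parsimony normalization (shared suffix then prefix trimmed, keeping one
base, position advanced over trimmed prefix) so differently written indels
compare equal; full left-alignment would need the reference sequence and
is out of scope. The truth universe is the declared positive plus negative
positions; calls outside it are ignored, so tp+fn and tn+fp always
partition the universe. The LOD is the minimum tested VAF level whose
replicate detection fraction is ≥ 0.95 (inclusive; ≥ 3 replicates per
level required). Concordance is the fraction of paired samples with
identical categorical calls. Linear fits are ordinary least squares with
R² = 1 − SSres/SStot (R² = 0 for constant y); two points are accepted so
the closed-form two-point line is reproduced exactly.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *structure* of the commercial reference
standards: a 228-variant (211 SNV + 17 indel) somatic truth set at
VAF ≥ 5% with decoys each violating exactly one eligibility criterion;
negative-binomial per-base depth around 500X (dispersion parameter 50,
mild overdispersion emulating FFPE coverage variability — Poisson would
understate it); ~800 microsatellite loci with unstable loci shifted by ≥ 2
repeat units against a 0.15/0.70/0.15 three-length background;
100-bp-binned CNV coverage with shared lognormal capture bias (σ = 0.15),
per-sample library-size variation, and six +3-copy oncogenes; the six
named fusion junctions with jittered split reads; and 100,000X plasma
amplicons with binomial alt counts at the planted ctDNA VAF plus a 10⁻⁴
per-read background error.

Replicate detection is emulated by a surrogate caller that requires ≥ 8
supporting reads, chosen so the surrogate reproduces the assay's published
operating point (LOD 5% VAF at the ≥ 95% rule, high sensitivity at
VAF ≥ 5%, partial sensitivity in the 1–5% band) from binomial structure
alone; it is a realistic evidence requirement for FFPE-calibrated callers.

Deliberately **not** modelled: read-level errors and mapping artifacts,
FFPE deamination damage spectra, GC-coverage coupling, UMI chemistry,
tumor heterogeneity/subclonality, and purity. Passing tests on these
fixtures therefore demonstrate the correctness of the decision logic and
its statistical behavior under idealized sampling noise — not the wet-lab
performance of any real assay on clinical material.

### Problem sizes

Test fixtures use desk-scale panels (50–200 kb coding; the TMB worked
example uses a full 1.7 Mb panel where the arithmetic demands it), 10–90
normals for CNV baselines, 100–800 MSI loci, and 10–200 replicates for
stochastic checks — sizes chosen so every statistical assertion retains
clear power while the whole suite remains quick to run.

## Numerical choices and degenerate inputs

- VAF is quantized to 6 decimals on VCF write *and* read so round-trips
  are bit-exact despite VCF Float being 32-bit.
- Modal repeat length and modal breakpoint ties break toward the smaller
  value for determinism; cluster gene labels take the majority vote.
- Chi-squared bin merging is greedy: the column with the smallest expected
  count merges into its neighbor until all expected counts are ≥ 5 or one
  column remains (one column ⇒ stable).
- Uncallable states are explicit everywhere (zero evaluable MSI loci,
  fully masked CNV genes, all-unsuccessful amplicon panels, zero effective
  panel size) and are never reported as negative.
- The clustered-events artifact filter drops every variant in any 10-bp
  window holding more than 2 variants; both parameters are configurable
  (the assay names the filter without parameters).
- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical seeds give byte-identical generator output.

## Known limitations

- The MSI surrogate is not the production tool's trained-baseline mode;
  its locus list is configuration-supplied.
- Fusion detection consumes breakpoint evidence (or SAM with SA tags); it
  does not reconstruct breakpoints from raw reads by k-mer realignment.
- No purity/ploidy model: amplification calls on low-purity samples will
  under-call, and the copy-ratio threshold assumes purity near 1.
- Tumor-only TMB and synonymous-inclusive TMB variants are out of scope;
  so are bootstrap confidence intervals for the validation statistics.
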