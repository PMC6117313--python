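# Methods

## Model and procedure

The pipeline treats a population frequency store as a set of normalized
biallelic sites, each carrying per-ancestry-group allele bookkeeping
(AC, AN, nhomalt) and a site-level PASS/fail quality verdict. A curated
catalogue supplies the variants of interest, each labelled `pathogenic` or
`unknown` by the source database; the pipeline takes those labels as given
and never re-derives them.

Stages:

1. **Normalization and matching.** Variant keys are reduced to their
   minimal left-anchored form: shared trailing bases are trimmed first,
   then shared leading bases (advancing the position), each while both
   alleles retain at least one base. Trimming the suffix before the prefix
   selects the left-most of the fully trimmed representations, so indels
   keep a single left anchor base. Multiallelic store sites are split per
   alternate allele before normalization, with Number=A INFO fields
   apportioned by alt index and AN shared across the split. Matching joins
   on the normalized genomic key when the catalogue carries coordinates,
   else on the exact (gene, cDNA HGVS) string against store annotations;
   a variant whose two join routes disagree is rejected as ambiguous
   rather than silently resolved.
2. **Classification.** MAF folds the alternate-allele frequency to the
   rarer allele, `min(f, 1−f)`, making the function total over AC ≤ AN;
   AN = 0 yields an undefined frequency that never clears a threshold
   (absence of called genotypes is not evidence of commonness). A variant
   is common under the global rule iff the pooled MAF ≥ t and under the
   popmax rule iff the maximum defined per-population MAF ≥ t, both
   inclusive at the boundary. Undefined populations are skipped by popmax;
   ties break by the fixed population-code order. Unmatched variants are
   `not_observed`, deliberately distinct from `rare`.
3. **Prevalence.** Unknown-class and unmatched variants are excluded; in
   genes with recessive inheritance, variants with no observed homozygote
   in any population are excluded (a lone allele is not an affected
   genotype, and compound heterozygosity is invisible in site-level data —
   a documented limitation, not an estimate). Each remaining variant's
   whole-cohort AC is bucketed common/rare per rule; the genotype
   prevalence denominator is `floor(N / Σ rare pathogenic AC)` under the
   assumption that every allele sits in a distinct individual, which can
   only overstate carrier frequency slightly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| threshold t | 0.001 (alt. 0.0001) | MAF cut separating rare from common; 0.001 suits dominant disease with reduced penetrance, 0.0001 is the stringent choice for highly penetrant, genetically heterogeneous disease |
| populations | AFR, AJ, EA, EUR, FIN, LAT, SA, OTH | gnomAD v2 ancestry groups; OTH participates in the popmax scan by default (configurable) |
| filter policy | `pass` | only PASS store sites are matchable; `all` admits failed sites for sensitivity analysis |
| N_individuals | 138,632 | cohort size for the prevalence denominator; always an explicit input, never inferred from AN |
| exome+genome pooling | summed per population | when two stores cover the same cohort their AC/AN/nhomalt are summed per population before MAF |

Rounding policies are part of the reported surface: presence percentages
round half-up to integers, cross-ethnic common fractions to one decimal,
variant densities (store variants per amino acid) half-up to two decimals,
and the prevalence denominator uses floor.

## Synthetic cohorts

The generator emulates the store side of the analysis: ancestry groups of
fixed sizes (defaults proportional to gnomAD v2, totalling 138,632), a
call rate (default 0.95) setting AN = round(2·n·call_rate), allele counts
drawn binomially from assigned true frequencies, and homozygote counts
drawn binomially with probability f² over individuals (Hardy–Weinberg),
capped at floor(AC/2). Background variants draw one true frequency
log-uniformly from [1e-6, 5e-5] — deep enough in the rare regime that a
sampled MAF essentially never crosses 0.001. Planted variants carry
expected verdicts derived from their true frequencies (popmax from the
per-group maximum, global from the size-weighted pool), so recovery is
checkable without reference to the sampler. One global seed spawns a
counter-based substream per variant index, making output byte-identical
under a fixed seed and independent of generation order.

What the generator does *not* emulate: linkage and relatedness, sequencing
error and coverage variation across sites, ancestry misassignment, and
real site-frequency spectra. Passing recovery tests therefore demonstrate
the correctness of the classification and aggregation logic under clean
binomial sampling, not robustness to real-data artefacts.

## Bundled reference tables

The motivating five-gene ARVC analysis ran on external resources (the
ARVC/D Genetic Variants Database catalogue and the gnomAD v2 callset) that
cannot be redistributed or re-downloaded at test time. The package bundles
the published per-gene summary tallies and pathogenic allele-count buckets
instead, and recomputes every derived number — percentages, densities,
totals, rule-comparison counts, prevalence denominators — through the same
code paths that serve arbitrary inputs. One bucket row (PKP2 at t = 0.001)
is typographically ambiguous in its source and is reconstructed from the
per-gene allele-mass conservation identity together with the printed
column totals; it is marked as reconstructed in the source. The published
unknown-common fraction is quoted as 34.2% in prose while the direct
computation from the underlying counts (57 of 152) gives 37.5%; the
pipeline always reports the directly computed fraction. The computed DSC2
density (1374/901 = 1.52) likewise differs in the last digit from the
printed 1.53; the robust PKP2 and DSP densities are the tested values.

## Numerical and design choices

* Threshold comparisons are exact float comparisons on ratios of integers;
  at the printed thresholds (1e-3, 1e-4) and gnomAD-scale AN no tolerance
  is needed, and the inclusive boundary is honoured exactly (AC = 20,
  AN = 20,000 is common at t = 0.001).
* The folded pooled MAF is ≤ the folded popmax MAF whenever the alternate
  allele is the minor allele in every population — the regime this method
  targets (disease alleles, f ≪ 0.5). With some per-population f > 0.5 the
  fold can invert the inequality; property tests generate in the
  minor-alternate regime.
* Duplicate catalogue rows keep the first occurrence with a counted
  warning; out-of-vocabulary classification labels are dropped and
  counted. Both are warnings, never silent.
* The whole-cohort AC of a popmax-common variant is bucketed common in its
  entirety, regardless of which single population triggered the verdict —
  the comparison partitions one fixed allele mass two ways, which is what
  makes the per-gene conservation identity an invariant.
* Recessive-gene retention asks only "nhomalt ≥ 1 in any population";
  modelling compound heterozygotes is out of scope by design.
* Problem sizes in the test suite (cohorts of ≤ 200 planted variants,
  1,000 random mini-datasets for invariant checks) were chosen as the
  smallest sizes at which the binomial tails involved are negligible
  (< 1e-19 for the planted-common recovery), keeping the suite fast
  without weakening the checks.

## Known limitations

* No liftover, no transcript-model projection of cDNA HGVS to genomic
  coordinates: matching relies on provided coordinates or exact string
  annotations.
* Prevalence is cohort-wide; per-ancestry prevalence and penetrance
  modelling are out of scope.
* The confidence-interval-based "filtering allele frequency" approach is
  not implemented; thresholds are applied to point estimates.
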