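"""Genotype-prevalence estimation from rare pathogenic allele counts.

The cohort-wide allele count of every eligible rare pathogenic variant is
summed and turned into a "1 in N" genotype prevalence, assuming each allele
sits in a distinct individual (an upper bound: a few individuals may carry
two).  Eligibility excludes unknown-class variants and, for genes with
recessive inheritance, variants with no observed homozygote in any
population — a single allele of a recessive gene does not produce the
phenotype, and compound heterozygosity cannot be detected from site-level
counts.

The same allele mass is partitioned into common/rare buckets under the
global rule and the popmax rule, at each requested MAF threshold, yielding
side-by-side comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalogue import GeneMeta
from .classify import (
    COMMON,
    ClassifiedVariant,
    validate_threshold,
)

__all__ = [
    "GeneBuckets",
    "PrevalenceReport",
    "eligible_variants",
    "aggregate_counts",
    "genotype_prevalence",
    "rule_comparison",
]

PREVALENCE_ASSUMPTION = (
    "each qualifying allele is assumed to occur in a distinct individual"
)


@dataclass(frozen=True)
class GeneBuckets:
    """Allele counts of one gene partitioned by rule verdict."""

    common_ac_global: int = 0
    rare_ac_global: int = 0
    common_ac_popmax: int = 0
    rare_ac_popmax: int = 0

    def __add__(self, other: "GeneBuckets") -> "GeneBuckets":
        return GeneBuckets(
            self.common_ac_global + other.common_ac_global,
            self.rare_ac_global + other.rare_ac_global,
            self.common_ac_popmax + other.common_ac_popmax,
            self.rare_ac_popmax + other.rare_ac_popmax,
        )

    @property
    def total_ac(self) -> int:
        return self.common_ac_global + self.rare_ac_global


@dataclass
class PrevalenceReport:
    """Per-gene and total allele-count buckets plus the "1 in N" prevalence.

    Invariants (asserted by ``validate``): for every gene the global and
    popmax partitions carry the same allele mass, totals are per-gene sums,
    and the popmax rule never leaves more alleles rare than the global rule.
    """

    threshold: float
    per_gene: dict[str, GeneBuckets]
    n_individuals: int
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (variant label, reason)
    prevalence_denominator: int | None = None
    assumption: str = PREVALENCE_ASSUMPTION

    @property
    def totals(self) -> GeneBuckets:
        return sum(self.per_gene.values(), GeneBuckets())

    def validate(self) -> None:
        for gene, b in self.per_gene.items():
            if b.common_ac_global + b.rare_ac_global != b.common_ac_popmax + b.rare_ac_popmax:
                raise AssertionError(f"allele mass not conserved for {gene}: {b}")
            if b.rare_ac_popmax > b.rare_ac_global:
                raise AssertionError(f"rule monotonicity violated for {gene}: {b}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.per_gene):
            b = self.per_gene[gene]
            rows.append({"gene": gene, "common_ac_global": b.common_ac_global,
                         "rare_ac_global": b.rare_ac_global,
                         "common_ac_popmax": b.common_ac_popmax,
                         "rare_ac_popmax": b.rare_ac_popmax})
        t = self.totals
        rows.append({"gene": "TOTAL", "common_ac_global": t.common_ac_global,
                     "rare_ac_global": t.rare_ac_global,
                     "common_ac_popmax": t.common_ac_popmax,
                     "rare_ac_popmax": t.rare_ac_popmax})
        return pd.DataFrame(rows)

    def summary_line(self) -> str:
        if self.prevalence_denominator is None:
            return f"t={self.threshold:g}: no rare pathogenic alleles; prevalence undefined"
        return (
            f"t={self.threshold:g}: genotype prevalence 1 in {self.prevalence_denominator} "
            f"({self.totals.rare_ac_popmax} rare pathogenic alleles in "
            f"{self.n_individuals} individuals)"
        )


def eligible_variants(
    classified: Sequence[ClassifiedVariant],
    gene_meta: Mapping[str, GeneMeta],
) -> tuple[list[ClassifiedVariant], list[tuple[str, str]]]:
    """Filter to the variants whose alleles count toward prevalence.

    Removes unknown-classification variants, unmatched variants (no allele
    counts to sum), and variants of recessive-inheritance genes with no
    observed homozygote in any population.  Every classified gene must have
    a GeneMeta entry; a missing one is a hard error naming the gene.
    """
    for cv in classified:
        if cv.gene not in gene_meta:
            raise KeyError(f"no gene metadata for gene {cv.gene!r}")
    eligible: list[ClassifiedVariant] = []
    excluded: list[tuple[str, str]] = []
    for cv in classified:
        label = cv.catalogue.label
        if cv.classification != "pathogenic":
            excluded.append((label, "unknown classification"))
            continue
        if not cv.matched:
            excluded.append((label, "not observed in frequency store"))
            continue
        meta = gene_meta[cv.gene]
        if meta.inheritance == "recessive" and cv.max_nhom < 1:
            excluded.append((label, "recessive gene, no homozygotes"))
            continue
        eligible.append(cv)
    return eligible, excluded


def aggregate_counts(
    eligible: Sequence[ClassifiedVariant],
    t: float,
    n_individuals: int = 138_632,
) -> PrevalenceReport:
    """Bucket each eligible variant's pooled allele count by rule verdict at t.

    The whole-cohort AC goes to the common or rare bucket of each rule
    according to that rule's verdict; which population triggered a popmax
    "common" does not restrict the allele count that is bucketed.
    """
    t = validate_threshold(t)
    per_gene: dict[str, GeneBuckets] = {}
    for cv in eligible:
        if not cv.matched:
            raise ValueError(f"unmatched variant {cv.catalogue.label} in eligible list")
        v = cv.reclassified(t)
        ac = v.total_ac
        add = GeneBuckets(
            common_ac_global=ac if v.class_global == COMMON else 0,
            rare_ac_global=0 if v.class_global == COMMON else ac,
            common_ac_popmax=ac if v.class_popmax == COMMON else 0,
            rare_ac_popmax=0 if v.class_popmax == COMMON else ac,
        )
        per_gene[v.gene] = per_gene.get(v.gene, GeneBuckets()) + add
    report = PrevalenceReport(threshold=t, per_gene=per_gene, n_individuals=n_individuals)
    report.validate()
    return report


def genotype_prevalence(total_rare_ac: int, n_individuals: int) -> int | None:
    """Denominator N of the "1 in N" genotype prevalence.

    floor(n_individuals / total_rare_ac), under the distinct-individuals
    assumption.  No rare alleles -> undefined (None).
    """
    if n_individuals <= 0:
        raise ValueError(f"n_individuals must be positive, got {n_individuals}")
    if total_rare_ac < 0:
        raise ValueError(f"total_rare_ac must be non-negative, got {total_rare_ac}")
    if total_rare_ac == 0:
        return None
    return n_individuals // total_rare_ac


def rule_comparison(
    classified: Sequence[ClassifiedVariant],
    gene_meta: Mapping[str, GeneMeta],
    thresholds: Sequence[float],
    n_individuals: int = 138_632,
) -> list[PrevalenceReport]:
    """One validated PrevalenceReport per threshold.

    The prevalence uses the popmax-rule rare allele total (the cross-ethnic
    analysis: an allele common in any single ancestry group is discounted).
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    eligible, excluded = eligible_variants(classified, gene_meta)
    reports = []
    for t in thresholds:
        report = aggregate_counts(eligible, t, n_individuals)
        report.excluded = list(excluded)
        report.prevalence_denominator = genotype_prevalence(
            report.totals.rare_ac_popmax, n_individuals
        )
        reports.append(report)
    return reports
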