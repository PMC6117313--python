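"""Synthetic gnomAD-like cohorts with known ground truth.

The generator emulates the frequency-store side of the analysis: a cohort of
ancestry groups with fixed sizes, per-population allele numbers set by a
call rate, allele counts drawn binomially from assigned true allele
frequencies, homozygote counts drawn under Hardy-Weinberg, PASS filters, and
"planted" variants whose expected rare/common class under each rule is known
from their true frequencies.  Every pipeline stage can then be tested for
recovery of the planted truth without any external download.

Default population sizes are proportional to the gnomAD v2 exome+genome
ancestry groups, scaled to total 138,632 individuals; the exact proportions
are configuration, not contract.

Randomness is counter-based: one global seed spawns an independent
substream per variant index, so output is reproducible and independent of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogue import CatalogueVariant, GeneMeta, GenomicKey, write_catalogue
from .classify import ClassifiedVariant, validate_threshold
from .frequencies import (
    DEFAULT_POPULATIONS,
    FrequencyRecord,
    PopCounts,
    write_frequency_table,
    write_frequency_vcf,
)

__all__ = [
    "DEFAULT_POPULATION_SIZES",
    "PlantedVariant",
    "CohortSpec",
    "SyntheticData",
    "generate_store",
    "recovery_report",
    "default_demo_spec",
    "write_bundle",
]

#: gnomAD-v2-like ancestry group sizes scaled to a 138,632-individual cohort.
DEFAULT_POPULATION_SIZES: dict[str, int] = {
    "AFR": 12_487,
    "AJ": 5_185,
    "EA": 9_977,
    "EUR": 61_741,
    "FIN": 12_897,
    "LAT": 17_720,
    "SA": 15_391,
    "OTH": 3_234,
}

#: Background (store-only) variants draw a single true frequency for all
#: populations log-uniformly from this range — deep in the rare regime.
BACKGROUND_AF_RANGE = (1e-6, 5e-5)


@dataclass(frozen=True)
class PlantedVariant:
    """A variant with assigned true allele frequencies per population.

    ``expected_class_popmax`` / ``expected_class_global`` at ``threshold``
    are derived from the true frequencies (not sampled counts): popmax is
    common iff some population's true frequency reaches the threshold;
    global is common iff the population-size-weighted pooled frequency does.
    """

    gene: str
    classification: str  # "pathogenic" | "unknown"
    true_af: Mapping[str, float]
    threshold: float = 0.001
    predictions: Mapping[str, str] = field(default_factory=dict)

    def expected_class_popmax(self) -> str:
        return "common" if max(self.true_af.values(), default=0.0) >= self.threshold else "rare"

    def expected_class_global(self, pop_sizes: Mapping[str, int]) -> str:
        num = sum(self.true_af.get(p, 0.0) * n for p, n in pop_sizes.items())
        den = sum(pop_sizes.values())
        return "common" if den and num / den >= self.threshold else "rare"


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort."""

    populations: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_SIZES)
    )
    call_rate: float = 0.95
    seed: int = 0
    n_background_variants: int = 100
    planted: list[PlantedVariant] = field(default_factory=list)
    #: catalogue entries deliberately absent from the store (unmatched truth)
    n_catalogue_only: int = 0

    def validate(self) -> None:
        if len(self.populations) != len(set(self.populations)):
            raise ValueError("population labels must be unique")
        if not self.populations:
            raise ValueError("at least one population required")
        for p, n in self.populations.items():
            if n <= 0:
                raise ValueError(f"population {p} size must be positive, got {n}")
        if not (0.0 < self.call_rate <= 1.0):
            raise ValueError(f"call_rate must lie in (0, 1], got {self.call_rate}")
        if self.n_background_variants < 0 or self.n_catalogue_only < 0:
            raise ValueError("variant counts must be non-negative")
        for pv in self.planted:
            if pv.classification not in ("pathogenic", "unknown"):
                raise ValueError(f"bad classification {pv.classification!r}")
            validate_threshold(pv.threshold)
            for p, f in pv.true_af.items():
                if p not in self.populations:
                    raise ValueError(f"planted frequency for unknown population {p!r}")
                if not (0.0 <= f <= 1.0):
                    raise ValueError(f"true frequency out of [0,1]: {f}")

    @property
    def n_individuals(self) -> int:
        return sum(self.populations.values())


@dataclass
class SyntheticData:
    """Generated store + catalogue + ground truth."""

    spec: CohortSpec
    records: list[FrequencyRecord]
    catalogue: list[CatalogueVariant]
    truth: pd.DataFrame  # one row per planted variant
    gene_meta: dict[str, GeneMeta]


def _variant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sample_counts(
    rng: np.random.Generator,
    true_af: Mapping[str, float],
    populations: Mapping[str, int],
    call_rate: float,
) -> dict[str, PopCounts]:
    per_pop: dict[str, PopCounts] = {}
    for pop, n_ind in populations.items():
        f = float(true_af.get(pop, 0.0))
        an = int(round(2 * n_ind * call_rate))
        ac = int(rng.binomial(an, f)) if f > 0 else 0
        nhom = int(rng.binomial(n_ind, f * f)) if f > 0 else 0
        nhom = min(nhom, ac // 2)
        per_pop[pop] = PopCounts(ac=ac, an=an, nhom=nhom)
    return per_pop


def _gene_layout(genes: Sequence[str]) -> dict[str, str]:
    return {g: f"chr{i + 1}" for i, g in enumerate(genes)}


def generate_store(spec: CohortSpec) -> SyntheticData:
    """Generate the synthetic store, catalogue and truth table.

    Planted variants come first (store + catalogue), then background
    variants (store only, true frequency log-uniform over the background
    range), then catalogue-only variants (catalogue, absent from the
    store).  Byte-identical output under a fixed seed.
    """
    spec.validate()
    genes = sorted({pv.gene for pv in spec.planted}) or ["SYNGENE1"]
    contig_of = _gene_layout(genes)
    pops = list(spec.populations)
    per_gene_counter: dict[str, int] = {g: 0 for g in genes}

    def next_position(gene: str) -> int:
        per_gene_counter[gene] += 1
        return 1000 + 10 * per_gene_counter[gene]

    records: list[FrequencyRecord] = []
    catalogue: list[CatalogueVariant] = []
    truth_rows: list[dict] = []
    index = 0

    for pv in spec.planted:
        rng = _variant_rng(spec.seed, index)
        contig = contig_of[pv.gene]
        pos = next_position(pv.gene)
        cdna = f"c.{pos}A>G"
        per_pop = _sample_counts(rng, pv.true_af, spec.populations, spec.call_rate)
        records.append(FrequencyRecord(
            contig, pos, "A", "G", filter_status="pass",
            per_population=per_pop, gene=pv.gene, cdna_hgvs=cdna,
        ))
        catalogue.append(CatalogueVariant(
            gene=pv.gene, transcript=f"SYNT_{pv.gene}", cdna_hgvs=cdna,
            classification=pv.classification,
            genomic_key=GenomicKey(contig, pos, "A", "G", build="syn1"),
            predictions=dict(pv.predictions),
        ))
        truth_rows.append({
            "gene": pv.gene, "cdna_hgvs": cdna,
            "contig": contig, "position": pos, "ref": "A", "alt": "G",
            "classification": pv.classification,
            "threshold": pv.threshold,
            "expected_class_popmax": pv.expected_class_popmax(),
            "expected_class_global": pv.expected_class_global(spec.populations),
        })
        index += 1

    lo, hi = BACKGROUND_AF_RANGE
    for i in range(spec.n_background_variants):
        rng = _variant_rng(spec.seed, index)
        gene = genes[i % len(genes)]
        contig = contig_of[gene]
        pos = next_position(gene)
        f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        per_pop = _sample_counts(rng, {p: f for p in pops}, spec.populations, spec.call_rate)
        records.append(FrequencyRecord(
            contig, pos, "A", "G", filter_status="pass",
            per_population=per_pop, gene=gene, cdna_hgvs=None,
        ))
        index += 1

    for i in range(spec.n_catalogue_only):
        gene = genes[i % len(genes)]
        contig = contig_of[gene]
        pos = next_position(gene)
        cdna = f"c.{pos}A>G"
        catalogue.append(CatalogueVariant(
            gene=gene, transcript=f"SYNT_{gene}", cdna_hgvs=cdna,
            classification="pathogenic" if i % 2 == 0 else "unknown",
            genomic_key=GenomicKey(contig, pos, "A", "G", build="syn1"),
        ))
        index += 1

    gene_meta = {
        g: GeneMeta(
            gene=g, transcript=f"SYNT_{g}", amino_acid_count=500,
            inheritance="dominant",
            interval=(contig_of[g], 1, 1000 + 10 * (per_gene_counter[g] + 1)),
        )
        for g in genes
    }
    truth = pd.DataFrame(truth_rows, columns=[
        "gene", "cdna_hgvs", "contig", "position", "ref", "alt",
        "classification", "threshold", "expected_class_popmax", "expected_class_global",
    ])
    return SyntheticData(spec=spec, records=records, catalogue=catalogue,
                         truth=truth, gene_meta=gene_meta)


def recovery_report(
    truth: pd.DataFrame, classified: Sequence[ClassifiedVariant]
) -> dict[str, pd.DataFrame | float]:
    """Cross-tabulate expected vs observed classes for each rule.

    Truth and classified are joined on (gene, cdna_hgvs); a truth row with
    no classified counterpart (or vice versa for catalogue-backed variants)
    is a hard error.  Returns confusion tables per rule and the overall
    discordance rate (fraction of (variant, rule) verdicts that differ from
    expectation; "not_observed" counts as discordant).
    """
    by_name = {(cv.gene, cv.catalogue.cdna_hgvs): cv for cv in classified}
    if truth.empty:
        empty = pd.DataFrame()
        return {"popmax": empty, "global": empty, "discordance_rate": 0.0}
    pairs = []
    for _, row in truth.iterrows():
        key = (row["gene"], row["cdna_hgvs"])
        if key not in by_name:
            raise KeyError(f"truth variant {key} missing from classified output")
        cv = by_name[key]
        pairs.append({
            "expected_popmax": row["expected_class_popmax"],
            "observed_popmax": cv.class_popmax,
            "expected_global": row["expected_class_global"],
            "observed_global": cv.class_global,
        })
    df = pd.DataFrame(pairs)
    confusion_popmax = pd.crosstab(df["expected_popmax"], df["observed_popmax"])
    confusion_global = pd.crosstab(df["expected_global"], df["observed_global"])
    n_discord = int((df["expected_popmax"] != df["observed_popmax"]).sum()
                    + (df["expected_global"] != df["observed_global"]).sum())
    return {
        "popmax": confusion_popmax,
        "global": confusion_global,
        "discordance_rate": n_discord / (2 * len(df)),
    }


def default_demo_spec(seed: int = 0) -> CohortSpec:
    """The demonstration cohort: ancestry-specific planted commons.

    Mirrors the qualitative headline of the motivating analysis — variants
    common in one minority ancestry group but rare in the pooled cohort are
    caught by the popmax rule and missed by the global rule.  Each
    population-specific common has a true frequency of 0.005 in its target
    group (binomial mean far above the 0.001 cut) and a background-level
    frequency elsewhere.
    """
    rare_bg = {p: 1e-5 for p in DEFAULT_POPULATIONS}
    planted = [
        # ancestry-specific commons: popmax common, globally rare
        PlantedVariant("SYNA", "pathogenic", {**rare_bg, "FIN": 0.005}),
        PlantedVariant("SYNA", "pathogenic", {**rare_bg, "EA": 0.005}),
        PlantedVariant("SYNB", "pathogenic", {**rare_bg, "AFR": 0.005},
                       predictions={"polyphen": "benign", "sift": "tolerated"}),
        # common everywhere: both rules agree
        PlantedVariant("SYNB", "pathogenic", {p: 0.005 for p in DEFAULT_POPULATIONS}),
        # genuinely rare pathogenic
        PlantedVariant("SYNA", "pathogenic", {p: 2e-5 for p in DEFAULT_POPULATIONS}),
        PlantedVariant("SYNB", "pathogenic", {p: 2e-5 for p in DEFAULT_POPULATIONS}),
        # unknown-class variants, one per verdict
        PlantedVariant("SYNA", "unknown", {**rare_bg, "SA": 0.005}),
        PlantedVariant("SYNB", "unknown", {p: 2e-5 for p in DEFAULT_POPULATIONS}),
    ]
    return CohortSpec(seed=seed, n_background_variants=100,
                      planted=planted, n_catalogue_only=4)


def write_bundle(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Write store VCF + TSV, catalogue TSV, truth TSV and gene meta TSV."""
    from .catalogue import write_gene_meta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "store_vcf": out / "store.vcf",
        "store_tsv": out / "store.tsv",
        "catalogue": out / "catalogue.tsv",
        "truth": out / "truth.tsv",
        "gene_meta": out / "gene_meta.tsv",
    }
    write_frequency_vcf(data.records, paths["store_vcf"], pops=list(data.spec.populations))
    write_frequency_table(data.records, paths["store_tsv"])
    write_catalogue(data.catalogue, paths["catalogue"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_gene_meta(data.gene_meta, paths["gene_meta"])
    return paths
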