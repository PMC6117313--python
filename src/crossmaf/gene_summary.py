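"""Per-gene summary tables and reclassification-review flags.

Summaries report, per gene: how many catalogued pathogenic/unknown variants
exist, how many were found in the population store (with integer
percentages), the store's total variant yield in the gene, and the variant
density per amino acid of the encoded protein.

Review flagging implements the curation recommendation that a variant
previously called pathogenic but common (MAF >= t) in at least one ancestry
group be re-examined; when every available in-silico prediction label
(PolyPhen-2-style, SIFT-style) maps to benign/tolerated, the flag carries a
"consensus benign" annotation.  Prediction labels are consumed as input
strings — this package never runs the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalogue import CatalogueVariant, GeneMeta
from .classify import ClassifiedVariant
from .frequencies import FrequencyRecord

__all__ = [
    "BENIGN_LABELS",
    "ReviewFlag",
    "variant_density",
    "percent_int",
    "presence_summary",
    "count_store_variants",
    "review_flags",
    "consensus_benign",
]

#: Case-insensitive prediction labels counted as benign evidence.
#: PolyPhen-2 reports benign / possibly damaging / probably damaging;
#: SIFT reports tolerated / deleterious.  ClinVar strings pass through
#: unmapped and never contribute to the consensus.
BENIGN_LABELS = frozenset({"benign", "tolerated"})
DAMAGING_LABELS = frozenset({
    "probably damaging", "possibly damaging", "damaging", "deleterious",
})
UNMAPPED_TOOLS = frozenset({"clinvar"})


def variant_density(n_store_variants: int, amino_acid_count: int) -> float:
    """Store variants per amino acid, rounded half-up to 2 decimals."""
    if amino_acid_count <= 0:
        raise ValueError(f"amino_acid_count must be positive, got {amino_acid_count}")
    if n_store_variants < 0:
        raise ValueError("n_store_variants must be non-negative")
    ratio = Decimal(n_store_variants) / Decimal(amino_acid_count)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def percent_int(numerator: int, denominator: int) -> int | None:
    """Integer percentage, half-up; None when the denominator is zero."""
    if denominator == 0:
        return None
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def count_store_variants(
    records: Iterable[FrequencyRecord],
    gene_meta: Mapping[str, GeneMeta],
) -> dict[str, int]:
    """Count store records per gene.

    A record is assigned by its gene annotation when present, else by
    overlap with a gene's configured interval.  All consequence classes
    count — the yield deliberately includes UTR, intronic and synonymous
    sites.
    """
    totals = {g: 0 for g in gene_meta}
    for rec in records:
        if rec.gene is not None:
            if rec.gene in totals:
                totals[rec.gene] += 1
            continue
        for g, meta in gene_meta.items():
            if meta.interval is None:
                continue
            contig, start, end = meta.interval
            if rec.contig == contig and start <= rec.position <= end:
                totals[g] += 1
                break
    return totals


def presence_summary(
    catalogue: Sequence[CatalogueVariant],
    classified: Sequence[ClassifiedVariant],
    store_gene_totals: Mapping[str, int],
    gene_meta: Mapping[str, GeneMeta],
) -> pd.DataFrame:
    """One summary row per gene plus a TOTAL row.

    Columns: amino_acid_count, catalogue counts by class, store variant
    total, variants_per_aa (2 decimals), and found counts with integer
    percentages.  Genes with an empty catalogue class render a blank
    percentage.
    """
    genes = sorted({v.gene for v in catalogue})
    for g in genes:
        if g not in gene_meta:
            raise KeyError(f"no gene metadata for gene {g!r}")
        if g not in store_gene_totals:
            raise KeyError(f"no store variant total for gene {g!r}")
    found = {
        (cv.gene, cv.catalogue.cdna_hgvs) for cv in classified if cv.matched
    }
    rows = []
    for g in genes:
        path = [v for v in catalogue if v.gene == g and v.classification == "pathogenic"]
        unk = [v for v in catalogue if v.gene == g and v.classification == "unknown"]
        n_path_found = sum(1 for v in path if (g, v.cdna_hgvs) in found)
        n_unk_found = sum(1 for v in unk if (g, v.cdna_hgvs) in found)
        rows.append({
            "gene": g,
            "transcript": gene_meta[g].transcript,
            "amino_acid_count": gene_meta[g].amino_acid_count,
            "n_pathogenic_catalogue": len(path),
            "n_unknown_catalogue": len(unk),
            "n_store_variants": store_gene_totals[g],
            "variants_per_aa": variant_density(
                store_gene_totals[g], gene_meta[g].amino_acid_count
            ),
            "n_pathogenic_found": n_path_found,
            "pct_pathogenic_found": percent_int(n_path_found, len(path)),
            "n_unknown_found": n_unk_found,
            "pct_unknown_found": percent_int(n_unk_found, len(unk)),
        })
    tot_path = sum(r["n_pathogenic_catalogue"] for r in rows)
    tot_unk = sum(r["n_unknown_catalogue"] for r in rows)
    tot_store = sum(r["n_store_variants"] for r in rows)
    tot_path_found = sum(r["n_pathogenic_found"] for r in rows)
    tot_unk_found = sum(r["n_unknown_found"] for r in rows)
    rows.append({
        "gene": "TOTAL", "transcript": "", "amino_acid_count": None,
        "n_pathogenic_catalogue": tot_path,
        "n_unknown_catalogue": tot_unk,
        "n_store_variants": tot_store,
        "variants_per_aa": None,
        "n_pathogenic_found": tot_path_found,
        "pct_pathogenic_found": percent_int(tot_path_found, tot_path),
        "n_unknown_found": tot_unk_found,
        "pct_unknown_found": percent_int(tot_unk_found, tot_unk),
    })
    return pd.DataFrame(rows)


def _map_label(tool: str, label: str) -> str | None:
    """benign / damaging / None (unmapped tool or unrecognised label)."""
    if tool.lower() in UNMAPPED_TOOLS:
        return None
    norm = label.strip().lower()
    if norm in BENIGN_LABELS:
        return "benign"
    if norm in DAMAGING_LABELS:
        return "damaging"
    return None


def consensus_benign(predictions: Mapping[str, str]) -> bool:
    """True when at least one label maps and every mapped label is benign."""
    mapped = [
        m for tool, label in predictions.items()
        if (m := _map_label(tool, label)) is not None
    ]
    return bool(mapped) and all(m == "benign" for m in mapped)


@dataclass(frozen=True)
class ReviewFlag:
    variant: ClassifiedVariant
    reasons: tuple[str, ...]

    @property
    def consensus_benign(self) -> bool:
        return "consensus benign predictions" in self.reasons


def review_flags(classified: Sequence[ClassifiedVariant]) -> list[ReviewFlag]:
    """Flag pathogenic variants that are common in at least one population.

    The frequency criterion alone triggers the flag; an all-benign
    prediction consensus only annotates it.  Removing prediction labels can
    therefore never remove a flag.
    """
    flags = []
    for cv in classified:
        if cv.four_way != "pathogenic_common":
            continue
        reasons = [
            "previously pathogenic, common in at least one population"
            + (f" (popmax {cv.popmax_population})" if cv.popmax_population else "")
        ]
        if consensus_benign(cv.catalogue.predictions):
            reasons.append("consensus benign predictions")
        flags.append(ReviewFlag(variant=cv, reasons=tuple(reasons)))
    return flags


def write_review_flags(flags: Sequence[ReviewFlag], path) -> None:
    rows = []
    for fl in flags:
        var = fl.variant.catalogue
        rows.append({
            "gene": var.gene,
            "cdna_hgvs": var.cdna_hgvs,
            "protein_hgvs": var.protein_hgvs or "",
            "popmax_population": fl.variant.popmax_population or "",
            "reasons": "; ".join(fl.reasons),
            "labels": "; ".join(f"{t}={v}" for t, v in sorted(var.predictions.items())),
        })
    pd.DataFrame(
        rows,
        columns=["gene", "cdna_hgvs", "protein_hgvs", "popmax_population", "reasons", "labels"],
    ).to_csv(path, sep="\t", index=False)
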